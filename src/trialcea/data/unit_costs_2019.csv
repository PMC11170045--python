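item,category,unit,mean_usd,public_usd,private_usd,source
sbs_intervention,intervention,usage,26.00,,,program budget estimate (see costing module)
euc_psychoeducation,intervention,online message,0.01,,,program budget estimate; ignored in analyses
gp,primary_care,contact,23.66,7.32,40.00,general practitioners
nurse,primary_care,contact,1.83,,,Ministry of Public Health tariff
social_worker,primary_care,contact,2.59,,,Ministry of Public Health tariff
psychiatrist,outpatient,consult,56.06,24.62,87.50,Ministry of Public Health tariff
neurologist,outpatient,consult,37.33,9.66,65.00,Ministry of Public Health tariff
psychologist,outpatient,session,25.37,13.23,37.50,Ministry of Public Health tariff
psych_ward_day,inpatient,day,325.00,150.00,500.00,hospital tariff
mental_hospital_day,inpatient,day,150.00,,150.00,hospital tariff (private only)
ambulance,emergency,transport,99.00,,,Red Cross
er_visit,emergency,visit,48.75,25.00,72.50,hospital tariff
antidepressant_ddd,medication,DDD,0.63,,,mean DDD price of frequently prescribed antidepressants (range 0.41-0.90)
anxiolytic_ddd,medication,DDD,0.36,,,mean DDD price of frequently prescribed anxiolytics (range 0.23-0.55)
hypnotic_ddd,medication,DDD,0.39,,,mean DDD price of frequently prescribed hypnotics (range 0.23-0.55)
paid_workday,productivity,workday,32.09,16.66,47.51,labour-market assessment indexed to 2019; Syrian-Lebanese wage range
unpaid_workday,productivity,workday,7.82,,,opportunity cost: per diem salary of domestic help in 2019
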