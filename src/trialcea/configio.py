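"""Read generator / evaluation configurations from YAML or JSON files.

A config file holds a subset of fields; anything omitted falls back to
the calibrated defaults. Example:

.. code-block:: yaml

    generator:
      n_per_arm: [614, 635]
      seed: 2019
      dropout:
        t1_targets: {SbS: 0.642, EUC: 0.515}
        t2_targets: {SbS: 0.681, EUC: 0.583}
    evaluation:
      perspective: societal
      outcome: response
      imputation: regression
      B: 2500
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from . import pipeline
from .errors import ConfigurationError
from .synthetic_trial import (
    DiscreteTruncatedScoreSpec,
    DropoutSpec,
    GeneratorConfig,
    HealthcareCostSpec,
    PhqTrajectorySpec,
    ProductivitySpec,
    TruncatedNormalSpec,
    calibrated_config,
)

_SPEC_TYPES = {
    "baseline_phq": DiscreteTruncatedScoreSpec,
    "baseline_whodas": TruncatedNormalSpec,
    "baseline_who5": TruncatedNormalSpec,
    "age": TruncatedNormalSpec,
    "trajectory": PhqTrajectorySpec,
    "cost_components": HealthcareCostSpec,
    "productivity": ProductivitySpec,
    "dropout": DropoutSpec,
}


def _load(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _merge_spec(default, cls, overrides: dict):
    """Rebuild a nested spec dataclass with field-level overrides."""
    if not isinstance(overrides, dict):
        raise ConfigurationError(f"{cls.__name__} section must be a mapping")
    base = dataclasses.asdict(default) if default is not None else {}
    base.update(overrides)
    try:
        return cls(**base)
    except TypeError as exc:
        raise ConfigurationError(f"{cls.__name__}: {exc}") from None


def generator_config_from_file(path) -> GeneratorConfig:
    """GeneratorConfig from a YAML/JSON file, defaulting to the calibrated one."""
    raw = _load(path) or {}
    section = raw.get("generator", raw)
    base = calibrated_config(int(section.get("seed", 2019)))
    kwargs = {}
    for key, value in section.items():
        if key in _SPEC_TYPES:
            kwargs[key] = _merge_spec(
                getattr(base, key), _SPEC_TYPES[key], value
            )
        elif key == "n_per_arm":
            kwargs[key] = tuple(value)
        elif hasattr(base, key):
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown generator config field {key!r}")
    return base.replace(**kwargs)


def eval_config_from_file(path, source=None) -> pipeline.EvalConfig:
    """EvalConfig from a YAML/JSON file.

    ``source`` (a dataset, generator config or CSV path) overrides the
    file's ``source`` entry; if neither is given the file must name one,
    or include a ``generator`` section to simulate from.
    """
    raw = _load(path) or {}
    section = dict(raw.get("evaluation", {}))
    if source is None:
        if "source" in section:
            source = section.pop("source")
        elif "generator" in raw:
            source = generator_config_from_file(path)
        else:
            raise ConfigurationError(
                "no data source: pass one or add 'source'/'generator' to the file"
            )
    section.pop("source", None)
    valid = {f.name for f in dataclasses.fields(pipeline.EvalConfig)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"unknown evaluation config fields {sorted(unknown)}")
    return pipeline.EvalConfig(source=source, **section)
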