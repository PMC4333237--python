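"""Configuration loading: parameters and study designs from YAML.

The configuration mirrors the module types: a ``parameters`` section with
one entry per population parameter (value, unit, fixed/estimated status)
and an optional ``design`` section for the study generator.  ``ka`` is a
required key — the absorption rate constant has no published value, so it
must be an explicit choice of the analyst.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .design import StudyDesignSpec
from .errors import ConfigurationError
from .model import PopulationParameters
from .simulate import DosingRegimen

__all__ = ["load_config", "params_from_config", "design_from_config",
           "reference_config_path"]


def reference_config_path() -> str:
    """Path of the packaged reference configuration (published estimates)."""
    return str(resources.files("pulmopk").joinpath("data/reference_config.yaml"))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"configuration {path} is not a mapping")
    return cfg


def params_from_config(cfg: dict) -> PopulationParameters:
    """Build :class:`PopulationParameters` from a configuration mapping."""
    if "parameters" not in cfg:
        raise ConfigurationError("configuration lacks a 'parameters' section")
    section = cfg["parameters"]
    values: dict[str, float] = {}
    estimated: list[str] = []
    for name, entry in section.items():
        if isinstance(entry, dict):
            values[name] = entry["value"]
            if not entry.get("fixed", True):
                estimated.append(name)
        else:
            values[name] = entry
    if "ka" not in values:
        raise ConfigurationError(
            "required configuration key 'ka' (absorption rate constant, 1/h) "
            "is missing: it has no published value and must be set explicitly")
    if "n_transit" in values:
        values["n_transit"] = int(values["n_transit"])
    return PopulationParameters(
        **values,
        scaling_mode=cfg.get("scaling_mode", "ffm"),
        estimated=tuple(estimated),
    )


def design_from_config(cfg: dict) -> StudyDesignSpec:
    """Build a :class:`StudyDesignSpec` from the ``design`` section;
    omitted keys fall back to the emulated-study defaults."""
    d = dict(cfg.get("design", {}))
    kwargs = {}
    if "regimen" in d:
        kwargs["regimen"] = DosingRegimen(**d.pop("regimen"))
    for key in ("n_subjects", "time_jitter", "seed"):
        if key in d:
            kwargs[key] = d.pop(key)
    for key in ("plasma_times", "bal_times"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    if "target_counts" in d:
        tc = d.pop("target_counts")
        kwargs["target_counts"] = dict(tc) if tc is not None else None
    if "groups" in d:
        kwargs["groups"] = tuple(tuple(g) for g in d.pop("groups"))
    if d:
        raise ConfigurationError(f"unknown design keys: {sorted(d)}")
    return StudyDesignSpec(**kwargs)
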