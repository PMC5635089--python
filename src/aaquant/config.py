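"""YAML run configuration.

One document drives the whole pipeline; every section is optional and
defaults to the package defaults::

    cohort:
      cf:      {base_AoutA: 1.05, per_generation_slope_AoutA: 0.03, ...}
      control: {base_AoutA: 1.0, ...}
    measure:    {n_rays: 64, position: 0.5, ...}
    thresholds: {be_AoutA_cut: 1.11, ...}
    analyze:    {use_peripheral_cuts: false, n_boot: 500}

Runs echo the resolved configuration (plus the seed) into their output
directory so any result is reproducible from its own metadata.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from aaquant.cross_section import MeasureConfig
from aaquant.phantom import CohortParams, cf_params, control_params
from aaquant.quantify import Thresholds


class ConfigError(ValueError):
    """Unknown or invalid configuration key (message carries the key path)."""


def _build(cls, section: Dict[str, Any], path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: Optional[str] = None) -> Dict[str, Any]:
    doc: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    return doc


def cohort_params_from(doc: Dict[str, Any]) -> Dict[str, CohortParams]:
    section = doc.get("cohort", {})
    cf_over = dict(section.get("cf", {}))
    ctrl_over = dict(section.get("control", {}))
    return {
        "CF": _build(CohortParams, {**dataclasses.asdict(cf_params()), **cf_over},
                     "cohort.cf"),
        "control": _build(
            CohortParams,
            {**dataclasses.asdict(control_params()), **ctrl_over},
            "cohort.control"),
    }


def measure_config_from(doc: Dict[str, Any]) -> MeasureConfig:
    section = dict(doc.get("measure", {}))
    if "artery_area_bounds" in section:
        section["artery_area_bounds"] = tuple(section["artery_area_bounds"])
    return _build(MeasureConfig, section, "measure")


def thresholds_from(doc: Dict[str, Any]) -> Thresholds:
    return _build(Thresholds, dict(doc.get("thresholds", {})), "thresholds")


def echo_config(doc: Dict[str, Any], out_dir, seed: Optional[int] = None,
                name: str = "config_used.yaml") -> None:
    out = dict(doc)
    if seed is not None:
        out["seed"] = seed
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(out_dir) / name, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
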