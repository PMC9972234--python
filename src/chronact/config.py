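"""Single-YAML configuration with per-module sections.

Layout::

    simulate: {... SimulationConfig fields ...}
    sel:      {... SelConfig fields ...}
    prl:      {... PrlConfig fields ...}

Missing sections or fields fall back to defaults; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Tuple, Union

import yaml

from chronact.prl_pipeline import PrlConfig
from chronact.sel_pipeline import SelConfig
from chronact.synthetic_cohort import SimulationConfig

ConfigTriple = Tuple[SimulationConfig, SelConfig, PrlConfig]


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    if cls is SimulationConfig:
        return SimulationConfig.from_dict(section)
    return cls(**section)


def load_config(path: Union[str, Path, None]) -> ConfigTriple:
    """Load the three module configs from one YAML file (or all defaults)."""
    if path is None:
        return SimulationConfig(), SelConfig(), PrlConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return (
        _build(SimulationConfig, doc.get("simulate", {}), "simulate"),
        _build(SelConfig, doc.get("sel", {}), "sel"),
        _build(PrlConfig, doc.get("prl", {}), "prl"),
    )


def dump_defaults() -> str:
    """YAML text of every default, for ``chronact config --dump``."""
    doc = {
        "simulate": SimulationConfig().to_dict(),
        "sel": dataclasses.asdict(SelConfig()),
        "prl": dataclasses.asdict(PrlConfig()),
    }
    return yaml.safe_dump(doc, sort_keys=True)
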