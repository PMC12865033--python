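"""Structured (YAML) configuration files for the pipeline.

A config file mirrors the dataclass field names, e.g.::

    population:
      n: 5000
      seed: 3
      ceiling_share: 0.7
    missingness:
      mechanisms:
        inc_hh: [mar, 0.22, [sph], [0.8]]
        gali: [mcar, 0.03]
    split:
      ratios: [0.6, 0.2, 0.2]
      strata: [sex, age_group]
      seed: 5
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .synth import MissingnessSpec, PopulationConfig, SplitSpec

__all__ = ["load_config", "population_config", "missingness_spec", "split_spec"]


def load_config(path: "str | Path") -> dict:
    """Parse a YAML config file into a plain dict (empty file -> {})."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def population_config(config: dict) -> PopulationConfig:
    section = dict(config.get("population", {}))
    if "category_distributions" in section:
        section["category_distributions"] = {
            k: tuple(v) for k, v in section["category_distributions"].items()
        }
    return PopulationConfig(**section)


def missingness_spec(config: dict) -> MissingnessSpec:
    section = dict(config.get("missingness", {}))
    mechanisms = {
        col: tuple(
            tuple(part) if isinstance(part, list) else part for part in mech
        )
        for col, mech in section.get("mechanisms", {}).items()
    }
    kwargs = {k: v for k, v in section.items() if k != "mechanisms"}
    return MissingnessSpec(mechanisms=mechanisms, **kwargs)


def split_spec(config: dict) -> SplitSpec:
    section = dict(config.get("split", {}))
    for key in ("ratios", "strata"):
        if key in section:
            section[key] = tuple(section[key])
    return SplitSpec(**section)
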