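"""Run configuration: validated, serializable, reproducible.

A :class:`RunConfig` captures everything needed to reproduce a simulation
run: the scenario family (or reduced grid axes), master seed, cohort size,
replicate count, intercept, and the convention for the two-covariate base
model.  Configs round-trip through JSON or YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .datagen import FAMILIES

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    family: str
    seed: int = 0
    n_subjects: int = 1000
    n_replicates: int = 1000
    intercept: float = -1.0
    two_covariate_rule: str = "half_or"
    out: Optional[str] = None
    log_level: str = "INFO"
    # optional reduced grid axes (None -> full factorial axis)
    or_c_values: Optional[list[float]] = None
    sigma_c_values: Optional[list[float]] = None
    or_rf_values: Optional[list[float]] = None
    p_binary_values: Optional[list[float]] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"config field 'family': unknown family {self.family!r}; "
                f"known: {sorted(FAMILIES)}"
            )
        if self.n_subjects < 2:
            raise ValueError("config field 'n_subjects': must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("config field 'n_replicates': must be >= 1")
        if self.two_covariate_rule not in ("half_or", "half_beta"):
            raise ValueError(
                "config field 'two_covariate_rule': must be 'half_or' or 'half_beta'"
            )
        for name in ("or_c_values", "sigma_c_values", "or_rf_values"):
            vals = getattr(self, name)
            if vals is not None and any(v <= 0 for v in vals):
                raise ValueError(f"config field {name!r}: values must be > 0")
        if self.p_binary_values is not None and any(
            not 0 < p < 1 for p in self.p_binary_values
        ):
            raise ValueError("config field 'p_binary_values': values must be in (0, 1)")

    def grid_kwargs(self) -> dict:
        """Axis overrides for :func:`markergain.datagen.factorial_grid`."""
        kw: dict = {
            "intercept": self.intercept,
            "two_covariate_rule": self.two_covariate_rule,
        }
        for cfg_name, grid_name in (
            ("or_c_values", "or_c_values"),
            ("sigma_c_values", "sigma_c_values"),
            ("or_rf_values", "or_rf_values"),
            ("p_binary_values", "p_binary_values"),
        ):
            vals = getattr(self, cfg_name)
            if vals is not None:
                kw[grid_name] = vals
        return kw

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Unknown keys and out-of-range values raise a ``ValueError`` naming the
    offending field; omitted fields take the defaults (1000 subjects, 1000
    replicates, intercept -1).
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    """Persist a config as JSON (loadable by :func:`load_config`)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
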