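"""Experiment configuration: TOML parsing, validation and named presets.

A configuration has sections [medium], [bubbles], [boundary], [source],
[mesh], [solver] and [output]; all physical quantities are SI and all
frequencies angular (rad/s).  Unknown keys are rejected with the offending
key path.  The defaults reproduce the reference simulation setup: the
ultrasound-contrast parameter set, a disk of radius 0.2 m, mesh size 0.003 m,
monopole source with r_delta = 0.004 m and a = 1e5 driven at the bubble
resonance, ten harmonics, complex-linearized cascade.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .cascade import SolverConfig, VARIANTS
from .fem import SourceSpec
from .physics import PrimitiveParams

__all__ = ["ExperimentConfig", "load_config", "fixture_presets", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "medium": {
        "c": 1500.0,
        "b": 1.0e-3,
        "rho0": 1000.0,
        "beta_a": 3.5,
    },
    "bubbles": {
        "R0": 2.0e-6,
        "n0": 1.0e12,  # per m^3
        "P0": 100.0,
        "kappa": 1.4,
        "nu": 8.9e-6,
    },
    "boundary": {
        "beta": 1.0 / 1500.0,
        "gamma": 1.0,
    },
    "source": {
        "a": 1.0e5,
        "r_delta": 0.004,
        "x0": [0.0, 0.0],
        "excited_harmonics": [1],
    },
    "mesh": {
        "radius": 0.2,
        "h": 0.003,
    },
    "solver": {
        "variant": "complex-linearized",
        "N": 10,
        "omega": 0.0,  # 0 means: drive at the bubble resonance omega0
        "with_bubbles": True,
    },
    "output": {
        "directory": "results",
        "time_samples": 256,
    },
}


def _check_keys(data: dict, template: dict, path: str = "") -> None:
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in template:
            raise ValueError(f"unknown configuration key {where!r}")
        if isinstance(template[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {where!r} must be a table")
            _check_keys(value, template[key], where)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully resolved experiment configuration."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))
    name: str = "custom"

    def __post_init__(self) -> None:
        _check_keys(self.data, DEFAULT_CONFIG)
        merged = _merge(DEFAULT_CONFIG, self.data)
        object.__setattr__(self, "data", merged)
        variant = merged["solver"]["variant"]
        if variant not in VARIANTS:
            raise ValueError(f"solver.variant must be one of {VARIANTS}, got {variant!r}")
        if merged["solver"]["N"] < 1:
            raise ValueError("solver.N must be >= 1")
        if not 0 < merged["mesh"]["h"] < merged["mesh"]["radius"]:
            raise ValueError("mesh.h must satisfy 0 < h < radius")

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def primitive_params(self) -> PrimitiveParams:
        med, bub, bnd = self.data["medium"], self.data["bubbles"], self.data["boundary"]
        return PrimitiveParams(
            c=med["c"],
            b=med["b"],
            rho0=med["rho0"],
            beta_a=med["beta_a"],
            R0=bub["R0"],
            n0=bub["n0"],
            P0=bub["P0"],
            kappa=bub["kappa"],
            nu=bub["nu"],
            beta_bc=bnd["beta"],
            gamma_bc=bnd["gamma"],
        )

    def source_spec(self) -> SourceSpec:
        s = self.data["source"]
        return SourceSpec(
            a=s["a"],
            r_delta=s["r_delta"],
            x0=tuple(s["x0"]),
            excited_harmonics=tuple(s["excited_harmonics"]),
        )

    def solver_config(self) -> SolverConfig:
        s = self.data["solver"]
        omega = s["omega"] if s["omega"] else None
        return SolverConfig(
            variant=s["variant"], N=int(s["N"]), omega=omega, with_bubbles=s["with_bubbles"]
        )

    def with_overrides(self, override: dict[str, Any], name: str | None = None) -> "ExperimentConfig":
        _check_keys(override, DEFAULT_CONFIG)
        return ExperimentConfig(data=_merge(self.data, override), name=name or self.name)

    def resolved(self) -> dict[str, Any]:
        return copy.deepcopy(self.data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a TOML configuration file merged over the defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    cfg = ExperimentConfig(data=data, name=str(path) if path else "default")
    if overrides:
        cfg = cfg.with_overrides(overrides)
    return cfg


def fixture_presets() -> dict[str, ExperimentConfig]:
    """Named immutable presets.

    * ``reference-default`` — the reference configuration (bubbly medium, N = 10).
    * ``reference-no-bubbles`` — identical but with n0 = 0.
    * ``reference-two-harmonic`` — the two-harmonic effective scheme.
    * ``tiny`` — coarse mesh, three harmonics; a fast smoke-test setup.
    """
    default = ExperimentConfig(name="reference-default")
    return {
        "reference-default": default,
        "reference-no-bubbles": default.with_overrides(
            {"bubbles": {"n0": 0.0}, "solver": {"with_bubbles": False}}, name="reference-no-bubbles"
        ),
        "reference-two-harmonic": default.with_overrides(
            {"solver": {"variant": "two-harmonic", "N": 2}}, name="reference-two-harmonic"
        ),
        "tiny": default.with_overrides(
            {"mesh": {"h": 0.02}, "solver": {"N": 3}}, name="tiny"
        ),
    }
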