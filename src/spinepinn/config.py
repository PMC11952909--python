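"""Configuration schema and validation for the end-to-end pipeline.

Configs are YAML with nested sections mirroring the pipeline stages
(phantom, dataset, net, loop). User-facing values use the field's natural
units — GPa for bone moduli, MPa for disc moduli, mm for lengths — and are
converted to SI on ingest; :meth:`RunConfig.to_si_dict` echoes the fully
resolved SI values. Unknown keys are rejected; an empty file yields the
fully defaulted configuration.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .dataset import SamplingRanges, LoadSweep
from .fea import AGGREGATIONS, LoadCase
from .geometry import PhantomSpec
from .network import NetConfig

__all__ = ["RunConfig", "validate_config", "ConfigError"]

GPA = 1e9
MPA = 1e6


class ConfigError(ValueError):
    """Configuration schema violation (names the offending key)."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class PhantomSection(_Section):
    n_vertebrae: int = 5
    vertebra_height_mm: float = 28.0
    disc_height_mm: float = 10.0
    cross_section: str = "cylinder"
    radius_mm: float = 20.0
    half_widths_mm: Tuple[float, float] = (20.0, 20.0)
    mesh_resolution_mm: float = 5.0

    @field_validator("n_vertebrae")
    @classmethod
    def _n(cls, v):
        if v < 1:
            raise ValueError("phantom.n_vertebrae must be >= 1")
        return v

    @field_validator("vertebra_height_mm", "disc_height_mm", "mesh_resolution_mm", "radius_mm")
    @classmethod
    def _pos(cls, v, info):
        if v <= 0:
            raise ValueError(f"phantom.{info.field_name} must be positive (mm)")
        return v

    def to_spec(self, seed: int = 0) -> PhantomSpec:
        return PhantomSpec(
            n_vertebrae=self.n_vertebrae,
            vertebra_height=self.vertebra_height_mm,
            disc_height=self.disc_height_mm,
            cross_section=self.cross_section,
            radius=self.radius_mm,
            half_widths=tuple(self.half_widths_mm),
            mesh_resolution=self.mesh_resolution_mm,
            seed=seed,
        )


class DatasetSection(_Section):
    e_bone_gpa: Tuple[float, float] = (10.0, 25.0)
    e_disc_mpa: Tuple[float, float] = (1.0, 4.1)
    nu_bone: Tuple[float, float] = (0.1, 0.4)
    nu_disc: Tuple[float, float] = (0.45, 0.48)
    hu_bone: Tuple[float, float] = (700.0, 2000.0)
    hu_disc: Tuple[float, float] = (30.0, 90.0)
    rho_coeff_bone: Tuple[float, float] = (47.0, 1.122)
    rho_coeff_disc: Tuple[float, float] = (1000.0, 0.5)
    rho_independent: bool = False
    n_materials: int = 29
    n_materials_calibration: int = 48
    magnitudes_mm: List[float] = [round(0.2 * i, 10) for i in range(1, 15)]
    n_steps: int = 10
    fractions: Tuple[float, float, float] = (0.7, 0.15, 0.15)
    aggregation: str = "split"
    u_mode: str = "centroid_node"

    @field_validator("nu_bone", "nu_disc")
    @classmethod
    def _nu(cls, v, info):
        lo, hi = v
        if not (-1.0 < lo <= hi < 0.5):
            raise ValueError(
                f"dataset.{info.field_name} = ({lo}, {hi}) must lie strictly "
                "inside (-1, 0.5): the bulk modulus diverges at nu = 0.5"
            )
        return v

    @field_validator("aggregation")
    @classmethod
    def _agg(cls, v):
        if v not in AGGREGATIONS:
            raise ValueError(f"dataset.aggregation must be one of {AGGREGATIONS}")
        return v

    @model_validator(mode="after")
    def _ranges(self):
        for name in ("e_bone_gpa", "e_disc_mpa"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"dataset.{name} must be a positive (lo, hi) range")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("dataset.fractions must sum to 1")
        return self

    def to_ranges(self) -> SamplingRanges:
        return SamplingRanges(
            E_bone=(self.e_bone_gpa[0] * GPA, self.e_bone_gpa[1] * GPA),
            E_disc=(self.e_disc_mpa[0] * MPA, self.e_disc_mpa[1] * MPA),
            nu_bone=tuple(self.nu_bone),
            nu_disc=tuple(self.nu_disc),
            hu_bone=tuple(self.hu_bone),
            hu_disc=tuple(self.hu_disc),
            rho_coeff_bone=tuple(self.rho_coeff_bone),
            rho_coeff_disc=tuple(self.rho_coeff_disc),
            rho_independent=self.rho_independent,
        )

    def to_sweep(self) -> LoadSweep:
        return LoadSweep(magnitudes=tuple(self.magnitudes_mm), n_steps=self.n_steps)


class NetSection(_Section):
    hidden_layers: List[int] = [64, 32, 16]
    activation: str = "relu"
    lambda1: float = 0.1
    lambda2: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: Optional[int] = None
    patience: int = 300
    sweep: bool = False
    finetune_epochs: int = 2000

    def to_net_config(self, seed: int = 0) -> NetConfig:
        return NetConfig(
            hidden_layers=tuple(self.hidden_layers),
            activation=self.activation,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            seed=seed,
        )


class LoopSection(_Section):
    max_iter: int = 10
    tol: float = 1e-3
    load_mm: float = 1.4
    n_steps: int = 10
    gain: object = "harmonic"
    n_truths: int = 5

    @field_validator("tol", "load_mm")
    @classmethod
    def _pos(cls, v, info):
        if v <= 0:
            raise ValueError(f"loop.{info.field_name} must be positive")
        return v

    def to_load(self) -> LoadCase:
        return LoadCase(magnitude=self.load_mm, n_steps=self.n_steps)


class RunConfig(_Section):
    """Top-level pipeline configuration (see module docstring for units)."""

    seed: int = 0
    outdir: str = "spinepinn_run"
    verbosity: str = "info"
    phantom: PhantomSection = PhantomSection()
    dataset: DatasetSection = DatasetSection()
    net: NetSection = NetSection()
    loop: LoopSection = LoopSection()

    def to_si_dict(self) -> dict:
        """Fully resolved configuration with physical values in SI units."""
        r = self.dataset.to_ranges()
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "phantom": {
                "n_vertebrae": self.phantom.n_vertebrae,
                "vertebra_height_m": self.phantom.vertebra_height_mm * 1e-3,
                "disc_height_m": self.phantom.disc_height_mm * 1e-3,
                "cross_section": self.phantom.cross_section,
                "radius_m": self.phantom.radius_mm * 1e-3,
                "mesh_resolution_m": self.phantom.mesh_resolution_mm * 1e-3,
            },
            "dataset": {
                "E_bone_pa": list(r.E_bone),
                "E_disc_pa": list(r.E_disc),
                "nu_bone": list(r.nu_bone),
                "nu_disc": list(r.nu_disc),
                "magnitudes_m": [m * 1e-3 for m in self.dataset.magnitudes_mm],
                "n_materials": self.dataset.n_materials,
                "aggregation": self.dataset.aggregation,
            },
            "net": self.net.model_dump(),
            "loop": {
                **self.loop.model_dump(),
                "load_m": self.loop.load_mm * 1e-3,
            },
        }


def validate_config(path) -> RunConfig:
    """Load, validate and default-fill a YAML run configuration.

    An empty (or absent content) file produces the fully defaulted config.
    Schema violations raise :class:`ConfigError` naming the offending key and
    constraint.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.exists() else None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
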