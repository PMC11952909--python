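"""Training-data generation: material sampling, load sweeps, feature tables.

Materials are drawn uniformly and independently within literature-based
ranges (bone E 10-25 GPa, disc E 1-4.1 MPa, nu 0.1-0.4 and 0.45-0.48);
bulk/shear moduli are derived through the isotropic identities so the target
matrix is internally consistent. Density is assigned through an affine
Hounsfield-unit relation rho = c + d*HU with the latent HU coupled
monotonically to the Young's modulus draw: quasi-static linear responses are
density-independent, so an uncoupled density would be unlearnable by
construction (``rho_independent=True`` reproduces that ill-posed variant).

Each dataset row is one (material draw, load magnitude) pair; the feature
columns are the 16 mechanical-response scalars, the target columns the 10
material properties. For the linear solver the load sweep is generated by
exact scaling of a single reference solve per material.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fea import FEATURE_NAMES, FEAModel, LoadCase, extract_features
from .geometry import LabeledTetMesh
from .materials import TARGET_NAMES, MaterialProperties

__all__ = [
    "SamplingRanges",
    "LoadSweep",
    "TrainingDataset",
    "sample_materials",
    "build_dataset",
    "split_and_normalize",
    "largest_remainder_sizes",
]

_DEFAULT_MAGNITUDES = tuple(np.round(np.arange(0.2, 2.81, 0.2), 10))


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges for the material draw (SI units, Pa).

    ``hu_*`` are latent Hounsfield ranges; ``rho_coeff_*`` the (c, d) of
    rho = c + d*HU in kg/m^3 per HU. The bone HU range defaults to the
    cortical attenuation band.
    """

    E_bone: Tuple[float, float] = (10e9, 25e9)
    E_disc: Tuple[float, float] = (1e6, 4.1e6)
    nu_bone: Tuple[float, float] = (0.1, 0.4)
    nu_disc: Tuple[float, float] = (0.45, 0.48)
    hu_bone: Tuple[float, float] = (700.0, 2000.0)
    hu_disc: Tuple[float, float] = (30.0, 90.0)
    rho_coeff_bone: Tuple[float, float] = (47.0, 1.122)
    rho_coeff_disc: Tuple[float, float] = (1000.0, 0.5)
    rho_independent: bool = False

    def __post_init__(self):
        for name in ("E_bone", "E_disc", "nu_bone", "nu_disc", "hu_bone", "hu_disc"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"range {name} has lower > upper: ({lo}, {hi})")
        for name in ("E_bone", "E_disc"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} range must be positive")
        for name in ("nu_bone", "nu_disc"):
            lo, hi = getattr(self, name)
            if not (-1.0 < lo and hi < 0.5):
                raise ValueError(
                    f"{name} range ({lo}, {hi}) must lie strictly inside (-1, 0.5)"
                )

    def midpoint(self) -> MaterialProperties:
        """Mid-range properties (the default calibration-loop initialisation)."""
        mid = lambda r: 0.5 * (r[0] + r[1])
        E_b, E_d = mid(self.E_bone), mid(self.E_disc)
        rho_b = self._rho("bone", np.array([mid(self.hu_bone)]))[0]
        rho_d = self._rho("disc", np.array([mid(self.hu_disc)]))[0]
        return MaterialProperties.from_elastic(
            E_b, mid(self.nu_bone), E_d, mid(self.nu_disc), rho_b, rho_d
        )

    def _rho(self, tissue: str, hu: np.ndarray) -> np.ndarray:
        c, d = getattr(self, f"rho_coeff_{tissue}")
        return c + d * hu

    def latent_hu(self, tissue: str, E: np.ndarray) -> np.ndarray:
        """Monotone map from the modulus draw to the latent HU value."""
        e_lo, e_hi = getattr(self, f"E_{tissue}")
        h_lo, h_hi = getattr(self, f"hu_{tissue}")
        if e_hi == e_lo:
            return np.full_like(E, 0.5 * (h_lo + h_hi))
        return h_lo + (E - e_lo) / (e_hi - e_lo) * (h_hi - h_lo)


@dataclass(frozen=True)
class LoadSweep:
    """The set of compression magnitudes (mm) applied to each material draw."""

    magnitudes: Tuple[float, ...] = _DEFAULT_MAGNITUDES
    n_steps: int = 10

    def __post_init__(self):
        mags = np.asarray(self.magnitudes, dtype=float)
        if mags.size == 0 or np.any(mags <= 0):
            raise ValueError("load magnitudes must be strictly positive")
        if np.any(np.diff(mags) <= 0):
            raise ValueError("load magnitudes must be strictly increasing")


def sample_materials(
    ranges: SamplingRanges, n: int, seed: int
) -> List[MaterialProperties]:
    """Draw ``n`` material-property sets uniformly within the ranges.

    Deterministic for a fixed seed. Bulk/shear moduli are derived from the
    (E, nu) draws; densities come from the latent-HU relation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    E_b = rng.uniform(*ranges.E_bone, size=n)
    E_d = rng.uniform(*ranges.E_disc, size=n)
    nu_b = rng.uniform(*ranges.nu_bone, size=n)
    nu_d = rng.uniform(*ranges.nu_disc, size=n)
    if ranges.rho_independent:
        hu_b = rng.uniform(*ranges.hu_bone, size=n)
        hu_d = rng.uniform(*ranges.hu_disc, size=n)
    else:
        hu_b = ranges.latent_hu("bone", E_b)
        hu_d = ranges.latent_hu("disc", E_d)
    rho_b = ranges._rho("bone", hu_b)
    rho_d = ranges._rho("disc", hu_d)
    return [
        MaterialProperties.from_elastic(
            E_b[i], nu_b[i], E_d[i], nu_d[i], rho_b[i], rho_d[i]
        )
        for i in range(n)
    ]


@dataclass
class TrainingDataset:
    """Feature/target table with optional splits and normalization statistics."""

    X: np.ndarray  # (n, 16)
    Y: np.ndarray  # (n, 10)
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    target_names: Tuple[str, ...] = TARGET_NAMES
    splits: Dict[str, np.ndarray] = field(default_factory=dict)
    x_mean: Optional[np.ndarray] = None
    x_std: Optional[np.ndarray] = None
    y_mean: Optional[np.ndarray] = None
    y_std: Optional[np.ndarray] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError(f"X must be (n, {len(self.feature_names)})")
        if self.Y.shape != (len(self.X), len(self.target_names)):
            raise ValueError(f"Y must be (n, {len(self.target_names)})")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def is_normalized(self) -> bool:
        return self.x_mean is not None

    def split_arrays(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        idx = self.splits[name]
        return self.X[idx], self.Y[idx]

    def normalize_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def normalize_Y(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.y_mean) / self.y_std

    def denormalize_Y(self, Yn: np.ndarray) -> np.ndarray:
        return Yn * self.y_std + self.y_mean

    # -- persistence ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {n: self.X[:, i] for i, n in enumerate(self.feature_names)}
        cols.update({n: self.Y[:, i] for i, n in enumerate(self.target_names)})
        return pd.DataFrame(cols)

    def save_csv(self, path, manifest_path=None) -> None:
        """Write the 16+10-column table; optionally a JSON manifest.

        Floats are written in shortest round-trip form, so load_csv restores
        the exact binary values and equal inputs produce byte-identical files.
        """
        self.to_frame().to_csv(path, index=False)
        if manifest_path is not None:
            manifest = dict(self.metadata)
            manifest["n_samples"] = self.n_samples
            manifest["splits"] = {k: v.tolist() for k, v in self.splits.items()}
            Path(manifest_path).write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load_csv(cls, path) -> "TrainingDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in FEATURE_NAMES + TARGET_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"dataset CSV missing columns: {missing}")
        return cls(
            X=df[list(FEATURE_NAMES)].to_numpy(),
            Y=df[list(TARGET_NAMES)].to_numpy(),
        )


def _mesh_hash(mesh: LabeledTetMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.tets).tobytes())
    return h.hexdigest()[:16]


def build_dataset(
    mesh: LabeledTetMesh,
    ranges: SamplingRanges,
    sweep: LoadSweep,
    n_materials: int,
    seed: int,
    aggregation: str = "split",
    u_mode: str = "centroid_node",
    exact_scaling: bool = True,
    model: Optional[FEAModel] = None,
) -> TrainingDataset:
    """Run the FEA sweep and assemble the 16-feature / 10-target table.

    One row per (material draw x load magnitude); row count is
    ``n_materials * len(sweep.magnitudes)``. With ``exact_scaling`` (default)
    each material is solved once at a reference magnitude and the sweep rows
    are exact linear scalings; otherwise every magnitude is re-solved.
    Failed solves skip the material's rows with a warning recorded in the
    manifest metadata.
    """
    model = model or FEAModel(mesh)
    mats = sample_materials(ranges, n_materials, seed)
    mags = np.asarray(sweep.magnitudes, dtype=float)

    rows_X, rows_Y, skipped = [], [], []
    for i, mat in enumerate(mats):
        try:
            if exact_scaling:
                ref = float(mags[-1])
                sol = model.solve(mat, LoadCase(magnitude=ref, n_steps=sweep.n_steps))
                f_ref = extract_features(sol, mesh, aggregation, u_mode).as_vector()
                feats = np.outer(mags / ref, f_ref)
            else:
                feats = np.stack(
                    [
                        extract_features(
                            model.solve(
                                mat, LoadCase(magnitude=float(m), n_steps=sweep.n_steps)
                            ),
                            mesh,
                            aggregation,
                            u_mode,
                        ).as_vector()
                        for m in mags
                    ]
                )
        except Exception as exc:
            warnings.warn(f"FEA failed for material draw {i}: {exc}", stacklevel=2)
            skipped.append({"material_index": i, "error": str(exc)})
            continue
        rows_X.append(feats)
        rows_Y.append(np.tile(mat.as_vector(), (len(mags), 1)))

    if not rows_X:
        raise RuntimeError("all FEA cases failed; no dataset rows produced")
    ds = TrainingDataset(
        X=np.concatenate(rows_X),
        Y=np.concatenate(rows_Y),
        metadata={
            "seed": seed,
            "n_materials": n_materials,
            "magnitudes_mm": mags.tolist(),
            "aggregation": aggregation,
            "u_mode": u_mode,
            "mesh_hash": _mesh_hash(mesh),
            "skipped": skipped,
        },
    )
    return ds


def largest_remainder_sizes(n: int, fractions: Sequence[float]) -> List[int]:
    """Integer split sizes summing to n (largest-remainder rounding)."""
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fr.sum()}")
    raw = n * fr
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for i in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes.tolist()


def split_and_normalize(
    ds: TrainingDataset,
    fractions: Sequence[float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> TrainingDataset:
    """Assign train/val/test splits and fit per-column z-scores on train only.

    Splits are disjoint and exhaustive; normalization statistics use the
    training rows exclusively, so permuting validation/test content cannot
    leak into them. Columns with zero variance keep std 1.
    """
    sizes = largest_remainder_sizes(ds.n_samples, fractions)
    if min(sizes) < 1:
        raise ValueError(f"split sizes {sizes} must all be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    names = ("train", "val", "test")[: len(sizes)]
    splits, start = {}, 0
    for name, size in zip(names, sizes):
        splits[name] = np.sort(perm[start : start + size])
        start += size

    Xt, Yt = ds.X[splits["train"]], ds.Y[splits["train"]]

    def stats(A):
        mean = A.mean(axis=0)
        std = A.std(axis=0)
        std = np.where(std <= 0.0, 1.0, std)
        return mean, std

    x_mean, x_std = stats(Xt)
    y_mean, y_std = stats(Yt)
    return replace(
        ds,
        splits=splits,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        metadata={**ds.metadata, "split_fractions": list(fractions), "split_seed": seed},
    )
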