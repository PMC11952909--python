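"""Linear-elastic tetrahedral finite-element solver for the phantom stack.

Four-node (constant-strain) tetrahedra, two isotropic material regions (bone
and disc), prescribed-displacement axial compression on the top endplate and
a fully constrained bottom endplate. Internally SI: mesh coordinates (mm) are
converted to metres, displacements are metres, stresses Pa, forces N.

For a linear model the quasi-static load steps are exact scalings of a single
solve; a true re-solve per step is available behind ``true_stepping`` for
future nonlinear constitutive laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LabeledTetMesh
from .materials import MaterialProperties

__all__ = [
    "LoadCase",
    "FieldSolution",
    "ResponseFeatures",
    "FEATURE_NAMES",
    "FEAModel",
    "assemble_and_solve",
    "extract_features",
    "RigidBodyModeError",
    "MeshQualityError",
]

MM = 1e-3  # mm -> m

FEATURE_NAMES = (
    "F_ext",
    "u_x",
    "u_y",
    "u_z",
    "sigma_x",
    "sigma_y",
    "sigma_z",
    "sigma_xy",
    "sigma_yz",
    "sigma_xz",
    "eps_x",
    "eps_y",
    "eps_z",
    "eps_xy",
    "eps_yz",
    "eps_xz",
)

AGGREGATIONS = ("whole_model", "bone", "disc", "split")


class RigidBodyModeError(RuntimeError):
    """The reduced stiffness matrix is singular (insufficient constraints)."""


class MeshQualityError(ValueError):
    """Mesh contains non-positive-volume elements."""


@dataclass(frozen=True)
class LoadCase:
    """Prescribed-displacement axial compression.

    magnitude : mm of -z displacement imposed on the loaded node set
    n_steps : number of quasi-static steps (step s carries s/n_steps of the
        magnitude for the linear model)
    constrained_set / loaded_set : endplate node-set names
    bc_mode : "fixed_bottom" fixes all translations of the constrained set
        (the physiological sacrum support); "uniaxial_free" fixes only axial
        translations plus the minimal lateral pins that remove rigid-body
        modes (used for closed-form uniaxial verification).
    """

    magnitude: float = 1.0
    n_steps: int = 10
    constrained_set: str = "bottom"
    loaded_set: str = "top"
    bc_mode: str = "fixed_bottom"
    true_stepping: bool = False

    def __post_init__(self):
        if self.magnitude <= 0:
            raise ValueError("load magnitude must be positive (mm)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.bc_mode not in ("fixed_bottom", "uniaxial_free"):
            raise ValueError(f"unknown bc_mode {self.bc_mode!r}")


@dataclass
class FieldSolution:
    """Fields at the final load step plus exact per-step scalings.

    ``strain``/``stress`` hold symmetric tensor components in the order
    (xx, yy, zz, xy, yz, xz); shears are tensor (not engineering) values.
    ``F_ext`` is the net axial reaction on the constrained set, positive in
    compression. ``reaction_per_step[s]`` is F_ext at step s+1.
    """

    u: np.ndarray  # (n, 3) m
    strain: np.ndarray  # (m, 6)
    stress: np.ndarray  # (m, 6) Pa
    reaction: np.ndarray  # (n, 3) N, nodal reactions K u
    F_ext: float  # N
    step_factors: np.ndarray
    reaction_per_step: np.ndarray
    load: LoadCase
    strain_energy: float  # J
    element_volumes: np.ndarray  # (m,) m^3
    balance_residual: float  # relative force-balance mismatch

    def external_work(self) -> float:
        """Work done by the prescribed displacement, (1/2) F u."""
        return 0.5 * self.F_ext * self.load.magnitude * MM

    def at_step(self, step: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, strain, stress) at quasi-static step ``step`` (1-based)."""
        f = self.step_factors[step - 1]
        return self.u * f, self.strain * f, self.stress * f


@dataclass(frozen=True)
class ResponseFeatures:
    """The 16 scalar mechanical-response features fed to the network."""

    F_ext: float
    u_x: float
    u_y: float
    u_z: float
    sigma_x: float
    sigma_y: float
    sigma_z: float
    sigma_xy: float
    sigma_yz: float
    sigma_xz: float
    eps_x: float
    eps_y: float
    eps_z: float
    eps_xy: float
    eps_yz: float
    eps_xz: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "ResponseFeatures":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (16,):
            raise ValueError(f"expected 16 features, got shape {vec.shape}")
        return cls(**dict(zip(FEATURE_NAMES, vec.tolist())))


def _isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 stiffness for engineering strain order (xx, yy, zz, xy, yz, xz)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2.0 * G
    D[np.arange(3, 6), np.arange(3, 6)] = G
    return D


class FEAModel:
    """Precomputed element kinematics for one mesh; reusable across materials.

    Splitting assembly from the mesh-dependent B-matrices makes material
    sweeps (dataset generation, calibration loops) cheap: only the 6x6
    constitutive blocks change between solves.
    """

    def __init__(self, mesh: LabeledTetMesh):
        self.mesh = mesh
        nodes = mesh.nodes * MM
        tets = mesh.tets
        X = nodes[tets]  # (m, 4, 3)
        J = X[:, 1:] - X[:, :1]  # rows are edge vectors
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise MeshQualityError(
                f"{int(np.sum(detJ <= 0))} tetrahedra have non-positive volume"
            )
        self.volumes = detJ / 6.0  # m^3
        Jinv = np.linalg.inv(J)
        # gradients of shape functions N1..N3 are the columns of inv(J);
        # N0 = 1 - sum
        grads = np.empty((len(tets), 4, 3))
        grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)

        # B matrix (6 x 12), engineering shear rows
        m = len(tets)
        B = np.zeros((m, 6, 12))
        gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
        for a in range(4):
            cx, cy, cz = 3 * a, 3 * a + 1, 3 * a + 2
            B[:, 0, cx] = gx[:, a]
            B[:, 1, cy] = gy[:, a]
            B[:, 2, cz] = gz[:, a]
            B[:, 3, cx] = gy[:, a]
            B[:, 3, cy] = gx[:, a]
            B[:, 4, cy] = gz[:, a]
            B[:, 4, cz] = gy[:, a]
            B[:, 5, cx] = gz[:, a]
            B[:, 5, cz] = gx[:, a]
        self.B = B

        dof = np.empty((m, 12), dtype=np.int64)
        for a in range(4):
            dof[:, 3 * a : 3 * a + 3] = 3 * tets[:, a : a + 1] + np.arange(3)
        self._dof = dof
        self._rows = np.repeat(dof, 12, axis=1).ravel()
        self._cols = np.tile(dof, (1, 12)).ravel()
        self.n_dof = 3 * len(nodes)

        names = mesh.region_names
        self.is_bone_region = np.array([n.startswith("vertebra") for n in names])
        self.tet_is_bone = self.is_bone_region[mesh.region_labels]

    def element_D(self, mat: MaterialProperties) -> np.ndarray:
        Db = _isotropic_D(mat.E_bone, mat.nu_bone)
        Dd = _isotropic_D(mat.E_disc, mat.nu_disc)
        D = np.where(self.tet_is_bone[:, None, None], Db, Dd)
        return D

    def assemble(self, mat: MaterialProperties) -> sp.csr_matrix:
        D = self.element_D(mat)
        DB = np.einsum("eij,ejk->eik", D, self.B)
        Ke = np.einsum("eji,ejk,e->eik", self.B, DB, self.volumes)
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
        )
        return K.tocsr()

    def _dirichlet(self, load: LoadCase) -> Tuple[np.ndarray, np.ndarray]:
        mesh = self.mesh
        for name in (load.constrained_set, load.loaded_set):
            if name not in mesh.endplate_sets or len(mesh.endplate_sets[name]) == 0:
                raise ValueError(f"node set {name!r} is missing or empty")
        cons = mesh.endplate_sets[load.constrained_set]
        loaded = mesh.endplate_sets[load.loaded_set]
        if np.intersect1d(cons, loaded).size:
            raise ValueError("constrained and loaded sets must be disjoint")

        dofs, vals = [], []
        uz = -load.magnitude * MM
        if load.bc_mode == "fixed_bottom":
            for d in range(3):
                dofs.append(3 * cons + d)
                vals.append(np.zeros(len(cons)))
        else:  # uniaxial_free: axial support + minimal lateral pins
            dofs.append(3 * cons + 2)
            vals.append(np.zeros(len(cons)))
            xy = mesh.nodes[cons, :2]
            pin_a = int(cons[np.argmin(np.linalg.norm(xy - xy.mean(axis=0), axis=1))])
            pin_b = int(cons[np.argmax(xy[:, 0])])
            dofs.append(np.array([3 * pin_a, 3 * pin_a + 1]))
            vals.append(np.zeros(2))
            if pin_b != pin_a:
                dofs.append(np.array([3 * pin_b + 1]))
                vals.append(np.zeros(1))
        dofs.append(3 * loaded + 2)
        vals.append(np.full(len(loaded), uz))
        return np.concatenate(dofs), np.concatenate(vals)

    def solve(self, mat: MaterialProperties, load: LoadCase) -> FieldSolution:
        K = self.assemble(mat)
        c_dofs, c_vals = self._dirichlet(load)
        order = np.argsort(c_dofs)
        c_dofs, c_vals = c_dofs[order], c_vals[order]
        free = np.setdiff1d(np.arange(self.n_dof), c_dofs, assume_unique=False)

        if load.true_stepping:
            u = None
            for s in range(1, load.n_steps + 1):
                f = s / load.n_steps
                u = self._solve_once(K, free, c_dofs, c_vals * f)
        else:
            u = self._solve_once(K, free, c_dofs, c_vals)

        return self._fields(K, u, mat, load)

    def _solve_once(self, K, free, c_dofs, c_vals):
        Kff = K[free][:, free].tocsc()
        rhs = -K[free][:, c_dofs] @ c_vals
        try:
            lu = spla.splu(Kff)
        except RuntimeError as exc:
            raise RigidBodyModeError(
                "reduced stiffness matrix is singular; the constraints do not "
                "remove all rigid-body modes"
            ) from exc
        # a rigid-body mode that survives rounding shows up as a collapsed pivot
        diag = np.abs(lu.U.diagonal())
        if diag.min() <= 1e-12 * diag.max():
            raise RigidBodyModeError(
                "reduced stiffness matrix is numerically singular "
                f"(pivot ratio {diag.min() / diag.max():.2e}); the constraints "
                "do not remove all rigid-body modes"
            )
        uf = lu.solve(rhs)
        if not np.all(np.isfinite(uf)):
            raise RigidBodyModeError("non-finite solution (singular system)")
        u = np.zeros(self.n_dof)
        u[free] = uf
        u[c_dofs] = c_vals
        return u

    def _fields(self, K, u, mat, load) -> FieldSolution:
        mesh = self.mesh
        ue = u[self._dof]  # (m, 12)
        eps_eng = np.einsum("eij,ej->ei", self.B, ue)
        D = self.element_D(mat)
        stress = np.einsum("eij,ej->ei", D, eps_eng)
        strain = eps_eng.copy()
        strain[:, 3:] *= 0.5  # engineering -> tensor shear

        R = (K @ u).reshape(-1, 3)
        cons = mesh.endplate_sets[load.constrained_set]
        loaded = mesh.endplate_sets[load.loaded_set]
        fz_cons = float(R[cons, 2].sum())
        fz_load = float(R[loaded, 2].sum())
        denom = max(abs(fz_cons), abs(fz_load), 1e-300)
        balance = abs(fz_cons + fz_load) / denom
        F_ext = abs(fz_cons)
        factors = np.arange(1, load.n_steps + 1) / load.n_steps
        energy = 0.5 * float(u @ (K @ u))
        return FieldSolution(
            u=u.reshape(-1, 3),
            strain=strain,
            stress=stress,
            reaction=R,
            F_ext=F_ext,
            step_factors=factors,
            reaction_per_step=F_ext * factors,
            load=load,
            strain_energy=energy,
            element_volumes=self.volumes,
            balance_residual=balance,
        )


def assemble_and_solve(
    mesh: LabeledTetMesh, mat: MaterialProperties, load: LoadCase
) -> FieldSolution:
    """One-shot assembly + solve (see :class:`FEAModel` for reuse across materials)."""
    return FEAModel(mesh).solve(mat, load)


def extract_features(
    sol: FieldSolution,
    mesh: LabeledTetMesh,
    aggregation: str = "split",
    u_mode: str = "centroid_node",
) -> ResponseFeatures:
    """Condense a solved field into the 16-feature response vector.

    F_ext is the axial reaction on the constrained endplate. The displacement
    triple is taken at the loaded-endplate node nearest the set centroid
    (``u_mode="centroid_node"``, default) or as the volume-weighted nodal mean
    (``"volume_mean"``). Stress/strain components are volume-weighted element
    averages over a chosen compartment:

    - ``"whole_model"``: all elements;
    - ``"bone"`` / ``"disc"``: one compartment only;
    - ``"split"`` (default): stresses over the disc, strains over the bone.

    The default samples each field where it is informative in a stiff-soft
    composite: global averages are dominated by the compliant disc, which
    leaves the bone compartment nearly invisible to the network; the split
    keeps every material parameter identifiable.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(
            f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}"
        )

    is_bone = np.array(
        [n.startswith("vertebra") for n in mesh.region_names]
    )[mesh.region_labels]
    has_disc = bool(np.any(~is_bone))

    def vol_avg(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
        w = sol.element_volumes[mask]
        return (field[mask] * w[:, None]).sum(axis=0) / w.sum()

    all_mask = np.ones(len(is_bone), dtype=bool)
    if aggregation == "whole_model":
        sig_mask = eps_mask = all_mask
    elif aggregation == "bone":
        sig_mask = eps_mask = is_bone
    elif aggregation == "disc":
        sig_mask = eps_mask = ~is_bone if has_disc else all_mask
    else:  # split
        sig_mask = ~is_bone if has_disc else all_mask
        eps_mask = is_bone

    sig = vol_avg(sol.stress, sig_mask)
    eps = vol_avg(sol.strain, eps_mask)

    loaded = mesh.endplate_sets[sol.load.loaded_set]
    if u_mode == "centroid_node":
        xy = mesh.nodes[loaded]
        node = loaded[np.argmin(np.linalg.norm(xy - xy.mean(axis=0), axis=1))]
        u = sol.u[node]
    elif u_mode == "volume_mean":
        # volume-weighted mean of element-average displacement
        ue = sol.u[mesh.tets].mean(axis=1)
        u = (ue * sol.element_volumes[:, None]).sum(axis=0) / sol.element_volumes.sum()
    else:
        raise ValueError(f"unknown u_mode {u_mode!r}")

    vec = np.concatenate([[sol.F_ext], u, sig, eps])
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite response feature")
    return ResponseFeatures.from_vector(vec)
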