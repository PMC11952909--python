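"""Constitutive utilities for isotropic bone and intervertebral-disc tissue.

Isotropic linear elasticity is described by any two of (E, nu, k, mu):

    k  = E / (3 (1 - 2 nu))        bulk modulus
    mu = E / (2 (1 + nu))          shear modulus

and the inverse map

    E  = 9 k mu / (3 k + mu),      nu = (3 k - 2 mu) / (2 (3 k + mu)).

The disc's nonlinear behaviour is available at constitutive level through a
one-term incompressible Ogden law (strain energy in principal stretches).
Hounsfield-unit helpers implement the empirical CT bands and power/affine
relations commonly used to assign bone properties from scan intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "MaterialProperties",
    "TARGET_NAMES",
    "isotropic_relations",
    "inverse_isotropic_relations",
    "ogden_uniaxial",
    "ogden_strain_energy_uniaxial",
    "ogden_shear_modulus",
    "hu_classify",
    "hu_to_properties",
]

#: Column order of the 10-dimensional material-property vector used by the
#: dataset builder, the network and the calibration loop.
TARGET_NAMES = (
    "E_bone",
    "E_disc",
    "nu_bone",
    "nu_disc",
    "k_bone",
    "k_disc",
    "mu_bone",
    "mu_disc",
    "rho_bone",
    "rho_disc",
)

_NU_LOWER = -1.0
_NU_UPPER = 0.5


class IncompressibilityError(ValueError):
    """Poisson's ratio at or beyond the incompressible limit (nu >= 0.5)."""


def _check_E_nu(E: float, nu: float) -> None:
    if not np.all(np.asarray(E) > 0.0):
        raise ValueError(f"Young's modulus must be positive, got {E!r}")
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr >= _NU_UPPER):
        raise IncompressibilityError(
            f"Poisson's ratio must be strictly below 0.5 (bulk modulus diverges), got {nu!r}"
        )
    if np.any(nu_arr <= _NU_LOWER):
        raise ValueError(f"Poisson's ratio must be strictly above -1, got {nu!r}")


def isotropic_relations(E, nu) -> Tuple[np.ndarray, np.ndarray]:
    """Bulk and shear modulus from Young's modulus and Poisson's ratio.

    Parameters
    ----------
    E : float or array, Pa
    nu : float or array, dimensionless, in the open interval (-1, 0.5)

    Returns
    -------
    (k, mu) : bulk and shear modulus in the units of ``E``.
    """
    _check_E_nu(E, nu)
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    k = E / (3.0 * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    if k.ndim == 0:
        return float(k), float(mu)
    return k, mu


def inverse_isotropic_relations(k, mu) -> Tuple[np.ndarray, np.ndarray]:
    """Young's modulus and Poisson's ratio from bulk and shear modulus."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(k <= 0.0) or np.any(mu <= 0.0):
        raise ValueError("bulk and shear moduli must be positive")
    denom = 3.0 * k + mu
    E = 9.0 * k * mu / denom
    nu = (3.0 * k - 2.0 * mu) / (2.0 * denom)
    if E.ndim == 0:
        return float(E), float(nu)
    return E, nu


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic elastic constants and density for the two tissue compartments.

    All moduli are in Pa, densities in kg/m^3. When constructed through
    :meth:`from_elastic` the bulk/shear moduli are derived from (E, nu) and the
    instance is flagged ``consistent``.
    """

    E_bone: float
    nu_bone: float
    E_disc: float
    nu_disc: float
    k_bone: float
    k_disc: float
    mu_bone: float
    mu_disc: float
    rho_bone: float
    rho_disc: float
    consistent: bool = field(default=False, compare=False)

    def __post_init__(self):
        _check_E_nu(self.E_bone, self.nu_bone)
        _check_E_nu(self.E_disc, self.nu_disc)
        if self.rho_bone <= 0 or self.rho_disc <= 0:
            raise ValueError("densities must be positive")

    @classmethod
    def from_elastic(
        cls,
        E_bone: float,
        nu_bone: float,
        E_disc: float,
        nu_disc: float,
        rho_bone: float = 1800.0,
        rho_disc: float = 1030.0,
    ) -> "MaterialProperties":
        k_b, mu_b = isotropic_relations(E_bone, nu_bone)
        k_d, mu_d = isotropic_relations(E_disc, nu_disc)
        return cls(
            E_bone=E_bone,
            nu_bone=nu_bone,
            E_disc=E_disc,
            nu_disc=nu_disc,
            k_bone=k_b,
            k_disc=k_d,
            mu_bone=mu_b,
            mu_disc=mu_d,
            rho_bone=rho_bone,
            rho_disc=rho_disc,
            consistent=True,
        )

    def as_vector(self) -> np.ndarray:
        """10-vector in :data:`TARGET_NAMES` order."""
        return np.array([getattr(self, name) for name in TARGET_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec, consistent: bool = False) -> "MaterialProperties":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (10,):
            raise ValueError(f"expected a 10-vector, got shape {vec.shape}")
        return cls(**dict(zip(TARGET_NAMES, vec.tolist())), consistent=consistent)

    def consistency_residuals(self) -> dict:
        """Relative residuals of the isotropic identities, per tissue.

        Returns ``{"k_bone": |k - E/(3(1-2nu))|/k, ...}`` for both moduli and
        both tissues. Zero for instances built with :meth:`from_elastic`.
        """
        out = {}
        for tissue in ("bone", "disc"):
            E = getattr(self, f"E_{tissue}")
            nu = getattr(self, f"nu_{tissue}")
            k_ref, mu_ref = isotropic_relations(E, nu)
            k = getattr(self, f"k_{tissue}")
            mu = getattr(self, f"mu_{tissue}")
            out[f"k_{tissue}"] = abs(k - k_ref) / abs(k)
            out[f"mu_{tissue}"] = abs(mu - mu_ref) / abs(mu)
        return out

    def with_(self, **kwargs) -> "MaterialProperties":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# One-term incompressible Ogden law (disc soft-tissue nonlinearity)
# ---------------------------------------------------------------------------

def ogden_strain_energy_uniaxial(mu_o: float, alpha: float, stretch) -> np.ndarray:
    """Strain energy density W(lambda) for incompressible uniaxial extension.

    One-term Ogden energy W = (mu_o/alpha) (l1^a + l2^a + l3^a - 3) with the
    incompressible uniaxial kinematics l1 = lambda, l2 = l3 = lambda^(-1/2).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    return (mu_o / alpha) * (lam**alpha + 2.0 * lam ** (-alpha / 2.0) - 3.0)


def ogden_uniaxial(mu_o: float, alpha: float, stretch) -> np.ndarray:
    """Nominal (first Piola-Kirchhoff) stress for uniaxial incompressible Ogden.

    P(lambda) = dW/dlambda = mu_o (lambda^(alpha-1) - lambda^(-alpha/2-1)).
    At lambda = 1 the stress vanishes; the small-strain tangent is
    3 mu with mu = mu_o alpha / 2 (see :func:`ogden_shear_modulus`).
    For alpha = 2 this reduces to the incompressible neo-Hookean closed form
    mu_o (lambda - lambda^-2).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    out = mu_o * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
    if out.ndim == 0:
        return float(out)
    return out


def ogden_shear_modulus(mu_o: float, alpha: float) -> float:
    """Small-strain shear modulus consistent with a one-term Ogden law."""
    return mu_o * alpha / 2.0


# ---------------------------------------------------------------------------
# Hounsfield-unit helpers
# ---------------------------------------------------------------------------

#: CT attenuation bands (HU) conventionally attributed to each bone type.
HU_CORTICAL_BAND = (700.0, 2000.0)
HU_CANCELLOUS_BAND = (100.0, 300.0)


def hu_classify(hu: float) -> str:
    """Classify a Hounsfield value as 'cortical', 'cancellous' or 'indeterminate'.

    Cortical bone attenuates in roughly +700..+2000 HU, cancellous bone in
    +100..+300 HU; values outside both bands are indeterminate.
    """
    if not np.isfinite(hu):
        raise ValueError(f"HU value must be finite, got {hu!r}")
    if HU_CORTICAL_BAND[0] <= hu <= HU_CORTICAL_BAND[1]:
        return "cortical"
    if HU_CANCELLOUS_BAND[0] <= hu <= HU_CANCELLOUS_BAND[1]:
        return "cancellous"
    return "indeterminate"


def hu_to_properties(hu, a: float, b: float, c: float, d: float):
    """Empirical HU -> (Young's modulus, density) relations.

    E (MPa) = a * HU**b   and   rho (kg/m^3) = c + d * HU.

    The coefficients are calibration-specific and must be supplied by the
    caller. The power law requires hu > 0 unless ``b`` is an integer.
    """
    hu_arr = np.asarray(hu, dtype=float)
    if np.any(hu_arr <= 0.0) and float(b) != int(b):
        raise ValueError("HU must be positive for a non-integer power-law exponent")
    E = a * hu_arr**b
    rho = c + d * hu_arr
    if E.ndim == 0:
        return float(E), float(rho)
    return E, rho
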