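"""Atrophy-coupled compressible neo-Hookean material law.

Volumetric tissue loss enters through the multiplicative split of the
deformation gradient, F = F^e . F^a with F^a = theta^(1/dim) I, where the
atrophy factor theta in (0, 1] is the fraction of local tissue measure
retained (theta = J^a).  Only the elastic part stores energy:

    Psi0(F, theta) = theta * Psi(F^e),
    Psi(F^e) = mu/2 [F^e:F^e - dim - 2 ln J^e] + lambda/2 ln^2 J^e.

The first Piola-Kirchhoff stress is the exact work conjugate
P = dPsi0/dF = theta^(1-2/dim) mu F + theta (lambda ln J^e - mu) F^{-T},
so P vanishes for any stress-free shrunken state F = theta^(1/dim) R.

theta evolves by a concentration-gated rate: a constant healthy loss rate
G_h, accelerated by G_c once the biomarker concentration c exceeds c_crit
(smooth sigmoidal gate of sharpness beta).  theta is non-increasing, starts
at 1, and is floored (default 0.5) to keep det F^a bounded away from zero.

In 2D the model is plane strain and theta measures in-plane area loss
(F^a = theta^(1/2) I_2); in 3D theta is the volume fraction retained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BETA = 50.0      # sigmoid sharpness: transition width ~0.1 in c
DEFAULT_THETA_FLOOR = 0.5


@dataclass(frozen=True)
class RegionMaterial:
    """Per-region constitutive parameters.

    lambda_, mu: Lame constants (kPa); G_h, G_c: healthy / disease atrophy
    rates (1/yr); c_crit: biomarker threshold; fluid-like regions
    (ventricles, CSF) carry no atrophy parameters (G_h is None).
    """
    lambda_: float
    mu: float
    G_h: float | None = None
    G_c: float | None = None
    c_crit: float | None = None

    def __post_init__(self):
        if self.mu <= 0 or self.lambda_ <= 0:
            raise ValueError("Lame constants must be positive")
        if self.G_h is not None:
            if self.G_h < 0 or (self.G_c or 0.0) < 0:
                raise ValueError("atrophy rates must be >= 0")
            if self.c_crit is not None and not 0.0 < self.c_crit < 1.0:
                raise ValueError("c_crit must lie in (0, 1)")

    @property
    def atrophying(self) -> bool:
        return self.G_h is not None


def default_material_table() -> dict[str, RegionMaterial]:
    """Region materials of the reference atrophy model (kPa, 1/yr)."""
    gm = RegionMaterial(lambda_=32.33, mu=1.0, G_h=0.001, G_c=0.002,
                        c_crit=0.5)
    return {
        "WM": RegionMaterial(lambda_=64.67, mu=2.0, G_h=0.0015, G_c=0.0035,
                             c_crit=0.5),
        "GM": gm,
        "HIPPO": gm,
        "VENT": RegionMaterial(lambda_=29.77, mu=15.34),
        "CSF": RegionMaterial(lambda_=7.22, mu=14.43),
    }


def ultrasoft_csf_table() -> dict[str, RegionMaterial]:
    """Alternative preset with fluid regions much softer than gray matter.

    The default table lists ventricle/CSF shear moduli above the tissue
    values; this preset instead realises the 'ultrasoft, highly
    compressible' reading (mu << mu_GM).  Not the default.
    """
    table = default_material_table()
    table["VENT"] = replace(table["VENT"], lambda_=0.05, mu=0.05)
    table["CSF"] = replace(table["CSF"], lambda_=0.05, mu=0.05)
    return table


# ------------------------------------------------------ atrophy evolution

def smooth_heaviside(c, c_crit, beta: float = DEFAULT_BETA):
    """Sigmoidal gate 1/(1+exp(-beta (c - c_crit))); 0.5 at threshold.

    Monotonically increasing in c so that atrophy accelerates once the
    biomarker exceeds c_crit.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    x = np.clip(beta * (np.asarray(c, dtype=float) - c_crit), -500, 500)
    return 1.0 / (1.0 + np.exp(-x))


def atrophy_rate(c, mat: RegionMaterial, beta: float = DEFAULT_BETA):
    """Volume-loss rate -d(theta)/dt = G_h + G_c * H(c - c_crit), 1/yr.

    Limits: G_h for c << c_crit, G_h + G_c for c >> c_crit.  Composed
    directly as G_h + G_c*H, so fluid-like regions (no atrophy parameters)
    simply return 0 and a G_h = 0 tissue with G_c > 0 remains well-defined.
    """
    if not mat.atrophying:
        return np.zeros_like(np.asarray(c, dtype=float))
    rate = np.full_like(np.asarray(c, dtype=float), mat.G_h)
    if mat.G_c:
        rate = rate + mat.G_c * smooth_heaviside(c, mat.c_crit, beta)
    return rate


def update_atrophy_factor(theta_n, c, dt: float, mat: RegionMaterial,
                          beta: float = DEFAULT_BETA,
                          floor: float = DEFAULT_THETA_FLOOR):
    """One explicit finite-difference decay step of the atrophy factor.

    theta = theta_n - rate(c) * dt, clamped at `floor` (with a logged
    warning) to guard against element inversion under extreme parameters.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    theta_n = np.asarray(theta_n, dtype=float)
    if np.any(theta_n <= 0) or np.any(theta_n > 1):
        raise ValueError("theta_n must lie in (0, 1]")
    theta = theta_n - atrophy_rate(c, mat, beta) * dt
    if np.any(theta < floor):
        logger.warning("atrophy factor clamped at floor %.2f", floor)
        theta = np.maximum(theta, floor)
    return theta


# ------------------------------------------------- kinematics and stress

def deformation_split(F: np.ndarray, theta, dim: int | None = None):
    """Multiplicative split F = F^e F^a with F^a = theta^(1/dim) I.

    Returns (F_a, F_e, J_a, J_e); det F_a = theta exactly and
    J_e = det(F)/theta.  Accepts a single matrix or a batch (..., d, d).
    """
    F = np.asarray(F, dtype=float)
    if dim is None:
        dim = F.shape[-1]
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det F must be > 0 (element inversion)")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0")
    s = theta ** (1.0 / dim)
    eye = np.eye(dim)
    F_a = s[..., None, None] * eye if s.ndim else s * eye
    F_e = F / (s[..., None, None] if s.ndim else s)
    return F_a, F_e, theta, J / theta


def strain_energy(F_e: np.ndarray, theta, mu: float, lambda_: float):
    """Atrophy-weighted stored energy density Psi0 = theta * Psi(F^e).

    Uses trace(F_e^T F_e) - dim (plane-strain convention in 2D).
    """
    F_e = np.asarray(F_e, dtype=float)
    dim = F_e.shape[-1]
    J_e = np.linalg.det(F_e)
    if np.any(J_e <= 0):
        raise ValueError("det F_e must be > 0")
    i1 = np.einsum("...ij,...ij->...", F_e, F_e)
    lnJ = np.log(J_e)
    psi = 0.5 * mu * (i1 - dim - 2.0 * lnJ) + 0.5 * lambda_ * lnJ ** 2
    return theta * psi


def piola_stress(F_e: np.ndarray, theta, mu: float, lambda_: float):
    """First Piola-Kirchhoff stress, exact work conjugate of Psi0.

    P = theta^(1-1/dim) [mu F^e + (lambda ln J^e - mu) F^{e,-T}];
    P = 0 whenever F^e is a rotation (frame indifference).
    """
    F_e = np.asarray(F_e, dtype=float)
    dim = F_e.shape[-1]
    J_e = np.linalg.det(F_e)
    if np.any(np.abs(J_e) < 1e-300):
        raise ValueError("F_e is singular")
    if np.any(J_e <= 0):
        raise ValueError("det F_e must be > 0")
    theta = np.asarray(theta, dtype=float)
    FinvT = np.swapaxes(np.linalg.inv(F_e), -1, -2)
    lnJ = np.log(J_e)
    core = mu * F_e + ((lambda_ * lnJ - mu)[..., None, None]
                       if np.ndim(lnJ) else (lambda_ * lnJ - mu)) * FinvT
    pref = theta ** (1.0 - 1.0 / dim)
    return (pref[..., None, None] if pref.ndim else pref) * core


def piola_stress_total(F: np.ndarray, theta, mu: float, lambda_: float):
    """P as a function of the total deformation gradient (batched)."""
    _, F_e, _, _ = deformation_split(F, theta)
    return piola_stress(F_e, theta, mu, lambda_)


def piola_tangent(F: np.ndarray, theta, mu: float, lambda_: float):
    """First elasticity tensor A_ijkl = dP_ij/dF_kl (batched).

    With P = c1 F + c2(J) F^{-T}, c1 = theta^(1-2/dim) mu and
    c2 = theta (lambda ln J^e - mu):
    A = c1 II + theta lambda F^{-T} x F^{-T} - c2 (F^{-T} ox F^{-T}).
    """
    F = np.asarray(F, dtype=float)
    dim = F.shape[-1]
    theta = np.asarray(theta, dtype=float)
    J = np.linalg.det(F)
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
    lnJe = np.log(J / theta)
    c1 = theta ** (1.0 - 2.0 / dim) * mu
    c2 = theta * (lambda_ * lnJe - mu)
    eye = np.eye(dim)
    batch = F.shape[:-2]
    A = np.zeros(batch + (dim, dim, dim, dim))
    A += (np.asarray(c1).reshape(batch + (1, 1, 1, 1))
          * np.einsum("ik,jl->ijkl", eye, eye))
    A += (np.asarray(theta * lambda_).reshape(batch + (1, 1, 1, 1))
          * np.einsum("...ij,...kl->...ijkl", FinvT, FinvT))
    A -= (np.asarray(c2).reshape(batch + (1, 1, 1, 1))
          * np.einsum("...il,...kj->...ijkl", FinvT, FinvT))
    return A


def cauchy_stress_and_tangent(F: np.ndarray, theta, mat: RegionMaterial):
    """Cauchy stress and the Jaumann-rate spatial tangent.

    sigma = [mu b^e + (lambda ln J^e - mu) I] / J^e with b^e = F^e F^e,T.
    The returned tangent C is the corotational (Jaumann) moduli of the
    Kirchhoff stress divided by J, i.e. the convention expected by
    corotational FE updates:  C:d = [theta lambda tr(d) I
    + theta mu (d b^e + b^e d)] / J.  It possesses both minor symmetries.
    """
    F = np.asarray(F, dtype=float)
    dim = F.shape[-1]
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det F must be > 0")
    mu, lam = mat.mu, mat.lambda_
    theta = np.asarray(theta, dtype=float)
    J_e = J / theta
    b_e = theta ** (-2.0 / dim) * np.einsum("...ij,...kj->...ik", F, F)
    lnJe = np.log(J_e)
    eye = np.eye(dim)
    sigma = (mu * b_e + (lam * lnJe - mu) * eye) / J_e
    if not np.all(np.isfinite(sigma)):
        raise FloatingPointError("non-finite Cauchy stress")

    tl = theta * lam / J
    tm = theta * mu / J
    C = (tl * np.einsum("ij,kl->ijkl", eye, eye)
         + tm * 0.5 * (np.einsum("ik,...jl->...ijkl", eye, b_e)
                       + np.einsum("il,...jk->...ijkl", eye, b_e)
                       + np.einsum("...ik,jl->...ijkl", b_e, eye)
                       + np.einsum("...il,jk->...ijkl", b_e, eye)))
    return sigma, C


def kirchhoff_stress(F: np.ndarray, theta, mu: float, lambda_: float):
    """tau = J sigma; used by the finite-difference tangent oracle."""
    F = np.asarray(F, dtype=float)
    dim = F.shape[-1]
    theta = np.asarray(theta, dtype=float)
    J = np.linalg.det(F)
    s = theta[..., None, None] if theta.ndim else theta
    b_e = s ** (-2.0 / dim) * np.einsum("...ij,...kj->...ik", F, F)
    lnJe = np.log(J / theta)
    g = lnJe[..., None, None] if np.ndim(lnJe) else lnJe
    return s * (mu * b_e + (lambda_ * g - mu) * np.eye(dim))


def lame_from_young_poisson(E: float, nu: float) -> tuple[float, float]:
    """(lambda, mu) from Young's modulus and Poisson ratio."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu
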