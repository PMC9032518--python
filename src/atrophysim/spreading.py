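"""Fisher-Kolmogorov spreading of the misfolded-protein biomarker.

Solves ``dc/dt = d * Laplacian(c) + alpha * c * (1 - c)`` on the labeled
mesh with region-wise diffusivity ``d`` (mm^2/yr) and logistic growth rate
``alpha`` (1/yr).  The exterior boundary carries the natural zero-flux
condition; regions with ``d = 0`` (ventricles, CSF) exchange no diffusive
flux and evolve by local reaction only.

Time integration is backward Euler with a Newton solve of the reaction
term and a row-sum lumped mass matrix; nodal values are clipped to [0, 1]
as a safety net (the clipped mass is tracked and reported when it exceeds
1e-6, which indicates too coarse a time step).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .phantom import REGION_IDS, REGION_NAMES, LabeledMesh

logger = logging.getLogger(__name__)

#: region-wise defaults: diffusivity mm^2/yr, growth rate 1/yr
DEFAULT_DIFFUSIVITY = {"WM": 15.0, "GM": 15.0, "HIPPO": 15.0,
                       "VENT": 0.0, "CSF": 0.0}
DEFAULT_GROWTH_RATE = {"WM": 0.09, "GM": 0.09, "HIPPO": 0.09,
                       "VENT": 0.09, "CSF": 0.09}


class ConvergenceError(RuntimeError):
    """Nonlinear solve failed; carries the final residual norm."""


@dataclass(frozen=True)
class KineticParams:
    """Two-species prion-like kinetics (all rates 1/yr).

    k0: healthy-protein production, k1: healthy clearance, k1_tilde:
    misfolded clearance, k12: healthy-to-misfolded conversion.
    """
    k0: float
    k1: float
    k1_tilde: float
    k12: float

    def __post_init__(self):
        if self.k1 <= 0:
            raise ValueError("k1 (healthy clearance rate) must be > 0")
        if min(self.k0, self.k1_tilde, self.k12) < 0:
            raise ValueError("kinetic rates must be non-negative")


def kinetic_alpha(k: KineticParams) -> float:
    """Effective logistic growth rate alpha = k12*k0/k1 - k1_tilde.

    May be negative; callers decide whether a net-clearing regime is
    admissible for their scenario.
    """
    return k.k12 * k.k0 / k.k1 - k.k1_tilde


def reaction_term(c, alpha):
    """Logistic source f = alpha*c*(1-c) and its derivative alpha*(1-2c)."""
    c = np.asarray(c, dtype=float)
    return alpha * c * (1.0 - c), alpha * (1.0 - 2.0 * c)


def closed_form_logistic(c0: float, alpha: float, t) -> np.ndarray | float:
    """Spatially uniform analytic solution (diffusion term vanishes)."""
    if not 0.0 <= c0 <= 1.0:
        raise ValueError("c0 must lie in [0, 1]")
    # overflow-safe form of c0 e^{at} / (1 - c0 + c0 e^{at})
    e = np.exp(-alpha * np.asarray(t, dtype=float))
    return c0 / (c0 + (1.0 - c0) * e)


@dataclass(frozen=True)
class SpreadingParams:
    d: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DIFFUSIVITY))
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROWTH_RATE))
    c0_seed: float = 0.3
    seed_region: str = "HIPPO"

    def __post_init__(self):
        if any(v < 0 for v in self.d.values()):
            raise ValueError("diffusivities must be >= 0")
        if any(v < 0 for v in self.alpha.values()):
            raise ValueError("growth rates must be >= 0")
        if not 0.0 <= self.c0_seed <= 1.0:
            raise ValueError("c0_seed must lie in [0, 1]")


@dataclass
class ConcentrationField:
    values: np.ndarray  # per node, dimensionless in [0, 1]
    time: float = 0.0   # years

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.values.copy(), self.time)


def seed_concentration(mesh: LabeledMesh,
                       params: SpreadingParams) -> ConcentrationField:
    """Initial field: c0_seed on every node incident to the seed region."""
    rid = REGION_IDS.get(params.seed_region)
    if rid is None or len(mesh.region_elements(rid)) == 0:
        raise ValueError(
            f"seed region {params.seed_region!r} not present in mesh")
    c = np.zeros(mesh.n_nodes)
    nodes = np.unique(mesh.simplices[mesh.region_elements(rid)])
    c[nodes] = params.c0_seed
    return ConcentrationField(values=c, time=0.0)


class FisherKolmogorovSolver:
    """Backward-Euler/Newton stepper with precomputed FE operators."""

    def __init__(self, mesh: LabeledMesh, params: SpreadingParams,
                 newton_tol: float = 1e-12, newton_max_iter: int = 30):
        self.mesh = mesh
        self.params = params
        self.newton_tol = newton_tol
        self.newton_max_iter = newton_max_iter

        region = mesh.element_region
        d_elem = np.array([params.d[REGION_NAMES[r]] for r in region])
        a_elem = np.array([params.alpha[REGION_NAMES[r]] for r in region])
        self.K = _fem.stiffness_matrix(mesh.nodes, mesh.simplices, d_elem)
        self.mass = _fem.lumped_mass(mesh.nodes, mesh.simplices)
        # nodal growth rate: mass-weighted average of incident elements
        num = _fem.lumped_mass(mesh.nodes, mesh.simplices, a_elem)
        self.alpha_node = num / self.mass
        self.max_clip = 0.0

    def step(self, field: ConcentrationField, dt: float) -> ConcentrationField:
        if dt <= 0:
            raise ValueError("dt must be > 0")
        cn = field.values
        M = self.mass
        c = cn.copy()
        scale = float(M.sum())  # total measure; residual is a mass rate
        for it in range(self.newton_max_iter):
            f, df = reaction_term(c, self.alpha_node)
            R = M * (c - cn) / dt + self.K @ c - M * f
            rnorm = np.linalg.norm(R) / scale
            if rnorm < self.newton_tol:
                break
            J = self.K + sp.diags(M / dt - M * df)
            c = c - spla.spsolve(J.tocsc(), R)
        else:
            raise ConvergenceError(
                f"concentration step at t={field.time:.3f} yr did not "
                f"converge: residual {rnorm:.3e}")
        clip = max(float(np.max(-c, initial=0.0)),
                   float(np.max(c - 1.0, initial=0.0)))
        if clip > 0:
            self.max_clip = max(self.max_clip, clip)
            if clip > 1e-6:
                logger.warning("clipped concentration overshoot %.2e at "
                               "t=%.2f yr; consider a smaller dt", clip,
                               field.time + dt)
            np.clip(c, 0.0, 1.0, out=c)
        return ConcentrationField(values=c, time=field.time + dt)


def step_concentration(field: ConcentrationField, mesh: LabeledMesh,
                       params: SpreadingParams, dt: float
                       ) -> ConcentrationField:
    """One implicit step (convenience wrapper building operators afresh)."""
    return FisherKolmogorovSolver(mesh, params).step(field, dt)


def front_position(mesh: LabeledMesh, field: ConcentrationField,
                   level: float = 0.5, axis: int = 0) -> float:
    """Largest axis-coordinate where c crosses `level` (front tracking).

    Interpolates along the sorted axis coordinate of the nodal max-profile;
    used as the brute-force travelling-wave oracle on bar meshes.
    """
    x = mesh.nodes[:, axis]
    order = np.argsort(x)
    xs, cs = x[order], field.values[order]
    # collapse transverse nodes: max per unique coordinate
    ux, inv = np.unique(np.round(xs, 9), return_inverse=True)
    prof = np.full(len(ux), -np.inf)
    np.maximum.at(prof, inv, cs)
    above = prof >= level
    if not above.any():
        return math.nan
    i = int(np.max(np.flatnonzero(above)))
    if i == len(ux) - 1:
        return float(ux[-1])
    c1, c2 = prof[i], prof[i + 1]
    w = 0.0 if c1 == c2 else (c1 - level) / (c1 - c2)
    return float(ux[i] + w * (ux[i + 1] - ux[i]))
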