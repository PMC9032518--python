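"""Quasistatic nonlinear equilibrium and the staggered aging driver.

The mechanical problem is the quasistatic balance of linear momentum,
Div P = 0 in the reference domain with zero body force, zero displacement
on the outer CSF surface, and the atrophy-coupled neo-Hookean law of
:mod:`atrophysim.constitutive`.  Linear simplices with one quadrature point
per element; full Newton with the analytic first elasticity tensor and
automatic bisection of the atrophy increment on divergence.

The aging driver advances the biomarker concentration (AD mode only),
decays the per-element atrophy factor, and re-equilibrates.  The coupling
is one-way (concentration -> theta -> mechanics on the reference
configuration), so equilibrium only needs to be solved at recording times.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem
from .constitutive import (DEFAULT_BETA, DEFAULT_THETA_FLOOR, RegionMaterial,
                           default_material_table, update_atrophy_factor)
from .phantom import REGION_NAMES, LabeledMesh
from .spreading import (FisherKolmogorovSolver, SpreadingParams,
                        seed_concentration)

logger = logging.getLogger(__name__)

HEALTHY, AD = "healthy", "ad"


class EquilibriumError(RuntimeError):
    """Newton divergence; message carries the iteration trace."""


@dataclass(frozen=True)
class SimulationConfig:
    t_end: float = 40.0          # simulated age span, years
    dt: float = 0.1              # years
    mode: str = AD               # "healthy" | "ad"
    newton_tol: float = 1e-10    # relative residual drop
    newton_abs_tol: float = 1e-9 # absolute residual (kPa*mm^(dim-1))
    newton_max_iter: int = 30
    dirichlet: str = "csf_outer"
    output_every: int = 5        # record/equilibrate every N steps
    seed: int = 0
    beta: float = DEFAULT_BETA
    theta_floor: float = DEFAULT_THETA_FLOOR
    max_substeps: int = 16

    def __post_init__(self):
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.dt <= 0 or (self.t_end > 0 and self.dt > self.t_end):
            raise ValueError("require 0 < dt <= t_end")
        if self.newton_tol <= 0 or self.newton_abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.mode not in (HEALTHY, AD):
            raise ValueError(f"mode must be '{HEALTHY}' or '{AD}'")


@dataclass
class AtrophyState:
    """Per-quadrature-point (= per-element) atrophy factor and history."""
    theta: np.ndarray
    history: list = field(default_factory=list)

    def commit(self, time: float) -> None:
        self.history.append((time, self.theta.copy()))


@dataclass
class SimulationResult:
    mesh: LabeledMesh
    mode: str
    times: np.ndarray
    displacements: list       # (n_nodes, dim) per recorded step
    thetas: list              # (n_elem,) per recorded step
    concentrations: list      # (n_nodes,) per recorded step or None
    convergence_log: list = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def deformed_coords(self, step: int) -> np.ndarray:
        return self.mesh.nodes + self.displacements[step]

    def region_volume(self, region, step: int) -> float:
        return self.mesh.region_volume(region, self.deformed_coords(step))


# ------------------------------------------------------------ equilibrium

class _Assembler:
    def __init__(self, mesh: LabeledMesh,
                 materials: dict[str, RegionMaterial]):
        self.mesh = mesh
        self.grads, vols = _fem.shape_gradients(mesh.nodes, mesh.simplices)
        self.vols = np.abs(vols)
        self.mu = np.array([materials[REGION_NAMES[r]].mu
                            for r in mesh.element_region])
        self.lam = np.array([materials[REGION_NAMES[r]].lambda_
                             for r in mesh.element_region])
        nv = mesh.simplices.shape[1]
        dim = mesh.dimension
        # sparse pattern: dof = node*dim + comp
        dofs = (mesh.simplices[:, :, None] * dim
                + np.arange(dim)[None, None, :]).reshape(len(self.vols), -1)
        self.rows = np.repeat(dofs, nv * dim, axis=1).ravel()
        self.cols = np.tile(dofs, (1, nv * dim)).ravel()
        self.ndof = mesh.n_nodes * dim

    def residual_and_F(self, u: np.ndarray, theta: np.ndarray):
        """Internal-force residual; returns (None, F) on element inversion."""
        mesh = self.mesh
        dim = mesh.dimension
        F = _fem.deformation_gradients(self.grads, mesh.simplices, u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            return None, F
        P = _batched_piola(F, theta, self.mu, self.lam)
        fe = np.einsum("e,eij,eaj->eai", self.vols, P, self.grads)
        R = np.zeros((mesh.n_nodes, dim))
        np.add.at(R, mesh.simplices, fe)
        return R.ravel(), F

    def tangent(self, F: np.ndarray, theta: np.ndarray) -> sp.csr_matrix:
        A = _batched_tangent(F, theta, self.mu, self.lam)
        ke = np.einsum("e,eaj,eijml,ebl->eaibm", self.vols, self.grads, A,
                       self.grads)
        n = self.ndof
        K = sp.coo_matrix((ke.reshape(len(self.vols), -1).ravel(),
                           (self.rows, self.cols)), shape=(n, n))
        return K.tocsr()


def _batched_piola(F, theta, mu, lam):
    dim = F.shape[-1]
    J = np.linalg.det(F)
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
    lnJe = np.log(J / theta)
    c1 = theta ** (1.0 - 2.0 / dim) * mu
    c2 = theta * (lam * lnJe - mu)
    return c1[:, None, None] * F + c2[:, None, None] * FinvT


def _batched_tangent(F, theta, mu, lam):
    dim = F.shape[-1]
    J = np.linalg.det(F)
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
    lnJe = np.log(J / theta)
    c1 = (theta ** (1.0 - 2.0 / dim) * mu)[:, None, None, None, None]
    tl = (theta * lam)[:, None, None, None, None]
    c2 = (theta * (lam * lnJe - mu))[:, None, None, None, None]
    eye = np.eye(dim)
    A = c1 * np.einsum("ik,jl->ijkl", eye, eye)[None]
    A = A + tl * np.einsum("eij,ekl->eijkl", FinvT, FinvT)
    A = A - c2 * np.einsum("eil,ekj->eijkl", FinvT, FinvT)
    return A


def solve_equilibrium(mesh: LabeledMesh, theta: np.ndarray | AtrophyState,
                      materials: dict[str, RegionMaterial] | None = None,
                      u_init: np.ndarray | None = None,
                      dirichlet: str | None = "csf_outer",
                      fixed_dofs: np.ndarray | None = None,
                      tol: float = 1e-10, abs_tol: float = 1e-9,
                      max_iter: int = 30,
                      assembler: _Assembler | None = None,
                      log: list | None = None) -> np.ndarray:
    """Newton solve of the displacement field for a given atrophy state.

    Zero displacement is imposed on the ``dirichlet`` boundary node set
    and/or explicit ``fixed_dofs`` (dof index = node*dim + component).
    Returns nodal displacements (mm).
    """
    if isinstance(theta, AtrophyState):
        theta = theta.theta
    if materials is None:
        materials = default_material_table()
    asm = assembler or _Assembler(mesh, materials)
    dim = mesh.dimension
    ndof = asm.ndof

    fixed = []
    if dirichlet is not None:
        if dirichlet not in mesh.boundary_sets:
            raise ValueError(f"boundary set {dirichlet!r} not in mesh")
        nodes = mesh.boundary_sets[dirichlet]
        fixed.append((nodes[:, None] * dim + np.arange(dim)).ravel())
    if fixed_dofs is not None:
        fixed.append(np.asarray(fixed_dofs, dtype=int))
    fixed = (np.unique(np.concatenate(fixed)) if fixed
             else np.array([], dtype=int))
    if len(fixed) == 0:
        raise ValueError("Dirichlet set is empty: rigid modes unconstrained")
    free = np.setdiff1d(np.arange(ndof), fixed)

    u = np.zeros((mesh.n_nodes, dim)) if u_init is None else u_init.copy()
    u.reshape(-1)[fixed] = 0.0

    R, F = asm.residual_and_F(u.reshape(mesh.n_nodes, dim), theta)
    if R is None:
        raise EquilibriumError("initial guess has inverted elements")
    r0 = np.linalg.norm(R[free])
    trace = [r0]
    if r0 <= abs_tol:
        if log is not None:
            log.append(trace)
        return u
    for it in range(max_iter):
        K = asm.tangent(F, theta)[free][:, free]
        du = spla.spsolve(K.tocsc(), R[free])
        step = 1.0
        for _ in range(12):  # backtracking line search
            u_try = u.copy()
            u_try.reshape(-1)[free] -= step * du
            R_try, F_try = asm.residual_and_F(u_try, theta)
            if R_try is not None and (np.linalg.norm(R_try[free])
                                      < (1.0 - 0.1 * step) * trace[-1]
                                      or step < 1e-3):
                u, R, F = u_try, R_try, F_try
                break
            step *= 0.5
        else:
            raise EquilibriumError(
                f"line search failed at iteration {it}; residuals {trace}")
        rn = np.linalg.norm(R[free])
        trace.append(rn)
        if rn <= abs_tol or rn <= tol * r0:
            if log is not None:
                log.append(trace)
            return u
    raise EquilibriumError(
        f"Newton did not converge in {max_iter} iterations; residual trace "
        f"{[f'{r:.3e}' for r in trace]}; consider substepping the atrophy "
        "increment")


def _solve_with_substepping(mesh, theta_old, theta_new, materials, u,
                            config: SimulationConfig, asm, log):
    """Equilibrium at theta_new, bisecting the theta increment on failure."""
    pending = [(theta_old, theta_new, 0)]
    while pending:
        t0, t1, depth = pending.pop()
        try:
            u = solve_equilibrium(
                mesh, t1, materials, u_init=u, dirichlet=config.dirichlet,
                tol=config.newton_tol, abs_tol=config.newton_abs_tol,
                max_iter=config.newton_max_iter, assembler=asm, log=log)
        except EquilibriumError:
            if depth >= config.max_substeps:
                raise
            mid = 0.5 * (t0 + t1)
            logger.info("bisecting atrophy increment (depth %d)", depth + 1)
            pending.append((mid, t1, depth + 1))
            pending.append((t0, mid, depth + 1))
    return u


# --------------------------------------------------------------- driver

def run_simulation(mesh: LabeledMesh,
                   materials: dict[str, RegionMaterial] | None = None,
                   config: SimulationConfig | None = None,
                   spreading_params: SpreadingParams | None = None
                   ) -> SimulationResult:
    """Staggered aging simulation (healthy or AD mode).

    Per time step: advance the biomarker concentration (AD only), decay the
    per-element atrophy factor from the element-mean concentration, and at
    recording times solve mechanical equilibrium (warm-started Newton).
    Healthy mode skips the concentration problem entirely (gate = 0).
    """
    materials = materials or default_material_table()
    config = config or SimulationConfig()
    asm = _Assembler(mesh, materials)
    dim = mesh.dimension
    n_elem = mesh.n_elements

    region_mats = [materials[REGION_NAMES[r]] for r in mesh.element_region]
    region_codes = mesh.element_region
    unique_regions = np.unique(region_codes)

    ad_mode = config.mode == AD
    if ad_mode:
        spreading_params = spreading_params or SpreadingParams()
        fk = FisherKolmogorovSolver(mesh, spreading_params)
        conc = seed_concentration(mesh, spreading_params)
    else:
        conc = None

    state = AtrophyState(theta=np.ones(n_elem))
    u = np.zeros((mesh.n_nodes, dim))
    log: list = []

    times = [0.0]
    displacements = [u.copy()]
    thetas = [state.theta.copy()]
    concentrations = [conc.values.copy() if conc is not None else None]
    state.commit(0.0)

    n_steps = int(round(config.t_end / config.dt)) if config.t_end > 0 else 0
    theta_at_last_solve = state.theta.copy()
    for step in range(1, n_steps + 1):
        t = step * config.dt
        if ad_mode:
            conc = fk.step(conc, config.dt)
            c_elem = conc.values[mesh.simplices].mean(axis=1)
        else:
            c_elem = np.zeros(n_elem)

        new_theta = state.theta.copy()
        for rid in unique_regions:
            mat = materials[REGION_NAMES[rid]]
            if not mat.atrophying:
                continue
            idx = region_codes == rid
            if ad_mode:
                new_theta[idx] = update_atrophy_factor(
                    state.theta[idx], c_elem[idx], config.dt, mat,
                    beta=config.beta, floor=config.theta_floor)
            else:
                # healthy aging: gate gamma = 0, plain linear decay
                new_theta[idx] = np.maximum(
                    state.theta[idx] - mat.G_h * config.dt,
                    config.theta_floor)
        state.theta = new_theta
        state.commit(t)

        if step % config.output_every == 0 or step == n_steps:
            u = _solve_with_substepping(mesh, theta_at_last_solve,
                                        state.theta, materials, u, config,
                                        asm, log)
            theta_at_last_solve = state.theta.copy()
            times.append(t)
            displacements.append(u.copy())
            thetas.append(state.theta.copy())
            concentrations.append(conc.values.copy() if ad_mode else None)

    return SimulationResult(
        mesh=mesh, mode=config.mode, times=np.asarray(times),
        displacements=displacements, thetas=thetas,
        concentrations=concentrations, convergence_log=log)


def region_volume_series(result: SimulationResult) -> pd.DataFrame:
    """Deformed per-region volumes at every recorded time."""
    rows = []
    for k, t in enumerate(result.times):
        coords = result.deformed_coords(k)
        vols = np.abs(result.mesh.element_volumes(coords))
        for rid in np.unique(result.mesh.element_region):
            idx = result.mesh.element_region == rid
            rows.append({"time": float(t), "region": REGION_NAMES[rid],
                         "volume": float(vols[idx].sum())})
    return pd.DataFrame(rows)
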