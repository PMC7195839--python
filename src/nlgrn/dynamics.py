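"""Bilinear ODE dynamics on an inferred network and the fit-error statistic.

Each gene's rate is a sum of linear contributions from its gene regulators,
bilinear contributions from its product-term (NLT) regulators and first-order
degradation:

    dx_i/dt = sum_j alpha_ij x_j + sum_(j,k) beta_ijk x_j x_k - k_i x_i

States are not clipped to non-negative values; the model has no positivity
guarantee.  Unstable parameter sets are handled by a divergence bound so
that perturbation sweeps terminate cleanly instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import (
    DataError,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    TimeGrid,
)

__all__ = [
    "Trajectory",
    "CompiledModel",
    "compile_model",
    "rhs",
    "simulate",
    "simulation_error",
    "trajectory_as_dataset",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

# looser tolerances for bulk parameter sweeps (fitting, perturbation runs)
SWEEP_RTOL = 1e-6
SWEEP_ATOL = 1e-8

STATUS_OK = "ok"
STATUS_DIVERGED = "diverged"
STATUS_SOLVER_FAILURE = "solver_failure"


@dataclass
class Trajectory:
    grid: TimeGrid
    values: np.ndarray  # m x M, NaN-padded past a divergence point
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class CompiledModel:
    """Index-array form of sparse model parameters for fast evaluation."""

    m: int
    gene_names: tuple
    A: np.ndarray          # dense m x m linear coefficient matrix (alpha)
    beta_t: np.ndarray     # target index per bilinear term
    beta_j: np.ndarray
    beta_k: np.ndarray
    beta_c: np.ndarray
    k: np.ndarray          # degradation rates

    def __call__(self, t, x):
        f = self.A @ x - self.k * x
        if self.beta_c.size:
            contrib = self.beta_c * x[self.beta_j] * x[self.beta_k]
            f += np.bincount(self.beta_t, weights=contrib, minlength=self.m)
        return f


def compile_model(params: ModelParameters, net: InferredNetwork) -> CompiledModel:
    idx = {g: i for i, g in enumerate(net.gene_names)}
    m = net.m
    A = np.zeros((m, m))
    for (tgt, src), v in params.alpha.items():
        A[idx[tgt], idx[src]] = v
    bt, bj, bk, bc = [], [], [], []
    for (tgt, (a, b)), v in params.beta.items():
        bt.append(idx[tgt])
        bj.append(idx[a])
        bk.append(idx[b])
        bc.append(v)
    k = np.zeros(m)
    for g, v in params.degradation.items():
        k[idx[g]] = v
    return CompiledModel(
        m=m,
        gene_names=net.gene_names,
        A=A,
        beta_t=np.asarray(bt, dtype=int),
        beta_j=np.asarray(bj, dtype=int),
        beta_k=np.asarray(bk, dtype=int),
        beta_c=np.asarray(bc, dtype=float),
        k=k,
    )


def rhs(params: ModelParameters, net: InferredNetwork, x: np.ndarray) -> np.ndarray:
    """Derivative vector of the model at state ``x`` (gene order of ``net``)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.m,):
        raise DataError(f"state vector must have length {net.m}")
    return compile_model(params, net)(0.0, x)


def simulate(
    params: ModelParameters,
    net: InferredNetwork,
    x0: np.ndarray,
    grid: TimeGrid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    divergence_bound: float = np.inf,
    _model: CompiledModel | None = None,
) -> Trajectory:
    """Integrate the model over the grid with adaptive stepping.

    Any state exceeding ``divergence_bound`` in magnitude terminates the
    integration with status ``diverged``.  Solver failures are reported as a
    status, never raised, so that parameter sweeps can proceed.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise DataError("initial state contains non-finite values")
    model = _model if _model is not None else compile_model(params, net)
    if x0.shape != (model.m,):
        raise DataError(f"initial state must have length {model.m}")
    times = grid.as_array()
    values = np.full((model.m, times.size), np.nan)
    values[:, 0] = x0

    events = None
    if np.isfinite(divergence_bound):

        def _blowup(t, x):
            return np.max(np.abs(x)) - divergence_bound

        _blowup.terminal = True
        _blowup.direction = 1.0
        events = [_blowup]

    for method in ("RK45", "LSODA"):
        try:
            sol = solve_ivp(
                model,
                (times[0], times[-1]),
                x0,
                t_eval=times,
                method=method,
                rtol=rtol,
                atol=atol,
                events=events,
            )
        except Exception:
            continue
        if sol.status == 1:  # terminated by the divergence event
            got = sol.y.shape[1]
            values[:, :got] = sol.y
            return Trajectory(grid, values, STATUS_DIVERGED)
        if sol.success:
            y = sol.y
            if y.shape[1] != times.size or not np.all(np.isfinite(y)):
                return Trajectory(grid, values, STATUS_SOLVER_FAILURE)
            if np.max(np.abs(y)) > divergence_bound:
                values[:, : y.shape[1]] = y
                return Trajectory(grid, values, STATUS_DIVERGED)
            return Trajectory(grid, y, STATUS_OK)
    return Trajectory(grid, values, STATUS_SOLVER_FAILURE)


def simulation_error(traj: Trajectory, ds: GeneExpressionDataset) -> float:
    """Root total squared deviation between trajectory and observations.

    ``sqrt(sum_i sum_j (x_ij - x*_ij)^2)`` — no normalization by the number
    of genes or time points.  A diverged or failed trajectory yields +inf
    (inspect ``traj.status`` for the reason).
    """
    if traj.grid.times != ds.grid.times:
        raise DataError("trajectory and dataset grids differ")
    if traj.values.shape != ds.values.shape:
        raise DataError("trajectory and dataset shapes differ")
    if not traj.ok:
        return float("inf")
    return float(np.sqrt(np.sum((ds.values - traj.values) ** 2)))


def trajectory_as_dataset(traj: Trajectory, gene_names) -> GeneExpressionDataset:
    """Export a successful trajectory in the expression-table shape.

    Simulated values may dip below zero, which the expression container
    forbids; such trajectories must be exported by other means.
    """
    if not traj.ok:
        raise DataError(f"cannot export a trajectory with status {traj.status!r}")
    return GeneExpressionDataset(tuple(gene_names), traj.grid, traj.values)
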