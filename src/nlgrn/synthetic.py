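"""Ground-truth network, parameter and noisy time-course generation.

Produces benchmark fixtures shaped like a microarray differentiation time
course: a random sparse DAG of gene regulations plus product-term (NLT)
regulations, bilinear-ODE parameters, and replicate datasets on a dense-early
sampling schedule over one week (30 points), averaged like repeated
experiments.  Noise is multiplicative log-normal, since intensity data are
positive with roughly scale-proportional scatter.

Everything is deterministic per seed; parameterizations whose noise-free
trajectory diverges or leaves the positive orthant are rejected and
resampled so that generated fixtures are always valid expression datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    DataError,
    GeneEdge,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    NltEdge,
    TimeGrid,
    average_replicates,
    enumerate_nlts,
)
from .dynamics import simulate

__all__ = [
    "SyntheticSpec",
    "reference_time_grid",
    "generate_network",
    "generate_dataset",
    "generate_benchmark",
    "TruthRecord",
]

GRID_SPAN_HOURS = 168.0


def reference_time_grid() -> TimeGrid:
    """The 30-point week-long schedule used for benchmark data.

    Start of observation, then every 2 h over the first day (12 points),
    every 3 h over the second day (8 points), every 4 h over the third day
    (6 points), every 24 h until the fifth day (2 points), and the seventh
    day (1 point).
    """
    times = (
        [0.0]
        + [float(t) for t in range(2, 25, 2)]      # 2..24 h, 12 points
        + [float(t) for t in range(27, 49, 3)]     # 27..48 h, 8 points
        + [float(t) for t in range(52, 73, 4)]     # 52..72 h, 6 points
        + [96.0, 120.0]                            # day 4 and day 5
        + [168.0]                                  # day 7
    )
    return TimeGrid(tuple(times))


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and sampling knobs for one synthetic benchmark instance.

    Coefficient ranges are magnitudes; each sampled coefficient gets an
    independent random sign.  Defaults keep the dynamics stable over a
    168-hour horizon (linear/bilinear strengths of order a few divided by
    the grid span).
    """

    m: int = 6
    m1: int = 8
    n1: int = 5
    alpha_range: tuple = (0.5 / GRID_SPAN_HOURS, 3.0 / GRID_SPAN_HOURS)
    beta_range: tuple = (0.5 / GRID_SPAN_HOURS, 3.0 / GRID_SPAN_HOURS)
    degradation_range: tuple = (0.01, 0.05)
    x0_range: tuple = (0.5, 2.0)
    noise_sd: float = 0.05
    replicates: int = 3
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self):
        if self.m < 2:
            raise DataError("need at least 2 genes")
        if self.n1 > self.m1:
            raise DataError(f"n1={self.n1} must not exceed m1={self.m1}")
        if self.m1 > self.m * (self.m - 1) // 2:
            raise DataError(
                f"m1={self.m1} exceeds the {self.m * (self.m - 1) // 2} "
                "orientable gene pairs"
            )
        n = self.m * (self.m - 1) // 2
        if self.n1 > self.m * n:
            raise DataError(f"n1={self.n1} exceeds the {self.m * n} gene-NLT pairs")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise DataError("need at least 1 replicate")
        for name in ("alpha_range", "beta_range", "degradation_range", "x0_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi):
                raise DataError(f"{name} must be a finite non-negative range")

    def gene_names(self) -> tuple:
        return tuple(f"G{i + 1}" for i in range(self.m))


@dataclass
class TruthRecord:
    """Ground truth bundled with a generated dataset."""

    network: InferredNetwork
    params: ModelParameters
    x0: np.ndarray
    noise_free: np.ndarray  # m x M trajectory the replicates were built from


def _signed_uniform(rng, lo, hi, size):
    mag = rng.uniform(lo, hi, size)
    sign = rng.choice([-1.0, 1.0], size)
    return mag * sign


def _sample_structure(spec: SyntheticSpec, rng):
    names = spec.gene_names()
    order = rng.permutation(spec.m)
    ordered_pairs = [
        (order[i], order[j]) for i in range(spec.m) for j in range(i + 1, spec.m)
    ]
    picks = rng.choice(len(ordered_pairs), size=spec.m1, replace=False)
    gene_edges = tuple(
        GeneEdge(names[ordered_pairs[p][0]], names[ordered_pairs[p][1]])
        for p in sorted(picks)
    )
    nlts = enumerate_nlts(spec.m)
    nlt_pairs = [(i, p) for i in range(spec.m) for p in range(len(nlts))]
    picks = rng.choice(len(nlt_pairs), size=spec.n1, replace=False)
    nlt_edges = tuple(
        NltEdge(
            (names[nlts[p][0]], names[nlts[p][1]]),
            names[i],
        )
        for i, p in (nlt_pairs[q] for q in sorted(picks))
    )
    return InferredNetwork(names, gene_edges, nlt_edges)


def _sample_params(net: InferredNetwork, spec: SyntheticSpec, rng) -> ModelParameters:
    alpha = {
        (e.target, e.source): float(v)
        for e, v in zip(
            net.gene_edges,
            _signed_uniform(rng, *spec.alpha_range, net.m1),
        )
    }
    beta = {
        (e.target, e.source): float(v)
        for e, v in zip(
            net.nlt_edges,
            _signed_uniform(rng, *spec.beta_range, net.n1),
        )
    }
    k = {
        g: float(v)
        for g, v in zip(net.gene_names, rng.uniform(*spec.degradation_range, net.m))
    }
    return ModelParameters(alpha=alpha, beta=beta, degradation=k)


def generate_network(spec: SyntheticSpec, grid: TimeGrid | None = None):
    """Sample a ground-truth network, parameters and initial state.

    Rejects (and resamples) draws whose noise-free trajectory on the grid
    diverges, fails, or leaves the strictly positive orthant, so generated
    fixtures always yield valid expression data.

    Returns ``(network, params, x0)``.
    """
    if grid is None:
        grid = reference_time_grid()
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        net = _sample_structure(spec, rng)
        params = _sample_params(net, spec, rng)
        x0 = rng.uniform(*spec.x0_range, spec.m)
        traj = simulate(params, net, x0, grid,
                        divergence_bound=1e6 * float(np.max(x0)))
        if traj.ok and np.all(traj.values > 0):
            return net, params, x0
    raise DataError(
        f"no stable positive parameterization found in {spec.max_attempts} "
        "attempts; widen degradation_range or shrink coefficient ranges"
    )


def generate_dataset(
    net: InferredNetwork,
    params: ModelParameters,
    x0: np.ndarray,
    grid: TimeGrid,
    spec: SyntheticSpec,
):
    """Simulate the truth and emit noisy replicates plus their average.

    Replicate r multiplies every noise-free value by ``exp(sd * Z)`` with
    independent standard-normal Z, so all outputs stay strictly positive.

    Returns ``(averaged dataset, list of replicate datasets, TruthRecord)``.
    """
    traj = simulate(params, net, x0, grid,
                    divergence_bound=1e6 * max(1.0, float(np.max(x0))))
    if not traj.ok:
        raise DataError(f"truth simulation failed with status {traj.status!r}")
    if np.any(traj.values <= 0):
        raise DataError("truth trajectory leaves the positive orthant")
    rng = np.random.default_rng([spec.seed, 10_000])
    reps = []
    for _ in range(spec.replicates):
        noise = np.exp(spec.noise_sd * rng.standard_normal(traj.values.shape))
        reps.append(
            GeneExpressionDataset(net.gene_names, grid, traj.values * noise)
        )
    avg = average_replicates(reps)
    truth = TruthRecord(network=net, params=params, x0=np.asarray(x0, float),
                        noise_free=traj.values.copy())
    return avg, reps, truth


def generate_benchmark(spec: SyntheticSpec, grid: TimeGrid | None = None):
    """Convenience wrapper: sample truth and data in one call.

    Returns ``(averaged dataset, replicates, TruthRecord)``.
    """
    if grid is None:
        grid = reference_time_grid()
    net, params, x0 = generate_network(spec, grid)
    return generate_dataset(net, params, x0, grid, spec)
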