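"""Genetic-algorithm estimation of model coefficients on a fixed support.

A real-coded elitist GA (tournament selection, blend/uniform crossover,
per-coordinate Gaussian mutation clipped to bounds) minimizes the root total
squared deviation between simulated and observed expression.  The classic
protocol — population 300, 1000 generations, 200 random restarts, keep the
ten best — is preserved as the default configuration; desk-scale presets
shrink those numbers for tests.

The parameter vector is laid out as: one linear coefficient per gene edge
(network order), one product coefficient per NLT edge (network order), one
degradation rate per gene (gene-name order).  Each class has its own box
bounds.

By default the data are normalized per gene by that gene's maximum before
fitting (positive scaling preserves the sign pattern of recovered
coefficients); the reported error is computed on the normalized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    DataError,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
)
from .dynamics import (
    SWEEP_ATOL,
    SWEEP_RTOL,
    CompiledModel,
    compile_model,
    simulate,
)

__all__ = [
    "GAConfig",
    "FitResult",
    "ga_fit",
    "multi_start",
    "normalize_dataset",
    "evaluate_parameters",
    "desk_scale_config",
]

DIVERGENCE_FACTOR = 1e6  # divergence bound = factor * max observed value


@dataclass(frozen=True)
class GAConfig:
    generations: int = 1000
    population: int = 300
    alpha_bounds: tuple = (-3.0, 3.0)
    beta_bounds: tuple = (-3.0, 3.0)
    k_bounds: tuple = (0.0, 1.0)
    n_restarts: int = 200
    top_k: int = 10
    base_seed: int = 0
    crossover_rate: float = 0.7
    mutation_rate: float | None = None  # default 1 / n_params
    mutation_sigma_frac: float = 0.1    # mutation sd as a fraction of the box width
    mutation_sigma_final: float = 0.003  # annealed down to this fraction by the end
    elitism_fraction: float = 0.1
    tournament_size: int = 3
    normalize: str = "per_gene_max"     # none | per_gene_max | zscore
    rtol: float = SWEEP_RTOL
    atol: float = SWEEP_ATOL

    def __post_init__(self):
        for name in ("alpha_bounds", "beta_bounds", "k_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DataError(f"{name}: lower bound must be below upper bound")
        if self.k_bounds[0] < 0:
            raise DataError("degradation lower bound must be >= 0")
        if self.population < 4:
            raise DataError("population must be at least 4")
        if self.normalize not in ("none", "per_gene_max", "zscore"):
            raise DataError(f"unknown normalize mode {self.normalize!r}")


def desk_scale_config(**overrides) -> GAConfig:
    """Scaled-down settings for tests and desk runs."""
    base = dict(
        generations=150, population=50, n_restarts=5, top_k=3, base_seed=0
    )
    base.update(overrides)
    return GAConfig(**base)


@dataclass
class FitResult:
    params: ModelParameters
    error: float
    seed: int
    generations_run: int


def _normalized_values(ds: GeneExpressionDataset, mode: str) -> np.ndarray:
    """Normalized value matrix for fitting (may contain negatives for zscore)."""
    if mode == "none":
        return ds.values.copy()
    if mode == "per_gene_max":
        mx = ds.values.max(axis=1)
        if np.any(mx <= 0):
            bad = [g for g, v in zip(ds.gene_names, mx) if v <= 0]
            raise DataError(f"per_gene_max normalization needs positive rows: {bad}")
        return ds.values / mx[:, None]
    if mode == "zscore":
        mu = ds.values.mean(axis=1)
        sd = ds.values.std(axis=1, ddof=1)
        if np.any(sd <= 0):
            bad = [g for g, v in zip(ds.gene_names, sd) if v <= 0]
            raise DataError(f"zscore normalization needs non-constant rows: {bad}")
        return (ds.values - mu[:, None]) / sd[:, None]
    raise DataError(f"unknown normalize mode {mode!r}")


def normalize_dataset(ds: GeneExpressionDataset, mode: str) -> GeneExpressionDataset:
    """Normalized copy of a dataset (``none`` or ``per_gene_max``).

    Z-scored data can be negative, which the expression container rejects;
    the fitting path applies that mode internally on raw arrays instead.
    """
    if mode == "zscore":
        raise DataError(
            "zscore produces negative values; it is available inside ga_fit "
            "only (the expression container requires non-negative data)"
        )
    return GeneExpressionDataset(ds.gene_names, ds.grid, _normalized_values(ds, mode))


# ---------------------------------------------------------------------------
# vector <-> ModelParameters
# ---------------------------------------------------------------------------


def _layout(net: InferredNetwork):
    alpha_keys = [(e.target, e.source) for e in net.gene_edges]
    beta_keys = [(e.target, e.source) for e in net.nlt_edges]
    return alpha_keys, beta_keys, list(net.gene_names)


def _vector_to_params(vec, net: InferredNetwork) -> ModelParameters:
    alpha_keys, beta_keys, genes = _layout(net)
    na, nb = len(alpha_keys), len(beta_keys)
    alpha = dict(zip(alpha_keys, (float(v) for v in vec[:na])))
    beta = dict(zip(beta_keys, (float(v) for v in vec[na: na + nb])))
    kvals = {}
    for g, v in zip(genes, vec[na + nb:]):
        v = float(v)
        if v == 0.0:
            warnings.warn(
                f"degradation rate for {g!r} fitted at exactly 0; nudged to 1e-9",
                stacklevel=2,
            )
            v = 1e-9
        kvals[g] = v
    return ModelParameters(alpha=alpha, beta=beta, degradation=kvals)


def _bounds_arrays(net: InferredNetwork, cfg: GAConfig):
    na, nb, m = net.m1, net.n1, net.m
    lo = np.concatenate(
        [
            np.full(na, cfg.alpha_bounds[0]),
            np.full(nb, cfg.beta_bounds[0]),
            np.full(m, cfg.k_bounds[0]),
        ]
    )
    hi = np.concatenate(
        [
            np.full(na, cfg.alpha_bounds[1]),
            np.full(nb, cfg.beta_bounds[1]),
            np.full(m, cfg.k_bounds[1]),
        ]
    )
    return lo, hi


def _make_objective(net: InferredNetwork, ds: GeneExpressionDataset, cfg: GAConfig):
    """Closure evaluating the fit error of a raw parameter vector."""
    values = _normalized_values(ds, cfg.normalize)
    grid = ds.grid
    x0 = values[:, 0].copy()
    bound = DIVERGENCE_FACTOR * float(np.max(np.abs(values)))
    alpha_keys, beta_keys, genes = _layout(net)
    template = compile_model(
        ModelParameters(
            alpha={key: 0.0 for key in alpha_keys},
            beta={key: 0.0 for key in beta_keys},
            degradation={g: 1.0 for g in net.gene_names},
        ),
        net,
    )
    idx = {g: i for i, g in enumerate(net.gene_names)}
    a_rows = np.array([idx[t] for t, _ in alpha_keys], dtype=int)
    a_cols = np.array([idx[s] for _, s in alpha_keys], dtype=int)
    na, nb = len(alpha_keys), len(beta_keys)

    def objective(vec) -> float:
        model = CompiledModel(
            m=template.m,
            gene_names=template.gene_names,
            A=template.A.copy(),
            beta_t=template.beta_t,
            beta_j=template.beta_j,
            beta_k=template.beta_k,
            beta_c=np.asarray(vec[na: na + nb], dtype=float),
            k=np.asarray(vec[na + nb:], dtype=float),
        )
        if na:
            model.A[a_rows, a_cols] = vec[:na]
        traj = simulate(
            None,
            net,
            x0,
            grid,
            rtol=cfg.rtol,
            atol=cfg.atol,
            divergence_bound=bound,
            _model=model,
        )
        if not traj.ok:
            return float("inf")
        return float(np.sqrt(np.sum((values - traj.values) ** 2)))

    return objective, values


def _make_batch_objective(net: InferredNetwork, ds: GeneExpressionDataset, cfg: GAConfig):
    """Vectorized fitness: all individuals integrated as one stacked system.

    Stacking the population into a single ODE amortizes the per-call solver
    overhead.  Individuals whose state exceeds the divergence bound are
    frozen (zero derivative) and reported as +inf, so one unstable draw
    cannot stall the batch.  The common adaptive step couples the
    individuals' error control, so batch fitness is a slightly coarser
    evaluation than the single-trajectory path; the final reported result is
    always re-scored with the exact objective.
    """
    from scipy.integrate import solve_ivp

    values = _normalized_values(ds, cfg.normalize)
    times = ds.grid.as_array()
    x0_single = values[:, 0].copy()
    bound = DIVERGENCE_FACTOR * float(np.max(np.abs(values)))
    alpha_keys, beta_keys, genes = _layout(net)
    idx = {g: i for i, g in enumerate(net.gene_names)}
    a_rows = np.array([idx[t] for t, _ in alpha_keys], dtype=int)
    a_cols = np.array([idx[s] for _, s in alpha_keys], dtype=int)
    b_t = np.array([idx[t] for t, _ in beta_keys], dtype=int)
    b_j = np.array([idx[a] for _, (a, _b) in beta_keys], dtype=int)
    b_k = np.array([idx[b] for _, (_a, b) in beta_keys], dtype=int)
    na, nb, m = len(alpha_keys), len(beta_keys), net.m

    def batch(pop: np.ndarray) -> np.ndarray:
        P = pop.shape[0]
        A = np.zeros((P, m, m))
        if na:
            A[:, a_rows, a_cols] = pop[:, :na]
        beta_c = pop[:, na: na + nb]
        k = pop[:, na + nb:]
        frozen = np.zeros(P, dtype=bool)

        def fun(t, z):
            x = z.reshape(P, m)
            over = np.max(np.abs(x), axis=1) > bound
            if over.any():
                frozen[over] = True
            f = np.einsum("pij,pj->pi", A, x) - k * x
            for q in range(nb):
                f[:, b_t[q]] += beta_c[:, q] * x[:, b_j[q]] * x[:, b_k[q]]
            if frozen.any():
                f[frozen] = 0.0
            return f.ravel()

        z0 = np.tile(x0_single, P)
        try:
            sol = solve_ivp(fun, (times[0], times[-1]), z0, t_eval=times,
                            method="RK45", rtol=cfg.rtol, atol=cfg.atol)
        except Exception:
            sol = None
        errors = np.full(P, np.inf)
        if sol is not None and sol.success and sol.y.shape[1] == times.size:
            traj = sol.y.reshape(P, m, times.size)
            with np.errstate(over="ignore", invalid="ignore"):
                res = np.sqrt(np.sum((traj - values[None]) ** 2, axis=(1, 2)))
            good = (
                ~frozen
                & np.all(np.isfinite(traj), axis=(1, 2))
                & (np.max(np.abs(traj), axis=(1, 2)) <= bound)
            )
            errors[good] = res[good]
        return errors

    return batch


def evaluate_parameters(
    net: InferredNetwork,
    ds: GeneExpressionDataset,
    params: ModelParameters,
    cfg: GAConfig = GAConfig(),
) -> float:
    """Fit error of a parameter set under the config's normalization.

    This is the same quantity the GA minimizes; use it to re-check a
    reported :class:`FitResult` independently of the optimizer.
    """
    values = _normalized_values(ds, cfg.normalize)
    x0 = values[:, 0]
    bound = DIVERGENCE_FACTOR * float(np.max(np.abs(values)))
    traj = simulate(
        params, net, x0, ds.grid, rtol=cfg.rtol, atol=cfg.atol,
        divergence_bound=bound,
    )
    if not traj.ok:
        return float("inf")
    return float(np.sqrt(np.sum((values - traj.values) ** 2)))


# ---------------------------------------------------------------------------
# the GA proper
# ---------------------------------------------------------------------------


def ga_fit(
    net: InferredNetwork,
    ds: GeneExpressionDataset,
    cfg: GAConfig = GAConfig(),
    seed: int = 0,
) -> FitResult:
    """Minimize the fit error over the box bounds with one GA run.

    Deterministic given ``seed``; elitism makes the best-so-far error
    non-increasing across generations.  Diverged or failed simulations get
    +inf fitness.
    """
    if ds.grid.count < 3:
        raise DataError("need at least 3 time points for fitting")
    objective, _ = _make_objective(net, ds, cfg)
    batch = _make_batch_objective(net, ds, cfg)

    def evaluate(pop):
        errors = batch(pop)
        if not np.any(np.isfinite(errors)):
            # batched solve degenerated: fall back to exact per-individual path
            errors = np.array([objective(ind) for ind in pop])
        return errors

    lo, hi = _bounds_arrays(net, cfg)
    n_params = lo.size
    rng = np.random.default_rng(seed)
    pop = rng.uniform(lo, hi, size=(cfg.population, n_params))
    fitness = evaluate(pop)
    if not np.any(np.isfinite(fitness)):
        raise DataError(
            "every individual of the initial population diverged; "
            "try narrower degradation (k) bounds or a larger lower bound"
        )
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_params
    sigma0 = cfg.mutation_sigma_frac * (hi - lo)
    anneal = cfg.mutation_sigma_final / cfg.mutation_sigma_frac
    n_elite = max(1, int(round(cfg.elitism_fraction * cfg.population)))

    for _gen in range(cfg.generations):
        # geometric annealing: broad exploration first, fine tuning late
        sigma = sigma0 * anneal ** (_gen / max(1, cfg.generations - 1))
        order = np.argsort(fitness, kind="stable")
        elites = pop[order[:n_elite]].copy()
        elite_fit = fitness[order[:n_elite]].copy()

        n_children = cfg.population - n_elite
        # tournament selection of parents
        t = cfg.tournament_size
        draws = rng.integers(0, cfg.population, size=(2 * n_children, t))
        winners = draws[np.arange(2 * n_children), np.argmin(fitness[draws], axis=1)]
        pa = pop[winners[:n_children]].copy()
        pb = pop[winners[n_children:]]

        # crossover: blend or uniform, per pair
        do_cx = rng.random(n_children) < cfg.crossover_rate
        blend = rng.random(n_children) < 0.5
        w = rng.random((n_children, n_params))
        children = pa
        bmask = do_cx & blend
        children[bmask] = w[bmask] * pa[bmask] + (1 - w[bmask]) * pb[bmask]
        umask = do_cx & ~blend
        swap = rng.random((n_children, n_params)) < 0.5
        children[umask] = np.where(swap[umask], pb[umask], pa[umask])

        # Gaussian mutation, clipped to the box
        mmask = rng.random((n_children, n_params)) < mut_rate
        noise = rng.normal(0.0, 1.0, size=(n_children, n_params)) * sigma
        children = np.clip(children + mmask * noise, lo, hi)

        child_fit = evaluate(children)
        pop = np.vstack([elites, children])
        fitness = np.concatenate([elite_fit, child_fit])

    # re-score the leading individuals with the exact single-trajectory
    # objective: the batched fitness shares one adaptive step across the
    # population, so it is a slightly coarser measure
    order = np.argsort(fitness, kind="stable")[: max(3, n_elite)]
    exact = [(float(objective(pop[i])), int(i)) for i in order]
    best_err, best = min(exact)
    params = _vector_to_params(pop[best], net)
    return FitResult(
        params=params,
        error=best_err,
        seed=seed,
        generations_run=cfg.generations,
    )


def multi_start(
    net: InferredNetwork,
    ds: GeneExpressionDataset,
    cfg: GAConfig = GAConfig(),
):
    """Independent restarts with seeds ``base_seed + i``; keep the best.

    Returns the ``top_k`` results sorted by error ascending.
    """
    results = [
        ga_fit(net, ds, cfg, seed=cfg.base_seed + i) for i in range(cfg.n_restarts)
    ]
    results.sort(key=lambda r: (r.error, r.seed))
    return results[: cfg.top_k]
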