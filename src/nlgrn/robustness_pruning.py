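"""Perturbation-robustness statistics and greedy edge-deletion pruning.

Robustness of a fitted model is measured by perturbing its parameters
multiplicatively, ``theta -> theta * (1 + mu * eps)`` with ``eps`` drawn from
a standard Gaussian (or a uniform), re-simulating, and summarizing the root
total squared displacement of each perturbed trajectory from the unperturbed
one: the mean over draws is the robust average (RA) and the sample standard
deviation (divisor N-1) is the robust spread (RSTD).  Smaller is more robust.

Pruning greedily deletes regulations whose removal (coefficient zeroed, no
refit by default) least changes the fit error: first product-term (NLT)
edges, then gene-gene edges.  When no single removal moves the error
noticeably, a small batch is removed as one step.  Deletion stops when the
best candidate would make BOTH the fit error and RA worse than the original
model by more than a tolerance factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import (
    DataError,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    remove_edges,
)
from .dynamics import SWEEP_ATOL, SWEEP_RTOL, simulate, simulation_error
from .estimation import DIVERGENCE_FACTOR, GAConfig, ga_fit

__all__ = [
    "RobustnessConfig",
    "RobustnessReport",
    "DeletionStep",
    "DeletionTrace",
    "PruneConfig",
    "perturb",
    "robustness",
    "score_removal",
    "greedy_prune",
    "replay_removals",
    "trace_to_csv",
]


@dataclass(frozen=True)
class RobustnessConfig:
    mu: float = 0.4
    n_perturb: int = 5000
    noise: str = "normal"               # normal | uniform (uniform on [-1, 1])
    targets: str = "all_parameters"     # all_parameters | degradation_only
    seed: int = 0
    rtol: float = SWEEP_RTOL
    atol: float = SWEEP_ATOL

    def __post_init__(self):
        if self.mu < 0:
            raise DataError("mu must be >= 0")
        if self.n_perturb < 1:
            raise DataError("n_perturb must be >= 1")
        if self.noise not in ("normal", "uniform"):
            raise DataError(f"unknown noise kind {self.noise!r}")
        if self.targets not in ("all_parameters", "degradation_only"):
            raise DataError(f"unknown perturbation target {self.targets!r}")


@dataclass
class RobustnessReport:
    RA: float
    RSTD: float
    distances: np.ndarray   # per successful perturbation
    n_failed: int

    @property
    def n_success(self) -> int:
        return int(self.distances.size)


@dataclass
class DeletionStep:
    label: str
    removed_gene_edges: tuple = ()
    removed_nlt_edges: tuple = ()
    SE: float = float("nan")
    RA: float = float("nan")
    RSTD: float = float("nan")

    @property
    def n_removed(self) -> int:
        return len(self.removed_gene_edges) + len(self.removed_nlt_edges)

    def describe_removed(self) -> str:
        parts = [f"{a}:{b} -> {t}" for (a, b), t in self.removed_nlt_edges]
        parts += [f"{s} -> {t}" for s, t in self.removed_gene_edges]
        return "; ".join(parts) if parts else "N/A"


@dataclass
class DeletionTrace:
    steps: tuple
    final_network: InferredNetwork
    final_params: ModelParameters

    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)


@dataclass(frozen=True)
class PruneConfig:
    tau: float = 0.10          # "much worse" tolerance on SE and RA
    delta: float = 1e-4        # SE-change threshold that triggers batching
    batch_max: int = 3
    screen_n: int = 500        # perturbation draws while screening candidates
    refit: bool = False        # rerun a short GA after each permanent removal
    refit_config: GAConfig | None = None
    max_steps: int = 100


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def _draw_eps(rng, cfg: RobustnessConfig, size: int) -> np.ndarray:
    if cfg.noise == "normal":
        return rng.standard_normal(size)
    return rng.uniform(-1.0, 1.0, size)


def perturb(params: ModelParameters, cfg: RobustnessConfig, rng) -> ModelParameters:
    """One multiplicative perturbation of the targeted parameters.

    Each targeted value theta becomes ``theta * (1 + mu * eps)`` with an
    independent draw per parameter.  Values are not clipped: a perturbed
    degradation rate may go non-positive, in which case the downstream
    simulation's divergence handling applies.
    """
    all_targets = cfg.targets == "all_parameters"
    alpha = dict(params.alpha)
    beta = dict(params.beta)
    if all_targets:
        keys = sorted(alpha)
        eps = _draw_eps(rng, cfg, len(keys))
        for key, e in zip(keys, eps):
            alpha[key] = alpha[key] * (1.0 + cfg.mu * e)
        keys = sorted(beta)
        eps = _draw_eps(rng, cfg, len(keys))
        for key, e in zip(keys, eps):
            beta[key] = beta[key] * (1.0 + cfg.mu * e)
    k = dict(params.degradation)
    keys = sorted(k)
    eps = _draw_eps(rng, cfg, len(keys))
    for key, e in zip(keys, eps):
        k[key] = k[key] * (1.0 + cfg.mu * e)
    out = ModelParameters.__new__(ModelParameters)
    out.alpha = alpha
    out.beta = beta
    out.degradation = k  # bypass validation: perturbed k may be <= 0 by design
    return out


def robustness(
    net: InferredNetwork,
    params: ModelParameters,
    ds: GeneExpressionDataset,
    cfg: RobustnessConfig = RobustnessConfig(),
) -> RobustnessReport:
    """Monte-Carlo robustness of a parameter set.

    Simulates once unperturbed from the dataset's first time point, then for
    each of ``n_perturb`` draws simulates the perturbed model and records the
    root total squared displacement from the *unperturbed simulation* (not
    the data).  Failed or diverged perturbed runs are excluded and counted.
    """
    x0 = ds.values[:, 0]
    bound = DIVERGENCE_FACTOR * float(np.max(ds.values))
    base = simulate(
        params, net, x0, ds.grid, rtol=cfg.rtol, atol=cfg.atol,
        divergence_bound=bound,
    )
    if not base.ok:
        raise DataError(f"baseline simulation failed with status {base.status!r}")
    rng = np.random.default_rng(cfg.seed)
    dists = []
    n_failed = 0
    for _ in range(cfg.n_perturb):
        p = perturb(params, cfg, rng)
        traj = simulate(
            p, net, x0, ds.grid, rtol=cfg.rtol, atol=cfg.atol,
            divergence_bound=bound,
        )
        if not traj.ok:
            n_failed += 1
            continue
        dists.append(float(np.sqrt(np.sum((traj.values - base.values) ** 2))))
    dists = np.asarray(dists)
    if dists.size == 0:
        return RobustnessReport(RA=float("inf"), RSTD=float("inf"),
                                distances=dists, n_failed=n_failed)
    ra = float(np.mean(dists))
    rstd = float(np.std(dists, ddof=1)) if dists.size > 1 else 0.0
    return RobustnessReport(RA=ra, RSTD=rstd, distances=dists, n_failed=n_failed)


# ---------------------------------------------------------------------------
# edge deletion
# ---------------------------------------------------------------------------


def _restrict_params(params: ModelParameters, net: InferredNetwork) -> ModelParameters:
    """Drop coefficients whose edges are no longer in the network."""
    gene_keys = {(e.target, e.source) for e in net.gene_edges}
    nlt_keys = {(e.target, frozenset(e.source)) for e in net.nlt_edges}
    alpha = {key: v for key, v in params.alpha.items() if key in gene_keys}
    beta = {
        key: v
        for key, v in params.beta.items()
        if (key[0], frozenset(key[1])) in nlt_keys
    }
    return ModelParameters(alpha=alpha, beta=beta,
                           degradation=dict(params.degradation))


def _fit_error(net, params, ds, rcfg) -> float:
    x0 = ds.values[:, 0]
    bound = DIVERGENCE_FACTOR * float(np.max(ds.values))
    traj = simulate(
        params, net, x0, ds.grid, rtol=rcfg.rtol, atol=rcfg.atol,
        divergence_bound=bound,
    )
    return simulation_error(traj, ds)


def score_removal(
    net: InferredNetwork,
    params: ModelParameters,
    ds: GeneExpressionDataset,
    gene_edges=(),
    nlt_edges=(),
    rcfg: RobustnessConfig = RobustnessConfig(),
    label: str = "DEL",
) -> DeletionStep:
    """Evaluate removing a set of edges: coefficients zeroed, no refit.

    Returns the reduced model's fit error against the data plus its RA/RSTD.
    """
    reduced_net = remove_edges(net, gene_edges=gene_edges, nlt_edges=nlt_edges)
    reduced_params = _restrict_params(params, reduced_net)
    se = _fit_error(reduced_net, reduced_params, ds, rcfg)
    rep = robustness(reduced_net, reduced_params, ds, rcfg)
    return DeletionStep(
        label=label,
        removed_gene_edges=tuple((str(s), str(t)) for s, t in gene_edges),
        removed_nlt_edges=tuple(((str(a), str(b)), str(t)) for (a, b), t in nlt_edges),
        SE=se,
        RA=rep.RA,
        RSTD=rep.RSTD,
    )


def _candidate_sets(net: InferredNetwork, phase: str):
    if phase == "nlt":
        return [((), ((e.source, e.target),)) for e in net.nlt_edges]
    return [(((e.source, e.target),), ()) for e in net.gene_edges]


def greedy_prune(
    net: InferredNetwork,
    params: ModelParameters,
    ds: GeneExpressionDataset,
    rcfg: RobustnessConfig = RobustnessConfig(),
    pcfg: PruneConfig = PruneConfig(),
) -> DeletionTrace:
    """Greedy edge deletion in two phases (NLT edges, then gene edges).

    Each iteration scores every single-edge removal in the current phase
    with a reduced number of perturbation draws; if none changes the fit
    error by more than ``delta``, up to ``batch_max`` of the smallest-change
    candidates are removed as one step.  The accepted step is re-scored at
    the full draw count.  Deletion stops when the best candidate would push
    both the fit error and RA above ``(1 + tau)`` times their starting
    values.
    """
    screen_cfg = replace(rcfg, n_perturb=min(rcfg.n_perturb, pcfg.screen_n))

    se0 = _fit_error(net, params, ds, rcfg)
    rep0 = robustness(net, params, ds, rcfg)
    steps = [DeletionStep(label="OES", SE=se0, RA=rep0.RA, RSTD=rep0.RSTD)]
    se_stop = (1.0 + pcfg.tau) * se0
    ra_stop = (1.0 + pcfg.tau) * rep0.RA

    cur_net, cur_params = net, params
    step_no = 1
    for phase in ("nlt", "gene"):
        while step_no <= pcfg.max_steps:
            candidates = _candidate_sets(cur_net, phase)
            if not candidates:
                break
            scored = []
            for gene_rm, nlt_rm in candidates:
                st = score_removal(
                    cur_net, cur_params, ds,
                    gene_edges=gene_rm, nlt_edges=nlt_rm,
                    rcfg=screen_cfg, label="screen",
                )
                scored.append((gene_rm, nlt_rm, st))
            cur_se = steps[-1].SE
            inert = all(abs(st.SE - cur_se) <= pcfg.delta for *_, st in scored)
            scored.sort(key=lambda item: (abs(item[2].SE - cur_se), item[2].RA))
            if inert and pcfg.batch_max > 1 and len(scored) > 1:
                chosen = scored[: pcfg.batch_max]
                gene_rm = tuple(e for item in chosen for e in item[0])
                nlt_rm = tuple(e for item in chosen for e in item[1])
            else:
                gene_rm, nlt_rm, _ = scored[0]
            final = score_removal(
                cur_net, cur_params, ds,
                gene_edges=gene_rm, nlt_edges=nlt_rm,
                rcfg=rcfg, label=f"DEL{step_no}",
            )
            if final.SE > se_stop and final.RA > ra_stop:
                break
            cur_net = remove_edges(cur_net, gene_edges=gene_rm, nlt_edges=nlt_rm)
            cur_params = _restrict_params(cur_params, cur_net)
            if pcfg.refit:
                fit_cfg = pcfg.refit_config or GAConfig(
                    generations=100, population=40, n_restarts=1, top_k=1
                )
                cur_params = ga_fit(cur_net, ds, fit_cfg, seed=fit_cfg.base_seed).params
                final = replace(
                    final,
                    SE=_fit_error(cur_net, cur_params, ds, rcfg),
                )
            steps.append(final)
            step_no += 1
    return DeletionTrace(steps=tuple(steps), final_network=cur_net,
                         final_params=cur_params)


def replay_removals(net: InferredNetwork, steps) -> InferredNetwork:
    """Apply the removals recorded in a sequence of deletion steps."""
    out = net
    for st in steps:
        if st.n_removed == 0:
            continue
        out = remove_edges(
            out,
            gene_edges=st.removed_gene_edges,
            nlt_edges=st.removed_nlt_edges,
        )
    return out


def trace_to_csv(trace: DeletionTrace, path) -> None:
    """Write a deletion trace as CSV with columns Model, RR, SE, RA, RSTD."""
    with open(path, "w") as fh:
        fh.write("Model,RR,SE,RA,RSTD\n")
        for st in trace.steps:
            rr = st.describe_removed().replace(",", ";")
            def fmt(x):
                return "N/A" if np.isnan(x) else f"{x:.6g}"
            fh.write(f"{st.label},{rr},{fmt(st.SE)},{fmt(st.RA)},{fmt(st.RSTD)}\n")
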