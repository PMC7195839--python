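"""Two-stage forward search over a Gaussian graphical model.

Stage 1 selects undirected gene-gene edges by greedy forward stepwise
selection: every candidate edge is scored by the deviance difference between
the constrained maximum-likelihood covariance fits with and without it
(iterative proportional scaling, IPS), referred to a chi-square distribution
with one degree of freedom.  The selected skeleton is oriented into a DAG.
Stage 2 repeats the search over gene-NLT positions, starting from the
stage-1 graph, with the number of NLT edges capped at the stage-1 edge
count; selected gene-NLT edges are directed NLT -> gene.

NLT-NLT positions are never candidates (that block of the graph stays an
identity), which keeps the constrained fit well posed even though there are
far more product terms than genes.

Notes on statistical conventions
--------------------------------
* Variables are standardized (mean 0, sample variance 1) before covariance
  assembly, so the working matrix is a correlation matrix.  Deviance
  differences are invariant to per-variable scaling; standardization only
  improves numerical conditioning of the product rows.
* Time points are treated as independent observations when scaling the
  deviance (``n_obs`` = number of time points).  This ignores temporal
  autocorrelation; p-values should be read as ranking scores rather than
  calibrated error rates on real time courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AugmentedDataset,
    DataError,
    GeneEdge,
    GeneExpressionDataset,
    InferredNetwork,
    NltEdge,
    build_augmented,
)

__all__ = [
    "EfsaError",
    "EfsaConfig",
    "CovarianceModel",
    "GraphState",
    "EdgeTest",
    "standardize",
    "sample_covariance",
    "ips_fit",
    "deviance",
    "edge_pvalue",
    "forward_search",
    "orient_genes",
    "run_efsa",
]


class EfsaError(RuntimeError):
    """Numerical failure inside the graphical-model machinery."""


@dataclass(frozen=True)
class EfsaConfig:
    cutoff: float = 0.1
    nlt_cap_mode: bool = True      # cap stage-2 edge count at the stage-1 count
    standardize: bool = True
    ips_tol: float = 1e-8
    ips_max_iter: int = 5000

    def __post_init__(self):
        if not 0 < self.cutoff < 1:
            raise DataError(f"cutoff must be in (0, 1), got {self.cutoff}")


@dataclass
class CovarianceModel:
    """Sample covariance over genes and NLTs, with the block partition."""

    matrix: np.ndarray
    m: int
    n: int
    n_obs: int

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (self.m + self.n, self.m + self.n):
            raise DataError("covariance matrix shape does not match m + n")
        if np.max(np.abs(M - M.T)) > 1e-10:
            raise DataError("covariance matrix is not symmetric")
        if np.any(np.diag(M) <= 0):
            raise DataError("covariance diagonal must be strictly positive")
        self.matrix = (M + M.T) / 2.0

    @property
    def N(self) -> int:
        return self.m + self.n

    @property
    def A(self) -> np.ndarray:
        return self.matrix[: self.m, : self.m]

    @property
    def B(self) -> np.ndarray:
        return self.matrix[: self.m, self.m:]

    @property
    def C(self) -> np.ndarray:
        return self.matrix[self.m:, self.m:]


@dataclass
class GraphState:
    """Undirected graph over m gene nodes and n NLT nodes.

    Edges are canonical ``(u, v)`` tuples with ``u < v`` over node indices
    ``0..m+n-1``; only gene-gene and gene-NLT positions are allowed.
    ``provenance`` logs permanently added edges in addition order.
    """

    m: int
    n: int = 0
    edges: frozenset = frozenset()
    provenance: tuple = ()

    @property
    def N(self) -> int:
        return self.m + self.n

    def is_allowed(self, edge) -> bool:
        u, v = edge
        if not (0 <= u < v < self.N):
            return False
        return u < self.m  # at least one endpoint must be a gene

    def with_edge(self, edge) -> "GraphState":
        edge = (min(edge), max(edge))
        if not self.is_allowed(edge):
            raise DataError(f"edge {edge} is not an allowed position")
        if edge in self.edges:
            raise DataError(f"edge {edge} already present")
        return GraphState(
            self.m, self.n, self.edges | {edge}, self.provenance + (edge,)
        )


@dataclass(frozen=True)
class EdgeTest:
    edge: tuple
    deviance_difference: float
    p_value: float


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------


def standardize(matrix: np.ndarray):
    """Scale each row to sample mean 0 and sample variance 1 (ddof=1).

    Returns ``(standardized, means, sds)``.  A zero-variance row is a hard
    error: a constant series carries no correlation information.
    """
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DataError(f"zero-variance row(s) at index {bad.tolist()}")
    Z = (X - means[:, None]) / sds[:, None]
    return Z, means, sds


def sample_covariance(matrix: np.ndarray, m: int, n_obs: int | None = None) -> CovarianceModel:
    """Unbiased sample covariance (divisor ``n_obs - 1``) with block partition."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] < 2:
        raise DataError("need at least 2 observations")
    if n_obs is None:
        n_obs = X.shape[1]
    S = np.cov(X, ddof=1)
    S = np.atleast_2d(S)
    return CovarianceModel(matrix=S, m=m, n=X.shape[0] - m, n_obs=n_obs)


# ---------------------------------------------------------------------------
# constrained MLE via iterative proportional scaling
# ---------------------------------------------------------------------------


def _newton_polish(S, edges, K, tol, max_steps=25):
    """Newton iteration on the moment-matching system for the GGM MLE.

    Unknowns are the free entries of K (diagonal + edges); constraints are
    ``Sigma(K) = S`` on those same positions.  Quadratically convergent near
    the solution, so it finishes what proportional scaling starts slowly.
    Returns ``(Sigma, K, residual)`` for the best iterate found.
    """
    N = S.shape[0]
    pa = np.concatenate([np.arange(N), np.array([e[0] for e in edges], int)]) \
        if edges else np.arange(N)
    pb = np.concatenate([np.arange(N), np.array([e[1] for e in edges], int)]) \
        if edges else np.arange(N)
    d = pa.size
    target = S[pa, pb]
    offdiag = pa != pb

    K = K.copy()
    Sigma = np.linalg.inv(K)
    res_vec = Sigma[pa, pb] - target
    best = (Sigma, K, float(np.max(np.abs(res_vec))))
    for _ in range(max_steps):
        if best[2] < tol:
            break
        # J[p, q] = d Sigma[pa_p, pb_p] / d K[pa_q, pb_q] (symmetric entries)
        Ua = Sigma[np.ix_(pa, pa)] * Sigma[np.ix_(pb, pb)]
        Ub = Sigma[np.ix_(pa, pb)] * Sigma[np.ix_(pb, pa)]
        J = -(Ua + np.where(offdiag[None, :], Ub, 0.0))
        try:
            delta = np.linalg.solve(J, -res_vec)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(10):  # damped: keep K positive definite, shrink residual
            K_new = best[1].copy()
            K_new[pa, pb] += step * delta
            K_new[pb, pa] = K_new[pa, pb]
            try:
                np.linalg.cholesky(K_new)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            Sigma_new = np.linalg.inv(K_new)
            r_new = Sigma_new[pa, pb] - target
            if np.max(np.abs(r_new)) < best[2]:
                best = (Sigma_new, K_new, float(np.max(np.abs(r_new))))
                Sigma, res_vec = Sigma_new, r_new
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return best


def _ips(S, edges, tol, max_iter, warm_K=None):
    """Fit the GGM MLE by clique-wise proportional scaling.

    The concentration matrix K keeps structural zeros on non-edges by
    construction; convergence is declared when the fitted covariance matches
    S on the diagonal and on every edge within ``tol``.  When the scaling
    sweeps approach the solution but stall (slow geometric tail on highly
    correlated data), a damped Newton iteration on the same moment-matching
    system finishes the job; it preserves the zero pattern exactly.
    Returns ``(Sigma, K)``.
    """
    N = S.shape[0]
    diag = np.diag(S)
    edges = sorted(edges)
    if warm_K is not None:
        K = warm_K.copy()
    else:
        K = np.diag(1.0 / diag)
    eidx = (
        (np.array([e[0] for e in edges]), np.array([e[1] for e in edges]))
        if edges
        else None
    )

    def residual(Sigma):
        r = np.max(np.abs(np.diag(Sigma) - diag))
        if eidx is not None:
            r = max(r, np.max(np.abs(Sigma[eidx] - S[eidx])))
        return r

    # isolated vertices: K_ii = 1/S_ii matches the marginal once and for all
    covered = {u for e in edges for u in e}
    for i in range(N):
        if i not in covered:
            K[i, i] = 1.0 / diag[i]

    Sigma = np.linalg.inv(K)
    for sweep in range(max_iter):
        r = residual(Sigma)
        if r < tol:
            return Sigma, K
        if r < 1e-2 and sweep >= 2:
            Sigma_n, K_n, r_n = _newton_polish(S, edges, K, tol)
            if r_n < tol:
                return Sigma_n, K_n
            if r_n < r:  # partial progress: continue scaling from there
                Sigma, K = Sigma_n, K_n
        # one sweep of edge-clique updates (each matches a 2x2 marginal)
        for (u, v) in edges:
            c = [u, v]
            Scc = S[np.ix_(c, c)]
            det = Scc[0, 0] * Scc[1, 1] - Scc[0, 1] ** 2
            if det <= 0:
                raise EfsaError(f"singular clique submatrix for edge {(u, v)}")
            Sigcc = Sigma[np.ix_(c, c)]
            try:
                K[np.ix_(c, c)] += np.linalg.inv(Scc) - np.linalg.inv(Sigcc)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
                raise EfsaError(f"clique update failed for edge {(u, v)}: {exc}")
            Sigma = np.linalg.inv(K)
    raise EfsaError(
        f"IPS did not converge in {max_iter} sweeps "
        f"(last residual {residual(Sigma):.3e})"
    )


def ips_fit(S, g: GraphState, tol: float = 1e-8, max_iter: int = 5000, warm_K=None):
    """Constrained Gaussian MLE of the covariance under graph ``g``.

    Matches ``S`` on the diagonal and on every edge; the inverse has exact
    zeros on non-adjacent pairs.  ``S`` may be a :class:`CovarianceModel` or
    a plain symmetric matrix.
    """
    mat = S.matrix if isinstance(S, CovarianceModel) else np.asarray(S, dtype=float)
    Sigma, _ = _ips(mat, g.edges, tol, max_iter, warm_K=warm_K)
    return Sigma


def deviance(S, Sigma_hat: np.ndarray, n_obs: int) -> float:
    """``n_obs * (logdet(Sigma_hat) - logdet(S))``.

    Meaningful only through differences between nested fits of the same node
    set, where the saturated term cancels.
    """
    mat = S.matrix if isinstance(S, CovarianceModel) else np.asarray(S, dtype=float)
    s1, ld1 = np.linalg.slogdet(Sigma_hat)
    s0, ld0 = np.linalg.slogdet(mat)
    if s1 <= 0 or s0 <= 0:
        raise EfsaError("deviance requires positive-definite matrices")
    return float(n_obs * (ld1 - ld0))


def _logdet(Sigma) -> float:
    sign, ld = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise EfsaError("fitted covariance is not positive definite")
    return float(ld)


def edge_pvalue(
    S,
    g: GraphState,
    edge,
    n_obs: int,
    cfg: EfsaConfig = EfsaConfig(),
    base_fit=None,
) -> EdgeTest:
    """Chi-square(1) test for adding one edge to the current graph.

    Deviance difference = ``n_obs * (logdet fit(g) - logdet fit(g+edge))``;
    negative numerical differences are clipped to zero.
    """
    edge = (min(edge), max(edge))
    if edge in g.edges:
        raise DataError(f"edge {edge} already in graph")
    mat = S.matrix if isinstance(S, CovarianceModel) else np.asarray(S, dtype=float)
    if base_fit is None:
        base_fit = _ips(mat, g.edges, cfg.ips_tol, cfg.ips_max_iter)
    Sigma0, K0 = base_fit
    Sigma1, _ = _ips(
        mat, g.edges | {edge}, cfg.ips_tol, cfg.ips_max_iter, warm_K=K0
    )
    dd = n_obs * (_logdet(Sigma0) - _logdet(Sigma1))
    dd = max(0.0, float(dd))
    p = float(stats.chi2.sf(dd, df=1))
    return EdgeTest(edge=edge, deviance_difference=dd, p_value=p)


# ---------------------------------------------------------------------------
# forward search
# ---------------------------------------------------------------------------


def forward_search(
    S,
    g0: GraphState,
    candidates,
    cfg: EfsaConfig = EfsaConfig(),
    cap: int | None = None,
    n_obs: int | None = None,
):
    """Greedy forward selection of edges below the p-value cutoff.

    Each round re-tests every remaining candidate against the current graph
    and permanently adds the smallest-p edge iff ``p < cutoff``.  Ties are
    broken by larger deviance difference, then lexicographic edge order.
    Stops when no candidate passes or ``cap`` edges have been added.

    Returns ``(graph, tests)`` where ``tests[i]`` records the i-th added
    edge (rank ``i + 1``).
    """
    mat = S.matrix if isinstance(S, CovarianceModel) else np.asarray(S, dtype=float)
    if n_obs is None:
        if not isinstance(S, CovarianceModel):
            raise DataError("n_obs required when S is a plain matrix")
        n_obs = S.n_obs
    remaining = [(min(e), max(e)) for e in candidates]
    for e in remaining:
        if e in g0.edges:
            raise DataError(f"candidate {e} already present in the graph")
        if not g0.is_allowed(e):
            raise DataError(f"candidate {e} is not an allowed position")
    g = g0
    base = _ips(mat, g.edges, cfg.ips_tol, cfg.ips_max_iter)
    added_tests = []
    while remaining and (cap is None or len(added_tests) < cap):
        tests = [
            edge_pvalue(mat, g, e, n_obs, cfg, base_fit=base) for e in remaining
        ]
        best = min(tests, key=lambda t: (t.p_value, -t.deviance_difference, t.edge))
        if best.p_value >= cfg.cutoff:
            break
        g = g.with_edge(best.edge)
        remaining.remove(best.edge)
        added_tests.append(best)
        base = _ips(mat, g.edges, cfg.ips_tol, cfg.ips_max_iter, warm_K=base[1])
    return g, added_tests


def orient_genes(g: GraphState):
    """Orient the gene-gene skeleton into a DAG.

    Surrogate orientation rule (the selection literature offers several;
    none is forced by the search itself): order nodes by first appearance in
    the provenance log (within one edge, lower gene index first) and direct
    every edge from the earlier node to the later one.  Orienting along a
    single total order guarantees acyclicity and determinism.
    """
    for (u, v) in g.edges:
        if v >= g.m:
            raise DataError("orient_genes expects gene-gene edges only")
    order = {}
    for (u, v) in g.provenance:
        for node in (u, v):
            if node not in order:
                order[node] = len(order)
    out = []
    for (u, v) in sorted(g.edges):
        if u not in order or v not in order:
            # edge supplied without provenance: fall back to index order
            out.append((u, v))
        elif order[u] <= order[v]:
            out.append((u, v))
        else:
            out.append((v, u))
    return out


# ---------------------------------------------------------------------------
# the full two-stage algorithm
# ---------------------------------------------------------------------------


def run_efsa(ds: GeneExpressionDataset, cfg: EfsaConfig = EfsaConfig()) -> InferredNetwork:
    """Infer a directed network of gene and NLT regulations from data.

    Stage 1 runs the forward search over gene-gene candidates on the gene
    covariance block (the NLT block is independent while no gene-NLT edges
    exist, so fitting the sub-block is exact) and orients the result.
    Stage 2 runs the forward search over gene-NLT candidates on the full
    augmented covariance, starting from the stage-1 graph, capped at the
    stage-1 edge count.
    """
    if ds.m < 2:
        raise DataError("need at least 2 genes")
    if ds.grid.count < 3:
        raise DataError("need at least 3 time points")
    aug = build_augmented(ds)
    X = aug.values
    if cfg.standardize:
        X, _, _ = standardize(X)
    m, n = aug.m, aug.n
    n_obs = ds.grid.count
    S_full = sample_covariance(X, m=m, n_obs=n_obs)

    # stage 1: gene-gene block only (exact while the graph has no gene-NLT edges)
    S_gene = CovarianceModel(S_full.A, m=m, n=0, n_obs=n_obs)
    gene_candidates = [(i, j) for i in range(m) for j in range(i + 1, m)]
    g1, tests1 = forward_search(S_gene, GraphState(m=m), gene_candidates, cfg)
    ranks1 = {t.edge: (r, t.p_value) for r, t in enumerate(tests1, start=1)}
    directed = orient_genes(g1)
    gene_edges = []
    for (u, v) in directed:
        rank, p = ranks1[(min(u, v), max(u, v))]
        gene_edges.append(
            GeneEdge(ds.gene_names[u], ds.gene_names[v], rank=rank, p_value=p)
        )
    gene_edges.sort(key=lambda e: e.rank)

    # stage 2: gene-NLT candidates on the full matrix, seeded with stage 1
    g_full = GraphState(m=m, n=n, edges=g1.edges, provenance=g1.provenance)
    nlt_candidates = [(i, m + p) for i in range(m) for p in range(n)]
    cap = len(gene_edges) if cfg.nlt_cap_mode else None
    _, tests2 = forward_search(S_full, g_full, nlt_candidates, cfg, cap=cap)
    nlt_edges = []
    for rank, t in enumerate(tests2, start=1):
        i, q = t.edge  # i is the gene (i < m), q - m indexes the NLT
        j, k = aug.nlt_indices[q - m]
        nlt_edges.append(
            NltEdge(
                (ds.gene_names[j], ds.gene_names[k]),
                ds.gene_names[i],
                rank=rank,
                p_value=t.p_value,
            )
        )
    return InferredNetwork(ds.gene_names, tuple(gene_edges), tuple(nlt_edges))
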