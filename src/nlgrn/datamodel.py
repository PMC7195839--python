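"""Core data types for time-course expression data, augmented non-linear-term
matrices, inferred networks and ODE model parameters.

Conventions
-----------
* Gene indices are 0-based internally; every file format and every user-facing
  label uses gene *names*, never indices.
* A non-linear term (NLT) is the elementwise product of two distinct gene
  rows.  NLT pairs are stored canonically with ``first < second`` and
  enumerated in lexicographic order; this ordering is fixed across the whole
  package so that results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DataError",
    "TimeGrid",
    "GeneExpressionDataset",
    "NLTIndex",
    "AugmentedDataset",
    "GeneEdge",
    "NltEdge",
    "InferredNetwork",
    "ModelParameters",
    "enumerate_nlts",
    "build_augmented",
    "count_parameters",
    "full_parameter_count",
    "candidate_gene_regulation_count",
    "average_replicates",
    "remove_edges",
    "isolated_nlts",
    "validate_support",
]


class DataError(ValueError):
    """An input violates a datatype contract."""


# ---------------------------------------------------------------------------
# basic containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeGrid:
    """Ordered observation times in hours."""

    times: tuple

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        arr = np.asarray(t, dtype=float)
        if arr.size < 2:
            raise DataError("time grid needs at least 2 points")
        if not np.all(np.isfinite(arr)):
            raise DataError("time grid contains non-finite values")
        if np.any(arr < 0):
            raise DataError("time grid contains negative times")
        if np.any(np.diff(arr) <= 0):
            raise DataError("time grid must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.times)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


@dataclass
class GeneExpressionDataset:
    """Expression levels for ``m`` genes at the grid's ``M`` time points."""

    gene_names: tuple
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self):
        self.gene_names = tuple(str(g) for g in self.gene_names)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DataError("duplicate gene names")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if vals.shape[0] != len(self.gene_names):
            raise DataError(
                f"row count {vals.shape[0]} does not match "
                f"{len(self.gene_names)} gene names"
            )
        if vals.shape[1] != self.grid.count:
            raise DataError(
                f"column count {vals.shape[1]} does not match "
                f"{self.grid.count} time points"
            )
        if not np.all(np.isfinite(vals)):
            raise DataError("expression values contain non-finite entries")
        if np.any(vals < 0):
            raise DataError("expression values must be non-negative")
        self.values = vals

    @property
    def m(self) -> int:
        return len(self.gene_names)

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise DataError(f"unknown gene {gene!r}") from None


class NLTIndex(NamedTuple):
    """Canonical unordered gene pair (0-based indices, ``first < second``)."""

    first: int
    second: int


@dataclass
class AugmentedDataset:
    """Gene rows stacked with all pairwise product (NLT) rows."""

    base: GeneExpressionDataset
    nlt_indices: tuple
    values: np.ndarray

    @property
    def m(self) -> int:
        return self.base.m

    @property
    def n(self) -> int:
        return len(self.nlt_indices)

    @property
    def N(self) -> int:
        return self.m + self.n

    def nlt_name(self, p: int) -> str:
        j, k = self.nlt_indices[p]
        return f"{self.base.gene_names[j]}:{self.base.gene_names[k]}"


# ---------------------------------------------------------------------------
# network containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneEdge:
    """Directed gene -> gene regulation."""

    source: str
    target: str
    rank: int | None = None
    p_value: float | None = None

    @property
    def key(self):
        return (self.source, self.target)


@dataclass(frozen=True)
class NltEdge:
    """Directed NLT -> gene regulation; ``source`` is the (geneA, geneB) pair."""

    source: tuple
    target: str
    rank: int | None = None
    p_value: float | None = None

    def __post_init__(self):
        a, b = self.source
        object.__setattr__(self, "source", (str(a), str(b)))

    @property
    def key(self):
        return (self.source, self.target)

    @property
    def label(self) -> str:
        return f"{self.source[0]}:{self.source[1]}"


@dataclass
class InferredNetwork:
    """Directed gene->gene edges plus directed NLT->gene edges.

    Invariants enforced on construction: no self-loop gene edges, the
    gene-edge subgraph is acyclic and there are no duplicate edges.  The
    selection-time cap (NLT-edge count never exceeding the gene-edge count)
    is guaranteed by the forward search, not by this container: edge
    deletion may legitimately leave more NLT edges than gene edges.
    """

    gene_names: tuple
    gene_edges: tuple = ()
    nlt_edges: tuple = ()

    def __post_init__(self):
        self.gene_names = tuple(str(g) for g in self.gene_names)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DataError("duplicate gene names")
        names = set(self.gene_names)
        self.gene_edges = tuple(self.gene_edges)
        self.nlt_edges = tuple(self.nlt_edges)
        seen = set()
        for e in self.gene_edges:
            if e.source not in names or e.target not in names:
                raise DataError(f"gene edge {e.key} references unknown gene")
            if e.source == e.target:
                raise DataError(f"self-loop gene edge on {e.source!r}")
            if e.key in seen:
                raise DataError(f"duplicate gene edge {e.key}")
            seen.add(e.key)
        seen = set()
        for e in self.nlt_edges:
            a, b = e.source
            if a not in names or b not in names or e.target not in names:
                raise DataError(f"NLT edge {e.key} references unknown gene")
            if a == b:
                raise DataError(f"NLT pair ({a!r}, {a!r}) is degenerate")
            if e.key in seen:
                raise DataError(f"duplicate NLT edge {e.key}")
            seen.add(e.key)
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_names)
        g.add_edges_from(e.key for e in self.gene_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("gene-edge subgraph contains a cycle")

    @property
    def m(self) -> int:
        return len(self.gene_names)

    @property
    def m1(self) -> int:
        return len(self.gene_edges)

    @property
    def n1(self) -> int:
        return len(self.nlt_edges)

    @property
    def total_edges(self) -> int:
        return self.m1 + self.n1


@dataclass
class ModelParameters:
    """Sparse coefficients of the bilinear ODE model.

    ``alpha`` maps (target, source) gene pairs to linear coefficients,
    ``beta`` maps (target, (geneA, geneB)) to product-term coefficients and
    ``degradation`` maps each gene to its positive decay rate.
    Auto-regulation (``alpha[(g, g)]``) and squared terms
    (``beta[(g, (h, h))]``) are excluded by construction.
    """

    alpha: dict
    beta: dict
    degradation: dict

    def __post_init__(self):
        for (tgt, src), v in self.alpha.items():
            if tgt == src:
                raise DataError(f"auto-regulation alpha[{tgt!r},{src!r}] not allowed")
            if not np.isfinite(v):
                raise DataError(f"non-finite alpha[{tgt!r},{src!r}]")
        beta = {}
        for (tgt, pair), v in self.beta.items():
            a, b = pair
            if a == b:
                raise DataError(f"squared term beta[{tgt!r},({a!r},{a!r})] not allowed")
            if not np.isfinite(v):
                raise DataError(f"non-finite beta[{tgt!r},{pair}]")
            beta[(tgt, (a, b))] = v
        self.beta = beta
        for g, k in self.degradation.items():
            if not np.isfinite(k) or k <= 0:
                raise DataError(f"degradation rate for {g!r} must be positive")

    def n_params(self) -> int:
        return len(self.alpha) + len(self.beta) + len(self.degradation)


def validate_support(params: ModelParameters, net: InferredNetwork) -> None:
    """Check that every non-zero coefficient sits on an edge of ``net``."""
    gene_keys = {e.key for e in net.gene_edges}
    for key in params.alpha:
        tgt, src = key
        if (src, tgt) not in gene_keys:
            raise DataError(f"alpha coefficient {key} outside network support")
    nlt_keys = {(frozenset(e.source), e.target) for e in net.nlt_edges}
    for tgt, pair in params.beta:
        if (frozenset(pair), tgt) not in nlt_keys:
            raise DataError(f"beta coefficient ({tgt}, {pair}) outside network support")
    for g in params.degradation:
        if g not in net.gene_names:
            raise DataError(f"degradation rate for unknown gene {g!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def enumerate_nlts(m: int):
    """All ``m*(m-1)/2`` canonical gene pairs in lexicographic order.

    Indices are 0-based; pair ``NLTIndex(j, k)`` always has ``j < k``.
    """
    if m < 2:
        raise DataError(f"need at least 2 genes to form pairs, got m={m}")
    return [NLTIndex(j, k) for j in range(m) for k in range(j + 1, m)]


def build_augmented(ds: GeneExpressionDataset) -> AugmentedDataset:
    """Stack all pairwise product rows under the gene rows."""
    pairs = enumerate_nlts(ds.m)
    prod = np.empty((len(pairs), ds.values.shape[1]))
    for p, (j, k) in enumerate(pairs):
        row = ds.values[j] * ds.values[k]
        if not np.all(np.isfinite(row)):
            raise DataError(
                f"non-finite product for pair "
                f"({ds.gene_names[j]!r}, {ds.gene_names[k]!r})"
            )
        prod[p] = row
    values = np.vstack([ds.values, prod])
    return AugmentedDataset(base=ds, nlt_indices=tuple(pairs), values=values)


def count_parameters(net: InferredNetwork, m: int | None = None) -> int:
    """Unknown-parameter count of the ODE model on a network's support.

    One linear coefficient per gene edge, one product coefficient per NLT
    edge and one degradation rate per gene.
    """
    if m is None:
        m = net.m
    elif m != net.m:
        raise DataError(f"network has {net.m} genes, not {m}")
    return net.m1 + net.n1 + m


def full_parameter_count(m: int) -> int:
    """Parameter count of the fully connected model over ``m`` genes.

    All ``m*(m-1)`` off-diagonal linear coefficients, all ``m * m(m-1)/2``
    NLT-to-gene coefficients and ``m`` degradation rates: ``m * (m + n)``
    with ``n = m(m-1)/2``.
    """
    if m < 2:
        raise DataError(f"need m >= 2, got {m}")
    n = m * (m - 1) // 2
    return m * (m + n)


def candidate_gene_regulation_count(m: int) -> int:
    """Number of possible directed gene->gene regulations (no self-loops)."""
    if m < 2:
        raise DataError(f"need m >= 2, got {m}")
    return m * (m - 1)


def average_replicates(datasets: Sequence[GeneExpressionDataset]) -> GeneExpressionDataset:
    """Elementwise arithmetic mean of replicate datasets.

    All replicates must share identical gene names and time grids; no
    interpolation is attempted.
    """
    if not datasets:
        raise DataError("no datasets given")
    ref = datasets[0]
    for i, ds in enumerate(datasets[1:], start=2):
        if ds.gene_names != ref.gene_names:
            raise DataError(
                f"replicate {i} gene names differ from replicate 1: "
                f"{sorted(set(ds.gene_names) ^ set(ref.gene_names))}"
            )
        if ds.grid.times != ref.grid.times:
            raise DataError(f"replicate {i} time grid differs from replicate 1")
    mean = np.mean([ds.values for ds in datasets], axis=0)
    return GeneExpressionDataset(ref.gene_names, ref.grid, mean)


def remove_edges(
    net: InferredNetwork,
    gene_edges: Iterable = (),
    nlt_edges: Iterable = (),
) -> InferredNetwork:
    """Return a copy of ``net`` with the named edges removed.

    ``gene_edges`` holds (source, target) pairs; ``nlt_edges`` holds
    ((geneA, geneB), target) pairs (NLT pair order is ignored).
    """
    gene_keys = {(str(s), str(t)) for s, t in gene_edges}
    nlt_keys = {(frozenset((str(a), str(b))), str(t)) for (a, b), t in nlt_edges}
    present_gene = {e.key for e in net.gene_edges}
    present_nlt = {(frozenset(e.source), e.target) for e in net.nlt_edges}
    for key in gene_keys:
        if key not in present_gene:
            raise DataError(f"gene edge {key} not present in network")
    for key in nlt_keys:
        if key not in present_nlt:
            raise DataError(f"NLT edge {tuple(sorted(key[0])), key[1]} not in network")
    kept_gene = tuple(e for e in net.gene_edges if e.key not in gene_keys)
    kept_nlt = tuple(
        e for e in net.nlt_edges if (frozenset(e.source), e.target) not in nlt_keys
    )
    return InferredNetwork(net.gene_names, kept_gene, kept_nlt)


def isolated_nlts(net: InferredNetwork):
    """Candidate NLT pairs (as name tuples) with no selected outgoing edge."""
    used = {frozenset(e.source) for e in net.nlt_edges}
    out = []
    for j, k in enumerate_nlts(net.m):
        pair = (net.gene_names[j], net.gene_names[k])
        if frozenset(pair) not in used:
            out.append(pair)
    return out
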