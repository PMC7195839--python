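"""Plain-text readers and writers.

Three dialects, all tab-separated UTF-8 text:

* expression table — header ``gene\t<t1>\t<t2>...`` (times in hours), one row
  per gene;
* network edge table — columns ``source  target  source_kind  rank  p_value
  coefficient`` (``source_kind`` is ``gene`` or ``nlt``; NLT sources are
  labelled ``geneA:geneB``);
* SIF — ``source regulates target`` rows for graph viewers;
* parameter document — versioned key/value rows for model coefficients.

Readers reject malformed input with line numbers instead of coercing it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datamodel import (
    DataError,
    GeneEdge,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    NltEdge,
    TimeGrid,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_parameters",
    "write_parameters",
]

PARAMS_FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression(path) -> GeneExpressionDataset:
    lines = Path(path).read_text().splitlines()
    rows = [(no, ln) for no, ln in enumerate(lines, start=1) if ln.strip()]
    if not rows:
        raise DataError(f"{path}: empty file")
    header_no, header = rows[0]
    fields = header.rstrip("\n").split("\t")
    if fields[0].strip().lower() != "gene":
        raise DataError(f"{path}:{header_no}: header must start with 'gene'")
    try:
        times = [float(x) for x in fields[1:]]
    except ValueError as exc:
        raise DataError(f"{path}:{header_no}: non-numeric time header ({exc})") from None
    if len(times) < 2:
        raise DataError(f"{path}:{header_no}: need at least 2 time columns")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise DataError(f"{path}:{header_no}: time header must be strictly increasing")
    grid = TimeGrid(tuple(times))

    names, values = [], []
    for no, ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) != len(fields):
            raise DataError(
                f"{path}:{no}: expected {len(fields)} columns, got {len(parts)}"
            )
        name = parts[0].strip()
        if name in names:
            raise DataError(f"{path}:{no}: duplicate gene name {name!r}")
        try:
            row = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise DataError(f"{path}:{no}: non-numeric expression value ({exc})") from None
        names.append(name)
        values.append(row)
    if not names:
        raise DataError(f"{path}: no gene rows")
    return GeneExpressionDataset(tuple(names), grid, np.asarray(values))


def write_expression(ds: GeneExpressionDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(f"{t:.17g}" for t in ds.grid.times) + "\n")
        for name, row in zip(ds.gene_names, ds.values):
            fh.write(name + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_NET_HEADER = ["source", "target", "source_kind", "rank", "p_value", "coefficient"]


def write_network(
    net: InferredNetwork,
    path,
    format: str = "edge-table",
    params: ModelParameters | None = None,
) -> None:
    """Serialize a network as an edge table or SIF.

    When ``params`` is given, fitted coefficients are filled into the edge
    table; otherwise the column is left blank.
    """
    if format == "edge-table":
        _write_edge_table(net, path, params)
    elif format == "sif":
        _write_sif(net, path)
    else:
        raise DataError(f"unknown network format {format!r}")


def _fmt(x) -> str:
    return "" if x is None else f"{x:.17g}"


def _write_edge_table(net, path, params) -> None:
    with open(path, "w") as fh:
        fh.write("#genes\t" + "\t".join(net.gene_names) + "\n")
        fh.write("\t".join(_NET_HEADER) + "\n")
        for e in net.gene_edges:
            coef = params.alpha.get((e.target, e.source)) if params else None
            fh.write(
                "\t".join(
                    [e.source, e.target, "gene",
                     "" if e.rank is None else str(e.rank),
                     _fmt(e.p_value), _fmt(coef)]
                )
                + "\n"
            )
        for e in net.nlt_edges:
            coef = params.beta.get((e.target, e.source)) if params else None
            if coef is None and params is not None:
                coef = params.beta.get((e.target, (e.source[1], e.source[0])))
            fh.write(
                "\t".join(
                    [e.label, e.target, "nlt",
                     "" if e.rank is None else str(e.rank),
                     _fmt(e.p_value), _fmt(coef)]
                )
                + "\n"
            )


def _write_sif(net, path) -> None:
    with open(path, "w") as fh:
        for e in net.gene_edges:
            fh.write(f"{e.source} regulates {e.target}\n")
        for e in net.nlt_edges:
            fh.write(f"{e.label} regulates {e.target}\n")


def read_network(path) -> InferredNetwork:
    """Read an edge-table network file (the writer's inverse)."""
    lines = Path(path).read_text().splitlines()
    rows = [(no, ln) for no, ln in enumerate(lines, start=1) if ln.strip()]
    if not rows or not rows[0][1].startswith("#genes\t"):
        raise DataError(f"{path}: missing '#genes' preamble line")
    gene_names = tuple(rows[0][1].split("\t")[1:])
    if len(rows) < 2 or rows[1][1].split("\t") != _NET_HEADER:
        raise DataError(f"{path}: missing or malformed edge-table header")
    gene_edges, nlt_edges = [], []
    for no, ln in rows[2:]:
        parts = ln.split("\t")
        if len(parts) != len(_NET_HEADER):
            raise DataError(f"{path}:{no}: expected {len(_NET_HEADER)} columns")
        source, target, kind, rank, p_value, _coef = parts
        rank_v = int(rank) if rank else None
        p_v = float(p_value) if p_value else None
        if kind == "gene":
            gene_edges.append(GeneEdge(source, target, rank_v, p_v))
        elif kind == "nlt":
            if ":" not in source:
                raise DataError(f"{path}:{no}: NLT source must be 'geneA:geneB'")
            a, b = source.split(":", 1)
            nlt_edges.append(NltEdge((a, b), target, rank_v, p_v))
        else:
            raise DataError(f"{path}:{no}: unknown source_kind {kind!r}")
    return InferredNetwork(gene_names, tuple(gene_edges), tuple(nlt_edges))


# ---------------------------------------------------------------------------
# parameter documents
# ---------------------------------------------------------------------------


def write_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"format_version\t{PARAMS_FORMAT_VERSION}\n")
        for (tgt, src), v in params.alpha.items():
            fh.write(f"alpha\t{src}\t{tgt}\t{v:.17g}\n")
        for (tgt, (a, b)), v in params.beta.items():
            fh.write(f"beta\t{a}:{b}\t{tgt}\t{v:.17g}\n")
        for g, k in params.degradation.items():
            fh.write(f"k\t{g}\t{k:.17g}\n")


def read_parameters(path) -> ModelParameters:
    lines = Path(path).read_text().splitlines()
    rows = [(no, ln) for no, ln in enumerate(lines, start=1) if ln.strip()]
    if not rows or not rows[0][1].startswith("format_version\t"):
        raise DataError(f"{path}: missing format_version line")
    version = rows[0][1].split("\t", 1)[1].strip()
    if version != PARAMS_FORMAT_VERSION:
        raise DataError(f"{path}: unsupported format_version {version!r}")
    alpha, beta, k = {}, {}, {}
    for no, ln in rows[1:]:
        parts = ln.split("\t")
        try:
            if parts[0] == "alpha" and len(parts) == 4:
                alpha[(parts[2], parts[1])] = float(parts[3])
            elif parts[0] == "beta" and len(parts) == 4:
                a, b = parts[1].split(":", 1)
                beta[(parts[2], (a, b))] = float(parts[3])
            elif parts[0] == "k" and len(parts) == 3:
                k[parts[1]] = float(parts[2])
            else:
                raise DataError(f"{path}:{no}: unrecognized record {parts[0]!r}")
        except ValueError as exc:
            raise DataError(f"{path}:{no}: bad numeric value ({exc})") from None
    return ModelParameters(alpha=alpha, beta=beta, degradation=k)
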