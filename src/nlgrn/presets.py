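"""Published hematopoietic network shapes used for structural replays.

The erythroid and neutrophil differentiation models over the 11-gene
hematopoiesis panel were reported with 46 gene-gene + 46 NLT-gene edges and
40 + 40 edges respectively, together with the regulations removed during
their edge-deletion analyses.  The full edge lists live in supplementary
material that is not redistributed here, so :func:`published_network` builds
a deterministic surrogate with the *reported shape*: the documented removed
edges are always present and the remaining slots are filled canonically.
That is sufficient for every structural computation (parameter counts, edge
counts, deletion-trace replays); it is NOT the biological edge list.
"""

from __future__ import annotations

from .datamodel import DataError, GeneEdge, InferredNetwork, NltEdge, enumerate_nlts
from .robustness_pruning import DeletionStep

__all__ = [
    "HEMATOPOIESIS_PANEL",
    "published_network",
    "published_removal_steps",
]

# Topologically ordered so that every documented removed gene edge points
# forward (Gata2->Ldb1, Runx1->Cbfa2t3, *->Lmo2).
HEMATOPOIESIS_PANEL = (
    "Gata1",
    "Gata2",
    "PU.1",
    "Runx1",
    "Cbfa2t3",
    "Ets1",
    "Notch1",
    "Tal1",
    "Ldb1",
    "Gfi1",
    "Lmo2",
)

_SHAPES = {
    "erythroid": {
        "m1": 46,
        "n1": 46,
        "removed_nlt": ((("Gata2", "Notch1"), "Notch1"),
                        (("Tal1", "Gfi1"), "Gfi1"),
                        (("Cbfa2t3", "Gfi1"), "Gfi1")),
        "removed_gene": (("Ldb1", "Lmo2"),
                         ("Notch1", "Lmo2"),
                         ("Cbfa2t3", "Lmo2"),
                         ("Runx1", "Lmo2")),
    },
    "neutrophil": {
        "m1": 40,
        "n1": 40,
        "removed_nlt": (),
        "removed_gene": (("Gata2", "Ldb1"),
                         ("Runx1", "Cbfa2t3"),
                         ("Ldb1", "Lmo2"),
                         ("Tal1", "Lmo2")),
    },
}


def published_network(lineage: str) -> InferredNetwork:
    """Deterministic network with the reported shape for a lineage.

    ``lineage`` is ``"erythroid"`` (46 + 46 edges) or ``"neutrophil"``
    (40 + 40 edges).  All edges recorded as removed in the corresponding
    deletion analysis are included; filler edges follow the panel's
    topological order (gene edges) and the component-target convention
    observed in the published selections (every NLT targets one of its own
    component genes).
    """
    try:
        shape = _SHAPES[lineage]
    except KeyError:
        raise DataError(
            f"unknown lineage {lineage!r}; expected 'erythroid' or 'neutrophil'"
        ) from None
    names = HEMATOPOIESIS_PANEL
    m = len(names)

    gene_keys = list(shape["removed_gene"])
    for i in range(m):
        for j in range(i + 1, m):
            key = (names[i], names[j])
            if len(gene_keys) >= shape["m1"]:
                break
            if key not in gene_keys:
                gene_keys.append(key)
        if len(gene_keys) >= shape["m1"]:
            break

    nlt_keys = list(shape["removed_nlt"])
    present = {(frozenset(p), t) for p, t in nlt_keys}
    for j, k in enumerate_nlts(m):
        pair = (names[j], names[k])
        for target in pair:  # NLT targets a component gene
            key = (pair, target)
            if len(nlt_keys) >= shape["n1"]:
                break
            if (frozenset(pair), target) not in present:
                nlt_keys.append(key)
                present.add((frozenset(pair), target))
        if len(nlt_keys) >= shape["n1"]:
            break

    gene_edges = tuple(
        GeneEdge(s, t, rank=r + 1) for r, (s, t) in enumerate(gene_keys)
    )
    nlt_edges = tuple(
        NltEdge(p, t, rank=r + 1) for r, (p, t) in enumerate(nlt_keys)
    )
    return InferredNetwork(names, gene_edges, nlt_edges)


def published_removal_steps(lineage: str):
    """The recorded deletion steps for a lineage, as replayable steps.

    The first step (OES) removes nothing; the NLT removals form one batch
    step; each gene removal is its own step.
    """
    try:
        shape = _SHAPES[lineage]
    except KeyError:
        raise DataError(
            f"unknown lineage {lineage!r}; expected 'erythroid' or 'neutrophil'"
        ) from None
    steps = [DeletionStep(label="OES")]
    n = 1
    if shape["removed_nlt"]:
        steps.append(
            DeletionStep(label=f"DEL{n}", removed_nlt_edges=shape["removed_nlt"])
        )
        n += 1
    else:
        steps.append(DeletionStep(label=f"DEL{n}"))  # "no suggestion" step
        n += 1
    for edge in shape["removed_gene"]:
        steps.append(DeletionStep(label=f"DEL{n}", removed_gene_edges=(edge,)))
        n += 1
    return steps
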