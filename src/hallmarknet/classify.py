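"""Oncogene / tumor-suppressor classification from path signs.

A driver gene's functional potential is read off the signed paths connecting
it to the hallmark phenotypes: a gene whose paths stimulate proliferation or
inhibit differentiation or apoptosis carries oncogenic potential; one that
activates differentiation or apoptosis or suppresses proliferation carries
tumor-suppressor potential. Genes with paths of both kinds are dual;
genes with no path to any hallmark stay unclassified.

The sign of a path is the product of its edge signs (an inhibitor of an
inhibitor acts as a net activator). Only simple paths are counted — a path
revisiting a node would thread a feedback loop, whose net sign is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import networkx as nx

from .graph import ACTIVATION, CausalGraph, NodeKind

PROLIFERATION = "proliferation"
DIFFERENTIATION = "differentiation"
APOPTOSIS = "apoptosis"

#: (hallmark, net path sign) pairs that witness oncogenic potential.
ONCOGENIC_EVIDENCE = {
    (PROLIFERATION, +1),
    (DIFFERENTIATION, -1),
    (APOPTOSIS, -1),
}
#: (hallmark, net path sign) pairs that witness tumor-suppressor potential.
SUPPRESSOR_EVIDENCE = {
    (PROLIFERATION, -1),
    (DIFFERENTIATION, +1),
    (APOPTOSIS, +1),
}


class Label(str, Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    DUAL = "dual"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PathEffect:
    """A simple path from a gene to a hallmark with its net sign."""

    gene: str
    hallmark: str
    net_sign: int
    path: tuple[str, ...]


@dataclass(frozen=True)
class GeneClassification:
    gene: str
    label: Label
    evidence: frozenset[tuple[str, int]]  # (hallmark, net_sign)


def enumerate_path_effects(
    graph: CausalGraph,
    gene: str,
    max_len: int | None = None,
) -> list[PathEffect]:
    """All simple paths from *gene* to any phenotype node, with sign products.

    *max_len* caps the number of edges per path (None = unbounded, practical
    on curated networks). A regulator pair carrying both signs yields one
    path effect per sign combination. Output is sorted lexicographically by
    (hallmark, path, sign) so results are deterministic.
    """
    if gene not in graph:
        raise KeyError(f"gene {gene!r} is not a node of the graph")
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be >= 1")

    g = graph.to_networkx()
    simple = nx.DiGraph()  # node-level skeleton; parallel signs expanded below
    simple.add_nodes_from(g.nodes)
    simple.add_edges_from({(u, v) for u, v, _ in g.edges(keys=True)})

    effects: list[PathEffect] = []
    for hallmark in graph.phenotypes():
        if hallmark == gene:
            continue
        cutoff = max_len if max_len is not None else None
        for node_path in nx.all_simple_paths(simple, gene, hallmark, cutoff=cutoff):
            for signs in _sign_combinations(g, node_path):
                net = 1
                for s in signs:
                    net *= s
                effects.append(
                    PathEffect(gene, hallmark, net, tuple(node_path))
                )
    effects.sort(key=lambda e: (e.hallmark, e.path, e.net_sign))
    return effects


def _sign_combinations(g: nx.MultiDiGraph, node_path: list[str]):
    """Yield one sign tuple per combination of parallel-edge signs along a path."""
    per_hop = [
        sorted(d["sign"] for d in g.get_edge_data(u, v).values())
        for u, v in zip(node_path, node_path[1:])
    ]
    def rec(i: int, acc: tuple[int, ...]):
        if i == len(per_hop):
            yield acc
            return
        for s in per_hop[i]:
            yield from rec(i + 1, acc + (s,))
    yield from rec(0, ())


def classify_gene(
    gene: str, effects: Iterable[PathEffect | tuple[str, int]]
) -> GeneClassification:
    """Label a gene from its path effects.

    Oncogenic evidence: any path that up-regulates proliferation or
    down-regulates differentiation or apoptosis. Suppressor evidence: the
    mirror image. Both kinds → dual; neither → unclassified.
    """
    pairs = frozenset(
        (e.hallmark, e.net_sign) if isinstance(e, PathEffect) else tuple(e)
        for e in effects
    )
    onco = bool(pairs & ONCOGENIC_EVIDENCE)
    ts = bool(pairs & SUPPRESSOR_EVIDENCE)
    if onco and ts:
        label = Label.DUAL
    elif onco:
        label = Label.ONCOGENE
    elif ts:
        label = Label.TUMOR_SUPPRESSOR
    else:
        label = Label.UNCLASSIFIED
    return GeneClassification(gene=gene, label=label, evidence=pairs)


def classify_graph(
    graph: CausalGraph,
    genes: Iterable[str] | None = None,
    max_len: int | None = None,
) -> dict[str, GeneClassification]:
    """Classify *genes* (default: all driver-tagged, else all non-phenotype nodes)."""
    if genes is None:
        drivers = [n.id for n in graph.nodes if n.kind == NodeKind.DRIVER]
        genes = drivers or [
            n.id for n in graph.nodes if n.kind != NodeKind.PHENOTYPE
        ]
    return {
        g: classify_gene(g, enumerate_path_effects(graph, g, max_len=max_len))
        for g in sorted(genes)
    }
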