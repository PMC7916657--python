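"""Signed directed causal networks: data model, SIF I/O, driver consensus, expression filtering.

A causal network is a signed directed graph whose nodes are genes, proteins,
fusion proteins, or hallmark phenotypes (``proliferation``, ``differentiation``,
``apoptosis``) and whose edges carry a sign: +1 for up-regulation (activation),
-1 for down-regulation (inhibition). Phenotype nodes are sinks — they summarize
cellular processes and regulate nothing downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

log = logging.getLogger(__name__)

#: Node names recognized as hallmark phenotypes (case-insensitive match).
DEFAULT_PHENOTYPE_NAMES = ("proliferation", "differentiation", "apoptosis")

ACTIVATION = 1
INHIBITION = -1

_RELATION_TOKENS = {
    "up-regulates": ACTIVATION,
    "activates": ACTIVATION,
    "down-regulates": INHIBITION,
    "inhibits": INHIBITION,
}
_SIGN_TO_RELATION = {ACTIVATION: "up-regulates", INHIBITION: "down-regulates"}


class NodeKind(str, Enum):
    DRIVER = "driver"
    PROTEIN = "protein"
    PHENOTYPE = "phenotype"


@dataclass(frozen=True)
class Node:
    """A gene/protein/fusion or hallmark phenotype. Ids are opaque, case-sensitive."""

    id: str
    kind: NodeKind = NodeKind.PROTEIN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be a non-empty string")


@dataclass(frozen=True)
class Edge:
    """A signed causal interaction source → target."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")


class SifParseError(ValueError):
    """Raised on a malformed SIF row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class CausalGraph:
    """A signed directed causal network.

    Backed by a :class:`networkx.MultiDiGraph` so that a regulator pair may
    carry both an activation and an inhibition edge (sign conflicts are a
    policy question for rule synthesis, not for the graph).
    """

    def __init__(
        self,
        nodes: Iterable[Node] = (),
        edges: Iterable[Edge] = (),
        name: str = "",
    ):
        self.name = name
        self._g = nx.MultiDiGraph()
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        existing = self._g.nodes.get(node.id)
        if existing is not None and existing["kind"] != node.kind:
            raise ValueError(
                f"node {node.id!r} already present with kind {existing['kind']}"
            )
        self._g.add_node(node.id, kind=node.kind)

    def add_edge(self, edge: Edge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._g:
                self._g.add_node(endpoint, kind=NodeKind.PROTEIN)
        # at most one edge per (source, target, sign): key on the sign
        self._g.add_edge(edge.source, edge.target, key=edge.sign, sign=edge.sign)

    # -- queries -------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def kind(self, node_id: str) -> NodeKind:
        return self._g.nodes[node_id]["kind"]

    @property
    def nodes(self) -> set[Node]:
        return {Node(n, d["kind"]) for n, d in self._g.nodes(data=True)}

    @property
    def edges(self) -> set[Edge]:
        return {Edge(u, v, d["sign"]) for u, v, d in self._g.edges(data=True)}

    def phenotypes(self) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d["kind"] == NodeKind.PHENOTYPE
        )

    def activators(self, node_id: str) -> set[str]:
        return {
            u
            for u, _, d in self._g.in_edges(node_id, data=True)
            if d["sign"] == ACTIVATION
        }

    def inhibitors(self, node_id: str) -> set[str]:
        return {
            u
            for u, _, d in self._g.in_edges(node_id, data=True)
            if d["sign"] == INHIBITION
        }

    def regulators(self, node_id: str) -> set[str]:
        return self.activators(node_id) | self.inhibitors(node_id)

    def to_networkx(self) -> nx.MultiDiGraph:
        """A copy of the underlying multigraph (node attr ``kind``, edge attr ``sign``)."""
        return self._g.copy()

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for p in self.phenotypes():
            if self._g.out_degree(p) > 0:
                raise ValueError(f"phenotype node {p!r} must be a sink")
        for u, v, d in self._g.edges(data=True):
            if d["sign"] not in (ACTIVATION, INHIBITION):
                raise ValueError(f"edge {u}->{v} has invalid sign {d['sign']!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"CausalGraph(name={self.name!r}, nodes={len(self)}, "
            f"edges={self._g.number_of_edges()})"
        )


# ---------------------------------------------------------------------------
# SIF dialect I/O
# ---------------------------------------------------------------------------

def read_sif(
    path: str | Path,
    phenotype_names: Iterable[str] = DEFAULT_PHENOTYPE_NAMES,
    driver_ids: Iterable[str] = (),
) -> CausalGraph:
    """Read a 3-column tab-separated causal network file.

    Columns: source, relation, target. Relations ``up-regulates`` /
    ``down-regulates`` (SIGNOR vocabulary), with ``activates`` / ``inhibits``
    accepted as synonyms, case-insensitively. Lines starting with ``#`` and
    blank lines are skipped; duplicate rows collapse silently. Nodes whose
    name matches a phenotype name case-insensitively are tagged as hallmark
    phenotypes; nodes listed in *driver_ids* are tagged as drivers.
    """
    path = Path(path)
    pheno_lc = {p.lower() for p in phenotype_names}
    drivers = set(driver_ids)
    graph = CausalGraph(name=path.stem)

    def _kind(node_id: str) -> NodeKind:
        if node_id.lower() in pheno_lc:
            return NodeKind.PHENOTYPE
        if node_id in drivers:
            return NodeKind.DRIVER
        return NodeKind.PROTEIN

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SifParseError(
                    f"expected 3 tab-separated columns, got {len(parts)}", lineno
                )
            source, relation, target = (p.strip() for p in parts)
            sign = _RELATION_TOKENS.get(relation.lower())
            if sign is None:
                raise SifParseError(f"unknown relation {relation!r}", lineno)
            if not source or not target:
                raise SifParseError("empty node identifier", lineno)
            graph.add_node(Node(source, _kind(source)))
            graph.add_node(Node(target, _kind(target)))
            graph.add_edge(Edge(source, target, sign))
    graph.validate()
    return graph


def write_sif(graph: CausalGraph, path: str | Path) -> Path:
    """Write *graph* in the 3-column SIF dialect; rows sorted for stable output.

    Round-trips with :func:`read_sif` up to row order, except isolated nodes
    (the dialect only records edges).
    """
    path = Path(path)
    rows = sorted((e.source, _SIGN_TO_RELATION[e.sign], e.target) for e in graph.edges)
    with path.open("w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Driver-gene consensus
# ---------------------------------------------------------------------------

@dataclass
class GeneListCollection:
    """Named gene lists from independent resources; sets may overlap."""

    lists: dict[str, set[str]] = field(default_factory=dict)

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.lists.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class ConsensusResult:
    drivers: set[str]
    counts: dict[str, int]  # per-gene number of source lists
    membership: dict[str, dict[str, bool]]  # gene -> list name -> present
    manual_adds: set[str]


def consensus_drivers(
    collection: GeneListCollection,
    min_lists: int = 2,
    manual_adds: Iterable[str] = (),
) -> ConsensusResult:
    """Select genes present in at least *min_lists* of the collection's lists.

    Manual additions (connectivity genes, fusion proteins) are unioned in
    regardless of list membership. Returns the driver set plus per-gene
    membership counts for reporting.
    """
    if not collection.lists:
        raise ValueError("gene list collection is empty")
    if not 1 <= min_lists <= len(collection.lists):
        raise ValueError(
            f"min_lists must be in [1, {len(collection.lists)}], got {min_lists}"
        )
    counts = collection.membership_counts()
    adds = set(manual_adds)
    drivers = {g for g, c in counts.items() if c >= min_lists} | adds
    membership = {
        g: {name: g in genes for name, genes in collection.lists.items()}
        for g in sorted(set(counts) | adds)
    }
    return ConsensusResult(drivers=drivers, counts=counts, membership=membership,
                           manual_adds=adds)


def read_gene_list(path: str | Path) -> tuple[str, set[str]]:
    """Read a one-column TSV whose header names the list."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty gene list file")
    return lines[0], set(lines[1:])


def write_consensus_report(result: ConsensusResult, path: str | Path) -> Path:
    """TSV report: gene, n_lists, one flag column per list, manual_add flag."""
    path = Path(path)
    list_names = sorted(next(iter(result.membership.values())).keys()) if result.membership else []
    with path.open("w") as fh:
        fh.write("\t".join(["gene", "n_lists", *list_names, "manual_add"]) + "\n")
        for gene in sorted(result.membership):
            flags = result.membership[gene]
            fh.write(
                "\t".join(
                    [
                        gene,
                        str(result.counts.get(gene, 0)),
                        *("1" if flags[n] else "0" for n in list_names),
                        "1" if gene in result.manual_adds else "0",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Expression filtering
# ---------------------------------------------------------------------------

def expression_filter(
    graph: CausalGraph,
    expressed: Iterable[str],
    keep_drivers: bool = False,
) -> CausalGraph:
    """Restrict *graph* to genes expressed in the disease context.

    Phenotype nodes are never removed; driver-tagged nodes survive when
    *keep_drivers* is set. Edges incident to removed nodes are dropped.
    The input graph is not modified.
    """
    expressed = set(expressed)
    keep = {
        n.id
        for n in graph.nodes
        if n.id in expressed
        or n.kind == NodeKind.PHENOTYPE
        or (keep_drivers and n.kind == NodeKind.DRIVER)
    }
    out = CausalGraph(
        nodes={n for n in graph.nodes if n.id in keep},
        edges={e for e in graph.edges if e.source in keep and e.target in keep},
        name=graph.name,
    )
    if len(out) == len(out.phenotypes()):
        log.warning("expression filter removed every non-phenotype node")
    return out
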