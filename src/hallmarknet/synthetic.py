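"""Random signed networks, genotypes, and synthetic clinical tables.

These generators supply reproducible test inputs: random signed causal graphs
whose phenotype nodes are sinks, random genotypes over a graph's genes, and
clinical feature tables built as a linear function of the integrated score
plus Gaussian noise (the simplest mean-zero noise model for
correlation-recovery checks). All draws come from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .clinical import ClinicalTable
from .graph import ACTIVATION, INHIBITION, CausalGraph, Edge, Node, NodeKind
from .model import Genotype
from .scoring import PhenotypeScores

DEFAULT_PHENOTYPES = ("proliferation", "differentiation", "apoptosis")


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of a random signed causal network.

    ``edge_density`` is the probability of each ordered protein pair being
    connected; ``inhibition_fraction`` the probability an edge is inhibitory;
    ``n_phenotypes`` phenotype sinks each receive at least one incoming edge.
    """

    n_nodes: int = 10
    edge_density: float = 0.25
    inhibition_fraction: float = 0.3
    n_phenotypes: int = 3
    allow_feedback: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ValueError("inhibition_fraction must be in [0, 1]")
        if self.n_phenotypes < 0 or self.n_phenotypes > len(DEFAULT_PHENOTYPES):
            raise ValueError(
                f"n_phenotypes must be in [0, {len(DEFAULT_PHENOTYPES)}]"
            )


def generate_network(spec: SyntheticNetworkSpec) -> CausalGraph:
    """Draw a random signed network; identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    proteins = [f"G{i:02d}" for i in range(spec.n_nodes)]
    phenotypes = list(DEFAULT_PHENOTYPES[: spec.n_phenotypes])

    def draw_sign() -> int:
        return INHIBITION if rng.random() < spec.inhibition_fraction else ACTIVATION

    edges: set[Edge] = set()
    for i, u in enumerate(proteins):
        for j, v in enumerate(proteins):
            if i == j:
                continue
            if not spec.allow_feedback and j < i:
                continue
            if rng.random() < spec.edge_density:
                edges.add(Edge(u, v, draw_sign()))
    # every phenotype is a regulated sink
    for p in phenotypes:
        regulators = rng.choice(
            spec.n_nodes, size=min(3, spec.n_nodes), replace=False
        )
        for k in regulators:
            if rng.random() < spec.edge_density or not any(
                e.target == p for e in edges
            ):
                edges.add(Edge(proteins[int(k)], p, draw_sign()))

    graph = CausalGraph(
        nodes=[Node(g) for g in proteins]
        + [Node(p, NodeKind.PHENOTYPE) for p in phenotypes],
        edges=edges,
        name=f"synthetic-{spec.seed}",
    )
    graph.validate()
    return graph


def generate_genotype(
    graph: CausalGraph, n_lesions: int, seed: int
) -> Genotype:
    """A random genotype over the graph's non-phenotype nodes."""
    rng = np.random.default_rng(seed)
    genes = sorted(
        n.id for n in graph.nodes if n.kind != NodeKind.PHENOTYPE
    )
    if n_lesions > len(genes):
        raise ValueError("more lesions requested than available genes")
    chosen = rng.choice(len(genes), size=n_lesions, replace=False)
    lesions = tuple(
        (genes[int(i)], "LOF" if rng.random() < 0.5 else "GOF") for i in chosen
    )
    return Genotype(lesions=lesions)


def generate_clinical(
    sweep: Sequence[tuple[Genotype, PhenotypeScores]],
    slope: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    feature: str = "hazard_ratio",
    intercept: float = 0.0,
) -> ClinicalTable:
    """Synthesize a clinical feature as slope * integrated + Gaussian noise."""
    if not sweep:
        raise ValueError("sweep must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, scores in sweep:
        value = intercept + slope * scores.integrated()
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        rows.append((genotype.label, feature, float(value)))
    return ClinicalTable(rows=rows)
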