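"""Hallmark phenotype scores and genotype sweeps.

At equilibrium, the activity of each hallmark phenotype is scored additively
over its direct regulators: the sum of active upstream activators minus the
sum of active upstream inhibitors. A hallmark is maximally active when every
activator is on and every inhibitor off, so raw scores live in
``[-|inhibitors|, |activators|]``. Fractional activations (cycle averages)
propagate linearly. The single prognostic readout is the integrated network
phenotype score::

    integrated = proliferation - apoptosis - differentiation

so that a high value means unchecked growth with blocked differentiation and
evasion of cell death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .classify import APOPTOSIS, DIFFERENTIATION, PROLIFERATION
from .graph import CausalGraph, NodeKind
from .model import (
    AttractorResult,
    BooleanModel,
    Genotype,
    default_initial_state,
    find_attractors,
    prime_with_genotype,
)


@dataclass
class PhenotypeScores:
    """Per-hallmark scores at equilibrium for one genotype."""

    genotype_label: str
    scores: dict[str, float]  # hallmark -> raw additive score
    normalized: dict[str, float] = field(default_factory=dict)
    n_attractors: int = 1
    aggregated: bool = False  # True when basin-weighted over >1 attractor
    per_attractor: list[dict[str, float]] = field(default_factory=list)

    def integrated(self) -> float:
        return integrated_score(self.scores)


def phenotype_activation(
    graph: CausalGraph,
    attractor: AttractorResult,
    hallmark: str,
    attractor_index: int = 0,
    normalized: bool = False,
) -> float:
    """Additive activation of *hallmark* in one attractor.

    Sum of the hallmark's direct activators' activation values minus the sum
    of its direct inhibitors' values, cycle-averaged on cyclic attractors.
    The normalized variant divides each sum by the corresponding regulator
    count, giving a score in [-1, 1].
    """
    if hallmark not in graph or graph.kind(hallmark) != NodeKind.PHENOTYPE:
        raise ValueError(f"{hallmark!r} is not a phenotype node")
    act = attractor.activation(attractor_index)
    activators = sorted(graph.activators(hallmark))
    inhibitors = sorted(graph.inhibitors(hallmark))
    missing = [r for r in activators + inhibitors if r not in act]
    if missing:
        raise ValueError(f"attractor lacks activation values for {missing}")
    pos = sum(act[a] for a in activators)
    neg = sum(act[i] for i in inhibitors)
    if normalized:
        pos = pos / len(activators) if activators else 0.0
        neg = neg / len(inhibitors) if inhibitors else 0.0
    return pos - neg


def integrated_score(scores: Mapping[str, float]) -> float:
    """proliferation - apoptosis - differentiation."""
    missing = [h for h in (PROLIFERATION, APOPTOSIS, DIFFERENTIATION)
               if h not in scores]
    if missing:
        raise KeyError(f"missing hallmark scores: {missing}")
    return scores[PROLIFERATION] - scores[APOPTOSIS] - scores[DIFFERENTIATION]


def score_attractors(
    graph: CausalGraph,
    result: AttractorResult,
    genotype_label: str = "WT",
    hallmarks: Sequence[str] | None = None,
) -> PhenotypeScores:
    """Score every attractor; headline value is the basin-weighted mean.

    With a single attractor the headline equals that attractor's scores.
    With several, each is reported in ``per_attractor`` and the headline is
    their basin-count-weighted average, flagged via ``aggregated``.
    """
    hallmarks = list(hallmarks or graph.phenotypes())
    if not result.attractors:
        raise ValueError("attractor result is empty")
    per: list[dict[str, float]] = []
    for i in range(len(result.attractors)):
        per.append(
            {h: phenotype_activation(graph, result, h, attractor_index=i)
             for h in hallmarks}
        )
    weights = [result.basin_counts.get(i, 1) for i in range(len(per))]
    total = sum(weights)
    headline = {
        h: sum(w * p[h] for w, p in zip(weights, per)) / total for h in hallmarks
    }
    normalized = {}
    for h in hallmarks:
        norm_per = [
            phenotype_activation(graph, result, h, attractor_index=i,
                                 normalized=True)
            for i in range(len(per))
        ]
        normalized[h] = sum(w * v for w, v in zip(weights, norm_per)) / total
    return PhenotypeScores(
        genotype_label=genotype_label,
        scores=headline,
        normalized=normalized,
        n_attractors=len(per),
        aggregated=len(per) > 1,
        per_attractor=per,
    )


def genotype_sweep(
    model: BooleanModel,
    genes: Sequence[tuple[str, str]],
    initial_overrides: Mapping[str, int] | None = None,
    mode: Literal["exhaustive", "trajectory"] = "trajectory",
    n_starts: int = 1,
    seed: int | None = None,
) -> list[tuple[Genotype, PhenotypeScores]]:
    """Simulate every subset of *genes* as a mutation-specific model.

    *genes* is an ordered list of (gene, ``LOF``/``GOF``) lesions; the sweep
    enumerates its 2^m subsets in binary counting order, wild-type (empty
    subset) first. Each genotype primes a fresh copy of *model*, which is
    simulated to its attractors and scored. ``initial_overrides`` set the
    starting values of source nodes (e.g. constitutively expressed genes) in
    every run; clamps take precedence.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    if model.graph is None:
        raise ValueError("model must carry its source graph for scoring")
    records: list[tuple[Genotype, PhenotypeScores]] = []
    m = len(genes)
    for mask in range(2 ** m):
        lesions = tuple(genes[i] for i in range(m) if mask >> i & 1)
        genotype = Genotype(lesions=lesions)
        primed = prime_with_genotype(model, genotype)
        if mode == "trajectory":
            init = default_initial_state(primed, overrides=initial_overrides)
            result = find_attractors(primed, mode="trajectory", init=init,
                                     n_starts=n_starts, seed=seed)
        else:
            result = find_attractors(primed, mode="exhaustive")
        records.append(
            (genotype, score_attractors(model.graph, result, genotype.label))
        )
    return records


def sweep_table(records: Iterable[tuple[Genotype, PhenotypeScores]]):
    """Sweep results as a pandas DataFrame (one row per genotype)."""
    import pandas as pd

    rows = []
    for genotype, ps in records:
        rows.append(
            {
                "genotype": genotype.label,
                "proliferation": ps.scores.get(PROLIFERATION),
                "differentiation": ps.scores.get(DIFFERENTIATION),
                "apoptosis": ps.scores.get(APOPTOSIS),
                "integrated": ps.integrated(),
                "n_attractors": ps.n_attractors,
                "aggregated": ps.aggregated,
            }
        )
    return pd.DataFrame(rows)
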