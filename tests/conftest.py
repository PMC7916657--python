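"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hallmarknet import (
    CausalGraph,
    load_fixture,
    synthesize_rules,
)
from hallmarknet.synthetic import SyntheticNetworkSpec, generate_network


@pytest.fixture(scope="session")
def aml_module():
    return load_fixture("flt3_npm1_dnmt3a")


@pytest.fixture(scope="session")
def aml_model(aml_module):
    return synthesize_rules(aml_module.graph, overrides=aml_module.overrides)


def random_graph(seed: int, n_nodes: int = 8, density: float = 0.3,
                 inhibition: float = 0.35, n_phenotypes: int = 3) -> CausalGraph:
    return generate_network(
        SyntheticNetworkSpec(
            n_nodes=n_nodes,
            edge_density=density,
            inhibition_fraction=inhibition,
            n_phenotypes=n_phenotypes,
            seed=seed,
        )
    )


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; no calls into the code paths
# they check)
# ---------------------------------------------------------------------------

def dfs_path_effects_oracle(graph: CausalGraph, gene: str,
                            max_len: int | None = None):
    """Exhaustive DFS over signed simple paths gene -> phenotypes.

    Returns a sorted list of (hallmark, path tuple, net sign). Parallel
    both-sign edges are expanded one branch per sign.
    """
    # signed adjacency: u -> list of (v, sign)
    adj: dict[str, list[tuple[str, int]]] = {}
    for e in graph.edges:
        adj.setdefault(e.source, []).append((e.target, e.sign))
    phenotypes = set(graph.phenotypes())
    out = []

    def walk(node, path, sign):
        if node in phenotypes:
            out.append((node, tuple(path), sign))
            return
        if max_len is not None and len(path) - 1 >= max_len:
            return
        for nxt, s in adj.get(node, ()):
            if nxt in path:
                continue
            walk(nxt, path + [nxt], sign * s)

    if gene in phenotypes:
        return []
    walk(gene, [gene], 1)
    # a phenotype hit may still exceed max_len: filter by edge count
    if max_len is not None:
        out = [rec for rec in out if len(rec[1]) - 1 <= max_len]
    return sorted(out)


def truth_table_oracle(model):
    """Map every full state tuple to its successor by direct rule evaluation."""
    nodes = model.nodes
    table = {}
    for bits in itertools.product((0, 1), repeat=len(nodes)):
        state = dict(zip(nodes, bits))
        for n, v in model.clamps.items():
            state[n] = v
        key = tuple(state[n] for n in nodes)
        succ = tuple(model.rules[n].evaluate(state) for n in nodes)
        table[key] = succ
    return table


def attractors_by_table_walk(table):
    """All attractors of a successor table: follow every state until a repeat."""
    attractors = set()
    for start in table:
        seen = {}
        s = start
        path = []
        while s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = table[s]
        cycle = path[seen[s]:]
        k = min(range(len(cycle)), key=lambda i: cycle[i])
        attractors.add(tuple(cycle[k:] + cycle[:k]))
    return attractors
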