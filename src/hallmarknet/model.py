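"""Boolean model synthesis, genotype priming, and synchronous attractor analysis.

A signed causal graph is turned into a Boolean network by giving every node an
update rule built from its regulators under a combination policy:

* ``inhibitor_wins`` — any active inhibitor switches the target off:
  ``v' = OR(activators) & !OR(inhibitors)``. Nodes with only activators get
  ``OR(activators)``; nodes with only inhibitors are constitutively active
  unless inhibited, ``!OR(inhibitors)``.
* ``activator_wins`` — any active activator switches the target on regardless
  of inhibitors; with no active activator the node is off if inhibited and
  off by default, which reduces to ``OR(activators)`` when activators exist.

Nodes with no regulators hold their initial value (identity rule). Patient
genotypes enter as clamps: loss-of-function lesions pin a node to 0 (in-silico
knockout), gain-of-function lesions pin it to 1 (constitutive activation).
State updates are synchronous; attractors are fixed points or cycles of the
synchronous update map and are interpreted as stable expression patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .graph import CausalGraph
from .rules import Const, Expr, Not, Or, Var, any_of, format_expr, parse_expr

Policy = Literal["inhibitor_wins", "activator_wins", "custom"]

POLICIES = ("inhibitor_wins", "activator_wins", "custom")


@dataclass(frozen=True)
class BooleanRule:
    """An update rule: *target* takes the value of *expression* next step."""

    target: str
    expression: Expr


@dataclass(frozen=True)
class Genotype:
    """A set of (gene, lesion) pairs; LOF clamps to 0, GOF clamps to 1."""

    lesions: tuple[tuple[str, str], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.lesions]
        if len(genes) != len(set(genes)):
            raise ValueError("a gene may appear at most once in a genotype")
        for gene, lesion in self.lesions:
            if lesion not in ("LOF", "GOF"):
                raise ValueError(f"lesion for {gene} must be LOF or GOF, got {lesion!r}")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        if not self.lesions:
            return "WT"
        return "+".join(f"{g}:{t}" for g, t in sorted(self.lesions))

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        """Parse ``"GENE:LOF,GENE:GOF"``; empty or ``"WT"`` is wild-type."""
        text = text.strip()
        if not text or text.upper() == "WT":
            return cls()
        lesions = []
        for chunk in text.split(","):
            gene, _, lesion = chunk.strip().partition(":")
            lesions.append((gene, lesion.upper()))
        return cls(lesions=tuple(lesions))


class BooleanModel:
    """One update rule per node, plus clamps pinning mutated genes.

    The source :class:`CausalGraph` is retained so downstream phenotype
    scoring can find each hallmark's direct regulators.
    """

    def __init__(
        self,
        rules: Mapping[str, Expr],
        clamps: Mapping[str, int] | None = None,
        policy: str = "inhibitor_wins",
        graph: CausalGraph | None = None,
    ):
        self.rules = dict(rules)
        self.clamps = dict(clamps or {})
        self.policy = policy
        self.graph = graph
        for node, value in self.clamps.items():
            self.rules[node] = Const(int(value))
        self.nodes: tuple[str, ...] = tuple(sorted(self.rules))
        known = set(self.nodes)
        for node, expr in self.rules.items():
            unknown = expr.variables() - known
            if unknown:
                raise ValueError(
                    f"rule for {node} references unknown variables {sorted(unknown)}"
                )

    @property
    def free_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.clamps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BooleanModel):
            return NotImplemented
        return (
            {n: format_expr(e) for n, e in self.rules.items()}
            == {n: format_expr(e) for n, e in other.rules.items()}
            and self.clamps == other.clamps
            and self.policy == other.policy
        )

    def __repr__(self) -> str:
        return (
            f"BooleanModel({len(self.nodes)} nodes, {len(self.clamps)} clamps, "
            f"policy={self.policy!r})"
        )


# ---------------------------------------------------------------------------
# Rule synthesis
# ---------------------------------------------------------------------------

def synthesize_rules(
    graph: CausalGraph,
    policy: Policy = "inhibitor_wins",
    overrides: Mapping[str, Expr | str] | None = None,
) -> BooleanModel:
    """Build a Boolean model from a signed causal graph under a policy.

    Same-sign regulators combine with OR. With mixed-sign input the policy
    decides: under ``inhibitor_wins`` an active inhibitor vetoes activation;
    under ``activator_wins`` an active activator overrides inhibition.
    *overrides* replace synthesized rules verbatim (experimentally known AND
    gates enter here) and may be expression trees or rule-dialect strings.
    """
    if policy not in ("inhibitor_wins", "activator_wins"):
        raise ValueError(f"unknown policy {policy!r}")
    overrides = {
        k: (parse_expr(v) if isinstance(v, str) else v)
        for k, v in (overrides or {}).items()
    }
    node_ids = set(graph.node_ids)
    for target in overrides:
        if target not in node_ids:
            raise ValueError(f"override target {target!r} is not a node of the graph")

    rules: dict[str, Expr] = {}
    for node in graph.node_ids:
        if node in overrides:
            rules[node] = overrides[node]
            continue
        activators = sorted(graph.activators(node))
        inhibitors = sorted(graph.inhibitors(node))
        if not activators and not inhibitors:
            rules[node] = Var(node)  # input node: holds its value
        elif not inhibitors:
            rules[node] = any_of(activators)
        elif not activators:
            rules[node] = Not(any_of(inhibitors))
        elif policy == "inhibitor_wins":
            rules[node] = _and2(any_of(activators), Not(any_of(inhibitors)))
        else:  # activator_wins: off unless an activator is on
            rules[node] = any_of(activators)

    model = BooleanModel(rules, policy=policy, graph=graph)
    for target, expr in overrides.items():
        unknown = expr.variables() - node_ids
        if unknown:
            raise ValueError(
                f"override for {target} references unknown variables {sorted(unknown)}"
            )
    return model


def _and2(a: Expr, b: Expr) -> Expr:
    from .rules import And

    return And((a, b))


# ---------------------------------------------------------------------------
# Genotype priming
# ---------------------------------------------------------------------------

def prime_with_genotype(model: BooleanModel, genotype: Genotype) -> BooleanModel:
    """Return a new model with the genotype's lesions applied as clamps.

    LOF genes get the constant rule 0 (never reactivated during simulation),
    GOF genes the constant rule 1. The input model is unmodified; priming is
    idempotent.
    """
    clamps = dict(model.clamps)
    for gene, lesion in genotype.lesions:
        if gene not in model.rules:
            raise KeyError(f"genotype gene {gene!r} is not a node of the model")
        clamps[gene] = 0 if lesion == "LOF" else 1
    return BooleanModel(
        {n: e for n, e in model.rules.items()},
        clamps=clamps,
        policy=model.policy,
        graph=model.graph,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

State = dict[str, int]


def synchronous_step(model: BooleanModel, state: Mapping[str, int]) -> State:
    """Evaluate every rule simultaneously against *state*; clamps stay pinned."""
    missing = set(model.nodes) - set(state)
    if missing:
        raise ValueError(f"state vector missing nodes: {sorted(missing)}")
    return {n: model.rules[n].evaluate(state) for n in model.nodes}


def default_initial_state(
    model: BooleanModel,
    fill: int = 0,
    overrides: Mapping[str, int] | None = None,
) -> State:
    """All unclamped nodes at *fill* (default 0), clamps applied, then overrides."""
    state = {n: fill for n in model.nodes}
    state.update({n: int(v) for n, v in (overrides or {}).items() if n in state})
    state.update(model.clamps)
    return state


@dataclass
class AttractorResult:
    """Fixed points and cycles of the synchronous update map.

    Each attractor is a tuple of states (length 1 = fixed point). Basin counts
    are exact under exhaustive search, sampled counts under trajectory search.
    ``activation`` gives per-node values in [0, 1]: 0/1 at fixed points,
    cycle-averaged fractions on cycles.
    """

    nodes: tuple[str, ...]
    attractors: list[tuple[tuple[int, ...], ...]]
    basin_counts: dict[int, int] = field(default_factory=dict)
    mode: str = "exhaustive"
    n_states_explored: int = 0

    def states(self, i: int) -> list[State]:
        return [dict(zip(self.nodes, s)) for s in self.attractors[i]]

    def activation(self, i: int) -> dict[str, float]:
        arr = np.array(self.attractors[i], dtype=float)
        return dict(zip(self.nodes, arr.mean(axis=0)))

    @property
    def fixed_points(self) -> list[State]:
        return [
            dict(zip(self.nodes, a[0])) for a in self.attractors if len(a) == 1
        ]

    def is_fixed_point(self, i: int) -> bool:
        return len(self.attractors[i]) == 1


def _canonical_cycle(
    cycle: Sequence[tuple[int, ...]]
) -> tuple[tuple[int, ...], ...]:
    """Rotate a cycle so its lexicographically smallest state comes first."""
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


def find_attractors(
    model: BooleanModel,
    mode: Literal["exhaustive", "trajectory"] = "exhaustive",
    init: Mapping[str, int] | None = None,
    n_starts: int = 1,
    seed: int | None = None,
    exhaustive_bound: int = 25,
    max_steps: int = 100_000,
) -> AttractorResult:
    """Locate attractors of the synchronous dynamics.

    Exhaustive mode enumerates the full transition graph over the free
    (unclamped) nodes — exact attractors and basin sizes, feasible up to
    *exhaustive_bound* free nodes. Trajectory mode iterates from *init* (or
    *n_starts* random initial states drawn with *seed*) until a state repeats
    and reports the attractors entered, with sampled basin counts.
    """
    nodes = model.nodes
    free = model.free_nodes

    def step_tuple(state_t: tuple[int, ...]) -> tuple[int, ...]:
        state = dict(zip(nodes, state_t))
        return tuple(model.rules[n].evaluate(state) for n in nodes)

    if mode == "exhaustive":
        if len(free) > exhaustive_bound:
            raise ValueError(
                f"{len(free)} free nodes exceed the exhaustive bound "
                f"{exhaustive_bound}; use mode='trajectory'"
            )
        base = dict(model.clamps)
        all_states = []
        for bits in itertools.product((0, 1), repeat=len(free)):
            s = dict(base)
            s.update(zip(free, bits))
            all_states.append(tuple(s.get(n, 0) for n in nodes))
        return _attractors_from_starts(step_tuple, all_states, nodes, "exhaustive")

    # trajectory mode
    starts: list[tuple[int, ...]] = []
    if init is not None:
        full = default_initial_state(model, overrides=init)
        starts.append(tuple(full[n] for n in nodes))
    if not starts or n_starts > len(starts):
        if seed is None and init is None:
            raise ValueError("trajectory mode requires init or (n_starts, seed)")
        if seed is not None and n_starts > len(starts):
            rng = np.random.default_rng(seed)
            for _ in range(n_starts - len(starts)):
                bits = rng.integers(0, 2, size=len(free))
                s = dict(model.clamps)
                s.update(zip(free, (int(b) for b in bits)))
                starts.append(tuple(s.get(n, 0) for n in nodes))
    result = _attractors_from_starts(step_tuple, starts, nodes, "trajectory",
                                     max_steps=max_steps)
    return result


def _attractors_from_starts(step, starts, nodes, mode, max_steps=100_000):
    attractors: list[tuple[tuple[int, ...], ...]] = []
    attractor_index: dict[tuple[tuple[int, ...], ...], int] = {}
    state_to_attractor: dict[tuple[int, ...], int] = {}
    basin: dict[int, int] = {}

    for start in starts:
        path: list[tuple[int, ...]] = []
        seen_at: dict[tuple[int, ...], int] = {}
        s = start
        idx: int | None = None
        for _ in range(max_steps):
            if s in state_to_attractor:
                idx = state_to_attractor[s]
                break
            if s in seen_at:
                cycle = _canonical_cycle(path[seen_at[s]:])
                idx = attractor_index.get(cycle)
                if idx is None:
                    idx = len(attractors)
                    attractors.append(cycle)
                    attractor_index[cycle] = idx
                break
            seen_at[s] = len(path)
            path.append(s)
            s = step(s)
        if idx is None:
            raise RuntimeError("trajectory did not close within max_steps")
        for visited in path:
            state_to_attractor[visited] = idx
        basin[idx] = basin.get(idx, 0) + 1

    return AttractorResult(
        nodes=nodes,
        attractors=attractors,
        basin_counts=basin,
        mode=mode,
        n_states_explored=len(starts),
    )


# ---------------------------------------------------------------------------
# BoolNet text dialect I/O
# ---------------------------------------------------------------------------

def write_boolnet(model: BooleanModel, path: str | Path) -> Path:
    """Export in the "targets, factors" rules dialect for external tools.

    Clamps and the combination policy are recorded in ``#`` comment lines that
    other tools ignore and :func:`read_boolnet` restores.
    """
    path = Path(path)
    lines = [f"# policy: {model.policy}"]
    for node, value in sorted(model.clamps.items()):
        lines.append(f"# clamp: {node}={value}")
    lines.append("targets, factors")
    for node in model.nodes:
        lines.append(f"{node}, {format_expr(model.rules[node])}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_boolnet(path: str | Path) -> BooleanModel:
    """Import a rules file written by :func:`write_boolnet` or compatible tools."""
    path = Path(path)
    policy = "custom"
    clamps: dict[str, int] = {}
    rules: dict[str, Expr] = {}
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("policy:"):
                policy = body.split(":", 1)[1].strip()
            elif body.startswith("clamp:"):
                node, _, value = body.split(":", 1)[1].strip().partition("=")
                clamps[node.strip()] = int(value)
            continue
        if not header_seen:
            normalized = [t.strip().lower() for t in line.split(",")]
            if normalized != ["targets", "factors"]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'targets, factors' header"
                )
            header_seen = True
            continue
        target, _, factors = line.partition(",")
        target = target.strip()
        if not target or not factors.strip():
            raise ValueError(f"{path}:{lineno}: malformed rule line {line!r}")
        rules[target] = parse_expr(factors)
    if not header_seen:
        raise ValueError(f"{path}: missing 'targets, factors' header")
    return BooleanModel(rules, clamps=clamps, policy=policy)
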