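"""Packaged data: the synthetic FLT3-NPM1-DNMT3A module and toy driver lists.

The FLT3-NPM1-DNMT3A module is a synthetic reconstruction built from
canonical AML signaling biology (FLT3 receptor signaling through the STAT5,
PI3K-AKT and RAS-MAPK axes; NPM1 stabilization of the ARF-p53 axis; DNMT3A
repression of the HOXA9-MEIS1 program). It is sized and wired to the
published description of such co-mutation modules — 21 protein nodes plus the
three hallmark phenotypes, every genotype reaching a fixed point — but it is
not a transcription of any published rule table.

Fixture files are immutable; tests pin their SHA-256 checksums so silent
edits fail loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .graph import CausalGraph, GeneListCollection, read_gene_list, read_sif
from .rules import Expr, parse_expr

_DATA = resources.files(__package__) / "data"

FIXTURE_NAMES = ("flt3_npm1_dnmt3a",)

#: Genes retained for connectivity despite missing the consensus threshold.
CONNECTIVITY_GENES = frozenset({"MYC", "ETV6", "CBFB"})

#: Onco-fusion proteins frequently observed in AML, modeled as single nodes.
FUSION_PROTEINS = frozenset(
    {
        "AML1-ETO",
        "BCR-ABL",
        "CBFbeta-MYH11",
        "MLL-fusions",
        "PML-RARalpha",
        "NUP98-fusions",
    }
)

_DRIVER_LIST_FILES = {
    "tcga_laml": "driver_list_tcga_laml.synthetic.tsv",
    "papaemmanuil_nejm": "driver_list_papaemmanuil_nejm.synthetic.tsv",
    "cancer_gene_census": "driver_list_cancer_gene_census.synthetic.tsv",
    "disgenet_aml": "driver_list_disgenet_aml.synthetic.tsv",
}


@dataclass
class Fixture:
    """A packaged module: graph, gate overrides, and simulation defaults."""

    name: str
    graph: CausalGraph
    overrides: dict[str, Expr] = field(default_factory=dict)
    initial_state: dict[str, int] = field(default_factory=dict)
    sweep_genes: list[tuple[str, str]] = field(default_factory=list)
    drivers: list[str] = field(default_factory=list)

    def __iter__(self):
        # allow `graph, overrides = load_fixture(...)`
        return iter((self.graph, self.overrides))


def fixture_path(name: str, suffix: str) -> Path:
    return Path(str(_DATA / f"{name}.synthetic{suffix}"))


def load_fixture(name: str = "flt3_npm1_dnmt3a") -> Fixture:
    """Load a packaged module by name; raises listing available fixtures."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    config = yaml.safe_load(fixture_path(name, ".yaml").read_text())
    graph = read_sif(fixture_path(name, ".sif"), driver_ids=config.get("drivers", ()))
    overrides = {
        target: parse_expr(text)
        for target, text in (config.get("overrides") or {}).items()
    }
    return Fixture(
        name=name,
        graph=graph,
        overrides=overrides,
        initial_state={k: int(v) for k, v in (config.get("initial_state") or {}).items()},
        sweep_genes=[tuple(pair) for pair in config.get("sweep_genes", [])],
        drivers=list(config.get("drivers", [])),
    )


def load_driver_list_collection() -> GeneListCollection:
    """The packaged toy four-resource AML driver-gene lists."""
    lists = {}
    for filename in _DRIVER_LIST_FILES.values():
        name, genes = read_gene_list(Path(str(_DATA / filename)))
        lists[name] = genes
    return GeneListCollection(lists=lists)


def data_checksums() -> dict[str, str]:
    """SHA-256 of every packaged data file (immutability check)."""
    out = {}
    for entry in sorted(_DATA.iterdir(), key=lambda p: p.name):
        if entry.is_file():
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out
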