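"""The end-to-end chain: build model -> prime/sweep -> score -> correlate.

``run_pipeline`` executes the full strategy from a :class:`RunConfig` and
writes a self-describing JSON report (embedding the resolved configuration)
plus TSV tables, so a run can be reproduced exactly from its own report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .clinical import ClinicalTable, correlate_scores
from .config import RunConfig
from .fixtures import FIXTURE_NAMES, load_fixture
from .graph import read_sif
from .model import synthesize_rules
from .scoring import genotype_sweep, sweep_table

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_network(config: RunConfig):
    if config.network in FIXTURE_NAMES:
        fixture = load_fixture(config.network)
        overrides = fixture.overrides
        graph = fixture.graph
        if not config.sweep_genes:
            config.sweep_genes = [list(p) for p in fixture.sweep_genes]
        if not config.initial_overrides:
            config.initial_overrides = dict(fixture.initial_state)
        return graph, overrides
    path = Path(config.network)
    if not path.exists():
        raise PipelineError("build", f"network input {config.network!r} not found")
    return read_sif(path), {}


def run_pipeline(config: RunConfig) -> dict:
    """Run build → sweep → score → (optional) correlate; return the report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        graph, overrides = _load_network(config)
        model = synthesize_rules(graph, policy=config.policy, overrides=overrides)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build", str(exc)) from exc

    try:
        if not config.sweep_genes:
            raise ValueError("no sweep genes configured")
        genes = [(g, t) for g, t in config.sweep_genes]
        records = genotype_sweep(
            model,
            genes,
            initial_overrides=config.initial_overrides,
            mode=config.simulation_mode,
            n_starts=config.n_starts,
            seed=config.seed,
        )
    except Exception as exc:
        raise PipelineError("sweep", str(exc)) from exc

    table = sweep_table(records)
    sweep_path = out_dir / "sweep.tsv"
    table.to_csv(sweep_path, sep="\t", index=False)
    log.info("sweep: %d genotypes -> %s", len(table), sweep_path)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "hallmarknet_version": __version__,
        "config": config.to_dict(),
        "n_nodes": len(graph),
        "n_genotypes": len(records),
        "genotypes": table["genotype"].tolist(),
        "integrated_scores": table["integrated"].tolist(),
        "outputs": {"sweep": str(sweep_path)},
    }

    if config.clinical:
        try:
            clinical = ClinicalTable.read_tsv(config.clinical)
            corr = correlate_scores(
                records, clinical, use_normalized=config.normalized_scores
            )
        except Exception as exc:
            raise PipelineError("correlate", str(exc)) from exc
        corr_path = out_dir / "correlations.tsv"
        corr.to_csv(corr_path, sep="\t")
        report["outputs"]["correlations"] = str(corr_path)
        report["correlations"] = {
            score: {
                feat: corr.loc[score, feat] for feat in clinical.features
            }
            for score in corr.index
        }

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["outputs"]["report"] = str(report_path)
    return report
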