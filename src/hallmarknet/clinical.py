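"""Correlation of model phenotype scores with clinical features.

Genotype-class-level model readouts (proliferation, differentiation,
apoptosis, integrated) are matched by genotype label against user-supplied
clinical features — typically mutation-specific death hazard ratios and
peripheral-blood / bone-marrow blast percentages — and compared with the
Pearson product-moment correlation. Correlation is computed across genotype
classes, the only granularity the model produces, so n is small (8 for a
three-gene module); correlation strength, not significance, is the readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import APOPTOSIS, DIFFERENTIATION, PROLIFERATION
from .model import Genotype
from .scoring import PhenotypeScores

SCORE_TYPES = (PROLIFERATION, DIFFERENTIATION, APOPTOSIS, "integrated")


@dataclass
class ClinicalTable:
    """Long-format clinical features: (genotype label, feature, value)."""

    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for label, feature, value in self.rows:
            if not np.isfinite(value):
                raise ValueError(f"non-finite value for ({label}, {feature})")
            if (label, feature) in seen:
                raise ValueError(f"duplicate (genotype, feature) pair ({label}, {feature})")
            seen.add((label, feature))

    @property
    def features(self) -> list[str]:
        return sorted({f for _, f, _ in self.rows})

    def series(self, feature: str) -> dict[str, float]:
        return {label: v for label, f, v in self.rows if f == feature}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t")
        required = {"genotype_label", "feature", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        return cls(rows=[
            (str(r.genotype_label), str(r.feature), float(r.value))
            for r in df.itertuples()
        ])

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.rows, columns=["genotype_label", "feature", "value"]) \
            .to_csv(path, sep="\t", index=False)
        return path


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson product-moment correlation; returns (r, n).

    Raises on length mismatch, n < 3, or a constant vector (the correlation
    is undefined there — never silently reported as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, n


def correlate_scores(
    sweep: Iterable[tuple[Genotype, PhenotypeScores]],
    clinical: ClinicalTable,
    use_normalized: bool = False,
) -> pd.DataFrame:
    """Pearson r of every score type against every clinical feature.

    Genotypes are matched by label; (genotype, feature) pairs absent from the
    clinical table are dropped pairwise. Returns a DataFrame indexed by score
    type with one column per feature, plus an ``n_<feature>`` column counting
    the genotypes used.
    """
    score_rows: dict[str, dict[str, float]] = {}
    for genotype, ps in sweep:
        source = ps.normalized if use_normalized else ps.scores
        score_rows[genotype.label] = {
            PROLIFERATION: source[PROLIFERATION],
            DIFFERENTIATION: source[DIFFERENTIATION],
            APOPTOSIS: source[APOPTOSIS],
            "integrated": (
                source[PROLIFERATION] - source[APOPTOSIS] - source[DIFFERENTIATION]
            ),
        }

    matrix: dict[str, dict[str, float]] = {s: {} for s in SCORE_TYPES}
    counts: dict[str, int] = {}
    for feature in clinical.features:
        feat = clinical.series(feature)
        shared = sorted(set(score_rows) & set(feat))
        if len(shared) < 3:
            raise ValueError(
                f"feature {feature!r}: only {len(shared)} genotype labels shared "
                f"between sweep ({sorted(score_rows)}) and clinical table "
                f"({sorted(feat)}); need >= 3"
            )
        counts[feature] = len(shared)
        y = [feat[g] for g in shared]
        for score_type in SCORE_TYPES:
            x = [score_rows[g][score_type] for g in shared]
            r, _ = pearson_r(x, y)
            matrix[score_type][feature] = r

    df = pd.DataFrame(matrix).T.loc[list(SCORE_TYPES)]
    for feature, n in counts.items():
        df[f"n_{feature}"] = n
    return df
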