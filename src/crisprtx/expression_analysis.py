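"""DNA vs cDNA spacer abundance: PPTS normalization, rank correlation and
high-expression calling.

Abundances are normalized to Percentage Per Thousand Spacers (PPTS), so
each sample-fraction sums to 1000 and DNA (baseline, locus presence) and
cDNA (transcription) can be compared directly.  A spacer group is called
highly expressed when its cDNA excess over baseline is more than
``multiplier`` (default 3) times the baseline, among groups with baseline
PPTS of at least ``min_baseline`` (default 5).  Repertoire-level agreement
between fractions is summarized by Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ppts_normalize",
    "spearman_rho",
    "build_expression_records",
    "call_high_expression",
    "transcription_fraction",
    "TranscriptionSummary",
]


def ppts_normalize(counts: Mapping[Hashable, float]) -> dict[Hashable, float]:
    """Normalize counts so they sum to 1000 (Percentage Per Thousand Spacers)."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("cannot normalize all-zero counts")
    return {k: 1000.0 * v / total for k, v in counts.items()}


def spearman_rho(
    x: Mapping[Hashable, float],
    y: Mapping[Hashable, float],
    keys: Literal["union", "intersection"] = "union",
) -> float:
    """Spearman rank correlation between two abundance maps.

    Keys absent from one map count as abundance 0 under the default
    ``union`` policy.  Ranks use average-rank tie handling; with ties the
    coefficient is Pearson's r on the ranks, without ties the classical
    1 - 6*sum(d^2) / (n(n^2-1)).  Requires >= 3 shared keys; constant
    inputs (all ranks tied) are undefined and raise.
    """
    if keys == "union":
        ks = sorted(set(x) | set(y), key=repr)
    else:
        ks = sorted(set(x) & set(y), key=repr)
    if len(ks) < 3:
        raise ValueError("need >= 3 shared keys for a rank correlation")
    xv = np.array([float(x.get(k, 0.0)) for k in ks])
    yv = np.array([float(y.get(k, 0.0)) for k in ks])
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rx = rankdata(xv)
    ry = rankdata(yv)
    n = len(ks)
    ties = len(np.unique(xv)) < n or len(np.unique(yv)) < n
    if ties:
        return float(np.corrcoef(rx, ry)[0, 1])
    d = rx - ry
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def build_expression_records(
    dna_counts: Mapping[Hashable, float],
    cdna_counts: Mapping[Hashable, float],
    multiplier: float = 3.0,
    min_baseline: float = 5.0,
) -> pd.DataFrame:
    """Per-group expression table over the union of DNA and cDNA groups.

    Columns: ppts_dna, ppts_cdna, residual (= ppts_cdna - ppts_dna),
    eligible (baseline >= ``min_baseline``), highly_expressed (eligible and
    residual > multiplier * baseline).  Groups present only in cDNA have
    baseline 0 and are never eligible; they are kept in the table so the
    caller can report them separately.
    """
    ppts_dna = ppts_normalize(dna_counts)
    ppts_cdna = ppts_normalize(cdna_counts)
    ids = sorted(set(ppts_dna) | set(ppts_cdna), key=repr)
    df = pd.DataFrame(
        {
            "group_id": ids,
            "ppts_dna": [ppts_dna.get(i, 0.0) for i in ids],
            "ppts_cdna": [ppts_cdna.get(i, 0.0) for i in ids],
        }
    )
    df["residual"] = df["ppts_cdna"] - df["ppts_dna"]
    df["eligible"] = df["ppts_dna"] >= min_baseline
    df["highly_expressed"] = df["eligible"] & (df["residual"] > multiplier * df["ppts_dna"])
    return df


def call_high_expression(
    records: pd.DataFrame, multiplier: float = 3.0, min_baseline: float = 5.0
) -> pd.DataFrame:
    """Re-apply the high-expression rule and return the flagged subset."""
    df = records.copy()
    df["eligible"] = df["ppts_dna"] >= min_baseline
    df["highly_expressed"] = df["eligible"] & (
        (df["ppts_cdna"] - df["ppts_dna"]) > multiplier * df["ppts_dna"]
    )
    return df[df["highly_expressed"]].reset_index(drop=True)


@dataclass(frozen=True)
class TranscriptionSummary:
    fraction_transcribed: float  # of DNA groups, the share also seen in cDNA
    n_dna: int
    n_both: int
    n_cdna_only: int


def transcription_fraction(
    dna_counts: Mapping[Hashable, float], cdna_counts: Mapping[Hashable, float]
) -> TranscriptionSummary:
    """Share of DNA-detected spacer groups that are also detected in cDNA.

    Groups found only in cDNA are counted separately, never in the
    denominator.  Raises if no group has a positive DNA count.
    """
    dna = {k for k, v in dna_counts.items() if v > 0}
    cdna = {k for k, v in cdna_counts.items() if v > 0}
    if not dna:
        raise ValueError("transcription fraction undefined without DNA groups")
    both = dna & cdna
    return TranscriptionSummary(
        fraction_transcribed=len(both) / len(dna),
        n_dna=len(dna),
        n_both=len(both),
        n_cdna_only=len(cdna - dna),
    )
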