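"""End-to-end orchestration: reads -> spacers -> groups -> loci.

Thin glue over the per-stage modules, used by the command-line interface
and by whole-pipeline evaluations against simulated truth sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from . import locus_assembly, read_processing, spacer_binning, synthetic_data
from .locus_assembly import AssemblyResult, EncodedRead
from .read_processing import AmpliconRead, RepeatMotifSpec
from .spacer_binning import SpacerGroup
from .synthetic_data import SimulationConfig, TruthSet

__all__ = [
    "extract_sample_spacers",
    "SubjectAnalysis",
    "analyze_sample",
    "RecoveryReport",
    "locus_recovery",
    "spacer_count_table",
]


def extract_sample_spacers(
    reads: Iterable[AmpliconRead],
    motif: RepeatMotifSpec,
    error_cutoff: float = 0.05,
    complexity_threshold: float = 1.5,
) -> tuple[list[tuple[str, list[str]]], pd.DataFrame]:
    """Trim/filter reads and extract their spacers.

    Returns ([(read_id, [spacer, ...]), ...] for reads with >= 1 spacer,
    reject log as a DataFrame(read_id, reason)).
    """
    per_read: list[tuple[str, list[str]]] = []
    rejects = []
    for read in reads:
        result = read_processing.trim_and_filter(read, error_cutoff, complexity_threshold)
        if not result.passed:
            rejects.append({"read_id": read.id, "reason": result.reason})
            continue
        spacers = read_processing.extract_spacers(result.read, motif)
        if spacers:
            per_read.append((read.id, [s.sequence for s in spacers]))
    return per_read, pd.DataFrame(rejects, columns=["read_id", "reason"])


@dataclass
class SubjectAnalysis:
    subject: Optional[str]
    fraction: Optional[str]
    groups: list[SpacerGroup]
    encoded_reads: list[EncodedRead]
    n_unencoded_reads: int
    assembly: AssemblyResult

    def locus_spacer_tuples(self) -> list[tuple[str, ...]]:
        """Auto loci as ordered representative-sequence tuples."""
        rep = {g.group_id: g.representative for g in self.groups}
        return [tuple(rep[i] for i in locus.id_sequence) for locus in self.assembly.auto_loci]


def analyze_sample(
    reads: Iterable[AmpliconRead],
    motif: RepeatMotifSpec,
    subject: Optional[str] = None,
    fraction: Optional[str] = None,
    error_cutoff: float = 0.05,
    complexity_threshold: float = 1.5,
    min_group_count: int = 2,
    high: float = 0.60,
    low: float = 0.20,
    denominator: Literal["opportunity", "min_occurrence"] = "opportunity",
    binning_mode: Literal["edit", "adaptive"] = "edit",
) -> SubjectAnalysis:
    """Run one sample through extraction, binning, encoding and assembly.

    ``min_group_count`` suppresses groups supported by fewer reads before
    encoding; such singleton "spacers" are overwhelmingly repeat-corruption
    artifacts (a sequencing error inside an interior repeat fuses two
    spacers and the broken repeat into one novel sequence) and would
    otherwise seed spurious high-support adjacencies.
    """
    per_read, _ = extract_sample_spacers(reads, motif, error_cutoff, complexity_threshold)
    if not per_read:
        raise ValueError("no spacers extracted from sample")
    groups = spacer_binning.bin_spacers(
        (s for _, seqs in per_read for s in seqs), mode=binning_mode
    )
    kept = [g for g in groups if g.total >= min_group_count]
    mapping = locus_assembly.group_index(kept)
    encoded, dropped = locus_assembly.encode_reads(per_read, mapping)
    table = locus_assembly.build_adjacency(encoded)
    assembly = locus_assembly.assemble_loci(
        table, encoded, high=high, low=low, denominator=denominator,
        subject=subject, fraction=fraction,
    )
    return SubjectAnalysis(
        subject=subject,
        fraction=fraction,
        groups=kept,
        encoded_reads=encoded,
        n_unencoded_reads=dropped,
        assembly=assembly,
    )


@dataclass
class RecoveryReport:
    n_truth_loci: int
    n_exact: int
    per_subject: pd.DataFrame

    @property
    def recovery_rate(self) -> float:
        return self.n_exact / self.n_truth_loci if self.n_truth_loci else 0.0


def locus_recovery(
    config: SimulationConfig,
    truth: Optional[TruthSet] = None,
    fraction: Literal["DNA", "cDNA"] = "DNA",
    **analyze_kwargs,
) -> tuple[RecoveryReport, TruthSet]:
    """Simulate a study and measure exact locus reconstruction.

    A truth locus counts as exactly recovered when some automatically
    assembled locus of the same subject has the identical ordered spacer
    sequence (representatives), in either orientation.
    """
    if truth is None:
        truth = synthetic_data.generate_repertoire(config)
    reads = synthetic_data.generate_amplicon_reads(truth, config, fraction)
    motif = RepeatMotifSpec(crispr_type="SIM", repeat=config.repeat_sequence)
    demux = read_processing.demultiplex(reads, truth.barcodes)
    rows = []
    n_truth = 0
    n_exact = 0
    for label, _status in truth.subjects:
        truth_tuples = [lt.spacers for lt in truth.loci[label]]
        n_truth += len(truth_tuples)
        subject_reads = demux.assigned.get(label, [])
        if not subject_reads:
            rows.append({"subject": label, "n_truth": len(truth_tuples), "n_exact": 0})
            continue
        analysis = analyze_sample(
            subject_reads, motif, subject=label, fraction=fraction, **analyze_kwargs
        )
        assembled = {t for t in analysis.locus_spacer_tuples()}
        assembled |= {t[::-1] for t in analysis.locus_spacer_tuples()}
        exact = sum(1 for t in truth_tuples if t in assembled)
        n_exact += exact
        rows.append({"subject": label, "n_truth": len(truth_tuples), "n_exact": exact})
    report = RecoveryReport(
        n_truth_loci=n_truth,
        n_exact=n_exact,
        per_subject=pd.DataFrame(rows, columns=["subject", "n_truth", "n_exact"]),
    )
    return report, truth


def spacer_count_table(
    reads_by_fraction: dict[str, Iterable[AmpliconRead]],
    motif: RepeatMotifSpec,
    barcodes: dict[str, str],
    error_cutoff: float = 0.05,
    complexity_threshold: float = 1.5,
) -> pd.DataFrame:
    """Demultiplex both fractions and tabulate spacer counts.

    Returns a long DataFrame(sequence, subject, fraction, count) suitable
    for :func:`crisprtx.spacer_binning.bin_spacer_table`.
    """
    rows: dict[tuple[str, str, str], int] = {}
    for fraction, reads in reads_by_fraction.items():
        demux = read_processing.demultiplex(reads, barcodes)
        for label, subject_reads in demux.assigned.items():
            per_read, _ = extract_sample_spacers(
                subject_reads, motif, error_cutoff, complexity_threshold
            )
            for _, seqs in per_read:
                for s in seqs:
                    key = (s, label, fraction)
                    rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [
            {"sequence": s, "subject": subj, "fraction": frac, "count": c}
            for (s, subj, frac), c in rows.items()
        ],
        columns=["sequence", "subject", "fraction", "count"],
    )
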