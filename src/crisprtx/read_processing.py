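"""Demultiplexing, trimming, filtering and repeat-anchored spacer extraction.

Amplicon reads produced by repeat-based PCR have the layout

    barcode + [partial repeat] spacer repeat spacer ... [partial repeat]

A spacer is any sequence of length >= ``min_spacer_length`` (default 20)
found between two *exact, full* copies of the direct-repeat motif.  Reads
are demultiplexed on exact 10-nt barcodes, quality-trimmed with a
running-sum (Mott-style) algorithm, and screened for ambiguous characters
and low 3-mer entropy before extraction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "AmpliconRead",
    "RepeatMotifSpec",
    "ExtractedSpacer",
    "DemultiplexResult",
    "TrimFilterResult",
    "revcomp",
    "demultiplex",
    "trim_and_filter",
    "extract_spacers",
    "read_fastq",
    "read_fasta",
    "write_fastq",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AmpliconRead:
    """A single amplicon read, optionally with Phred qualities.

    ``qualities`` are Phred scores (Sanger scale), one per base, or None
    for FASTA input.  ``subject`` and ``fraction`` are filled in by
    demultiplexing / the caller.
    """

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    subject: Optional[str] = None
    fraction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class RepeatMotifSpec:
    """Direct-repeat motif used to anchor spacer extraction.

    ``crispr_type`` is a free label (SGI, SGII, GHI, VSI, or user-defined);
    the repeat string itself is what extraction matches against, exactly.
    """

    crispr_type: str
    repeat: str
    min_spacer_length: int = 20

    def __post_init__(self) -> None:
        if not self.repeat:
            raise ValueError("repeat motif must be non-empty")
        if self.min_spacer_length < 20:
            raise ValueError("min_spacer_length must be >= 20")


@dataclass(frozen=True)
class ExtractedSpacer:
    read_id: str
    ordinal: int  # 0-based index among the read's qualifying spacers
    sequence: str


@dataclass
class DemultiplexResult:
    assigned: dict[str, list[AmpliconRead]]
    rejected: list[AmpliconRead]
    counts: dict[str, int]


def demultiplex(
    reads: Iterable[AmpliconRead], barcode_map: Mapping[str, str]
) -> DemultiplexResult:
    """Bin reads by 100%-matching barcode prefixes.

    A read is assigned to a label iff its prefix equals that label's
    barcode exactly; the barcode (and its qualities) are stripped from
    assigned reads.  Everything else goes to the reject bin.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError("barcodes must all have the same length")
    blen = lengths.pop() if lengths else 0

    lookup = {bc: label for label, bc in barcode_map.items()}
    assigned: dict[str, list[AmpliconRead]] = {label: [] for label in barcode_map}
    rejected: list[AmpliconRead] = []
    for read in reads:
        label = lookup.get(read.sequence[:blen]) if blen else None
        if label is None:
            rejected.append(read)
            continue
        quals = None if read.qualities is None else list(read.qualities)[blen:]
        assigned[label].append(
            replace(read, sequence=read.sequence[blen:], qualities=quals, subject=label)
        )
    counts = {label: len(rs) for label, rs in assigned.items()}
    counts["rejected"] = len(rejected)
    return DemultiplexResult(assigned=assigned, rejected=rejected, counts=counts)


def _mott_trim_end(qualities: Sequence[int], error_cutoff: float) -> int:
    """Return the end index of the best prefix under running-sum trimming.

    Accumulates (cutoff - p_error) per base from the 5' end and keeps the
    prefix ending at the running-sum maximum; a read whose first bases are
    already bad is trimmed to nothing (end = 0).
    """
    best_end = 0
    best_score = 0.0
    score = 0.0
    for i, q in enumerate(qualities):
        score += error_cutoff - 10.0 ** (-q / 10.0)
        if score > best_score:
            best_score = score
            best_end = i + 1
    return best_end


def kmer_entropy(seq: str, k: int = 3) -> float:
    """Shannon entropy (bits) of the overlapping k-mer composition."""
    n = len(seq) - k + 1
    if n <= 0:
        return 0.0
    counts = Counter(seq[i : i + k] for i in range(n))
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


@dataclass
class TrimFilterResult:
    read: Optional[AmpliconRead]
    reason: Optional[str]  # None if the read passed

    @property
    def passed(self) -> bool:
        return self.read is not None


def trim_and_filter(
    read: AmpliconRead,
    error_cutoff: float = 0.05,
    complexity_threshold: float = 1.5,
) -> TrimFilterResult:
    """Quality-trim and screen one read; rejection is an outcome, not an error.

    Order of operations: Mott-style prefix trim (skipped for FASTA input),
    then rejection of empty reads, reads with non-ACGT characters, and reads
    whose 3-mer entropy falls below ``complexity_threshold`` bits.

    ``error_cutoff`` is a per-base error probability.  The value 0.5 is
    accepted as a legacy alias for the default 0.05.
    """
    if error_cutoff >= 0.5:
        error_cutoff = 0.05
    seq = read.sequence
    quals = read.qualities
    if quals is not None:
        end = _mott_trim_end(quals, error_cutoff)
        seq = seq[:end]
        quals = list(quals)[:end]
    if not seq:
        return TrimFilterResult(None, "empty_after_trim")
    if any(c not in "ACGT" for c in seq):
        return TrimFilterResult(None, "ambiguous")
    if kmer_entropy(seq) < complexity_threshold:
        return TrimFilterResult(None, "low_complexity")
    return TrimFilterResult(replace(read, sequence=seq, qualities=quals), None)


def _occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of non-overlapping, leftmost occurrences of motif."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + len(motif))
    return out


def extract_spacers(read: AmpliconRead, motif: RepeatMotifSpec) -> list[ExtractedSpacer]:
    """Extract repeat-anchored spacers from one read, in repeat orientation.

    The read is first canonicalized: if the reverse complement of the
    repeat occurs more often than the repeat itself, the read is reverse
    complemented, so spacer order is always reported in repeat orientation.
    A spacer must be flanked by exact, full repeat copies on both sides and
    be at least ``min_spacer_length`` long; reads with no qualifying spacer
    return an empty list.
    """
    seq = read.sequence
    fwd = _occurrences(seq, motif.repeat)
    rev = _occurrences(seq, revcomp(motif.repeat))
    if len(rev) > len(fwd):
        seq = revcomp(seq)
        fwd = _occurrences(seq, motif.repeat)
    spacers = []
    rlen = len(motif.repeat)
    for a, b in zip(fwd, fwd[1:]):
        inner = seq[a + rlen : b]
        if len(inner) >= motif.min_spacer_length:
            spacers.append(
                ExtractedSpacer(read_id=read.id, ordinal=len(spacers), sequence=inner)
            )
    return spacers


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (Sanger Phred+33)


def read_fastq(path, fraction: Optional[str] = None) -> list[AmpliconRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            AmpliconRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                fraction=fraction,
            )
        )
    return reads


def read_fasta(path, fraction: Optional[str] = None) -> list[AmpliconRead]:
    return [
        AmpliconRead(id=rec.id, sequence=str(rec.seq).upper(), fraction=fraction)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads: Iterable[AmpliconRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.qualities is None:
                raise ValueError(f"read {r.id!r} has no qualities; use write_fasta")
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(reads: Iterable[AmpliconRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
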