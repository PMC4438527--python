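"""Exact matching of spacer groups against virome reads.

A spacer group matches a virome read when any of its member sequences
occurs verbatim as a substring of the read (or of the read's reverse
complement, by default) — the protospacer criterion.  Matches are
aggregated per reconstructed locus into none / single / multiple
categories, and a permutation test asks whether virome-matched spacers
concentrate in fewer loci than random placement would produce.

An import hook for externally produced BLAST tabular hits (outfmt 6) with
the conventional bit-score >= 45 filter is provided for users who search
large nucleotide databases outside this package.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .locus_assembly import Locus
from .read_processing import revcomp
from .spacer_binning import SpacerGroup

__all__ = [
    "ViromeMatch",
    "ViromeMatchTable",
    "match_spacers",
    "summarize_locus_matches",
    "match_enrichment_test",
    "load_blast_hits",
]


@dataclass(frozen=True)
class ViromeMatch:
    group_id: int
    read_id: str
    strand: str  # "forward" | "reverse"
    member: str


@dataclass
class ViromeMatchTable:
    hits: list[ViromeMatch]

    def by_group(self) -> dict[int, list[ViromeMatch]]:
        out: dict[int, list[ViromeMatch]] = defaultdict(list)
        for h in self.hits:
            out[h.group_id].append(h)
        return dict(out)

    def matched_groups(self) -> set[int]:
        return {h.group_id for h in self.hits}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group_id": h.group_id, "read_id": h.read_id, "strand": h.strand, "member": h.member}
                for h in self.hits
            ],
            columns=["group_id", "read_id", "strand", "member"],
        )


def _scan(seq: str, seeds: Mapping[str, list[tuple[int, str]]], seed_len: int):
    """Yield (group_id, member, position) for full-length member hits in seq."""
    for i in range(len(seq) - seed_len + 1):
        bucket = seeds.get(seq[i : i + seed_len])
        if not bucket:
            continue
        for gid, member in bucket:
            if seq.startswith(member, i):
                yield gid, member, i


def match_spacers(
    groups: Iterable[SpacerGroup],
    virome: Iterable[tuple[str, str]],
    search_revcomp: bool = True,
) -> ViromeMatchTable:
    """Find exact, full-length occurrences of any group member in virome reads.

    ``virome`` yields (read_id, sequence) pairs over {A, C, G, T, N}.
    Matching is seed-and-verify: 20-mer prefixes of all members are hashed
    and each read (and, when enabled, its reverse complement) is scanned
    once, so runtime scales with total read length rather than with
    groups x reads.
    """
    seed_len = 20  # spacers are >= 20 nt by definition
    seeds: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in groups:
        for member in g.member_counts:
            if len(member) < seed_len:
                raise ValueError(f"spacer member shorter than {seed_len} nt: {member!r}")
            seeds[member[:seed_len]].append((g.group_id, member))
    hits: list[ViromeMatch] = []
    seen: set[tuple[int, str, str]] = set()
    for read_id, seq in virome:
        seq = seq.upper()
        for gid, member, _ in _scan(seq, seeds, seed_len):
            key = (gid, read_id, "forward")
            if key not in seen:
                seen.add(key)
                hits.append(ViromeMatch(gid, read_id, "forward", member))
        if search_revcomp:
            rc = revcomp(seq)
            for gid, member, _ in _scan(rc, seeds, seed_len):
                key = (gid, read_id, "reverse")
                if key not in seen:
                    seen.add(key)
                    hits.append(ViromeMatch(gid, read_id, "reverse", member))
    return ViromeMatchTable(hits=hits)


def summarize_locus_matches(
    loci: Iterable[Locus],
    table: ViromeMatchTable,
    transcribed_ids: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-locus virome-match summary.

    Columns: locus_id, n_groups, n_matched (distinct matched groups in the
    locus), category (none / single / multiple), match_ratio, transcribed.
    Category counts are orientation-free by construction (membership does
    not depend on spacer order).
    """
    matched = table.matched_groups()
    rows = []
    for locus in loci:
        m = sum(1 for gid in locus.id_sequence if gid in matched)
        category = "none" if m == 0 else ("single" if m == 1 else "multiple")
        rows.append(
            {
                "locus_id": locus.locus_id,
                "n_groups": len(locus.id_sequence),
                "n_matched": m,
                "category": category,
                "match_ratio": m / len(locus.id_sequence),
                "transcribed": (
                    locus.locus_id in transcribed_ids if transcribed_ids is not None else None
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "n_groups", "n_matched", "category", "match_ratio", "transcribed"],
    )


def category_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    """Aggregate none/single/multiple percentages, split by transcription
    status when available (the shape behind locus-level match figures)."""
    df = summary.copy()
    if df["transcribed"].notna().any():
        out = (
            df.groupby(["transcribed", "category"]).size().unstack(fill_value=0)
        )
    else:
        out = df.groupby("category").size().to_frame().T
    for cat in ("none", "single", "multiple"):
        if cat not in out.columns:
            out[cat] = 0
    out = out[["none", "single", "multiple"]]
    return 100.0 * out.div(out.sum(axis=1), axis=0)


def match_enrichment_test(
    summary: pd.DataFrame,
    n_iterations: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Do virome matches concentrate in fewer loci than chance placement?

    The concentration statistic is the number of "excess" matches beyond
    one per matched locus, sum(max(0, m_l - 1)); the null redistributes the
    observed number of matched spacer slots uniformly (without
    replacement) across all spacer slots of the same loci.  Returns the
    fraction of permutations with concentration >= observed.  A single
    locus admits no alternative arrangement: p = 1 by convention.
    """
    sizes = summary["n_groups"].to_numpy()
    matched = summary["n_matched"].to_numpy()
    m_total = int(matched.sum())
    if m_total == 0:
        raise ValueError("enrichment test undefined with zero matches")
    if len(sizes) < 2:
        return 1.0
    observed = int(np.maximum(matched - 1, 0).sum())
    locus_of_slot = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    n_slots = len(locus_of_slot)
    hits = 0
    for _ in range(n_iterations):
        chosen = rng.choice(n_slots, size=m_total, replace=False)
        per_locus = np.bincount(locus_of_slot[chosen], minlength=len(sizes))
        if int(np.maximum(per_locus - 1, 0).sum()) >= observed:
            hits += 1
    return hits / n_iterations


def load_blast_hits(path, min_bitscore: float = 45.0) -> pd.DataFrame:
    """Import BLAST tabular (outfmt 6) hits, keeping bit scores >= 45.

    For users who run an external nucleotide-database search; the returned
    frame has the standard 12 outfmt-6 columns filtered on ``bitscore``.
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    return df[df["bitscore"] >= min_bitscore].reset_index(drop=True)
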