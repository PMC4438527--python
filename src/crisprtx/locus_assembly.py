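"""Reconstruction of CRISPR loci from multi-spacer reads.

Each read becomes an ordered list of spacer-group identifiers; directed
adjacencies between identifiers are counted across reads, and loci are
rebuilt by greedily chaining well-supported adjacencies.  Adjacency
support is, by default, the fraction of *opportunities* realized: a read
offers an opportunity for the ordered pair (a, b) when a is observed with
some flanked successor or b with some flanked predecessor, so a perfectly
linked pair scores 1.0 even though a short read rarely spans a whole
locus.  (The alternative denominator min(occurrences) is available but
systematically underscores true pairs when reads span only ~2 spacers.)

Edges with support above ``high`` (default 0.60) are chained automatically;
edges between ``low`` (0.20) and ``high`` form lower-confidence
"manual candidate" loci for review; reads whose spacer order contradicts
the majority orientation of a pair are discarded before assembly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .spacer_binning import SpacerGroup

__all__ = [
    "EncodedRead",
    "AdjacencyTable",
    "Locus",
    "AssemblyResult",
    "group_index",
    "encode_reads",
    "build_adjacency",
    "assemble_loci",
    "compare_fraction_loci",
    "loci_to_fasta",
]


@dataclass(frozen=True)
class EncodedRead:
    read_id: str
    id_sequence: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.id_sequence) < 1:
            raise ValueError("encoded read needs at least one id")


def group_index(groups: Iterable[SpacerGroup]) -> dict[str, int]:
    """Map every member sequence to its group id; duplicates are a binning bug."""
    mapping: dict[str, int] = {}
    for g in groups:
        for member in g.member_counts:
            if member in mapping and mapping[member] != g.group_id:
                raise ValueError(
                    f"sequence {member!r} maps to groups {mapping[member]} and {g.group_id}"
                )
            mapping[member] = g.group_id
    return mapping


def encode_reads(
    spacer_reads: Iterable[tuple[str, Sequence[str]]],
    seq_to_group: Mapping[str, int],
) -> tuple[list[EncodedRead], int]:
    """Turn per-read spacer sequences into ordered id lists.

    Reads with zero mapped spacers are dropped; the count of dropped reads
    is returned alongside the encoded reads.
    """
    encoded = []
    dropped = 0
    for read_id, seqs in spacer_reads:
        ids = tuple(seq_to_group[s] for s in seqs if s in seq_to_group)
        if ids:
            encoded.append(EncodedRead(read_id=read_id, id_sequence=ids))
        else:
            dropped += 1
    return encoded, dropped


@dataclass
class AdjacencyTable:
    """Directed adjacency statistics over encoded reads.

    ``counts[(a, b)]`` — reads in which b immediately follows a.
    ``occurrences[a]`` — total read occurrences of a.
    ``opportunities[(a, b)]`` — reads in which the pair could have been
    observed adjacent (a seen with a successor, or b with a predecessor).
    ``flagged_read_ids`` — reads carrying a minority-direction adjacency
    (order-altered reads, excluded from assembly).
    """

    counts: dict[tuple[int, int], int]
    occurrences: dict[int, int]
    opportunities: dict[tuple[int, int], int]
    flagged_read_ids: set[str]

    def support(
        self,
        a: int,
        b: int,
        denominator: Literal["opportunity", "min_occurrence"] = "opportunity",
    ) -> float:
        c = self.counts.get((a, b), 0)
        if c == 0:
            return 0.0
        if denominator == "min_occurrence":
            denom = min(self.occurrences[a], self.occurrences[b])
        else:
            denom = self.opportunities[(a, b)]
        return c / denom if denom else 0.0


def build_adjacency(reads: Iterable[EncodedRead]) -> AdjacencyTable:
    """Count directed adjacencies, occurrences and opportunities.

    If both (a, b) and (b, a) are observed, the minority direction's reads
    are flagged as order-altered (ties flag the lexicographically larger
    ordered pair, deterministically).
    """
    reads = list(reads)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    occurrences: dict[int, int] = defaultdict(int)
    pair_reads: dict[tuple[int, int], list[str]] = defaultdict(list)
    has_successor: dict[int, set[int]] = defaultdict(set)  # id -> read indices
    has_predecessor: dict[int, set[int]] = defaultdict(set)

    for ridx, read in enumerate(reads):
        ids = read.id_sequence
        for x in ids:
            occurrences[x] += 1
        for j, (a, b) in enumerate(zip(ids, ids[1:])):
            counts[(a, b)] += 1
            pair_reads[(a, b)].append(read.read_id)
            has_successor[a].add(ridx)
            has_predecessor[b].add(ridx)

    opportunities = {
        (a, b): len(has_successor[a] | has_predecessor[b]) for (a, b) in counts
    }

    flagged: set[str] = set()
    for (a, b), c_ab in list(counts.items()):
        if a < b and (b, a) in counts:
            c_ba = counts[(b, a)]
            minority = (b, a) if c_ba <= c_ab else (a, b)
            flagged.update(pair_reads[minority])
    return AdjacencyTable(
        counts=dict(counts),
        occurrences=dict(occurrences),
        opportunities=opportunities,
        flagged_read_ids=flagged,
    )


@dataclass
class Locus:
    locus_id: str
    subject: Optional[str]
    fraction: Optional[str]
    id_sequence: tuple[int, ...]
    min_support: float
    status: Literal["auto", "manual_candidate"]

    def __post_init__(self) -> None:
        if len(self.id_sequence) < 2:
            raise ValueError("a locus needs >= 2 spacer groups")
        if len(set(self.id_sequence)) != len(self.id_sequence):
            raise ValueError("group ids repeat within a locus")

    def canonical(self) -> tuple[int, ...]:
        """Orientation-free form: the lexicographically smaller direction."""
        rev = self.id_sequence[::-1]
        return min(self.id_sequence, rev)


@dataclass
class AssemblyResult:
    auto_loci: list[Locus]
    manual_candidates: list[Locus]
    discarded_read_ids: set[str]

    @property
    def loci(self) -> list[Locus]:
        return self.auto_loci + self.manual_candidates


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _chain_edges(
    edges: list[tuple[float, int, tuple[int, int]]],
) -> list[tuple[tuple[int, ...], float]]:
    """Greedy path assembly: highest support first, one successor/predecessor
    per id, cycles refused (the lowest-support closing edge is skipped)."""
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    support_of: dict[tuple[int, int], float] = {}
    uf = _UnionFind()
    for support, count, (a, b) in sorted(
        edges, key=lambda e: (-e[0], -e[1], e[2])
    ):
        if a in succ or b in pred:
            continue
        if uf.find(a) == uf.find(b):
            continue  # would close a cycle; this is its lowest-support edge
        succ[a] = b
        pred[b] = a
        support_of[(a, b)] = support
        uf.union(a, b)
    chains = []
    starts = [a for a in succ if a not in pred]
    for start in starts:
        chain = [start]
        supports = []
        while chain[-1] in succ:
            nxt = succ[chain[-1]]
            supports.append(support_of[(chain[-1], nxt)])
            chain.append(nxt)
        if len(chain) >= 2:
            chains.append((tuple(chain), min(supports)))
    return chains


def assemble_loci(
    table: AdjacencyTable,
    reads: Iterable[EncodedRead],
    high: float = 0.60,
    low: float = 0.20,
    denominator: Literal["opportunity", "min_occurrence"] = "opportunity",
    subject: Optional[str] = None,
    fraction: Optional[str] = None,
) -> AssemblyResult:
    """Chain well-supported adjacencies into loci.

    Order-altered reads flagged in ``table`` are excluded and adjacency is
    recounted on the remainder.  Edges with support > ``high`` are chained
    greedily into ``auto`` loci (an id joins at most one); edges with
    ``low`` < support <= ``high`` are chained separately into
    ``manual_candidate`` loci (an automated stand-in for by-hand placement
    of lower-abundance alternative loci); edges at or below ``low`` are
    ignored.  Loci are sorted longest first and numbered deterministically.
    """
    reads = list(reads)
    kept = [r for r in reads if r.read_id not in table.flagged_read_ids]
    clean = build_adjacency(kept)

    edges_high = []
    edges_manual = []
    for (a, b), count in clean.counts.items():
        # drop residual minority directions so chains are orientation-consistent
        if (b, a) in clean.counts and clean.counts[(b, a)] > count:
            continue
        s = clean.support(a, b, denominator)
        if s > high:
            edges_high.append((s, count, (a, b)))
        elif s > low:
            edges_manual.append((s, count, (a, b)))

    auto = _chain_edges(edges_high)
    manual = _chain_edges(edges_manual)

    def _emit(chains, status):
        chains = sorted(chains, key=lambda c: (-len(c[0]), c[0]))
        out = []
        for i, (ids, min_support) in enumerate(chains):
            prefix = f"{subject}:" if subject else ""
            frac = f"{fraction}:" if fraction else ""
            out.append(
                Locus(
                    locus_id=f"{prefix}{frac}{status}:L{i + 1:03d}",
                    subject=subject,
                    fraction=fraction,
                    id_sequence=ids,
                    min_support=min_support,
                    status=status,
                )
            )
        return out

    return AssemblyResult(
        auto_loci=_emit(auto, "auto"),
        manual_candidates=_emit(manual, "manual_candidate"),
        discarded_read_ids=set(table.flagged_read_ids),
    )


def _longest_common_run(x: tuple[int, ...], y: tuple[int, ...]) -> int:
    """Length of the longest contiguous run of ids shared by x and y."""
    best = 0
    for y_or in (y, y[::-1]):
        prev = [0] * (len(y_or) + 1)
        for xi in x:
            cur = [0] * (len(y_or) + 1)
            for j, yj in enumerate(y_or):
                if xi == yj:
                    cur[j + 1] = prev[j] + 1
                    best = max(best, cur[j + 1])
            prev = cur
    return best


def compare_fraction_loci(
    dna: Iterable[Locus], cdna: Iterable[Locus]
) -> pd.DataFrame:
    """Match DNA-fraction loci to cDNA-fraction loci of the same subject.

    Pairs are formed greedily by descending shared-run length (orientation
    free).  Labels: ``identical`` (same id sequence up to orientation),
    ``partial`` (shared contiguous run of >= 2 ids), ``fraction_unique``.
    """
    dna = list(dna)
    cdna = list(cdna)
    scores = []
    for i, d in enumerate(dna):
        for j, c in enumerate(cdna):
            run = _longest_common_run(d.id_sequence, c.id_sequence)
            if run >= 2:
                scores.append((run, i, j))
    scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_c: set[int] = set()
    rows = []
    for run, i, j in scores:
        if i in used_d or j in used_c:
            continue
        used_d.add(i)
        used_c.add(j)
        label = (
            "identical"
            if dna[i].canonical() == cdna[j].canonical()
            else "partial"
        )
        rows.append(
            {
                "dna_locus": dna[i].locus_id,
                "cdna_locus": cdna[j].locus_id,
                "shared_ids": run,
                "label": label,
            }
        )
    for i, d in enumerate(dna):
        if i not in used_d:
            rows.append(
                {"dna_locus": d.locus_id, "cdna_locus": None, "shared_ids": 0, "label": "fraction_unique"}
            )
    for j, c in enumerate(cdna):
        if j not in used_c:
            rows.append(
                {"dna_locus": None, "cdna_locus": c.locus_id, "shared_ids": 0, "label": "fraction_unique"}
            )
    return pd.DataFrame(rows, columns=["dna_locus", "cdna_locus", "shared_ids", "label"])


def loci_to_fasta(
    loci: Iterable[Locus],
    groups: Iterable[SpacerGroup],
    repeat: str,
    path,
) -> None:
    """Write each locus as its concatenated repeat-spacer consensus sequence
    (repeat + representative spacers + repeat), e.g. for primer design."""
    rep_of = {g.group_id: g.representative for g in groups}
    with open(path, "w") as fh:
        for locus in loci:
            seq = repeat
            for i in locus.id_sequence:
                seq += rep_of[i] + repeat
            fh.write(f">{locus.locus_id} status={locus.status} min_support={locus.min_support:.3f}\n")
            fh.write(seq + "\n")
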