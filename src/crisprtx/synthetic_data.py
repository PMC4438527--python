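"""Ground-truth simulator for repeat-anchored CRISPR amplicon studies.

Generates per-subject CRISPR repertoires (ordered loci of unique spacers
with controlled inter-subject sharing), DNA- and cDNA-fraction amplicon
reads with configurable per-base error, and virome reads carrying planted
protospacers — everything the analysis pipeline consumes, with a known
truth set for parameter-recovery testing.

The model emulates an oral-microbiome amplicon design: each CRISPR locus
is ``repeat (spacer repeat)+``, amplified with repeat-anchored barcoded
primers and sequenced as single-end reads of roughly 100-200 bp.  Defaults
follow the study conditions this package targets: 16 subjects (9 healthy /
7 periodontal disease), ~20 loci per subject with 2-12 spacers of 20-40 nt,
~12% pairwise inter-subject spacer sharing, ~12% cDNA dropout, ~10% highly
expressed spacers at a planted five-fold change, and a virome in which a
~10% minority of spacers occurs verbatim as protospacers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .read_processing import AmpliconRead, revcomp

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "LocusTruth",
    "MutationResult",
    "DEFAULT_REPEAT",
    "generate_repertoire",
    "mutate_sequence",
    "generate_amplicon_reads",
    "generate_virome",
    "simulate_expression_counts",
    "write_truth_tables",
]

# Placeholder 32-nt direct repeat.  The real SGI/SGII/GHI/VSI motifs are not
# public; users studying real data must supply their own repeat string.
DEFAULT_REPEAT = "GTCGCACTCTACATGAGTGCGAACCTCATTGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

IntRange = tuple[int, int]


def _as_range(value: Union[int, IntRange]) -> IntRange:
    if isinstance(value, int):
        return (value, value)
    lo, hi = value
    return (int(lo), int(hi))


@dataclass
class SimulationConfig:
    """Study-level simulation parameters; defaults are the study conditions.

    Rates are probabilities in [0, 1]; lengths are in bases.  ``fold`` is
    the *realized* cDNA:DNA abundance ratio planted for highly expressed
    spacers (non-spiked spacers are scaled down to conserve totals, so
    ``fold * high-expression mass`` must stay below 1).
    """

    n_subjects: int = 16
    loci_per_subject: Union[int, IntRange] = 20
    spacers_per_locus: IntRange = (2, 12)
    spacer_length: IntRange = (20, 40)
    repeat_sequence: str = DEFAULT_REPEAT
    barcode_length: int = 10
    read_length_mean: int = 200
    read_length_sd: float = 0.0
    coverage: float = 50.0
    substitution_rate: float = 0.005
    indel_rate: float = 0.0005
    shared_fraction: float = 0.12
    shared_partners: int = 1
    dropout_cdna: float = 0.12
    high_expression_fraction: float = 0.10
    fold: float = 5.0
    virome_protospacer_fraction: float = 0.10
    virome_read_length: int = 500
    virome_background_reads: int = 500
    disease_fraction: float = 7 / 16
    both_strands: bool = True
    quality_score: int = 30
    quality_ramp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "indel_rate",
            "shared_fraction",
            "dropout_cdna",
            "high_expression_fraction",
            "virome_protospacer_fraction",
            "disease_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if _as_range(self.spacers_per_locus)[0] < 2:
            raise ValueError("a locus needs >= 2 spacers to be assemblable")
        if self.spacer_length[0] < 20:
            raise ValueError("minimum spacer length must be >= 20")
        if self.fold <= 1.0:
            raise ValueError("fold must be > 1")
        if self.fold * self.high_expression_fraction >= 1.0:
            raise ValueError(
                "fold * high_expression_fraction must be < 1 so that "
                "non-spiked spacers keep positive cDNA abundance"
            )
        if not self.repeat_sequence or set(self.repeat_sequence) - set("ACGT"):
            raise ValueError("repeat_sequence must be a non-empty ACGT string")
        min_read = 2 * len(self.repeat_sequence) + self.spacer_length[0]
        if self.read_length_mean < min_read:
            raise ValueError(
                f"read_length_mean {self.read_length_mean} cannot contain one "
                f"repeat-anchored spacer (need >= {min_read})"
            )

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("loci_per_subject", "spacers_per_locus", "spacer_length"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class LocusTruth:
    locus_id: str
    spacers: tuple[str, ...]


@dataclass
class TruthSet:
    """Everything the simulator decided, for recovery checks downstream."""

    subjects: list[tuple[str, str]]  # (label, "healthy" | "disease")
    barcodes: dict[str, str]
    loci: dict[str, list[LocusTruth]]  # subject -> ordered loci
    expression_truth: pd.DataFrame  # subject, locus_id, spacer, w_dna, w_cdna, high, dropout
    virome_truth: Optional[pd.DataFrame] = None  # spacer, read_id, strand

    def spacers_of(self, subject: str) -> list[str]:
        return [s for locus in self.loci[subject] for s in locus.spacers]

    def all_spacers(self) -> list[str]:
        seen: dict[str, None] = {}
        for label, _ in self.subjects:
            for s in self.spacers_of(label):
                seen.setdefault(s)
        return list(seen)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _unique_spacer(
    rng: np.random.Generator, length: int, taken: set, forbidden: tuple[str, str]
) -> str:
    while True:
        s = _random_seq(rng, length)
        if s in taken:
            continue
        if forbidden[0] in s or forbidden[1] in s:
            continue
        return s


def generate_repertoire(config: SimulationConfig) -> TruthSet:
    """Draw per-subject CRISPR loci with controlled inter-subject sharing.

    Spacers are unique random sequences except that, for each subject after
    the first, ``shared_fraction`` of its spacer slots are filled with
    spacers donated by earlier subjects; each donated spacer is reused in
    exactly ``shared_partners`` recipients (default 1, so shared spacers
    occur in exactly 2 subjects — the predominantly pairwise sharing seen
    in oral repertoires).  Also plants the expression truth used for cDNA
    read generation.
    """
    rng = np.random.default_rng(config.seed)
    n_dis = int(round(config.disease_fraction * config.n_subjects))
    n_healthy = config.n_subjects - n_dis
    subjects = [(f"H{i + 1}", "healthy") for i in range(n_healthy)]
    subjects += [(f"D{i + 1}", "disease") for i in range(n_dis)]

    barcodes: dict[str, str] = {}
    taken_bc: set[str] = set()
    for label, _ in subjects:
        while True:
            bc = _random_seq(rng, config.barcode_length)
            if bc not in taken_bc:
                taken_bc.add(bc)
                barcodes[label] = bc
                break

    forbidden = (config.repeat_sequence, revcomp(config.repeat_sequence))
    lo_loci, hi_loci = _as_range(config.loci_per_subject)
    lo_sp, hi_sp = _as_range(config.spacers_per_locus)
    lo_len, hi_len = config.spacer_length

    taken: set[str] = set()
    loci: dict[str, list[LocusTruth]] = {}
    # donor pool: spacers from earlier subjects not yet donated shared_partners times
    donor_pool: list[str] = []
    donor_uses: dict[str, int] = {}

    for label, _ in subjects:
        n_loci = int(rng.integers(lo_loci, hi_loci + 1))
        sizes = rng.integers(lo_sp, hi_sp + 1, size=n_loci)
        flat: list[str] = []
        for k in range(int(sizes.sum())):
            length = int(rng.integers(lo_len, hi_len + 1))
            s = _unique_spacer(rng, length, taken, forbidden)
            taken.add(s)
            flat.append(s)
        n_shared = int(round(config.shared_fraction * len(flat)))
        if donor_pool and n_shared > 0:
            n_shared = min(n_shared, len(donor_pool))
            slot_idx = rng.choice(len(flat), size=n_shared, replace=False)
            donor_idx = rng.choice(len(donor_pool), size=n_shared, replace=False)
            donors = [donor_pool[i] for i in donor_idx]
            for slot, donor in zip(slot_idx, donors):
                flat[int(slot)] = donor
                donor_uses[donor] = donor_uses.get(donor, 0) + 1
            exhausted = {d for d in donors if donor_uses[d] >= config.shared_partners}
            if exhausted:
                donor_pool = [d for d in donor_pool if d not in exhausted]
        subject_loci = []
        pos = 0
        for j, size in enumerate(sizes):
            spacers = tuple(flat[pos : pos + int(size)])
            pos += int(size)
            subject_loci.append(LocusTruth(locus_id=f"{label}.L{j + 1:02d}", spacers=spacers))
        loci[label] = subject_loci
        # only this subject's never-shared spacers become future donors
        donor_pool.extend(s for s in flat if s not in donor_uses and s in taken)

    expression = _plant_expression(rng, config, loci)
    return TruthSet(
        subjects=subjects,
        barcodes=barcodes,
        loci=loci,
        expression_truth=expression,
    )


def _plant_expression(
    rng: np.random.Generator, config: SimulationConfig, loci: dict[str, list[LocusTruth]]
) -> pd.DataFrame:
    """Per-subject cDNA weights: spiked spacers at exactly ``fold`` times their
    DNA weight, dropout spacers at zero, the rest scaled to conserve totals."""
    rows = []
    for label, subject_loci in loci.items():
        entries = [(lt.locus_id, s) for lt in subject_loci for s in lt.spacers]
        n = len(entries)
        n_high = int(round(config.high_expression_fraction * n))
        high_idx = set(rng.choice(n, size=n_high, replace=False).tolist()) if n_high else set()
        drop = rng.random(n) < config.dropout_cdna
        w_dna = np.ones(n)
        w_cdna = np.ones(n)
        for i in range(n):
            if i in high_idx:
                w_cdna[i] = config.fold
                drop[i] = False
            elif drop[i]:
                w_cdna[i] = 0.0
        normal = [i for i in range(n) if i not in high_idx and not drop[i]]
        if normal:
            remaining = n - config.fold * len(high_idx)
            beta = max(remaining, 0.0) / len(normal)
            for i in normal:
                w_cdna[i] = beta
        for i, (locus_id, spacer) in enumerate(entries):
            rows.append(
                {
                    "subject": label,
                    "locus_id": locus_id,
                    "spacer": spacer,
                    "w_dna": w_dna[i],
                    "w_cdna": w_cdna[i],
                    "high": i in high_idx,
                    "dropout": bool(drop[i]) and i not in high_idx,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MutationResult:
    sequence: str
    n_edits: int


def _mutate_arr(
    arr: np.ndarray, substitution_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Apply per-base substitutions and indels to a uint8 base array."""
    n = arr.size
    edits = 0
    n_sub = rng.binomial(n, substitution_rate) if substitution_rate > 0 else 0
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        arr = arr.copy()
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
        edits += n_sub
    n_indel = rng.binomial(arr.size, indel_rate) if indel_rate > 0 else 0
    if n_indel:
        out = arr.tolist()
        for _ in range(n_indel):
            p = int(rng.integers(len(out) + 1)) if out else 0
            if rng.random() < 0.5 and out:
                del out[min(p, len(out) - 1)]
            else:
                out.insert(p, int(rng.choice(_BASES)))
        arr = np.array(out, dtype=np.uint8)
        edits += n_indel
    return arr, edits


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float,
    seed: Union[int, np.random.Generator],
) -> MutationResult:
    """Return a mutated copy of ``seq`` and the number of edits applied.

    Substitutions always change the base (drawn from the other three);
    indels are 50/50 insertions/deletions at uniform positions.  With both
    rates zero the input is returned unchanged.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    for name, rate in (("substitution_rate", substitution_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out, edits = _mutate_arr(arr, substitution_rate, indel_rate, rng)
    return MutationResult(sequence=out.tobytes().decode(), n_edits=edits)


def _locus_sequence(repeat: str, spacers: Iterable[str]) -> str:
    parts = [repeat]
    for s in spacers:
        parts.append(s)
        parts.append(repeat)
    return "".join(parts)


def _qualities(length: int, config: SimulationConfig) -> list[int]:
    if not config.quality_ramp:
        return [config.quality_score] * length
    # linear degradation from quality_score to 5 over the final 30% of the read
    ramp_start = int(length * 0.7)
    quals = [config.quality_score] * ramp_start
    tail = length - ramp_start
    for i in range(tail):
        q = config.quality_score - (config.quality_score - 5) * (i + 1) / max(tail, 1)
        quals.append(max(2, int(round(q))))
    return quals


def _read_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.read_length_sd <= 0:
        return config.read_length_mean
    min_len = 2 * len(config.repeat_sequence) + config.spacer_length[0]
    return max(min_len, int(round(rng.normal(config.read_length_mean, config.read_length_sd))))


def _finish_read(
    read_id: str, window: str, rng: np.random.Generator, config: SimulationConfig, barcode: str
) -> AmpliconRead:
    arr = np.frombuffer(window.encode(), dtype=np.uint8)
    arr, _ = _mutate_arr(arr, config.substitution_rate, config.indel_rate, rng)
    window = arr.tobytes().decode()
    if config.both_strands and rng.random() < 0.5:
        window = revcomp(window)
    seq = barcode + window
    return AmpliconRead(id=read_id, sequence=seq, qualities=_qualities(len(seq), config))


def generate_amplicon_reads(
    truth: TruthSet, config: SimulationConfig, fraction: Literal["DNA", "cDNA"]
) -> list[AmpliconRead]:
    """Simulate barcoded amplicon reads for one nucleic-acid fraction.

    DNA reads are windows of the locus sequence starting inside a repeat
    copy (amplification is repeat-primed), at ``coverage`` mean reads per
    locus position.  cDNA reads are allocated to spacers multinomially in
    proportion to the planted expression weights; each cDNA read is placed
    so its target spacer is fully repeat-flanked.  Per-base substitution /
    indel errors and random strand flips are applied to every read.
    """
    if fraction not in ("DNA", "cDNA"):
        raise ValueError("fraction must be 'DNA' or 'cDNA'")
    rng = np.random.default_rng((config.seed, 1 if fraction == "DNA" else 2))
    repeat = config.repeat_sequence
    rlen = len(repeat)
    reads: list[AmpliconRead] = []
    expr = truth.expression_truth.set_index(["subject", "locus_id", "spacer"])

    for label, _ in truth.subjects:
        barcode = truth.barcodes[label]
        subject_loci = truth.loci[label]
        locus_seqs = {lt.locus_id: _locus_sequence(repeat, lt.spacers) for lt in subject_loci}
        n_reads_per_locus = {
            lt.locus_id: int(round(config.coverage * len(locus_seqs[lt.locus_id]) / config.read_length_mean))
            for lt in subject_loci
        }
        if fraction == "DNA":
            for lt in subject_loci:
                seq = locus_seqs[lt.locus_id]
                # repeat-primed amplicons start exactly at a repeat copy;
                # collect the start position of each repeat that precedes a spacer
                starts = [0]
                pos = rlen
                for s in lt.spacers[:-1]:
                    pos += len(s)
                    starts.append(pos)
                    pos += rlen
                for k in range(n_reads_per_locus[lt.locus_id]):
                    start = starts[int(rng.integers(len(starts)))]
                    length = _read_length(rng, config)
                    window = seq[start : start + length]
                    reads.append(
                        _finish_read(f"DNA|{label}|{lt.locus_id}|{k}", window, rng, config, barcode)
                    )
        else:
            total = sum(n_reads_per_locus.values())
            entries = []
            weights = []
            for lt in subject_loci:
                for i, s in enumerate(lt.spacers):
                    entries.append((lt, i, s))
                    weights.append(float(expr.loc[(label, lt.locus_id, s), "w_cdna"]))
            weights = np.asarray(weights, dtype=float)
            if weights.sum() <= 0 or total == 0:
                continue
            alloc = rng.multinomial(total, weights / weights.sum())
            dropped_of = {
                (row.locus_id, row.spacer): row.w_cdna == 0.0
                for row in truth.expression_truth[
                    truth.expression_truth.subject == label
                ].itertuples()
            }
            for (lt, i, s), n_reads in zip(entries, alloc):
                if n_reads == 0:
                    continue
                seq = locus_seqs[lt.locus_id]
                # full repeat-copy start positions along the locus
                starts = [0]
                pos = rlen
                for sp in lt.spacers:
                    pos += len(sp)
                    starts.append(pos)
                    pos += rlen
                start_rep = starts[i]
                # never let the window fully flank a downstream dropout spacer
                cap = len(seq)
                for j in range(i + 1, len(lt.spacers)):
                    if dropped_of.get((lt.locus_id, lt.spacers[j]), False):
                        cap = starts[j + 1] + rlen - 1
                        break
                for k in range(int(n_reads)):
                    # start at the repeat 5' of the target spacer, long enough
                    # to keep it fully repeat-flanked
                    length = max(_read_length(rng, config), 2 * rlen + len(s))
                    window = seq[start_rep : min(start_rep + length, cap)]
                    reads.append(
                        _finish_read(
                            f"cDNA|{label}|{lt.locus_id}|S{i}|{k}", window, rng, config, barcode
                        )
                    )
    return reads


def generate_virome(truth: TruthSet, config: SimulationConfig) -> list[tuple[str, str]]:
    """Simulate virome reads with a planted protospacer minority.

    ``round(virome_protospacer_fraction * n_distinct_spacers)`` spacers are
    embedded verbatim (forward or reverse-complement, chosen at random)
    inside otherwise-random reads; ``virome_background_reads`` purely random
    reads are appended.  The planted set and strands are recorded on
    ``truth.virome_truth``.  Returns (read_id, sequence) pairs.
    """
    frac = config.virome_protospacer_fraction
    rng = np.random.default_rng((config.seed, 3))
    spacers = truth.all_spacers()
    n_plant = int(round(frac * len(spacers)))
    planted_idx = rng.choice(len(spacers), size=n_plant, replace=False) if n_plant else []
    reads: list[tuple[str, str]] = []
    rows = []
    L = config.virome_read_length
    for j, idx in enumerate(planted_idx):
        sp = spacers[int(idx)]
        strand = "forward" if rng.random() < 0.5 else "reverse"
        insert = sp if strand == "forward" else revcomp(sp)
        pos = int(rng.integers(0, L - len(insert) + 1))
        seq = _random_seq(rng, pos) + insert + _random_seq(rng, L - pos - len(insert))
        read_id = f"virome_p{j}"
        reads.append((read_id, seq))
        rows.append({"spacer": sp, "read_id": read_id, "strand": strand})
    for j in range(config.virome_background_reads):
        reads.append((f"virome_b{j}", _random_seq(rng, L)))
    truth.virome_truth = pd.DataFrame(rows, columns=["spacer", "read_id", "strand"])
    return reads


def simulate_expression_counts(
    n_groups: int,
    depth: int,
    high_fraction: float,
    fold: float,
    dropout: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[dict[int, int], dict[int, int], pd.DataFrame]:
    """Group-level DNA/cDNA count simulation (no reads), for calibration work.

    DNA counts are multinomial over uniform weights; cDNA counts are
    multinomial over weights where a ``high_fraction`` of groups is spiked
    to a realized ``fold`` ratio, ``dropout`` of the rest (Bernoulli per
    group) is zeroed, and the remainder is scaled to conserve the total.
    Returns (dna_counts, cdna_counts, truth) keyed by group id 1..n.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 < n_groups:
        raise ValueError("n_groups must be positive")
    n_high = int(round(high_fraction * n_groups))
    if fold * n_high / n_groups >= 1.0:
        raise ValueError("fold * high_fraction must be < 1")
    high = np.zeros(n_groups, dtype=bool)
    if n_high:
        high[rng.choice(n_groups, size=n_high, replace=False)] = True
    drop = (rng.random(n_groups) < dropout) & ~high
    w_dna = np.ones(n_groups)
    w_cdna = np.ones(n_groups)
    w_cdna[high] = fold
    w_cdna[drop] = 0.0
    normal = ~high & ~drop
    if normal.any():
        w_cdna[normal] = (n_groups - fold * n_high) / normal.sum()
    dna = rng.multinomial(depth, w_dna / w_dna.sum())
    cdna = rng.multinomial(depth, w_cdna / w_cdna.sum())
    truth = pd.DataFrame(
        {
            "group_id": np.arange(1, n_groups + 1),
            "high": high,
            "dropout": drop,
            "w_dna": w_dna,
            "w_cdna": w_cdna,
        }
    )
    dna_counts = {i + 1: int(c) for i, c in enumerate(dna)}
    cdna_counts = {i + 1: int(c) for i, c in enumerate(cdna)}
    return dna_counts, cdna_counts, truth


def write_truth_tables(truth: TruthSet, outdir) -> None:
    """Write loci.tsv, expression_truth.tsv and virome_truth.tsv."""
    import os

    rows = []
    for label, subject_loci in truth.loci.items():
        for lt in subject_loci:
            for i, s in enumerate(lt.spacers):
                rows.append({"subject": label, "locus_id": lt.locus_id, "position": i, "spacer": s})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "loci.tsv"), sep="\t", index=False)
    truth.expression_truth.to_csv(
        os.path.join(outdir, "expression_truth.tsv"), sep="\t", index=False
    )
    if truth.virome_truth is not None:
        truth.virome_truth.to_csv(os.path.join(outdir, "virome_truth.tsv"), sep="\t", index=False)
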