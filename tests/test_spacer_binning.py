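"""Trinucleotide profiles, binning and residual polymorphism rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisprtx import spacer_binning as sb

SEQ = st.text(alphabet="ACGT", min_size=3, max_size=40)


class TestProfiles:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAAA", {"AAA": 3}),
            ("ACGT", {"ACG": 1, "CGT": 1}),
            ("ACGTACGT", {"ACG": 2, "CGT": 2, "GTA": 1, "TAC": 1}),
        ],
    )
    def test_known_compositions(self, seq, expected):
        p = sb.trinucleotide_profile(seq)
        got = {sb.TRINUCLEOTIDES[i]: int(c) for i, c in enumerate(p) if c}
        assert got == expected

    @given(SEQ)
    @settings(max_examples=50, deadline=None)
    def test_counts_sum_to_length_minus_two(self, seq):
        assert sb.trinucleotide_profile(seq).sum() == len(seq) - 2

    def test_ambiguous_characters_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            sb.trinucleotide_profile("ACGNACG")

    def test_difference_enumerated_example(self):
        # AAAA -> {AAA:2}; AAAC -> {AAA:1, AAC:1}; |2-1| + |0-1| = 2
        d = sb.profile_difference(
            sb.trinucleotide_profile("AAAA"), sb.trinucleotide_profile("AAAC")
        )
        assert d == 2

    @given(SEQ, SEQ)
    @settings(max_examples=50, deadline=None)
    def test_difference_is_symmetric_and_zero_on_identity(self, a, b):
        pa, pb = sb.trinucleotide_profile(a), sb.trinucleotide_profile(b)
        assert sb.profile_difference(pa, pb) == sb.profile_difference(pb, pa)
        assert sb.profile_difference(pa, pa) == 0


def brute_force_bin(counts, mode="edit", max_edits=2, core_fraction=0.05):
    """Independent re-implementation with plain loops: all pairwise profile
    differences, threshold, hand-rolled connected components, then the same
    core refinement — used as the oracle for the vectorized implementation."""
    distinct = sorted(counts)
    profs = {s: sb.trinucleotide_profile(s) for s in distinct}

    def diff(a, b):
        return sum(abs(int(x) - int(y)) for x, y in zip(profs[a], profs[b]))

    if mode == "edit":
        def linked(a, b):
            return diff(a, b) <= 6 * max_edits
    else:
        pair_d = [diff(a, b) for i, a in enumerate(distinct) for b in distinct[i + 1 :]]
        if pair_d:
            t = max(np.mean(pair_d) - np.std(pair_d), np.finfo(float).tiny)
        else:
            t = np.finfo(float).tiny

        def linked(a, b):
            return diff(a, b) < t

    # naive connected components
    comp = {s: s for s in distinct}

    def find(x):
        while comp[x] != x:
            x = comp[x]
        return x

    for i, a in enumerate(distinct):
        for b in distinct[i + 1 :]:
            if linked(a, b):
                comp[find(a)] = find(b)
    comps = {}
    for s in distinct:
        comps.setdefault(find(s), []).append(s)

    # core refinement, naive version
    groups = []
    for members in comps.values():
        max_c = max(counts[m] for m in members)
        core_min = max(2, int(np.ceil(core_fraction * max_c)))
        cores = [m for m in members if counts[m] >= core_min]
        if len(cores) < 2:
            groups.append(members)
            continue
        ccomp = {c: c for c in cores}

        def cfind(x):
            while ccomp[x] != x:
                x = ccomp[x]
            return x

        for i, a in enumerate(cores):
            for b in cores[i + 1 :]:
                if linked(a, b):
                    ccomp[cfind(a)] = cfind(b)
        subs = {}
        for c in cores:
            subs.setdefault(cfind(c), []).append(c)
        if len(subs) == 1:
            groups.append(members)
            continue
        clusters = {root: list(cs) for root, cs in subs.items()}
        for m in members:
            if m in cores:
                continue
            best = min(cores, key=lambda c: (diff(m, c), -counts[c], c))
            clusters[cfind(best)].append(m)
        groups.extend(clusters.values())
    return {frozenset(g) for g in groups}


class TestBinning:
    def test_duplicates_collapse_to_one_group(self):
        groups = sb.bin_spacers(["A" * 10 + "CGTACGTACG"] * 3)
        assert len(groups) == 1 and groups[0].total == 3

    def test_mutant_joins_parent_and_unrelated_stays_apart(self, rng):
        parent = "".join(rng.choice(list("ACGT"), 30))
        mutant = parent[:12] + ("A" if parent[12] != "A" else "C") + parent[13:]
        other = "".join(rng.choice(list("ACGT"), 30))
        counts = {parent: 10, mutant: 1, other: 10}
        groups = sb.bin_spacers(counts)
        # oracle: brute-force pairwise differences and threshold on this instance
        assert {frozenset(g.member_counts) for g in groups} == brute_force_bin(counts)
        assert len(groups) == 2
        big = next(g for g in groups if parent in g.member_counts)
        assert mutant in big.member_counts
        assert big.representative == parent

    def test_adaptive_equal_pair_stays_separate(self):
        # one distinct pair: SD = 0 so the threshold equals the difference
        # itself and "strictly less" leaves two singletons
        counts = {"ACGTACGTACGTACGTACGTACGT": 1, "TTTTACGTACGTACGTACGTACGT": 1}
        groups = sb.bin_spacers(counts, mode="adaptive")
        assert len(groups) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sb.bin_spacers({})

    def test_group_ids_ordered_by_total_count(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        counts = {s: 10 * (i + 1) for i, s in enumerate(seqs)}
        groups = sb.bin_spacers(counts)
        totals = [g.total for g in groups]
        assert totals == sorted(totals, reverse=True)
        assert [g.group_id for g in groups] == list(range(1, len(groups) + 1))

    @pytest.mark.parametrize("mode", ["edit", "adaptive"])
    def test_oracle_equivalence_on_random_instances(self, mode, rng):
        """Vectorized groups match the plain-loop oracle exactly."""
        for _ in range(10):
            n = int(rng.integers(5, 30))
            parents = ["".join(rng.choice(list("ACGT"), int(rng.integers(20, 41)))) for _ in range(n)]
            counts = {}
            for p in parents:
                counts[p] = counts.get(p, 0) + int(rng.integers(1, 20))
                if rng.random() < 0.5:  # add a 1-substitution variant
                    i = int(rng.integers(len(p)))
                    alt = str(rng.choice([c for c in "ACGT" if c != p[i]]))
                    v = p[:i] + alt + p[i + 1 :]
                    counts[v] = counts.get(v, 0) + 1
            got = {frozenset(g.member_counts) for g in sb.bin_spacers(counts, mode=mode)}
            assert got == brute_force_bin(counts, mode=mode)

    def test_idempotent_on_representatives(self, rng):
        parents = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(20)]
        counts = {}
        for p in parents:
            counts[p] = 10
            v = p[:5] + ("G" if p[5] != "G" else "T") + p[6:]
            counts[v] = 1
        groups = sb.bin_spacers(counts)
        again = sb.bin_spacers({g.representative: g.total for g in groups})
        assert len(again) == len(groups)


class TestPolymorphismRate:
    def test_zero_when_all_members_identical(self):
        g = sb.SpacerGroup(1, "A" * 30, {"A" * 30: 50})
        assert sb.polymorphism_rate([g]) == 0.0

    def test_single_mismatch_arithmetic(self):
        rep = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt
        mut = "TCGTACGTACGTACGTACGTACGTACGTAC"
        g = sb.SpacerGroup(1, rep, {rep: 9, mut: 1})
        # 1 mismatched base over 300 total bases
        assert sb.polymorphism_rate([g]) == pytest.approx(100 * 1 / 300)

    def test_invariant_to_group_id_relabeling(self):
        rep = "ACGTACGTACGTACGTACGTACGTACGTAC"
        mut = rep[:-1] + "G"
        a = sb.SpacerGroup(1, rep, {rep: 9, mut: 1})
        b = sb.SpacerGroup(99, rep, {rep: 9, mut: 1})
        assert sb.polymorphism_rate([a]) == sb.polymorphism_rate([b])


def test_bin_spacer_table_per_sample_counts(rng):
    import pandas as pd

    s1 = "".join(rng.choice(list("ACGT"), 30))
    s2 = "".join(rng.choice(list("ACGT"), 30))
    df = pd.DataFrame(
        [
            {"sequence": s1, "subject": "H1", "fraction": "DNA", "count": 5},
            {"sequence": s1, "subject": "H1", "fraction": "cDNA", "count": 2},
            {"sequence": s2, "subject": "H2", "fraction": "DNA", "count": 7},
        ]
    )
    groups, assigned = sb.bin_spacer_table(df)
    assert assigned["group_id"].notna().all()
    g1 = next(g for g in groups if s1 in g.member_counts)
    assert g1.sample_counts.set_index(["subject", "fraction"])["count"].to_dict() == {
        ("H1", "DNA"): 5,
        ("H1", "cDNA"): 2,
    }
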