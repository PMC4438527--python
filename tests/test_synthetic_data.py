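"""The simulator: determinism, planted structure, mutation model, virome."""

import numpy as np
import pytest

from crisprtx import read_processing as rp
from crisprtx import synthetic_data as sd
from crisprtx.synthetic_data import SimulationConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"substitution_rate": 1.5},
            {"shared_fraction": -0.1},
            {"spacers_per_locus": (1, 5)},  # a locus needs >= 2 spacers
            {"spacer_length": (15, 30)},
            {"fold": 1.0},
            {"fold": 9.0, "high_expression_fraction": 0.2},  # fold*frac >= 1
            {"read_length_mean": 60},  # cannot contain repeat+spacer+repeat
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_subjects=3, seed=9, spacers_per_locus=(2, 7))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestRepertoire:
    def test_forced_range_gives_exact_locus(self):
        cfg = SimulationConfig(n_subjects=1, loci_per_subject=1, spacers_per_locus=(2, 2))
        truth = sd.generate_repertoire(cfg)
        (label, _), = truth.subjects
        assert len(truth.loci[label]) == 1
        assert len(truth.loci[label][0].spacers) == 2

    def test_locus_sizes_inside_configured_range(self):
        cfg = SimulationConfig(n_subjects=4, loci_per_subject=10, spacers_per_locus=(3, 8), seed=2)
        truth = sd.generate_repertoire(cfg)
        for label, _ in truth.subjects:
            for lt in truth.loci[label]:
                assert 3 <= len(lt.spacers) <= 8

    def test_zero_shared_fraction_means_disjoint_repertoires(self):
        cfg = SimulationConfig(n_subjects=4, loci_per_subject=5, shared_fraction=0.0, seed=3)
        truth = sd.generate_repertoire(cfg)
        sets = [set(truth.spacers_of(label)) for label, _ in truth.subjects]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_shared_spacers_occur_in_exactly_two_subjects(self):
        cfg = SimulationConfig(n_subjects=6, loci_per_subject=8, shared_fraction=0.15, seed=4)
        truth = sd.generate_repertoire(cfg)
        incidence = {}
        for label, _ in truth.subjects:
            for s in set(truth.spacers_of(label)):
                incidence[s] = incidence.get(s, 0) + 1
        counts = np.array(list(incidence.values()))
        assert counts.max() == 2  # default: one extra subject per shared spacer
        shared = (counts == 2).sum()
        assert shared > 0

    def test_health_status_split(self):
        truth = sd.generate_repertoire(SimulationConfig(n_subjects=16, loci_per_subject=2, seed=0))
        statuses = [s for _, s in truth.subjects]
        assert statuses.count("healthy") == 9 and statuses.count("disease") == 7

    def test_determinism_identical_truthsets(self):
        cfg = SimulationConfig(n_subjects=3, loci_per_subject=4, seed=7)
        a, b = sd.generate_repertoire(cfg), sd.generate_repertoire(cfg)
        assert a.subjects == b.subjects
        assert a.barcodes == b.barcodes
        assert a.loci == b.loci
        assert a.expression_truth.equals(b.expression_truth)


class TestMutateSequence:
    def test_zero_rates_identity(self):
        assert sd.mutate_sequence("ACGT", 0, 0, 1).sequence == "ACGT"

    def test_rate_one_substitution_changes_every_base(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 50))
        out = sd.mutate_sequence(seq, 1.0, 0.0, 5)
        assert len(out.sequence) == 50
        assert all(a != b for a, b in zip(seq, out.sequence))
        assert out.n_edits == 50

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sd.mutate_sequence("", 0.1, 0.0, 1)

    def test_mean_edit_count_matches_binomial_expectation(self):
        """1,000 draws at rate 0.01 on length-30 spacers: mean ~ 0.3."""
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), 30))
        edits = [sd.mutate_sequence(seq, 0.01, 0.0, rng).n_edits for _ in range(1000)]
        expected = 30 * 0.01
        se = np.sqrt(30 * 0.01 * 0.99 / 1000)
        assert abs(np.mean(edits) - expected) < 3 * se


class TestAmpliconReads:
    def test_zero_coverage_empty_read_set(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, coverage=0.0)
        truth = sd.generate_repertoire(cfg)
        assert sd.generate_amplicon_reads(truth, cfg, "DNA") == []

    def test_reads_are_barcoded_and_qualities_match(self, small_config):
        truth = sd.generate_repertoire(small_config)
        reads = sd.generate_amplicon_reads(truth, small_config, "DNA")
        barcodes = set(truth.barcodes.values())
        assert reads
        for r in reads[:50]:
            assert r.sequence[:10] in barcodes
            assert len(r.qualities) == len(r.sequence)

    def test_short_read_regime_yields_at_most_one_spacer(self):
        # 100 bp reads with a 32-nt repeat can flank one ~30-nt spacer at most
        cfg = SimulationConfig(
            n_subjects=1, loci_per_subject=2, spacers_per_locus=(3, 5),
            spacer_length=(20, 30), read_length_mean=100,
            substitution_rate=0.0, indel_rate=0.0, coverage=20, seed=6,
        )
        truth = sd.generate_repertoire(cfg)
        reads = sd.generate_amplicon_reads(truth, cfg, "DNA")
        motif = rp.RepeatMotifSpec("SIM", cfg.repeat_sequence)
        demux = rp.demultiplex(reads, truth.barcodes)
        for label, subject_reads in demux.assigned.items():
            for r in subject_reads:
                assert len(rp.extract_spacers(r, motif)) <= 1

    def test_error_free_extraction_recovers_every_truth_spacer(self, small_config):
        truth = sd.generate_repertoire(small_config)
        reads = sd.generate_amplicon_reads(truth, small_config, "DNA")
        motif = rp.RepeatMotifSpec("SIM", small_config.repeat_sequence)
        demux = rp.demultiplex(reads, truth.barcodes)
        for label, _ in truth.subjects:
            seen = set()
            for r in demux.assigned[label]:
                seen |= {s.sequence for s in rp.extract_spacers(r, motif)}
            assert seen == set(truth.spacers_of(label))

    def test_byte_identical_fastq_for_fixed_seed(self, small_config, tmp_path):
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        for p in (p1, p2):
            truth = sd.generate_repertoire(small_config)
            rp.write_fastq(sd.generate_amplicon_reads(truth, small_config, "DNA"), p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cdna_dropout_spacers_receive_no_reads(self):
        cfg = SimulationConfig(
            n_subjects=2, loci_per_subject=6, spacers_per_locus=(4, 8),
            dropout_cdna=0.3, substitution_rate=0.0, indel_rate=0.0,
            coverage=40, seed=8,
        )
        truth = sd.generate_repertoire(cfg)
        reads = sd.generate_amplicon_reads(truth, cfg, "cDNA")
        motif = rp.RepeatMotifSpec("SIM", cfg.repeat_sequence)
        demux = rp.demultiplex(reads, truth.barcodes)
        # dropout is per subject: a spacer shared with another subject may be
        # dropped there but still transcribed here
        et = truth.expression_truth
        assert et.dropout.any()
        for label, subject_reads in demux.assigned.items():
            dropped = set(et[(et.subject == label) & et.dropout].spacer)
            for r in subject_reads:
                for s in rp.extract_spacers(r, motif):
                    assert s.sequence not in dropped


class TestVirome:
    def _cfg(self, frac, seed=0):
        return SimulationConfig(
            n_subjects=2, loci_per_subject=5, virome_protospacer_fraction=frac, seed=seed
        )

    def test_conservation_of_planted_count(self):
        cfg = self._cfg(0.13)
        truth = sd.generate_repertoire(cfg)
        reads = sd.generate_virome(truth, cfg)
        n_distinct = len(truth.all_spacers())
        assert len(truth.virome_truth) == round(0.13 * n_distinct)
        assert len(reads) == len(truth.virome_truth) + cfg.virome_background_reads

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_extremes(self, frac):
        cfg = self._cfg(frac)
        truth = sd.generate_repertoire(cfg)
        sd.generate_virome(truth, cfg)
        n = len(truth.all_spacers())
        assert len(truth.virome_truth) == (0 if frac == 0.0 else n)

    def test_planted_spacer_occurs_verbatim_on_recorded_strand(self):
        cfg = self._cfg(0.5, seed=5)
        truth = sd.generate_repertoire(cfg)
        reads = dict(sd.generate_virome(truth, cfg))
        for _, row in truth.virome_truth.iterrows():
            seq = reads[row.read_id]
            probe = row.spacer if row.strand == "forward" else rp.revcomp(row.spacer)
            assert probe in seq


def test_truth_tables_written(tmp_path):
    cfg = SimulationConfig(n_subjects=2, loci_per_subject=3, seed=1)
    truth = sd.generate_repertoire(cfg)
    sd.generate_virome(truth, cfg)
    sd.write_truth_tables(truth, tmp_path)
    for name in ("loci.tsv", "expression_truth.tsv", "virome_truth.tsv"):
        assert (tmp_path / name).exists()
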