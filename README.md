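# crisprtx

Community-level analysis of CRISPR locus transcription from
repeat-anchored amplicon sequencing.

Oral bacteria carry CRISPR loci — arrays of a conserved direct repeat
interleaved with short "spacers" acquired from phage — and amplifying the
arrays with primers anchored in the repeat motif captures the spacer
repertoires of many bacterial species at once, in both genomic DNA (which
loci are *present*) and cDNA (which loci are *transcribed*) from the same
saliva sample. `crisprtx` implements the full analysis for such paired
DNA/cDNA amplicon studies:

* **Read processing** — exact-barcode demultiplexing, Mott-style quality
  trimming, ambiguity/low-complexity filtering, and extraction of spacers
  (length ≥ 20 nt) flanked by exact, full copies of the repeat.
* **Spacer binning** — spacers are grouped by trinucleotide content: the
  L1 distance between 64-long overlapping 3-mer count vectors links
  near-identical sequences (sequencing-error variants) into *spacer
  groups*, the unit of all downstream analysis, with a residual
  polymorphism-rate estimate.
* **Locus assembly** — each read becomes an ordered list of spacer-group
  identifiers; directed adjacencies whose support exceeds 60% of their
  opportunities are chained greedily into loci, mid-support (20–60%)
  adjacencies form flagged alternative-locus candidates, and reads with
  contradictory spacer order are discarded.
* **Expression analysis** — abundances are normalized to PPTS (Percentage
  Per Thousand Spacers, Σ = 1000 per sample); a group with baseline
  (DNA) PPTS ≥ 5 is called **highly expressed** when its cDNA − DNA
  residual exceeds 3× baseline; repertoire agreement between fractions is
  summarized by Spearman's ρ = 1 − 6Σd²/(n(n²−1)) with average-rank ties.
* **Community statistics** — between-subject sharing spectra, a
  permutation test for subject specificity of DNA↔cDNA overlap (10,000
  iterations, 1,000 groups sampled per iteration by default), richness
  rarefaction by repeated subsampling, heatmap matrices, Welch t-tests.
* **Virome matching** — a spacer group matches a virome read when any
  member occurs verbatim (either strand) as a full-length substring — the
  protospacer criterion — with per-locus none/single/multiple summaries
  and a permutation test for match concentration.
* **Synthetic data** — a generator that plants known repertoires,
  expression fold-changes, cDNA dropout and protospacers so that every
  stage can be validated end to end without external data.

## Worked example

Simulate a 16-subject study (20 loci per subject, 200 bp reads at 50×
coverage, 0.5% substitution + 0.05% indel error), run one subject's DNA
fraction through the pipeline, and compare against the planted truth:

```python
from crisprtx import synthetic_data as sd, read_processing as rp, workflow
from crisprtx.synthetic_data import SimulationConfig

cfg = SimulationConfig(n_subjects=16, loci_per_subject=20,
                       spacers_per_locus=(5, 15), seed=11)
report, truth = workflow.locus_recovery(cfg)
print(f"{report.n_exact}/{report.n_truth_loci} loci exact "
      f"({100 * report.recovery_rate:.1f}%)")
```

prints

```
315/320 loci exact (98.4%)
```

i.e. 98.4% of the planted CRISPR arrays are reconstructed with exactly
the right spacers in exactly the right order, from error-bearing 200 bp
reads alone. Expression calling works the same way at the group-count
level:

```python
from crisprtx import expression_analysis as ea
from crisprtx.synthetic_data import simulate_expression_counts

dna, cdna, spike_truth = simulate_expression_counts(
    n_groups=100, depth=10_000, high_fraction=0.10, fold=5.0, seed=77)
records = ea.build_expression_records(dna, cdna)
print(records.highly_expressed.sum(), "groups flagged highly expressed")
```

prints `10 groups flagged highly expressed` — the ten spiked groups, no
false flags.

The command line mirrors the first steps:

```bash
crisprtx simulate --seed 4 --outdir sim/
crisprtx extract sim/dna.fastq --repeat GTCGCACTCTACATGAGTGCGAACCTCATTGC \
    --barcodes sim/barcodes.tsv --out spacers.tsv
```

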