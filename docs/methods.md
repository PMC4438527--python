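# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic-data validation does and does not
demonstrate.

## Amplicon model and read processing

A CRISPR locus is modelled as `R (S R)+`: a direct repeat `R` (default: a
fixed 32-nt placeholder; real repeat motifs are study-specific and must be
supplied by the user) alternating with spacers `S` of 20–40 nt.
Amplification is repeat-primed, so simulated reads start exactly at a
repeat copy, carry a 10-nt subject barcode, and extend for roughly the
configured read length (200 bp by default; a 100 bp regime flanks at most
one spacer and is useful only for repertoire profiling, not assembly).
Reads may come from either strand; extraction canonicalizes each read to
repeat orientation by reverse-complementing when the reverse-complement
repeat is the more frequent match.

Demultiplexing requires a 100% barcode match; there is no fuzzy barcode
correction. Quality trimming is a running-sum (Mott-style) prefix trim:
the kept prefix maximizes Σ(cutoff − p_err) with a per-base error cutoff
of 0.05 (the historical parameter value 0.5 is accepted as an alias for
this default). Reads with non-ACGT characters, or 3-mer Shannon entropy
below 1.5 bits, are rejected with a logged reason. A spacer must be
flanked on both sides by *exact, full* repeat copies and be at least
20 nt long; partial terminal repeats never anchor a spacer.

## Spacer binning

Each spacer is summarized by its 64-long vector of overlapping
trinucleotide counts; profiles are compared by L1 distance, exact
duplicates are collapsed first, and groups are the connected components
of the linkage graph (single linkage).

The default linkage rule is a fixed edit-scale cutoff: link two distinct
sequences when their profile distance is ≤ 6 × `max_edits` (default
`max_edits = 2`, so L1 ≤ 12). One substitution alters at most three
overlapping 3-mers (L1 ≤ 6), so this tolerates the ~2-edit error scale of
amplicon sequencing while unrelated random 30-mers sit at L1 ≈ 39 ± 5 —
five standard deviations away. An adaptive alternative
(`mode="adaptive"`: link when the distance falls below mean − SD of all
pairwise distances in the sample) is provided for comparison, but in
realistic samples the pairwise-distance distribution is dominated by
unrelated pairs, so that threshold lands near mean − SD ≈ 34 and links a
double-digit percentage of unrelated pairs; under single linkage this
percolates the sample into a handful of giant groups, which is
inconsistent with the thousands of groups and ~10⁻³ % polymorphism rates
such studies report. It is therefore not the default.

Single-linkage components are refined along abundant **cores**: members
with count ≥ max(2, 5% of the component maximum) are re-linked among
themselves, and if the cores separate, each low-count member joins its
nearest core (ties to the more abundant, then lexicographically smaller
core). This prevents a single count-1 error variant from bridging two
distinct, abundant spacers whose own profiles are outside the linkage
threshold — without it, roughly 5% of simulated loci are corrupted by
such chance bridges at study scale.

The residual polymorphism rate is 100 × (mismatched bases of members vs
their group representative, per read occurrence, using end-gap-free edit
distance via edlib) / (total spacer bases). At the default simulated
error of 0.5% per base this is ~0.6%; reproducing the ~0.001–0.003%
scale reported for real instruments requires correspondingly lower
configured error rates (the per-base error of the instrument is not
derivable from published summaries, so the default is a deliberately
harsh stress setting rather than a calibration).

## Locus assembly

Reads are encoded as ordered spacer-group identifier lists. For an
ordered pair (a, b), the adjacency count is the number of reads where b
immediately follows a, and the **support** is that count divided by the
pair's *opportunities* — reads where a is seen with some flanked
successor or b with some flanked predecessor. With ~200 bp reads a read
flanks only ~2 spacers, so a perfectly linked pair realizes essentially
all of its opportunities (support ≈ 1) while only ~40–50% of either id's
raw occurrences; dividing by min(occurrences) (available as
`denominator="min_occurrence"`) systematically underscores true pairs in
this geometry, which is why opportunities are the default.

If both (a, b) and (b, a) are observed, the minority direction's reads
are flagged as order-altered and excluded (ties flag the lexicographically
larger direction). Assembly recounts adjacencies on the remaining reads,
then chains edges greedily from the highest support (ties: higher count,
then lexicographic edge), giving each id at most one predecessor and one
successor and refusing cycle-closing edges — the lowest-support edge of a
cycle is the one skipped. Edges with support > 0.60 form `auto` loci;
edges in (0.20, 0.60] are chained separately into `manual_candidate`
loci, an automated stand-in for the by-hand placement of lower-abundance
alternative loci that an interactive analysis would perform. Loci report
their minimum chain support; orientation is arbitrary, so comparisons use
the lexicographically smaller direction as canonical. Within-locus
adjacency-frequency spread is reported as a diagnostic only, never used
as a filter. Spurious "spacers" created by a sequencing error inside an
interior repeat (which fuses two spacers and the broken repeat into one
novel sequence) are suppressed before encoding by a minimum group count
of 2.

## Expression analysis

Counts are normalized to Percentage Per Thousand Spacers (PPTS):
ppts_i = 1000 · c_i / Σc. The residual is ppts_cdna − ppts_dna — defined
so that the "residual > 3 × baseline" rule flags *up*-expression, which
requires cDNA > 4 × DNA on the PPTS scale — and only groups with baseline
ppts_dna ≥ 5 are eligible. Groups seen only in cDNA have baseline 0,
are never eligible, and are reported separately rather than dropped.
Spearman's ρ uses average ranks; without ties it equals
1 − 6Σd²/(n(n²−1)), with ties it is Pearson's r on the ranks. By default
ρ is computed over the union of the two fractions' groups with absent
groups scored 0 (intersection is available). Constant vectors are
undefined and raise.

The group-level simulator plants the *realized* fold change: spiked
groups receive cDNA weight = fold × DNA weight exactly, and the
non-spiked, non-dropout remainder is scaled down uniformly so both
fractions still sum to 1000 (this requires fold × spiked mass < 1, which
is validated). A multiply-then-renormalize scheme would dilute the
planted ratio to fold/(1 − m + fold·m) — 3.57× at fold 5 with 10% spiked
mass, *below* the 4× implied by the 3×-residual rule — so fold changes
would be planted that the detection rule is by construction unable to
see; planting the realized ratio keeps "fold" meaningful against the
flagging threshold. cDNA dropout is Bernoulli per group (never applied to
spiked groups); at the read level, cDNA windows are truncated so a
dropout spacer is never fully repeat-flanked.

## Community statistics

The subject-specificity permutation test observes the intra-subject
DNA↔cDNA shared fraction |A∩B|/|A| and draws, per iteration, two random
group sets of the observed sizes (capped at `groups_per_iteration`,
default 1,000; sampling switches to with-replacement and is flagged if
the cap exceeds the universe) from the group universe — by default the
union of all subjects' sets, overridable when the true pool is known.
The p-value is the fraction of 10,000 (default) null draws at least as
large as the observation; 0 means "below 1/n_iterations". The published
wording for this test ("fraction of times the intra-subject statistic
exceeded the inter-subject statistic") is implemented verbatim as
`mode="literal"`; note that under that reading *small* values indicate a
lack of subject specificity, so the conditional mode is the default.

Rarefaction subsamples the observed count vector without replacement;
one permutation per iteration serves all depths (richness at depth d is
the number of groups first seen within the first d draws), which leaves
the per-depth marginal distributions exact while reusing work. Sharing
spectra report, per stratum (all subjects, healthy only, disease only,
and groups crossing both strata), the percentage of groups present in
exactly k subjects; health labels are input metadata with no planted
effect by default. Mean shared fractions are compared with Welch's
two-tailed t-test; two zero-variance samples with equal means give p = 1
by convention.

## Virome matching

A group matches a read when any member sequence occurs verbatim and
full-length in the read or (by default) its reverse complement.
Matching is seed-and-verify on hashed 20-mer prefixes, so it scans each
read once. The expected chance match rate for a 30-mer against a 500-nt
read is ≈ 2 × 471 × 4⁻³⁰ ≈ 10⁻¹⁵ per pair — effectively zero, which the
decoy test confirms. Per-locus summaries count distinct matched groups
(none / single / multiple); the concentration test permutes the observed
number of matched spacer slots uniformly across all loci's slots and
scores Σ max(0, m_l − 1), with p the fraction of permutations at least
as concentrated. Database searches beyond a user-supplied FASTA are out
of scope; externally produced BLAST outfmt-6 tables can be imported with
the conventional bit-score ≥ 45 filter.

## Synthetic-data scope and problem sizes

The generator emulates: 16 subjects (9 healthy / 7 disease labels,
carrying no planted signal), ~20 loci per subject of 2–12 spacers
(5–15 in the assembly stress test), spacers 20–40 nt between fixed
repeats, ~12% pairwise inter-subject sharing (each shared spacer in
exactly 2 subjects by default), 200 bp reads at 50× coverage with 0.5%
substitutions and 0.05% indels, ~12% cDNA dropout, 10% highly expressed
groups at a realized fold of 5, and a virome planting protospacers for
~10% of spacers in 500-nt reads. Fixed seeds make every output
byte-identical. It does **not** simulate PCR chimeras, homopolymer-
specific error spectra, abundance skew across loci, or cross-reactive
repeats, so passing tests demonstrate correctness of the algorithms
under the stated model, not robustness to every artifact of real
amplicon data.

Validation problem sizes were chosen to give stable statistics at
interactive runtimes: the full pipeline run uses 16 × 20 loci (~50k
reads, ~10 s); binning validation uses 100 seeded trials of 16 parents
plus mutants; numeric oracles use 1,000 random vectors; expression
spike-ins use 50 replicates at depth 10,000; permutation calibration
uses 100–200 replicate worlds at 1,000 iterations; rarefaction uses
10,000 iterations on a 100-group sample.
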