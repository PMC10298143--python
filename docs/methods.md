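# Methods

## Pileup model

The engine walks every alignment overlapping the mitochondrial contig and
tallies A/C/G/T base calls per reference position per cell. Only
aligned-match CIGAR operations (M/=/X) contribute; insertions, deletions,
reference skips and soft clips are ignored, so a deletion spanning a
position contributes nothing to coverage there, and coverage at a position
is by construction the sum of the four base counts. Base calls of N are
never counted.

Default filters follow the samtools-family pileup conventions the
surrounding ecosystem inherits: minimum base quality 13 (Phred), no
mapping-quality floor, and exclusion of secondary, supplementary,
duplicate, QC-fail and unmapped reads. Raising either quality threshold
can only remove calls — monotonicity is a tested invariant. Two optional
modes depart from plain pileup semantics and are off by default, keeping
the engine exactly equivalent to a naive per-read tally:

* `count_overlaps_once` — where the two mates of a pair overlap, the base
  call with the higher base quality is kept once instead of both calls
  counting;
* `collapse_umis` — reads sharing (barcode, UMI) collapse to one vote per
  position: majority base, ties broken by summed base quality, then
  alphabetically. Reads without a UMI tag count as their own molecule.

Contig resolution tries the FASTA record name against the BAM header
first (erroring on a length mismatch for an exact name match), then the
common aliases chrM/MT/chrMT/M accepted only when the header length equals
the FASTA length. Reads are taken as the aligner placed them; alignments
spanning the circular origin are not re-piled — a known limitation, and
the simulator correspondingly emits no origin-spanning reads.

## Matrices and allele frequency

All three possible substitutions are materialised (sparsely) for every
position whose reference base is not N, ordered by position then alt base
A<C<G<T. A stable, reference-determined row universe lets matrices from
different runs align row-for-row. N-reference positions (e.g. rCRS 3107)
still receive coverage values but define no variants.

AF(v, c) = alt(v, c) / coverage(p_v, c) when coverage ≥ `min_coverage`
(default 1), else missing. The denominator is counted-base coverage, not
raw read depth, which keeps alt ≤ coverage exact under the pileup rules
above. Missing is distinct from zero everywhere downstream: statistics
drop missing entries rather than imputing 0, because a dropout imputed as
0 would fabricate reference-homoplasmy evidence in sparse single-cell
data. Matrices serialise as MatrixMarket with TSV sidecars (variant and
cell tables) and a JSON manifest that records the reference identity and
filter settings; round-trips are lossless including orderings.

## Statistical layer

Each variant is tested with a one-way fixed-effects ANOVA of AF on donor
identity, computed from group sums: F = (SSB/df_b)/(SSW/df_w) with
df_b = G−1 over the G donors having ≥1 non-missing cell and
df_w = N−G. This is numerically identical to a linear model with a single
categorical donor predictor, and for two donors F equals the squared
pooled-variance t statistic (asserted to 1e-10 relative in the tests).
Degenerate cases are defined explicitly: SSW = 0 with SSB > 0 gives
F = ∞, p = 0; SSB = SSW = 0 gives F = 0, p = 1. Sums of squares below a
1e-12 relative floor of the total are treated as exactly zero to keep
these branches stable against floating-point residue of the centering
subtraction. p-values come from the F distribution's upper tail; the
log-survival function is kept alongside so that comparisons against
thresholds far below 1 (the 1e-100 regime used for informative variants)
happen in log10 space and never rely on an underflowed double.

A variant is *testable* when at least two donors have
`min_cells_per_group` (default 2) non-missing cells. Downstream rules:

* **variable sites** — unbiased sample variance of non-missing AFs,
  requiring `min_covered_cells` (default 10) covered cells; top *n*
  (default 500), ties by position then alt base;
* **informative variants** — testable sites with raw p below
  `anova_p_threshold` (default 1e-100), sorted by p;
* **discriminative germline** — donor mean AF above
  `germline_af_threshold` (default 0.9) in exactly one donor and at or
  below it in every other; annotated with the carrier, sorted by ANOVA p;
* **heteroplasmy scan** — germline set excluded first (optionally the
  informative set instead), then sites with any donor mean strictly
  inside (`het_lo`, `het_hi`) = (0.01, 0.25), then ANOVA significance at
  a Bonferroni-adjusted 0.05 over the banded, testable sites. The raw-p
  modes deliberately use no multiple-testing correction (their thresholds
  are extreme by design); the band scan, where no published cutoff
  exists, defaults to the conservative adjusted threshold.

Donor mean AF is the unweighted mean over cells with non-missing AF — the
literal per-individual average. A pooled pseudobulk alternative
(Σalt/Σcov) is available for uneven-depth data; it weights cells by
coverage and is less sensitive to low-depth noise cells.

## Cell-level analyses

The cell–cell distance is 1 − |Pearson r| between two cells' AF profiles
over the sites non-missing in both. Pairs sharing fewer than
`min_shared_sites` (default 20) sites, or with a constant profile over the
shared sites (correlation undefined), receive the maximal distance 1 and
are counted. Taking |r| means perfectly anti-correlated profiles also map
to distance 0 — a documented property of the formula, irrelevant in
practice because AF profiles of unrelated cells decorrelate rather than
anti-correlate. The distance is invariant to positive affine rescaling of
a profile (Pearson invariance; tested).

Embedding delegates to t-SNE on the precomputed distance matrix
(perplexity 10 by default, seeded, deterministic). Donor classification
delegates to a random forest on AF features; missing AF is encoded as the
out-of-range sentinel −1 rather than imputed, so tree splits can isolate
dropout from any real frequency. The published workflow reports a
classification accuracy without naming a validation protocol; here the
default is out-of-bag scoring (each cell predicted by the trees that did
not sample it), with stratified k-fold as an option — a
deviation-by-necessity, chosen because it gives an honest held-out
estimate without a second data split.

## Simulator

The generator emulates the structure such studies rely on: K donors, each
with donor-exclusive fixed germline variants (every covering read carries
the alt) and donor-specific heteroplasmies. A heteroplasmic cell's own
allele fraction is drawn from a Beta distribution with donor mean μ and
dispersion ρ (Var = μ(1−μ)ρ; shapes μ(1−ρ)/ρ and (1−μ)(1−ρ)/ρ), and each
covering read then carries the alt base with that probability —
cell-to-cell AF spread over read-sampling noise, matching the qualitative
per-cell scatter seen in real heteroplasmy data. Sequencing errors are
independent per base (default 1e-3), substituting a uniform different
base. Reads are single-end, uniformly placed on the linear contig, base
quality Q30 (with an option to inject low-quality bases to exercise the
filter), mapping quality 60. Default conditions are a 16,569 bp contig,
4 donors × 50 cells and 8,300 reads/cell (~50× per-cell coverage), error
1e-3, μ = 0.10 with ρ = 0.05 — ρ chosen once so the simulated per-cell AF
standard deviation (~0.07 at μ = 0.10) resembles the spread reported for
real donor-specific heteroplasmies.

What the simulator does **not** model: transcript structure and 3′
coverage bias, UMI duplication families, strand effects, alignment
artefacts, nuclear-embedded mitochondrial sequences (NUMTs), or
origin-spanning reads. Passing recovery tests therefore demonstrate the
correctness of the counting and statistics under the stated generative
model, not robustness to those real-data confounders.

## Problem sizes in the test suite

The statistical fixtures keep the study-like conditions (4 donors × 50
cells with ten markers each; 8 donors × 100 cells with one μ = 0.10
heteroplasmy each; ~50× per-cell coverage; error 1e-3) but run them on a
shortened 2–3 kb contig. Per-cell depth at every tested position — the
quantity the statistics actually see — is unchanged; only the number of
uninformative positions shrinks. The pileup engine itself is verified
exactly, against an independent naive per-read CIGAR-walking oracle, on
deliberately messy randomized BAMs (soft clips, indels, reference skips,
flag and quality mixtures), and the droplet path is verified bit-identical
to the well path on barcode-split copies of the same reads.

## Numerical and tie-breaking choices

* Row/column orderings are deterministic everywhere (position then alt;
  input order for well cells; whitelist order, else lexicographic, for
  barcodes).
* All simulator randomness derives from one integer seed; identical
  configs reproduce identical reads.
* Ties in UMI consensus: votes, then summed quality, then alphabetical
  base. Ties in site rankings: position, then alt base.
* `max_depth`, when set, caps counted bases per position in read order —
  deterministic, matching the fetch order of the BAM.
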