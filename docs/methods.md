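# Methods

## Coordinate and data conventions

All internal coordinates are 0-based half-open; GTF input/output is
converted at the boundary. Capture fragments are unstranded insert
intervals (the capture step enriches double-stranded fragments; the unit of
evidence is the fragment, not the stranded read). Duplicate removal — one
representative per exact (chrom, start, end) — applies to capture fragments
only: RRBS and RNA-seq duplicates arise legitimately from enzymatic cutting
and library complexity and are retained.

## RRBS summarisation

Counts from the two strands of a CpG are summed per CpG start before the
degree m/(m+u) is computed, because CpG methylation is palindromic. A CpG
with zero coverage keeps an *undefined* (NaN) degree rather than 0 —
treating missing as unmethylated would bias every downstream comparison —
and the coverage filter (default ≥ 10 reads) removes such sites explicitly.

## Threshold calibration and peak definition

The pooled coverage of the two control (solvent-treated) libraries is
compared against RRBS degrees at covered CpGs. For each candidate threshold
*t* ∈ {1..20}, CpGs split into capture-methylated (coverage ≥ *t*) and the
rest; the separation of their degree distributions is scored with a
two-group Kruskal–Wallis H (tie-corrected, p from χ²₁). Selection keys on H
rather than p: the ordering is identical, but H survives p-value underflow
at large CpG counts. Ties break toward the smallest *t* (maximal
sensitivity). The ≥ *t* convention is used both for CpG classification and
for the peak definition; since *t* is scanned, the alternative strict->
convention differs only by an index shift. The per-CpG "capture coverage"
is the pileup value at the C base — fragments are ≥ 50 bp, so the
single-base lookup is immaterial relative to the dinucleotide.

Peaks are maximal runs with pooled control coverage ≥ *t*, trimmed to
[first CpG start, last CpG start + 2); runs containing no complete CpG are
discarded. A run's trimmed peak therefore always starts and ends on a CpG,
and peaks are disjoint by construction. The caller is verified against an
independent brute-force per-base scanner on random tracks.

Fragment counting is regional: a fragment is counted for every peak it
overlaps by ≥ 1 bp (capture enrichment is a regional signal; a straddling
fragment is evidence for both regions), and a fragment overlapping no peak
is a "noise read". Distinct-fragment assignment plus noise always equals
the library size.

## Differential testing

Counts are modelled per feature as negative binomial with a log link,
design = intercept + cell-line block + treatment, fit by iteratively
reweighted least squares vectorised across all features. The p-value is a
likelihood-ratio test of the treatment coefficient against χ²₁; log₂ fold
change is the treatment coefficient / ln 2. With two blocks × two
treatments there is one residual degree of freedom, so only a **common**
dispersion is identifiable; it is estimated by maximising the Cox–Reid
adjusted profile likelihood (penalty ½·log det XᵀWX) on a log-spaced grid
refined by golden-section search — deterministic, no tuning. At dispersion
→ 0 the fit reproduces a Poisson GLM (checked against an independent
implementation to ~1e-10). Features whose IRLS does not converge are
reported with undefined p and excluded from the multiple-testing m, so they
neither inflate nor deflate the correction. All-zero features are the exact
null (logFC 0, p 1).

Normalisation offsets:

- **Methylation**: log(noise library size). Rationale: a demethylating
  treatment redistributes capture away from peaks, so between-peak reads
  are the stable part of the library; since putative noise regions may
  still contain signal, this is conservative.
- **Expression**: an iterative χ²-goodness-of-fit depth estimator —
  depths from column sums, per-feature Poisson GOF against those depths,
  keep features between the 25th and 75th GOF percentiles (the least
  differential ones), re-estimate, iterate to a fixed point (≤ 10 rounds),
  rescale to mean 1. The offsets anchor the relative factors to absolute
  scale: offset_j = log(d_j · N_j / mean(N)). The 25–75% window follows the
  estimator's standard convention.

Fold changes are invariant to jointly doubling counts and offsets; p-values
are not and cannot be — doubled counts carry doubled Fisher information —
they can only sharpen. The test suite asserts exactly this.

Benjamini–Hochberg step-up q-values; significance at q ≤ 0.1 by default.

## Annotation

Promoter: [tss − 2000, tss + 500) on the + strand, mirrored on −, clipped
to the chromosome. Each peak collects its distinct genic contexts —
(category, strand, location) triples over promoters, exons and introns of
all overlapping genes; identical triples from multiple transcripts count
once (the deduplication rule is isolated in one function so alternatives
are swappable). With k contexts, each contributes weight 1/k (exact
rational arithmetic; scores always sum to 1). Intergenic (score 1) applies
only when k = 0, and the intergenic complement excludes promoters — a
promoter base is genic. Gene deserts are intergenic intervals strictly
longer than 500 kb (literal "> 500 kb").

## Enrichment

The null for category enrichment of the significantly demethylated peak
set draws, per chromosome and per iteration, that chromosome's observed
significant count of peaks uniformly **without replacement** (a resampled
set should be a possible set of distinct peaks) from the chromosome's
universe; 1000 iterations with per-iteration derived seeds. Empirical
two-sided p uses the +1-corrected estimator, so p is never 0. The
restricted mode re-runs the test inside peaks of significantly upregulated
genes, over the genic categories only. The gene-desert contrast divides
pooled peak-fragment counts by the length of desert vs non-desert
intergenic space per chromosome and compares the per-chromosome pairs with
a paired t-test (pairing matches the per-chromosome structure of the
groups; a zero-variance difference is flagged instead of producing an
infinite t). A peak straddling desert and non-desert contributes to both,
with the straddler count reported.

## Integration

Promoter-demethylated genes: ≥ 1 peak with logFC < 0 and q ≤ FDR
overlapping the promoter by any amount (direction made explicit; the
"demethylated"/"upregulated" framing implies both filters). Candidates are
the intersection with significantly upregulated genes; the
expression-independent promoter-demethylation list is emitted alongside.
Every percentage in the run report is exactly 100·numerator/denominator of
the counts printed next to it, rounded to two decimals.

## The simulator

The generator emulates the study design end to end: two cell lines ×
{control, demethylated}, a toy genome with CpG-dense promoter islands
(two-rate Bernoulli CpG process, island/background ≈ 10:1), a bimodal
per-CpG degree mixture (low mode near 0, high near 1), and a planted
effect: a chosen set of regulated genes receives coherently high-methylated
promoters whose degrees are multiplied by δ (default 0.25) under treatment.
Key modelling choices:

- **Regional coherence.** Non-regulated promoter islands draw one
  island-level mixture state shared by their CpGs; background CpGs are
  independent. Real methylomes are regionally correlated, and without this
  the capture/bisulfite concordance cannot emerge — a low-degree CpG inside
  an otherwise methylated island is still captured, because the assay reads
  regions, not bases.
- **Gene spacing.** Genes are placed with gaps (4.6–5.4 kb) wide enough
  that neighbouring promoter windows never overlap, so "regulated gene" is
  well defined at the promoter level and truth-based scoring is exact.
- **Capture model.** Per-base fragment-start intensity = noise floor +
  window-sum (one mean fragment length) of CpG degrees; fragment lengths
  truncated-normal in [50, 400] bp around 200 bp; a configurable fraction
  of emitted fragments are exact copies (PCR duplicates). The library size
  is fixed at the expected depth regardless of global methylation — as in
  real sequencing — which is precisely the situation the noise-read
  normalisation exists to handle. The monotone coverage–degree relation is
  an emergent property, verified by test, not an input.
- **RRBS**: negative-binomial coverage (default mean 123) at a random
  ~11% of CpGs; methylated counts binomial(coverage, degree).
- **RNA-seq**: gene mean = fixed lognormal gene baseline ×
  exp(−β · mean promoter degree), scaled to the target depth with a
  condition-independent normaliser so the expected log₂ fold change is
  exactly β·Δdegree/ln 2; counts negative-binomial (dispersion 0.05).
- **Determinism**: one user seed fans out to per-stage generators via
  SeedSequence([seed, crc32(stage name)]); same seed + config reproduces
  every byte. Truth tables are exported alongside all data.

Default scale: 2 chromosomes × 2 Mb, 300 genes, 50 regulated, ~40k CpGs,
~50k fragments per capture library, one ~600 kb gene desert per chromosome
— the full pipeline runs in a few seconds on one CPU; the test suite's
problem sizes (e.g. 2000-feature calibration experiments, 10-seed
end-to-end replicates) were chosen to keep the whole suite under a minute
while leaving Monte-Carlo error well below the asserted margins.

What the simulator does **not** model: raw reads and base qualities,
bisulfite conversion failure, mappability and GC bias, copy-number
differences between cell lines (the paired design absorbs ploidy as a
block effect, as in the real analysis), distance-dependent enhancer
effects, or any pharmacology of the demethylating agent — the
multiplicative δ is a modelling device, not a dose-response claim. Passing
tests therefore demonstrate that the pipeline recovers the planted signal
under its own assumptions, not that those assumptions hold for any
particular real data set.

## Statistical reading of the stochastic checks

Sample means of a finite simulation cannot be exactly ordered where a
relation saturates: the concordance check asserts that capture coverage
rises strongly from the bottom to the top degree decile and that no
adjacent-decile decrease exceeds 3 standard errors (the plateaus of the
bimodal degree distribution make tiny, noise-dominated decrements
inevitable). Calibration checks (type-I error in [0.03, 0.07] at α = 0.05,
realized FDP ≤ 0.15 at q ≤ 0.1 with 10% signal, depth-factor recovery
within 5%) use fixed seeds and problem sizes at which their Monte-Carlo
error is small relative to the asserted bands.

## Known limitations

- Only a common NB dispersion is estimable from 2×2 designs; tagwise or
  trended shrinkage would be unidentifiable noise here.
- The GLM-LRT with χ²₁ is asymptotic in the counts; for peaks with very few
  fragments the test is conservative-to-anticonservative in the usual GLM
  way. At the simulator's default depths counts are large enough for the
  measured type-I error to sit at the nominal level.
- The annotation deduplication rule (distinct (category, strand, location)
  triples) is one of several defensible readings of multi-context scoring;
  it is isolated behind a single function.
- The desert contrast with only two desert-bearing chromosomes has one
  degree of freedom; the pipeline reports it but it is only powered on
  genomes with several desert chromosomes.
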