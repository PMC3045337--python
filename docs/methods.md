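# Methods

## The question and the estimand

Given case/control genotypes and a protein-coding gene annotation, the
pipeline asks where "suggestive" association signal (per-SNP p < α,
α ∈ {0.1, 0.01, 0.001}) sits relative to genes.  The estimand per
stratum — signed 10 kb distance windows up to ±100 kb, the transcript
window 0, and the coding-exon subset of window 0 — is the proportion of
that stratum's polymorphic SNPs that are suggestive, compared against
the distribution of the same proportion when the phenotype carries no
information.

## Association model

Per SNP, genotypes are coded as minor-allele dose 0/1/2 (minor = the
rarer allele in the pooled sample over non-missing calls; ties broken
by the lexicographically smaller symbol, so the coding is reproducible
from the files alone).  The test is the Cochran–Armitage trend
chi-square with scores (0, 1, 2), one degree of freedom; individuals
with a missing call are dropped from that SNP's table only; a
monomorphic table has no defined trend and is reported as p = 1 with a
degeneracy flag.  Degenerate SNPs are excluded from the genomic-control
median.

Genomic control: λ_median = median(χ²) / F⁻¹_{χ²₁}(½).  The χ²₁ median
is computed numerically (≈0.454936) rather than rounded to 0.456.  The
estimate is reported as-is, but the correction divisor is max(λ, 1):
dividing by a deflated λ would manufacture signal.  λ is a noisy
statistic — the median of m effectively independent chi-squares has
sd ≈ 1.07/√m on the λ scale, about 0.04 for the 5,000-SNP simulated
panels with block LD — which matters when interpreting single-run
values near 1.

## Permutation null

Case/control labels are shuffled preserving the case count; the
genotype matrix is never touched, so inter-SNP correlation (LD) is
carried into the null and the per-window count distributions account
for locally correlated p-values.  Within each permutation the full
pipeline is re-run: trend test, fresh λ estimate, correction.
Correcting inside permutations (switchable off via `gc_in_perm`) keeps
observed and permuted analyses exchangeable, which is what makes the
nearest-rank CI calibrated; the pointwise per-SNP p-value matrix is the
object consumed downstream, streamed in row chunks so only per-window
counts are ever resident.

CI convention: nearest-rank quantiles at (1−c)/2 and 1−(1−c)/2, i.e.
the sorted permuted count at 1-based rank ⌈qN⌉.  Nearest-rank returns
attainable integer counts (no interpolation), so bounds read as
realizable outcomes.  Significance is one-sided: observed count
strictly above the upper bound; depletion (strictly below the lower
bound) is recorded but is not a headline flag.

## SNP-to-gene assignment

Coordinates are 1-based and closed everywhere (MAP/annotation
convention); BED region files are converted exactly (start+1, end).
A SNP inside a primary transcript belongs to that gene (transcript
overlap is a hard error — the model presumes disjoint transcripts, and
the annotation reader enforces it rather than silently picking one).
Other SNPs go to the gene minimizing the distance to the nearer
transcript edge, ties to the lexicographically smaller gene id.
Distance d ≥ 1 maps to window ±⌈d/10,000⌉ — half-open at the inner
edge, closed at the outer, so exactly 10,000 bp is window 1 and every
distance has exactly one window.  Orientation is strand-aware
(upstream = 5′ of the transcript on the gene's strand); a
coordinate-only mode (`--no-strand`) exists for sensitivity analysis,
since with symmetric simulated annotations the choice is nearly
invisible.  SNPs farther than K·10 kb (default K = 10) from any gene
are unassigned — a value, not an error — and excluded from all strata.
Genes on sex chromosomes, the mitochondrion, and unassembled or
alternative contigs are dropped on read.

The exon stratum is the subset of window-0 SNPs inside a coding exon
(closed intervals, so boundary coordinates are exonic).  Window 0
keeps all transcript SNPs including exonic ones: the two strata are
reported separately with exon ⊂ gene, and the table invariants
(exon totals and counts never exceed gene-window totals and counts)
are asserted in tests.

## Smoothing and combination

Observed per-window proportions are smoothed for display with a
centred moving average spanning 50 kb (5 bins of 10 kb; the span must
be an odd multiple of the bin width).  Edges truncate to the bins
available.  The exon stratum is a different kind of object (a subset,
not a distance bin) and is never smoothed — it is drawn as a separate
marker at the gene position.

Combining traits averages observed counts and totals window-by-window
and averages permuted counts permutation-by-permutation (combined
permutation r = mean over traits of each trait's permutation r), then
takes the CI as usual.  This pairing treats traits as independent;
cohorts sharing controls would violate that, which is accepted and
noted rather than modelled.

## Quality control

Filters run on the pooled case/control data, each evaluated against
the pre-filter cohort (hence idempotent): call rate < 0.97, pooled
MAF < 0.01, Hardy–Weinberg exact p < 0.001.  The HWE test is the
standard exact conditional test (sum of probabilities of heterozygote
counts no more likely than observed, given the allele counts),
computed via log-gamma; the asymptotic chi-square agrees with it in
the rejection-relevant tail and serves as a large-sample oracle there,
while near p = 1 the two orderings legitimately diverge.  A SNP
failing several filters is reported once, under the first failing
filter in the order (call_rate, maf, hwe) — arbitrary but stable.
Setting `rare_maf_max = 0.05` restricts the surviving set to rare
SNPs for the rare-variant stratum.  Individual-level QC is out of
scope; the simulator emits clean samples.

## The synthetic cohort generator

The generator stands in for controlled-access genotype panels; no
claim is made that it reproduces human LD maps.  What it emulates, and
why:

* **Annotation.**  Non-overlapping transcripts (rejection placement
  with bounded retries; failure names the constraint) with ordered
  disjoint coding exons placed one per equal transcript segment.
  Default genome composition — ~37% genic sequence, coding exons under
  1% of SNP positions — mirrors the array-era landscape the analysis
  targets, so window populations peak at the gene and decay outward.
* **Genotypes.**  Per-SNP allele frequencies are Beta(0.8, 0.8) draws
  (mostly common, some rare).  Haplotypes are built left-to-right
  within blocks of `ld_block_len_bp`: each allele copies its left
  neighbour with probability `ld_r`, else redraws from the SNP's
  frequency.  This gives tunable, monotonically increasing adjacent
  correlation (tested) and block-limited range; it does not reproduce
  recombination-map heterogeneity.
* **Phenotype.**  log-odds = logit(prevalence) + Σ log(OR)·(dose−2p)
  over causal SNPs.  Centring the dose anchors the realized prevalence
  at the baseline whatever the causal count — with 30 planted effects
  an uncentred model drives prevalence toward 1 and makes controls
  unsamplable — while leaving all odds ratios untouched.  Individuals
  are rejection-sampled in batches until the case and control quotas
  fill; an unfillable quota raises an error suggesting a higher
  baseline prevalence.
* **Causal placement.**  `exon`, `gene`, `flank:<kb>` (strictly outside
  transcripts, within the distance), or `uniform` — supporting recovery
  experiments that plant signal where the enrichment statistic should
  find it.
* **Structure.**  Optional two subpopulations with Balding–Nichols
  frequencies (Beta with parameters p(1−F)/F, (1−p)(1−F)/F) and
  unequal case sampling: cases drawn from population 1 with probability
  `strat_case_frac_pop1`, controls with the complement.  This is a
  deliberately strong confounder that produces the λ inflation genomic
  control exists to correct.

Doses are re-oriented after generation so they count the pooled-sample
minor allele under exactly the convention the PED/MAP reader uses —
this is what makes write→read round-trips bit-identical.  All outputs
are pure functions of (config, seed): annotation and cohort use
disjoint seed streams spawned from the config seed.

What passing tests on these cohorts does *not* show: robustness to
realistic human LD structure, genotyping batch effects, relatedness,
or annotation error; those are properties of real panels the generator
deliberately does not model.

## Numerical and engineering choices

* Permutation batches are evaluated as three matrix products
  (label-matrix × genotype-class masks) in float64; counts are exact
  integers, so the batched statistics agree with the scalar path to
  machine precision and with exhaustive enumeration exactly.
* The trend p-value lattice is discrete: P(χ² = 0) is a few percent
  even at n = 1,000, putting a conservative atom at p = 1.  Calibration
  is therefore asserted as |ECDF(α) − α| < 0.02 over α ∈ [0.001, 0.95]
  rather than a raw KS distance against the continuous uniform.
* Window keys are the integers −K..K plus the string `"exon"`; the
  membership matrix repeats exonic SNPs in both their window-0 row and
  the exon row by construction.
* Tie-breaks (equidistant genes, allele-frequency ties) are always
  lexicographic, making every output order-independent of input
  enumeration.

## Validation study sizes

The studies in `genewin.validation` (run by the acceptance script and
the test suite) use: five null cohorts of 500+500 individuals × 5,000
SNPs with 1,000 permutations (calibration, λ, CI coverage); ten
structured cohorts of 1,000+1,000 × 5,000 SNPs (λ inflation); and
1,000+1,000 × 6,000-SNP planted-effect cohorts with 500 permutations
(detection).  These sizes give stable rates from a single-CPU run in
minutes while preserving the regime of the analysis (thousands of
samples, LD blocks wider than SNP spacing, exon stratum two orders of
magnitude smaller than the gene window).

## Known limitations

* λ_median on 5,000 LD-correlated SNPs is noisy (sd ≈ 0.04); single-run
  values in [0.95, 1.05] should be read as "consistent with 1", and
  replicate means are the right summary.
* The permutation engine materializes per-window counts per
  permutation; the full p-value matrix is only materialized by
  `permute_pvalues` for moderate sizes (tests, small studies).
* Combined-trait CIs assume independent traits.
* The generator's uniform gene placement has no gene deserts beyond
  what chance produces; the unassigned-SNP fraction is smaller than in
  real genomes.
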