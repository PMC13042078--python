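# Methods

This note documents the models behind each module, the tunable parameters
and their defaults, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and I/O (`genio`)

Genotypes are dense int8 matrices (individuals × SNPs) with 0/1/2 = count of
the alternative allele and 9 = missing; pseudohaploid individuals use only
{0, 2, 9} (a single sampled allele coded as a homozygote). Genetic positions
are carried in **Morgans** everywhere internally; centimorgans appear only
at I/O boundaries, and the EIGENSTRAT reader auto-detects cM input (any
per-chromosome span above 4) and converts with a logged warning. Only the
plain-text EIGENSTRAT dialect is supported. Jackknife blocks are greedy
contiguous segments: a new block starts at each chromosome start and
whenever a SNP lies ≥ 5 cM (configurable) past the block's first SNP.

## Synthetic data (`simdata`)

The generators define the conditions under which everything downstream is
validated; all are pure functions of (parameters, seed), with per-component
streams keyed by stable string hashes so outputs do not depend on iteration
order.

* **Drift graphs.** Allele frequencies evolve down an acyclic graph by
  Balding–Nichols sampling: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) given
  parent p and branch drift F ∈ (0,1), which preserves the mean and has
  variance F·p(1−p); Beta sampling was chosen over a Normal approximation
  because it has exact support with no truncation artifacts. Admixture
  events mix parent frequencies linearly (w·pA + (1−w)·pB) before child
  drift. Root frequencies are Uniform(0.05, 0.95).
* **Pseudohaploid sampling** draws one Bernoulli(freq) allele per individual
  per site with independent per-cell missingness.
* **Pileups.** Read depth is Poisson per site; each read carries strand,
  terminal/central flag (25% terminal by default), library id and two-level
  mapping/base-quality bins (70% ≥ 30). Errors flip the true base to the
  site's other allele at the stratum's rate — the substitution class the
  caller's reliability score is built from. Monomorphic "error-training"
  sites are flagged in the SNP table and have their true base fixed to the
  reference. The simulator does not model fragment-length distributions,
  indels, or reference bias.
* **Mosaic admixed chromosomes.** Each haplotype starts Bernoulli(w) in
  source-A ancestry and lays switch points down as a Poisson process of rate
  t per Morgan, redrawing Bernoulli(w) at each point (the many-generation
  limit of recombining against the admixed pool); the diploid genotype is
  the sum of two independent haplotypes. This yields ancestry covariance
  w(1−w)·e^(−t·d) exactly, the model the dating module fits. Sample-age
  staggering and continuous admixture are not emulated.
* **ROH genomes** are the generative twin of the Ne likelihood: per-bin
  segment counts are Poisson with the model expectations (fine 1–5 cM
  simulation bins from 2 cM), lengths drawn from the within-bin density, and
  positions uniform among placements that keep the segment wholly within a
  chromosome and non-overlapping. Placement deliberately avoids truncating
  segments at chromosome ends: the likelihood ignores edge effects by
  design, and truncation would systematically delete long-segment mass the
  model expects (a drawn length exceeding every chromosome — vanishing
  probability at sensible 2Ne — is clipped to the longest chromosome).
  Heterozygous sites occur at `het_rate` per SNP outside ROH and never
  inside. The default test genome is 20 chromosomes × 1.75 M (35 Morgans)
  at 5,000 SNPs/Morgan with `het_rate` 0.2, a realistic background
  heterozygote fraction for an ascertained variant panel; note that at a
  much lower het rate a window of 50 SNPs carries almost no heterozygotes
  outside ROH and no windowed caller can discriminate.
* **QC tables** are constructed so that exactly `n_pass` rows satisfy every
  threshold and each fail row violates precisely one named rule (checked at
  generation time).

## Pseudohaploid caller and QC (`pullcall`)

Error rates are estimated at monomorphic-flagged sites as the fraction of
reads observed as the site's other allele, per stratum (library,
substitution direction, terminal/central with >10 bp from either read end
merged as central, strand, MQ <30/≥30, BQ <30/≥30 — the two-level quality
bins are this package's choice; finer bins would fragment the training
data). Unobserved strata fall back to a configurable pseudo-rate (default
0.001) rather than 0, so a stratum with no training data is not certified
reliable. Calling discards reads whose stratum S = max of the two
directional rates is ≥ the threshold (default 0.02), then draws one base
uniformly from the survivors using a stream keyed by SNP id. QC comparisons
are strict inequalities throughout, so exact-threshold values pass: fail on
snps_covered < 15,000; damage < 3% (UDG) / < 10% (non-UDG);
contamination lower bound > 0.01; mtDNA match upper bound < 0.90;
sex ratio strictly between 0.05 and 0.3 (the sex ratio is computed as
Y/(X+Y) aligned reads — the window 0.05–0.3 is only consistent with this
ratio, but the algebraic definition is an assumption, flagged here). Among
passing 1st-degree relative pairs the lower-coverage member is dropped with
a distinct reason code (grouped analyses only).

## f-statistics (`fstats`)

Per-SNP terms use haploid counts (pseudohaploid = 1 observation, diploid =
2): f4 = (â−b̂)(ĉ−d̂); f3(X;A,B) = (x̂−â)(x̂−b̂) − h_x;
f2 = (â−b̂)² − h_a − h_b, with h = x(n−x)/(n²(n−1)) and the correction
skipped at n = 1. This haploid-count ("inbred") correction is the default;
a diploid observed-heterozygosity variant is selectable for outbred diploid
panels. Masks are per-statistic (no global intersection), and SNPs
monomorphic across the used populations are retained (they contribute 0).
One algebraic consequence worth noting: f3(X;A,A) computed from a single
sample of A equals f2(X,A) plus A's correction h_A, because f2 debiases the
source's sampling variance while f3 only debiases the target's; the two
estimators agree in expectation and converge at large n. The jackknife is
Busing's weighted delete-mⱼ with block weights = valid SNP counts; it
reduces exactly to the classic delete-one formula for equal blocks.

## Rank tests and admixture weights (`wave_adm`)

The f4 matrix's jackknife covariance uses per-entry block weights with
cross-entry terms symmetrized through √((h_e−1)(h_f−1)); near-singular
covariances (condition number > 1e12) receive a relative ridge of
1e−6 × mean diagonal with a logged warning — jackknife covariances from few
blocks are otherwise frequently non-invertible. Rank-r fits minimize the
covariance-weighted form over factor matrices by alternating GLS (initialized
from the SVD, iterated to 1e−12 relative convergence); df = (|L|−1−r)(|R|−1−r).
Weights solve min_w (X'w)' C(w)⁻¹ (X'w) subject to Σw = 1 by a fixed-point
iteration on the closed-form constrained GLS solution (C(w) is the exact
contraction of the vec-covariance, so no separate covariance re-estimation
is needed); weight SEs re-solve the system on each leave-one-block-out
matrix. Weights outside [0,1] are flagged infeasible, never clipped.
Grouping runs all pairwise rank-0 tests, joins pairs with p > α = 0.05, and
takes connected components; an individual whose neighbours fall into more
than one component of the graph with that individual removed is flagged
ambiguous and left ungrouped — a concrete rendering of a procedure whose
published description is only a sketch.

## Admixture dating (`datefit`)

The binned statistic is Σ w_i w_j cov(residual_i, residual_j) over
intra-chromosome pairs with d ≤ maxdis, bin ⌈d/binsize⌉, where residuals are
genotype − 2×pooled frequency (population-level residuals work for
pseudohaploid cohorts without per-individual ancestry estimates) and missing
genotypes are mean-imputed. Defaults binsize = 0.001 M, maxdis = 0.20 M.
The pair covariance is computed as a blocked matrix product; binning is
exact per pair (numba kernel), not grid-approximated. The fit
y = A·e^(−t·d) + c runs over bin midpoints in [0.005, 0.20]; the lower
cutoff excludes the shortest bins where background LD contaminates the
signal and is configurable. The decay exponent is t per Morgan with no +1
correction (stated explicitly because conventions differ). Uncertainty is a
delete-one-chromosome jackknife weighted by pair counts. Years use a
configurable generation time, default 28.9 years. An essentially flat curve
returns a "no-signal" fit rather than raising.

## ROH and Ne (`rohne`)

The caller marks non-overlapping 50-SNP windows with ≤ 1 heterozygote,
merges adjacent marked windows, refines each run's boundaries outward to
the nearest flanking heterozygote, and then pulls each boundary back by the
expected geometric overshoot (1−h)/h SNPs, with h the background het rate
estimated from unmarked windows — without this correction, called lengths
are biased upward by ~2/h SNPs and the Ne fit inherits a visible downward
bias. Runs shorter than 4 cM are dropped. This windowed scan is designed
for the synthetic diploid genomes; it is not a haplotype-copying HMM and is
not suitable for sparse real aDNA data, so the likelihood model — not real-
data Ne values — is the testable core here. Class sums are reported above
4/8/12/20 cM; individuals with > 50 cM of ROH > 20 cM are flagged as
close-kin unions and excluded from Ne fitting, and a 300,000-SNP coverage
gate controls eligibility. The likelihood treats per-bin counts as Poisson
with the closed-form expectations (geometric coalescence time truncated at
t_max = 3000, which changes results by < 0.1% for 2Ne ≤ 5000), maximized on
a 400-point log grid over 2Ne ∈ [20, 20000] with bounded refinement; the
95% CI is the profile set within 1.92 log-units, with an open upper bound
when no segments are observed.

## Kinship (`relate`)

pmr is the disagreement fraction over jointly non-missing sites with a
block-jackknife SE. The baseline b is the median pmr of within-group pairs
with ≥ 10,000 overlapping SNPs (median rather than mean so a few related
pairs cannot contaminate the background). r̂ = 2(1 − pmr/b); degree
boundaries sit at the midpoints 0.75/0.375/0.1875/0.0625 of the expected r
values (symmetric misclassification risk); pairs with < 3,000 overlapping
SNPs, or whose ±1 SE interval spans a boundary, are labelled insufficient.
Parent–offspring cannot be distinguished from siblings with this statistic.

## Outgroup-f3 trees (`f3tree`)

Distances are 1/f3 with no additional scaling. Neighbor joining is the
classic Q-criterion algorithm with Saitou–Nei branch lengths; ties in Q are
broken by the lexicographically smallest tip-label pair under each
candidate, making output deterministic. Rooting places the root at the
midpoint of the outgroup's pendant edge (configurable to attach at the
tip). Grafen's transform sets each node's height to
(descendant tips − 1)/(total tips − 1) — tips at 0, root at 1 — and the
power transform raises heights to an exponent (default 0.5) before branch
lengths are rewritten as height differences; normalizing to unit root
height first means the exponent acts on [0,1] and the root stays at 1.

## Radiocarbon (`c14`)

Combination is the inverse-variance-weighted mean with
T = Σ((xᵢ − pooled)/σᵢ)² compared to the upper 5% chi-square point at
n−1 df. Calibration interpolates the curve linearly onto a 1-year grid
(matching the reporting precision of calibrated ranges), forms the Normal
posterior with variance σ_m² + σ_curve(θ)², and reports the smallest set of
grid years reaching 95.4% mass as contiguous HPD intervals (HPD, not
central, to match how calibrated ranges are conventionally reported). No
reservoir or fractionation corrections are applied. Conversion to calendar
years uses the no-year-zero convention (1950 − calBP; 1950 calBP → 1 BCE).
The IntCal20 curve itself is not redistributed; calibration tests use
synthetic curves (identity and plateau constructions) unless a user
supplies `data/intcal20.14c`.

## PCA projection (`projection`)

The basis is fit on complete-data reference individuals; SNPs with any
reference missingness or monomorphic in the references are dropped
(normalization √(p(1−p)) undefined). Eigenvector signs are fixed by making
each vector's largest-magnitude entry positive. Samples are placed by least
squares of their normalized non-missing entries on the eigenvector rows —
the standard correction for shrinkage under missingness. No co-visualization
shrinkage remapping of reference scores is applied; reference individuals
are reported at their fitted scores.

## Problem sizes and runtime

Test and driver problem sizes are the package's own desk-scale choices: the
study-scale recovery experiments use 200k SNPs / 30 pseudohaploid targets
(weights) and 100k SNPs / 100 diploids / 20 chromosomes (dating); module
suites use 10k–60k SNPs, 200 replicates for null calibration of the rank-0
test, 20 replicates for Ne CI coverage at 2Ne = 240 / 21 individuals, and
60 pedigree replicates for kinship classification. The full suite runs in a
few minutes on one CPU.

## Known limitations

* The ROH caller and the damage/pileup simulator are deliberately simple;
  neither models real read-level artifacts (reference bias, mapping error,
  contamination mixtures), so passing tests demonstrate correctness of the
  estimators under their stated models, not field performance on real aDNA.
* Contamination estimates are consumed as scalar QC metrics, never computed.
* qpAdm here solves the weighted least-squares formulation; it does not
  implement rotating-outgroup model competition or nested model search.
* The admixture-date model is single-pulse; multi-pulse or continuous
  admixture will bias t toward an average.
* f-statistic graph fitting, PLINK/VCF interop, phasing and liftover are out
  of scope.
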