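# Methods

## The model-free interaction measure

Let *Y* be binary disease status and *X* the joint genotype of a *k*-SNP
combination, taking values in the 3ᵏ cells AA…×…aa. All statistics derive
from the 3ᵏ × 2 contingency table of counts n*ᵢⱼ*. Shannon entropies are
computed in bits with the 0·log 0 = 0 convention:

* H(Y) from the case/control margin;
* H(Y|X) = Σᵢ (nᵢ·/n)·H(Y | X = cell i), empty cells contributing zero;
* IG = H(Y) − H(Y|X), and R₀ = IG / H(Y) ∈ [0, 1].

The base of the logarithm cancels in R₀; bits are used throughout so the
G-statistic identity carries an explicit ln 2 factor: G² = 2·n·ln2·IG,
with independence-test degrees of freedom (3ᵏ − 1)(2 − 1). The G test's
chi-square approximation degrades on sparse tables, so `g_statistic` also
reports the number of non-empty rows as a diagnostic; R₀ itself needs no
asymptotics.

Cell indexing is mixed-radix base 3 with the first SNP most significant
and genotype order AA < Aa < aa (minor-allele counts 0 < 1 < 2). Any
bijection would do; this one is fixed so tables, scans and serialized
results are reproducible across runs and machines.

Missing genotypes are handled by per-combination complete-case exclusion:
a sample is dropped only from tables of combinations in which one of its
calls is missing. This matches the complete-data analyses the method is
intended for and keeps every table internally consistent (column margins
equal the case/control counts of the samples actually tabulated).

## Permutation standardization and error control

Empirical R₀ is biased upward in the interaction order: for S ⊂ S′,
R₀(S) ≤ R₀(S′) regardless of any real signal (conditioning on more cells
never increases H(Y|X)). Comparing orders therefore requires calibration.
The null ensemble shuffles the phenotype vector uniformly at random
(without replacement, preserving case/control margins) n_perm times with
genotypes fixed — the default n_perm is 1000 — and records
Mᵢ = max over all order-k combinations of R₀ in shuffle *i*. Then

* U_r = (R₀ − μ)/σ with μ, σ the mean and (n−1)-denominator SD of the Mᵢ;
* p_adj = #{Mᵢ ≥ R₀}/n_perm (the ≥ count is conservative; an observed 0 is
  rendered "< 1/n_perm");
* the α-level cutoff is the ⌈(1−α)·n_perm⌉-th smallest Mᵢ (ceiling order
  statistic, conservative for small ensembles), and a combination is
  flagged significant iff R₀ strictly exceeds it.

Because the maximum is taken across combinations within each shuffle, one
ensemble per order controls the family-wise error rate over all
combinations of that order; an ensemble per combination would not. Under a
global null the observed maximum is exchangeable with the permutation
maxima, so the strict-inequality rejection rule at α = 0.05 with
n_perm = 200 has exact level 11/201 ≈ 5.5% for continuous statistics —
the [3%, 7%] acceptance band around the nominal level reflects this plus
Monte-Carlo error.

Per-permutation RNG streams are spawned deterministically from one master
seed, so ensembles are reproducible and could be computed in any order or
in parallel. Null summaries serialize to JSON (order, n_perm, μ, σ,
quantiles, seed, maxima) so scans can be re-standardized without
re-permuting.

Degenerate inputs fail loudly: a single-class phenotype (H(Y) = 0), an
all-missing combination, and a zero-spread null (e.g. constant genotypes)
each raise a dedicated exception naming the cause.

## Scanning

The exhaustive order-k scan is vectorized over combinations and phenotype
vectors simultaneously: genotype cell membership is a sparse indicator
matrix built once per block of combinations, so an entire permutation
ensemble reduces to one dense-sparse matrix product per block, and cell
*totals* (which permutations do not change) are computed once. A safety
limit (default 2·10⁶ combinations) refuses accidentally huge scans with
the offending count; ties in the ranking break lexicographically on SNP
indices so results are deterministic.

## The two-locus penetrance simulator

Eight disease models are encoded as 3×3 odds-ratio grids over the joint
genotypes of two causal loci sharing one MAF, with a target population
prevalence (models 1–3: OR 5/3/2.5 checkerboards at MAF 0.1, prevalence
0.050; models 4–6 and 7–8: published epistasis benchmarks at prevalences
0.046/0.026/0.017 and MAF 0.2/0.4 with prevalence 0.052/0.048). All have
little marginal effect by construction. Odds ratios are interpreted as
multipliers of a common baseline odds *b*:

    penetrance_ij = OR_ij·b / (1 + OR_ij·b),

with *b* solved (Brent root find on the bracket 10⁻⁸–10³; the
HWE-weighted mean penetrance is strictly increasing in *b*) so that
Σᵢⱼ wᵢwⱼ·penetrance_ij equals the prevalence, w = ((1−q)², 2q(1−q), q²).
The residual is verified below 10⁻¹⁰. A zero odds ratio (model 4's aa/bb
cell) is a structural zero: penetrance exactly 0.

Case-control sampling is retrospective: case genotype pairs drawn with
probability ∝ wᵢwⱼ·penetrance_ij, controls ∝ wᵢwⱼ·(1−penetrance_ij).
Datasets are balanced 1:1, with the causal pair at SNP positions 0 and 1
(configurable) and the remaining noise SNPs drawn independently under HWE
with per-SNP MAF ~ Uniform(0.05, 0.5) — a documented choice, since the
original noise scheme is not restated in the sources the models come
from. No linkage disequilibrium, gene–environment terms, or population
structure are simulated; conclusions from these tests therefore speak to
independent-locus panels, not to LD-structured or stratified cohorts.
Design groups follow the 5 × 3 grid of SNP counts (10, 50, 100, 500,
1000) by sample sizes (400, 1000, 2000), numbered 1–15 down the columns;
replicates are deterministic in (master seed, replicate index).

The power protocol embeds one causal pair and reports the **hit ratio**:
the fraction of replicates (100 per model × group in the full protocol)
in which that pair ranks first among all C(p, 2) two-locus combinations.
Since U_r is an increasing affine transform of R₀ within an order, the
U_r and R₀ hit ratios are identical and no permutations are needed inside
the power loop.

## The MDR baseline

Multifactor dimensionality reduction labels each genotype cell high-risk
when its case:control ratio reaches the training data's overall ratio
(ties go high; a cell with cases and no controls is high; an empty cell is
low — the comparison is done in exact integer arithmetic) and scores a
combination by balanced accuracy (sensitivity + specificity)/2 of the
resulting 1-D classifier. Ten-fold cross-validation stratified by
phenotype yields mean testing BA and cross-validation consistency (CVC,
how many folds picked the combination by training BA); the overall winner
is chosen by CVC with testing-BA then lexicographic tie-breaks. A repeat
parameter (default 1) averages CVC over independent fold splits.

## Visualization

Scree plots rank the top 100 combinations by U_r (or R₀) with a dotted
line at the α cutoff; the elbow judgment is left to the user, but the
count of combinations above the line is reported. The MDS map applies
classical Torgerson scaling (double-center the squared pairwise matrix,
eigendecompose, keep the two leading non-negative eigenpairs, 1-D
fallback with a warning otherwise) to the matrix of pairwise two-locus
values — by default the R₀ values themselves, or shifted U_r (adding
−min U so the weakest pair has distance zero), which yields the same
configuration up to the shift. Marker areas are affine in single-locus
R₀ with a floor so weak main effects remain visible. Every figure has a
sidecar TSV twin with identical numbers.

## Problem sizes in the test and acceptance runs

The verification suite uses the protocol's own conditions at sizes a
single workstation handles in seconds to minutes: the type-I-error study
runs 500 global-null datasets of 10 SNPs × 400 samples with 200
permutations each; the simulator-consistency check forward-simulates 10⁶
individuals; the power comparison runs model 1 at 10 SNPs for 400 vs 2000
samples with 50 replicates, checked directionally (hit ratio non-
decreasing in sample size; the RIG ranking not significantly below MDR-BA
by a one-sided exact binomial test on discordant replicates). Entropy
identities are verified on 1000 random tables to 10⁻¹² and the G²
identity to 10⁻⁹.

## Known limitations

R₀ does not separate main effects from pure interaction: a pair containing
one strongly marginal SNP can rank highly without any epistasis. The scan
is exhaustive, so genome-wide use requires pre-screening to a candidate
set. Adjusted p-values are bounded below by the permutation resolution
1/n_perm. The simulator's independence assumptions are stated above.
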