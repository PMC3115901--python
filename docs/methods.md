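# Methods

## The model

The cohort is assumed to be a mixture of homogeneous subpopulations in
which the blood-pressure indicators are normally distributed; the
heterogeneous marginal distribution of the whole cohort carries no
distributional assumption.  With indicators **y** (diastolic, systolic;
mmHg) and covariates **z**, the density is

f(**y**|**z**) = Σₖ π(x=k|**z**) f(**y**|x=k, **z**),

where the gating π(·|**z**) is a multinomial logit (reference class 0)
and, in the default *latent-profile* configuration, f(**y**|x, **z**) is
a diagonal-covariance Gaussian N(ν_k, diag(σ²_k)) — covariates act on
class membership only, and within a class the indicators are
conditionally independent.  A perfect partition therefore decorrelates
the indicators inside every class, which is what `class_diagnostics`
checks (per-class Pearson correlation plus Shapiro–Wilk, Lilliefors and
Anderson–Darling normality tests).

An optional *one-factor* variant intersperses a latent variable η
("vascular bed") between covariates and indicators within each class:
y = ν_k + λ_k η + ε, η = γ_kᵀz + ζ, identified by fixing the first
loading to 1 and the factor intercept to 0 (γ_k carries no intercept).
The exact within-class specification of the original software is not
published, so the conditional-independence model with gating is the
default; both variants share the EM skeleton and are selected with the
same criteria.

### Estimation

EM with responsibilities as the E-step.  The Gaussian M-step is closed
form (responsibility-weighted means and variances, with a variance
floor of 10⁻⁶ × the marginal indicator variance against degenerate
spikes).  The gating M-step is a warm-started damped Newton ascent on
the responsibility-weighted multinomial-logit likelihood; step-halving
guarantees the Q-function never decreases, so the overall iteration is
a generalized EM and the log-likelihood is monotone non-decreasing — a
property asserted per iteration in the tests.  The factor variant's
M-step conditions on the posterior moments of η (scalar updates via the
Sherman–Morrison identity) and is an exact conditional maximization.

Initialization: k-means on standardized indicators for the first
restart, random data points with jitter thereafter; 20 restarts by
default, best log-likelihood kept.  Convergence when the relative
log-likelihood gain falls below 10⁻⁸, capped at 2,000 iterations;
non-convergence is flagged on the result, never silent.  A class whose
responsibility mass falls below 10⁻⁸·n is re-jittered (counted on the
result).  Classes are canonicalized by ascending first-indicator mean,
making output deterministic given the seed.  Complete-case analysis
throughout.

### Model selection

Adjusted BIC = −2ℓ + d·ln((n+2)/24), the conventional sample-size-
adjusted penalty of mixture software (the criterion is named but not
defined in the sources this package follows; this is the standard
form).  The minimum wins; models within a configurable margin (default
2.0) count as equivalent and the higher entropy,
1 − Σᵢₖ(−p_ik ln p_ik)/(n ln K), breaks the tie.  Per-K failures are
recorded in the selection table without aborting the sweep.

## Variance decomposition

For a biallelic SNP with counted-allele frequency p (estimated inside
the analyzed stratum), the Cockerham contrasts are
w_A: {0→−2p, 1→q−p, 2→2q} and w_D: {0→−p², 1→pq, 2→−q²}.  Under exact
HWE weights these have zero mean, zero mutual covariance,
Var(w_A) = 2pq and Var(w_D) = (pq)².  A SNP pair contributes eight
predictors (two marginal contrasts per locus and four products); the
trait is regressed on them by least squares and each component is
V_j = Var(β̂_j x_j).  Under exact orthogonality the components sum to
the explained variance (asserted to 10⁻¹⁰ on constructed exact-HWE
tables).  Epistasis significance is the joint F-test of the four
interaction terms (4 df against the marginal model); per-term t-tests
are also emitted for curation.  Relative epistatic variance divides
V_AA+V_AD+V_DA+V_DD by the stratum's sample trait variance V_P;
single-SNP heritability is (V_A+V_D)/V_P from the two-contrast
regression — a local, panel-level quantity.

Degenerate predictors (constant after complete-case filtering) are
dropped with a named flag and their components set to zero; a pair
stays testable while at least one interaction predictor survives and
at least 20 complete cases remain (the smallest stratum the reference
design scans has ~21 subjects; smaller strata return an empty flagged
result).  Missing genotypes are handled pairwise complete-case, no
imputation.

### Stratum QC

Within every stratum the scan recomputes allele frequencies and
monomorphism, and excludes SNPs failing the exact conditional HWE test
at p < 0.05/m (m = informative SNPs in the stratum; the exclusion rule
is inherited, the threshold is this package's choice).  The HWE test
enumerates heterozygote counts conditional on the allele counts and
sums probabilities ≤ the observed table's.  Pairwise LD is estimated by
a two-locus haplotype EM on unphased genotypes (double heterozygotes
split by current phase odds), reporting D, D′, r² and a 1-df
likelihood-ratio p against independence.  Intragenic pairs — possible
LD rather than biological interaction — are computed, flagged, and
excluded from epistasis summaries and networks.  The Bonferroni
threshold α* = α/(n_pairs·n_subpops·n_traits) is derived from declared
counts, so it reproduces exactly.

The case-control contrast (`dichotomized_scan`) thresholds the traits
at the office rule (diastolic > 90 or systolic > 140 mmHg) and applies
the same decomposition to the 0/1 trait, quantifying how much signal
dichotomization discards relative to the within-stratum analysis.

## Networks

Genes are nodes; a significant inter-genic SNP pair links its two genes
with weight = relative epistatic variance.  Curation is either
*max-edge* (per gene pair keep the largest-variance SNP pair) or
*representative-snp* (per gene keep the SNP with the most significant
inter-genic interactions; ties by larger maximal variance then
lexicographic id, so curation is deterministic).  Centralities are
computed on the unweighted topology — the weights select edges but no
weighted-distance convention is imposed: closeness (c−1)/Σd within the
node's component (isolated → 0), betweenness and stress from shortest-
path counts, centroid value min_u[γ_v(u) − γ_u(v)], Katz as row sums of
Σ_{k≥1} αᵏAᵏ with α = 0.85/λ_max by default (α ≥ 1/λ_max raises), and
closeness vitality as the Wiener-index change on node removal, with a
sentinel when removal splits a component.  Merging takes the edge union
with max weight; subtraction removes a core network's gene pairs while
preserving the node set.  Networks serialize to Pajek .net, GraphML and
a TSV edge list, all round-tripping through the package's readers.

## Synthetic cohorts

`simulate_genotypes` draws HWE genotypes (q², 2pq, p²) independently
per SNP; LD blocks are simulated as two independent haplotypes from a
Markov chain whose adjacent-pair r² equals the block target (solved
from the 2×2 haplotype table; infeasible frequency/r² combinations
raise rather than clip).  `simulate_population` draws independent
standard-normal covariates, class labels from the specified gating,
and indicators as class Gaussians plus planted genetic contributions
expressed through the true-frequency contrast scores, so every planted
effect has the analytic variance β²·Var(contrast product)
(`expected_components`), with Var(w_A) = 2pq and Var(w_D) = (pq)².
All randomness flows from one integer seed through a single generator;
fixed seed ⇒ byte-identical outputs.

The reference scenario (`monica_like`) mirrors the cohort scale the
method targets: 2,523 subjects, 45 SNPs in 23 sphingolipid-pathway
genes (identifiers and frequencies synthetic; two intragenic LD blocks
at r² = 0.8), two indicators, 10 covariates, K configurable 2–14 with
a fully hypertensive top class, and a planted additive×additive
interaction sized to relative variance 0.5 in that class — the scale of
the largest effect the method is meant to detect.  The planted
interaction acts on the diastolic indicator only: with both indicators
shifted, class misassignment becomes genotype-differential and
attenuates the recovered relative variance; keeping systolic clean for
classification removes that artifact while preserving the quantity
under study.  The planted loci sit at allele frequency 0.5, where the
contrast variances are largest.

What the generator does *not* emulate: realistic human LD maps,
covariate scales and intercorrelation (Gaussian i.i.d. covariates
only), measurement error structure, non-normal within-class tails, or
genotyping artifacts.  Passing recovery tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to their violation in real cohorts.

## Study sizes used by tests and the acceptance script

Chosen as the smallest sizes at which the analytic expectations are
sharp: planted-effect recovery at n = 50,000 (±0.02 on a relative
variance of 0.5); F-test calibration over 1,000 null pairs of n = 300;
class-count selection over 20 replicates of n = 800 with classes
separated by ≥ 4 residual SDs; the end-to-end run at the full reference
scale n = 2,523 with a K ∈ {3,4,5} sweep.  The pipeline's determinism
contract (identical config + seed ⇒ byte-identical bundle) is checked
on a scaled-down cohort.

## Known limitations

- The orthogonality of the decomposition is exact only under HWE and
  linkage equilibrium between the pair; within-stratum frequency
  estimation and HWE filtering keep departures small but nonzero, so
  components on real strata are near- rather than exactly additive.
- The gated mixture assumes Gaussian classes; heavy-tailed or skewed
  subpopulations can inflate the selected class count (large planted
  genetic effects inside a class act exactly like such a departure).
- No kinship/mixed-model correction, no X-chromosome dosage model, no
  haplotype inference beyond two loci, no imputation.
- Katz's attenuation and the HWE-exclusion threshold are conventions,
  configurable but not estimated from data.
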