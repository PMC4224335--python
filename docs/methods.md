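# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the judgement calls made where the design was
genuinely open.

## Study design and data model

The target design is a case-control sample: the numbers of affected and
unaffected subjects are fixed by recruitment, so the sample case
proportion (0.757 in the reference cohort of 1,118 cases and 359
controls) reflects the design, not population prevalence. Each subject
carries a binary status, optional sex/age covariates, an mtDNA
haplogroup cluster and a diploid nuclear genotype; the analysis unit is
the joint stratum `<CLUSTER>_<GENOTYPE>`. Genotypes are unphased and
normalised to sorted allele pairs (CG ≡ GC). Strata with zero members
are simply absent — no stage assumes a fixed stratum list. Records with
missing cluster or genotype are retained by I/O but excluded from
stratification, with a logged count; analyses never abort on missing
calls.

A nomenclature caveat carried over from the source material: the RFLP
assay defines C as the common (uncut) allele and G as the rare (cut)
allele of rs8875, while the accompanying allele-frequency prose labels
G the leucine allele at ~0.74 in controls. The package treats allele
labels as opaque strings — the frequency arithmetic is label-agnostic —
and does not attempt to resolve the discrepancy.

## RFLP genotyping

In-silico digestion scans the amplicon left to right for
non-overlapping motif occurrences (greedy scan — standard digestion
semantics) and cuts after a fixed offset within each; fragment lengths
always partition the sequence. The rs8875 assay model is a 326-bp
amplicon with the rare allele cut into 215+111 bp. Band matching uses a
per-band tolerance of 5 bp by default — agarose gel resolution; only
exact sizes are published — and any pattern other than {326}, {215,111}
or their union is a missing call, not an error. Haplogroup-to-cluster
mapping (HV←{H,V}, UK←{U,K}, JT←{J,T}, IW←{I,W,X,N1}) resolves
sub-haplogroups by longest-prefix match, so `N1b` hits `N1`/IW rather
than failing on a bare `N`; unmapped lineages (African/Asian L, M, …)
yield missing clusters with a warning.

## G-test of independence

`G = 2 Σ_{O>0} O ln(O/E)`, `E = (row total·column total)/grand total`,
df `(r−1)(c−1)`, p from the χ² survival function. No Williams or
continuity correction is applied by default: the uncorrected statistic
reproduces the reference values (3.933 on the 4×2 haplogroup table,
4.868 on the 3×2 genotype table) to ~0.1%, which is how the ambiguity
about the original software's settings was settled. The Williams
correction is available via `williams=True`. Zero observed cells
contribute 0 (the `x ln x → 0` limit); all-zero rows or columns are
rejected because the df would be undefined.

## Permutation enrichment test

Each replicate shuffles the full status vector uniformly (a permutation
of the fixed label multiset — stratum sizes and the overall case count
are conserved by construction) and recomputes every stratum's absolute
deviation from the overall proportion on the *same* shuffle (one shared
stream; a per-stratum independent-stream mode exists but is not the
default, since a single shuffled cohort naturally scores all strata at
once). The p-value estimator is the raw fraction `b/B` of replicates
with deviation ≥ observed — ties count as exceedances, compared with a
1e-12 guard against float noise — matching the "proportion of
replicates at least as extreme" definition; an add-one estimator
`(b+1)/(B+1)` is available where zero p-values are unacceptable.
B defaults to 10,000.

Internally the record arrays are sorted into a canonical order before
shuffling, so results depend only on the cohort's content and the seed,
not on input row order. A single-stratum cohort is degenerate but
well-defined (deviation 0, p = 1) and is handled with a warning.

Because the shuffle null for one stratum is exactly
Hypergeometric(N, K, n_g), the closed-form two-tailed tail sum is
computed for every stratum and reported next to the Monte-Carlo
estimate. The exact values for the two headline strata are 0.0058
(HV_CC) and 0.0388 (UK_CG), bracketing the published Monte-Carlo
0.006 and 0.036.

## Logistic odds-ratio contrasts

The stratum factor is dummy-coded: intercept plus k−1 indicators
against the reference stratum (12 strata → 11 indicators). Fitting is
IRLS to a deviance-change tolerance of 1e-10 (max 100 iterations);
standard errors come from the inverse Fisher information at the MLE.
The design must be full column rank (offending columns are named via
the QR diagonal); quasi-separation — any |β| > 15 while the deviance is
still falling — triggers a warning and a non-convergence flag rather
than penalisation, matching classic GLM behaviour. The counts-only
12-stratum model is saturated, so each OR equals the 2×2 cross-product
ratio against the reference; this closed form is the primary test
oracle, with statsmodels as an independent numerical cross-check. CIs
use the multiplier 1.959964 and are reported lower–upper (the source
tables print them upper–lower; we normalise).

The published contrast table was adjusted for sex and age, which are
not available at individual level; those adjusted coefficients are
therefore not reproducible here and are not asserted. The counts-only
fit is the supported surface — for HV_CG the adjustment was negligible
(1.586 unadjusted vs 1.58 published) — and the machinery is instead
validated by simulation: 95% Wald CI coverage of a known odds ratio is
checked at n = 5,000 over 200 seeded cohorts.

## Storey q-values

`π̂₀(λ) = #{p > λ}/(m(1−λ))` over the grid λ = 0.00, 0.05, …, 0.90 (the
classic QVALUE default; configurable). The smoother estimator fits a
cubic smoothing spline to π̂₀(λ) and evaluates it at the largest λ; the
penalty is tuned by bisection on the trace of the smoother matrix to 3
effective degrees of freedom, emulating `smooth.spline(df = 3)`. The
bootstrap estimator picks the λ minimising the bootstrapped MSE of
π̂₀(λ) around the plug-in minimum (default B = 100 resamples). Both are
clamped to (0, 1]. Q-values are the monotone transform
`q(i) = min_{j≥i} π₀ p(j) m / j` on the sorted p-values; tied p-values
share the q of their largest rank, and π₀ = 1 reduces exactly to
Benjamini–Hochberg.

With only m = 12 p-values, π₀ estimation is far below its stable regime
— the estimators warn below m = 100 — so reproducing the published
π₀ values (0.227/0.208 and 0.275/0.260) is not attempted; they are
accepted as fixed inputs (`pi0_mode = fixed:<value>`), and only the
q-value transform at fixed π₀ is asserted against the published
columns.

## Growth kinetics

Doubling time is the reciprocal slope of an ordinary least-squares fit
of log₂(OD) on time. The default exponential-phase window keeps
readings between 1.5× the first OD and 0.5× the final reading (a
plateau proxy); when fewer than two points qualify — short ideal curves
— the fit uses all points, so exact two- and three-point doubling
curves are recovered closed-form. An explicit time window overrides the
default. Interaction strength comparisons use the growth *rate* 1/T
(the quantity that changes ~40% in the motivating assay), as a
mean-rate ratio with a pooled two-sample Student's t-test (the cited
test; Welch is not used). No raw OD data are published, so the ~40%
decrease is validated as a simulation property (rate ratio 0.6, n = 4,
5% noise → estimate in [0.5, 0.7] and power ≥ 80%), not as a numeric
target.

## Synthetic cohorts

The generator emulates the study's statistical skeleton: 12 strata at
the reference cohort's frequencies, per-stratum disease odds ratios on
a logistic scale, and sex/age covariates (ages normal per status group,
defaults 65.8 y cases / 69.7 y controls, sd 8 — the reported cohort
profile; sd 8 is a typical late-onset T2DM cohort spread, chosen once).
Case-control sampling is the default mode, mirroring the design.
In population mode, status is Bernoulli with
logit = log(baseline odds) + log OR(stratum) + covariate terms, with
covariates centred at their generating means so the baseline odds is
interpretable at the cohort average. In case-control mode the stratum
is drawn from the Bayes-inverted status-conditional distribution with
covariates at baseline, and age/sex are then drawn per status group
independently of stratum; covariates are generated-but-ignored by the
counts-only analyses, which is exactly how they are used in testing.

Not emulated: linkage disequilibrium, haplotype structure, population
stratification, relatedness, genotyping error. Passing simulation tests
therefore demonstrates the estimators' statistical correctness under
the declared model, not robustness to those real-data complications.

`expand_counts` deterministically inflates a stratum count table into
an individual-level cohort (controls before cases within each stratum);
`stratify ∘ expand_counts` is the identity on any valid table, which is
how the published tables become the 1,477-record fixture cohort.

## Numerical choices and degenerate inputs

- Deviation ties and exceedance comparisons use a 1e-12 additive guard.
- The logistic mean is clipped to [1e-12, 1−1e-12] inside IRLS to keep
  the log-likelihood finite near separation.
- q-value sorting is stable (mergesort) so tie handling is
  deterministic.
- Empty cohorts, all-missing strata, all-zero table margins,
  non-binary statuses, impossible hypergeometric counts and
  non-increasing λ grids all raise `ValueError` with a message naming
  the offending input; unrecognised band patterns and unmapped
  haplogroups return missing values instead of raising, because a
  handful of failed calls must not abort cohort assembly.

## Problem sizes

The default verification suite runs the full 10,000-shuffle permutation
test on the 1,477-record cohort (sub-second), 200-replicate CI-coverage
simulations at n = 5,000, and a 500-cohort null-calibration study at
B = 2,000 with n = 500 — sizes chosen so the complete suite finishes in
well under a minute while keeping Monte-Carlo standard errors small
relative to every asserted tolerance.
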