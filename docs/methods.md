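# Methods

## Statistical model

### Expressed-gene filter

A gene is *expressed* when every library has at least one mapped read and
at least one library has ≥ 20 counts (both thresholds inclusive and
configurable). Removed genes are binned by the number of temperatures at
which all replicate libraries were nonzero, summarizing
temperature-specific expression. The filter is idempotent.

### TMM normalization

Between-library scaling follows the trimmed-mean-of-M-values procedure.
The reference library is the one whose 75th-percentile depth-normalized
count is closest to the across-library mean of those percentiles. For each
library k against the reference r, over genes with nonzero counts in both
(no pseudo-counts; log-ratios are undefined otherwise):

- M_g = log₂((y_gk/N_k)/(y_gr/N_r)), A_g = ½·log₂((y_gk/N_k)(y_gr/N_r));
- genes in the upper/lower 30% tail of M or 5% tail of A are discarded
  (rank-based, inclusive bounds — ties get average ranks);
- the scaling factor is 2^(Σ w_g M_g / Σ w_g) with precision weights
  w_g⁻¹ = (N_k − y_gk)/(N_k y_gk) + (N_r − y_gr)/(N_r y_gr), the
  delta-method binomial variance of M.

Factors are renormalized to geometric mean 1 so effective library sizes
(total count × factor) preserve the overall scale. The implementation
matches both an independently coded step-by-step transcription (to 1e-9)
and edgeR's `calcNormFactors(method="TMM")` on random matrices.
The idealized depth-equivariance property (scaling one library leaves
factors unchanged) holds to ~1% rather than exactly: the precision weights
depend weakly on depth.

### Reaction-norm GLM and model selection

Per gene, counts follow a negative binomial with log link,
log effective library size as offset, and variance μ + φμ² (NB2).
Temperature is a continuous covariate in °C; the printed
parameterizations e = E_a + g₁(t − T_a) and e = E_m + g₂(t − T_m)² are
over-parameterized (intercept and anchor trade off), so the identifiable
polynomial basis {1, T, T²} is fit and slope g₁ (log₂/°C), vertex
T_m = −b₁/(2b₂), curvature g₂ and vertex expression E_m are reported as
derived quantities. Temperature is centered at its mean internally for
conditioning and coefficients are back-transformed; reported coefficients
are on the log₂ counts-per-million scale.

All genes share the same design, so the three nested models are fit by a
batched IRLS (`thermonorm._nbglm`) — a few einsums and a batched p×p solve
per iteration for the whole matrix, with per-gene step-halving. This keeps
the Monte-Carlo experiments in the test suite (thousands of genes) at
seconds. statsmodels' NB GLM serves as an independent oracle in the tests
(coefficients and log-likelihoods agree to ≤1e-5 at fixed φ); it is never
the production path.

**Dispersion.** φ is estimated per gene by maximizing the NB likelihood at
the fitted means of the quadratic design with the Cox–Reid adjustment
−½ log det(XᵀWX), W = μ/(1+φμ), which removes the (n−p)/n downward bias of
the unadjusted profile (measured: φ̂ ≈ 0.042 vs true 0.05 without the
adjustment, φ̂ ≈ 0.050 with it, at n = 24, p = 3). Search is a vectorized
ternary search on log φ over [1e-8, 50], two passes (Poisson-start fit →
φ → NB refit → φ). If IRLS fails to converge the method-of-moments
estimate Σ((y−μ)²−μ)/Σμ² is used and flagged in the output.

**Likelihood-ratio tests.** Linear-vs-null tests temperature significance;
quadratic-vs-linear tests curvature; both at the shared per-gene φ, so the
statistics are non-negative by construction. With φ estimated from the
same 24 observations the one-df statistic is slightly inflated relative to
χ²(1) (null rejection ≈ 0.065 at nominal 0.05); p-values therefore use an
F(1, n − 3) reference, which restores calibration (≈ 0.053, inside the
binomial 99% band). χ²(1) is used only when the residual df is < 3.
P-values are Benjamini–Hochberg adjusted separately per test family
(pooling is available via `pooled_fdr=True`; the family structure is a
declared choice). The most complex model whose defining test reaches
q ≤ α = 0.05 is selected.

**Differential call.** q ≤ 0.05 on the selected model's test *and*
max/min fitted-mean ratio > 1.25. Fold change uses fitted per-temperature
means by default (robust to replicate noise); observed means are available
via `fold_change_on="observed"`.

### Classification and SOC

Non-differential genes are conserved (curvature "none"). Linear genes are
increasing/decreasing by the sign of the slope. For quadratic genes the
80% rule decides monotone versus interior-extremum shapes on the log₂
fitted means at the design temperatures: with Δ_end = |log₂ f(T_max) −
log₂ f(T_min)| and Δ_range = log₂ max f − log₂ min f, the gene is U
(b₂ > 0) or bell (b₂ < 0) when Δ_end < 0.8·Δ_range, otherwise
increasing/decreasing by the sign of f(T_max) − f(T_min). Log scale is
used because every other expression contrast in the pipeline is a
log-fold-change. Class labels are explicit strings; no Roman numerals.

SOC is the sum of |log₂ fold changes| of per-temperature averages of
TMM-normalized counts (mean by default, median available) between
consecutive temperatures ≤ 6 °C apart. The absolute-value convention makes
SOC non-negative (required by the fourth-root transform downstream),
additive over segments, scale-invariant, and zero exactly for flat genes;
the signed-to-absolute ratio is reported separately as a direction
diagnostic and is not used in linkage.

### Linking plasticity to the regulatory architecture

Only monotone (increasing/decreasing) genes with all five covariates
present enter linkage; U/bell genes are excluded because their expression
change is not a monotone function of temperature.

- **SOC model:** Gaussian GLM of SOC^(1/4) on TFs, microRNAs, UTR and
  first-intron lengths; backward AIC elimination over the five main
  effects, then the TFs:microRNAs interaction (the only interaction
  considered) is added if it lowers the AIC. Each term's R² share is the
  full-model explained deviance minus that of the model with the term and
  its interactions removed; shares are non-negative for nested reductions
  up to numerical tolerance.
- **LDA:** two-class discriminant on a simple random (unstratified) 60/40
  split with training-proportion priors; coefficients reported raw and
  standardized by training-set feature standard deviations; zero-variance
  features dropped with a warning; accuracy computed on the holdout only.
- **Random forest:** 500 trees on the same split design; holdout accuracy
  and permutation importances (10 repeats) on the held-out genes.

All split and forest seeds are recorded in the outputs.

### GO enrichment

Per-class over-representation uses the upper-tail hypergeometric
p = P(X ≥ b | N, B, n) against the expressed-gene background, with BH
q-values across the terms of a run and enrichment (b/n)/(B/N); the default
significance cut is q ≤ 1e-5 (inclusive). For U/bell genes ranked by the
magnitude of the quadratic coefficient (signed ranking available), the
minimum-hypergeometric statistic — the best tail probability over all
ranking cutoffs, attained just after a member gene — is evaluated against
a permutation null of uniformly placed member genes,
p = (1 + #{null ≤ observed})/(n_perm + 1), with null samples shared
between terms of equal size. The permutation p replaces the exact
dynamic-programming mHG p-value: it is simpler and directly verifiable by
brute force at toy scale. Exact tails come from a precomputed log-gamma
table, checked against `scipy.stats.hypergeom` and one-sided Fisher tests.
GO-hierarchy propagation is not performed; the annotation is taken as
given.

## Synthetic-data generator

The generator emulates the target experimental design: four developmental
temperatures (13, 18, 23, 29 °C), six replicate libraries per temperature
by default (two reciprocal crosses × three replicates pooled into one
analysis), NB counts, log-uniform library sizes in [5×10⁵, 2×10⁶], shared
dispersion φ = 0.05, and default class proportions equal to the observed
fly class table (1,667 : 1,403 : 1,947 : 1,892 : 1,538 : 818 : 730 over
9,995 genes).

Per-gene log₂ means are polynomials in temperature: conserved genes have
b₁ = b₂ = 0 exactly; linear genes draw |slope| uniform in
[0.5, 1]·`effect_size_g1` (default 0.1 log₂/°C); monotone quadratics place
their vertex just outside the temperature range; U/bell genes place it
between the two central temperatures (shrunk 10% inward so the 80% rule
holds with margin). All plastic genes are floored at a 1.5-fold noiseless
range (5% above the 1.25 call threshold), which makes noiseless
classification unambiguous — the generator's contract with the
classification tests.

Counts are NB draws with mean μ_gs = L_s · 2^(f_g(T_s)) / Z. The
normalizer Z is a *constant* (the across-library mean of the column sums
of 2^f): a per-library normalizer would cancel any trend shared by all
genes and make single-class parameter-recovery experiments ill-posed. The
nominal library sizes L_s are recorded in the sample sheet so recovery
experiments can use exact offsets. φ = 0 is a deterministic mode (rounded
means, no sampling). A composition-shift option spikes a fraction of genes
in the first library to exercise TMM's composition correction.

The architecture table draws TF/microRNA counts as Poisson with
direction-class means from the fly analysis (TFs 11.7 decreasing vs 18.2
increasing; microRNAs 11.6 vs 7.1), modulated on the log-rate scale by the
standardized true SOC (defaults: tf_effect = −0.3, mirna_effect = +0.3,
i.e. dynamic genes carry fewer TFs and more microRNAs). UTR/intron lengths
are log-normal with class-dependent means; the distributional family is a
modeling choice — no source distribution is available.

What the generator does **not** emulate: mean–dispersion trends and
empirical-Bayes-style information sharing across genes, gene–gene count
correlations, batch or lane effects, temperature-specific expression
(genes absent at some temperatures), and annotation realism. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artifact of real libraries.

## Numerical choices and degenerate inputs

- IRLS: damped start at (y + ȳ)/2, linear predictor clipped at ±30,
  per-gene step-halving (≤20), ridge 1e-10 on the normal equations,
  convergence at |Δll| ≤ 1e-10·(|ll|+1); genes whose fits never converge
  are reported as model "null" with `converged=False`.
- φ floored at 1e-8 and capped at 50; constant-count genes land in the
  floor region (the Cox–Reid term makes the objective non-monotone very
  close to the floor, so estimates may sit at ~1e-7 — operationally
  Poisson).
- TMM: libraries with all-zero counts are an error; a pair with no
  usable genes yields factor 1.
- SOC requires strictly positive per-temperature means (guaranteed for
  filtered genes).
- Ranked enrichment breaks score ties by gene id (stable sort).
- Empty targets, single-class labels, < 20 genes per class, singular
  linkage designs and invalid p-values raise errors rather than returning
  silently degraded results.

## Problem sizes and runtimes

The test suite simulates 300–5,000 genes per experiment and the
acceptance script 3,000 (plus dedicated 2,000-gene null-calibration and
500-gene recovery runs); the full suite runs in ~1.5 min and the
acceptance script in ~20 s on one CPU. These sizes give Monte-Carlo
standard errors comfortably inside every asserted tolerance; all
experiments scale linearly in genes and can be enlarged via
`SimulationConfig`.

## Known limitations

- Dispersion is estimated per gene with no shrinkage across genes; at
  6 replicates per temperature this is adequate for the simulated
  settings, but real data with 3 replicates would benefit from
  empirical-Bayes moderation.
- The F(1, n−3) reference is a pragmatic small-sample calibration, not an
  exact finite-sample distribution.
- The mHG permutation p-value has resolution 1/(n_permutations + 1);
  q-values below ~1e-4 require raising `n_permutations` beyond the
  default 10,000.
- LDA assumes homoscedastic Gaussian classes; the random forest is the
  robustness check, and on strongly nonlinear boundaries only the forest
  is reliable.
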