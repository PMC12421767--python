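# Methods

This note documents the statistical models behind `saltnet`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations. Notation: genes
are indexed by g, samples by i, metabolites by m; factors are *batch*,
*stress* (treatment: control/salt), *time* (unordered factor with a declared
baseline level) and *ecotype* (genotype).

## Differential temporal response (NB GLM)

Counts are modelled per gene as NB2: `K_gi ~ NB(mu_gi, alpha_g)` with
`Var = mu + alpha mu^2` and `log mu_gi = x_i' beta_g + log s_i`, where `s_i`
are median-of-ratios size factors (median over all-positive genes of
`count / geometric-mean reference`; a positive-count pseudo-reference is
available via a flag when no gene is positive everywhere). Factors are
dummy-coded against their first declared level, so the *stress* main effect
is the salt/control difference at the baseline time and the `stress:time_t`
coefficients are the genuinely time-varying part of the salt response.

* **SSET test.** Full model `batch + stress + time + stress:time` vs
  reduced `batch + stress + time`, both fitted by per-gene IRLS
  (log link, weights `mu/(1+alpha mu)`, ridge 1e-6 on the weighted
  cross-product, max 100 iterations, relative log-likelihood tolerance
  1e-8 — all configurable). The statistic `max(0, 2(l_full - l_red))` is
  referred to chi-square with df = rank(full) − rank(reduced) (robust to
  aliased levels). Default call threshold: BH-FDR < 0.01.
* **Dispersion.** One per-gene `alpha` estimated on the full design by
  maximising the Cox–Reid adjusted profile likelihood
  `l(alpha) - 0.5 log det(X'WX)` over `log alpha` in `[log 1e-8, log 30]`,
  then (by default) shrunk toward a fitted mean–dispersion trend
  `alpha(mu) = a0/mu + a1` (non-negative least squares with outlier
  trimming) using a log-normal prior. The prior variance is the
  trend-residual spread (MAD-based) minus the expected estimation noise
  `trigamma((n-p)/2)`, floored at 0.05; the floor is a numerical guard so
  the prior never collapses to zero width. The same `alpha` is reused in
  the reduced fit, the standard practice for nested NB tests. Genes with
  zero total count are excluded and reported.
* **DEAT test.** From the full fit, for each stress level and time t the
  contrast `c = stress + stress:time_t` is tested with a Wald statistic
  using the IRLS Fisher information; two-sided normal p-values are
  BH-adjusted per time level, and `fdr < 0.05 AND |log2FC| >= 1` flags a
  DEAT call. `log2FC = c'beta / ln 2`; coefficients are kept on the
  natural-log scale internally for IRLS stability. Both tests are meant to
  be run within one ecotype (`*_by_ecotype` helpers subset the samples
  first) rather than through a three-way design.

**Small-sample caveat.** At the default design scale (56 samples per
ecotype, 29 design columns) the NB LRT statistic is inflated by roughly
10% relative to its chi-square reference (mean ≈ 14.4 at df 13 at the exact
MLE), so the empirical type-I error at p < 0.05 is ≈ 0.06 even when the
true dispersion is supplied, and ≈ 0.07–0.08 with estimated dispersion.
This is a property of the plug-in NB likelihood-ratio test at this
parameter-to-sample ratio, not of the implementation (the widely used
reference framework for this test shows a larger inflation, ≈ 0.10, on the
same simulated data). Interpret borderline SSET p-values accordingly;
calls at FDR < 0.01 are driven by far smaller p-values and are essentially
unaffected, as the planted-effect recall study shows.

## Temporal ratio clustering

For each gene, ecotype and time point the response is summarised as
`mean log2(TPM+1 over salt samples) − mean log2(TPM+1 over control
samples)` (pseudocount and log base configurable); the ecotype profiles are
concatenated so each gene is one joint ratio vector. Agglomerative
clustering uses Euclidean distance and complete linkage by default (both
exposed), and clusters are the connected components of merges strictly
below a fixed cut height (default 14), labelled 1..k by first gene
occurrence. The tree can be exported as Newick.

## PLS-DA and VIP

The metabolite matrix (log intensities, samples × metabolites,
column-centred and by default unit-variance scaled) is regressed on the
centred one-hot coding of one factor (time, ecotype or stress) with NIPALS
PLS2 (scikit-learn backend; 3 components by default — the model is used
for variable ranking, not prediction, and VIP rankings are stable in 1–5
components). With unit-norm X-weights `w_a`, scores `t_a` and Y-loadings
`q_a`, the Y variance explained by component a is
`SSY_a = |t_a|^2 |q_a|^2` and

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ),

which satisfies `sum_j VIP_j^2 = p` exactly. Metabolites with
`VIP_stress > 1` are called salt-responsive; per-factor selections and
their intersections (Venn counts) are reported. PCA (SVD on the same
matrix, centred, scaling optional) provides the variance decomposition.

## LASSO decision algorithm

Per metabolite y (log intensity vector over samples):

1. **Prefilter.** Pearson correlation of every expressed gene
   (mean TPM ≥ 1; expression fed to the model as log2(TPM+1),
   configurable) with y; keep `r >= 0.5`. The signed rule is the
   algorithm's literal form; it discards negative regulators, which is a
   real loss of information, so an `absolute` flag is provided —
   the default remains signed.
2. **Resampling loop** (100 repeats): random 80/20 split;
   10-fold CV on the training 80% over the penalty grid
   `0.01, 0.02, ..., 1.00`; the one-SE rule picks the largest λ whose
   mean CV error is within one standard error (taken at the CV minimum)
   of the minimum, scanning the grid in descending order so ties resolve
   toward stronger regularisation; refit at the chosen λ and predict the
   held-out 20%; record the test-set Pearson r and the selected genes.
   Predictors are standardized and y centred with **training** statistics
   only (per CV fold inside CV, per training split for the final fit), and
   the model has no intercept. A repeat is invalid if the prediction is
   constant or non-finite; a metabolite with < 50% valid repeats is
   *non-converged* (there is no standard definition of a "converged"
   metabolite; this is the package's formalisation).
3. **Classification.** mean r > 0.8 (strict) ⇒ predictable;
   selection frequency > 0.5 (strict) ⇒ regulator; regulator edges over
   predictable (optionally also salt-responsive) metabolites form the
   network; degree ≥ 5 ⇒ hub gene.

The LASSO solver minimises `(1/2n)||y - X b||^2 + λ||b||_1` by cyclic
coordinate descent with soft-thresholding and covariance updates,
warm-started along the descending penalty grid with active-set inner
sweeps (convergence: max coefficient change < 1e-10; KKT conditions hold
to ~1e-7 or better, verified in tests against the orthonormal closed form
and an independent solver). A compiled (numba) kernel and an equivalent
pure-Python path exist; both are tested for agreement.

**Reproducibility.** One master seed; each metabolite gets an independent
substream via hashing its identifier into the seed sequence, so results do
not depend on processing order. Re-running the full pipeline with the same
seed reproduces every exported file byte-for-byte.

## Synthetic data

The generator emulates the assumed data model of all stages on a
2-ecotype × 2-treatment × 14-time-point × 2-replicate factorial
(112 samples; time labels mirror a 0 h–24 h + 4–18 days sampling grid):

* **Counts.** `log mu = baseline + batch + ecotype + stress +
  loading·module_profile(time) + idiosyncratic(time) [+ interaction] +
  library offset`; `K ~ NB(mu, alpha)` via gamma–Poisson (alpha = 0.2 by
  default; baseline ~ logN(log 200, 1)). Genes belong to co-expression
  modules of 4 sharing a latent temporal profile normalized to a fixed
  RMS amplitude (0.40 on the natural-log scale; loadings ~ N(1, 0.1),
  idiosyncratic per-time SD 0.25), giving within-module expression
  correlations around 0.2–0.25 — the generator's stand-in for
  co-regulated stress-response programmes. Homogeneous module amplitude
  keeps recovery benchmarks stable across seeds; real co-expression
  strength is more heterogeneous.
* **Interactions.** A configurable gene fraction (default 0.1) receives a
  stress:time effect of |log2FC| = 2 at all times from a random
  post-baseline onset (at least 3 affected times), with an independently
  drawn sign per time point. The sign draw keeps the planted signal
  genuinely time-varying: a constant same-sign shift is nearly collinear
  with the stress main effect and is not an interaction in any useful
  sense.
* **TPM** is computed from the realized counts (counts/library × 1e6), so
  expression estimates carry quantifier-like sampling noise; deriving TPM
  from the noiseless means would make co-expressed genes near-perfectly
  correlated and the network benchmark degenerate.
* **Metabolites.** y = Σ_j w_j z_j + ε with z_j the standardized
  log2(TPM+1) of k = 3 regulator genes drawn from one module (weights 1;
  a uniform-random regulator mode exists) and ε scaled so
  Var(signal)/Var(y) equals the target R² (default 0.9).

What passing the recovery benchmarks does **not** show: the generator has
no batch-specific metabolite drift, no missing values, no lipid-class
structure, no compositional artefacts beyond library-size scaling, and its
regulator sets are cleanly module-nested. Real candidate sets are larger
and messier; on real data the frequency and r thresholds control, but do
not eliminate, correlated false positives.

## Validation battery and problem sizes

`saltnet.benchmarks` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) uses desk-scale sizes chosen to finish in
minutes on one CPU: 2000 genes for null calibration, 2000 genes with 500
planted interactions for power, 200 orthonormal instances for the solver
check, 20 metabolites × 500 genes × 100 repeats (with a 50-permutation
null) for network recovery, 50-row fixtures against a brute-force O(n³)
agglomeration, 1000 random vectors against an independent BH step-up, and
a 250-gene end-to-end determinism run. The network benchmark sits close to
its own feasibility boundary (the PCC ≥ 0.5 prefilter admits correlated
decoys at nearly the same rate it retains true regulators), so its edge
precision hovers in 0.80–0.91 across seeds.

## Known limitations

* NB LRT small-sample inflation as described above; no Bartlett-type
  correction is applied because the statistic and reference distribution
  are part of the method's definition.
* No independent filtering, fold-change shrinkage, or outlier replacement
  in the differential-expression stage.
* PLS-DA component count is fixed rather than cross-validated by default.
* The decision algorithm's "converged" notion is formalised here as
  ≥ 50% valid repeats; other readings are possible.
* Edges are undirected associations; no causal orientation is implied.
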