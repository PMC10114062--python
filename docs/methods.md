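# Methods

This note records the statistical models implemented by `mrscreen`, the
choices made where the literature leaves room, and what the synthetic-data
validation does and does not establish.

## Two-sample MR model

All estimators consume per-variant summary associations
(b_Xj, se_Xj, b_Yj, se_Yj) for L instruments, harmonized to a common effect
allele, with exposure and outcome estimated in non-overlapping samples (so
their sampling errors are independent).  The target is the causal effect of
one SD (continuous) or one log-odds unit (binary) of the exposure on the
outcome scale.

**IVW, multiplicative random effects.**  Weighted regression of b_Y on b_X
through the origin with weights 1/se_Y².  Cochran's Q on L−1 df measures
over-dispersion; the fixed-effects SE is scaled by max(1, √(Q/df)).  The
floor means the random-effects model never reports more certainty than the
fixed-effects model; a pure multiplicative scaling (no floor) is available
via `se_floor=False`.  p-values use the normal reference distribution by
default; Student t via `use_t=True`.  Both are conventions, not
derivations, and they match the dominant practice in two-sample MR
software.

**MR-Egger.**  The same weighted regression with a free intercept, after
orienting all instruments to b_X > 0 (the intercept — average directional
pleiotropy — is only defined relative to a fixed orientation).  The NOME
diagnostic I²GX = max(0, (Q_GX − (L−1))/Q_GX) uses the precision-weighted
dispersion Q_GX = Σ(b_Xj − b̄_w)²/se²_Xj with b̄_w the 1/se²_X-weighted
mean.  The weighting of Q_GX is a genuine open point; the unweighted
variant can be obtained by passing constant se_X.  Gates: I²GX > 0.9 — use
Egger as is; 0.6 < I²GX ≤ 0.9 — correct by SIMEX; I²GX ≤ 0.6 — disregard
the Egger family.

**SIMEX.**  For each λ in {0, 0.5, 1, 1.5, 2}, noise N(0, λ·se²_Xj) is
added to the (already oriented) exposure effects B times (default 1000),
the Egger slope is refit (the perturbation is never re-oriented: flipping
signs conditional on perturbed values would bias the added error), the
B-averaged slopes are fit by a quadratic in λ and extrapolated to λ = −1.
The SE combines a jackknife over simulation batches (default 20) with the
naive Egger sampling variance.  Quadratic extrapolation of the underlying
hyperbola undershoots slightly; this residual attenuation is visible in the
validation study and is the price of the standard quadratic choice.

**Weighted median.**  Per-variant ratios b_Y/b_X with first-order delta SEs
se_Y/|b_X|; the estimate interpolates the inverse-variance-weighted
empirical CDF at 1/2 (cumulative midpoints sⱼ = Σ_{k≤j}w_k − w_j/2).
Consistent when ≥50% of the weight comes from valid instruments.

**Weighted mode.**  Weighted normal-kernel density over the ratios;
bandwidth = `bandwidth_factor` × 0.9·min(sd_w, 1.4826·mad_w)·L^(−1/5) on the
weighted data (modified Silverman; factor defaults to 1).  The maximizer is
located by evaluating the density at the data points and refining on a
local grid around the best point.  A single uniform grid over the full
ratio range is *not* used: when outlier ratios stretch the range, the grid
spacing can exceed the bandwidth and the argmax can land on an isolated
low-weight kernel — a pure discretization artifact that showed up as rare
wild estimates in early validation runs.  SEs for median and mode come from
a parametric bootstrap (resampling b_X, b_Y from their sampling normals,
default B = 1000, explicit seed); `boot_B=0` returns the point estimate
alone.

**MR-PRESSO.**  The observed statistic is RSS = Σⱼ wⱼ(b_Yj − β̂₍₋ⱼ₎b_Xj)²
with β̂₍₋ⱼ₎ the leave-one-out IVW estimate.  The null is simulated by
redrawing b*_X ~ N(b_X, se_X) and b*_Y ~ N(β̂₍₋ⱼ₎b_X, se_Y); p-values use
the add-one estimator (never exactly zero, floor 1/(n_sim+1)).  Per-SNP
outlier p-values are Bonferroni-adjusted over L; flagged SNPs are removed
and IVW refit.  The distortion note reports how far the corrected estimate
moved; no formal distortion p-value is computed.  Simulation draws come
from per-variant streams keyed by variant id, so the p-value is invariant
to instrument order.

**Steiger filtering.**  An instrument is kept iff it explains strictly more
variance in the exposure than in the outcome.  "Substantially more" is
implemented as the strict inequality; an explicit directionality test is
deliberately not imposed by default (the strict rule matches common
practice; the comparison already normalizes for the two sample sizes
through the variance-explained scale).  Variance explained: continuous
traits t²/(t²+n−2); binary traits via the liability conversion below.

**Liability-scale variance explained.**  A per-allele log odds ratio b with
effect-allele frequency p in a sample with case proportion P is first
mapped to the observed (0/1 regression) scale by the logistic-derivative
approximation R²_obs = 2p(1−p)·b²·P(1−P), then to the latent liability
scale by the ascertainment transformation R²_l = C·R²_obs/(1 + C·θ·R²_obs)
with C = K²(1−K)²/(z²P(1−P)), θ = d(d−t), d = (z/K)(P−K)/(K(1−K)), where K
is the population prevalence, t the liability threshold Φ⁻¹(1−K) and z the
normal density at t.  When no population prevalence is supplied the case
proportion is used and logged — this biases the conversion for strongly
ascertained studies and should be overridden when K is known.  The
transformation saturates at R²_l = 1/θ under strong ascertainment; the
synthetic binary-margin generator inverts the same map and clamps below
that ceiling, which makes the generate-then-convert round trip exact by
construction in the small-effect regime.

**F statistics.**  Per-SNP F = (b_X/se_X)²; the aggregate
F = ((n−L−1)/L)·R²/(1−R²) with R² the summed per-SNP variance explained.
Both are reported because the literature is ambiguous about which single
number "the" F statistic denotes; the decision rules use the mean per-SNP F
against the >10 rule of thumb, for continuous exposures only.

## Instrument selection

Greedy clumping ranks candidates by ascending p (ties broken by variant id
for determinism) and accepts a candidate iff its r² with every
already-accepted variant within the window is below the threshold
(r² < 0.001, 10 000 kb, P < 5×10⁻⁸ for instruments; r² < 0.01, 250 kb,
P < 10⁻³ for the model-comparison variant set).  Without an LD reference
only the distance rule applies, with a warning.  Variants genome-wide
significant in both traits are removed.  Proxy substitution: a missing
instrument is replaced by the highest-r² (≥0.8) variant present in the
outcome.  Because the LD reference carries r² only, the allele phase
between original and proxy is unknowable; the substituted instrument
therefore uses the proxy's own harmonized exposure and outcome effects (and
records `proxy_of`), rather than splicing the proxy's outcome effect onto
the original's exposure effect.

Harmonization handles direct matches, effect/other swaps (sign flip, eaf
complement) and strand complements.  Palindromic variants (A/T, C/G) are
kept only when both frequencies are present and informative (MAF below
0.42, configurable) and orientation is inferred from frequency agreement;
otherwise they are dropped.  The consistency check between p and |b/se| is
warn-only: public summary statistics routinely carry rounded p-values.

## Sharing-vs-causal model comparison

Per variant, with probability q the variant acts through a shared heritable
factor and E[b_Y] = (γ+η)β_X; otherwise E[b_Y] = γβ_X.  β_X is marginalized
over a zero-mean K-component normal mixture (K = 5 with a fixed point mass
at zero) fitted to the selected exposure effects by generalized EM
deconvolution: weights by the standard E/M steps, free component sds by
bounded one-dimensional likelihood maximization, so the marginal likelihood
is non-decreasing.  Conditional on (γ, η, q) each variant's likelihood is
an analytic bivariate normal mixture, so the joint posterior is computed on
a grid: γ on 40 points centered at an IVW anchor (half-width 8 anchor-SEs,
clipped to [0.25, 4σ_prior] — the clip makes the no-information limit
return the prior instead of a degenerate grid), η on 40 points over ±3
prior sds, q on 30 points in (0,1).  Priors: γ, η ~ N(0, 0.6²),
q ~ Beta(1, 10).  If more than 1% of posterior mass lands in the outermost
grid cells the axis is doubled once; a second failure raises.

Models are scored by in-sample log pointwise predictive densities:
lppdⱼ = log Σ_points posterior × p(bⱼ | point).  ΔELPD = Σⱼ(lppd_sharing,ⱼ −
lppd_causal,ⱼ), SE = √L·sd of the per-variant differences, z = Δ/SE, and
the one-sided p is the lower normal tail — negative Δ favors the causal
model, matching the reporting convention of the screening literature.
This is a deliberate simplification of the reference CAUSE machinery
(which uses Pareto-smoothed importance-sampling LOO and MCMC/adaptive
quadrature): the grid fit is deterministic and runs in well under a second
per pair, and its validity here is established by calibration — on
causal simulations the comparison detects the effect, on pure
correlated-pleiotropy simulations it stays quiet while IVW rejects — not
by bit-compatibility with the reference implementation.

## Decision rules

Evidence for a causal relationship requires (i) IVW FDR p < 0.05 (BH over
the pooled set of all IVW tests in the screen; per-direction pooling is a
config switch); (ii) the weighted median, weighted mode, outlier-corrected
MR-PRESSO and Steiger-filtered IVW all agreeing in sign with IVW at
p < 0.05, plus — only when the Egger intercept itself signals pleiotropy
(p < 0.05) — agreement of MR-Egger (I²GX > 0.9) or SIMEX-Egger
(0.6 < I²GX ≤ 0.9); when I²GX ≤ 0.6 with intercept evidence of pleiotropy
the Egger family is unusable and the pair conservatively fails this
criterion (a lenient mode skips it instead — the corner is genuinely
undefined by the rules as stated); (iii) mean F > 10 for continuous
exposures.  The model comparison runs only for directions passing (i)–(iii)
and is Bonferroni-corrected over the number of comparisons actually run —
the divisor is computed from the gate, never hard-coded.  Class chain:
none → mr_main → mr_sensitivity → cause_confirmed, structurally monotone.

## Synthetic data

The generator draws per-variant MAF ~ U(0.05, 0.5), true exposure effects
from the configured mixture (default a single N(0, 0.05²) — strong,
instrument-grade effects at the default n = 100 000), assigns shared-factor
membership Z ~ Bern(q) and uncorrelated pleiotropy θ with probability
pi_uncorr, and composes β_Y = γβ_X + ηZβ_X + θ (+ reverse components).
Reverse variants draw their primary effect on the outcome and expose only a
damped echo (β_X = reverse_effect·β_Y).  Observed effects add independent
noise with the asymptotic SE 1/√(2·maf(1−maf)·n) for standardized
continuous traits, inflated by 1/√(P(1−P)) on the log-OR scale.  A
configurable fraction of outcome rows is emitted allele-swapped (default
20%) and palindromic (default 0) so harmonization is exercised end to end.
LD blocks, when configured, emit a pairwise r² table with block members 2 kb
apart and blocks 1 Mb apart.  All randomness flows from a single seed
through per-variant Philox streams keyed by variant id: outputs are
byte-identical across runs and row orders, and the first L variants of a
larger panel reproduce the smaller panel exactly.

What this emulates — the exact sampling model the estimators assume
(independent normal errors, known SEs, independent variants, two-sample
independence).  What it does not — realistic LD beyond rectangular blocks,
allele-frequency-dependent architectures, sample overlap (a knob exists but
defaults to independence), population stratification, dynastic effects, or
misreported/rounded summary statistics.  Passing the validation suite
therefore shows the machinery is correct and calibrated under its own
assumptions; it does not certify robustness to violations real GWAS data
can exhibit.

## Validation study conditions

Chosen once as the package's standard desk-scale conditions (each study a
few minutes on one CPU):

* **Null calibration** — 2000 pairs, L = 50, n = 100 000, γ = η = 0: IVW
  rejection at 5% within the 99% binomial margin; MR-PRESSO global p
  uniform by KS.  The SE floor makes the test mildly conservative (measured
  rates sit around 4.3–5.0%), which the margin accommodates.
* **Recovery** — 500 pairs, γ = 0.3, L = 100, n = 200 000: mean bias of
  IVW, weighted median, weighted mode and the causal-model posterior median
  all below 0.02 (measured ≤ 0.004).
* **False-positive avoidance** — 100 pairs, γ = 0, η = 0.3, q = 0.3:
  IVW calls ≥80% of replicates significant (measured 99%) while the model
  comparison calls ≤10% (measured 1%).
* **Steiger efficacy** — the reverse-causation fixture plants 30% reverse
  variants with outcome-GWAS-grade primary effects (sd 0.08) and a 0.6
  echo, so reverse SNPs genuinely reach instrument significance.
  Instruments are selected on the exposure p-value alone here: with equal
  sample sizes the shared-significance rule would remove every reverse SNP
  before Steiger could act, and the study isolates what the directionality
  filter itself achieves.  Measured: 100% of planted reverse instruments
  removed, IVW bias 0.28 → 0.001.
* **SIMEX benefit** — 200 replicates, L = 50, true slope 0.5, exposure
  effects U(0.05, 0.25) with se_X = 0.04 (realized I²GX ≈ 0.7, bounded away
  from zero so orientation never flips); replicates gated on realized
  0.6 < I²GX ≤ 0.9 exactly as the pipeline gates them.  SIMEX beats the
  naive slope in ≈93–95% of gated replicates.

## Known limitations

* Generalized (correlated-instrument) IVW is out of scope; clumped
  instruments are treated as independent.
* The ELPD comparison is in-sample; with very small variant sets the
  causal model's extra parameter gives it a slight systematic edge that the
  SE over variants must absorb.  Calibration at the standard conditions is
  demonstrated; behaviour at L < ~30 selected variants is untested.
* Proxy substitution assumes the proxy's own associations are exchangeable
  with the missing instrument's; with r²-only LD input nothing better is
  identifiable.
* The liability conversion is a small-effect approximation and uses the
  sample case proportion when prevalence is unknown.
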