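# Methods

## Problem and data model

The package analyzes binned 1D ¹H-NMR plasma profiles from a two-group
case–control design (T1DM children vs matched controls, n = 7 per group in
the motivating study). A spectrum enters as a two-column text file
(chemical shift in ppm, intensity in arbitrary units) and is reduced to a
K-vector of region integrals by trapezoidal integration over a fixed region
scheme; all downstream statistics operate on the N × K profile matrix.

**Region scheme.** A region is a closed ppm interval with an assignment
label and a glucose flag. Tables are validated on load: positive unique
variable ids, upper bound strictly above lower bound, no overlaps (regions
may share a single boundary point — both trapezoids then include that
abscissa, which is exact, not double counting, for integrals). The packaged
default has 110 regions spanning 0.80–8.60 ppm, excluding the 4.50–5.00 ppm
water band, with 15 glucose-flagged regions. Only 17 of the 110 boundaries
(and 8 of the 15 glucose flags) come from published tables; the other 93
regions are contiguous equal-width *synthetic fillers*, with 7 filler
glucose flags placed inside the glucose envelopes near 5.23, 3.96–4.00 and
3.20–3.40 ppm. The fillers make the 110/95-variable bookkeeping executable
but carry no measured meaning; custom schemes can be supplied as CSV.

**Integration rule.** Per region, the trapezoidal integral of intensity
over ppm with both endpoints included by linear interpolation at the exact
bounds. This is linear in the spectrum, invariant to the storage direction
of the ppm axis, exact for piecewise-linear spectra (hence grid-refinement
stable), and bit-reproducible. No rectangle-sum mode is offered. No
normalization (total-area or reference-peak) is applied by default: the
integrals are treated as relative concentrations acquired under a fixed
protocol. Partially covered regions are an error, not a silent truncation.

## Synthetic-data generator

The generator exists so every pipeline stage is testable without access to
clinical spectra; its defaults *are* the study conditions.

* **Effect template.** One row per variable: arithmetic mean ± SD per
  group. The default template carries the 17 published case/control
  summaries verbatim (glucose regions up ~23–68% in cases, lipids down
  ~17–36%, serine/tryptophan/cysteine down ~25–64%) and null effects
  (case ≡ control) for the 93 filler variables, whose baseline means are
  drawn once from log-uniform(0.5, 50) with SD = 15% of the mean, under a
  fixed internal seed so the template is a reproducible constant.
* **Marginals.** Integrals are drawn log-normally: on the log scale a
  multivariate normal with parameters moment-matched so the *arithmetic*
  mean and SD equal the template exactly (σ² = ln(1+cv²), μ = ln m − σ²/2).
  Log-normality guarantees positivity and the right skew typical of plasma
  NMR intensities, and keeps the template directly comparable to published
  group-summary tables.
* **Correlation.** Optional disjoint variable blocks share a common
  log-scale correlation ρ ∈ [0, 0.95] (defaults: all glucose regions at
  ρ = 0.8, the five lipid regions at ρ = 0.6), imposed through the Cholesky
  factor of the block correlation matrix. The ρ values are plausible
  "multiple bins per metabolite" defaults, not estimates from data.
* **Determinism.** One seed is split by purpose (case draws, control draws,
  row shuffle) via `SeedSequence.spawn`, so regeneration is bit-identical
  and adding spectral noise never perturbs group draws. Class coding is
  control = +1, case = −1 throughout, so discriminating variables that are
  *elevated* in cases (glucose) carry negative p(corr)[1].
* **Spectra.** Each region's integral is rendered as one Lorentzian peak
  centered mid-region with half-width 20% of the region width, *truncated
  at the region bounds* with its edge value subtracted (the peak goes
  continuously to zero at the boundary) and scaled so its within-region
  trapezoidal integral equals the profile value. Truncation is deliberate:
  untruncated Lorentzian tails at this half-width would deposit ~10% of a
  peak's mass in adjacent contiguous regions, destroying the designed
  round-trip identity; inter-region peak overlap is exactly the
  spectroscopic effect the generator does not model. White Gaussian noise
  is added at a configurable peak-amplitude/noise SNR (None = noise-free).

What passing tests on these data do **not** show: robustness to chemical
shift drift, baseline distortion, peak overlap between metabolites,
non-log-normal heavy tails, or real biological covariance structure — the
generator targets the binned-variable statistical structure only.

## Preprocessing

Column means μⱼ and sample SDs sⱼ (n−1 denominator, matching the t-test
convention) are fitted once on a training matrix and stored, so the
identical transform applies to held-out folds. Pareto mode computes
(x−μⱼ)/√sⱼ; "none" centers only. Constant columns are rejected by name
(the Pareto divisor degenerates). Inside cross-validation the scaling is
refitted on each training fold by default (`rescale_per_fold`), the
conservative, leakage-free choice; the global-scaling convention of some
commercial tools is available behind the flag.

## PCA quality control

NIPALS with deflation (score-change tolerance 1e-12, up to 10 000
iterations — iid-noise matrices routinely have eigenvalue gaps too small
for a few hundred power iterations; non-convergence raises an error naming
the component). The start score is the column with the largest variance;
each loading's largest-magnitude element is forced positive so results are
platform-reproducible. Default A = 2 components for QC, matching the
two-dimensional score plot convention; R²X per component is tᵀt/‖X‖²_F.

Hotelling's T² per sample is Σₐ t²ₐ/var(tₐ) with limit
A(N²−1)/(N(N−A))·F₁₋α(A, N−A), α = 0.05 by default. DModX is
(sᵢ/s₀)·√(N/(N−A−1)) with sᵢ the per-sample residual SD over K−A degrees of
freedom, s₀ the pooled residual SD over (N−A−1)(K−A), and limit
√F₁₋α(K−A, (N−A−1)(K−A)); the √(N/(N−A−1)) factor compensates the deflation
of in-model residuals. Both flag rates calibrate to α within ±0.01 on
homogeneous Gaussian data at moderate N (the acceptance script measures
this at N = 200, K = 20). A numerically perfect fit (total residual sum of
squares ≤ 1e-16·‖X‖²_F) reports DModX ≡ 0 rather than a 0/0 ratio. DModX
highlights samples that do not fit the model plane; a sample so extreme
that it *captures* the principal components will instead surface in T².

## OPLS-DA

Single-response OPLS: the predictive weight is w ∝ Xᵀy_c from the
undeflated scaled matrix, fixed thereafter. Each of the A_o orthogonal
components takes the current loading p = Xᵀt/(tᵀt), removes the predictive
direction (w_o ∝ p − (wᵀp)w), and deflates X by t_o p_oᵀ. The predictive
score t_pred = X_deflated·w, y-loading q = y_cᵀt_pred/(t_predᵀt_pred).
R²Y(cum) = 1 − ‖y_c − t_pred q‖²/‖y_c‖²; R²X(cum) sums the Frobenius
fractions of predictive and orthogonal components. Default A_o = 1
(one predictive + one orthogonal component), configurable. New samples are
scored by applying the stored scaling, sequentially removing orthogonal
variation, then projecting on w; the class label is the sign of
ŷ = t·q + ȳ_train.

**Cross-validation.** Stratified round-robin fold assignment (per class,
seed-permuted, dealt cyclically so fold sizes differ by at most one and,
at n = 7 + 7 with 7 folds, every fold holds one case and one control).
Per fold: refit scaling on the training rows, refit the full model, predict
the held-out rows; Q²(cum) = 1 − PRESS/SS with SS the centered total sum of
squares of y computed once on all samples. A fold layout that strips a
class from some training set is an error suggesting fewer folds.

**S-line statistics.** p(ctr)ⱼ = cov(t_pred, xⱼ) (n−1 denominator) and
p(corr)ⱼ = p(ctr)ⱼ/(sd(t_pred)·sd(xⱼ)), both against the Pareto-scaled
variables — the model's working space — as recorded in every output table.

**VIP.** Default "predictive" mode: VIPⱼ = √K·|wⱼ|, so importance reflects
only the class-predictive direction and mean(VIP²) = 1 exactly. A "total"
mode additionally weights orthogonal weight vectors by their explained
X-variation (the same identity holds since all weight vectors are unit
norm). The mode used is recorded in the output metadata. cvSE is the
jack-knife SE over the G cross-validation submodels:
√(((G−1)/G)·Σ_g(VIP⁽ᵍ⁾ⱼ − V̄IPⱼ)²); whether a published "± cvSE" is a
jack-knife SE or a plain SD across rounds is not generally recoverable, so
the formula is fixed as above to be testable.

**Sign conventions.** Flipping the class coding negates w, t_pred, p_pred,
p(ctr) and p(corr) but leaves q (both factors of y_cᵀt flip), R²Y, Q² and
VIP unchanged — so ŷ flips with y, as it must.

## Univariate testing and selection

Pooled-variance Student t (Welch behind a flag), df = n₁+n₂−2, two-sided;
equal group sizes make pooled the natural reading and the summary-statistic
mode (`ttest_summary`, computed from means/SDs/n) exactly equivalent to the
raw-data mode. Benjamini–Hochberg step-up adjustment is applied across all
K variables of the active model (110 or 95). %-change is
100·(mean_case − mean_control)/mean_control, reported to one decimal.
The selection verdict is the conjunction p_adj < α ∧ |p(corr)| > 0.6 ∧
VIP > 0.5 with α = 0.05 by default (the univariate significance level is a
package default, recorded in output); it is monotone in all three
thresholds.

## Pipeline

Fixed stage order: ingest (matrix + metadata, or spectra directory) →
scale → PCA QC → full-profile OPLS-DA → glucose-excluded refit → univariate
tests → selection → report. Missing values are rejected, never imputed.
The glucose-excluded branch is audited: a glucose-flagged column reaching
it is a hard error. Figures are rendered from the exported CSV tables, not
from in-memory state, so plots are reproducible from artifacts alone.
Identical config + seed reproduces every table byte for byte.

## Calibration properties and known limitations

The acceptance script measures, per seed sweep of 100 regenerated cohorts
at n = 7 + 7: the effect-template Q² positive rate and p(corr) sign
agreement (≈100%), the null-template false-selection count (≈0.04 variables
of 110), the outlier-flag rates (≈0.045–0.05 at α = 0.05), and the
noise-free spectra round-trip error (<1%).

One calibration property deserves emphasis: under the all-null template the
sevenfold-CV Q² is *non-positive in only ≈72–76% of seeds*. At N = 14,
K = 110 the null Q² distribution is wide (roughly mean −0.4, SD 0.35,
right-skewed), so a noticeable minority of null datasets shows Q² slightly
above zero; class-stratified folds, by balancing every held-out pair,
remove the intercept penalty that unstratified assignment would add and
make null Q² *less* negative (unstratified assignment raises the
non-positive rate to ≈85%, still far from certainty). The per-dataset Q²
values were cross-checked against an independent PLS implementation
(mixOmics, R) on identical data and agree closely. The practical
consequence is the usual one for tiny cohorts: a mildly positive Q² alone
is weak evidence; judge models by the joint pattern of Q², the selection
table and, where possible, held-out prediction.

Other limitations: two classes only (no multi-class or O2PLS variants); no
permutation p-values for model statistics; no spectral preprocessing
(phasing, baseline, alignment) — inputs are assumed processed; JCAMP-DX
input is not supported (two-column text only); and the 93 filler regions
of the default scheme are stand-ins, so analyses of real spectra should
supply the laboratory's own region table.
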