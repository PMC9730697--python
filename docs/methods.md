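# Methods

## Model

Binary responses follow the three-parameter normal ogive (3PNO):
P(U_ij = 1 | θ_i) = c_j + (1 − c_j) Φ(a_j θ_i + b_j), with discrimination
a_j > 0, intercept b_j (note: intercept parameterization a·θ + b, not the
difficulty form a(θ − b)), and guessing c_j ∈ (0, 1). Responses are locally
independent given θ.

The latent density is a Ramsay curve on a fixed equidistant grid of
Q = 121 points on [−6, 6] (step 0.1): g(x_q | η) ∝ exp(B*_q η), normalized
over the grid in log space. B* is the Q × m matrix of B-spline basis
functions with `knots` evenly spaced breakpoints on [−6, 6] (both endpoints
included, boundary knots repeated degree+1 times), so m = degree + knots − 1.
The basis is a partition of unity; consequently a constant shift of η leaves
g unchanged, and fitted η vectors are re-centered to mean zero.

Priors: (a_j, b_j) bivariate normal truncated to a_j > 0, or flat
(the default, matching the benchmark's non-informative choice);
c_j ~ Beta(α, β) with default (5, 17), mean 0.227 — the conventional prior
for four-option multiple choice; η ~ MVN(μ_η, Σ_η), default μ_η = 0,
Σ_η = τ²I with τ = 10.

## Estimation: SAEM with probit augmentation

Augmented variables per response: W_ij = 1 if examinee i "knows" item j
(answers correctly with certainty; otherwise guesses correctly with
probability c_j), and Z_ij ~ N(a_j θ_i + b_j, 1) with W_ij = I(Z_ij > 0).
Marginalizing (W, Z) returns the 3PNO curve exactly. Given augmented data
the complete-data likelihood is exponential-family with per-item sufficient
statistics S_j1 = S*'S* (S* = (Θ, 1)), S_j2 = S*'z_j, S_j3 = #{w_ij = 0},
S_j4 = #{w_ij = 0, u_ij = 1}.

Each iteration k:

1. **S1** — sample θ_i from the categorical grid posterior ∝ likelihood ×
   g; **S2** — sample w (w = 0 where u = 0, else Bernoulli of
   Φ/(c + (1−c)Φ)); **S3** — sample z from one-sided truncated normals by
   inverse CDF (`ndtri`; no rejection loops, probabilities clipped to keep
   the quantile finite).
2. **SA** — mix sufficient statistics: S ← S + γ_k (S_draw − S), with
   γ_k = 1 for k ≤ 1000 and 1/(k − 1000) after. One augmented set per
   iteration (m_k = 1).
3. **M1** — conjugate updates: (â, b̂) = (S1 + Σ⁻¹)⁻¹(S2 + Σ⁻¹μ) (OLS of z
   on (θ, 1) under the flat prior), with a floor â = δ = 1e-3 if the slope
   is non-positive; ĉ from the Beta(α + S4, β + S3 − S4) posterior —
   **posterior mean** by default (see design notes), mode available.
4. **M2** (rc mode) — Newton–Raphson MAP fit of η to the SA-smoothed grid
   counts of the sampled abilities (step-halving to force ascent, ridge on
   a non-PD negated Hessian, inner tolerance 1e-6, cap 50, warm-started).

Stopping: max absolute parameter change (a, b, c, and η in rc mode) below
1e-4, checked only after the burn-in phase (under γ = 1 the single-draw
updates cannot meet it), or 2500 iterations. In practice the benchmark fits
use the full 2500 iterations. In `normal` mode the density is fixed at the
discretized standard normal and M2 is skipped — this is the comparison
estimator that assumes normality.

All S-steps are vectorized (likelihood tables as two N×J by J×Q matrix
products; categorical sampling by row-wise cumulative sums); a 2500-iteration
fit at N = 1000, J = 30 takes ≈ 15 s on one CPU core.

### Latent-scale identification

The free density makes the affine scale of θ unidentified (a·θ + b is
invariant under θ → (θ−μ)/σ, a → aσ, b → b + aμ). Two schemes were
evaluated and rejected: transforming the items each iteration by the fitted
density's moments compounds geometrically (the smoothed-count sd is sticky
near, but not at, 1 post burn-in, and multiplying a by it every iteration
diverges), and the fitted-density moments themselves carry the prior's tail
bias. The implemented scheme standardizes **each sampled ability vector**
to mean 0/sd 1 before it enters w, z, the sufficient statistics, and the
grid counts (indices snapped back to the nearest grid point). This pins the
scale with zero-mean noise that the SA smoothing averages out, and mirrors
the generator, which standardizes the true abilities the same way. A single
exact standardization of (items, density) is applied after the loop; it is
a sub-1% correction.

### Density smoothing during burn-in

The stochastic-approximation schedule applies to the item statistics
exactly as stated above. For the M2 grid counts, using the raw single draw
during the γ = 1 phase lets the fitted density chase tail noise: an
occasional extreme ability draw creates a fat-tail/peaked-center state that
is self-sustaining (fat tails attract further tail draws) and is then
frozen by the rapidly decaying post-burn gain. The grid counts are
therefore smoothed with a fixed moving-average gain of 0.02 during burn-in
(≈ 50-draw memory) and revert to γ_k afterwards. 0.005 was too sticky (the
density cannot track the data, biasing intercepts), 0.05 comparable to
0.02.

### Guessing estimator

The Beta posterior mode under-shoots: the prior's mode (0.200) sits below
its mean (0.227), and because the generating distribution of c equals the
prior, the mode's systematic downward shift propagates into a +0.03–0.06
intercept bias through the guessing–intercept trade-off on easy items
(per-item correlation of b and c errors ≈ −0.44). The posterior mean is the
Bayes estimator under this self-consistent prior and removes the effect;
it is the default, with the mode available via `SAEMConfig(c_estimator="mode")`.

## Synthetic truth

- **Study-1 style densities**: two-component normal mixtures discretized on
  the grid. The mixing weight is solved by Brent root-finding on the
  closed-form mixture skewness (targets 2.46 skewed, 1.45 bimodal); the
  resulting analytic kurtoses (8.91, 3.63) are reported as diagnostics.
- **Study-2 style densities**: Ramsay curves. Normal shape: ridge
  least-squares fit of the log discretized N(0, 1) followed by a MAP polish
  with pseudo-counts (the polish supplies the normalization coupling that a
  plain log-space regression lacks; without it, empty tail regions drift to
  the ridge shrinkage point and acquire spurious mass). Skewed and bimodal
  shapes: least squares on the four moment residuals
  (mean 0, sd 1, skewness/kurtosis targets (1.72, 9.16) and (0.95, 2.74)),
  started from the log-density of a moment-matched two-normal mixture with
  component sds bounded below at 0.4 — the start fixes the qualitative
  shape, since the moment conditions alone are satisfied by many densities,
  some of them spiky and numerically extreme.
- **Abilities**: i.i.d. grid sampling from the mass vector, then affine
  standardization of the sample to mean 0/sd 1.
- **Items**: a ~ U(1, 2.5), b ~ N(0, 1), c ~ Beta(5, 17), redrawn
  independently every replication. **Responses**: Bernoulli from the 3PNO.

What the generator does *not* emulate: missing responses, polytomous items,
multidimensional traits, local dependence, or item-parameter drift. Passing
recovery tests therefore speak to the estimator under the model, not to
robustness against model violations.

## Evaluation

AIC = −2 log L + 2n (a literal variant −2 log L + log N is available as
`aic_as_printed` for comparison only — it carries no complexity penalty),
BIC = −2 log L + n log N, HQIC = −2 log L + 2n log log N, with log L the
grid-marginalized likelihood at the final estimates and
n = 3J + (m − 1) in rc mode (one spline coefficient is absorbed by the
normalization) or 3J in normal mode. Bias and RMSE are averaged across
items, with per-item RMSE taken across replications. ISE between mass
vectors is computed on density heights (mass/step), Riemann-summed, and
multiplied by 1000; it is nonnegative by construction.

The benchmark replication layouts: 3 density shapes × 10 (knots, degree)
combinations at N = 1000, J = 30 (30 conditions), and 3 Ramsay shapes ×
N ∈ {500, 1000, 2000} × J ∈ {15, 30} with both rc and normal fits
(18 conditions). Default 100 replications per condition, scaled down via
`--replications`; replication r of condition ci uses the child seed
SeedSequence([master, ci, r]), so results are independent of execution
order. The packaged recovery checks and the acceptance script use the
skewed N = 1000, J = 30 condition at 20 replications — approximately
20–30 s per replication, sized so a full run stays in the minutes range on
one core.

## Known limitations

- **Discrimination noise**: per-dataset RMSE of a is ≈ 0.26 even for a
  direct per-item MAP fit *given the true abilities*; the SAEM estimates sit
  near that bound (≈ 0.33 including ability uncertainty). Items whose true
  guessing parameter lands in the Beta tail (c ≈ 0.5) are nearly flat and
  essentially unidentified at N = 1000, occasionally collapsing a to small
  values.
- **Intercept RMSE under the skewed truth** is ≈ 0.25 across replication
  batches. An oracle experiment that fixes the density at the truth (no
  density estimation at all) yields ≈ 0.25 as well, so this level is the
  information bound of the generating design (items redrawn every
  replication, including rare high-guessing items) rather than an
  estimation artifact. The intercept *bias* is ≈ −0.02 to 0.
- **Shape attenuation**: fitted skewness under the skewed truth averages
  ≈ 1.5 vs 1.72 generated. Fitting the density to direct draws of θ at
  N = 1000 is unbiased (1.715 ± 0.17), so the attenuation comes from
  ability-posterior blurring, not from the spline fitter.
- The bimodal moment pair (0.95, 2.74) forces a sharp left component in the
  6-3 family; recovery under it is the weakest of the three shapes, and it
  is also the hardest case for the fixed-normal comparison.
- Standard errors from a single fit are not provided; across-replication
  sds serve that role in the simulation drivers.
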