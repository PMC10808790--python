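# Methods

## Model

The stochastic cusp treats the observed state as a draw from the
stationary distribution of a diffusion on the cusp potential, with the
controls moving slowly relative to the state.  Only the stationary
density is used:

    f(y | α, β) = exp(U(y; α, β)) / ψ(α, β),
    U(y; α, β) = α y + ½ β y² − ¼ y⁴.

Sign convention: `U` itself is the log-density kernel (Cobb's
convention, matching the estimation tradition for this model); the
"physics" potential is −U.  The discriminant δ = 27α² − 4β³ classifies
control points: δ < 0 inside the bifurcation set (two stable equilibria,
bimodal density), δ > 0 outside, δ = 0 on the boundary.  Boundary points
are labelled `boundary` and treated as unimodal for prediction; repeated
cubic roots are deduplicated at 1e-8 relative tolerance.

The regression maps observation i to the control plane through linear
submodels α_i = a0 + a1·x1_i, β_i = b0 + b1·x2_i and rescales the
outcome z_i = w0 + w1·Y_i.  The likelihood is assembled in observed
outcome units — each term is U(z_i) − log ψ(α_i, β_i) + log|w1| — so the
fitted log-likelihood is directly comparable with the linear and
logistic comparators.  Implementations in the estimation tradition this
follows may differ from ours by a data-independent constant in how they
handle the Jacobian; orderings and likelihood ratios are unaffected.

The likelihood is invariant under the sign flip
(a0, a1, w0, w1) → −(a0, a1, w0, w1); fits are canonicalized to w1 > 0.

## Numerics

**Normalization and moments.**  ψ(α, β) = ∫ exp(U) dy is computed two
ways.  The scalar API uses adaptive quadrature (`scipy.integrate.quad`,
default relative tolerance 1e-8) on the window where U is within 40
log-units of its maximum, with the stationary points as break points.
The likelihood path evaluates log ψ for thousands of control points at
once with fixed 128-node Gauss–Legendre quadrature on per-row windows
(the window brackets all stationary points and is located by vectorized
doubling + bisection).  Agreement between the two routes is at the
1e-14 level over the control box [−3, 3]².

**Score.**  ∂logψ/∂α = E[y] and ∂logψ/∂β = ½E[y²] under the density, so
the same quadrature sweep that evaluates the likelihood also yields its
exact gradient.  The fit therefore runs L-BFGS-B with the analytic
score rather than numerically differenced gradients — faster and free
of step-size noise.  Convergence: relative objective change below 1e-9,
500 iterations per start.

**Starting values and multi-start.**  The heuristic start standardizes
the outcome (w0, w1 from its mean/SD) and seeds a1, b1 from the
standardized multiple-regression slopes; by default 9 seeded random
perturbations are added (the objective surface can in principle hold
distinct optima).  On generator output all starts have consistently
reached one canonical optimum, which is why the bulk simulation runs
(parameter recovery, SE calibration) use 4 and 2 starts respectively;
single-fit defaults stay at 10.  The reported optimum is never worse
than the heuristic starting point by construction.

**Inference.**  Wald covariance is the inverse observed information,
with the Hessian obtained by central finite differences of the analytic
gradient (relative step 1e-5).  CIs use estimate ± 1.96·SE; the default
significance policy for flags is 0.01.  A singular Hessian degrades to
a pseudo-inverse with a warning and a `cov_ok = False` flag.

**Cubic roots.**  Stationary points solve α + βy − y³ = 0 and are
computed by the trigonometric (three-root) / Cardano (one-root) closed
forms, then polished by two Newton steps — no iterative solver branch
ambiguity.  Maxwell-convention ties (α = 0 in the bimodal region) return
the positive root and raise `MaxwellAmbiguityWarning`, unless a previous
state resolves the tie.

## Comparators

The linear model is OLS with both predictors entered in one step;
its log-likelihood is the Gaussian MLE value (σ² = RSS/n), k = 4.  The
logistic alternative keeps the cusp's control submodels and runs them
through the S-curve mean 1/(1 + exp(−α_i/β_i²)) with Gaussian error and
the outcome min–max rescaled to [0, 1], k = 5 — the comparator
convention of the estimation tradition, and the only published form
consistent with a printed parameter count of 5.  Its reported
log-likelihood is transformed back to raw outcome units (subtracting
n·log(range)) so all three models are compared on one scale.  The
S-curve mean is exactly invariant under (a, β²) → (c·a, c·β²), so the
k = 5 parameterization carries one flat direction; optimization is
unaffected and Wald inference uses the pseudo-inverse.  β_i² is floored
at 1e-8 (flagged) to avoid the singular denominator.

Information criteria use AIC = 2k − 2ℓ, AICc = AIC + 2k(k+1)/(n−k−1),
BIC = k·ln(n) − 2ℓ with n the post-deletion row count of the analyzed
table.  Parameter counts are explicit inputs, so printed tables
produced under other counting conventions (e.g. a 7-parameter cusp
count) can be replayed verbatim; the package's internal counts are
(4, 5, 6).  The likelihood-ratio contrast clamps a negative χ² at 0
with a warning (a misfit indicator, not an error).

**Diagnostics.**  Fitted values use the delay convention with the
observed state as the previous state: the stable equilibrium nearest
z_i.  Residuals are in canonical state units; pseudo-R² =
1 − Var(residual)/Var(z).  Because the delay fit snaps each observation
to the nearest attractor, residuals anti-correlate mildly with fitted
values by construction — a slight negative trend in the
residual-vs-fitted plot is expected, not a defect.  Under study-preset
conditions pseudo-R² is small (≈ 0.01–0.05): the per-row densities are
wide relative to the spread of the equilibria, so most state variance
is diffusion, not equilibrium movement.

## Multimodality battery

**Dip.**  The dip statistic is the sup-distance between the empirical
CDF and the nearest unimodal CDF (convex, then concave, an atom allowed
at the mode).  For a candidate mode at the j-th order statistic the
convex branch's deficiency is half the largest gap between the upper
step values and the greatest convex minorant of the lower step values
(mirrored for the concave branch via the least concave majorant), and
the two branches must also hand over at the mode — the lowest value the
convex branch can attain there must not exceed the highest value the
concave branch can.  The dip is the smallest deviation budget for which
some mode satisfies all three conditions, found by bisection over a
monotone feasibility check; the left/right deficiencies are monotone in
j, which confines candidate modes to a window, and the handover values
are computed across the window in one sweep (tangents over an
incremental hull of the band, a Li Chao envelope for the extrapolated
chords).  The kernels are numba-compiled; the implementation matches an
independent linear-programming oracle (direct minimization over
unimodal CDFs) to ~1e-11 across sample sizes and degenerate cases.

Dip p-values come from a seeded Monte-Carlo uniform(0, 1) null
(default 9,999 replicates, +1 continuity correction) rather than
interpolation tables — no hidden data dependency, and each null
replicate needs only a threshold feasibility check, not a full dip.

**Critical bandwidth.**  h_crit(k) is the smallest Gaussian-KDE
bandwidth at which the estimate has ≤ k modes, found by bisection
(tolerance 1e-4 × sample SD) using the Gaussian kernel's mode-count
monotonicity.  Mode counting evaluates the KDE on a 512-point grid over
the data range ± 3 bandwidths, counts rise→fall sign transitions
(plateau-safe), and pins exact data locations into the grid when the
bandwidth falls below the grid resolution.  The p-value is the fraction
of variance-corrected smoothed-bootstrap resamples (resample, add
kernel noise at h_crit, rescale to the sample variance) whose KDE at
h_crit shows > k modes.  The Hall–York calibration is deliberately
omitted; the test is known to be somewhat anti-conservative, which the
test suite tolerates up to ~1.5× nominal.  A stepwise ladder
(`mode_ladder`) runs k = 1, 2, … and reports the first retained k
together with the full ladder, so either reading of a reported
reference mode count can be recovered.

**SiZer.**  A simplified significant-zero-crossings map: per
location/bandwidth cell, the Gaussian-KDE derivative estimate with a
pointwise normal CI classifies the slope as increasing / decreasing /
zero; cells with effective local sample size below 5 are marked
insufficient-data.  Bandwidths are 21 log-spaced values from twice the
grid spacing to the data range.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
two predictors from a bivariate normal on a PIRLS-like score scale
(location 10, spread 2, correlation 0 by default), and a state drawn
exactly from the stationary density at each row's control point by
inverse-CDF on a per-row adaptive grid (4,096 points across the
40-log-unit window, trapezoid CDF, linear interpolation) — O(1) per
draw and bit-reproducible under a seed.  A rejection sampler under a
uniform envelope serves as the independent oracle in the tests only.
The observed outcome is the affine back-transform Y = (z − w0)/w1.
Optional missingness injection (default off, 2% when enabled)
exercises listwise deletion.

The "paper" preset fixes n = 2,420 and the six published coefficient
estimates as generating truth.  Predictors are simulated at location
10 / scale 2 — not standardized — because the preset intercept/slope
magnitudes only produce a bimodal-capable control range on that score
scale.  Two consequences worth knowing:

- under the preset, β_i is negative for most rows and only a sparse
  minority (typically 0–5 rows in 2,420, seed-dependent) falls inside
  the bifurcation set — echoing the sparse bifurcation-area occupancy
  seen in real data of this kind;
- the marginal outcome distribution under the preset is close to
  unimodal: the multimodality battery run on preset data typically
  retains k = 1.  Real survey outcomes can be strongly multimodal for
  reasons the generator does not emulate (discrete item scales, Rasch
  scoring artifacts, population mixture).  Passing recovery tests on
  generator output therefore validates the estimation machinery, not
  the claim that any particular real dataset is cusp-distributed.

The generator also does not emulate survey design features (strata,
school clustering, weights, plausible values) or item-level responses.

## Simulation sizes

Parameter recovery runs 20 replicates at n = 2,420 with 4 optimizer
starts per fit; SE calibration runs 50 replicates at n = 1,000 with 2
starts; the dip null calibration uses 200 replicates of n = 50 with 199
Monte-Carlo draws each.  These sizes give Monte-Carlo standard errors
an order of magnitude below the effects being checked while keeping the
full suite comfortably fast.

## Known limitations

- Only the stationary density is modelled; no time-dependent dynamics,
  hysteresis simulation, or transition-path analysis.
- One predictor per control axis (the general linear submodel beyond
  that is out of scope), no Bayesian estimation, no bootstrap CIs.
- The logistic comparator's flat scale direction means its individual
  coefficients (as opposed to identified combinations like a1/b0²)
  should not be interpreted.
- Wald inference assumes the usual regularity; near the bifurcation
  boundary the likelihood surface can be markedly non-quadratic and the
  intercept SEs (a0, b0) are the first to degrade.
- The quartic term biases the Gaussian-limit variance below −1/β by
  O(β⁻²): about 2.8% at β = −10, under 2% from β ≈ −15.
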