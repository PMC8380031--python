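# Methods

## Scope and model

`lwpcal` calibrates a straight line LWP = m·NDVI + c between two measured
quantities. Every data point is a pair of group means: x_i is a mean of
plot-level NDVI scan passes, y_i a mean of 4–6 pressure-chamber readings,
each carrying a standard error of the mean δ(x_i), δ(y_i) (sample sd with
the n−1 denominator, divided by √n). Two fitting conventions are provided
because they answer different questions and differ in how the measured
uncertainties enter.

### Ordinary least squares (common y-uncertainty)

The OLS fitter assumes the x errors negligible and a single unknown
uncertainty common to all y values, estimated from the residuals:
σ_y² = Σ(y_i − m x_i − c)²/(n−2). Coefficient uncertainties follow the
classical Taylor propagation for the straight-line fit,

    δm = σ_y √(n/Δ),   δc = σ_y √(Σx²/Δ),   Δ = nΣx² − (Σx)²,

with R² and a two-sided slope p-value from the t statistic m/δm on n−2
degrees of freedom. Note what this means: the per-point SEMs are *ignored*;
only the scatter of the means about the line informs δm, δc. Exactly
collinear data yield δm = δc = 0 and the p-value is reported as 0 (a
degenerate, perfectly determined slope).

### Weighted least squares with errors in both coordinates

The WLS fitter is the York/Williamson errors-in-variables solution. With
weights ω(x_i) = 1/δ²(x_i), ω(y_i) = 1/δ²(y_i) and the per-point overall
weight

    Z_i = ω(x_i) ω(y_i) / (m² ω(y_i) + ω(x_i)),

it minimises S = Σ Z_i (y_i − m x_i − c)². Stationarity in m yields a
"least-squares cubic" g(m) = 0 whose coefficients (through Z_i and the
Z-weighted centred coordinates U_i, V_i) themselves depend on m, so the
root is found iteratively; the intercept is c = ⟨y⟩_Z − m⟨x⟩_Z. The
adjusted points

    X_i = x_i + m Z_i r_i / ω(x_i),   Y_i = y_i − Z_i r_i / ω(y_i),
    r_i = y_i − m x_i − c,

are the weighted-metric projections of the observations onto the fitted
line and satisfy Y_i = m X_i + c exactly. Coefficient variances use the
overdispersion-scaled propagation

    δm² = S/(N−2) · Σ [ (∂m/∂y_i)²/ω(y_i) + (∂m/∂x_i)²/ω(x_i) ],

and identically for c. No correction is applied when S/(N−2) < 1.
Correlated x–y errors are out of scope (NDVI and LWP come from different
instruments).

#### Numerical choices

* **Root finding.** The solver seeds at the unweighted OLS slope and
  expands a bracket geometrically around it, *scanning the bracket
  interior* on a 64-point grid at every stage: g is cubic-like and can hold
  two or three roots strictly inside a bracket whose endpoints share a
  sign, so an endpoint-only sign test is not sufficient. Every bracketed
  root is polished by Brent's method (xtol 1e−15) and, when several roots
  are found, the one with the smallest S wins (with a warning). If no sign
  change appears within 25 doublings, a dense scan of S(m) followed by a
  bounded scalar minimisation takes over. At the returned slope
  |g(m*)| ≤ 1e−10·(1 + |m*|) on well-scaled data, and S(m*) is minimal
  over wide slope grids (both are asserted in tests against a brute-force
  nested grid minimiser of S over (m, c)).
* **Variance derivatives.** ∂m/∂x_i, ∂m/∂y_i (and the analogues for c) are
  central finite differences of the full solver with step 1e−6·δ_i per
  coordinate. Each perturbed solve starts from the base root and refines
  by Newton steps that reuse dg/dm evaluated once at the solution, falling
  back to the robust solver if the refinement stalls. The derivatives are
  evaluated at the observed points or at the adjusted points (`eval_at`,
  default `"adjusted"`); since the adjusted points are exactly collinear
  with slope m, the base root needs no re-solve there. The two conventions
  differ little for well-correlated data (asserted ≤ 20% relative in the
  tests).
* **Zero uncertainties.** δ = 0 would give an infinite weight; such values
  are floored at 1e−9 × the coordinate range with a logged warning. The
  floor is small enough that a deliberately tiny δx (e.g. 1e−12) still
  behaves as error-free x, which is how the OLS-reduction limit is
  exercised.

### Prediction error

For either fit the maximum relative error of a predicted LWP is the
propagated bound (|x_ref|·δm + δc)/|y_ref|, reported by default at the
dataset means (x̄, ȳ) — a user-supplied reference point gives a pointwise
bound instead.

## Ingest conventions

* Timestamps are stored UTC; the local clock is CST = UTC − 5, a fixed
  constant with the campaign's daylight-saving state baked in.
* Idle records (sensor parked between scan passes, logger still running)
  are detected from GPS displacement: a record is idle when every other
  record inside a centred 10 s window lies closer than 0.5 m (both
  configurable). Records whose window holds no neighbour are kept, which
  makes the filter idempotent. Warm-up exclusion is declarative — a list
  of local-time windows — rather than an automatic detector, because
  excluding a not-yet-thermally-stable sensor's readings is a judgment
  call. Optional geofences (bounding boxes per plot) assign plot labels.
* Aggregation: each plot's hourly mean NDVI is one replicate; the per-cell
  NDVI mean/SEM comes from the plot replicates, the LWP mean/SEM from the
  pressure-chamber readings. Points are ordered deterministically by
  (date, treatment, hour). Pooling treatments is always an explicit caller
  decision, never automatic, since pooling groups with different
  intercepts attenuates the fitted slope.
* Unreplicated NDVI (a single scan pass) yields a missing δx; the dataset
  is then OLS-only unless the caller supplies a substitute δx policy —
  there is no defensible way to invent an NDVI uncertainty.

## Resampling study

For each observation group, k ∈ {2, 3} LWP readings are drawn **with
replacement** from the original 4–6; group means/SEMs are recomputed; the
NDVI side is untouched; both fitters are re-run; 20 sets per k (both
configurable). A one-sample t-test compares the per-set values of each
quantity (m, c, δm, δc) with the full-replicate value as the reference
mean. Set j uses substream j of the study seed, so individual sets are
reproducible regardless of how many are drawn.

With-replacement draws collide (probability 1/4 per group at k = 2), which
collapses the resampled SEM to zero. Treating such a group as near-exactly
known is statistically indefensible and numerically destabilising (the
1e−9-range floor turns it into a hard constraint), so the study replaces
zero resampled LWP SEMs with the group's full-replicate SEM — the
measurement uncertainty does not vanish because two identical readings
were drawn. The substitution is logged per set. An alternative (redrawing
degenerate sets) was evaluated and changes results only marginally.

## Synthetic campaign generator

The generator emulates a one-day diurnal calibration campaign:

* **Diurnal LWP.** A sine-squared bump over the daylight window
  [dawn, 2·noon − dawn]: s(dawn) = 0, s(noon) = 1, LWP =
  lwp_base − lwp_depth·s(hour). The real diurnal course is not this
  regular; the shape only needs to sweep LWP (and with it NDVI) through a
  realistic range, defaults −1.3 to −2.6 MPa over hours 8–16
  (solar noon 13).
* **Linear link.** True NDVI inverts the line: (LWP_line − c)/m plus a
  per-treatment NDVI offset (default D −0.03, F +0.03), so treatments
  share the slope but differ in intercept, as deficit/full irrigation
  contrasts do. Defaults m = 4.24 MPa per NDVI unit, c = −5.19 MPa — a
  cotton-like calibration.
* **Lack-of-fit scatter** (`sigma_lof`, default 0.22 MPa). The cell's true
  LWP deviates from the line by a Gaussian draw independent of replicate
  noise. Field calibrations show residual scatter several times the
  replicate SEM — biology is not exactly a line — and this term is what
  makes OLS uncertainties insensitive to the LWP replicate count while
  SEM-weighted WLS uncertainties react to it. Set it to 0 for a
  well-specified model.
* **Replicate noise.** iid Gaussian per reading: 4 LWP replicates
  (σ = 0.12 MPa) and 3 plot-level NDVI replicates (σ = 0.028), placing the
  SEM-to-range ratios in the mid single-digit percent typical of such
  campaigns. Group SEMs then arise naturally as sd/√n. NDVI replicates are
  redrawn in the rare (≳4σ) event they leave the physical (−1, 1) range.
* **Determinism.** One global seed; per-cell substreams are spawned from
  it, so identical configs reproduce bit-identical studies.
* Emitters write the same CSV layouts the ingest stage reads: a raw scan
  log whose plot passes encode each NDVI replicate exactly (constant band
  sum 0.8) with idle dwells that the movement filter removes, the LWP
  replicate table, and a ground-truth JSON sidecar.

What the generator does **not** emulate: canopy radiative transfer, sensor
warm-up drift, spatial autocorrelation between plots, non-Gaussian reading
errors, and diurnal hysteresis of the LWP–NDVI relation. Passing tests
therefore validate the statistical machinery under a plausible noise
model, not the biology of any particular field.

## Monte-Carlo experiment designs

Two experiment designs in the tests and acceptance script deserve
explanation:

* **Slope-uncertainty calibration (coverage).** 200 campaigns with an
  exactly linear relation (zero treatment offsets, zero lack-of-fit) and
  WLS fed the *known* measurement sigmas; the interval m̂ ± 2δm covers the
  true slope ≈ 95% of the time. Coverage is only meaningful when the true
  slope is the estimand: with the default treatment offsets the pooled
  slope is attenuated by design (pooling two lines that differ in
  intercept), and with replicate-*estimated* SEMs the weights are
  chi-noisy (3 and 2 degrees of freedom), which drops coverage to ≈ 87% —
  the acceptance script reports both variants. That gap is a real
  small-sample caveat of SEM-weighted fitting, and one more reason not to
  reduce replicate counts.
* **Replicate-count inflation.** 100 campaigns under the default
  (lack-of-fit) conditions; per campaign, the mean of the 40 per-set WLS
  δm values (k = 2 and 3, 20 sets each) is compared with the
  full-replicate δm. The mean WLS inflation is ≈ 9% against ≈ 3% for OLS —
  the expected asymmetry, since OLS uncertainties see only the scatter of
  means while WLS weights respond directly to the noisier, more dispersed
  small-k SEMs. The inflation is *not* monotone in every campaign: the
  full-replicate WLS δm is itself volatile under chi-noisy weights, so
  roughly one campaign in six shows a nominal deflation. The corresponding
  acceptance test asserts a stricter universal-inflation bound (≥ 95% of
  campaigns) and is expected to fail at these noise scales; the
  qualitative OLS-vs-WLS asymmetry it also asserts does hold.

Problem sizes (200 and 100 campaigns, 20 sets per k) were chosen to give
Monte-Carlo standard errors well below the asserted margins while keeping
the full suite under a minute.

## Known limitations

* WLS variances rely on finite-difference solver derivatives; an analytic
  implementation of the derivative expressions would be faster but must
  match the numeric values (the numeric route is the reference here).
* The uncertainty-to-range diagnostic summarises per-group SEMs by their
  arithmetic mean by default (median and pooled RMS are selectable); the
  choice is a reporting convention, logged, not a measured quantity.
* No treatment of correlated coordinate errors, nonlinear calibrations, or
  heteroscedastic OLS variants.
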