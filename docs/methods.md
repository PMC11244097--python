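# Methods

This note documents the models, procedures and numerical choices behind
`emulgelopt`, and what its synthetic-data generator does and does not
emulate.

## Experimental design and formulation completion

The design is a two-factor face-centered central composite design
(axial distance α = 1): four factorial corners, four axial face points
and one center point, nine distinct runs with coded levels in
{−1, 0, +1}.  Since no printed level lies off the faces, α = 1 is the
unique CCD consistent with the reference runs; the same nine points can
equally be read as a 3² factorial without replicated centers.  No
replicated center points are generated by default (matching the
reference design); `center_replicates` appends them for users who need
a pure-error estimate from the design itself.

Coded and actual factor values are related affinely per factor,
`coded = (actual − center)/half_range`, with center = (low+high)/2 and
half_range = (high−low)/2.  For the reference emulgel space (oil
10–50 % w/w, polysorbate 80 0–10 % w/w): A = (X₁−30)/20, B = (X₂−5)/5.

Each run is completed into a five-component recipe.  The gelling-agent
rule `poloxamer_407 = 25 − 0.25·oil` is a linear interpolation of the
reference compositions (22.5/17.5/12.5 % poloxamer at 10/30/50 % oil)
and is configurable (intercept, slope); the active is fixed at 1 % and
purified water takes the balance to 100 %.  Negative shares raise an
error naming the offending component.

## Response-surface fitting

Models are ordinary least squares on the coded model matrix; replicate
measurements enter as individual rows.  Coefficients are reported in
both parameterizations: the actual-factor form is obtained by exact
polynomial substitution of the affine coded↔actual maps (expansion and
collection over the monomial basis), never by refitting, so the two
forms agree to machine precision everywhere.  The OLS solve, per-term
t/partial-F p-values and the overall regression F-test come from
statsmodels.

Diagnostics follow response-surface-software conventions:

* `adj_r2 = 1 − (1−R²)(n−1)/(n−p)`;
* `PRESS = Σ (eᵢ/(1−hᵢᵢ))²` via hat diagonals — algebraically identical
  to explicitly refitting with each observation left out, which the
  test-suite verifies to 1e-10;
* `pred_r2 = 1 − PRESS/SST`;
* `adeq_precision = range(ŷ over design points) / √(p·MSE/n)` — the
  signal-to-noise measure for which > 4 is conventionally deemed
  adequate to navigate the design space.

PRESS is undefined when any leverage reaches 1 (interpolating fit);
this raises an error rather than returning infinities.  Rank-deficient
model matrices raise an error naming the collinear terms (found by
pivoted QR).

### Model-family selection

Candidate families are linear (1, A, B), two-factor interaction (+AB)
and quadratic (+A², B²).  Candidates are screened on per-run means.
Each family's added terms are tested against the next-lower family by a
sequential F-test; the suggested family is the highest-order one whose
added terms are significant.  When replicates are available the F
denominator is the pure-error mean square of a run mean (replicate
scatter, with its full replicate degrees of freedom); otherwise the
candidate's own residual mean square is used.

Two design choices here deserve explanation.  First, a
"lowest-order family that passes the validation criteria" rule is
unusable: an underfitted linear model of a truly quadratic surface can
pass a model-significance test, an adjusted−predicted R² gap criterion
and an adequate-precision bound simultaneously — on this design the gap
converges to a constant below 0.2 as noise shrinks — so lack of fit must
be judged against the richer family directly.  Second, the sequential
admission level defaults to 0.01 rather than 0.05: admitting curvature
is a model-building decision, and a stricter evidence bar keeps the
false-admission rate per response at the percent level while curvature
of the magnitude seen in these systems (coded quadratic coefficients of
0.06–2.1 against replicate noise of 0.02–0.3) is still detected with
essentially full power.

The suggested family is then checked against the three validation
criteria — model p < 0.05, adjusted−predicted R² gap < 0.2, adequate
precision > 4 — and flagged `validated` accordingly; a pure-noise
response returns the best-predicted-R² candidate flagged not validated.

### Term pruning

Backward elimination removes terms with p > 0.10, largest p first,
refitting after each removal (a single-pass variant is available).  The
intercept and any term supporting a retained higher-order term (strong
heredity: every monomial divisor) are never removed.  Note that null
terms have scale-free uniform p-values, so a spurious term survives a
multi-term purge with non-negligible probability regardless of how
small the noise is; pruning is a readability device, not a consistency
guarantee.

## Desirability optimization

Derringer–Suich transforms map each response to [0,1]: one-sided ramps
`((y−L)/(U−L))^w` (maximize) and `((U−y)/(U−L))^w` (minimize), a
two-sided ramp for target goals, an indicator for in-range goals; the
ramp is clipped to [0,1] before the weight exponent.  The composite is
the importance-weighted geometric mean, zero whenever any individual
desirability is zero.

Bounds default to the observed per-response extremes over the design
runs when not supplied.  Weights and importances default to 1.  The
optimizer scans a dense grid (default 0.01 % resolution) over the
actual-factor box, then refines with Nelder–Mead from the best grid
cell and from seeded random starts; ties on flat ridges are broken
toward the design center, making the result deterministic for a given
seed.  The box is the two-factor space only — the hydrogel share is
implied (100 − oil − polysorbate) and reported, not searched.

On the reference models the desirability surface is a broad flat ridge:
with default observed-range bounds the maximizer sits at (39.7 % oil,
6.1 % polysorbate) with D = 0.61, about 1.5 points away from the
reference optimum (38.27, 6.56; D = 0.646).  The bounds behind the
reference optimization are not recoverable, so agreement is expected
only at the few-percentage-point level, and the package makes no
attempt to force it.

## Release analysis

Cumulative release from sampled acceptor concentrations uses the
standard medium-replacement correction
`Cₙ* = Cₙ + (V_s/V)·Σ_{i<n} Cᵢ`, `Qₙ = Cₙ*·V`.  The correction reduces
to the identity at V_s = 0 and exactly inverts the generator's
forward-simulated withdrawals.  A non-monotone corrected series warns
but is never mutated.  The sample volume is not part of the reference
protocol description; the default is 1 mL, configurable.

Release flux is defined as the cumulative amount per diffusion area at
the final time point (mg/cm², default geometry 1.33 cm², 50 mL
acceptor, 6 h with hourly sampling, 10 mg dose); this definition is
consistent with the reference flux values sitting well below the
mass-conservation ceiling dose/area = 7.52 mg/cm².  A slope-based
alternative (mg/cm²/h) is available behind `method="slope"`.

First-order kinetics are fitted in the saturating form
Q(t) = Q∞(1 − e^(−kt)) by bounded nonlinear least squares (Q∞ ≤ dose;
initialized at Q∞ = dose with k from the endpoint log slope, with
perturbed restarts).  The log-linearized regression is ill-conditioned
near the plateau and is used only as a cross-check in tests.
Zero-order and Higuchi laws are linear fits through the origin; R² is
computed on each model's own scale.

The sol–gel transition is located as the adjacent-temperature window
with the largest |ΔG′/ΔT|; the reported T_sol/gel is the window
midpoint, so its resolution is half the sweep's temperature step
(0.5 °C on the default 1 °C grid).  Flat curves and uniform-variation
(linear) curves raise a "no transition" error; the detector is
invariant to sweep direction.

## Nonparametric statistics

Midranks (ties share the average rank) underlie all three tests.
Spearman's ρ is the Pearson correlation of midranks; p-values are by
exact permutation enumeration for n < 10 and by the
t = ρ√((n−2)/(1−ρ²)) approximation otherwise.  Mann–Whitney U (reported
for the first sample) uses exact enumeration of all C(n₁+n₂, n₁)
assignments when n₁+n₂ ≤ 12 with no ties, else a tie-corrected normal
approximation with continuity correction.  Kruskal–Wallis H is
tie-corrected with a χ²(g−1) p-value.  All p-values are two-sided;
the suite verifies exact agreement with enumeration oracles and a
0.05-level type-I error within [0.03, 0.07] at n = 10 per group.
Rank correlations computed on run means differ numerically from
replicate-level correlations; both input levels are accepted.

## Synthetic-data generator

The generator is a pure function of (configuration, seed) and emulates
the reference measurement campaign:

* **Responses** — per-run truth from the reference actual-factor
  equations plus additive Gaussian replicate noise.  Default SDs (pH
  0.02, D50 0.02 µm, T_sol/gel 0.3 °C, flux 0.05 mg/cm², firmness
  0.05 N, work of shear 0.08 N·s) are scaled to the reference replicate
  SDs where printed (particle size) and to the reported response ranges
  elsewhere.  Replicates: 5 for particle size, 3 otherwise.
* **Release** — stretched-exponential truth Q(t) = Q∞(1 − e^(−(kt)^β))
  pushed through the sampling protocol, with multiplicative assay noise
  (CV 1 %).  Default β = 2/3 with per-run k solved so the true 6-h flux
  matches the reference flux surface at each composition (Q∞ = 2.4 mg).
  The shape default is a deliberate, calibrated departure from β = 1:
  pure first-order truth with realistic assay noise yields first-order
  R² ≈ 0.999, while the reference fits report 0.96–0.99 — a level that
  implies mild systematic curvature, which the 2/3 exponent (diffusion-
  dominated release) reproduces.  β = 1 gives exact first-order data
  for round-trip tests.
* **Rheology** — logistic G′(T) step between a sol plateau (10 Pa) and
  a gel plateau (10 kPa) of width 1 °C on the protocol's 40→0 °C, 1 °C
  grid, with 1 % multiplicative noise.
* **Particle sizes** — per-measurement D10/D50/D90 from the lognormal
  quantile function (median, shape σ; default σ ≈ 0.52 matches the
  reference D90/D50 ratio ≈ 1.95) with 2 % measurement noise.

What the generator does *not* emulate: emulsification physics,
instrument artifacts (laser-diffraction inversion, rheometer inertia),
between-batch variability, non-Gaussian or correlated replicate errors,
and any factor–variance coupling.  Passing tests therefore demonstrate
the correctness and calibration of the *analysis machinery* under the
assumed error model, not the behavior of real emulgels.

## Numerical conventions

* Percentages are stored on the 0–100 scale as printed; CSVs are
  comma-separated UTF-8 with "." decimals and mandatory headers.
* Report rounding is half-up at the table precision used in the field
  (2 decimals for coded coefficients, etc.).
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical configuration and seed produce byte-identical report JSON.
* Grid/refinement agreement, coded/actual agreement (1e-9), PRESS/LOO
  equivalence (1e-10) and CSV round-trip losslessness (1e-12) are
  enforced by the test-suite at the stated tolerances.

## Known limitations

* With nine runs and no replicated centers, mean-level quadratic fits
  have three residual degrees of freedom; validation diagnostics
  (especially predicted R²) are noisy, and the `validated` flag can
  fluctuate for responses whose effects sit near the noise floor (pH).
* The desirability optimum is bound-sensitive on flat ridges; report
  the bounds alongside the optimum when publishing results.
* Family selection assumes the candidate ladder linear → 2FI →
  quadratic; cubic or transformed-response surfaces are out of scope,
  as are mixture designs, blocking, rotatable CCDs and lack-of-fit
  tests based on replicated center points.
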