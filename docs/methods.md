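# Methods

## Model

The package implements a five-variable ODE model of type-2-diabetes onset in
which islet inflammation acts as a bistable switch.  State variables (units in
parentheses): fasting glucose `G` (mM), fasting insulin `I` (pM), β-cell mass
`B` (mg), islet interleukin-1β `L` (pg/ml) and islet IL-1 receptor antagonist
`A` (pg/ml).  Insulin resistance `R(t)` (pM·d) is an external input derived
from longitudinal HOMA2 %S insulin-sensitivity data.

```
dG/dt = r0 − (dG + I/R)·G
dI/dt = h·B·s(G) − dI·I,        s(G) = G²/(KG² + G²)
dB/dt = τ·B·(p(F) − λ·a(F))
dL/dt = b(L)·(k5·g(G) + k6·l(F)) − dL·L
dA/dt = k1 + k2·(L/k3)/(1 + (L/k3)²) − dA·A
```

with the receptor occupancy `F = (L/KL) / (1 + L/KL + A/KA)` — competitive
binding of the agonist IL-1β and the antagonist IL-1Ra at the IL-1 receptor,
assumed at equilibrium (ligand binding is seconds-fast).  `F`, not `L`, is
the inflammatory stimulus seen by β-cells.

* `g(G) = G^s/(v^s + G^s)` — glucose-stimulated IL-1β production (Hill),
  half-point `v = 3.52 mM`, exponent `s = 2.77`.
* `l(F) = F^t/(KF^t + F^t)` — IL-1β auto-stimulation (Hill in occupancy),
  half-point `KF = 0.1575`, exponent `t = 3`.
* `b(L) = 1/(1 + (k4·L/u)^r)` — inhibition of both production routes by
  basal IL-1β mRNA (`k4` converts protein concentration to mRNA units;
  midpoint `u = 5.8`, steepness `r = 2`).  At high `L` this decouples the
  high-IL-1β states from glucose.
* IL-1Ra production is a Haldane-type bell in `L`: basal `k1`, peak
  `k1 + k2/2` at `L = k3`, returning towards basal at high `L` — the
  measured restoration of IL-1Ra to near-basal levels under strong IL-1β.
  The declining limb is what creates a third (advanced-disease) stable state.
* `p(F)` and `a(F)` are parabolas in `ln F` (proliferation concave, apoptosis
  convex), fitted to islet-culture turnover measured as percent of control.
  The natural-log convention is forced by that normalisation: with the
  published coefficients both rates are ≈ 1 at the culture's endogenous
  occupancy (`L = 0.228`, `A = 114` pg/ml, `F ≈ 1.6×10⁻⁴`) only under `ln`.
* `R = R0 + m·ln(S_H(0)/S_H(t))` — log-linear conversion of the HOMA2 %S
  sensitivity index to the model's resistance, anchored so `R = R0` at the
  cohort baseline, clipped below at `0.1·R0` to keep `I/R` finite.

Several of these functional forms are reconstructions constrained by the
stated qualitative behaviour (bimodality, sigmoidality) and by the
steady-state anchors below; the published rate constants `k1–k6` and the
history-fit parameters depend on the exact forms and are therefore treated
as order-of-magnitude references, re-derived here by the calibration
pipeline.

## Timescale structure and integrators

The model spans three timescales: cytokine turnover (`dL = 55.45/d`,
`dA = 166.36/d`; minutes–hours), glucose/insulin (days) and β-cell mass
(`τ ≈ 5×10⁻⁴/d`; months–years).  Two integrators are provided:

* **stiff-full** — all five equations, BDF, `rtol 1e-8`, `atol 1e-9`.
* **qssa** — `(L, A)` are pinned to a stable equilibrium branch of the fast
  subsystem at the current glucose.  On the IL-1Ra nullcline
  `A = production(L)/dA`, fast equilibria reduce to roots of a scalar
  residual in `L`; the occupied branch is followed by Newton continuation in
  `ln L`, and `(L, A)` are frozen over short chunks (default 15 d) while
  `(G, I, B)` are integrated with LSODA.  When the occupied branch
  disappears at a saddle-node, the new state is the adjacent stable root of
  the scalar residual in the direction of flow, and a `branch-jump` event is
  recorded.  Direct short time-integration is *not* used for the jump:
  trajectories linger arbitrarily long in the saddle-node ghost, so the
  flow-direction rule is the robust limit of that procedure.  The two modes
  agree on `G(t)` to ≲0.25% away from jump times (tested at 1%).

For history fitting a further reduction is used: at yearly sampling, glucose
and insulin are themselves quasi-static relative to `B`, so only `B` is
integrated (exponentially over 30-d chunks) with `G` solved from the
insulin supply/demand balance.  This "slaved" simulator agrees with the
qssa integrator to <0.25% in `G` at sample times and is ~50× faster; a test
pins the agreement.

## Equilibrium analysis

`find_equilibria` brackets roots of the scalar residual on a 3200-point
log-spaced grid over `L ∈ [10⁻⁴, 10⁶]` pg/ml and polishes them; stability
comes from the eigenvalues of the analytic 2×2 Jacobian (an eigenvalue real
part within 10⁻¹⁰ of zero is labelled fold-degenerate).  The determinant of
that Jacobian equals `−dA` times the scalar residual's `L`-derivative, so
the 1-D reduction loses no fold information.  `critical_glucose` continues a
branch in `G`, bisects its disappearance to 10⁻⁴ mM and then polishes the
saddle-node exactly (residual and its derivative both zero), so the
determinant at the returned fold vanishes to rounding.  The IL-1β nullcline
is evaluated in closed form by inverting the auto-stimulation Hill curve and
the occupancy relation at each `L`.

## Steady-state calibration

Anchors (glucose, IL-1β, IL-1Ra): compensation (5.47 mM, 12, 6000 pg/ml),
bifurcation (5.84 mM, `L_b`, `A_b` free) and overt diabetes (13.4 mM,
12·55.8, 6000·1.8).  The islet levels derive from serum IL-1Ra 300 pg/ml,
an IL-1Ra/IL-1β ratio of 500 and a 20-fold tissue/blood ratio.  Requiring
equilibrium of the fast subsystem at all three anchors gives six equations
that decouple: the IL-1Ra balances determine `(k1, k2, k3)` and the IL-1β
balances `(k4, k5, k6)`; given `k3` (resp. `k4`) the other two constants
follow linearly from the compensation and diabetes rows, leaving one scalar
root problem per side.

`(L_b, A_b)` are restricted by requiring an actual switch.  A random scan of
the plane maps feasibility (non-negative constants), switch existence (the
compensation branch is annihilated at a fold before the diabetic glucose,
verified by the vanishing Jacobian determinant and the equilibrium count
dropping by two) and the post-switch IL-1β fold change.  Most switch points
under-shoot the 55.8-fold target.  The final calibration therefore solves
`(L_b, k3, k4)` at fixed `A_b` so that the bifurcation anchor is an *exact*
saddle-node of the calibrated subsystem (residual derivative zero, with
positive curvature so the pair annihilates as glucose rises), and bisects
`A_b` towards the structural boundary at which the post-switch branch
carries the full anchored fold changes while the five-state structure
(three stable states below the fold, two above) survives.  The selected
calibration sits at `A_b ≈ 1.0075·A_c`, `L_b ≈ 14.4 pg/ml` and reproduces:
fold at 5.8400 mM; IL-1β fold change 55.800; IL-1Ra fold change 1.8000;
five equilibria (three stable) at 4.5 mM and three (two stable) above the
fold.  λ is then re-derived from proliferation/apoptosis balance at healthy
glucose (4.5 mM), giving λ ≈ 2.386 (reference value 2.33; the 2% shift is
the footprint of the reconstructed forms).  Because λ balances turnover at
4.5 mM, the compensation anchor is not a full fixed point: β-cell mass
grows slowly there (≈ +0.008 mg/d), which *is* the compensation phase.

Rescaling the tissue/blood ratio (e.g. 200 instead of 20, cytokine ratio
fixed) leaves the fold glucose and both fold changes unchanged while the
derived constants and λ absorb the rescaling; occupancies shift only mildly
because the binding denominator is antagonist-dominated.

## Synthetic study inputs

The longitudinal generator emulates the natural history of incident
diabetes over the 13 years before diagnosis: cases start at 5.47 mM
(controls 5.25 mM, both with insulin and β-cell mass at the corresponding
glucose/insulin steady state), insulin sensitivity declines slowly to year
−5 and then steeply (knots 100 → 82% by year 8, → 38% at diagnosis;
controls stay within 5% of baseline), and fasting glucose is sampled yearly
with Gaussian measurement noise (default sd 0.1 mM, 100 subjects).  The
generator truth uses τ* = 5.2×10⁻⁴/d (the reference value) and m* = 5.0
pM·d.  The published m (1.688) is an output of the original fit with the
original unprinted forms; under the reconstructed forms the glucose/insulin
algebra requires `R ≈ 13 pM·d` to cross the critical glucose, which at
m = 1.688 would imply an ~8-fold sensitivity collapse.  m* = 5.0 with the
%S decline above reproduces the published features — switch ≈ 2 years
before diagnosis, slow-then-rapid glucose rise (5.47 → ≈7 mM), β-cell mass
rising through compensation and falling after the switch — with a
clinically plausible sensitivity trajectory.  These choices are the study
conditions of the package and are not tuned per run.

The in-vitro generator evaluates the true curves at fixed designs
(glucose 5.5–40 mM; exogenous IL-1β 0–5000 pg/ml on the endogenous culture
background; mRNA levels 0.5–64), applies multiplicative lognormal noise
(default CV 10%, three replicates) and reports turnover on the percent
scale (the control row sits at ≈97.7%, not exactly 100, because the
published parabolas are fits that do not pass exactly through control —
preserving this makes the zero-noise round-trip exact).  What passing the
recovery tests shows about real data is limited: real islet preparations
have donor-level heterogeneity, non-lognormal error and unknown endogenous
backgrounds, none of which are emulated.

## Fitting

`fit_history` fits `(m, τ)` by seeded differential evolution (population
20, bounds m ∈ [0.1, 20], τ ∈ [10⁻⁵, 10⁻²]) against the unweighted sum of
squared glucose residuals over both cohorts.  Every evaluated candidate is
recorded; candidates whose misfit is within 8× the optimum (RMS within
~2.8×) form the near-optimal ensemble used for identifiability analysis.
The ensemble exhibits the m–τ ridge (|r| ≈ 0.85–0.95): a steeper resistance
conversion can be traded against faster β-cell turnover with almost no
change in the pre-diagnosis glucose curve.  The terminal DE population
itself collapses to the optimum and is not a reliable ridge estimator,
which is why the ensemble is used.

`reduced_fit` removes the presupposed bifurcation: only `(k3, k4, m, τ)`
are free (searched in log space for the first two), with `k1, k2, k5, k6`
eliminated through the compensation and diabetes anchor equations,
reducing eight unknowns to four.  The 4-D objective is multimodal, so the
evolution restarts twice from derived seeds and keeps the best run.
Whether the IL-1β switch occurs before diagnosis is recorded per accepted
ensemble member rather than imposed; on the synthetic cohorts every
accepted member switches pre-diagnosis, and m correlates strongly with
log k4 (|r| ≈ 0.6–0.95).

## Therapy simulation

Clamps are hard: the clamped variable is set to the prescribed level and
its equation suspended for the segment.  Disease stages: *mild* = 6
simulated years after the switch on the post-switch branch; *strong* = 11
years, with `(L, A)` re-assigned to the highest-IL-1β stable state (which
has a lower endogenous IL-1Ra level).  During overt-phase simulations the
resistance input is held at its end-of-observation value (≈14.5 pM·d).

The threshold dose is the interior peak of the IL-1β nullcline in `A`
(≈11 200 pg/ml ≈ 1.9× the compensation IL-1Ra level): the nullcline falls
from a vertical asymptote at the purely glucose-driven root, passes a
nadir, rises to this peak and decays; clamping above the peak leaves a
single low-IL-1β state.  The dose–response sweep (90-day clamp vs
untreated control) shows the discontinuous improvement jump at the
threshold, a single interior optimum just above it (higher doses push the
occupancy below the healthy balance point and lose β-cell mass), and a
larger optimal dose and ≈2–3× larger best improvement for strong vs mild
disease (the strong control group deteriorates faster).  In this
calibration the threshold depends only weakly on glucose, so the
stage-dependence of the *optimal dose* is small though consistently
ordered.

## Numerical choices and limitations

* Equilibrium dedup tolerance 10⁻⁶ relative; anchor residuals required
  <10⁻⁸ (achieved ~10⁻¹³).
* Branch tracking is nearest-in-`ln L`; branches are ≥ ln 4 apart where it
  matters, and the jump tolerance is 1.0.
* All stochastic components (scan, noise, differential evolution) are
  driven by explicit integer seeds; simulations themselves are
  deterministic.
* The model has no receptor down-regulation at high IL-1β, no macrophage,
  free-fatty-acid or amyloid contributions, no postprandial dynamics, and
  insulin resistance is an input, not a state; results in the strongly
  hyperglycaemic regime are qualitative.
* The turnover parabolas are extrapolated below the culture's occupancy
  range under strong IL-1Ra clamps; there the model predicts net β-cell
  loss whose magnitude should not be taken quantitatively.
* Control-cohort glucose drifts slowly downward over the 13-year window
  (β-cell mass keeps adapting towards the 4.5 mM balance point); the
  emulation reproduces levels and separation of the cohorts, not the slight
  upward control trend of the source study.
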