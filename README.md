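# il1switch

Modelling tools for the hypothesis that the onset of type-2 diabetes is an
**IL-1β bistable switch**: a sudden, hysteretic transition of islet
inflammation from a compensated low-IL-1β state to a self-sustaining
high-IL-1β state, driven by slowly rising fasting glucose.  The package is
aimed at systems biologists and quantitative physiologists who want to
reproduce, probe or extend this class of multi-timescale
disease-progression models.

## The model

Five coupled ODEs over three timescales — islet IL-1β *L* and its receptor
antagonist IL-1Ra *A* (fast), fasting glucose *G* and insulin *I*
(intermediate, Topp-type single compartment), and β-cell mass *B* (slow):

```
dG/dt = r₀ − (d_G + I/R)·G
dI/dt = h·B·s(G) − d_I·I              s(G) = G²/(K_G² + G²)
dB/dt = τ·B·(p(F) − λ·a(F))
dL/dt = b(L)·(k₅·g(G) + k₆·l(F)) − d_L·L
dA/dt = k₁ + k₂·(L/k₃)/(1 + (L/k₃)²) − d_A·A
```

The inflammatory stimulus is the receptor occupancy under competitive
binding, `F = (L/K_L)/(1 + L/K_L + A/K_A)`.  Glucose stimulation `g`,
auto-stimulation `l`, mRNA-mediated inhibition `b` and the β-cell turnover
parabolas `p`, `a` (in ln F) are fitted to islet-culture dose–response
data.  Insulin resistance `R = R₀ + m·ln(S_H(0)/S_H(t))` is an input
derived from longitudinal HOMA2 %S insulin-sensitivity trajectories.

At fixed glucose the fast subsystem is multistable: below a critical
glucose *G_b* it has five steady states (three stable — compensation, mild
and advanced disease); at *G_b* the compensation state is annihilated in a
saddle-node and IL-1β jumps ~56-fold.  Because the high state is stable at
all physiological glucose levels, glucose-lowering therapy alone can never
reverse the switch — only an IL-1Ra clamp above the peak of the IL-1β
nullcline resets it, and it must be combined with glucose control and then
*released* for β-cell mass to regrow.

The package provides the model and both integrators (full stiff and
quasi-steady-state with branch tracking), the steady-state calibration
pipeline that re-derives k₁–k₆ and λ from three anchored states, fixed
point/nullcline/bifurcation analysis, differential-evolution fitting of
(m, τ) to fasting-glucose histories (plus a reduced four-parameter fit that
does not presuppose the bifurcation), in-silico therapy protocols with
dose–response sweeps, and synthetic-data generators for all inputs.

## Worked example

```python
from il1switch import calibrate, find_equilibria, simulate, SystemState
from il1switch.calibration import dbss_initial_state
from il1switch.synth import CohortSpec, generate_sensitivity_input

cal = calibrate(seed=1)              # re-derive k1–k6 and λ from the anchors
p = cal.params
print(f"fold glucose  {cal.G_fold:.4f} mM")
print(f"IL-1β fold change {cal.fold_change_L:.2f}, "
      f"IL-1Ra fold change {cal.fold_change_A:.3f}")
print(f"lambda {cal.lam:.3f}")
for e in find_equilibria(4.5, p):
    print(f"  L*={e.L_star:9.2f}  A*={e.A_star:9.0f}  {e.stability}")

spec = CohortSpec()                  # emulated incident-diabetes cohort
sens = generate_sensitivity_input(spec)["cases"]
p_run = p.replace(m=spec.m_true, tau=spec.tau_true)
I0, B0 = dbss_initial_state(5.47, p_run.R0, p_run)
traj = simulate(SystemState(t=0, G=5.47, I=I0, B=B0, L=12, A=6000),
                sens, 13 * 365, p_run, mode="qssa")
print("switch events:", [(round(t / 365, 2), kind) for t, kind in traj.events])
print(f"glucose at diagnosis {traj.G[-1]:.2f} mM")
```

prints

```
fold glucose  5.8400 mM
IL-1β fold change 55.80, IL-1Ra fold change 1.800
lambda 2.386
  L*=     9.09  A*=     5946  stable
  L*=    19.33  A*=     6136  unstable
  L*=   668.84  A*=    10801  stable
  L*=   757.83  A*=    10646  unstable
  L*=  1009.52  A*=    10082  stable
switch events: [(11.14, 'branch-jump')]
glucose at diagnosis 7.02 mM
```

— the calibrated fast subsystem loses its compensated state at 5.84 mM
glucose; at the diabetic glucose level the occupied branch carries 55.8×
more IL-1β and 1.8× more IL-1Ra than compensation; at healthy glucose the
system has five fixed points (three stable); and the emulated case cohort
switches ≈ 1.9 years before diagnosis, after which glucose rises rapidly.

The same operations are exposed on the command line
(`il1switch calibrate|simulate|bifurcation|nullclines|scan|fit-history|therapy|dose-sweep|synth`);
every output table carries a provenance header with version, seed and
configuration hash.

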