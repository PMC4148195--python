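"""In-silico therapy protocols: glucose and IL-1Ra clamps, dose–response sweeps.

Therapies are modelled as hard clamps — the clamped variable is set to the
prescribed level and its ODE suspended for the duration of a protocol
segment — matching how glucose-lowering and IL-1Ra administration are
idealised in the underlying switch analysis.  Because the high-IL-1β state
is bistable, a glucose clamp alone can never restore the pre-diabetic
branch; an IL-1Ra clamp above the peak of the IL-1β nullcline collapses the
fast subsystem to a single low-IL-1β state, and a combined clamp followed
by release of the IL-1Ra clamp parks the system back on a restored stable
low-IL-1β equilibrium with regrowing β-cell mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from . import kinetics as kin
from .calibration import AnchorConditions, CalibrationResult, dbss_initial_state
from .equilibria import AnalysisError, find_equilibria, nullclines
from .model import (TRAJECTORY_COLUMNS, SensitivityInput, SystemState,
                    Trajectory, _resistance_fn, rhs_full, simulate)
from .params import KineticParameters

__all__ = ["TherapyProtocol", "DoseResponseResult", "construct_disease_state",
           "simulate_therapy", "threshold_dose", "dose_sweep"]

DAYS_PER_YEAR = 365.0

#: disease duration (years) mapped to the mild / strong T2D stages
STAGE_YEARS = {"mild": 6.0, "strong": 11.0}


@dataclass(frozen=True)
class TherapyProtocol:
    """Ordered, non-overlapping clamp segments.

    Each segment is ``(start_day, end_day, clamps)`` with ``clamps`` a dict
    holding any of ``{"G": level_mM, "A": level_pg_ml}``.
    """
    segments: tuple

    def __post_init__(self):
        prev_end = -math.inf
        for start, end, clamps in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed its start")
            if start < prev_end:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_end = end
            unknown = set(clamps) - {"G", "A"}
            if unknown:
                raise ValueError(f"unknown clamp variable(s): {sorted(unknown)}")
            if any(level <= 0 for level in clamps.values()):
                raise ValueError("clamp levels must be positive")

    @classmethod
    def single(cls, start: float, end: float, **clamps: float) -> "TherapyProtocol":
        return cls(segments=((start, end, dict(clamps)),))


@dataclass
class DoseResponseResult:
    """End-of-treatment glycaemia per dose, against untreated control."""
    stage: str
    duration: float
    table: pd.DataFrame      # dose_pg_ml, G_treated_end_mM, G_control_end_mM, improvement_mM

    @property
    def optimal_dose(self) -> float:
        idx = self.table["improvement_mM"].idxmax()
        return float(self.table.loc[idx, "dose_pg_ml"])

    @property
    def best_improvement(self) -> float:
        return float(self.table["improvement_mM"].max())


def _overt_resistance(p: KineticParameters,
                      R_overt: float | SensitivityInput | None) -> float | SensitivityInput:
    """Insulin resistance during the overt phase.

    The longitudinal sensitivity input ends at diagnosis; beyond it the last
    value is held, so a constant R at the end-of-observation level is the
    default overt-phase input.
    """
    if R_overt is None:
        from .synth import CohortSpec, generate_sensitivity_input
        spec = CohortSpec()
        sens = generate_sensitivity_input(spec)["cases"]
        return float(sens.resistance(spec.diagnosis_time, p.replace(m=spec.m_true)))
    return R_overt


def construct_disease_state(stage: str, p: KineticParameters,
                            calib: CalibrationResult | AnchorConditions | None = None,
                            R_overt: float | None = None) -> SystemState:
    """A representative model state for a disease stage.

    ``compensation`` — the calibrated pre-diabetic anchor state.  ``mild`` —
    the state reached 6 years after the IL-1β switch (post-switch branch).
    ``strong`` — 11 years after the switch, with (L, A) re-assigned to the
    highest-IL-1β stable equilibrium at the current glucose (the advanced
    disease branch, which has a lower endogenous IL-1Ra level).
    """
    anchors = (calib.anchors if isinstance(calib, CalibrationResult)
               else calib) or AnchorConditions()
    if stage == "compensation":
        I, B = dbss_initial_state(anchors.G_comp, p.R0, p)
        return SystemState(t=0.0, G=anchors.G_comp, I=I, B=B,
                           L=anchors.L_comp, A=anchors.A_comp)
    if stage not in STAGE_YEARS:
        raise ValueError(f"unknown stage {stage!r}")
    R = _overt_resistance(p, R_overt)
    # start on the post-switch branch at the bifurcation glucose
    eqs = find_equilibria(anchors.G_bif + 0.02, p)
    stable = sorted((e for e in eqs if e.stable), key=lambda e: e.L_star)
    if not stable:
        raise AnalysisError("no stable post-switch equilibrium")
    mid = stable[0]
    I, B0 = dbss_initial_state(anchors.G_bif, p.R0, p)
    init = SystemState(t=0.0, G=anchors.G_bif, I=I, B=B0,
                       L=mid.L_star, A=mid.A_star)
    traj = simulate(init, R, STAGE_YEARS[stage] * DAYS_PER_YEAR, p,
                    mode="qssa", n_out=200)
    state = traj.final_state()
    if stage == "mild":
        return state
    eqs = find_equilibria(state.G, p)
    stable = sorted((e for e in eqs if e.stable), key=lambda e: e.L_star)
    if len(stable) < 2:
        raise AnalysisError(f"no distinct advanced branch at G={state.G:.4g}")
    top = stable[-1]
    return SystemState(t=state.t, G=state.G, I=state.I, B=state.B,
                       L=top.L_star, A=top.A_star)


def simulate_therapy(initial: SystemState, protocol: TherapyProtocol,
                     R_input, horizon: float, p: KineticParameters,
                     n_out: int = 300) -> Trajectory:
    """Integrate the full model under a clamp protocol.

    Within a segment the clamped variables are frozen at the prescribed
    levels (their derivatives suspended); outside segments all five ODEs
    evolve.  Clamp boundaries are logged as events.
    """
    Rfn = _resistance_fn(R_input, p)
    boundaries = [initial.t]
    for start, end, _ in protocol.segments:
        boundaries.extend([start, end])
    t_end = initial.t + horizon
    boundaries = sorted({b for b in boundaries if initial.t <= b <= t_end})
    if boundaries[-1] < t_end:
        boundaries.append(t_end)
    t_eval_all = np.linspace(initial.t, t_end, n_out)

    def active_clamps(t: float) -> dict[str, float]:
        for start, end, clamps in protocol.segments:
            if start <= t < end:
                return clamps
        return {}

    idx = {"G": 0, "A": 4}
    y = initial.as_vector()
    events: list[tuple[float, str]] = []
    t_rec: list[float] = []
    rows: list[np.ndarray] = []
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        clamps = active_clamps(0.5 * (t0 + t1))
        for name, level in clamps.items():
            y[idx[name]] = level
        if clamps:
            events.append((t0, "clamp-on"))

        def rhs(t, yy, clamps=clamps):
            yy = np.maximum(yy, 0.0)
            d = rhs_full(yy, Rfn(t), p)
            for name in clamps:
                d[idx[name]] = 0.0
            return d

        te = np.unique(np.concatenate(
            [t_eval_all[(t_eval_all >= t0) & (t_eval_all <= t1)], [t1]]))
        sol = solve_ivp(rhs, (t0, t1), y, method="BDF", t_eval=te,
                        rtol=1e-8, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"therapy integration failed at t={sol.t[-1]:.2f}: "
                               f"{sol.message}")
        for ti, yi in zip(sol.t, sol.y.T):
            if not t_rec or ti > t_rec[-1] + 1e-9:
                t_rec.append(float(ti))
                rows.append(yi)
        y = sol.y[:, -1].copy()
        if clamps:
            events.append((t1, "clamp-off"))
    arr = np.maximum(np.array(rows), 0.0)
    G, I, B, L, A = arr.T
    F = kin.receptor_occupancy(L, A, p)
    frame = pd.DataFrame(dict(zip(TRAJECTORY_COLUMNS,
                                  [np.array(t_rec), G, I, B, L, A, F])))
    return Trajectory(frame=frame, events=events)


def threshold_dose(G: float, p: KineticParameters,
                   L_range: tuple[float, float] = (1e-2, 5e3)) -> float:
    """IL-1Ra level above which only the low-IL-1β fast state remains.

    The IL-1β nullcline A(L) falls from a vertical asymptote at the purely
    glucose-driven root, passes a nadir and rises to an interior peak before
    decaying — the typical auto-stimulation profile.  Clamping IL-1Ra above
    that interior peak leaves a single low-L intersection, so IL-1β resets
    to low levels regardless of history; the peak height is the threshold.
    """
    curves = nullclines(G, p, L_range=L_range, n_points=2000)
    l_null = curves["il1b"]
    if len(l_null) < 5:
        raise AnalysisError(f"IL-1β nullcline has no solution at G={G:.4g}")
    L = l_null["L_pg_ml"].to_numpy()
    A = l_null["A_pg_ml"].to_numpy()
    dA = np.diff(A)
    turns = np.nonzero(np.sign(dA[:-1]) != np.sign(dA[1:]))[0] + 1
    minima = [i for i in turns if A[i] <= A[i - 1] and A[i] <= A[i + 1]]
    if not minima:
        raise AnalysisError(f"IL-1β nullcline has no nadir at G={G:.4g}; "
                            "no fold threshold exists")
    nadir = minima[0]
    i_peak = nadir + int(np.argmax(A[nadir:]))
    if i_peak + 1 >= len(A):
        raise AnalysisError("IL-1β nullcline peak not bracketed; widen L_range")

    def neg_A(lnL: float) -> float:
        Lx = math.exp(lnL)
        g = kin.glucose_stim(G, p)
        y = (p.dL * Lx / kin.mrna_inhibition(Lx, p) - p.k5 * g) / p.k6
        if not 0.0 < y < 1.0:
            return 0.0
        F = p.KF * (y / (1.0 - y)) ** (1.0 / p.t_hill)
        if not 0.0 < F < 1.0:
            return 0.0
        return -kin.occupancy_to_ilra(Lx, F, p)

    res = minimize_scalar(neg_A, bounds=(math.log(L[i_peak - 1]),
                                         math.log(L[i_peak + 1])),
                          method="bounded", options={"xatol": 1e-12})
    return float(-res.fun)


def dose_sweep(stage: str, doses=None, p: KineticParameters | None = None,
               calib: CalibrationResult | AnchorConditions | None = None,
               duration: float = 90.0,
               R_overt: float | None = None) -> DoseResponseResult:
    """Glycaemia improvement after a fixed-duration IL-1Ra clamp, per dose.

    For each dose the disease-stage state is simulated for ``duration`` days
    with IL-1Ra clamped; the untreated control runs from the same initial
    state.  Improvement is the control-minus-treated end glucose.  The sweep
    exhibits a jump at the nullcline-peak threshold dose and an interior
    optimum above it.  When ``doses`` is omitted a log-spaced grid around
    the stage's threshold dose is used.
    """
    p = p or KineticParameters()
    initial = construct_disease_state(stage, p, calib, R_overt)
    if doses is None:
        thr = threshold_dose(initial.G, p)
        doses = np.concatenate([thr * np.geomspace(0.25, 0.97, 8),
                                [thr * 1.01], thr * np.geomspace(1.1, 3.0, 6)])
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    R = _overt_resistance(p, R_overt)
    control = simulate(initial, R, duration, p, mode="stiff-full", n_out=50)
    G_control = float(control.G[-1])
    rows = []
    for dose in doses:
        protocol = TherapyProtocol.single(initial.t, initial.t + duration, A=dose)
        traj = simulate_therapy(initial, protocol, R, duration, p, n_out=50)
        G_treated = float(traj.G[-1])
        rows.append((dose, G_treated, G_control, G_control - G_treated))
    table = pd.DataFrame(rows, columns=["dose_pg_ml", "G_treated_end_mM",
                                        "G_control_end_mM", "improvement_mM"])
    return DoseResponseResult(stage=stage, duration=duration, table=table)
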