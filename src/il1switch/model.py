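"""State containers, ODE right-hand sides and the two integrators.

The model couples three timescales:

* fast — islet IL-1β (``L``) and IL-1Ra (``A``), turnover of minutes–hours;
* intermediate — fasting glucose ``G`` and insulin ``I`` (days);
* slow — β-cell mass ``B`` (months–years).

``simulate(..., mode="stiff-full")`` integrates all five ODEs with a stiff
solver.  ``mode="qssa"`` exploits the separation: (L, A) are pinned to a
stable equilibrium branch of the fast subsystem at the current glucose,
tracked by continuity; when the occupied branch disappears (saddle-node),
the fast subsystem is relaxed by short time integration from the pre-jump
state and a ``branch-jump`` event is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from . import kinetics as kin
from .params import KineticParameters

__all__ = [
    "SystemState", "SensitivityInput", "Trajectory",
    "rhs_full", "fast_rhs", "fast_jacobian", "reduced_residual",
    "reduced_residual_deriv", "relax_fast_subsystem", "FastBranchTracker", "simulate",
]

TRAJECTORY_COLUMNS = ["t_days", "G_mM", "I_pM", "B_mg", "L_pg_ml", "A_pg_ml", "F"]


@dataclass(frozen=True)
class SystemState:
    """Full model state at one instant (units: d, mM, pM, mg, pg/ml)."""
    t: float
    G: float
    I: float
    B: float
    L: float
    A: float

    def __post_init__(self):
        for name in ("G", "I", "B", "L", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"state variable {name} must be non-negative")

    def occupancy(self, p: KineticParameters) -> float:
        return kin.receptor_occupancy(self.L, self.A, p)

    def as_vector(self) -> np.ndarray:
        return np.array([self.G, self.I, self.B, self.L, self.A])


class SensitivityInput:
    """Longitudinal HOMA2 %S insulin-sensitivity input.

    Samples are interpolated with a monotone piecewise-cubic (PCHIP) rule and
    held constant beyond either end.  ``resistance(t, p)`` converts to the
    model's insulin-resistance parameter R via the log-linear HOMA mapping,
    anchored at the first sample unless an explicit baseline is given.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float],
                 baseline: float | None = None):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.size < 1 or t.shape != v.shape:
            raise ValueError("times and values must be equal-length 1-D sequences")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("insulin sensitivity must be strictly positive")
        self.times = t
        self.values = v
        self.baseline = float(v[0]) if baseline is None else float(baseline)
        self._interp = PchipInterpolator(t, v, extrapolate=False) if t.size > 1 else None

    @classmethod
    def constant(cls, value: float) -> "SensitivityInput":
        return cls([0.0], [value])

    def value(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self._interp is None:
            out = np.full(t.shape, self.values[0])
        else:
            out = self._interp(np.clip(t, self.times[0], self.times[-1]))
        return out if out.ndim else float(out)

    def resistance(self, t, p: KineticParameters):
        return kin.homa_to_resistance(self.value(t), self.baseline, p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_days": self.times, "S_H_percent": self.values})


def _resistance_fn(R_input, p: KineticParameters) -> Callable[[float], float]:
    if isinstance(R_input, SensitivityInput):
        return lambda t: R_input.resistance(t, p)
    R = float(R_input)
    if R <= 0:
        raise ValueError("insulin resistance must be positive")
    return lambda t: R


@dataclass
class Trajectory:
    """Time-ordered model output plus discrete events.

    ``frame`` has columns ``t_days G_mM I_pM B_mg L_pg_ml A_pg_ml F``;
    ``events`` is a list of ``(time, kind)`` with kind in
    {branch-jump, clamp-on, clamp-off}.
    """
    frame: pd.DataFrame
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        t = self.frame["t_days"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError("trajectory times must be non-decreasing")

    @property
    def t(self) -> np.ndarray:
        return self.frame["t_days"].to_numpy()

    def __getattr__(self, name: str):
        cols = {"G": "G_mM", "I": "I_pM", "B": "B_mg", "L": "L_pg_ml",
                "A": "A_pg_ml", "F": "F"}
        if name in cols:
            return self.frame[cols[name]].to_numpy()
        raise AttributeError(name)

    def final_state(self) -> SystemState:
        row = self.frame.iloc[-1]
        return SystemState(t=row["t_days"], G=row["G_mM"], I=row["I_pM"],
                           B=row["B_mg"], L=row["L_pg_ml"], A=row["A_pg_ml"])

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t_days", "event"])


# ---------------------------------------------------------------------------
# right-hand sides

def rhs_full(state: SystemState | Sequence[float], R: float, p: KineticParameters):
    """Time derivatives (dG, dI, dB, dL, dA) of the full five-variable model."""
    if isinstance(state, SystemState):
        G, I, B, L, A = state.as_vector()
    else:
        G, I, B, L, A = (float(x) for x in state)
    if R <= 0:
        raise ValueError("insulin resistance must be positive")
    F = kin.receptor_occupancy(L, A, p)
    dG = p.r0 - (p.dG + I / R) * G
    dI = p.h * B * kin.insulin_secretion_factor(G, p) - p.dI * I
    dB = p.tau * B * kin.net_beta_growth(F, p) if (B > 0 and F > 0) else 0.0
    dL = kin.mrna_inhibition(L, p) * (
        p.k5 * kin.glucose_stim(G, p) + p.k6 * kin.autostim(F, p)) - p.dL * L
    dA = kin.ilra_production(L, p) - p.dA * A
    return np.array([dG, dI, dB, dL, dA])


def fast_rhs(L: float, A: float, G: float, p: KineticParameters):
    """(dL/dt, dA/dt) of the fast IL-1β/IL-1Ra subsystem at fixed glucose."""
    F = kin.receptor_occupancy(L, A, p)
    dL = kin.mrna_inhibition(L, p) * (
        p.k5 * kin.glucose_stim(G, p) + p.k6 * kin.autostim(F, p)) - p.dL * L
    dA = kin.ilra_production(L, p) - p.dA * A
    return np.array([dL, dA])


def fast_jacobian(L: float, A: float, G: float, p: KineticParameters) -> np.ndarray:
    """Analytic 2×2 Jacobian of the fast subsystem at (L, A)."""
    F = kin.receptor_occupancy(L, A, p)
    b = kin.mrna_inhibition(L, p)
    db = kin.mrna_inhibition_deriv(L, p)
    lF = kin.autostim(F, p)
    dl = kin.autostim_deriv(F, p)
    FL, FA = kin.occupancy_partials(L, A, p)
    prod = p.k5 * kin.glucose_stim(G, p) + p.k6 * lF
    j11 = db * prod + b * p.k6 * dl * FL - p.dL
    j12 = b * p.k6 * dl * FA
    j21 = kin.ilra_production_deriv(L, p)
    j22 = -p.dA
    return np.array([[j11, j12], [j21, j22]], dtype=float)


def reduced_residual(L, G: float, p: KineticParameters):
    """Scalar equilibrium residual of the fast subsystem.

    On the IL-1Ra nullcline A = production(L)/dA, so fast-subsystem equilibria
    are exactly the roots in L of this residual (units pg/ml/d).
    """
    L = np.asarray(L, dtype=float)
    A = kin.ilra_production(L, p) / p.dA
    F = kin.receptor_occupancy(L, A, p)
    out = kin.mrna_inhibition(L, p) * (
        p.k5 * kin.glucose_stim(G, p) + p.k6 * kin.autostim(F, p)) - p.dL * L
    return out if out.ndim else float(out)


def reduced_residual_deriv(L: float, G: float, p: KineticParameters) -> float:
    A = kin.ilra_production(L, p) / p.dA
    dAdL = kin.ilra_production_deriv(L, p) / p.dA
    F = kin.receptor_occupancy(L, A, p)
    FL, FA = kin.occupancy_partials(L, A, p)
    b = kin.mrna_inhibition(L, p)
    db = kin.mrna_inhibition_deriv(L, p)
    prod = p.k5 * kin.glucose_stim(G, p) + p.k6 * kin.autostim(F, p)
    dprod = p.k6 * kin.autostim_deriv(F, p) * (FL + FA * dAdL)
    return float(db * prod + b * dprod - p.dL)


def _scalar_residual(L: float, G: float, p: KineticParameters,
                     with_deriv: bool = False):
    """Pure-scalar reduced residual (and optional dres/dL) — hot path.

    Identical to :func:`reduced_residual` but avoids array dispatch; used by
    the branch tracker's Newton iteration.
    """
    x = L / p.k3
    phi = x / (1.0 + x * x)
    prodA = p.k1 + p.k2 * phi
    A = prodA / p.dA
    dL_KL = L / p.KL
    D = 1.0 + dL_KL + A / p.KA
    F = dL_KL / D
    z = p.k4 * L / p.u
    zr = z**p.r
    b = 1.0 / (1.0 + zr)
    kt = p.KF**p.t_hill
    ft = F**p.t_hill
    l = ft / (kt + ft)
    g = kin.glucose_stim(G, p)
    prod = p.k5 * g + p.k6 * l
    res = b * prod - p.dL * L
    if not with_deriv:
        return res
    dAdL = (p.k2 / p.k3) * (1.0 - x * x) / (1.0 + x * x) ** 2 / p.dA
    FL = (1.0 / p.KL) * (1.0 + A / p.KA) / D**2
    FA = -dL_KL / p.KA / D**2
    db = -(p.r * zr / L) / (1.0 + zr) ** 2 if L > 0 else 0.0
    dl = p.t_hill * kt * F ** (p.t_hill - 1.0) / (kt + ft) ** 2
    dres = db * prod + b * p.k6 * dl * (FL + FA * dAdL) - p.dL
    return res, dres


def relax_fast_subsystem(L0: float, A0: float, G: float, p: KineticParameters,
                         duration: float = 2.0) -> tuple[float, float]:
    """Time-integrate the fast subsystem at fixed G to (near) its attractor."""
    sol = solve_ivp(lambda t, y: fast_rhs(max(y[0], 0.0), max(y[1], 0.0), G, p),
                    (0.0, duration), [L0, A0], method="BDF",
                    rtol=1e-8, atol=[1e-9, 1e-6])
    if not sol.success:
        raise RuntimeError(f"fast-subsystem relaxation failed: {sol.message}")
    return float(sol.y[0, -1]), float(sol.y[1, -1])


class FastBranchTracker:
    """Follows one equilibrium branch of the fast subsystem by continuity.

    Newton iteration in ln L on the reduced residual, seeded from the last
    occupied equilibrium.  When the iteration fails or lands more than
    ``jump_tol`` away in ln L (the occupied branch has disappeared at a
    fold), the new branch is found by relaxing the fast subsystem from the
    pre-jump state and the jump is logged.
    """

    #: branches reported in the bifurcation structure are ≥ ln 55.8 ≈ 4 apart
    jump_tol = 1.0

    def __init__(self, L0: float, A0: float, G0: float, p: KineticParameters):
        self.p = p
        self.events: list[tuple[float, str]] = []
        # fast path: the seed usually sits on (or near) a stable branch
        L = self._newton(math.log(max(L0, 1e-12)), G0)
        if L is not None and _scalar_residual(L, G0, p, with_deriv=True)[1] >= 0:
            L = None                      # converged to a saddle — not a basin
        if L is None:
            Lr, _ = relax_fast_subsystem(L0, A0, G0, p)
            L = self._newton(math.log(max(Lr, 1e-12)), G0)
            if L is None:
                L_land = self._next_attractor(max(Lr, 1e-12), G0)
                L = None if L_land is None else self._newton(math.log(L_land), G0)
            if L is None:
                raise RuntimeError(
                    "initial (L, A) is not in the basin of a fast equilibrium")
        self.L = L
        self.A = kin.ilra_production(L, p) / p.dA

    def _newton(self, lnL: float, G: float, max_iter: int = 50) -> float | None:
        for _ in range(max_iter):
            L = math.exp(lnL)
            f, df_dL = _scalar_residual(L, G, self.p, with_deriv=True)
            df = df_dL * L                                  # d/d lnL
            if df == 0:
                return None
            step = f / df
            step = max(min(step, 0.5), -0.5)
            lnL -= step
            if abs(step) < 1e-13:
                return math.exp(lnL)
        return None

    def _next_attractor(self, L_prev: float, G: float) -> float | None:
        """Stable root reached by the 1-D flow from L_prev after a fold.

        The fast subsystem relaxes onto the IL-1Ra nullcline quickly, after
        which L follows the sign of the reduced residual; the occupied state
        after a branch disappears is therefore the adjacent stable root in
        the flow direction.  (Direct time integration is unreliable here:
        trajectories linger in the saddle-node ghost for a long time.)
        """
        grid = np.geomspace(1e-4, 1e6, 2000)
        res = reduced_residual(grid, G, self.p)
        sign = np.sign(res)
        roots = []
        for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
            stable = res[i] > 0 > res[i + 1]     # downward crossing
            if stable:
                lo, hi = grid[i], grid[i + 1]
                for _ in range(60):
                    mid = math.sqrt(lo * hi)
                    if reduced_residual(mid, G, self.p) > 0:
                        lo = mid
                    else:
                        hi = mid
                roots.append(math.sqrt(lo * hi))
        if not roots:
            return None
        f_prev = reduced_residual(L_prev, G, self.p)
        if f_prev > 0:
            above = [r for r in roots if r > L_prev]
            return min(above) if above else max(roots)
        below = [r for r in roots if r < L_prev]
        return max(below) if below else min(roots)

    def update(self, t: float, G: float) -> tuple[float, float]:
        lnL_prev = math.log(self.L)
        root = self._newton(lnL_prev, G)
        if root is None or abs(math.log(root) - lnL_prev) > self.jump_tol:
            landing = self._next_attractor(self.L, G)
            root = None if landing is None else self._newton(math.log(landing), G)
            if root is None:
                raise RuntimeError(f"no fast-subsystem equilibrium found at G={G:.4g}")
            if abs(math.log(root) - lnL_prev) > self.jump_tol and (
                    not self.events or t - self.events[-1][0] > 1.0):
                self.events.append((t, "branch-jump"))
        self.L = root
        self.A = kin.ilra_production(root, self.p) / self.p.dA
        return self.L, self.A


# ---------------------------------------------------------------------------
# integrators

def _sample_times(t0: float, horizon: float, n_out: int) -> np.ndarray:
    return np.linspace(t0, t0 + horizon, n_out)


def simulate(initial: SystemState, R_input, horizon: float, p: KineticParameters,
             mode: str = "stiff-full", n_out: int = 400,
             rtol: float = 1e-8, atol: float = 1e-9,
             qssa_chunk: float = 15.0) -> Trajectory:
    """Integrate the model forward by ``horizon`` days from ``initial``.

    ``R_input`` is either a :class:`SensitivityInput` (HOMA2 %S trajectory,
    converted internally to insulin resistance) or a constant resistance in
    pM·d.  Output is sampled at ``n_out`` evenly spaced times.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    Rfn = _resistance_fn(R_input, p)
    t_eval = _sample_times(initial.t, horizon, n_out)
    if mode == "stiff-full":
        def rhs(t, y):
            y = np.maximum(y, 0.0)
            return rhs_full(y, Rfn(t), p)
        sol = solve_ivp(rhs, (initial.t, initial.t + horizon), initial.as_vector(),
                        method="BDF", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"stiff integration failed at t={sol.t[-1]:.3f}: {sol.message}")
        G, I, B, L, A = sol.y
        events: list[tuple[float, str]] = []
    elif mode == "qssa":
        # (L, A) are held at the tracked fast equilibrium over short chunks
        # and re-solved at chunk boundaries.  They feed back on the slow
        # variables only through the occupancy F in dB/dt, so freezing them
        # for a few days introduces negligible error while keeping the slow
        # integration smooth and stateless.
        chunk = float(qssa_chunk)
        tracker = FastBranchTracker(initial.L, initial.A, initial.G, p)
        t_rec, rows = [], []
        y = np.array([initial.G, initial.I, initial.B])
        t0 = initial.t
        t_end = initial.t + horizon
        next_sample = 0
        while t0 < t_end - 1e-9:
            t1 = min(t0 + chunk, t_end)
            L, A = tracker.L, tracker.A
            F = kin.receptor_occupancy(L, A, p)
            growth = kin.net_beta_growth(F, p) if F > 0 else 0.0

            def rhs(t, yy, growth=growth):
                G, I, B = np.maximum(yy, 0.0)
                R = Rfn(t)
                dG = p.r0 - (p.dG + I / R) * G
                dI = p.h * B * kin.insulin_secretion_factor(G, p) - p.dI * I
                dB = p.tau * B * growth if B > 0 else 0.0
                return [dG, dI, dB]

            samples = [tv for tv in t_eval[next_sample:] if t0 - 1e-9 <= tv < t1]
            te = np.unique(np.concatenate([samples, [t1]]))
            sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=te,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(
                    f"QSSA integration failed at t={sol.t[-1]:.3f}: {sol.message}")
            for ti, yi in zip(sol.t, sol.y.T):
                if next_sample < len(t_eval) and abs(ti - t_eval[next_sample]) < 1e-6:
                    t_rec.append(ti)
                    rows.append([yi[0], yi[1], yi[2], L, A])
                    next_sample += 1
            y = sol.y[:, -1]
            t0 = t1
            tracker.update(t1, max(y[0], 0.0))
        if next_sample < len(t_eval):  # horizon endpoint
            t_rec.append(t_end)
            rows.append([y[0], y[1], y[2], tracker.L, tracker.A])
        arr = np.array(rows)
        G, I, B, L, A = arr.T
        sol_t = np.array(t_rec)
        F = kin.receptor_occupancy(np.maximum(L, 0.0), np.maximum(A, 0.0), p)
        frame = pd.DataFrame(dict(zip(TRAJECTORY_COLUMNS, [sol_t, G, I, B, L, A, F])))
        return Trajectory(frame=frame, events=list(tracker.events))
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'stiff-full' or 'qssa'")

    F = kin.receptor_occupancy(np.maximum(L, 0.0), np.maximum(A, 0.0), p)
    frame = pd.DataFrame(dict(zip(TRAJECTORY_COLUMNS, [sol.t, G, I, B, L, A, F])))
    return Trajectory(frame=frame, events=events)
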