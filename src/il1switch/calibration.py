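"""Parameter determination from steady-state anchors and longitudinal data.

The production constants k1–k6 are fixed by requiring that the fast
IL-1β/IL-1Ra subsystem is at equilibrium in three anchored states:
compensation (G=5.47 mM, L=12, A=6000 pg/ml), the bifurcation state
(G=5.84 mM, L_b and A_b free) and overt diabetes (G=13.4 mM, L=12·55.8,
A=6000·1.8).  The six equations decouple: the IL-1Ra balance at the three
anchors determines (k1, k2, k3) and the IL-1β balance determines
(k4, k5, k6); given k3 (resp. k4) the remaining two constants follow
linearly from the compensation and diabetes rows, leaving one scalar root
problem per side.

(L_b, A_b) themselves are free and are restricted by the requirement that a
saddle-node of the low-IL-1β branch exists at the bifurcation glucose and
that the switch reaches the measured 55.8-fold IL-1β increase: random
scanning of the (L_b, A_b) plane maps the feasible region, and the final
calibration refines (L_b, k3, k4) at fixed A_b so that the bifurcation
anchor sits exactly on the fold (zero derivative of the reduced equilibrium
residual, equivalently zero Jacobian determinant).

λ follows from requiring β-cell proliferation/apoptosis balance at healthy
glucose, and the last two free parameters (m, τ) are fitted to the fasting
glucose history by differential evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import kinetics as kin
from .equilibria import (AnalysisError, NoFoldError, critical_glucose,
                         find_equilibria, track_branch)
from .model import (SensitivityInput, SystemState, fast_rhs,
                    reduced_residual, reduced_residual_deriv,
                    relax_fast_subsystem)
from .params import KineticParameters

__all__ = [
    "AnchorConditions", "CalibrationResult", "CalibrationError",
    "estimate_tissue_levels", "solve_rate_constants", "scan_bifurcation_plane",
    "derive_lambda", "dbss_initial_state", "calibrate",
    "fit_dose_response", "fit_history", "reduced_fit",
    "HistoryFit", "ReducedFit",
]


class CalibrationError(RuntimeError):
    """No feasible calibration found."""


@dataclass(frozen=True)
class AnchorConditions:
    """Steady-state anchors of the IL-1β/IL-1Ra subsystem.

    Compensation and diabetes fix (G, L, A); the bifurcation anchor fixes
    only G, with (L_b, A_b) determined by the calibration.  Fold changes are
    relative to the compensation values.
    """
    G_comp: float = 5.47
    L_comp: float = 12.0
    A_comp: float = 6000.0
    G_bif: float = 5.84
    G_diab: float = 13.4
    L_fold_change: float = 55.8
    A_fold_change: float = 1.8
    healthy_G: float = 4.5
    tissue_blood_ratio: float = 20.0
    ilra_il1b_ratio: float = 500.0

    def __post_init__(self):
        if not (self.healthy_G < self.G_comp < self.G_bif < self.G_diab):
            raise ValueError("anchor glucose levels must be ordered "
                             "healthy < compensation < bifurcation < diabetes")
        if self.L_fold_change <= 1 or self.A_fold_change <= 1:
            raise ValueError("diabetic L and A must exceed compensation values")

    @property
    def L_diab(self) -> float:
        return self.L_comp * self.L_fold_change

    @property
    def A_diab(self) -> float:
        return self.A_comp * self.A_fold_change


@dataclass
class CalibrationResult:
    """Outcome of the steady-state calibration."""
    params: KineticParameters            # with re-derived k1–k6 and λ
    anchors: AnchorConditions
    L_b: float
    A_b: float
    lam: float
    G_fold: float
    fold_change_L: float                 # post-switch L at diabetic G / L_comp
    fold_change_A: float
    anchor_residuals: dict[str, float]   # max |d/dt| per anchor, own units/day
    high_branch_birth_G: float           # G where the post-switch branch first exists
    scan: pd.DataFrame | None = None

    @property
    def switch_fold_change(self) -> float:
        return self.fold_change_L


def estimate_tissue_levels(serum_ilra: float, ratio_ilra_il1b: float = 500.0,
                           tissue_blood_ratio: float = 20.0
                           ) -> tuple[float, float, float]:
    """Infer islet cytokine levels from a serum IL-1Ra measurement.

    Serum IL-1β follows from the IL-1Ra/IL-1β concentration ratio; islet
    levels are ``tissue_blood_ratio``-fold the serum levels (locally produced,
    short half-life).  Returns (L_islet, A_islet, L_serum) in pg/ml.
    """
    if min(serum_ilra, ratio_ilra_il1b, tissue_blood_ratio) <= 0:
        raise ValueError("all concentration inputs must be positive")
    L_serum = serum_ilra / ratio_ilra_il1b
    return L_serum * tissue_blood_ratio, serum_ilra * tissue_blood_ratio, L_serum


def _phi(L, k3):
    x = np.asarray(L, dtype=float) / k3
    return x / (1.0 + x**2)


def _ilra_side(anchors: AnchorConditions, L_b: float, A_b: float,
               p: KineticParameters, k3: float) -> tuple[float, float, float]:
    """(k1, k2, residual at the bifurcation anchor) for a given k3."""
    pc, pd_ = _phi(anchors.L_comp, k3), _phi(anchors.L_diab, k3)
    if abs(pd_ - pc) < 1e-30:
        return math.nan, math.nan, math.nan
    k2 = p.dA * (anchors.A_diab - anchors.A_comp) / (pd_ - pc)
    k1 = p.dA * anchors.A_comp - k2 * pc
    resid = k1 + k2 * _phi(L_b, k3) - p.dA * A_b
    return k1, k2, resid


def _il1b_side(anchors: AnchorConditions, L_b: float, A_b: float,
               p: KineticParameters, k4: float) -> tuple[float, float, float]:
    """(k5, k6, residual at the bifurcation anchor) for a given k4."""
    def beta(L):
        return p.dL * L * (1.0 + (k4 * L / p.u) ** p.r)

    g = [kin.glucose_stim(G, p) for G in (anchors.G_comp, anchors.G_bif, anchors.G_diab)]
    F = [kin.receptor_occupancy(anchors.L_comp, anchors.A_comp, p),
         kin.receptor_occupancy(L_b, A_b, p),
         kin.receptor_occupancy(anchors.L_diab, anchors.A_diab, p)]
    l = [kin.autostim(f, p) for f in F]
    M = np.array([[g[0], l[0]], [g[2], l[2]]])
    rhs = np.array([beta(anchors.L_comp), beta(anchors.L_diab)])
    det = np.linalg.det(M)
    if abs(det) < 1e-30:
        return math.nan, math.nan, math.nan
    k5, k6 = np.linalg.solve(M, rhs)
    resid = k5 * g[1] + k6 * l[1] - beta(L_b)
    return float(k5), float(k6), float(resid)


def _scalar_roots(fun: Callable[[float], float], grid: np.ndarray) -> list[float]:
    vals = np.array([fun(x) for x in grid])
    roots = []
    ok = np.isfinite(vals)
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
            roots.append(optimize.brentq(fun, grid[i], grid[i + 1],
                                         xtol=1e-12, rtol=1e-14))
    return roots


def solve_rate_constants(anchors: AnchorConditions, L_b: float, A_b: float,
                         p: KineticParameters) -> list[dict[str, float]]:
    """All non-negative (k1…k6) making the three anchors fast equilibria.

    Given (L_b, A_b) the two decoupled sides each reduce to a scalar root
    problem (in k3 and k4); every combination of feasible side solutions is
    returned.  An empty list means the candidate (L_b, A_b) is infeasible.
    """
    if L_b <= 0 or A_b <= 0:
        raise ValueError("L_b and A_b must be positive")
    close_c = abs(L_b - anchors.L_comp) < 1e-9 * anchors.L_comp
    close_d = abs(L_b - anchors.L_diab) < 1e-9 * anchors.L_diab
    if close_c or close_d:
        raise CalibrationError("bifurcation anchor duplicates another anchor: "
                               "the six steady-state equations are singular")
    k3_grid = np.geomspace(1e-1, 1e8, 200)
    k4_grid = np.geomspace(1e-6, 1e3, 200)
    a_solutions = []
    for k3 in _scalar_roots(lambda k3: _ilra_side(anchors, L_b, A_b, p, k3)[2], k3_grid):
        k1, k2, _ = _ilra_side(anchors, L_b, A_b, p, k3)
        if k1 >= 0 and k2 >= 0:
            a_solutions.append((k1, k2, k3))
    l_solutions = []
    for k4 in _scalar_roots(lambda k4: _il1b_side(anchors, L_b, A_b, p, k4)[2], k4_grid):
        k5, k6, _ = _il1b_side(anchors, L_b, A_b, p, k4)
        if k5 >= 0 and k6 >= 0:
            l_solutions.append((k4, k5, k6))
    out = []
    for k1, k2, k3 in a_solutions:
        for k4, k5, k6 in l_solutions:
            out.append(dict(k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6))
    return out


def anchor_residuals(p: KineticParameters, anchors: AnchorConditions,
                     L_b: float, A_b: float) -> dict[str, float]:
    """Max |dL/dt|, |dA/dt| (relative to turnover) at each anchor state."""
    out = {}
    states = {"compensation": (anchors.G_comp, anchors.L_comp, anchors.A_comp),
              "bifurcation": (anchors.G_bif, L_b, A_b),
              "diabetes": (anchors.G_diab, anchors.L_diab, anchors.A_diab)}
    for name, (G, L, A) in states.items():
        dL, dA = fast_rhs(L, A, G, p)
        out[name] = max(abs(dL) / (p.dL * L), abs(dA) / (p.dA * A))
    return out


# ---------------------------------------------------------------------------
# feasibility scan of the (L_b, A_b) plane

def _count_roots(G: float, p: KineticParameters, n: int = 500) -> int:
    grid = np.geomspace(1e-4, 1e6, n)
    res = reduced_residual(grid, G, p)
    sign = np.sign(res)
    return int(np.sum(sign[:-1] * sign[1:] < 0))


def _landing_branch_L(p: KineticParameters, anchors: AnchorConditions,
                      L_from: float, G_start: float) -> float | None:
    """L of the branch occupied after the switch, continued to the diabetic G."""
    grid = np.geomspace(1e-4, 1e6, 800)
    res = reduced_residual(grid, G_start, p)
    sign = np.sign(res)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = []
    for i in idx:
        roots.append(optimize.brentq(lambda L: reduced_residual(L, G_start, p),
                                     grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12))
    above = [r for r in roots if r > L_from * 1.05]
    if not above:
        return None
    landing = min(above)
    try:
        L_diab, _ = track_branch(landing, G_start, anchors.G_diab, p, n_steps=30)
    except AnalysisError:
        return None
    return L_diab


def scan_bifurcation_plane(anchors: AnchorConditions, p: KineticParameters,
                           n_random: int = 20000, seed: int = 0,
                           Lb_rel_range: tuple[float, float] = (1.0, 60.0),
                           Ab_rel_range: tuple[float, float] = (0.5, 3.0),
                           ) -> pd.DataFrame:
    """Feasibility map of the (L_b, A_b) plane.

    Uniform random candidates (normalised to the compensation values) are
    classified as ``infeasible`` (no non-negative k1–k6), ``no-switch``
    (calibrated subsystem keeps the same number of equilibria on both sides
    of the bifurcation glucose) or ``switch``; for switch points the
    post-switch IL-1β fold change at the diabetic glucose is recorded.
    """
    rng = np.random.default_rng(seed)
    Lb = anchors.L_comp * rng.uniform(*Lb_rel_range, size=n_random)
    Ab = anchors.A_comp * rng.uniform(*Ab_rel_range, size=n_random)
    rows = []
    for L_b, A_b in zip(Lb, Ab):
        label, fc = "infeasible", math.nan
        for ks in solve_rate_constants(anchors, L_b, A_b, p):
            cand = p.replace(**ks)
            # switch = the compensation branch is annihilated at a fold
            # (vanishing Jacobian determinant) before the diabetic glucose,
            # with the equilibrium count dropping by two across it
            try:
                G_fold, fold_eq = critical_glucose(
                    cand, (anchors.G_comp, anchors.G_diab), tol=1e-3)
            except (AnalysisError, NoFoldError):
                if label != "switch":
                    label = "no-switch"
                continue
            if _count_roots(G_fold - 0.02, cand) != _count_roots(G_fold + 0.02,
                                                                 cand) + 2:
                if label != "switch":
                    label = "no-switch"
                continue
            label = "switch"
            L_diab = _landing_branch_L(cand, anchors, fold_eq.L_star,
                                       G_fold + 0.02)
            fc_cand = L_diab / anchors.L_comp if L_diab else math.nan
            if math.isnan(fc) or (not math.isnan(fc_cand)
                                  and abs(fc_cand - anchors.L_fold_change)
                                  < abs(fc - anchors.L_fold_change)):
                fc = fc_cand
        rows.append((L_b / anchors.L_comp, A_b / anchors.A_comp, label, fc))
    return pd.DataFrame(rows, columns=["Lb_rel", "Ab_rel", "label", "fold_change_L"])


# ---------------------------------------------------------------------------
# fold-anchored calibration

def _fold_system(anchors: AnchorConditions, A_b: float, p: KineticParameters
                 ) -> Callable[[np.ndarray], np.ndarray]:
    """Residuals for unknowns x = (ln L_b, ln k3, ln k4) at fixed A_b.

    Equations: IL-1Ra balance at the bifurcation anchor, IL-1β balance at the
    bifurcation anchor, and the saddle-node condition (zero derivative of the
    reduced equilibrium residual) at (L_b, A_b, G_bif).
    """
    def residuals(x: np.ndarray) -> np.ndarray:
        if np.any(np.abs(x) > 25.0) or not np.all(np.isfinite(x)):
            return np.full(3, 1e6)
        L_b, k3, k4 = np.exp(x)
        try:
            k1, k2, rA = _ilra_side(anchors, L_b, A_b, p, k3)
            k5, k6, rL = _il1b_side(anchors, L_b, A_b, p, k4)
            if not np.isfinite(rA) or not np.isfinite(rL):
                return np.full(3, 1e6)
            cand = p.replace(k1=max(k1, 0.0), k2=max(k2, 0.0), k3=k3,
                             k4=k4, k5=max(k5, 0.0), k6=max(k6, 0.0))
            fold = reduced_residual_deriv(L_b, anchors.G_bif, cand)
        except (ValueError, FloatingPointError, OverflowError):
            return np.full(3, 1e6)
        return np.array([rA / (p.dA * A_b), rL / (p.dL * L_b), fold / p.dL])
    return residuals


def _candidate_from_solution(anchors: AnchorConditions, A_b: float,
                             x: np.ndarray, p: KineticParameters
                             ) -> tuple[KineticParameters, float, dict[str, float]] | None:
    L_b, k3, k4 = np.exp(x)
    if not anchors.L_comp * 1.02 < L_b < anchors.L_diab * 0.98:
        return None
    k1, k2, _ = _ilra_side(anchors, L_b, A_b, p, k3)
    k5, k6, _ = _il1b_side(anchors, L_b, A_b, p, k4)
    ks = dict(k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6)
    if any(v < 0 for v in ks.values()):
        return None
    cand = p.replace(**ks)
    # orientation: the anchor must be a pair-annihilation fold (the residual
    # has a local minimum touching zero, so the pair vanishes as G rises)
    h = 1e-4 * L_b
    curv = (reduced_residual(L_b + h, anchors.G_bif, cand)
            - 2 * reduced_residual(L_b, anchors.G_bif, cand)
            + reduced_residual(L_b - h, anchors.G_bif, cand)) / h**2
    if curv <= 0:
        return None
    resid = anchor_residuals(cand, anchors, L_b, A_b)
    if max(resid.values()) > 1e-8:
        return None
    return cand, L_b, resid


def _solve_family(anchors: AnchorConditions, p: KineticParameters, A_b: float,
                  x_seed: np.ndarray | None = None):
    """Solve the fold-anchored system at one A_b.

    Returns (x, params, L_b, residuals) or None.  With ``x_seed`` the root is
    continued from a neighbouring family member; otherwise a coarse
    multi-start over (L_b, k3, k4) is used.
    """
    system = _fold_system(anchors, A_b, p)
    if x_seed is not None:
        seeds = [x_seed]
    else:
        seeds = [np.log([Ls, k3s, k4s])
                 for Ls in anchors.L_comp * np.array([1.1, 1.2, 1.4, 1.8, 2.5, 4.0])
                 for k3s in (1e2, 3e2, 1e3, 1e4, 1e5)
                 for k4s in (1e-2, 3e-2, 0.1, 0.3)]
    for x0 in seeds:
        sol = optimize.root(system, x0, method="hybr",
                            options={"xtol": 1e-12, "maxfev": 400})
        if not sol.success or np.max(np.abs(system(sol.x))) > 1e-9:
            continue
        built = _candidate_from_solution(anchors, A_b, sol.x, p)
        if built is not None:
            return (sol.x, *built)
    return None


def calibrate(anchors: AnchorConditions | None = None,
              p: KineticParameters | None = None,
              n_scan: int = 2000, seed: int = 0,
              fc_tolerance: float = 0.005,
              with_scan: bool = False) -> CalibrationResult:
    """Full steady-state calibration pipeline.

    (L_b, k3, k4) are solved, for candidate IL-1Ra levels A_b, so that the
    bifurcation anchor is an exact saddle-node of the fast subsystem at the
    bifurcation glucose (k1, k2, k5, k6 follow linearly from the other two
    anchors).  Along this one-parameter family the post-switch IL-1β fold
    change at the diabetic glucose grows continuously toward the anchored
    value as A_b approaches the boundary at which the multi-equilibrium
    structure collapses; A_b is bisected toward that boundary until the fold
    change is within ``fc_tolerance`` of the target while the five-state
    structure (three stable states below the fold, two above) survives.
    λ is then re-derived from β-cell balance at healthy glucose.
    """
    anchors = anchors or AnchorConditions()
    p = p or KineticParameters()
    rng = np.random.default_rng(seed)
    target = anchors.L_fold_change

    # establish the family well inside the five-state region
    A_start = anchors.A_comp * 1.05
    found = _solve_family(anchors, p, A_start)
    if found is None:
        raise CalibrationError("fold-anchored family not found near the "
                               "compensation IL-1Ra level")
    x, cand, L_b, resid = found
    best = None                           # (fc_err, A_b, x, cand, L_b, resid, metrics)
    metrics = _assess_candidate(cand, anchors, L_b, A_start)
    if metrics is not None:
        best = (abs(metrics["fold_change_L"] / target - 1), A_start, x, cand,
                L_b, resid, metrics)

    # walk down in A_b until the five-state structure is lost, then bisect
    A_good, x_good = A_start, x
    A_bad = None
    step = anchors.A_comp * 0.01
    A_next = A_start - step
    while A_bad is None and A_next > anchors.A_comp * 0.9:
        found = _solve_family(anchors, p, A_next, x_good)
        metrics = None
        if found is not None:
            x, cand, L_b, resid = found
            metrics = _assess_candidate(cand, anchors, L_b, A_next)
        if metrics is None:
            A_bad = A_next
        else:
            err = abs(metrics["fold_change_L"] / target - 1)
            if best is None or err < best[0]:
                best = (err, A_next, x, cand, L_b, resid, metrics)
            A_good, x_good = A_next, x
            A_next -= step
    if A_bad is not None:
        for _ in range(60):
            if best is not None and best[0] <= fc_tolerance:
                break
            A_mid = 0.5 * (A_good + A_bad)
            if A_good - A_bad < 1e-9 * anchors.A_comp:
                break
            found = _solve_family(anchors, p, A_mid, x_good)
            metrics = None
            if found is not None:
                x, cand, L_b, resid = found
                metrics = _assess_candidate(cand, anchors, L_b, A_mid)
            if metrics is None:
                A_bad = A_mid
            else:
                err = abs(metrics["fold_change_L"] / target - 1)
                if best is None or err < best[0]:
                    best = (err, A_mid, x, cand, L_b, resid, metrics)
                A_good, x_good = A_mid, x

    if best is None:
        raise CalibrationError(
            "no (L_b, A_b) candidate reproduces the anchored switch structure")
    err, A_b, x, cand, L_b, resid, metrics = best
    if err > 0.01:
        raise CalibrationError(
            f"best candidate misses the IL-1β fold-change target by {err:.1%}")
    lam = derive_lambda(cand, healthy_G=anchors.healthy_G)
    final = cand.replace(lam=lam)
    scan = None
    if with_scan:
        scan = scan_bifurcation_plane(anchors, p, n_random=n_scan,
                                      seed=int(rng.integers(2**31 - 1)))
    return CalibrationResult(
        params=final, anchors=anchors, L_b=L_b, A_b=A_b, lam=lam,
        G_fold=metrics["G_fold"], fold_change_L=metrics["fold_change_L"],
        fold_change_A=metrics["fold_change_A"], anchor_residuals=resid,
        high_branch_birth_G=metrics["high_branch_birth_G"], scan=scan)


def _assess_candidate(cand: KineticParameters, anchors: AnchorConditions,
                      L_b: float, A_b: float) -> dict[str, float] | None:
    """Check the switch structure of a calibrated candidate; None if unusable.

    Required structure: the compensation anchor is the lowest stable state;
    five equilibria (three stable) at healthy glucose; three (two stable)
    just above the bifurcation glucose; the low branch folds at the
    bifurcation glucose; and the post-switch branch carries (approximately)
    the anchored IL-1β and IL-1Ra fold changes at the diabetic glucose, with
    a stable state near the diabetic anchor.
    """
    try:
        eqs_comp = find_equilibria(anchors.G_comp, cand)
        low = min(eqs_comp, key=lambda e: e.L_star)
        if not low.stable or abs(low.L_star - anchors.L_comp) > 1e-4 * anchors.L_comp:
            return None
        eqs_h = find_equilibria(anchors.healthy_G, cand)
        if len(eqs_h) != 5 or sum(e.stable for e in eqs_h) != 3:
            return None
        eqs_up = find_equilibria(anchors.G_bif + 0.05, cand)
        if len(eqs_up) != 3 or sum(e.stable for e in eqs_up) != 2:
            return None
        G_fold, _ = critical_glucose(cand, (anchors.G_comp, anchors.G_diab),
                                     tol=1e-5)
    except (AnalysisError, NoFoldError):
        return None
    if abs(G_fold - anchors.G_bif) > 0.01:
        return None
    L_diab = _landing_branch_L(cand, anchors, L_b, anchors.G_bif + 0.02)
    if L_diab is None:
        return None
    fc_L = L_diab / anchors.L_comp
    A_diab = kin.ilra_production(L_diab, cand) / cand.dA
    fc_A = A_diab / anchors.A_comp
    # the landing state itself must be stable at the diabetic glucose
    try:
        eqs_d = find_equilibria(anchors.G_diab, cand)
    except AnalysisError:
        return None
    near = min((e for e in eqs_d if e.stable),
               key=lambda e: abs(math.log(e.L_star / L_diab)), default=None)
    if near is None or abs(math.log(near.L_star / L_diab)) > 0.02:
        return None
    birth = _high_branch_birth(cand, anchors, L_diab)
    return {"G_fold": G_fold, "fold_change_L": fc_L, "fold_change_A": fc_A,
            "high_branch_birth_G": birth}


def _high_branch_birth(cand: KineticParameters, anchors: AnchorConditions,
                       L_diab: float) -> float:
    """Glucose at which the post-switch branch first exists (its lower fold)."""
    L = L_diab
    G = anchors.G_diab
    step = 0.1
    while G > 0.5:
        G_next = G - step
        from .equilibria import _continue_root
        L_next = _continue_root(L, G_next, cand)
        if L_next is None:
            lo, hi = G_next, G
            while hi - lo > 1e-3:
                mid = 0.5 * (lo + hi)
                L_mid = _continue_root(L, mid, cand)
                if L_mid is None:
                    lo = mid
                else:
                    hi, L = mid, L_mid
            return 0.5 * (lo + hi)
        L, G = L_next, G_next
    return 0.5


def derive_lambda(p: KineticParameters, healthy_G: float = 4.5) -> float:
    """Proliferation/apoptosis ratio λ from β-cell balance at healthy glucose.

    λ = p(F₀)/a(F₀) with F₀ the receptor occupancy on the low-IL-1β branch at
    the healthy glucose level, so that dB/dt = 0 exactly there.
    """
    eqs = find_equilibria(healthy_G, p)
    stable = [e for e in eqs if e.stable]
    if not stable:
        raise AnalysisError(f"no stable fast equilibrium at G={healthy_G:.4g}")
    low = min(stable, key=lambda e: e.L_star)
    F0 = low.occupancy(p)
    prolif, apop = kin.beta_turnover(F0, p)
    if apop <= 0:
        raise AnalysisError("apoptosis rate non-positive at the healthy occupancy")
    return prolif / apop


def dbss_initial_state(G: float, R: float, p: KineticParameters
                       ) -> tuple[float, float]:
    """Insulin and β-cell mass at the glucose/insulin steady state.

    From dG/dt = 0: I = R·(r0/G − dG); from dI/dt = 0: B = I·dI/(h·s(G)).
    """
    if G <= 0 or R <= 0:
        raise ValueError("G and R must be positive")
    I = R * (p.r0 / G - p.dG)
    if I <= 0:
        raise ValueError(f"no positive-insulin steady state: G ≥ r0/dG = "
                         f"{p.r0 / p.dG:.4g} mM")
    B = I * p.dI / (p.h * kin.insulin_secretion_factor(G, p))
    return float(I), float(B)


# ---------------------------------------------------------------------------
# in-vitro dose-response fits

#: endogenous background of the islet-culture experiments, pg/ml
INVITRO_ENDOGENOUS_L = 0.228
INVITRO_ENDOGENOUS_A = 114.0


def exogenous_to_occupancy(dose, p: KineticParameters,
                           endo_L: float = INVITRO_ENDOGENOUS_L,
                           endo_A: float = INVITRO_ENDOGENOUS_A):
    """Occupancy produced by an exogenous IL-1β dose on the culture background."""
    return kin.receptor_occupancy(np.asarray(dose, dtype=float) + endo_L, endo_A, p)


def fit_dose_response(curve: str, data: pd.DataFrame | Mapping[str, Sequence[float]],
                      p: KineticParameters | None = None,
                      weights: Sequence[float] | None = None,
                      add_hypo_anchor: bool = True,
                      control_x: float | None = None) -> dict:
    """Weighted least-squares fit of one in-vitro response curve.

    ``curve`` selects the functional form and the meaning of ``x``:

    * ``"g"`` — glucose (mM) vs IL-1β production (fold of control); Hill
      curve with free amplitude.  Points above 20 mM are excluded
      (supra-physiological), and a pseudo-point pinning half of the control
      response at 3 mM (the hypoglycaemia limit) is appended by default.
    * ``"l"`` — exogenous IL-1β (pg/ml) vs auto-stimulated production (fold);
      the dose is first converted to receptor occupancy on the endogenous
      culture background.
    * ``"b"`` — basal IL-1β mRNA level vs relative production (≤ 1);
      decreasing sigmoid, no free amplitude.
    * ``"prolif"`` / ``"apop"`` — exogenous IL-1β (pg/ml) vs rate in percent
      of control; parabola in ln occupancy.

    Returns a dict with named ``coefficients``, ``sse``, ``r2`` and ``n_used``.
    """
    p = p or KineticParameters()
    df = pd.DataFrame(data)
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)
    elif "sd" in df.columns:
        sigma = df["sd"].to_numpy(dtype=float)

    if curve == "g":
        keep = x <= 20.0
        x, y = x[keep], y[keep]
        if sigma is not None:
            sigma = sigma[keep]
        if add_hypo_anchor:
            cx = control_x if control_x is not None else float(x.min())
            y_ctrl = float(y[np.argmin(np.abs(x - cx))])
            x = np.append(x, 3.0)
            y = np.append(y, 0.5 * y_ctrl)
            if sigma is not None:
                sigma = np.append(sigma, np.median(sigma))

        def model(G, a, s, v):
            return a * G**s / (v**s + G**s)
        p0 = (float(y.max()), 2.5, float(np.median(x)))
        bounds = ([1e-6, 0.3, 0.3], [50.0 * max(float(y.max()), 1.0), 12.0, 40.0])
        names = ("a", "s", "v")
    elif curve == "l":
        F = exogenous_to_occupancy(x, p)

        def model(_x, a, t_hill, KF):
            return a * F**t_hill / (KF**t_hill + F**t_hill)
        p0 = (float(y.max()), 3.0, 0.1)
        bounds = ([1e-6, 0.3, 1e-4], [50.0 * max(float(y.max()), 1.0), 12.0, 0.999])
        names = ("a", "t_hill", "KF")
    elif curve == "b":
        def model(M, u, r):
            return 1.0 / (1.0 + (M / u) ** r)
        p0 = (float(np.median(x)), 2.0)
        bounds = ([1e-6, 0.3], [1e4, 12.0])
        names = ("u", "r")
    elif curve in ("prolif", "apop"):
        F = exogenous_to_occupancy(x, p)
        lx = np.log(F)
        w = None if sigma is None else 1.0 / sigma**2
        coef = np.polyfit(lx, y / 100.0, 2, w=w)
        yhat = np.polyval(coef, lx) * 100.0
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        names = ("ap", "bp", "cp") if curve == "prolif" else ("aa", "ba", "ca")
        return {"coefficients": dict(zip(names, coef)), "sse": sse,
                "r2": 1.0 - sse / sst if sst > 0 else 1.0, "n_used": len(x)}
    else:
        raise ValueError(f"unknown curve {curve!r}")

    if len(x) < len(p0):
        raise ValueError(f"under-determined fit: {len(x)} points for "
                         f"{len(p0)} coefficients")
    popt, _ = optimize.curve_fit(model, x, y, p0=p0, sigma=sigma,
                                 bounds=bounds, maxfev=20000)
    yhat = model(x, *popt)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return {"coefficients": dict(zip(names, popt)), "sse": sse,
            "r2": 1.0 - sse / sst if sst > 0 else 1.0, "n_used": len(x)}


# ---------------------------------------------------------------------------
# glucose-history fits

@dataclass
class HistoryFit:
    m: float
    tau: float
    sse: float
    population: pd.DataFrame        # final DE population: columns m, tau, sse
    ensemble: pd.DataFrame          # near-optimal evaluated candidates
    m_tau_correlation: float        # over the near-optimal ensemble
    converged: bool


#: acceptance band for "reasonable" fits: squared misfit within this factor
#: of the best member (RMS within ~2.8× the best fit)
ENSEMBLE_SSE_FACTOR = 8.0


@dataclass
class ReducedFit:
    k3: float
    k4: float
    m: float
    tau: float
    derived: dict[str, float]       # k1, k2, k5, k6 at the optimum
    sse: float
    population: pd.DataFrame        # columns k3, k4, m, tau, sse, feasible, switch_time_d
    switch_fraction: float          # accepted members with a pre-diagnosis switch
    m_tau_correlation: float
    m_k4_correlation: float


def _solve_quasi_static_glucose(B: float, R: float, p: KineticParameters,
                                G_seed: float) -> float:
    """Glucose at the (G, I) equilibrium for fixed β-cell mass and resistance.

    Solves R·(r0/G − dG) = h·B·s(G)/dI (insulin demand = supply); the left
    side is strictly decreasing and the right strictly increasing in G, so
    the root is unique.  Newton from the previous glucose with a bisection
    fallback.
    """
    G_max = p.r0 / p.dG
    G = min(max(G_seed, 0.2), G_max * 0.999)
    c = p.h * B / p.dI
    for _ in range(50):
        s = G**2 / (p.KG**2 + G**2)
        f = R * (p.r0 / G - p.dG) - c * s
        ds = 2 * p.KG**2 * G / (p.KG**2 + G**2) ** 2
        df = -R * p.r0 / G**2 - c * ds
        step = f / df
        G_new = G - step
        if not 0.0 < G_new < G_max:
            break
        G = G_new
        if abs(step) < 1e-12 * G:
            return G
    lo, hi = 1e-3, G_max * 0.99999
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = mid**2 / (p.KG**2 + mid**2)
        if R * (p.r0 / mid - p.dG) - c * s > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _fast_history_sim(p: KineticParameters, obs_times: np.ndarray, G0: float,
                      B0: float, R_input: SensitivityInput,
                      anchors: AnchorConditions, chunk: float = 30.0
                      ) -> tuple[np.ndarray, list[tuple[float, str]]]:
    """Slaved-timescale disease-course simulation for history fitting.

    On the yearly sampling cadence of the longitudinal data, glucose and
    insulin equilibrate essentially instantaneously relative to β-cell mass,
    so (L, A) are pinned to the tracked fast branch, (G, I) to their
    quasi-static balance, and only B is integrated (exponentially within
    short chunks).  Agrees with the qssa integrator to well under 0.1% in G
    at the sample times while being orders of magnitude faster.
    """
    from .model import FastBranchTracker

    tracker = FastBranchTracker(anchors.L_comp, anchors.A_comp, G0, p)
    t0, t_end = float(obs_times[0]), float(obs_times[-1])
    t_grid = np.unique(np.concatenate(
        [np.arange(t0, t_end, chunk), np.asarray(obs_times, dtype=float)]))
    R_grid = np.maximum(np.atleast_1d(R_input.resistance(t_grid, p)),
                        kin.R_MIN_FRACTION * p.R0)
    is_obs = np.isin(t_grid, np.asarray(obs_times, dtype=float))
    B = B0
    G = G0
    out = [G0]
    lam_ap = (p.ap, p.bp, p.cp, p.aa, p.ba, p.ca, p.lam)
    for i in range(1, len(t_grid)):
        dt = t_grid[i] - t_grid[i - 1]
        F = tracker.L / p.KL / (1.0 + tracker.L / p.KL + tracker.A / p.KA)
        if F > 0:
            x = math.log(F)
            ap_, bp_, cp_, aa_, ba_, ca_, lam = lam_ap
            growth = (ap_ * x * x + bp_ * x + cp_
                      - lam * (aa_ * x * x + ba_ * x + ca_))
        else:
            growth = 0.0
        B *= math.exp(p.tau * growth * dt)
        G = _solve_quasi_static_glucose(B, float(R_grid[i]), p, G)
        tracker.update(float(t_grid[i]), G)
        if is_obs[i]:
            out.append(G)
    return np.array(out), list(tracker.events)


def _cohort_initial_state(obs: pd.DataFrame, R_input: SensitivityInput,
                          p: KineticParameters, anchors: AnchorConditions
                          ) -> SystemState:
    t0 = float(obs["t_days"].iloc[0])
    G0 = float(obs["G_mM"].iloc[0])
    R = R_input.resistance(t0, p)
    I0, B0 = dbss_initial_state(G0, R, p)
    L0, A0 = relax_fast_subsystem(anchors.L_comp, anchors.A_comp, G0, p)
    return SystemState(t=t0, G=G0, I=I0, B=B0, L=L0, A=A0)


def _history_sse(p: KineticParameters, observed: Mapping[str, pd.DataFrame],
                 R_inputs: Mapping[str, SensitivityInput],
                 anchors: AnchorConditions, qssa_chunk: float = 30.0,
                 return_events: bool = False):
    total = 0.0
    events_all: list[tuple[float, str]] = []
    for cohort, obs in observed.items():
        R_input = R_inputs[cohort]
        t_obs = obs["t_days"].to_numpy(dtype=float)
        G0 = float(obs["G_mM"].iloc[0])
        try:
            I0, B0 = dbss_initial_state(G0, R_input.resistance(t_obs[0], p), p)
            G_model, events = _fast_history_sim(p, t_obs, G0, B0, R_input,
                                                anchors, chunk=qssa_chunk)
        except (RuntimeError, ValueError):
            return (1e9, []) if return_events else 1e9
        total += float(np.sum((G_model - obs["G_mM"].to_numpy()) ** 2))
        events_all.extend(events)
    return (total, events_all) if return_events else total


def fit_history(observed: Mapping[str, pd.DataFrame],
                R_inputs: Mapping[str, SensitivityInput],
                p: KineticParameters,
                anchors: AnchorConditions | None = None,
                seed: int = 0,
                bounds: tuple = ((0.1, 20.0), (1e-5, 1e-2)),
                popsize: int = 10, maxiter: int = 15,
                qssa_chunk: float = 30.0) -> HistoryFit:
    """Fit the resistance slope m and β-cell turnover τ to glucose histories.

    Minimises the unweighted sum of squared glucose residuals over all
    cohorts (equal weight per time point) with seeded differential evolution.
    Every candidate evaluated during the search is recorded; those whose
    misfit lies within ``ENSEMBLE_SSE_FACTOR`` of the optimum form the
    near-optimal ensemble used for identifiability analysis — the glucose
    history constrains m and τ only along a ridge, so the ensemble exhibits
    a strong m–τ correlation.
    """
    anchors = anchors or AnchorConditions()
    evaluations: list[tuple[float, float, float]] = []

    def objective(x):
        sse = _history_sse(p.replace(m=x[0], tau=x[1]), observed, R_inputs,
                           anchors, qssa_chunk)
        evaluations.append((float(x[0]), float(x[1]), float(sse)))
        return sse

    res = optimize.differential_evolution(
        objective, bounds=bounds, seed=seed, popsize=popsize, maxiter=maxiter,
        tol=1e-8, init="latinhypercube", polish=True, updating="immediate")
    pop = pd.DataFrame(res.population, columns=["m", "tau"])
    pop["sse"] = res.population_energies
    evals = pd.DataFrame(evaluations, columns=["m", "tau", "sse"])
    ensemble = evals[evals["sse"] <= ENSEMBLE_SSE_FACTOR * float(res.fun)]
    ensemble = ensemble.drop_duplicates(subset=["m", "tau"]).reset_index(drop=True)
    r = (float(np.corrcoef(ensemble["m"], ensemble["tau"])[0, 1])
         if len(ensemble) > 2 else math.nan)
    return HistoryFit(m=float(res.x[0]), tau=float(res.x[1]), sse=float(res.fun),
                      population=pop, ensemble=ensemble, m_tau_correlation=r,
                      converged=bool(res.success))


def _reduced_candidate(p: KineticParameters, anchors: AnchorConditions,
                       k3: float, k4: float) -> KineticParameters | None:
    """k1, k2, k5, k6 from the compensation and diabetes anchors alone."""
    pc, pd_ = _phi(anchors.L_comp, k3), _phi(anchors.L_diab, k3)
    if abs(pd_ - pc) < 1e-30:
        return None
    k2 = p.dA * (anchors.A_diab - anchors.A_comp) / (pd_ - pc)
    k1 = p.dA * anchors.A_comp - k2 * pc

    def beta(L):
        return p.dL * L * (1.0 + (k4 * L / p.u) ** p.r)
    g_c = kin.glucose_stim(anchors.G_comp, p)
    g_d = kin.glucose_stim(anchors.G_diab, p)
    l_c = kin.autostim(kin.receptor_occupancy(anchors.L_comp, anchors.A_comp, p), p)
    l_d = kin.autostim(kin.receptor_occupancy(anchors.L_diab, anchors.A_diab, p), p)
    det = g_c * l_d - g_d * l_c
    if abs(det) < 1e-30:
        return None
    k5 = (beta(anchors.L_comp) * l_d - beta(anchors.L_diab) * l_c) / det
    k6 = (g_c * beta(anchors.L_diab) - g_d * beta(anchors.L_comp)) / det
    if min(k1, k2, k5, k6) < 0:
        return None
    return p.replace(k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, k6=k6)


def reduced_fit(observed: Mapping[str, pd.DataFrame],
                R_inputs: Mapping[str, SensitivityInput],
                p: KineticParameters,
                anchors: AnchorConditions | None = None,
                seed: int = 0,
                bounds: tuple = ((1.5, 6.0), (-3.0, 0.5), (0.1, 20.0), (1e-5, 1e-2)),
                popsize: int = 8, maxiter: int = 80,
                qssa_chunk: float = 30.0,
                diagnosis_time: float | None = None,
                n_restarts: int = 2) -> ReducedFit:
    """Four-parameter fit without a presupposed bifurcation.

    Free parameters are (log10 k3, log10 k4, m, τ); k1, k2, k5 and k6 are
    eliminated through the compensation and diabetes steady-state equations
    at each candidate, reducing eight unknowns to four.  Whether the IL-1β
    switch occurs before diagnosis is recorded per accepted ensemble member
    rather than imposed.

    The 4-D objective is multimodal, so the evolution is restarted
    ``n_restarts`` times from seeds derived from ``seed`` and the run with
    the lowest misfit is kept.
    """
    anchors = anchors or AnchorConditions()
    cases = observed["cases"] if "cases" in observed else observed[list(observed)[0]]
    t_dx = (float(cases["t_days"].iloc[-1]) if diagnosis_time is None
            else diagnosis_time)
    evaluations: list[tuple[float, float, float, float, float]] = []

    def build(x):
        return _reduced_candidate(p.replace(m=x[2], tau=x[3]), anchors,
                                  10.0 ** x[0], 10.0 ** x[1])

    def objective(x):
        cand = build(x)
        sse = (1e9 if cand is None
               else _history_sse(cand, observed, R_inputs, anchors, qssa_chunk))
        evaluations.append((float(x[0]), float(x[1]), float(x[2]), float(x[3]),
                            float(sse)))
        return sse

    res = None
    for restart in range(max(1, n_restarts)):
        evaluations.clear()
        attempt = optimize.differential_evolution(
            objective, bounds=bounds, seed=seed + 1009 * restart,
            popsize=popsize, maxiter=maxiter, tol=1e-8, init="sobol",
            mutation=(0.5, 1.5), recombination=0.9, polish=True,
            updating="immediate")
        if res is None or attempt.fun < res.fun:
            res = attempt
            kept_evaluations = list(evaluations)
    evaluations[:] = kept_evaluations

    best = float(res.fun)
    evals = pd.DataFrame(evaluations,
                         columns=["log_k3", "log_k4", "m", "tau", "sse"])
    accepted = (evals[evals["sse"] <= ENSEMBLE_SSE_FACTOR * best]
                .drop_duplicates(subset=["log_k3", "log_k4", "m", "tau"])
                .reset_index(drop=True))
    # per-member switch check on a bounded, deterministic subsample
    subsample = accepted.iloc[:: max(1, len(accepted) // 60)]
    rows = []
    for _, mem in subsample.iterrows():
        cand = build([mem["log_k3"], mem["log_k4"], mem["m"], mem["tau"]])
        switch_t = math.nan
        if cand is not None:
            _, events = _history_sse(cand, observed, R_inputs, anchors,
                                     qssa_chunk, return_events=True)
            jumps = [t for t, kind in events if kind == "branch-jump"]
            if jumps:
                switch_t = min(jumps)
        rows.append((10.0 ** mem["log_k3"], 10.0 ** mem["log_k4"], mem["m"],
                     mem["tau"], mem["sse"], cand is not None, switch_t))
    pop = pd.DataFrame(rows, columns=["k3", "k4", "m", "tau", "sse",
                                      "feasible", "switch_time_d"])
    feasible = pop[pop["feasible"]]
    switch_frac = (float(np.mean(feasible["switch_time_d"] < t_dx))
                   if len(feasible) else math.nan)
    r_mtau = (float(np.corrcoef(accepted["m"], accepted["tau"])[0, 1])
              if len(accepted) > 2 else math.nan)
    r_mk4 = (float(np.corrcoef(accepted["m"], accepted["log_k4"])[0, 1])
             if len(accepted) > 2 else math.nan)
    best_cand = build(res.x)
    derived = ({k: getattr(best_cand, k) for k in ("k1", "k2", "k5", "k6")}
               if best_cand else {})
    return ReducedFit(k3=10.0 ** res.x[0], k4=10.0 ** res.x[1],
                      m=float(res.x[2]), tau=float(res.x[3]), derived=derived,
                      sse=best, population=pop,
                      switch_fraction=switch_frac,
                      m_tau_correlation=r_mtau, m_k4_correlation=r_mk4)
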