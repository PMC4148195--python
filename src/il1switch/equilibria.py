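"""Fixed points, nullclines and bifurcation structure of the fast subsystem.

At fixed glucose the IL-1β/IL-1Ra pair (L, A) forms an autonomous planar
system.  Every equilibrium lies on the IL-1Ra nullcline A = production(L)/dA,
so equilibria are located as roots of a scalar residual in L (bracketing on a
dense log-spaced grid followed by Brent/Newton polishing) rather than by 2-D
multi-start root finding; the reduction is exact, misses no branch that a
planar search would find, and makes fold detection a matter of following a
single scalar root.

The determinant of the 2×2 fast Jacobian equals −dA times the derivative of
the scalar residual, so a saddle-node (fold) of the reduced problem is a fold
of the planar system and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import kinetics as kin
from .model import fast_jacobian, reduced_residual, relax_fast_subsystem
from .params import KineticParameters

__all__ = [
    "Equilibrium", "BifurcationDiagram", "AnalysisError", "NoFoldError",
    "find_equilibria", "nullclines", "critical_glucose", "hysteresis_scan",
    "track_branch", "compute_bifurcation_diagram",
]

# L search window (pg/ml, log-spaced); generous around every branch the
# calibrated model produces (~1e-1 … ~3e3)
L_GRID_BOUNDS = (1e-4, 1e6)
L_GRID_POINTS = 1600

#: |Re eigenvalue| below this is treated as numerically zero (fold-degenerate)
EIGENVALUE_TIE_TOL = 1e-10


class AnalysisError(RuntimeError):
    """Equilibrium analysis failed (no root / branch lost)."""


class NoFoldError(AnalysisError):
    """The tracked branch persists over the whole requested glucose range."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the fast subsystem at fixed glucose."""
    G: float
    L_star: float
    A_star: float
    stability: str                      # "stable" | "unstable" | "fold-degenerate"
    eigenvalues: tuple[complex, complex]

    @property
    def stable(self) -> bool:
        return self.stability == "stable"

    def occupancy(self, p: KineticParameters) -> float:
        return kin.receptor_occupancy(self.L_star, self.A_star, p)


@dataclass
class BifurcationDiagram:
    """Equilibrium branches over a glucose range plus fold locations."""
    branches: list[list[Equilibrium]]
    critical_points: list[tuple[float, float, float]]   # (G, L, A)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bid, branch in enumerate(self.branches):
            for eq in branch:
                rows.append((eq.G, bid, eq.L_star, eq.A_star, int(eq.stable)))
        return pd.DataFrame(rows, columns=["G_mM", "branch_id", "L_pg_ml",
                                           "A_pg_ml", "stable"])


def _classify(L: float, A: float, G: float, p: KineticParameters) -> Equilibrium:
    J = fast_jacobian(L, A, G, p)
    eig = np.linalg.eigvals(J)
    re = np.real(eig)
    if np.any(np.abs(re) < EIGENVALUE_TIE_TOL):
        stability = "fold-degenerate"
    elif np.all(re < 0):
        stability = "stable"
    else:
        stability = "unstable"
    return Equilibrium(G=G, L_star=L, A_star=A, stability=stability,
                       eigenvalues=(complex(eig[0]), complex(eig[1])))


def _polish_root(L: float, G: float, p: KineticParameters, iters: int = 6) -> float:
    """Newton-polish a bracketed root of the reduced residual."""
    for _ in range(iters):
        f = reduced_residual(L, G, p)
        h = max(abs(L), 1e-8) * 1e-7
        df = (reduced_residual(L + h, G, p) - reduced_residual(L - h, G, p)) / (2 * h)
        if df == 0:
            break
        step = f / df
        if abs(step) > 0.5 * L:
            break
        L -= step
        if abs(step) <= 1e-14 * L:
            break
    return L


def find_equilibria(G: float, p: KineticParameters,
                    L_bounds: tuple[float, float] = L_GRID_BOUNDS,
                    n_grid: int = L_GRID_POINTS) -> list[Equilibrium]:
    """All fixed points of the fast subsystem at glucose ``G``, classified.

    Roots of the reduced scalar residual are bracketed on a log-spaced L grid
    and polished; duplicates within 1e-6 relative are merged.  Raises
    :class:`AnalysisError` if no root is found.
    """
    if G <= 0:
        raise ValueError("G must be positive")
    grid = np.geomspace(L_bounds[0], L_bounds[1], n_grid)
    res = reduced_residual(grid, G, p)
    roots: list[float] = []
    sign = np.sign(res)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(lambda L: reduced_residual(L, G, p), grid[i], grid[i + 1],
                      xtol=1e-14, rtol=1e-14)
        roots.append(_polish_root(root, G, p))
    for i in np.nonzero(res == 0)[0]:       # exact grid hits
        roots.append(float(grid[i]))
    merged: list[float] = []
    for root in sorted(roots):
        if not merged or abs(root - merged[-1]) > 1e-6 * max(abs(root), 1e-30):
            merged.append(root)
    if not merged:
        raise AnalysisError(f"no fast-subsystem equilibrium found at G={G:.4g}")
    out = []
    for L in merged:
        A = kin.ilra_production(L, p) / p.dA
        out.append(_classify(L, A, G, p))
    return out


def nullclines(G: float, p: KineticParameters,
               L_range: tuple[float, float] = (1e-3, 1e4),
               n_points: int = 400) -> dict[str, pd.DataFrame]:
    """The two nullclines of the fast subsystem in the (L, A) plane.

    The IL-1Ra nullcline is ``A = production(L)/dA`` (single interior peak at
    L = k3 under the default bell form).  The IL-1β nullcline is solved in
    closed form for A at each L from dL/dt = 0; L values admitting no
    positive-A solution are omitted.
    """
    if L_range[0] <= 0 or L_range[1] <= L_range[0]:
        raise ValueError("L_range must be positive and increasing")
    L = np.geomspace(L_range[0], L_range[1], n_points)
    a_null = pd.DataFrame({"L_pg_ml": L, "A_pg_ml": kin.ilra_production(L, p) / p.dA})

    # dL/dt = 0  =>  l(F) = (dL·L/b(L) − k5·g(G)) / k6, then invert l and F
    g = kin.glucose_stim(G, p)
    rows = []
    for Li in L:
        y = (p.dL * Li / kin.mrna_inhibition(Li, p) - p.k5 * g) / p.k6
        if not 0.0 < y < 1.0:
            continue
        F = p.KF * (y / (1.0 - y)) ** (1.0 / p.t_hill)
        if not 0.0 < F < 1.0:
            continue
        A = kin.occupancy_to_ilra(Li, F, p)
        if A > 0:
            rows.append((Li, A))
    l_null = pd.DataFrame(rows, columns=["L_pg_ml", "A_pg_ml"])
    return {"il1ra": a_null, "il1b": l_null}


def _continue_root(L_seed: float, G: float, p: KineticParameters,
                   jump_tol: float = 0.7) -> float | None:
    """Newton continuation of a reduced-residual root from a nearby seed.

    Returns None when the root has moved more than ``jump_tol`` in ln L or
    the iteration fails — i.e. the tracked branch no longer exists here.
    """
    lnL = math.log(L_seed)
    x = lnL
    for _ in range(60):
        L = math.exp(x)
        f = reduced_residual(L, G, p)
        h = max(abs(L), 1e-8) * 1e-7
        df = (reduced_residual(L + h, G, p) - reduced_residual(L - h, G, p)) / (2 * h)
        dfdx = df * L
        if dfdx == 0:
            return None
        step = max(min(f / dfdx, 0.4), -0.4)
        x -= step
        if abs(x - lnL) > 2.5:
            return None
        if abs(step) < 1e-13:
            root = math.exp(x)
            if abs(x - lnL) > jump_tol:
                return None
            # guard: Newton in log space can slide to a spurious stationary point
            if abs(reduced_residual(root, G, p)) > 1e-6 * max(p.dL * root, 1.0):
                return None
            return root
    return None


def track_branch(L_seed: float, G_from: float, G_to: float, p: KineticParameters,
                 n_steps: int = 80) -> tuple[float, float]:
    """Follow one equilibrium branch from ``G_from`` to ``G_to`` by continuation.

    Returns the branch (L*, A*) at ``G_to``; raises :class:`AnalysisError` if
    the branch disappears on the way.
    """
    L = _continue_root(L_seed, G_from, p, jump_tol=2.0)
    if L is None:
        raise AnalysisError(f"seed is not near an equilibrium at G={G_from:.4g}")
    for G in np.linspace(G_from, G_to, n_steps + 1)[1:]:
        L_next = _continue_root(L, G, p)
        if L_next is None:
            raise AnalysisError(f"tracked branch disappears before G={G:.4g}")
        L = L_next
    return L, kin.ilra_production(L, p) / p.dA


def critical_glucose(p: KineticParameters,
                     G_range: tuple[float, float] = (4.0, 8.0),
                     tol: float = 1e-4,
                     branch: str = "low") -> tuple[float, Equilibrium]:
    """Glucose at which the tracked stable branch disappears (saddle-node).

    The branch ("low" = smallest L, "high" = largest L at the range start) is
    continued upward in G; once lost, the fold glucose is bisected to ``tol``.
    Returns the fold glucose and the last equilibrium on the branch, at which
    the fast-subsystem Jacobian determinant approaches zero.  Raises
    :class:`NoFoldError` if the branch persists across the whole range.
    """
    G_lo, G_hi = G_range
    eqs = find_equilibria(G_lo, p)
    stable = [e for e in eqs if e.stable]
    if not stable:
        raise AnalysisError(f"no stable equilibrium at G={G_lo:.4g}")
    eq0 = min(stable, key=lambda e: e.L_star) if branch == "low" else \
        max(stable, key=lambda e: e.L_star)
    L, G = eq0.L_star, G_lo
    step = max((G_hi - G_lo) / 50.0, 2 * tol)
    lost_at = None
    while G < G_hi - 1e-12:
        G_next = min(G + step, G_hi)
        L_next = _continue_root(L, G_next, p)
        if L_next is None:
            lost_at = G_next
            break
        L, G = L_next, G_next
    if lost_at is None:
        raise NoFoldError(
            f"branch persists over G ∈ [{G_lo:.4g}, {G_hi:.4g}]")
    lo, hi = G, lost_at
    L_last, G_last = L, G
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        L_mid = _continue_root(L_last, mid, p)
        if L_mid is None:
            hi = mid
        else:
            lo, L_last, G_last = mid, L_mid, mid
    G_fold = 0.5 * (lo + hi)
    # polish the saddle-node exactly: residual and its L-derivative both zero
    from scipy.optimize import root as _root
    from .model import reduced_residual_deriv

    def fold_system(x):
        L_, G_ = x
        if L_ <= 0 or G_ <= 0:
            return [1e6, 1e6]
        return [reduced_residual(L_, G_, p), reduced_residual_deriv(L_, G_, p)]

    sol = _root(fold_system, [L_last, G_fold], method="hybr",
                options={"xtol": 1e-13})
    if sol.success and abs(sol.x[1] - G_fold) < max(10 * tol, 1e-3):
        L_last, G_fold = float(sol.x[0]), float(sol.x[1])
        G_last = G_fold
    A_last = kin.ilra_production(L_last, p) / p.dA
    fold_eq = _classify(L_last, A_last, G_last, p)
    return G_fold, fold_eq


def hysteresis_scan(p: KineticParameters, G_path,
                    start: tuple[float, float] | None = None
                    ) -> tuple[list[Equilibrium], list[tuple[int, str]]]:
    """Occupied fast equilibria along a piecewise-constant glucose path.

    The occupied branch is followed by continuity; when it disappears the
    fast subsystem is relaxed from the pre-jump state (jump-on-disappearance)
    and a ``(path index, "branch-jump")`` event is recorded.  The returned
    sequence demonstrates hysteresis: raising G above the fold and lowering
    it back leaves the system on the high-IL-1β branch.
    """
    from .model import FastBranchTracker

    G_path = [float(G) for G in G_path]
    if not G_path:
        raise ValueError("G_path must be non-empty")
    if start is None:
        eqs = find_equilibria(G_path[0], p)
        stable = [e for e in eqs if e.stable]
        if not stable:
            raise AnalysisError(f"no stable equilibrium at G={G_path[0]:.4g}")
        low = min(stable, key=lambda e: e.L_star)
        L0, A0 = low.L_star, low.A_star
    else:
        L0, A0 = relax_fast_subsystem(start[0], start[1], G_path[0], p)
    try:
        tracker = FastBranchTracker(L0, A0, G_path[0], p)
    except RuntimeError as exc:
        raise AnalysisError(str(exc)) from exc
    occupied: list[Equilibrium] = []
    for i, G in enumerate(G_path):
        try:
            L, A = tracker.update(2.0 * i, G)
        except RuntimeError as exc:
            raise AnalysisError(str(exc)) from exc
        occupied.append(_classify(L, A, G, p))
    events = [(int(round(t / 2.0)), kind) for t, kind in tracker.events]
    return occupied, events


def compute_bifurcation_diagram(p: KineticParameters, G_min: float = 3.0,
                                G_max: float = 20.0, n_steps: int = 200
                                ) -> BifurcationDiagram:
    """Assemble equilibrium branches over a glucose range.

    Equilibria at successive glucose values are matched greedily by nearest
    neighbour in (ln L, ln A); an unmatched equilibrium opens a new branch.
    Fold locations are recorded where a branch terminates inside the range.
    """
    G_values = np.linspace(G_min, G_max, n_steps)
    branches: list[list[Equilibrium]] = []
    open_branches: dict[int, Equilibrium] = {}
    critical: list[tuple[float, float, float]] = []
    next_id = 0
    for G in G_values:
        eqs = find_equilibria(G, p)
        assigned: dict[int, Equilibrium] = {}
        used = set()
        for bid, prev in sorted(open_branches.items()):
            best, best_d = None, None
            for j, eq in enumerate(eqs):
                if j in used:
                    continue
                d = math.hypot(math.log(eq.L_star) - math.log(prev.L_star),
                               math.log(max(eq.A_star, 1e-30)) -
                               math.log(max(prev.A_star, 1e-30)))
                if best_d is None or d < best_d:
                    best, best_d = j, d
            if best is not None and best_d < 1.0:
                assigned[bid] = eqs[best]
                used.add(best)
        for bid, prev in open_branches.items():
            if bid not in assigned:       # branch ended: fold inside the range
                critical.append((prev.G, prev.L_star, prev.A_star))
        for j, eq in enumerate(eqs):
            if j not in used:
                assigned[next_id] = eq
                branches.append([])
                next_id += 1
        new_open: dict[int, Equilibrium] = {}
        for bid, eq in assigned.items():
            branches[bid].append(eq)
            new_open[bid] = eq
        open_branches = new_open
    return BifurcationDiagram(branches=[b for b in branches if b],
                              critical_points=critical)
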