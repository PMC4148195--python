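"""Elementary kinetic functions of the IL-1β switch model.

These are the building blocks of the ODE right-hand sides: competitive
receptor occupancy, the glucose and auto-stimulation Hill curves, the
mRNA-mediated inhibition sigmoid, the bell-shaped IL-1Ra production term,
the insulin-secretion sigmoid, the β-cell turnover parabolas (in ln F) and
the HOMA-sensitivity → insulin-resistance conversion.

All functions accept scalars or numpy arrays and raise ``ValueError`` on
out-of-domain input.  Analytic partial derivatives needed for the fast
subsystem Jacobian are provided alongside.
"""

from __future__ import annotations

import numpy as np

from .params import KineticParameters

__all__ = [
    "receptor_occupancy", "glucose_stim", "autostim", "mrna_inhibition",
    "ilra_production", "insulin_secretion_factor", "beta_turnover",
    "homa_to_resistance", "net_beta_growth",
]

# floor on R as a multiple of R0: keeps I/R finite for extreme sensitivities
R_MIN_FRACTION = 0.1


def _check_nonneg(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(np.isnan(x)):
        raise ValueError(f"{name} must be non-negative")
    return x


def receptor_occupancy(L, A, p: KineticParameters):
    """Fraction F of IL-1 receptors occupied by IL-1β.

    Competitive binding of agonist L and antagonist A at equilibrium:
    ``F = (L/KL) / (1 + L/KL + A/KA)``, strictly increasing in L and
    strictly decreasing in A, always in [0, 1).
    """
    L = _check_nonneg(L, "L")
    A = _check_nonneg(A, "A")
    x = L / p.KL
    out = x / (1.0 + x + A / p.KA)
    return out if out.ndim else float(out)


def occupancy_partials(L, A, p: KineticParameters):
    """(∂F/∂L, ∂F/∂A) of the competitive-binding occupancy."""
    L = np.asarray(L, dtype=float)
    A = np.asarray(A, dtype=float)
    D = 1.0 + L / p.KL + A / p.KA
    dFdL = (1.0 / p.KL) * (1.0 + A / p.KA) / D**2
    dFdA = -(L / p.KL) / p.KA / D**2
    return dFdL, dFdA


def occupancy_to_ilra(L, F, p: KineticParameters):
    """Invert F(L, A) for A at given L and occupancy F (F in (0,1))."""
    return p.KA * ((L / p.KL) * (1.0 / F - 1.0) - 1.0)


def glucose_stim(G, p: KineticParameters):
    """Glucose-stimulated IL-1β production, Hill curve g(G) = G^s/(v^s+G^s)."""
    G = _check_nonneg(G, "G")
    gs = G**p.s
    out = gs / (p.v**p.s + gs)
    return out if out.ndim else float(out)


def autostim(F, p: KineticParameters):
    """IL-1β auto-stimulation l(F) = F^t/(KF^t + F^t) on occupancy F ∈ [0,1)."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0) or np.any(F >= 1) or np.any(np.isnan(F)):
        raise ValueError("occupancy F must lie in [0, 1)")
    ft = F**p.t_hill
    out = ft / (p.KF**p.t_hill + ft)
    return out if out.ndim else float(out)


def autostim_deriv(F, p: KineticParameters):
    """dl/dF of the auto-stimulation Hill curve."""
    F = np.asarray(F, dtype=float)
    kt = p.KF**p.t_hill
    ft = F**p.t_hill
    return p.t_hill * kt * F ** (p.t_hill - 1.0) / (kt + ft) ** 2


def mrna_inhibition(L, p: KineticParameters):
    """Inhibition of IL-1β production by basal IL-1β mRNA.

    Decreasing two-parameter sigmoid b(L) = 1/(1 + (k4·L/u)^r); b(0)=1 and
    the midpoint sits at mRNA level u, i.e. at protein level u/k4.
    """
    L = _check_nonneg(L, "L")
    z = p.k4 * L / p.u
    out = 1.0 / (1.0 + z**p.r)
    return out if out.ndim else float(out)


def mrna_inhibition_deriv(L, p: KineticParameters):
    """db/dL of the mRNA-inhibition sigmoid."""
    L = np.asarray(L, dtype=float)
    z = p.k4 * L / p.u
    zr = z**p.r
    with np.errstate(divide="ignore", invalid="ignore"):
        dz = np.where(L > 0, p.r * zr / np.maximum(L, 1e-300), 0.0)
    return -dz / (1.0 + zr) ** 2


def ilra_production(L, p: KineticParameters, k1=None, k2=None, k3=None):
    """IL-1β-stimulated IL-1Ra production rate (pg/ml/d).

    Haldane-type bell: ``k1 + k2·(L/k3)/(1 + (L/k3)²)`` — basal k1 at L=0,
    peak k1 + k2/2 at L=k3, returning towards k1 at high L (the measured
    restoration of IL-1Ra to near-basal level under strong IL-1β).
    """
    L = _check_nonneg(L, "L")
    k1 = p.k1 if k1 is None else k1
    k2 = p.k2 if k2 is None else k2
    k3 = p.k3 if k3 is None else k3
    if min(k1, k2, k3) < 0:
        raise ValueError("k1, k2, k3 must be non-negative")
    x = L / k3
    out = k1 + k2 * x / (1.0 + x**2)
    return out if out.ndim else float(out)


def ilra_production_deriv(L, p: KineticParameters):
    """d/dL of the IL-1Ra production bell."""
    L = np.asarray(L, dtype=float)
    x = L / p.k3
    return (p.k2 / p.k3) * (1.0 - x**2) / (1.0 + x**2) ** 2


def insulin_secretion_factor(G, p: KineticParameters):
    """Glucose-stimulated insulin secretion sigmoid s(G) = G²/(KG² + G²)."""
    G = _check_nonneg(G, "G")
    out = G**2 / (p.KG**2 + G**2)
    return out if out.ndim else float(out)


def beta_turnover(F, p: KineticParameters):
    """(proliferation, apoptosis) rates relative to in-vitro control.

    Both are parabolas in x = ln F; proliferation is concave (interior
    maximum), apoptosis convex (interior minimum).  The natural-log
    convention makes both ≈ 1 at the control occupancy of the islet-culture
    experiments (percent-of-control normalisation).
    """
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0) or np.any(F >= 1) or np.any(np.isnan(F)):
        raise ValueError("occupancy F must lie in (0, 1) for beta_turnover")
    x = np.log(F)
    prolif = p.ap * x**2 + p.bp * x + p.cp
    apop = p.aa * x**2 + p.ba * x + p.ca
    if prolif.ndim:
        return prolif, apop
    return float(prolif), float(apop)


def net_beta_growth(F, p: KineticParameters):
    """Relative net β-cell growth rate p(F) − λ·a(F) (multiplied by τ·B in the ODE)."""
    prolif, apop = beta_turnover(F, p)
    return prolif - p.lam * apop


def homa_to_resistance(S_H, S_H_baseline, p: KineticParameters):
    """Convert a HOMA2 %S insulin-sensitivity index into insulin resistance R.

    Log-linear mapping ``R = R0 + m·ln(S_H_baseline/S_H)`` anchored at the
    cohort baseline (R = R0 when S_H equals baseline), clipped from below at
    ``R_MIN_FRACTION·R0`` so that the insulin-dependent glucose uptake I/R
    stays finite for arbitrarily high sensitivity.
    """
    S_H = np.asarray(S_H, dtype=float)
    if np.any(S_H <= 0) or S_H_baseline <= 0:
        raise ValueError("insulin sensitivity must be strictly positive")
    R = p.R0 + p.m * np.log(S_H_baseline / S_H)
    out = np.maximum(R, R_MIN_FRACTION * p.R0)
    return out if out.ndim else float(out)
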