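"""Synthetic study inputs: longitudinal cohorts and in-vitro dose–response tables.

The cohort generator emulates the Whitehall-II-style natural history of
incident type-2 diabetes: a slowly declining insulin sensitivity that
accelerates about five years before diagnosis, a fasting glucose that rises
slowly for ~11 years and then rapidly in the final ~2 years after the
IL-1β switch, and near-constant controls.  The in-vitro generator emulates
cultured-islet experiments in which exogenous IL-1β is applied on a small
endogenous background and responses are read out as fold- or
percent-of-control values.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as kin
from .calibration import (INVITRO_ENDOGENOUS_A, INVITRO_ENDOGENOUS_L,
                          AnchorConditions, dbss_initial_state,
                          exogenous_to_occupancy)
from .model import SensitivityInput, SystemState, simulate
from .params import KineticParameters

__all__ = ["CohortSpec", "generate_sensitivity_input",
           "generate_glucose_history", "generate_invitro_tables"]

DAYS_PER_YEAR = 365.0

# Insulin-sensitivity knots (HOMA2 %S) defining the emulated cohorts, as
# (years since observation start, %S).  Cases: slow decline over years 0–8
# (years −13…−5 relative to diagnosis), accelerating thereafter; chosen so
# that with the true (m*, τ*) below the case trajectory crosses the critical
# glucose ≈2 years before diagnosis.  Controls: near-constant.
CASE_SENSITIVITY_KNOTS = ((0.0, 100.0), (4.0, 95.0), (8.0, 82.0),
                          (10.0, 65.0), (11.0, 49.0), (12.0, 42.0),
                          (13.0, 38.0))
CONTROL_SENSITIVITY_KNOTS = ((0.0, 100.0), (4.0, 99.0), (8.0, 98.0),
                             (10.0, 97.0), (11.0, 96.5), (12.0, 96.0),
                             (13.0, 95.5))

#: resistance-conversion slope and β-cell turnover used as generator truth
TRUE_M = 5.0
TRUE_TAU = 0.00052

#: baseline fasting glucose (mM) 13 years before diagnosis
CASE_BASELINE_G = 5.47
CONTROL_BASELINE_G = 5.25


@dataclass(frozen=True)
class CohortSpec:
    """Design of the emulated longitudinal study."""
    n_subjects: int = 100
    diagnosis_time: float = 13.0 * DAYS_PER_YEAR   # days since start
    case_knots: tuple = CASE_SENSITIVITY_KNOTS
    control_knots: tuple = CONTROL_SENSITIVITY_KNOTS
    glucose_noise_sd: float = 0.1                  # mM, per subject-year
    sampling_interval: float = DAYS_PER_YEAR
    m_true: float = TRUE_M
    tau_true: float = TRUE_TAU
    seed: int = 0

    def __post_init__(self):
        if self.glucose_noise_sd < 0:
            raise ValueError("glucose noise sd must be non-negative")
        for knots in (self.case_knots, self.control_knots):
            years = [t for t, _ in knots]
            if any(b <= a for a, b in zip(years, years[1:])):
                raise ValueError("sensitivity knots must be time-ordered")


def generate_sensitivity_input(spec: CohortSpec | None = None
                               ) -> dict[str, SensitivityInput]:
    """Interpolated HOMA2 %S inputs for the case and control cohorts."""
    spec = spec or CohortSpec()
    out = {}
    for name, knots in (("cases", spec.case_knots),
                        ("controls", spec.control_knots)):
        t = np.array([k[0] for k in knots]) * DAYS_PER_YEAR
        v = np.array([k[1] for k in knots], dtype=float)
        out[name] = SensitivityInput(t, v)
    return out


def _true_params(p: KineticParameters, spec: CohortSpec) -> KineticParameters:
    return p.replace(m=spec.m_true, tau=spec.tau_true)


def generate_glucose_history(spec: CohortSpec | None = None,
                             p: KineticParameters | None = None,
                             anchors: AnchorConditions | None = None,
                             ) -> dict[str, pd.DataFrame]:
    """Observed fasting-glucose tables for both cohorts.

    The model is forward-simulated (quasi-steady-state mode) with the true
    (m*, τ*), sampled at the study cadence, and i.i.d. Gaussian measurement
    noise is added per subject; the returned tables carry the cohort mean,
    its standard deviation and the noise-free model value.
    Cases start at 5.47 mM and controls at 5.25 mM.
    """
    spec = spec or CohortSpec()
    p = p or KineticParameters()
    anchors = anchors or AnchorConditions()
    p_true = _true_params(p, spec)
    rng = np.random.default_rng(spec.seed)
    sens = generate_sensitivity_input(spec)
    t_obs = np.arange(0.0, spec.diagnosis_time + 0.5 * spec.sampling_interval,
                      spec.sampling_interval)
    out: dict[str, pd.DataFrame] = {}
    for cohort, G0 in (("cases", CASE_BASELINE_G),
                       ("controls", CONTROL_BASELINE_G)):
        R0 = sens[cohort].resistance(0.0, p_true)
        I0, B0 = dbss_initial_state(G0, R0, p_true)
        init = SystemState(t=0.0, G=G0, I=I0, B=B0,
                           L=anchors.L_comp, A=anchors.A_comp)
        traj = simulate(init, sens[cohort], spec.diagnosis_time, p_true,
                        mode="qssa", n_out=400)
        G_true = np.interp(t_obs, traj.t, traj.G)
        noise = rng.normal(0.0, spec.glucose_noise_sd,
                           size=(spec.n_subjects, t_obs.size))
        samples = G_true[None, :] + noise
        out[cohort] = pd.DataFrame({
            "t_days": t_obs,
            "G_mM": samples.mean(axis=0),
            "G_sd_mM": samples.std(axis=0, ddof=1) if spec.n_subjects > 1
                       else np.zeros_like(t_obs),
            "G_true_mM": G_true,
        })
        out[cohort].attrs["events"] = list(traj.events)
    return out


# in-vitro designs: exogenous IL-1β doses (pg/ml) and glucose levels (mM)
IL1B_DOSE_DESIGN = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0, 5000.0)
GLUCOSE_DESIGN = (5.5, 7.0, 8.5, 10.0, 12.0, 15.0, 17.5, 20.0, 30.0, 40.0)
MRNA_DESIGN = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


def generate_invitro_tables(p: KineticParameters | None = None,
                            design: dict | None = None,
                            cv: float = 0.10, n_replicates: int = 3,
                            seed: int = 0) -> dict[str, pd.DataFrame]:
    """Synthetic islet-culture dose–response tables for the five curve fits.

    Each table has long-format columns (x, replicate, y): ``g`` — glucose vs
    IL-1β production (fold of the 5.5 mM control); ``l`` — exogenous IL-1β
    vs auto-stimulated production (fold scale); ``b`` — basal IL-1β mRNA
    level vs relative production; ``prolif``/``apop`` — exogenous IL-1β vs
    β-cell turnover in percent of control.  Exogenous doses act on the
    endogenous culture background (0.228 pg/ml IL-1β, 114 pg/ml IL-1Ra).
    Noise is multiplicative lognormal with coefficient of variation ``cv``.
    """
    p = p or KineticParameters()
    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    design = design or {}
    doses = np.asarray(design.get("il1b", IL1B_DOSE_DESIGN), dtype=float)
    glucose = np.asarray(design.get("glucose", GLUCOSE_DESIGN), dtype=float)
    mrna = np.asarray(design.get("mrna", MRNA_DESIGN), dtype=float)
    rng = np.random.default_rng(seed)
    F = exogenous_to_occupancy(doses, p)

    curves = {
        "g": (glucose, kin.glucose_stim(glucose, p) / kin.glucose_stim(glucose[0], p)),
        "l": (doses, kin.autostim(F, p)),
        "b": (mrna, 1.0 / (1.0 + (mrna / p.u) ** p.r)),
        "prolif": (doses, 100.0 * kin.beta_turnover(F, p)[0]),
        "apop": (doses, 100.0 * kin.beta_turnover(F, p)[1]),
    }
    sigma = np.sqrt(np.log1p(cv**2))
    out = {}
    for name, (x, y_true) in curves.items():
        rows = []
        for xi, yi in zip(x, y_true):
            for rep in range(n_replicates):
                factor = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if cv > 0 else 1.0
                rows.append((xi, rep, yi * factor))
        out[name] = pd.DataFrame(rows, columns=["x", "replicate", "y"])
    return out
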