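"""Steady-state calibration pipeline and in-vitro curve fits."""

import numpy as np
import pytest

from il1switch import kinetics as kin
from il1switch.calibration import (AnchorConditions, CalibrationError,
                                   calibrate, dbss_initial_state,
                                   derive_lambda, estimate_tissue_levels,
                                   fit_dose_response, scan_bifurcation_plane,
                                   solve_rate_constants)
from il1switch.equilibria import find_equilibria
from il1switch.model import fast_rhs
from il1switch.synth import generate_invitro_tables


class TestTissueLevels:
    def test_serum_to_islet_bookkeeping(self):
        L_islet, A_islet, L_serum = estimate_tissue_levels(300.0, 500.0, 20.0)
        assert L_serum == pytest.approx(0.6)
        assert (L_islet, A_islet) == (pytest.approx(12.0), pytest.approx(6000.0))

    def test_invitro_endogenous_il1b(self):
        _, _, L = estimate_tissue_levels(114.0, 500.0, 1.0)
        assert L == pytest.approx(0.228)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            estimate_tissue_levels(-1.0)


class TestSolveRateConstants:
    def test_solutions_satisfy_anchor_equations(self, params, anchors):
        solutions = solve_rate_constants(anchors, 30.0, 7200.0, params)
        assert solutions, "expected at least one feasible rate-constant set"
        for ks in solutions:
            assert all(v >= 0 for v in ks.values())
            cand = params.replace(**ks)
            for G, L, A in [(anchors.G_comp, anchors.L_comp, anchors.A_comp),
                            (anchors.G_bif, 30.0, 7200.0),
                            (anchors.G_diab, anchors.L_diab, anchors.A_diab)]:
                dL, dA = fast_rhs(L, A, G, cand)
                assert abs(dL) / (cand.dL * L) < 1e-10
                assert abs(dA) / (cand.dA * A) < 1e-10

    def test_degenerate_anchor_rejected(self, params, anchors):
        with pytest.raises(CalibrationError):
            solve_rate_constants(anchors, anchors.L_comp, 6000.0, params)


class TestCalibrate:
    def test_anchor_roundtrip(self, calib):
        assert max(calib.anchor_residuals.values()) < 1e-8

    def test_fold_and_fold_changes(self, calib, anchors):
        assert calib.G_fold == pytest.approx(anchors.G_bif, abs=0.01)
        assert calib.fold_change_L == pytest.approx(anchors.L_fold_change, rel=0.01)
        assert calib.fold_change_A == pytest.approx(anchors.A_fold_change, rel=0.01)

    def test_lambda_reference(self, calib):
        assert calib.lam == pytest.approx(2.33, rel=0.15)

    def test_beta_balance_at_healthy_glucose(self, cal_params, anchors):
        low = min((e for e in find_equilibria(anchors.healthy_G, cal_params)
                   if e.stable), key=lambda e: e.L_star)
        growth = kin.net_beta_growth(low.occupancy(cal_params), cal_params)
        assert growth == pytest.approx(0.0, abs=1e-10)
        # β-cell mass declines just below the healthy level, grows just above
        for G, sign in ((4.3, -1), (4.7, +1)):
            low = min((e for e in find_equilibria(G, cal_params) if e.stable),
                      key=lambda e: e.L_star)
            assert sign * kin.net_beta_growth(low.occupancy(cal_params),
                                              cal_params) > 0

    def test_tissue_blood_ratio_scale_invariance(self, params, calib):
        """Recalibrating with 10× islet levels preserves the switch geometry.

        The anchored critical glucose and both fold changes are ratios or
        imposed conditions and must be unchanged; receptor occupancies at the
        anchors shift only mildly (the competitive-binding denominator is
        antagonist-dominated), while λ and k1–k6 absorb the rescaling.
        """
        a10 = AnchorConditions(L_comp=120.0, A_comp=60000.0,
                               tissue_blood_ratio=200.0)
        c10 = calibrate(anchors=a10, p=params, seed=1)
        assert c10.G_fold == pytest.approx(calib.G_fold, abs=0.01)
        assert c10.fold_change_L == pytest.approx(calib.fold_change_L, rel=0.01)
        assert c10.fold_change_A == pytest.approx(calib.fold_change_A, rel=0.01)
        F_ref = kin.receptor_occupancy(12.0, 6000.0, params)
        F_10 = kin.receptor_occupancy(120.0, 60000.0, params)
        assert F_10 == pytest.approx(F_ref, rel=0.25)
        assert c10.lam == pytest.approx(calib.lam, rel=0.25)


@pytest.fixture(scope="module")
def scan(params, anchors):
    return scan_bifurcation_plane(anchors, params, n_random=300, seed=7)


class TestScanBifurcationPlane:
    def test_labels_and_regions(self, scan):
        assert set(scan["label"]) <= {"infeasible", "no-switch", "switch"}
        n_switch = (scan["label"] == "switch").sum()
        assert n_switch > 0
        # only a small subset reaches the full anchored fold change
        fc = scan.loc[scan["label"] == "switch", "fold_change_L"].dropna()
        assert (np.abs(fc / 55.8 - 1) < 0.01).mean() < 0.5

    def test_deterministic_under_seed(self, params, anchors, scan):
        again = scan_bifurcation_plane(anchors, params, n_random=300, seed=7)
        assert again.equals(scan)


class TestDbss:
    @pytest.mark.parametrize("G, I_expected, B_expected", [
        (5.47, 70.73, 312.1),
        (5.25, 74.28, 346.7),
    ])
    def test_reference_initial_values(self, params, G, I_expected, B_expected):
        I, B = dbss_initial_state(G, 9.643, params)
        assert I == pytest.approx(I_expected, abs=0.005)
        assert B == pytest.approx(B_expected, abs=0.05)

    def test_hyperglycaemic_limit_rejected(self, params):
        with pytest.raises(ValueError):
            dbss_initial_state(params.r0 / params.dG + 1.0, 9.643, params)


@pytest.fixture(scope="module")
def clean_tables(params):
    return generate_invitro_tables(params, cv=0.0, n_replicates=1, seed=0)


class TestDoseResponseFits:
    @pytest.mark.parametrize("curve, names", [
        ("g", ("s", "v")),
        ("l", ("t_hill", "KF")),
        ("b", ("u", "r")),
        ("prolif", ("ap", "bp", "cp")),
        ("apop", ("aa", "ba", "ca")),
    ])
    def test_noise_free_recovery(self, params, clean_tables, curve, names):
        fit = fit_dose_response(curve, clean_tables[curve], params,
                                add_hypo_anchor=False)
        for name in names:
            assert fit["coefficients"][name] == pytest.approx(
                getattr(params, name), rel=1e-6), name

    def test_supraphysiological_glucose_excluded(self, params, clean_tables):
        fit = fit_dose_response("g", clean_tables["g"], params,
                                add_hypo_anchor=False)
        n_points = (clean_tables["g"]["x"] <= 20).sum()
        assert fit["n_used"] == n_points

    def test_hypoglycaemia_anchor_appended(self, params, clean_tables):
        fit = fit_dose_response("g", clean_tables["g"], params,
                                add_hypo_anchor=True)
        n_points = (clean_tables["g"]["x"] <= 20).sum()
        assert fit["n_used"] == n_points + 1

    def test_noisy_recovery_monte_carlo(self, params):
        """Median coefficient error stays within 20% at 5% assay noise."""
        errors = []
        for seed in range(100):
            tables = generate_invitro_tables(params, cv=0.05, n_replicates=1,
                                             seed=seed)
            fit = fit_dose_response("g", tables["g"], params,
                                    add_hypo_anchor=True)
            errors.append(max(abs(fit["coefficients"]["s"] / params.s - 1),
                              abs(fit["coefficients"]["v"] / params.v - 1)))
        assert np.median(errors) < 0.20

    def test_underdetermined_rejected(self, params):
        with pytest.raises(ValueError):
            fit_dose_response("b", {"x": [1.0], "y": [0.9]}, params)
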