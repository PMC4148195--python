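import numpy as np
import pytest

np.seterr(all="ignore")

from il1switch.calibration import AnchorConditions, calibrate
from il1switch.params import default_parameters


@pytest.fixture(scope="session")
def params():
    """Published reference parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def anchors():
    return AnchorConditions()


@pytest.fixture(scope="session")
def calib():
    """Steady-state calibration from the anchor conditions (shared, ~2 s)."""
    return calibrate(seed=1)


@pytest.fixture(scope="session")
def cal_params(calib):
    """Calibrated parameter set (re-derived k1–k6 and λ)."""
    return calib.params


@pytest.fixture(scope="session")
def cohort_data(cal_params):
    """Synthetic longitudinal cohorts plus their sensitivity inputs."""
    from il1switch.synth import (CohortSpec, generate_glucose_history,
                                 generate_sensitivity_input)
    spec = CohortSpec(seed=5)
    histories = generate_glucose_history(spec, cal_params)
    observed = {c: df[["t_days", "G_mM"]] for c, df in histories.items()}
    sens = generate_sensitivity_input(spec)
    return {"spec": spec, "histories": histories, "observed": observed,
            "sensitivity": sens}


@pytest.fixture(scope="session")
def history_fit(cohort_data, cal_params):
    """(m, τ) fit to the synthetic histories (shared, ~20 s)."""
    from il1switch.calibration import fit_history
    return fit_history(cohort_data["observed"], cohort_data["sensitivity"],
                       cal_params, seed=1, maxiter=25)


@pytest.fixture(scope="session")
def reduced_fit_result(cohort_data, cal_params):
    """Four-parameter fit without presupposed bifurcation (shared, ~2.5 min)."""
    from il1switch.calibration import reduced_fit
    return reduced_fit(cohort_data["observed"], cohort_data["sensitivity"],
                       cal_params, seed=1)


@pytest.fixture(scope="session")
def stages(cal_params, calib):
    """Representative compensation / mild / strong disease states."""
    from il1switch.therapy import construct_disease_state
    return {stage: construct_disease_state(stage, cal_params, calib)
            for stage in ("compensation", "mild", "strong")}


@pytest.fixture(scope="session")
def R_overt(cal_params):
    from il1switch.therapy import _overt_resistance
    return _overt_resistance(cal_params, None)


@pytest.fixture(scope="session")
def sweeps(cal_params, calib):
    """IL-1Ra dose-response sweeps for both disease stages (shared)."""
    from il1switch.therapy import dose_sweep
    return {stage: dose_sweep(stage, None, cal_params, calib)
            for stage in ("mild", "strong")}
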