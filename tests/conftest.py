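"""Shared fixtures.

Expensive artifacts (the reduced-scale calibration and the paired-pulse
runs) are session-scoped so the acceptance tests and module tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gababsim import (
    CALIBRATED,
    KineticParams,
    build_signaling_network,
    make_fixture_targets,
)


@pytest.fixture(scope="session")
def unit_params() -> KineticParams:
    return KineticParams.unit()


@pytest.fixture(scope="session")
def fitted_params() -> KineticParams:
    return CALIBRATED


@pytest.fixture(scope="session")
def fixture_targets():
    return make_fixture_targets()


@pytest.fixture(scope="session")
def post_network(unit_params):
    return build_signaling_network("post", unit_params)


@pytest.fixture(scope="session")
def reduced_fit(fixture_targets):
    """Reduced-scale calibration (population 200, 10 generations)."""
    from gababsim import fit

    return fit(fixture_targets, pop_size=200, n_gen=10, n_trials=1,
               seed=12345)


@pytest.fixture(scope="session")
def reduced_fit_curves(reduced_fit):
    from gababsim import simulate_response_curves
    from gababsim.fitting import SimSettings

    settings = SimSettings(rtol=1e-8, dt_post=1.0, dt_pre_E=2.0,
                           dt_pre_I=2.0, t_end_post=1200.0,
                           t_end_pre_E=2400.0)
    return simulate_response_curves(reduced_fit.selected, settings)


@pytest.fixture(scope="session")
def paired_pulse_ie(fitted_params):
    """I->E paired-pulse runs at ISI 350 ms, GABA_B active and blocked."""
    from gababsim import PairedPulseProtocol, build_axon_model, \
        run_paired_pulse

    model = build_axon_model(kind="pre_I", params=fitted_params)
    on = run_paired_pulse(model, PairedPulseProtocol(
        synapse_type="IE", isi_ms=350.0, gabab_active=True))
    off = run_paired_pulse(model, PairedPulseProtocol(
        synapse_type="IE", isi_ms=350.0, gabab_active=False))
    return on, off


@pytest.fixture(scope="session")
def bath_decay_times(fitted_params):
    """GIRK decay-to-10% times for RGS scales 1, 0.2, 0.1, 0.05."""
    from gababsim import ScenarioSpec, girk_decay_time, \
        simulate_bath_application

    times = {}
    for scale in (1.0, 0.2, 0.1, 0.05):
        sc = ScenarioSpec(rgs_scale=scale, bath_uM=100.0,
                          bath_on_ms=2000.0, bath_off_ms=12000.0)
        traj, g = simulate_bath_application(fitted_params, sc,
                                            t_end=150000.0, dt_out=20.0)
        times[scale] = girk_decay_time(traj.times, g, washout_ms=12000.0)
    return times


@pytest.fixture(scope="session")
def recovery_refit(fitted_params):
    """Parameter-recovery refit against targets generated by the model.

    Synthetic targets are produced from a known parameter set via the
    forward model, then refit at test scale; curve recovery (not
    parameter identifiability) is what is asserted downstream.
    """
    from gababsim import FitTargets, fit, simulate_response_curves
    from gababsim.fitting import (EE_ISIS, IE_ISIS, POST_SAMPLE_TIMES,
                                  SimSettings)

    curves = simulate_response_curves(fitted_params,
                                      SimSettings(rtol=1e-8))
    g = np.interp(POST_SAMPLE_TIMES, curves.t_post, curves.girk_rel)
    post = np.column_stack([POST_SAMPLE_TIMES, g / curves.girk_rel.max()])
    bE = np.interp(EE_ISIS, curves.t_pre_E, curves.binding_E)
    ppr_e = 1.0 - 0.45 * bE / curves.binding_E.max()
    bI = np.interp(IE_ISIS, curves.t_pre_I, curves.binding_I)
    ppr_i = 1.0 - 0.35 * bI / curves.binding_I.max()
    targets = FitTargets(post=post,
                         pre_E=np.column_stack([EE_ISIS, ppr_e]),
                         pre_I=np.column_stack([IE_ISIS, ppr_i]))
    return fit(targets, pop_size=200, n_gen=15, n_trials=1, seed=7)
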