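"""Tests of the calibration machinery: fixtures, objectives, NSGA-II."""

import numpy as np
import pytest

from gababsim.fitting import (
    EE_ISIS,
    IE_ISIS,
    INF_OBJ,
    POST_SAMPLE_TIMES,
    FitTargets,
    ResponseCurves,
    SimSettings,
    _gamma_bump,
    evaluate_objectives,
    make_fixture_targets,
    objective_f1,
    objective_f2,
    objective_f3,
    params_to_vector,
    select_final,
    vector_to_params,
)
from gababsim.network import KineticParams
from gababsim.nsga2 import fast_nondominated_sort, nsga2_minimize


def make_curves(t_post=None, girk=None, t_e=None, b_e=None,
                t_i=None, b_i=None) -> ResponseCurves:
    t_post = np.arange(0.0, 901.0, 10.0) if t_post is None else t_post
    girk = np.zeros_like(t_post) if girk is None else girk
    t_e = np.arange(0.0, 1801.0, 10.0) if t_e is None else t_e
    b_e = np.zeros_like(t_e) if b_e is None else b_e
    t_i = np.arange(0.0, 2201.0, 10.0) if t_i is None else t_i
    b_i = np.zeros_like(t_i) if b_i is None else b_i
    return ResponseCurves(t_post=t_post, girk_rel=girk,
                          girk_weighted=girk, t_pre_E=t_e, binding_E=b_e,
                          t_pre_I=t_i, binding_I=b_i)


class TestFixtures:
    def test_postsynaptic_landmarks(self, fixture_targets):
        """GIRK target peaks at 200 ms and is <5% of peak by 800 ms."""
        t = np.linspace(0.0, 2000.0, 20001)
        curve = _gamma_bump(t, 200.0, order=2)
        assert t[np.argmax(curve)] == pytest.approx(200.0, abs=0.5)
        assert curve[t >= 800.0][0] < 0.05 * curve.max()
        assert fixture_targets.post[:, 0] == pytest.approx(
            POST_SAMPLE_TIMES)

    def test_depression_landmarks(self, fixture_targets):
        t = np.linspace(1.0, 3000.0, 30000)
        depress = 1.0 - np.interp(
            t, fixture_targets.pre_E[:, 0], fixture_targets.pre_E[:, 1])
        # tabulated points bracket a maximum at ISI 300
        e = fixture_targets.pre_E
        assert e[np.argmin(e[:, 1]), 0] == 300.0
        assert e[e[:, 0] == 1600.0, 1][0] >= 0.95

    def test_comparable_ie_dynamics(self, fixture_targets):
        i = fixture_targets.pre_I
        assert i[np.argmin(i[:, 1]), 0] == pytest.approx(300.0, rel=0.2)
        assert np.all((i[:, 1] > 0) & (i[:, 1] <= 1.5))

    def test_deterministic(self):
        a, b = make_fixture_targets(1), make_fixture_targets(2)
        np.testing.assert_array_equal(a.post, b.post)

    def test_csv_round_trip(self, fixture_targets, tmp_path):
        p = tmp_path / "targets.csv"
        fixture_targets.to_csv(p)
        back = FitTargets.from_csv(p)
        np.testing.assert_allclose(back.pre_I, fixture_targets.pre_I)

    def test_validation(self):
        with pytest.raises(ValueError, match="increase"):
            FitTargets(post=np.array([[2.0, 0.5], [1.0, 0.6]]),
                       pre_E=np.array([[1.0, 0.9]]),
                       pre_I=np.array([[1.0, 0.9]]))
        with pytest.raises(ValueError, match="PPR"):
            FitTargets(post=np.array([[1.0, 0.5]]),
                       pre_E=np.array([[1.0, 1.6]]),
                       pre_I=np.array([[1.0, 0.9]]))


class TestObjectives:
    def test_f1_proportional_curve_is_zero(self, fixture_targets):
        # grid includes the (non-integer) sample times so interpolation
        # reproduces the target values exactly
        t = np.unique(np.concatenate([np.arange(0.0, 901.0, 1.0),
                                      fixture_targets.post[:, 0]]))
        model = 7.7 * np.interp(t, fixture_targets.post[:, 0],
                                fixture_targets.post[:, 1])
        model[t > 700] = 0.0  # peak stays within the sampled window
        f1 = objective_f1(make_curves(t_post=t, girk=model),
                          fixture_targets)
        assert f1 == pytest.approx(0.0, abs=1e-12)

    def test_f1_hand_case(self):
        """Two points, targets (1, 0.5), normalized model (1, 0.25)."""
        targets = FitTargets(post=np.array([[100.0, 1.0], [200.0, 0.5]]),
                             pre_E=np.array([[100.0, 0.5]]),
                             pre_I=np.array([[100.0, 0.5]]))
        t = np.array([0.0, 100.0, 200.0])
        girk = np.array([0.0, 8.0, 2.0])  # normalized: 1, 0.25
        f1 = objective_f1(make_curves(t_post=t, girk=girk), targets)
        assert f1 == pytest.approx(0.25)

    def test_f1_zero_signal_flagged(self, fixture_targets):
        assert objective_f1(make_curves(), fixture_targets) == INF_OBJ

    def test_f2_proportional_binding_is_zero(self, fixture_targets):
        tE = np.arange(0.0, 1801.0, 1.0)
        tI = np.arange(0.0, 2201.0, 1.0)
        dE = 1 - np.interp(tE, *fixture_targets.pre_E.T)
        dI = 1 - np.interp(tI, *fixture_targets.pre_I.T)
        f2 = objective_f2(make_curves(t_e=tE, b_e=3.3 * dE,
                                      t_i=tI, b_i=0.1 * dI),
                          fixture_targets)
        assert f2 == pytest.approx(0.0, abs=1e-9)

    def test_f2_hand_case(self):
        targets = FitTargets(
            post=np.array([[100.0, 1.0]]),
            pre_E=np.array([[100.0, 0.6], [200.0, 0.8]]),  # depress .4,.2
            pre_I=np.array([[100.0, 0.5]]))                # depress .5
        tE = np.array([0.0, 100.0, 200.0])
        bE = np.array([0.0, 10.0, 10.0])   # normalized 1, 1
        tI = np.array([0.0, 100.0])
        bI = np.array([0.0, 4.0])          # normalized 1
        f2 = objective_f2(make_curves(t_e=tE, b_e=bE, t_i=tI, b_i=bI),
                          targets)
        # E: |1-1| + |0.5-1| = 0.5 ; I: |1-1| = 0
        assert f2 == pytest.approx(0.5)

    def test_f2_zero_binding_flagged(self, fixture_targets):
        tE = np.arange(0.0, 1801.0, 1.0)
        dE = 1 - np.interp(tE, *fixture_targets.pre_E.T)
        assert objective_f2(make_curves(t_e=tE, b_e=dE),
                            fixture_targets) == INF_OBJ

    def test_f3_product_of_maxima(self):
        t = np.array([0.0, 1.0, 2.0])
        cur = make_curves(t_post=t, girk=np.array([0, 2.0, 1.0]),
                          t_e=t, b_e=np.array([0, 3.0, 1.0]),
                          t_i=t, b_i=np.array([0, 4.0, 1.0]))
        assert objective_f3(cur) == pytest.approx(-24.0)

    def test_f3_zero_signal_is_zero(self):
        assert objective_f3(make_curves()) == 0.0

    def test_scale_invariance(self, fixture_targets):
        t = np.arange(0.0, 901.0, 1.0)
        girk = _gamma_bump(t, 180.0, 2)
        tE = np.arange(0.0, 1801.0, 1.0)
        bE = _gamma_bump(tE, 350.0, 1)
        tI = np.arange(0.0, 2201.0, 1.0)
        bI = _gamma_bump(tI, 280.0, 1)
        base = make_curves(t_post=t, girk=girk, t_e=tE, b_e=bE,
                           t_i=tI, b_i=bI)
        scaled = make_curves(t_post=t, girk=17.0 * girk, t_e=tE,
                             b_e=0.003 * bE, t_i=tI, b_i=5.0 * bI)
        assert objective_f1(base, fixture_targets) == pytest.approx(
            objective_f1(scaled, fixture_targets))
        assert objective_f2(base, fixture_targets) == pytest.approx(
            objective_f2(scaled, fixture_targets))

    def test_pure_function_repeatable(self, fixture_targets):
        p = KineticParams.unit()
        a = evaluate_objectives(p, fixture_targets)
        b = evaluate_objectives(p, fixture_targets)
        assert (a.f1, a.f2, a.f3) == (b.f1, b.f2, b.f3)

    def test_dose_monotonicity_of_f3(self, fixture_targets):
        lo = evaluate_objectives(KineticParams.unit(f_gaba=200.0),
                                 fixture_targets)
        hi = evaluate_objectives(KineticParams.unit(f_gaba=400.0),
                                 fixture_targets)
        assert hi.f3 < lo.f3

    def test_no_activation_flagged(self, fixture_targets):
        ov = evaluate_objectives(KineticParams.unit(k3=0.0),
                                 fixture_targets)
        assert ov.flagged


class TestSelection:
    def test_singleton(self):
        assert select_final(np.array([[1.0, 2.0, -3.0]])) == 0

    def test_tie_broken_by_lower_f1(self):
        F = np.array([[1.0, 3.0, 0.0], [2.0, 2.0, 0.0], [3.0, 1.0, 0.0]])
        # medians 2, 2 -> all scores equal 2.0; lowest f1 wins
        assert select_final(F) == 0

    def test_dominating_member_selected(self):
        F = np.array([[0.5, 0.5, 0.0], [1.0, 2.0, 0.0], [2.0, 1.0, 0.0]])
        assert select_final(F) == 0

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError):
            select_final(np.full((4, 3), INF_OBJ))


class TestNSGA2:
    @staticmethod
    def _sch(x):
        """Schaffer problem: convex front f2 = (sqrt(f1) - 2)^2."""
        return np.array([x[0] ** 2, (x[0] - 2.0) ** 2])

    def test_converges_to_known_front(self):
        res = nsga2_minimize(self._sch, [(-5.0, 5.0)], pop_size=40,
                             n_gen=40, seed=3)
        fronts = fast_nondominated_sort(res.F)
        lead = res.F[fronts[0]]
        # all nondominated points close to the analytic front
        expected = (np.sqrt(lead[:, 0]) - 2.0) ** 2
        assert np.all(np.abs(lead[:, 1] - expected) < 0.05)
        # and the front is covered end to end
        assert lead[:, 0].min() < 0.05 and lead[:, 0].max() > 3.5

    def test_deterministic_given_seed(self):
        a = nsga2_minimize(self._sch, [(-5.0, 5.0)], pop_size=16,
                           n_gen=5, seed=11)
        b = nsga2_minimize(self._sch, [(-5.0, 5.0)], pop_size=16,
                           n_gen=5, seed=11)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.F, b.F)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nsga2_minimize(self._sch, [(-5.0, 5.0)], pop_size=6,
                           n_gen=5, seed=0)
        with pytest.raises(ValueError):
            nsga2_minimize(self._sch, [(-5.0, 5.0)], pop_size=16,
                           n_gen=0, seed=0)

    def test_vector_round_trip(self):
        p = KineticParams.unit(k2=3.3, rgs_pre_I=0.7)
        assert vector_to_params(params_to_vector(p)) == p


class TestFitPipeline:
    def test_median_objective_improves(self, reduced_fit):
        """Median f1 over the population is nonincreasing in at least 80%
        of the generation steps of the reduced-scale run."""
        hist = reduced_fit.trials[0].history
        med = np.array([np.median(F[:, 0][F[:, 0] < INF_OBJ])
                        for F in hist])
        steps = np.diff(med)
        assert np.mean(steps <= 1e-12) >= 0.8

    def test_selected_objectives_reasonable(self, reduced_fit):
        ov = reduced_fit.selected_objectives
        assert ov.f1 < INF_OBJ and ov.f2 < INF_OBJ
        assert ov.f3 < 0

    def test_population_frame_schema(self, reduced_fit):
        df = reduced_fit.population_frame()
        assert {"k1", "f1", "f2", "f3", "trial", "member"} <= set(df)
        assert len(df) == 200
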