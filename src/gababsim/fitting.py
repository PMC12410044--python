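"""Multi-objective calibration of the signaling kinetics.

Three objectives constrain the nine free parameters (k1..k5, three
domain-specific RGS concentrations, GABA flux magnitude):

* f1 — L1 distance between the max-normalized postsynaptic GIRK
  conductance time course and the max-normalized target IPSC samples
  (16 points, 80-700 ms after stimulus onset);
* f2 — L1 distance between max-normalized depression (1 - PPR) and the
  max-normalized G_ibg-bound VGCC time course, summed over the E->E
  (6 ISIs) and I->E (7 ISIs) synapse types;
* f3 — negative product of the three absolute signal maxima, pushing the
  search away from well-shaped but vanishing responses.  f3 is never used
  for the final selection.

NSGA-II explores the bounded parameter box; the final set is the member
minimizing f1/median(f1) + f2/median(f2) over the final population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import girk_relative_conductance, girk_weighted_occupancy
from .network import (
    PARAM_BOUNDS,
    IntegrationError,
    KineticParams,
    StimulusSchedule,
    build_signaling_network,
    simulate_signaling,
)
from .nsga2 import NSGA2Result, nsga2_minimize

__all__ = [
    "FitTargets",
    "ObjectiveValues",
    "SimSettings",
    "PARAM_NAMES",
    "INF_OBJ",
    "CALIBRATED",
    "make_fixture_targets",
    "simulate_response_curves",
    "objective_f1",
    "objective_f2",
    "objective_f3",
    "evaluate_objectives",
    "run_nsga2",
    "select_final",
    "fit",
    "FitResult",
]

#: Large finite sentinel standing in for an infinite (flagged) objective,
#: keeping nondominated sorting well-defined.
INF_OBJ = 1e9

PARAM_NAMES = ("k1", "k2", "k3", "k4", "k5",
               "rgs_post", "rgs_pre_E", "rgs_pre_I", "f_gaba")
BOUNDS = [PARAM_BOUNDS[n] for n in PARAM_NAMES]
# Rate multipliers span several decades, so the genetic search runs in
# log coordinates for k2..k5 (floored just above zero where the printed
# lower bound is 0): crossover and mutation then act on the order of
# magnitude, the natural scale for rate constants.  Objectives are always
# evaluated on the linear (bounded) parameters.
LOG_SEARCH = [n in ("k2", "k3", "k4", "k5") for n in PARAM_NAMES]
LOG_FLOOR = 1e-3


def _ga_bounds() -> list[tuple[float, float]]:
    out = []
    for (lo, hi), is_log in zip(BOUNDS, LOG_SEARCH):
        if is_log:
            out.append((np.log(max(lo, LOG_FLOOR)), np.log(hi)))
        else:
            out.append((lo, hi))
    return out


def _from_ga(x: np.ndarray) -> np.ndarray:
    y = np.asarray(x, float).copy()
    for i, ((lo, hi), is_log) in enumerate(zip(BOUNDS, LOG_SEARCH)):
        if is_log:
            y[i] = np.exp(y[i])
        # exp/log round trips can overshoot a bound by a few ulp
        y[i] = min(max(y[i], lo), hi)
    return y


def _to_ga(x: np.ndarray) -> np.ndarray:
    y = np.asarray(x, float).copy()
    for i, is_log in enumerate(LOG_SEARCH):
        if is_log:
            y[i] = np.log(np.clip(y[i], LOG_FLOOR, None))
    return y


def params_to_vector(p: KineticParams) -> np.ndarray:
    return np.array([getattr(p, n) for n in PARAM_NAMES], float)


def vector_to_params(x: np.ndarray,
                     stim_duration: float = 1.0) -> KineticParams:
    kw = {n: float(v) for n, v in zip(PARAM_NAMES, x)}
    return KineticParams(stim_duration=stim_duration, **kw)


@dataclass(frozen=True)
class FitTargets:
    """Normalized target curves for the three calibration data sets.

    ``post``: (time ms, normalized IPSC) pairs; ``pre_E``/``pre_I``:
    (ISI ms, PPR) pairs.
    """

    post: np.ndarray    # (16, 2)
    pre_E: np.ndarray   # (6, 2)
    pre_I: np.ndarray   # (7, 2)

    def __post_init__(self) -> None:
        for name in ("post", "pre_E", "pre_I"):
            arr = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name}: expected (n, 2) array")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name}: times must increase")
        if np.any((self.post[:, 1] < 0) | (self.post[:, 1] > 1)):
            raise ValueError("post targets must lie in [0, 1]")
        for name in ("pre_E", "pre_I"):
            ppr = getattr(self, name)[:, 1]
            if np.any((ppr <= 0) | (ppr > 1.5)):
                raise ValueError(f"{name}: PPR must lie in (0, 1.5]")

    def to_csv(self, path) -> None:
        rows = []
        for cid, arr in (("post", self.post), ("preE", self.pre_E),
                         ("preI", self.pre_I)):
            for t, v in arr:
                rows.append((t, v, cid))
        pd.DataFrame(rows, columns=["t_ms_or_isi_ms", "value", "curve_id"]) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FitTargets":
        df = pd.read_csv(path)
        def grab(cid):
            sub = df[df["curve_id"] == cid]
            return sub[["t_ms_or_isi_ms", "value"]].to_numpy(float)
        return cls(post=grab("post"), pre_E=grab("preE"), pre_I=grab("preI"))


def _gamma_bump(t, t_peak, order=2):
    """Smooth unimodal curve with peak 1 at ``t_peak``; (x e^(1-x))^order."""
    x = np.asarray(t, float) / t_peak
    return (x * np.exp(1.0 - x)) ** order


# Landmark constants of the target dynamics: postsynaptic GIRK response
# peaking at 200 ms and near zero by 800 ms; E->E depression maximal at
# 300 ms, recovered by 1600 ms; comparable I->E dynamics.
POST_PEAK_MS = 200.0
EE_PEAK_MS = 300.0
IE_PEAK_MS = 300.0
EE_DEPTH = 0.45
IE_DEPTH = 0.35
POST_SAMPLE_TIMES = 80.0 + (700.0 - 80.0) / 15.0 * np.arange(16)
EE_ISIS = np.array([100.0, 200.0, 300.0, 500.0, 800.0, 1600.0])
IE_ISIS = np.array([50.0, 100.0, 200.0, 350.0, 500.0, 1000.0, 2000.0])


def make_fixture_targets(seed: int = 0) -> FitTargets:
    """Synthetic stand-in target curves built from the stated landmarks.

    The experimental sample values behind the calibration are not public;
    these smooth curves reproduce their landmark features and are intended
    as fixtures only — user-supplied target tables override them.  The
    curves are deterministic; ``seed`` is accepted for interface stability.
    """
    del seed
    post = _gamma_bump(POST_SAMPLE_TIMES, POST_PEAK_MS, order=2)
    ppr_e = 1.0 - EE_DEPTH * _gamma_bump(EE_ISIS, EE_PEAK_MS, order=1)
    ppr_i = 1.0 - IE_DEPTH * _gamma_bump(IE_ISIS, IE_PEAK_MS, order=1)
    return FitTargets(
        post=np.column_stack([POST_SAMPLE_TIMES, post]),
        pre_E=np.column_stack([EE_ISIS, ppr_e]),
        pre_I=np.column_stack([IE_ISIS, ppr_i]),
    )


@dataclass(frozen=True)
class SimSettings:
    """Simulation protocol and solver settings used by the objectives."""

    rtol: float = 1e-6
    atol: float = 1e-3
    t_end_post: float = 900.0
    dt_post: float = 3.0
    t_end_pre_E: float = 1800.0
    dt_pre_E: float = 6.0
    t_end_pre_I: float = 2200.0
    dt_pre_I: float = 8.0
    #: GABA boluses in the E->E conditioning train (5-pulse 50 Hz burst).
    n_boluses_E: int = 5
    bolus_interval_E: float = 20.0


DEFAULT_SETTINGS = SimSettings()
STRICT_SETTINGS = SimSettings(rtol=1e-8, dt_post=1.0, dt_pre_E=2.0,
                              dt_pre_I=2.0)


@dataclass(frozen=True)
class ResponseCurves:
    t_post: np.ndarray
    girk_rel: np.ndarray       # relative conductance in [0, 1]
    girk_weighted: np.ndarray  # unnormalized weighted occupancy (nM)
    t_pre_E: np.ndarray
    binding_E: np.ndarray      # [VGCCGibg] (nM), E->E terminal
    t_pre_I: np.ndarray
    binding_I: np.ndarray      # [VGCCGibg] (nM), I->E terminal


from .channels import GIRK_STATE_SPECIES as _GIRK_STATES


def simulate_response_curves(params: KineticParams,
                             settings: SimSettings = DEFAULT_SETTINGS
                             ) -> ResponseCurves:
    """Run the three compartment simulations behind the objectives.

    Postsynaptic: a single GABA bolus.  E->E terminal: a conditioning
    train of boluses (the heterosynaptic protocol's burst).  I->E
    terminal: a single bolus (autoreceptor protocol).
    """
    bolus = params.f_gaba
    dur = params.stim_duration

    post_net = build_signaling_network("post", params, rtol=settings.rtol,
                                       atol=settings.atol)
    post = simulate_signaling(
        post_net, StimulusSchedule(((0.0, dur, bolus),)),
        t_end=settings.t_end_post, dt_out=settings.dt_post)
    occ = np.column_stack([post[s] for s in _GIRK_STATES])
    girk_rel = girk_relative_conductance(occ)
    girk_w = girk_weighted_occupancy(occ)

    pre_e_net = build_signaling_network("pre_E", params, rtol=settings.rtol,
                                        atol=settings.atol)
    stim_e = StimulusSchedule.bolus_train(
        settings.n_boluses_E, settings.bolus_interval_E, bolus, dur)
    pre_e = simulate_signaling(pre_e_net, stim_e,
                               t_end=settings.t_end_pre_E,
                               dt_out=settings.dt_pre_E)

    pre_i_net = build_signaling_network("pre_I", params, rtol=settings.rtol,
                                        atol=settings.atol)
    pre_i = simulate_signaling(pre_i_net,
                               StimulusSchedule(((0.0, dur, bolus),)),
                               t_end=settings.t_end_pre_I,
                               dt_out=settings.dt_pre_I)
    return ResponseCurves(
        t_post=post.times, girk_rel=girk_rel, girk_weighted=girk_w,
        t_pre_E=pre_e.times, binding_E=pre_e["VGCCGibg"],
        t_pre_I=pre_i.times, binding_I=pre_i["VGCCGibg"])


@dataclass(frozen=True)
class ObjectiveValues:
    f1: float
    f2: float
    f3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3])

    @property
    def flagged(self) -> bool:
        return self.f1 >= INF_OBJ or self.f2 >= INF_OBJ


def _normalized_l1(target_t, target_v, model_t, model_v) -> float:
    vmax = float(np.max(model_v))
    if not np.isfinite(vmax) or vmax <= 0:
        return INF_OBJ
    tmax = float(np.max(target_v))
    model_at = np.interp(target_t, model_t, model_v)
    return float(np.sum(np.abs(target_v / tmax - model_at / vmax)))


def objective_f1(curves: ResponseCurves, targets: FitTargets) -> float:
    """Postsynaptic discrepancy between normalized conductance and IPSC."""
    return _normalized_l1(targets.post[:, 0], targets.post[:, 1],
                          curves.t_post, curves.girk_rel)


def objective_f2(curves: ResponseCurves, targets: FitTargets) -> float:
    """Presynaptic discrepancy: normalized (1-PPR) vs normalized binding."""
    total = 0.0
    for tgt, t, b in ((targets.pre_E, curves.t_pre_E, curves.binding_E),
                      (targets.pre_I, curves.t_pre_I, curves.binding_I)):
        depress = 1.0 - tgt[:, 1]
        dmax = float(np.max(depress))
        if dmax <= 0:
            raise ValueError("target PPR curve shows no depression")
        bmax = float(np.max(b))
        if not np.isfinite(bmax) or bmax <= 0:
            return INF_OBJ
        b_at = np.interp(tgt[:, 0], t, b)
        total += float(np.sum(np.abs(depress / dmax - b_at / bmax)))
    return total


def objective_f3(curves: ResponseCurves) -> float:
    """Negative product of the three absolute signal maxima (<= 0)."""
    return -(float(np.max(curves.girk_weighted))
             * float(np.max(curves.binding_E))
             * float(np.max(curves.binding_I)))


def evaluate_objectives(params: KineticParams, targets: FitTargets,
                        settings: SimSettings = DEFAULT_SETTINGS
                        ) -> ObjectiveValues:
    """Pure function of (params, targets, settings) -> (f1, f2, f3)."""
    try:
        curves = simulate_response_curves(params, settings)
    except (IntegrationError, FloatingPointError):
        return ObjectiveValues(INF_OBJ, INF_OBJ, 0.0)
    return ObjectiveValues(objective_f1(curves, targets),
                           objective_f2(curves, targets),
                           objective_f3(curves))


def run_nsga2(targets: FitTargets, pop_size: int = 2000, n_gen: int = 25,
              seed: int = 0, n_trials: int = 15,
              settings: SimSettings = DEFAULT_SETTINGS,
              stim_duration: float = 1.0) -> list[NSGA2Result]:
    """Seeded NSGA-II over (f1, f2, f3); one result per independent trial.

    Reference scale is 2000 x 25 x 15 trials; test-scale runs simply pass
    smaller numbers.
    """
    # The GA minimizes (f1, f2, -log(1 - f3)): a strictly monotone
    # transform of the amplitude objective, which spans many orders of
    # magnitude.  Pareto dominance is unchanged; only the crowding
    # metric sees the compressed scale, so diversity slots are not
    # monopolized by extreme-amplitude members.  Reported objectives are
    # always on the defined scale.
    def _eval(x: np.ndarray) -> np.ndarray:
        p = vector_to_params(_from_ga(x), stim_duration)
        f = evaluate_objectives(p, targets, settings).as_array()
        f[2] = -np.log1p(-f[2])
        return f

    # Low-eta SBX with certain crossover: children interpolate between
    # parents rather than hugging them, which keeps the short generation
    # budget filling the middle of the (f1, f2) front instead of its ends.
    results = []
    for trial in range(n_trials):
        res = nsga2_minimize(_eval, _ga_bounds(), pop_size=pop_size,
                             n_gen=n_gen, seed=seed + trial,
                             eta_c=5.0, p_c=1.0, eta_m=15.0)
        res.X = np.array([_from_ga(x) for x in res.X])
        res.F[:, 2] = -np.expm1(-res.F[:, 2])
        for F in res.history:
            F[:, 2] = -np.expm1(-F[:, 2])
        results.append(res)
    return results


def select_final(F: np.ndarray) -> int:
    """Index of the member minimizing f1/median(f1) + f2/median(f2).

    Medians are taken over non-flagged members; ties broken by lower f1,
    then lower index.  f3 plays no role in the selection.
    """
    F = np.asarray(F, float)
    finite = (F[:, 0] < INF_OBJ) & (F[:, 1] < INF_OBJ)
    if not finite.any():
        raise ValueError("no member with finite objectives")
    med1 = float(np.median(F[finite, 0]))
    med2 = float(np.median(F[finite, 1]))
    med1 = med1 if med1 > 0 else 1.0
    med2 = med2 if med2 > 0 else 1.0
    score = F[:, 0] / med1 + F[:, 1] / med2
    order = np.lexsort((np.arange(len(F)), F[:, 0], score))
    return int(order[0])


@dataclass
class FitResult:
    trials: list[NSGA2Result]
    selected: KineticParams
    selected_objectives: ObjectiveValues
    seed: int

    def population_frame(self) -> pd.DataFrame:
        rows = []
        for t, res in enumerate(self.trials):
            for i, (x, f) in enumerate(zip(res.X, res.F)):
                row = dict(zip(PARAM_NAMES, x))
                row.update(f1=f[0], f2=f[1], f3=f[2], trial=t,
                           generation=len(res.history) - 1, member=i)
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.population_frame().to_csv(path, index=False)


def fit(targets: FitTargets | None = None, pop_size: int = 2000,
        n_gen: int = 25, n_trials: int = 15, seed: int = 0,
        settings: SimSettings = DEFAULT_SETTINGS,
        stim_duration: float = 1.0) -> FitResult:
    """Calibrate the kinetics and select the final parameter set.

    The selection rule is applied to the pooled final populations of all
    trials (for a single trial this is the plain per-population rule).
    """
    if targets is None:
        targets = make_fixture_targets()
    trials = run_nsga2(targets, pop_size, n_gen, seed, n_trials,
                       settings, stim_duration)
    X = np.vstack([r.X for r in trials])
    F = np.vstack([r.F for r in trials])
    idx = select_final(F)
    params = vector_to_params(X[idx], stim_duration)
    return FitResult(trials=trials, selected=params,
                     selected_objectives=ObjectiveValues(*F[idx]),
                     seed=seed)


#: Parameter set selected by the package's reference calibration against
#: the fixture targets: fit(pop_size=400, n_gen=20, n_trials=1, seed=0),
#: objectives f1 = 0.645, f2 = 0.344.  The calibrated model's postsynaptic
#: conductance peaks at 217 ms (below 5% of peak by 912 ms) and its E->E
#: VGCC binding peaks at 272 ms (below 5% by 1620 ms).  Regenerate with
#: examples/05_fit.py.
CALIBRATED = KineticParams(
    k1=921.94023,
    k2=7.223732,
    k3=690.139086,
    k4=2.068984,
    k5=30.80268,
    rgs_post=5.741795,
    rgs_pre_E=3.246376,
    rgs_pre_I=2.342711,
    f_gaba=3000.0,
)
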