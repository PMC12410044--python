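"""Single-compartment postsynaptic surrogate.

A leak + GIRK membrane coupled to the signaling cascade, with
neurotransmitter-gated AMPA/NMDA synaptic gating variables.  It supports
the mechanistic manipulation experiments — agonist bath application and
washout, RGS knockdown, increased agonist sensitivity, and tonic (basal)
receptor activity — on a single compartment.  The surrogate reproduces
directions of effect and relative time courses; it does not attempt the
absolute millivolt or threshold numbers of full multicompartmental
morphologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .channels import (
    GIRK_GMAX_PS,
    areal_density,
    girk_gate_inf,
    girk_relative_conductance,
)
from .network import (
    KineticParams,
    ReactionSpec,
    StimulusSchedule,
    Trajectory,
    build_signaling_network,
    simulate_signaling,
)

__all__ = [
    "SynapseParams",
    "synapse_rhs",
    "nmda_calcium_current",
    "ScenarioSpec",
    "apply_scenario",
    "PostsynapticModel",
    "simulate_bath_application",
    "girk_decay_time",
    "MembraneParams",
]

#: 1 A.U. of basal receptor activity corresponds to 1 pM agonist.
PM_PER_AU = 1e-3  # nM


@dataclass(frozen=True)
class SynapseParams:
    """NT-gated AMPA/NMDA gating-variable parameters."""

    tau_s_ampa: float = 2.0    # ms
    tau_x_nmda: float = 2.0    # ms
    tau_s_nmda: float = 100.0  # ms
    alpha_s_nmda: float = 0.5  # 1/ms
    c_nt: float = 1.0          # 1/(ms*mM)
    g_ampa_max: float = 1.0
    g_nmda_max: float = 1.0


def synapse_rhs(s_ampa: float, x_nmda: float, s_nmda: float, nt_mM: float,
                p: SynapseParams = SynapseParams()) -> tuple[float, float, float]:
    """Time derivatives of the three synaptic gating variables.

    ds_AMPA/dt = -s_AMPA/tau_s,AMPA + c_NT*[NT]
    dx_NMDA/dt = -x_NMDA/tau_x,NMDA + c_NT*[NT]
    ds_NMDA/dt = -s_NMDA/tau_s,NMDA + alpha_s,NMDA * x_NMDA * (1 - s_NMDA)
    """
    if nt_mM < 0:
        raise ValueError("NT concentration must be nonnegative")
    ds_ampa = -s_ampa / p.tau_s_ampa + p.c_nt * nt_mM
    dx_nmda = -x_nmda / p.tau_x_nmda + p.c_nt * nt_mM
    ds_nmda = (-s_nmda / p.tau_s_nmda
               + p.alpha_s_nmda * x_nmda * (1.0 - s_nmda))
    return ds_ampa, dx_nmda, ds_nmda


def nmda_calcium_current(i_nmda):
    """Ca2+ component of the NMDAR current: 10% of the total."""
    return 0.1 * np.asarray(i_nmda) if np.ndim(i_nmda) else 0.1 * i_nmda


@dataclass(frozen=True)
class ScenarioSpec:
    """Mechanistic manipulation of the GABA_B pathway.

    ``rgs_scale`` scales the RGS concentration (0.1 = 90% knockdown);
    ``sensitivity_scale`` models increased agonist sensitivity by scaling
    every agonist concentration the receptors see (flux, bath, basal);
    ``basal_au`` is tonic receptor activity as a constant non-depleting
    agonist concentration (1 A.U. = 1 pM).
    """

    rgs_scale: float = 1.0
    sensitivity_scale: float = 1.0
    basal_au: float = 0.0
    bath_uM: float = 0.0
    bath_on_ms: float = 0.0
    bath_off_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.rgs_scale <= 1.0):
            raise ValueError("rgs_scale must be in (0, 1]")
        if self.sensitivity_scale < 1.0:
            raise ValueError("sensitivity_scale must be >= 1")
        if self.basal_au < 0 or self.bath_uM < 0:
            raise ValueError("negative agonist level")


#: The RGS7-knockout scenario: 90% RGS reduction + fivefold sensitivity.
RGS7_KO = ScenarioSpec(rgs_scale=0.1, sensitivity_scale=5.0)


def apply_scenario(params: KineticParams,
                   scenario: ScenarioSpec) -> KineticParams:
    """Scale the kinetic parameters for one scenario.

    RGS concentrations are multiplied by ``rgs_scale`` (clipped to the
    lower bound of the parameter box); agonist-side scaling is applied at
    simulation time to the agonist inputs, not here.
    """
    lo = 0.1
    return params.replace(
        rgs_post=max(lo, params.rgs_post * scenario.rgs_scale),
        rgs_pre_E=max(lo, params.rgs_pre_E * scenario.rgs_scale),
        rgs_pre_I=max(lo, params.rgs_pre_I * scenario.rgs_scale),
    )


@dataclass(frozen=True)
class MembraneParams:
    """Leak + GIRK single-compartment membrane."""

    g_leak_mS_cm2: float = 0.05
    e_leak_mV: float = -70.0
    e_k_mV: float = -90.0
    #: GIRK surface density from 1 uM channels in a 0.8 um compartment.
    girk_conc_nM: float = 1000.0
    diameter_um: float = 0.8

    @property
    def girk_density_um2(self) -> float:
        return areal_density(self.girk_conc_nM, self.diameter_um)

    @property
    def g_girk_max_mS_cm2(self) -> float:
        # density (1/um^2) * 33 pS = S/um^2 * 1e8 um^2/cm^2 -> mS/cm^2
        return self.girk_density_um2 * GIRK_GMAX_PS * 1e-12 * 1e8 * 1e3


from .channels import GIRK_STATE_SPECIES as _GIRK_STATES


class PostsynapticModel:
    """Signaling cascade + surrogate membrane under a scenario."""

    def __init__(self, params: KineticParams | None = None,
                 scenario: ScenarioSpec = ScenarioSpec(),
                 membrane: MembraneParams = MembraneParams(),
                 rtol: float = 1e-8, atol: float = 1e-4):
        self.base_params = params or KineticParams()
        self.scenario = scenario
        self.membrane = membrane
        self.params = apply_scenario(self.base_params, scenario)
        self.network = build_signaling_network("post", self.params,
                                               rtol=rtol, atol=atol)

    # -- agonist plumbing ---------------------------------------------
    def _basal_clamp_nM(self) -> float:
        return (self.scenario.basal_au * PM_PER_AU
                * self.scenario.sensitivity_scale)

    def girk_relative(self, traj: Trajectory) -> np.ndarray:
        occ = np.column_stack([traj[s] for s in _GIRK_STATES])
        return girk_relative_conductance(occ)

    def simulate(self, stimulus: StimulusSchedule | None = None,
                 t_end: float = 1000.0, dt_out: float = 1.0,
                 y0=None) -> Trajectory:
        clamps = dict(stimulus.clamps) if stimulus else {}
        basal = self._basal_clamp_nM()
        if basal > 0:
            clamps.setdefault("gaba", basal)
        pulses = stimulus.pulses if stimulus else ()
        s = self.scenario.sensitivity_scale
        pulses = tuple((o, d, f * s) for o, d, f in pulses)
        return simulate_signaling(self.network,
                                  StimulusSchedule(pulses, clamps),
                                  t_end=t_end, dt_out=dt_out, y0=y0)

    # -- bath application ---------------------------------------------
    def simulate_bath_application(self, t_end: float,
                                  dt_out: float = 10.0) -> Trajectory:
        """Agonist bath with washout.

        During the bath, the extracellular pool is clamped at the bath
        concentration and an added reverse uptake reaction (same rate as
        the forward one) sources agonist into the synaptic compartment;
        after washout the pool clamps to zero and forward uptake clears
        the remaining agonist.
        """
        sc = self.scenario
        if t_end <= sc.bath_off_ms:
            raise ValueError("t_end must extend past washout")
        bath_nM = sc.bath_uM * 1000.0 * sc.sensitivity_scale
        k1f = self.params.k1 * 0.0005
        rev = ReactionSpec("R1b", (("gabaOut", 1),), (("gaba", 1),), kf=k1f)
        net_bath = self.network.with_reaction(rev)
        segs = []
        y = self.network.y0
        basal = self._basal_clamp_nM()
        phases = [
            (self.network, 0.0, sc.bath_on_ms, {"gabaOut": 0.0}),
            (net_bath, sc.bath_on_ms, sc.bath_off_ms, {"gabaOut": bath_nM}),
            (self.network, sc.bath_off_ms, t_end, {"gabaOut": 0.0}),
        ]
        out_t, out_y = [], []
        for net, a, b, clamps in phases:
            if b <= a:
                continue
            if basal > 0:
                clamps = {**clamps, "gaba": basal}
                # a non-depleting basal tone coexists with the bath only
                # before onset and after washout
                if net is net_bath:
                    clamps.pop("gaba")
            traj = simulate_signaling(net, StimulusSchedule((), clamps),
                                      t_end=b, dt_out=dt_out, y0=y, t0=a)
            y = traj.final_state()
            keep = slice(0, len(traj.times)) if not out_t else slice(1, None)
            out_t.append(traj.times[keep])
            out_y.append(traj.states[keep])
        times = np.concatenate(out_t)
        states = np.concatenate(out_y)
        return Trajectory(times=times, states=states,
                          species=self.network.species,
                          metadata={"scenario": sc, "kind": "post",
                                    "bath_nM": bath_nM})

    # -- membrane observables -----------------------------------------
    def resting_potential(self, t_ss: float = 300_000.0) -> float:
        """Resting V of the leak+GIRK membrane under the basal tone.

        The cascade is run to (near) steady state under the constant
        non-depleting agonist clamp; the membrane equation is then solved
        for the zero-current potential.
        """
        traj = self.simulate(t_end=t_ss, dt_out=t_ss / 100.0)
        rel = float(self.girk_relative(traj)[-1])
        m = self.membrane
        g_g = m.g_girk_max_mS_cm2 * rel

        def balance(v):
            return (m.g_leak_mS_cm2 * (v - m.e_leak_mV)
                    + g_g * girk_gate_inf(v) * (v - m.e_k_mV))

        return brentq(balance, m.e_k_mV, m.e_leak_mV + 1e-9)


def simulate_bath_application(params: KineticParams,
                              scenario: ScenarioSpec,
                              t_end: float, dt_out: float = 10.0
                              ) -> tuple[Trajectory, np.ndarray]:
    """Convenience wrapper: bath run returning (trajectory, g_rel trace)."""
    model = PostsynapticModel(params=params, scenario=scenario)
    traj = model.simulate_bath_application(t_end, dt_out)
    return traj, model.girk_relative(traj)


def girk_decay_time(times_ms: np.ndarray, conductance: np.ndarray,
                    washout_ms: float,
                    threshold: float = 0.1) -> float:
    """Time (ms) from washout until conductance < threshold x peak.

    The peak is taken over the whole trace.  Returns nan (censored) when
    the conductance never crosses the threshold within the trace.
    """
    times_ms = np.asarray(times_ms, float)
    g = np.asarray(conductance, float)
    if times_ms[-1] < washout_ms:
        raise ValueError("trace contains no washout phase")
    peak = float(np.max(g))
    if peak <= 0:
        return 0.0
    after = times_ms >= washout_ms
    below = after & (g < threshold * peak)
    if not below.any():
        return math.nan
    return float(times_ms[np.argmax(below)] - washout_ms)
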