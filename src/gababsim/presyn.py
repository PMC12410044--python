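"""Composite presynaptic model: axon, bouton, release machinery.

A five-compartment cable — passive (myelinated) end segments, two active
segments with transient Na+ / delayed-rectifier K+ currents, and a small
bouton in between — carries an action potential to the terminal, where a
two-mode N-type Ca2+ current drives Ca2+-triggered vesicle fusion and
neurotransmitter release.  The bouton additionally hosts the GABA_B
signaling cascade; its G_ibg-bound VGCC fraction dynamically sets the
proportion of Ca2+ channels gating in the reluctant mode (+10 mV midpoint,
1.31x slower activation).

The active-membrane Na+/K+ kinetics are a standard Hodgkin-Huxley pair,
kept as a named, swappable mechanism: the downstream quantities of interest
are ratios of neurotransmitter peaks, which are insensitive to the exact
action-potential waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .channels import RELUCTANT_SHIFT_MV, RELUCTANT_TAU_FACTOR
from .network import (
    IntegrationError,
    KineticParams,
    build_signaling_network,
)

__all__ = [
    "CableGeometry",
    "Compartment",
    "PairedPulseProtocol",
    "PresynapticModel",
    "build_axon_model",
    "run_paired_pulse",
    "ppr_curve",
    "facilitation_index",
]

FARADAY = 96485.332  # C/mol


@dataclass(frozen=True)
class Compartment:
    name: str
    length_um: float
    diameter_um: float
    kind: str  # passive | active | bouton

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError(f"{self.name}: dimensions must be positive")
        if self.kind not in ("passive", "active", "bouton"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def lateral_area_cm2(self) -> float:
        return math.pi * self.diameter_um * self.length_um * 1e-8

    @property
    def cross_area_cm2(self) -> float:
        return math.pi * (self.diameter_um / 2.0) ** 2 * 1e-8

    @property
    def volume_L(self) -> float:
        return self.cross_area_cm2 * self.length_um * 1e-4 * 1e-3


@dataclass(frozen=True)
class CableGeometry:
    """Ordered compartments; default is the standard axon-bouton layout."""

    compartments: tuple[Compartment, ...] = (
        Compartment("passive_L", 100.0, 1.0, "passive"),
        Compartment("active_L", 20.0, 1.0, "active"),
        Compartment("bouton", 0.8, 0.4, "bouton"),
        Compartment("active_R", 20.0, 1.0, "active"),
        Compartment("passive_R", 100.0, 1.0, "passive"),
    )
    axial_resistivity_ohm_cm: float = 100.0
    capacitance_uF_cm2: float = 1.0

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.compartments]
        if kinds.count("bouton") != 1:
            raise ValueError("geometry must contain exactly one bouton")

    @property
    def bouton_index(self) -> int:
        return [c.kind for c in self.compartments].index("bouton")


@dataclass(frozen=True)
class ActiveMembraneParams:
    """Hodgkin-Huxley transient Na+ / delayed-rectifier K+ mechanism."""

    g_na: float = 120.0   # mS/cm^2
    e_na: float = 50.0    # mV
    g_k: float = 36.0
    e_k: float = -77.0
    g_leak: float = 0.3
    e_leak: float = -54.387
    v_rest: float = -65.0


@dataclass(frozen=True)
class CaChannelParams:
    """Willing-mode N-type channel; reluctant mode derived by the fixed
    +10 mV shift and 1.31x time-constant factor."""

    #: Bouton Ca2+ conductance density, set so single-AP Ca2+ transients
    #: peak near 1-2 uM — the steep, non-saturated regime of the
    #: fourth-order fusion reaction, where release tracks Ca2+ amplitude.
    g_ca: float = 0.12      # mS/cm^2 in the bouton
    e_ca: float = 60.0      # mV
    v_half: float = -5.0    # activation midpoint (mV)
    slope: float = 6.0      # activation slope (mV)
    tau_act: float = 1.5    # activation time constant (ms)
    n_gates: int = 2        # activation-gate cooperativity

    def m_inf(self, V, reluctant: bool = False):
        vh = self.v_half + (RELUCTANT_SHIFT_MV if reluctant else 0.0)
        return 1.0 / (1.0 + np.exp(-(V - vh) / self.slope))

    def tau(self, reluctant: bool = False):
        return self.tau_act * (RELUCTANT_TAU_FACTOR if reluctant else 1.0)


@dataclass(frozen=True)
class BoutonParams:
    g_leak: float = 0.3     # mS/cm^2
    e_leak: float = -65.0   # mV
    ca_rest_nM: float = 100.0
    #: Free-Ca2+ clearance time constant.  Small boutons with high
    #: surface-to-volume ratio clear Ca2+ within tens of ms; 45 ms keeps
    #: residual-Ca2+ facilitation below ~2% at ISIs >= 350 ms while
    #: preserving strong paired-pulse facilitation at ~50 ms.
    ca_tau_ms: float = 45.0


def _hh_rates(V: float) -> tuple[float, ...]:
    """Classic HH rate functions (rest at about -65 mV)."""
    # guard the removable singularities
    dv = V + 40.0
    a_m = 0.1 * dv / (1.0 - math.exp(-dv / 10.0)) if abs(dv) > 1e-7 else 1.0
    b_m = 4.0 * math.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * math.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    dn = V + 55.0
    a_n = (0.01 * dn / (1.0 - math.exp(-dn / 10.0))
           if abs(dn) > 1e-7 else 0.1)
    b_n = 0.125 * math.exp(-(V + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@dataclass(frozen=True)
class PairedPulseProtocol:
    """Stimulation protocol of the paired-pulse experiments.

    I->E (autoreceptor): the axon fires for both stimuli and, when GABA_B
    signaling is active, each firing also delivers a GABA bolus to the
    terminal.  E->E (heterosynaptic): the first event delivers only the
    GABA bolus train (spillover from neighboring terminals; no axonal
    stimulus) and the axon fires for the second event alone.
    """

    synapse_type: str = "IE"   # "IE" | "EE"
    isi_ms: float = 350.0
    gabab_active: bool = True
    #: boluses in the E->E conditioning event (5-pulse 50 Hz burst); the
    #: I->E protocol always uses a single bolus per firing.
    n_conditioning_boluses: int = 5
    conditioning_interval_ms: float = 20.0
    stim_amp_nA: float = 0.3
    stim_dur_ms: float = 0.5
    pre_run_ms: float = 20.0   # settle time before the first event
    post_run_ms: float = 60.0  # observation window after the last event

    def __post_init__(self) -> None:
        if self.synapse_type not in ("IE", "EE"):
            raise ValueError("synapse_type must be 'IE' or 'EE'")
        if self.isi_ms <= 0:
            raise ValueError("ISI must be positive")


class PresynapticModel:
    """Axon + bouton electrical model coupled to the signaling cascade."""

    def __init__(self, geometry: CableGeometry | None = None,
                 params: KineticParams | None = None,
                 kind: str = "pre_I",
                 active: ActiveMembraneParams | None = None,
                 ca: CaChannelParams | None = None,
                 bouton: BoutonParams | None = None,
                 rtol: float = 1e-6, atol: float = 1e-6,
                 clamp_reluctant_fraction: float | None = None):
        self.geometry = geometry or CableGeometry()
        self.params = params or KineticParams()
        self.kind = kind
        self.active = active or ActiveMembraneParams()
        self.ca = ca or CaChannelParams()
        self.bouton = bouton or BoutonParams()
        self.rtol = rtol
        self.atol = atol
        self.clamp_reluctant_fraction = clamp_reluctant_fraction
        self.network = build_signaling_network(kind, self.params,
                                               include_release=True)
        comps = self.geometry.compartments
        self.n_comp = len(comps)
        self.bouton_i = self.geometry.bouton_index
        self.active_is = [i for i, c in enumerate(comps)
                          if c.kind == "active"]
        # axial conductances between adjacent compartments (mS): current
        # (uA) = g * dV (mV); half-cylinder resistances in series.
        Ra = self.geometry.axial_resistivity_ohm_cm
        g = []
        for a, b in zip(comps, comps[1:]):
            r = (Ra * (a.length_um * 1e-4 / 2) / a.cross_area_cm2
                 + Ra * (b.length_um * 1e-4 / 2) / b.cross_area_cm2)  # Ohm
            g.append(1e3 / r)  # mS
        self.g_axial = np.array(g)
        self.areas = np.array([c.lateral_area_cm2 for c in comps])
        bc = comps[self.bouton_i]
        # inward Ca current (uA/cm^2) -> free-Ca influx (nM/ms)
        self.ca_influx_factor = (bc.lateral_area_cm2 * 1e-6
                                 / (2 * FARADAY * bc.volume_L) * 1e6)
        # state layout: V(n_comp) | m,h,n per active comp | mCa_w, mCa_r |
        # signaling species
        self.n_gate = 3 * len(self.active_is) + 2
        self.n_state = self.n_comp + self.n_gate + self.network.n_species
        self.ca_index = self.n_comp + self.n_gate \
            + self.network.index["Ca"]
        self.gaba_index = self.n_comp + self.n_gate \
            + self.network.index["gaba"]
        self.nt_index = self.n_comp + self.n_gate \
            + self.network.index["NT"]
        self.vgcc_free_i = self.n_comp + self.n_gate \
            + self.network.index["VGCC"]
        self.vgcc_bound_i = self.n_comp + self.n_gate \
            + self.network.index["VGCCGibg"]

    # -- state helpers -------------------------------------------------
    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_state)
        vr = self.active.v_rest
        y[: self.n_comp] = vr
        k = self.n_comp
        a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(vr)
        for _ in self.active_is:
            y[k] = a_m / (a_m + b_m)
            y[k + 1] = a_h / (a_h + b_h)
            y[k + 2] = a_n / (a_n + b_n)
            k += 3
        y[k] = self.ca.m_inf(vr)
        y[k + 1] = self.ca.m_inf(vr, reluctant=True)
        sig = self.network.y0.copy()
        sig[self.network.index["Ca"]] = self.bouton.ca_rest_nM
        y[self.n_comp + self.n_gate:] = sig
        return y

    def reluctant_fraction(self, y: np.ndarray) -> float:
        if self.clamp_reluctant_fraction is not None:
            return self.clamp_reluctant_fraction
        free, bound = y[self.vgcc_free_i], y[self.vgcc_bound_i]
        tot = free + bound
        return bound / tot if tot > 0 else 0.0

    # -- dynamics ------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, stim_uA_cm2,
            gaba_flux) -> np.ndarray:
        dy = np.zeros_like(y)
        V = y[: self.n_comp]
        comps = self.geometry.compartments
        i_mem = np.zeros(self.n_comp)  # uA/cm^2, outward positive
        k = self.n_comp
        for ci in self.active_is:
            m, h, n = y[k], y[k + 1], y[k + 2]
            v = V[ci]
            a_m, b_m, a_h, b_h, a_n, b_n = _hh_rates(v)
            dy[k] = a_m * (1 - m) - b_m * m
            dy[k + 1] = a_h * (1 - h) - b_h * h
            dy[k + 2] = a_n * (1 - n) - b_n * n
            p = self.active
            i_mem[ci] += (p.g_na * m ** 3 * h * (v - p.e_na)
                          + p.g_k * n ** 4 * (v - p.e_k)
                          + p.g_leak * (v - p.e_leak))
            k += 3
        # bouton: leak + two-mode N-type Ca current
        bi = self.bouton_i
        vb = V[bi]
        m_w, m_r = y[k], y[k + 1]
        dy[k] = (self.ca.m_inf(vb) - m_w) / self.ca.tau()
        dy[k + 1] = (self.ca.m_inf(vb, reluctant=True) - m_r) \
            / self.ca.tau(reluctant=True)
        frac_r = self.reluctant_fraction(y)
        gate = ((1.0 - frac_r) * m_w ** self.ca.n_gates
                + frac_r * m_r ** self.ca.n_gates)
        i_ca = self.ca.g_ca * gate * (vb - self.ca.e_ca)
        i_mem[bi] += self.bouton.g_leak * (vb - self.bouton.e_leak) + i_ca

        # axial currents (uA) and external stimulus
        dv = np.zeros(self.n_comp)
        for j, g in enumerate(self.g_axial):
            i_ax = g * (V[j] - V[j + 1])  # uA flowing j -> j+1
            dv[j] -= i_ax / self.areas[j]
            dv[j + 1] += i_ax / self.areas[j + 1]
        dv -= i_mem
        dv += stim_uA_cm2(t)
        dy[: self.n_comp] = dv / self.geometry.capacitance_uF_cm2

        # signaling + release cascade in the bouton
        sig = y[self.n_comp + self.n_gate:]
        dsig = self.network.rhs(sig)
        dy[self.n_comp + self.n_gate:] = dsig
        dy[self.gaba_index] += gaba_flux(t)
        ca_i = self.ca_index
        dy[ca_i] += (-i_ca * self.ca_influx_factor
                     - (y[ca_i] - self.bouton.ca_rest_nM)
                     / self.bouton.ca_tau_ms)
        return dy

    def simulate(self, t_end: float,
                 stim_times: list[float] = (),
                 gaba_times: list[float] = (),
                 stim_amp_nA: float = 0.3, stim_dur_ms: float = 0.5,
                 dt_out: float = 0.25,
                 y0: np.ndarray | None = None) -> pd.DataFrame:
        """Integrate the composite model under a stimulation schedule.

        ``stim_times`` are onsets of square current pulses injected at the
        first (passive) compartment; ``gaba_times`` are onsets of GABA
        boluses (flux ``params.f_gaba`` for ``params.stim_duration``) onto
        the bouton's receptors.
        """
        stim_times = sorted(stim_times)
        gaba_times = sorted(gaba_times)
        amp = stim_amp_nA * 1e-3 / self.areas[0]  # nA -> uA/cm^2

        def stim(t):
            out = np.zeros(self.n_comp)
            for s in stim_times:
                if s <= t < s + stim_dur_ms:
                    out[0] = amp
                    break
            return out

        fg = self.params.f_gaba
        dur = self.params.stim_duration

        def gaba_flux(t):
            for s in gaba_times:
                if s <= t < s + dur:
                    return fg
            return 0.0

        edges = {0.0, t_end}
        for s in stim_times:
            edges.update((s, min(s + stim_dur_ms, t_end)))
        for s in gaba_times:
            edges.update((s, min(s + dur, t_end)))
        edges = sorted(e for e in edges if 0.0 <= e <= t_end)

        y = self.initial_state() if y0 is None else np.asarray(y0, float)
        t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
        rows = [y.copy()]
        filled = 1
        out = np.empty((len(t_grid), self.n_state))
        out[0] = y
        for a, b in zip(edges, edges[1:]):
            mask = (t_grid > a) & (t_grid <= b)
            t_eval = t_grid[mask]
            sol = solve_ivp(self.rhs, (a, b), y, method="LSODA",
                            args=(stim, gaba_flux), t_eval=t_eval
                            if len(t_eval) else None,
                            rtol=self.rtol, atol=self.atol,
                            max_step=max(0.05, (b - a) / 4))
            if not sol.success:
                raise IntegrationError(
                    f"presynaptic solve failed on [{a},{b}]: {sol.message}")
            if len(t_eval):
                out[filled:filled + len(t_eval)] = sol.y.T
                filled += len(t_eval)
            y = sol.y[:, -1]
        df = pd.DataFrame(out[:filled, : self.n_comp],
                          columns=[f"V_{c.name}"
                                   for c in self.geometry.compartments])
        df.insert(0, "time_ms", t_grid[:filled])
        df["Ca_nM"] = out[:filled, self.ca_index]
        df["NT_nM"] = np.clip(out[:filled, self.nt_index], 0.0, None)
        df["VGCCGibg_nM"] = out[:filled, self.vgcc_bound_i]
        df["VGCC_nM"] = out[:filled, self.vgcc_free_i]
        return df


def build_axon_model(geometry: CableGeometry | None = None,
                     params: KineticParams | None = None,
                     kind: str = "pre_I", **kwargs) -> PresynapticModel:
    """Construct the composite axon/bouton model for one synapse type."""
    return PresynapticModel(geometry=geometry, params=params, kind=kind,
                            **kwargs)


def _nt_peak(df: pd.DataFrame, t_from: float, t_to: float) -> float:
    window = df[(df.time_ms >= t_from) & (df.time_ms <= t_to)]
    return float(window["NT_nM"].max()) if len(window) else 0.0


def _crossed_zero(df: pd.DataFrame, column: str) -> bool:
    return bool((df[column] > 0.0).any())


@dataclass
class PairedPulseResult:
    trace: pd.DataFrame
    peaks: list[float]
    ppr: float
    warnings: list[str] = field(default_factory=list)


def run_paired_pulse(model: PresynapticModel,
                     protocol: PairedPulseProtocol) -> PairedPulseResult:
    """Run one paired-pulse experiment and extract per-event NT peaks.

    For I->E the PPR is the second NT peak over the first.  For E->E only
    the second event fires the axon, so the conditioned peak is compared
    against an unconditioned run of the same model (no GABA delivery).
    """
    pre = protocol.pre_run_ms
    isi = protocol.isi_ms
    t_end = pre + isi + protocol.post_run_ms
    warnings = []
    if protocol.synapse_type == "IE":
        stims = [pre, pre + isi]
        gabas = list(stims) if protocol.gabab_active else []
        df = model.simulate(t_end, stims, gabas,
                            protocol.stim_amp_nA, protocol.stim_dur_ms)
        p1 = _nt_peak(df, pre, pre + isi)
        p2 = _nt_peak(df, pre + isi, t_end)
        if not _crossed_zero(df, f"V_{model.geometry.compartments[model.bouton_i].name}"):
            warnings.append("no action potential reached the bouton")
        peaks = [p1, p2]
        ppr = p2 / p1 if p1 > 0 else math.nan
    else:  # EE: conditioning GABA train, axon fires only at the test pulse
        gabas = ([pre + i * protocol.conditioning_interval_ms
                  for i in range(protocol.n_conditioning_boluses)]
                 if protocol.gabab_active else [])
        stims = [pre + isi]
        df = model.simulate(t_end, stims, gabas,
                            protocol.stim_amp_nA, protocol.stim_dur_ms)
        conditioned = _nt_peak(df, pre + isi, t_end)
        first_window_peak = _nt_peak(df, 0.0, pre + isi - 1.0)
        # unconditioned reference: same model, no GABA delivery
        ref = model.simulate(pre + protocol.post_run_ms, [pre], [],
                             protocol.stim_amp_nA, protocol.stim_dur_ms)
        unconditioned = _nt_peak(ref, pre, pre + protocol.post_run_ms)
        peaks = [first_window_peak, conditioned]
        ppr = conditioned / unconditioned if unconditioned > 0 else math.nan
        if not _crossed_zero(df, f"V_{model.geometry.compartments[model.bouton_i].name}"):
            warnings.append("no action potential reached the bouton")
    return PairedPulseResult(trace=df, peaks=peaks, ppr=ppr,
                             warnings=warnings)


def ppr_curve(model_on: PresynapticModel, synapse_type: str,
              isis, model_off: PresynapticModel | None = None,
              **protocol_kwargs) -> pd.DataFrame:
    """PPR vs ISI with GABA_B signaling on and off, plus their ratio.

    ``model_off`` defaults to the same model run without GABA delivery.
    Columns: isi_ms, ppr_on, ppr_off, ppr_norm.
    """
    model_off = model_off or model_on
    rows = []
    for isi in isis:
        on = run_paired_pulse(model_on, PairedPulseProtocol(
            synapse_type=synapse_type, isi_ms=isi, gabab_active=True,
            **protocol_kwargs))
        off = run_paired_pulse(model_off, PairedPulseProtocol(
            synapse_type=synapse_type, isi_ms=isi, gabab_active=False,
            **protocol_kwargs))
        rows.append((isi, on.ppr, off.ppr, on.ppr / off.ppr))
    return pd.DataFrame(rows, columns=["isi_ms", "ppr_on", "ppr_off",
                                       "ppr_norm"])


def facilitation_index(model: PresynapticModel, isi_ms: float = 50.0,
                       gabab_active: bool = True,
                       conditioning_lead_ms: float = 300.0,
                       stim_amp_nA: float = 0.3,
                       stim_dur_ms: float = 0.5) -> float:
    """Ratio of second to first NT peak with both pulses firing.

    When GABA_B signaling is active, a conditioning GABA bolus is
    delivered ``conditioning_lead_ms`` before the pulse pair so that both
    pulses experience an established (roughly equal) VGCC inhibition.
    Reduced release moves the Ca2+ transients into the steeper region of
    the fourth-order fusion cooperativity, which raises the facilitation
    index — the direction observed experimentally.
    """
    pre = 20.0 + (conditioning_lead_ms if gabab_active else 0.0)
    stims = [pre, pre + isi_ms]
    gabas = [pre - conditioning_lead_ms] if gabab_active else []
    t_end = pre + isi_ms + 60.0
    df = model.simulate(t_end, stims, gabas, stim_amp_nA, stim_dur_ms)
    p1 = _nt_peak(df, stims[0], stims[1])
    p2 = _nt_peak(df, stims[1], t_end)
    return p2 / p1 if p1 > 0 else math.nan
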