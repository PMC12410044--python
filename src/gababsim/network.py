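"""Mass-action reaction network of GABA_B receptor signaling.

The module builds and integrates the deterministic ODE system describing
GABA binding to the GABA_B receptor, G_i protein activation, RGS-accelerated
GTP hydrolysis, and G_ibg binding to GIRK channels (postsynaptic) or N-type
voltage-gated Ca2+ channels (presynaptic).  An optional Ca2+-triggered
neurotransmitter-release cascade can be appended for presynaptic terminals.

Canonical units are nM and ms throughout: unimolecular forward/backward
rates are 1/ms, each additional reactant order contributes 1/nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "RELEASE_SPECIES",
    "ReactionSpec",
    "KineticParams",
    "PARAM_BOUNDS",
    "StimulusSchedule",
    "Trajectory",
    "SignalingNetwork",
    "derive_k2x",
    "build_signaling_network",
    "mass_action_rhs",
    "simulate_signaling",
    "conserved_totals",
    "MOIETIES",
]

# Species of the receptor/G-protein cascade, in canonical order.
SPECIES: tuple[str, ...] = (
    "gaba",
    "gabaOut",
    "GABA_B_R",
    "gabaGABA_B_R",
    "G_i",
    "GABA_B_RGi",
    "gabaGABA_B_RGi",
    "gabaGABA_B_RGibg",
    "GiaGTP",
    "GiaGTPRGS",
    "GiaGDP",
    "RGS",
    "Gibg",
    "GIRK",
    "GIRKGibg",
    "GIRKGibg2",
    "GIRKGibg3",
    "GIRKGibg4",
    "VGCC",
    "VGCCGibg",
)

# Additional species of the Ca2+-triggered vesicle-fusion cascade.
RELEASE_SPECIES: tuple[str, ...] = (
    "Ca",
    "Ffactor",
    "FfactorCa4",
    "Ves",
    "FfactorCa4Ves",
    "NT",
)

#: Molecules of transmitter delivered to the cleft per fusion event,
#: expressed as the stoichiometric coefficient of NT in the fusion reaction.
NT_PER_FUSION = 10_000.0

#: Default initial concentrations (nM).  GIRK is zeroed in presynaptic
#: compartments and VGCC in postsynaptic ones, which silently disables the
#: corresponding binding reactions.
INIT_RECEPTOR_NM = 400.0
INIT_GI_NM = 2600.0
INIT_GIRK_NM = 1000.0
INIT_VGCC_NM = 100.0
INIT_FFACTOR_NM = 1000.0
INIT_VES_NM = 1000.0


@dataclass(frozen=True)
class ReactionSpec:
    """One mass-action reaction.

    ``reactants``/``products`` are ``(species, stoichiometric count)``
    pairs; ``kf`` is in 1/ms for one reactant and gains 1/nM per extra
    reactant order; ``kb`` is analogous over the products.
    """

    name: str
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    kf: float
    kb: float = 0.0

    @property
    def reversible(self) -> bool:
        return self.kb != 0.0

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kb < 0:
            raise ValueError(f"{self.name}: negative rate coefficient")
        for sp, _ in (*self.reactants, *self.products):
            if sp not in SPECIES and sp not in RELEASE_SPECIES:
                raise ValueError(f"{self.name}: unknown species {sp!r}")


# Bounds of the calibrated parameters.  k1..k5 are dimensionless multipliers
# on the base rates; RGS concentrations are in uM; f_gaba is in nM/ms.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (0.0, 1000.0),
    "k2": (1e-4, 1000.0),
    "k3": (0.0, 1000.0),
    "k4": (0.0, 100.0),
    "k5": (0.0, 100.0),
    "rgs_post": (0.1, 10.0),
    "rgs_pre_E": (0.1, 10.0),
    "rgs_pre_I": (0.1, 10.0),
    "f_gaba": (0.0, 3000.0),
}


@dataclass(frozen=True)
class KineticParams:
    """Coefficients of the signaling model.

    k1..k5 multiply the base rates of the source models; the RGS
    concentrations (uM) differ between postsynaptic spines and E/I
    presynaptic terminals; ``f_gaba`` (nM/ms) is the magnitude of the GABA
    flux into the synaptic vicinity.  Defaults are the uncalibrated base
    rates (all multipliers 1); a calibrated set selected by the package's
    multi-objective fit is available as ``gababsim.fitting.CALIBRATED``.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    k5: float = 1.0
    rgs_post: float = 1.0
    rgs_pre_E: float = 1.0
    rgs_pre_I: float = 1.0
    f_gaba: float = 1000.0
    stim_duration: float = 1.0  # ms, duration of one GABA-flux bolus

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"parameter {name}={v} outside bounds [{lo}, {hi}]"
                )
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")

    @classmethod
    def unit(cls, **overrides) -> "KineticParams":
        """Base rates of the source models: every multiplier set to 1."""
        base = dict(k1=1.0, k2=1.0, k3=1.0, k4=1.0, k5=1.0,
                    rgs_post=1.0, rgs_pre_E=1.0, rgs_pre_I=1.0,
                    f_gaba=1000.0)
        base.update(overrides)
        return cls(**base)

    def rgs_for(self, kind: str) -> float:
        return {"post": self.rgs_post,
                "pre_E": self.rgs_pre_E,
                "pre_I": self.rgs_pre_I}[kind]

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)


COMPARTMENT_KINDS = ("post", "pre_E", "pre_I")


def derive_k2x(k2: float) -> float:
    """Backward rate (1/ms) of agonist-receptor binding.

    Chosen so that the dissociation constant kb/kf of the binding reaction
    equals the experimentally measured 110 nM affinity for every k2.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    return 5.555e-6 * k2 * 110.0


def _cascade_reactions(params: KineticParams) -> list[ReactionSpec]:
    k1, k2, k3, k4, k5 = params.k1, params.k2, params.k3, params.k4, params.k5
    k2f = k2 * 5.555e-6
    k2x = derive_k2x(k2)
    R = ReactionSpec
    return [
        R("R1", (("gaba", 1),), (("gabaOut", 1),), kf=k1 * 0.0005),
        R("R2", (("gaba", 1), ("GABA_B_R", 1)), (("gabaGABA_B_R", 1),),
          kf=k2f, kb=k2x),
        R("R3", (("gaba", 1), ("GABA_B_RGi", 1)), (("gabaGABA_B_RGi", 1),),
          kf=k2f, kb=k2x),
        R("R4", (("GABA_B_R", 1), ("G_i", 1)), (("GABA_B_RGi", 1),),
          kf=k3 * 7.5e-5, kb=k3 * 0.000125),
        R("R5", (("gabaGABA_B_R", 1), ("G_i", 1)), (("gabaGABA_B_RGi", 1),),
          kf=k3 * 0.00015, kb=k3 * 0.00025),
        R("R6", (("gabaGABA_B_RGi", 1),),
          (("gabaGABA_B_RGibg", 1), ("GiaGTP", 1)), kf=k3 * 0.000125),
        R("R7", (("gabaGABA_B_RGibg", 1),),
          (("gabaGABA_B_R", 1), ("Gibg", 1)), kf=k3 * 0.001),
        R("R8", (("GiaGTP", 1), ("RGS", 1)), (("GiaGTPRGS", 1),),
          kf=2e-6, kb=0.002),
        R("R9", (("GiaGTPRGS", 1),), (("GiaGDP", 1), ("RGS", 1)), kf=0.03),
        R("R10", (("GiaGDP", 1), ("Gibg", 1)), (("G_i", 1),), kf=0.00125),
        R("R11", (("GIRK", 1), ("Gibg", 1)), (("GIRKGibg", 1),),
          kf=k4 * 1.4e-5, kb=k5 * 0.001),
        R("R12", (("GIRKGibg", 1), ("Gibg", 1)), (("GIRKGibg2", 1),),
          kf=k4 * 1.4e-5, kb=k5 * 0.001),
        R("R13", (("GIRKGibg2", 1), ("Gibg", 1)), (("GIRKGibg3", 1),),
          kf=k4 * 1.4e-5, kb=k5 * 0.001),
        R("R14", (("GIRKGibg3", 1), ("Gibg", 1)), (("GIRKGibg4", 1),),
          kf=k4 * 1.4e-5, kb=k5 * 0.001),
        R("R15", (("VGCC", 1), ("Gibg", 1)), (("VGCCGibg", 1),),
          kf=k4 * 1.4e-5, kb=k5 * 0.001),
    ]


def _release_reactions() -> list[ReactionSpec]:
    # Source rates 50e9/(ms*mM^4) and 100,000/(ms*mM) converted once to the
    # canonical nM system (1 mM = 1e6 nM): 5e-14/(ms*nM^4), 0.1/(ms*nM).
    R = ReactionSpec
    return [
        R("R16", (("Ca", 4), ("Ffactor", 1)), (("FfactorCa4", 1),),
          kf=5e-14, kb=0.1),
        R("R17", (("FfactorCa4", 1), ("Ves", 1)), (("FfactorCa4Ves", 1),),
          kf=0.1, kb=0.1),
        R("R18", (("FfactorCa4Ves", 1),),
          (("NT", NT_PER_FUSION), ("Ffactor", 1), ("Ves", 1), ("Ca", 4)),
          kf=4.0),
        R("R19", (("NT", 1),), (), kf=10.0),
    ]


class SignalingNetwork:
    """Compiled reaction network: species registry, stoichiometry, rates.

    Holds exponent matrices for forward/backward rate laws and the net
    stoichiometry matrix, so the RHS and its Jacobian are plain array
    expressions.
    """

    def __init__(self, reactions: Sequence[ReactionSpec],
                 species: Sequence[str], y0: np.ndarray,
                 params: KineticParams | None = None,
                 kind: str | None = None,
                 rtol: float = 1e-8, atol: float = 1e-3):
        self.reactions = list(reactions)
        self.species = tuple(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.y0 = np.asarray(y0, dtype=float).copy()
        self.params = params
        self.kind = kind
        self.rtol = rtol
        self.atol = atol
        n_r, n_s = len(self.reactions), len(self.species)
        self.kf = np.array([r.kf for r in self.reactions])
        self.kb = np.array([r.kb for r in self.reactions])
        self.Ef = np.zeros((n_r, n_s))   # reactant orders
        self.Eb = np.zeros((n_r, n_s))   # product orders
        self.S = np.zeros((n_r, n_s))    # net stoichiometry
        for j, r in enumerate(self.reactions):
            for sp, nu in r.reactants:
                self.Ef[j, self.index[sp]] += nu
                self.S[j, self.index[sp]] -= nu
            for sp, nu in r.products:
                self.Eb[j, self.index[sp]] += nu
                self.S[j, self.index[sp]] += nu
        # Backward rate laws only exist for reversible reactions; zero the
        # exponents elsewhere so product stoichiometries of irreversible
        # reactions (e.g. the 10^4 NT of vesicle fusion) never enter a pow.
        self._Eb_rate = np.where(self.kb[:, None] > 0, self.Eb, 0.0)
        # Sparse helpers for the Jacobian.
        self._f_nonzero = [np.nonzero(self.Ef[j])[0] for j in range(n_r)]
        self._b_nonzero = [np.nonzero(self._Eb_rate[j])[0]
                           for j in range(n_r)]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def with_reaction(self, reaction: ReactionSpec) -> "SignalingNetwork":
        return SignalingNetwork(self.reactions + [reaction], self.species,
                                self.y0, self.params, self.kind,
                                self.rtol, self.atol)

    def replace_reaction(self, name: str,
                         reaction: ReactionSpec) -> "SignalingNetwork":
        rxns = [reaction if r.name == name else r for r in self.reactions]
        return SignalingNetwork(rxns, self.species, self.y0, self.params,
                                self.kind, self.rtol, self.atol)

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        """Net reaction rates kf*prod(c^Ef) - kb*prod(c^Eb) (nM/ms)."""
        cpos = np.maximum(c, 0.0)
        vf = self.kf * np.prod(cpos[None, :] ** self.Ef, axis=1)
        vb = self.kb * np.prod(cpos[None, :] ** self._Eb_rate, axis=1)
        return vf - vb

    def rhs(self, c: np.ndarray) -> np.ndarray:
        return self.fluxes(c) @ self.S

    def jac(self, c: np.ndarray) -> np.ndarray:
        cpos = np.maximum(c, 1e-300)
        J = np.zeros((self.n_species, self.n_species))
        pf = self.kf * np.prod(cpos[None, :] ** self.Ef, axis=1)
        pb = self.kb * np.prod(cpos[None, :] ** self._Eb_rate, axis=1)
        for j in range(len(self.reactions)):
            for i in self._f_nonzero[j]:
                J[:, i] += self.S[j] * (pf[j] * self.Ef[j, i] / cpos[i])
            for i in self._b_nonzero[j]:
                J[:, i] -= self.S[j] * (pb[j] * self._Eb_rate[j, i]
                                        / cpos[i])
        return J


def build_signaling_network(kind: str, params: KineticParams | None = None,
                            include_release: bool = False,
                            rtol: float = 1e-8,
                            atol: float = 1e-3) -> SignalingNetwork:
    """Assemble the cascade for one compartment kind.

    ``kind`` selects the RGS concentration and which effector starts
    nonzero: GIRK channels exist only postsynaptically (``post``), N-type
    VGCCs only presynaptically (``pre_E``/``pre_I``).  ``include_release``
    appends the Ca2+-triggered vesicle-fusion reactions.
    """
    if kind not in COMPARTMENT_KINDS:
        raise ValueError(f"unknown compartment kind {kind!r}; "
                         f"expected one of {COMPARTMENT_KINDS}")
    if params is None:
        params = KineticParams()
    params.validate()
    reactions = _cascade_reactions(params)
    species = list(SPECIES)
    if include_release:
        reactions += _release_reactions()
        species += list(RELEASE_SPECIES)
    y0 = np.zeros(len(species))
    idx = {s: i for i, s in enumerate(species)}
    y0[idx["GABA_B_R"]] = INIT_RECEPTOR_NM
    y0[idx["G_i"]] = INIT_GI_NM
    y0[idx["RGS"]] = params.rgs_for(kind) * 1000.0  # uM -> nM
    if kind == "post":
        y0[idx["GIRK"]] = INIT_GIRK_NM
    else:
        y0[idx["VGCC"]] = INIT_VGCC_NM
    if include_release:
        y0[idx["Ffactor"]] = INIT_FFACTOR_NM
        y0[idx["Ves"]] = INIT_VES_NM
    return SignalingNetwork(reactions, species, y0, params=params, kind=kind,
                            rtol=rtol, atol=atol)


def mass_action_rhs(state: np.ndarray | Mapping[str, float],
                    network: SignalingNetwork,
                    gaba_flux: float = 0.0) -> np.ndarray:
    """Per-species rate of change (nM/ms) at one state.

    ``gaba_flux`` adds a constant source term to d[gaba]/dt, as during an
    active GABA-flux pulse.
    """
    if isinstance(state, Mapping):
        c = np.zeros(network.n_species)
        for sp, v in state.items():
            c[network.index[sp]] = v
    else:
        c = np.asarray(state, dtype=float)
    if c.shape != (network.n_species,):
        raise ValueError("state length does not match species registry")
    if np.any(~np.isfinite(c)):
        raise ValueError("non-finite concentration in state")
    if np.min(c) < -1e-6:
        raise ValueError("negative concentration beyond tolerance")
    dc = network.rhs(c)
    if gaba_flux:
        dc[network.index["gaba"]] += gaba_flux
    return dc


@dataclass(frozen=True)
class StimulusSchedule:
    """GABA input protocol: flux pulses and/or concentration clamps.

    ``pulses`` are ``(onset_ms, duration_ms, flux_nM_per_ms)``; ``clamps``
    holds named species at fixed concentrations for the whole run (used for
    basal receptor activity and bath application).
    """

    pulses: tuple[tuple[float, float, float], ...] = ()
    clamps: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pulses = tuple(sorted(self.pulses))
        for onset, dur, flux in pulses:
            if dur <= 0 or flux < 0:
                raise ValueError("pulse needs duration > 0 and flux >= 0")
        for (o1, d1, _), (o2, _, _) in zip(pulses, pulses[1:]):
            if o1 + d1 > o2:
                raise ValueError("overlapping GABA pulses")
        object.__setattr__(self, "pulses", pulses)

    @classmethod
    def bolus_train(cls, n: int, interval_ms: float, flux: float,
                    duration_ms: float = 1.0,
                    start_ms: float = 0.0) -> "StimulusSchedule":
        return cls(tuple((start_ms + i * interval_ms, duration_ms, flux)
                         for i in range(n)))

    def flux_at(self, t: float) -> float:
        for onset, dur, flux in self.pulses:
            if onset <= t < onset + dur:
                return flux
        return 0.0

    def breakpoints(self, t_end: float) -> list[float]:
        pts = {0.0, t_end}
        for onset, dur, _ in self.pulses:
            if onset < t_end:
                pts.add(onset)
                pts.add(min(onset + dur, t_end))
        return sorted(pts)


@dataclass
class Trajectory:
    """Deterministic simulation output: times (ms) x species (nM)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_species)
    species: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time_ms", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    pass


def simulate_signaling(network: SignalingNetwork,
                       stimulus: StimulusSchedule | None = None,
                       t_end: float = 1000.0, dt_out: float = 1.0,
                       y0: np.ndarray | None = None,
                       t0: float = 0.0) -> Trajectory:
    """Integrate the cascade with a stiff implicit solver (LSODA).

    Integration is split at pulse boundaries so the piecewise-constant GABA
    flux is exact; output is sampled on a uniform ``dt_out`` grid.
    Solver-level negative round-off is clipped to zero on output; larger
    excursions trigger one retry at tighter tolerance, then an error.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    stimulus = stimulus or StimulusSchedule()
    try:
        return _simulate_once(network, stimulus, t_end, dt_out, y0, t0,
                              network.atol)
    except IntegrationError:
        # stiff corner cases can leave negative excursions beyond the
        # guard; retry with a tighter absolute tolerance before failing
        return _simulate_once(network, stimulus, t_end, dt_out, y0, t0,
                              network.atol * 1e-3)


def _simulate_once(network: SignalingNetwork, stimulus: StimulusSchedule,
                   t_end: float, dt_out: float,
                   y0: np.ndarray | None, t0: float,
                   atol: float) -> Trajectory:
    y = (network.y0 if y0 is None else np.asarray(y0, float)).copy()
    clamp_idx = {network.index[s]: v for s, v in stimulus.clamps.items()}
    for i, v in clamp_idx.items():
        y[i] = v
    gaba_i = network.index["gaba"]

    def make_rhs(flux):
        def rhs(t, c):
            dc = network.rhs(c)
            if flux:
                dc[gaba_i] += flux
            for i in clamp_idx:
                dc[i] = 0.0
            return dc
        return rhs

    def jac(t, c):
        J = network.jac(c)
        for i in clamp_idx:
            J[i, :] = 0.0
        return J

    t_grid = np.arange(t0, t_end + 0.5 * dt_out, dt_out)
    t_grid[-1] = min(t_grid[-1], t_end)
    out = np.empty((len(t_grid), network.n_species))
    out[0] = y
    seg_edges = [t0 + b for b in stimulus.breakpoints(t_end - t0)]
    # merge segment edges with nothing else; integrate segment by segment
    filled = 1
    for a, b in zip(seg_edges, seg_edges[1:]):
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[mask]
        # the flux is constant within a segment; evaluate it mid-segment
        # so the solver never sees a discontinuous right-hand side
        rhs = make_rhs(stimulus.flux_at((a + b) / 2.0 - t0))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", jac=jac,
                        t_eval=t_eval if len(t_eval) else None,
                        rtol=network.rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{a}, {b}] ms: {sol.message}")
        if len(t_eval):
            out[filled:filled + len(t_eval)] = sol.y.T
            filled += len(t_eval)
        # project round-off negatives back onto the physical domain
        y = np.maximum(sol.y[:, -1], 0.0)
        for i, v in clamp_idx.items():
            y[i] = v
    states = out[:filled]
    # Negative excursions within solver error are clipped; anything larger
    # signals a genuine integration failure.
    neg_tol = max(100.0 * atol, 1e-6 * float(np.max(states)))
    if np.min(states) < -neg_tol:
        raise IntegrationError(
            f"negative concentration {np.min(states):.3e} nM beyond "
            "solver tolerance; tighten rtol/atol")
    states = np.clip(states, 0.0, None)
    # snap solver round-off to an exact zero: 1e-15 nM is ~1e-9 molecules
    # in a femtoliter compartment, far below physical meaning
    states[states < 1e-15] = 0.0
    return Trajectory(
        times=t_grid[:filled], states=states, species=network.species,
        metadata={"kind": network.kind, "rtol": network.rtol,
                  "atol": atol, "params": network.params,
                  "stimulus": stimulus})


# Moiety definitions: name -> {species: weight}.  GIRK states carry 1..4
# G_ibg subunits, hence the multiplicities in the G_ibg total.
MOIETIES: dict[str, dict[str, float]] = {
    "receptor": {"GABA_B_R": 1, "gabaGABA_B_R": 1, "GABA_B_RGi": 1,
                 "gabaGABA_B_RGi": 1, "gabaGABA_B_RGibg": 1},
    "Gialpha": {"G_i": 1, "GABA_B_RGi": 1, "gabaGABA_B_RGi": 1,
                "GiaGTP": 1, "GiaGTPRGS": 1, "GiaGDP": 1},
    "Gibg": {"G_i": 1, "GABA_B_RGi": 1, "gabaGABA_B_RGi": 1,
             "gabaGABA_B_RGibg": 1, "Gibg": 1, "GIRKGibg": 1,
             "GIRKGibg2": 2, "GIRKGibg3": 3, "GIRKGibg4": 4, "VGCCGibg": 1},
    "RGS": {"RGS": 1, "GiaGTPRGS": 1},
    "GIRK": {"GIRK": 1, "GIRKGibg": 1, "GIRKGibg2": 1, "GIRKGibg3": 1,
             "GIRKGibg4": 1},
    "VGCC": {"VGCC": 1, "VGCCGibg": 1},
    "Ffactor": {"Ffactor": 1, "FfactorCa4": 1, "FfactorCa4Ves": 1},
    "Ves": {"Ves": 1, "FfactorCa4Ves": 1},
}


def conserved_totals(state: np.ndarray | Mapping[str, float],
                     species: Sequence[str] = SPECIES) -> dict[str, float]:
    """Weighted totals of each conserved moiety (nM)."""
    if isinstance(state, Mapping):
        get = lambda sp: float(state.get(sp, 0.0))  # noqa: E731
    else:
        arr = np.asarray(state, float)
        index = {s: i for i, s in enumerate(species)}
        get = lambda sp: float(arr[index[sp]]) if sp in index else 0.0  # noqa: E731
    return {name: sum(w * get(sp) for sp, w in members.items())
            for name, members in MOIETIES.items()}
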