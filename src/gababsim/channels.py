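"""Coupling of the signaling cascade to channel observables.

GIRK conductance follows an occupancy-weighted rule: a channel bound by
1, 2, 3, or 4 G_ibg subunits conducts 1%, 6%, 26%, or 100% of the maximal
single-channel conductance (33 pS).  The GIRK current carries an additional
voltage gate with Kir-type kinetics.  N-type VGCCs bound by a single G_ibg
enter a "reluctant" gating mode: activation midpoint shifted +10 mV and
activation time constant 1.31x the willing mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GIRK_OCCUPANCY_WEIGHTS",
    "GIRK_GMAX_PS",
    "RELUCTANT_SHIFT_MV",
    "RELUCTANT_TAU_FACTOR",
    "girk_relative_conductance",
    "girk_gate_inf",
    "girk_gate_tau",
    "girk_current",
    "vgcc_reluctant_fraction",
    "areal_density",
    "GirkChannelParams",
]

#: Fractional conductance for 0..4 bound G_ibg subunits.
GIRK_OCCUPANCY_WEIGHTS = np.array([0.0, 0.01, 0.06, 0.26, 1.0])

#: Species names of the five GIRK binding states, in occupancy order.
GIRK_STATE_SPECIES = ("GIRK", "GIRKGibg", "GIRKGibg2", "GIRKGibg3",
                      "GIRKGibg4")

#: Theoretical maximum single-channel GIRK conductance (pS).
GIRK_GMAX_PS = 33.0

#: Reluctant-mode activation midpoint shift (mV) and time-constant factor.
RELUCTANT_SHIFT_MV = 10.0
RELUCTANT_TAU_FACTOR = 1.31

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class GirkChannelParams:
    g_max_pS: float = GIRK_GMAX_PS
    E_K_mV: float = -90.0
    weights: tuple[float, ...] = tuple(GIRK_OCCUPANCY_WEIGHTS)


def girk_relative_conductance(occupancy) -> float | np.ndarray:
    """Whole-population GIRK conductance as a fraction of maximum.

    ``occupancy`` holds concentrations of the unbound and 1..4-bound GIRK
    states, either as a length-5 sequence or an array with the five states
    along the last axis.  The result is the occupancy-weighted mean of the
    fractional conductances, in [0, 1].
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape[-1] != 5:
        raise ValueError("expected 5 GIRK occupancy states (0..4 bound)")
    if np.any(occ < 0):
        raise ValueError("negative occupancy")
    total = occ.sum(axis=-1)
    if np.any(total <= 0):
        raise ZeroDivisionError("total GIRK concentration is zero")
    return (occ @ GIRK_OCCUPANCY_WEIGHTS) / total


def girk_weighted_occupancy(occupancy) -> float | np.ndarray:
    """Unnormalized numerator of the conductance rule (nM units).

    Used by the amplitude objective of the calibration, where the absolute
    amount of bound channel matters.
    """
    occ = np.asarray(occupancy, dtype=float)
    return occ @ GIRK_OCCUPANCY_WEIGHTS


def girk_gate_inf(V) -> float | np.ndarray:
    """Steady-state Kir-type voltage gate, strictly decreasing in V."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(-98.92 - V) / 10.89))
    return out.item() if out.ndim == 0 else out


def girk_gate_tau(V) -> float | np.ndarray:
    """Voltage-gate time constant (ms), strictly positive."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (0.0061 * np.exp(-V / 67.0) + 0.082 * np.exp(V / 67.0))
    return out.item() if out.ndim == 0 else out


def girk_current(g, l, V, E_K=-90.0):
    """GIRK current g*l*(E_K - V).

    Positive values are restorative (hyperpolarizing) by this sign
    convention; membrane models that sum outward-positive currents negate
    the result.
    """
    g = np.asarray(g, float)
    if np.any(g < 0):
        raise ValueError("negative conductance")
    l = np.asarray(l, float)
    if np.any((l < 0) | (l > 1)):
        raise ValueError("gate out of [0, 1]")
    out = g * l * (E_K - np.asarray(V, float))
    return out.item() if out.ndim == 0 else out


def vgcc_reluctant_fraction(vgcc_free, vgcc_bound) -> float | np.ndarray:
    """Fraction of N-type channels in the G_ibg-bound (reluctant) mode."""
    free = np.asarray(vgcc_free, float)
    bound = np.asarray(vgcc_bound, float)
    total = free + bound
    if np.any(total <= 0):
        raise ZeroDivisionError("VGCC moiety total is zero")
    out = bound / total
    return out.item() if out.ndim == 0 else out


def areal_density(conc_nM: float, diameter_um: float) -> float:
    """Channels per um^2 of lateral membrane of a cylindrical compartment.

    A cylinder of diameter d has volume/lateral-area ratio d/4, so a
    volumetric density rho (molecules/um^3) maps to rho*d/4 per um^2.
    1 uM in a 0.8 um cylinder gives ~120 molecules/um^2.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    if conc_nM < 0:
        raise ValueError("negative concentration")
    per_um3 = conc_nM * 1e-9 * AVOGADRO / 1e15  # nM -> molecules/um^3
    return per_um3 * diameter_um / 4.0
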