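"""GIRK channel observables: occupancy-weighted conductance and gating.

Evaluates the conductance rule for hand-picked occupancy states, the
voltage gate's steady state and time constant, and the areal channel
density implied by a volumetric concentration.
"""

import numpy as np

from gababsim import (
    areal_density,
    girk_current,
    girk_gate_inf,
    girk_gate_tau,
    girk_relative_conductance,
)

# all channels triply bound -> 26% of the 33 pS maximum
print("triply bound:", girk_relative_conductance([0, 0, 0, 1000.0, 0]))
# equal mass in all five states -> mean of (0, 1, 6, 26, 100)%
print("equal fifths:", girk_relative_conductance([200.0] * 5))

v = -98.92
print(f"gate midpoint l_inf({v} mV) = {girk_gate_inf(v):.3f}")
print(f"gate tau at -87 mV (near its maximum) = "
      f"{girk_gate_tau(-87.05):.1f} ms")
print(f"current at g=10 pS, l=0.5, V=-60, E_K=-90: "
      f"{girk_current(10.0, 0.5, -60.0, -90.0):.0f} pS*mV")
print(f"1 uM GIRK in a 0.8 um cylinder = "
      f"{areal_density(1000.0, 0.8):.1f} channels/um^2")
# 1 uM of channels in a 0.8-um-diameter compartment corresponds to about
# 120 channels per um^2 of lateral membrane.
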