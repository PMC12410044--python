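"""Calibrate the kinetic parameters against the fixture target curves.

Runs NSGA-II at a reduced scale (population 200, 10 generations, one
trial) over the three objectives, applies the median-normalized selection
rule, and reports the selected parameters and the landmark times of the
calibrated model.  The reference calibration frozen into
``gababsim.fitting.CALIBRATED`` was produced by this script with
pop_size=400, n_gen=20, seed=0 (about 30 minutes on one CPU).
"""

import numpy as np

from gababsim import fit, make_fixture_targets, simulate_response_curves
from gababsim.fitting import STRICT_SETTINGS

targets = make_fixture_targets()
result = fit(targets, pop_size=200, n_gen=10, n_trials=1, seed=0)
p = result.selected
print("selected parameters:")
for name in ("k1", "k2", "k3", "k4", "k5", "rgs_post", "rgs_pre_E",
             "rgs_pre_I", "f_gaba"):
    print(f"  {name:10s} = {getattr(p, name):.4g}")
print(f"objectives: f1={result.selected_objectives.f1:.3f} "
      f"f2={result.selected_objectives.f2:.3f}")

curves = simulate_response_curves(p, STRICT_SETTINGS)
t_peak = curves.t_post[np.argmax(curves.girk_rel)]
t_bind = curves.t_pre_E[np.argmax(curves.binding_E)]
print(f"postsynaptic conductance peaks at {t_peak:.0f} ms "
      "(target landmark: 200 ms)")
print(f"E->E VGCC binding peaks at {t_bind:.0f} ms "
      "(target landmark: 300 ms)")
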