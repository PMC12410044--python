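"""Agonist bath application and RGS knockdown.

A saturating (100 uM) agonist bath activates postsynaptic GIRK
conductance; after washout the conductance decays at a rate set by the
RGS-accelerated G-protein deactivation.  Reducing the RGS concentration
(as in an RGS7 knockout) prolongs the decay.
"""

from gababsim import CALIBRATED, ScenarioSpec, girk_decay_time, \
    simulate_bath_application

for rgs_scale in (1.0, 0.2, 0.1, 0.05):
    sc = ScenarioSpec(rgs_scale=rgs_scale, bath_uM=100.0,
                      bath_on_ms=2000.0, bath_off_ms=12000.0)
    traj, g = simulate_bath_application(CALIBRATED, sc, t_end=120000.0,
                                        dt_out=20.0)
    decay = girk_decay_time(traj.times, g, washout_ms=12000.0)
    print(f"RGS x{rgs_scale:>4}: peak g_rel = {g.max():.3f}, "
          f"decay to 10% of peak = {decay/1000.0:.2f} s after washout")
# Decay time grows monotonically as RGS is reduced — the knockout
# signature on GIRK current termination.
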