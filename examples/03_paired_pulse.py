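"""Paired-pulse depression at an inhibitory presynaptic terminal.

Two axonal stimuli 350 ms apart; with GABA_B autoreceptor signaling
active, the first stimulus' GABA release puts part of the bouton's N-type
Ca2+ channels in the reluctant mode, shrinking the second Ca2+ transient
and the second neurotransmitter peak (PPR < 1).  Without receptor
signaling the two releases are nearly identical.
"""

from gababsim import CALIBRATED, PairedPulseProtocol, build_axon_model, \
    run_paired_pulse

model = build_axon_model(kind="pre_I", params=CALIBRATED)
for active in (False, True):
    res = run_paired_pulse(model, PairedPulseProtocol(
        synapse_type="IE", isi_ms=350.0, gabab_active=active))
    label = "GABA_B active " if active else "GABA_B blocked"
    print(f"{label}: NT peaks = {res.peaks[0]:.3e} / {res.peaks[1]:.3e} nM"
          f" -> PPR = {res.ppr:.3f}")
# PPR is the second NT peak over the first: ~1 when the receptors are
# blocked, < 1 (depression) when they are active.
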