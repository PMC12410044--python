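# gababsim

Biochemically detailed simulation of GABA_B receptor signaling and its
pre- and postsynaptic effects on neuronal inhibition.

GABA_B receptors are metabotropic (G protein-coupled) GABA receptors.
Their activation releases the G_iβγ subunit complex, which gates
G protein-coupled inwardly rectifying K⁺ (GIRK) channels — the slow
inhibitory postsynaptic current — and inhibits presynaptic N-type
voltage-gated Ca²⁺ channels (VGCCs), producing short-term synaptic
depression.  Regulators of G protein signaling (RGS) terminate the signal
by accelerating GTP hydrolysis on G_iα.  `gababsim` implements this
cascade as a mass-action ODE system with strict unit (nM, ms) and
moiety-conservation discipline, couples it to channel observables, embeds
it in a composite axon/bouton model with Ca²⁺-triggered neurotransmitter
release, and calibrates the kinetics with NSGA-II multi-objective
optimization.

## The model

Fifteen mass-action reactions describe agonist uptake, agonist-receptor
binding (with the equilibrium constant pinned to the measured 110 nM
affinity), receptor-catalyzed G_i activation, the RGS-assisted hydrolysis
cycle, sequential binding of up to four G_iβγ to GIRK, and single G_iβγ
binding to VGCC.  Four more reactions give Ca²⁺-cooperative (fourth-order)
vesicle fusion and transmitter release.  The channel couplings are:

- GIRK conductance: `g = ḡ · (0.01·[GIRK·βγ] + 0.06·[GIRK·βγ₂] +
  0.26·[GIRK·βγ₃] + [GIRK·βγ₄]) / Σ[GIRK states]`, with ḡ = 33 pS,
  times a Kir-type voltage gate `l` with
  `l∞(V) = 1/(1+exp((98.92 mV + V)/10.89 mV))`;
  the current is `i_GIRK = g·l·(E_K − V)`.
- VGCC modulation: a G_iβγ-bound channel gates in a "reluctant" mode —
  activation midpoint +10 mV, time constant ×1.31 — with the reluctant
  fraction `[VGCC·βγ]/([VGCC]+[VGCC·βγ])` set dynamically by the cascade.

Free parameters (multipliers k₁…k₅ on the base rates, per-domain RGS
concentrations, GABA flux magnitude) are calibrated by minimizing three
objectives — normalized postsynaptic conductance mismatch (f₁),
normalized presynaptic depression mismatch for E→E and I→E synapses (f₂),
and a negative signal-amplitude product (f₃) — with NSGA-II, selecting
the final set by `argmin f₁/median(f₁) + f₂/median(f₂)`.

## Worked example

```bash
python examples/03_paired_pulse.py
```

```
GABA_B blocked: NT peaks = 3.960e+05 / 3.964e+05 nM -> PPR = 1.001
GABA_B active : NT peaks = 3.959e+05 / 2.383e+05 nM -> PPR = 0.602
```

Two axonal stimuli are delivered 350 ms apart.  With GABA_B autoreceptor
signaling blocked, the two neurotransmitter peaks are equal (paired-pulse
ratio ≈ 1).  With signaling active, GABA released by the first stimulus
puts part of the terminal's N-type channels into the reluctant mode, the
second Ca²⁺ transient shrinks, and — through the fourth-order cooperativity
of vesicle fusion — the second release drops by a third (PPR < 1):
GABA_B-mediated short-term depression.

Other examples: `01_signaling_cascade.py` (cascade time course and
conservation), `02_girk_channel.py` (conductance/gating arithmetic),
`04_bath_rgs_knockdown.py` (bath application; RGS knockdown prolongs GIRK
current decay), `05_fit.py` (NSGA-II calibration), `06_export.py`
(SBtab/SBML round trip).

A thin CLI wraps the same functionality:

```bash
gababsim --out out fixtures
gababsim --out out --seed 1 fit --targets out/targets.csv --scale reduced
gababsim --out out ppr --type IE --isi 350 --gabab on,off
gababsim --out out export sbml --kind post
```

## Layout

- `src/gababsim/network.py` — species registry, reactions, stiff ODE
  integration, conservation accounting
- `src/gababsim/channels.py` — GIRK/VGCC coupling rules and unit helpers
- `src/gababsim/presyn.py` — 5-compartment axon + bouton, two-mode N-type
  current, release cascade, paired-pulse protocols
- `src/gababsim/postsyn.py` — single-compartment surrogate: bath
  application, RGS knockdown, basal-activity scenarios, AMPA/NMDA gating
- `src/gababsim/fitting.py`, `nsga2.py` — objectives, fixtures, NSGA-II
- `src/gababsim/exchange.py` — SBtab/SBML export-import, run manifests
- `docs/methods.md` — model description, assumptions, numerical choices
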