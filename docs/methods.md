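# Methods

## Signaling network

The cascade is a closed mass-action system in a single well-mixed
compartment.  Species: extracellular/cleared agonist (gaba, gabaOut), the
receptor and its agonist/G-protein complexes, the heterotrimeric G_i
protein and its activation products (GiaGTP, GiaGTPRGS, GiaGDP, free
G_iβγ), RGS, GIRK channels with 0–4 bound G_iβγ, and N-type VGCC with 0–1
bound G_iβγ.  Units are nM and ms throughout; bimolecular rate constants
are 1/(nM·ms).

Reactions R1–R15 (multipliers k₁…k₅ on the base rates):

| # | reaction | kf | kb |
|---|----------|----|----|
| R1 | gaba → gabaOut | k₁·5e-4 | 0 |
| R2 | gaba + R ⇌ gabaR | k₂·5.555e-6 | k₂ₓ |
| R3 | gaba + RG_i ⇌ gabaRG_i | k₂·5.555e-6 | k₂ₓ |
| R4 | R + G_i ⇌ RG_i | k₃·7.5e-5 | k₃·1.25e-4 |
| R5 | gabaR + G_i ⇌ gabaRG_i | k₃·1.5e-4 | k₃·2.5e-4 |
| R6 | gabaRG_i → gabaRG_iβγ + GiaGTP | k₃·1.25e-4 | 0 |
| R7 | gabaRG_iβγ → gabaR + G_iβγ | k₃·1e-3 | 0 |
| R8 | GiaGTP + RGS ⇌ GiaGTPRGS | 2e-6 | 2e-3 |
| R9 | GiaGTPRGS → GiaGDP + RGS | 0.03 | 0 |
| R10 | GiaGDP + G_iβγ → G_i | 1.25e-3 | 0 |
| R11–14 | GIRK·βγₙ₋₁ + G_iβγ ⇌ GIRK·βγₙ | k₄·1.4e-5 | k₅·1e-3 |
| R15 | VGCC + G_iβγ ⇌ VGCC·βγ | k₄·1.4e-5 | k₅·1e-3 |

k₂ₓ = 5.555e-6·k₂·110, so the agonist-receptor dissociation constant is
110 nM for every k₂ (the experimentally measured affinity).  Initial
concentrations: receptor 400 nM, G_i heterotrimer 2,600 nM, GIRK 1,000 nM
(postsynaptic only), VGCC 100 nM (presynaptic only), RGS per-domain
(0.1–10 µM, a fitted parameter).  The "[G_iβγ] = 2.6 µM" initial pool is
interpreted as the intact heterotrimer G_i, with all activation products
starting at zero: R4–R7 consume G_i, and no separate heterotrimer value
exists.  Zero initial GIRK (presynaptic) or VGCC (postsynaptic)
concentration silently disables the corresponding binding reactions, so
one reaction set serves all three compartment kinds (post, pre_E, pre_I).

The release cascade R16–R19 (presynaptic terminals only) is converted
once from its source units to the canonical system: 4 Ca + Ffactor ⇌
FfactorCa4 (kf 5e-14 1/(ms·nM⁴), kb 0.1), FfactorCa4 + Ves ⇌
FfactorCa4Ves (kf 0.1 1/(ms·nM), kb 0.1), FfactorCa4Ves → 10⁴ NT +
Ffactor + Ves + 4 Ca (4/ms), NT → ∅ (10/ms).  The 10⁴ transmitter
molecules per fusion are carried as a stoichiometric coefficient with the
cleft volume taken equal to the bouton volume; only relative NT peaks
enter any downstream quantity, the absolute scale is absorbed by the
synaptic coupling constant c_NT.

GABA input is a flux (nM/ms) into the gaba pool, delivered as
rectangular boluses of configurable duration (default 1 ms — a brief
transmitter transient; duration trades off exactly against the fitted
magnitude).  Tonic (basal) receptor activity and bath application are
modeled as concentration clamps: a clamped species has its derivative
zeroed, making the source non-depleting.

## Integration and conservation

The system is stiff (rate constants span >10 orders of magnitude), so
integration uses LSODA with an analytic Jacobian assembled from the
stoichiometry, rtol 1e-8 and atol 1e-3 nM by default, split at stimulus
boundaries so piecewise-constant fluxes are exact.  Five moieties
(receptor, G_iα, G_iβγ with multiplicity 1–4 over the GIRK states, RGS,
GIRK, VGCC, and the release factors) are conserved to ≤1e-6 relative
error at these tolerances; the test suite checks this on every simulated
protocol.  Negative excursions within solver error (bounded by
100·atol or 1e-6 of the trajectory maximum) are clipped to zero on
output; larger excursions raise an integration error.  During
calibration the solver runs at rtol 1e-6 for speed; all reported
landmark simulations use rtol 1e-8.

## Channel coupling

GIRK: conductance fraction = occupancy-weighted mean of
(0, 1%, 6%, 26%, 100%) over the five binding states; maximum
single-channel conductance 33 pS; 1 µM of channels in a 0.8-µm-diameter
cylinder corresponds to ≈120 channels/µm² of lateral membrane
(volume-to-lateral-area ratio d/4).  The voltage gate uses
l∞(V) = 1/(1+exp((98.92+V)/10.89)) and
τ_l = 1 ms/(0.0061·e^(−V/67) + 0.082·e^(V/67)); the current is
g·l·(E_K − V) (positive = restorative; membrane consumers negate).

VGCC: reluctant mode = willing mode shifted +10 mV with τ ×1.31.  The
literature reports both "30%" and "31%" for the slowdown; 1.31 is used
(the presynaptic-model value, matching the cited source) and is a single
named constant.  The base willing-mode kinetics (midpoint −5 mV, slope
6 mV, τ 1.5 ms, two activation gates) are a generic N-type description:
only the willing/reluctant contrast is constrained by data, and the
mechanism is swappable.

## Presynaptic composite model

Geometry: passive 100×1 µm — active 20×1 µm — bouton 0.8×0.4 µm — active
20×1 µm — passive 100×1 µm (axial resistivity 100 Ω·cm, 1 µF/cm²).
Passive segments are fully myelinated (capacitance + axial coupling
only).  Active segments carry a standard Hodgkin–Huxley transient-Na⁺ /
delayed-rectifier-K⁺ pair tuned once to give a single overshooting AP per
0.3 nA / 0.5 ms stimulus at the passive end; downstream quantities are
ratios of NT peaks and are insensitive to the exact AP waveform.  The
bouton hosts the two-mode N-type current, first-order Ca²⁺ clearance to a
100 nM rest, the release cascade, and the signaling network.

Numerical choices that matter here:

- Bouton Ca²⁺ conductance (0.12 mS/cm²) puts single-AP Ca²⁺ transients
  near 1–2 µM — the steep, unsaturated regime of the fourth-order fusion
  step.  At several-fold higher densities the fusion factor saturates and
  release stops tracking Ca²⁺ amplitude (and hence VGCC inhibition).
- Ca²⁺ clearance τ = 45 ms.  Residual Ca²⁺ is the model's facilitation
  mechanism; at this τ, paired pulses 50 ms apart still facilitate
  strongly while pulses ≥350 ms apart are independent to within 2%,
  making the GABA_B-off protocol time-translation invariant at the ISIs
  used for depression.

Protocols: I→E (autoreceptor) — the axon fires for both stimuli and each
firing also delivers a GABA bolus when signaling is active; PPR = second
NT peak / first.  E→E (heterosynaptic) — the first event delivers only a
GABA bolus train (default five boluses at 50 Hz, the conditioning burst;
configurable to one) and the axon fires only for the test stimulus;
the conditioned peak is normalized by an unconditioned run of the same
model.  The facilitation protocol delivers a
conditioning GABA bolus well before (default 300 ms) a close pulse pair,
so both pulses see an established, near-equal VGCC inhibition; reduced
release then moves both Ca²⁺ transients into the steeper region of the
fusion cooperativity and the facilitation index rises — the direction
observed experimentally.  (With boluses locked to the stimuli instead,
the second pulse accumulates strictly more binding and the index moves
the other way.)

## Postsynaptic surrogate

One compartment with leak (E_L −70 mV, 0.05 mS/cm²) and GIRK (density
from the 1 µM / 0.8 µm conversion, E_K −90 mV).  It reproduces directions
of effect and relative time courses, not the absolute millivolt or
threshold numbers of full multicompartmental morphologies.  Bath
application installs a reverse uptake reaction (same rate as forward
uptake) and clamps the extracellular pool at the bath concentration;
washout clamps it to zero.  Scenarios: RGS knockdown scales the RGS
initial concentration; increased agonist sensitivity is modeled literally
as a scaling of every agonist concentration the receptors see (flux,
bath, basal) — this conflates receptor-level sensitivity with ligand
scaling by construction, and is documented as such; basal activity is a
constant non-depleting clamp with 1 A.U. = 1 pM.  The resting potential
solves the algebraic current balance after driving the cascade to steady
state.  AMPA/NMDA gating: ds_AMPA/dt = −s_AMPA/2 ms + c_NT·[NT];
dx_NMDA/dt = −x_NMDA/2 ms + c_NT·[NT]; ds_NMDA/dt = −s_NMDA/100 ms +
α·x_NMDA·(1−s_NMDA) with α = 0.5/ms (unstated in the source data;
exposed in the configuration); NMDAR Ca²⁺ current = 0.1 × total NMDAR
current.

## Calibration

Objectives (all minimized):

- f₁ = Σᵢ |IPSCᵢ/IPSC_max − g(tᵢ)/max g| over 16 postsynaptic sample
  times (80–700 ms, uniform grid — the exact experimental times are not
  public; the grid is overridable),
- f₂ = the same normalized L1 form comparing (1−PPR) against the
  G_iβγ-bound VGCC time course, summed over 6 E→E and 7 I→E ISIs,
- f₃ = −(max weighted GIRK occupancy)·(max E binding)·(max I binding),
  which penalizes well-shaped but vanishing signals and is never used for
  selection.

The presynaptic objectives use the biochemical binding curves directly
(the composite electrical model is a downstream verification, not part of
the fit).  The E→E conditioning stimulus is the five-bolus 50 Hz train;
the postsynaptic and I→E stimuli are single boluses.  Failures inside an
evaluation yield a large finite sentinel (1e9) so nondominated sorting
stays defined.  NSGA-II is seeded and fully deterministic, with three
choices made for convergence at small generation budgets: (i) the
genetic search runs in log coordinates for k₂…k₅, whose useful ranges
span several decades (floored at 1e-3 where the printed lower bound is
0), so crossover and mutation act on the order of magnitude; (ii)
initialization is a Latin hypercube over the (transformed) box; (iii)
the amplitude objective, which itself spans orders of magnitude, enters
the crowding computation as −log(1−f₃) — a strictly monotone transform
that leaves every Pareto front identical while keeping diversity slots
from being monopolized by extreme-amplitude members (reported f₃ values
are always on the defined scale).  Variation uses simulated binary
crossover with a low distribution index (η_c=5, p_c=1), whose children
interpolate between parents and populate the middle of the (f₁, f₂)
front, and polynomial mutation (η_m=15, p=1/9).
Reference scale is population 2,000 × 25 generations × 15 trials.  The
package's calibrated default parameter set comes from a population 400 ×
20 generations run (seed 0, ~30 min one CPU; all landmark times within
±25% of their literature values).  The acceptance script runs a further
reduced scale (population 200 × 10 generations, minutes on one CPU)
which retains the peak-time landmarks; at that budget the selected
set's postsynaptic decay time is the least-converged landmark, because
the f₁ samples end at 700 ms and constrain the conductance tail only
weakly until f₁ drops below ≈0.6.  Final
selection: argmin of f₁/median(f₁) + f₂/median(f₂) over the final
population (medians over non-flagged members; ties broken by lower f₁,
then lower index).

### Fixture targets

The experimental sample values behind the three data sets are not
printed in the public sources, so the package synthesizes stand-in
curves from the stated landmark features; user-supplied target tables
override them.  The postsynaptic curve is ((t/200)·e^(1−t/200))² —
peak at 200 ms and below 5% of peak by 800 ms.  A difference of two
exponentials cannot satisfy both landmarks (its extremal case, the alpha
function, still holds 19.9% of peak at four times the peak time), hence
the squared-gamma form.  Depression fixtures: 1−PPR =
depth·(t/300)·e^(1−t/300) with depth 0.45 (E→E, sampled at ISIs 100,
200, 300, 500, 800, 1,600 ms) and 0.35 (I→E, at 50, 100, 200, 350, 500,
1,000, 2,000 ms) — maximal depression at 300 ms, recovered (PPR ≥ 0.95)
by 1,600 ms.  What passing tests show is that the pipeline recovers
curves with these landmark dynamics; they say nothing about the
quantitative shape of the real experimental curves.

### Test scales

The suite runs the reduced-scale calibration once (session fixture) and a
parameter-recovery refit (targets generated from a known parameter set by
the forward model, refit at population 200 × 15 generations, one seed)
asserting curve recovery f₁ ≤ 0.5, f₂ ≤ 0.7 — recovery of the curves,
not identifiability of the parameters; many distinct parameter sets fit
comparably well.

## Known limitations

- Spatial effects (diffusion between compartments, dendritic gradients)
  and stochastic single-channel behavior are out of scope; simulations
  are deterministic mass-action.
- The postsynaptic surrogate has no voltage-gated conductances beyond
  GIRK; firing-rate and threshold statistics require full morphologies.
- G_iα downstream targets (e.g. adenylyl cyclase) and GABA_B effects on
  the release machinery downstream of Ca²⁺ are not modeled.
- Vesicle-pool depletion beyond the four release reactions is absent, so
  depression in this model is entirely VGCC-mediated.
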