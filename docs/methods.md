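# Methods

This note records the modelling choices behind `cbgtclaw`: what each stage
assumes, which parameters matter, and what the synthetic circuit can and
cannot say about real recordings.

## The reduced CBGT rate network

The simulator replaces a conductance-based spiking circuit with a
stochastic firing-rate network over the same population graph.  Each of the
18 streams obeys

    tau_p dr_p/dt = −r_p + [Σ_q w_{q→p} r_q + I_p]_+ + ξ_p(t),

with a rectifying-linear gain, rates clipped at zero, and independent
Ornstein–Uhlenbeck noise ξ (correlation time 5 ms, amplitude 2.5 Hz),
integrated by Euler–Maruyama at 1 ms.  Edge signs follow the canonical
pathway diagram: the direct pathway (Cx→dSPN→GPi→Th) disinhibits the
thalamus, the indirect pathway (Cx→iSPN→GPeP→{STN, GPi}) suppresses it, and
the pallidostriatal pathway (GPeP→GPeA→{dSPN, iSPN}) feeds back onto the
striatum.  CxI and FSI are shared across channels, which matters: shared
inhibition cancels in the left−right difference mode, so it stabilises the
overall activity level while leaving the channel competition free to
diverge.

Baseline inputs `I_p` are chosen so that the target baseline rates (GPi
30 Hz and GPeP 40 Hz tonically active, Th 8 Hz, cortex 5 Hz, striatum
silent) form a noise-free fixed point.  The striatal drive additionally
carries a constant −3 Hz bias (`spn_offset_hz`), holding dSPN/iSPN below
their rectification threshold at rest.  This is the key dynamical device:
at baseline the striatum is silent and the circuit is stable, while the
cortical stimulus (12.8 Hz to both Cx populations) lifts the SPNs into
their gain region, closing the positive disinhibition loop
Cx→dSPN⊣GPi⊣Th→Cx.  That loop is strong enough to destabilise the
left−right difference mode, so noise (and any learned weight asymmetry)
seeds a winner-take-all race; the first thalamic stream to reach 30 Hz
selects the action.  The loser's dSPN population is pushed back below
rectification by the shared FSI inhibition, which is what later gives the
committed CLAW states their one-sided bit pattern.

The shipped default configuration was calibrated once to the study
conditions — unbiased choices with mean decision time near 130 ms before
learning, and roughly 90% left choice with mean decision time near 100 ms
after 30 rewarded-left training trials — and is not intended as a
biophysically fitted model.  Network instances are drawn by multiplying
each type-level weight by an independent factor uniform on
[1−jitter, 1+jitter] (default jitter 0.05), which preserves exact
left/right symmetry by construction.

### Plasticity

Learning is a trial-level abstraction of dopamine-modulated corticostriatal
plasticity.  After each rewarded-task trial the reward-prediction error
δ = r − V updates the value estimate (V ← V + α_V δ, α_V = 0.3) and the
plastic weights

    Δw(Cx→dSPN_c) = +η δ e_c,    Δw(Cx→iSPN_c) = −η δ e_c,

with η = 0.10 and a per-channel eligibility trace e_c: the trial-mean dSPN
rate of channel c, raised to the third power and normalised across
channels.  The exponent makes the trace winner-dominated — credit goes
almost entirely to the channel whose striatal activity produced the choice
— which is what lets error-driven *suppression* of the unrewarded channel
accumulate instead of indiscriminate speed-up of both.  The fast value
learning rate serves the same end: once V saturates, further left rewards
carry little dopamine, while residual right choices (r = 0, δ = −V) are
strongly punished.  Plastic weights are clipped per projection
(Cx→dSPN to [1.0, 2.0], Cx→iSPN to [1.0, 1.45]); the saturating upper
bound on the rewarded side shifts late learning toward suppression of the
unrewarded channel, keeping the post-learning decision time from
collapsing while accuracy rises.  Trials that end without a decision
receive no reward and trigger no update.

Consolidation times are drawn from N(250, 1.5²) ms (read as standard
deviation 1.5; the alternative variance reading would make the SD 1.2 ms —
immaterial at these scales).  Trials without a threshold crossing within
1000 ms are recorded as choice "none" and excluded from behavioural
summaries; with the default configuration they are rare (≲0.2%).

## CLAW discretisation

Rates are averaged in Δt = 10 ms bins and binarised for the ten
state-defining populations.  Thresholds come from the pooled per-stream
histogram (Freedman–Diaconis bins): the minimum-density antimode between
the two largest modes, where the count profile is first smoothed with a
short moving average and the two modes must be separated in value with a
dip at most 0.8 of the smaller mode — without the smoothing and prominence
requirements, sampling wrinkles on a single bump read as separate modes
and the threshold lands on the baseline mean, making the bit flicker.
Streams that remain effectively unimodal fall back to median ± 2·MAD, with
the sign chosen by the skew of the pooled sample so that tonically active,
decision-suppressed populations (GPi, GPeP) threshold below their baseline
and engagement-driven populations above it.

Each trial becomes a run-length-collapsed walk through base-2 states
(indices 0–1023, most-significant bit dSPN-L in the documented default
order).  The walk's first element is the trial's modal pre-stimulus state,
so every walk departs from the launching state rather than from a
noise-flipped first bin.  Transition probabilities pool all walks,
including dwell self-loops; the CLAW diagram keeps states with ≥ 20
visiting trials and edges with probability ≥ 0.01.

Zones are assigned by an explicit rule-based classifier (precedence order
I, VI, III, IV, V, II):

- **I** — the modal pre-stimulus state;
- **VI** (reversal) — a committed pattern in one channel while the opposite
  channel still carries the disinhibition trace of an earlier commitment
  (its GPi bit off and thalamic bit on although its dSPN has turned off).
  This static signature was chosen because the loser's GPi is never
  suppressed in a normal one-sided commitment, so the pattern can only
  arise after the other channel had committed first;
- **III / IV** (commitment) — dSPN on, GPi off, Th on in one channel with
  the opposite dSPN off;
- **V** (deep deliberation) — member of a directed cycle of length ≥ 3
  (strongly connected component of size ≥ 3) among the remaining states,
  not entered directly from baseline;
- **II** (initial deliberation) — remaining states with bilateral iSPN
  engagement or without dSPN dominance; anything else is "other".

A user-supplied state→zone table overrides the classifier.  Trajectory
classes follow from the zone path: D if VI follows a committed zone, else
B if II precedes commitment, else C if a committed zone is reached, else
A.  Paths not starting in zone I are flagged unclassified rather than
raising.

## Control ensembles

Per network, activity is summarised as 18 elements (channel sums and
differences of the eight channelized types over the decision period, plus
CxI and FSI), and the behaviour of its baseline trials is fitted with the
static drift-diffusion model.  Both blocks are column-standardised and
related by canonical correlation (SVD-based); when a block has fewer
networks than variables the canonical system is solved in its
principal-component subspace.  Reported loadings are structure
correlations — correlations between each original variable and the
canonical variate of its own set — rather than raw canonical weights,
which are unstable when variables are correlated.  Components are labelled
by signature: *choice* is the component dominated by the difference
elements; of the remaining two, *responsiveness* loads more on the
corticothalamic/direct sums (Cx, dSPN, Th) and *pliancy* on the
indirect/pallidostriatal sums (iSPN, GPeP, GPeA).  Signs are fixed so that
choice correlates positively with leftward drift and each of the other two
points along its defining pathway; a warning is raised if responsiveness
and pliancy then fail to load on boundary height with opposite signs.

Within-trial engagement uses ΔF_k, the standardised change of the summary
at bin k relative to the cue-onset bin (ΔF_0 ≡ 0), projected through the
activity loadings and expressed in percent of the cross-network standard
deviation of the corresponding structure-projected score — a fixed
reference scale, since the zero baseline rules out self-relative percent.
Trial averages are formed separately under cue-onset alignment (first
50 ms, the launching phase) and decision alignment (final 30 ms, the
committed phase); the variable-duration middle is omitted.

## Drift-diffusion modelling

The static model uses symmetric boundaries ±a, start a(−1+2z), drift v,
onset tr and unit diffusion.  The first-passage density is evaluated with
the small-time/large-time series pair with per-time-point adaptive term
counts (target error 1e−8); maximum likelihood uses bounded L-BFGS-B from
five seeded starts (a ∈ (0.1, 5), v ∈ (−8, 8), tr ∈ (0, min RT),
z ∈ (0.05, 0.95)).  Response times may include the consolidation interval
when fits are meant to cover the full response duration.

The piecewise model assigns each phase of a trajectory constant (v_i, a_i)
solved from the static fit and the percent changes implied by between-zone
activity differences projected through the canonical loadings; the percent
change is expressed relative to the static fitted value.  The solver
inverts the time-weighted-average constraint exactly (residual < 1e−12).
Simulation holds the evidence at its starting point until tr, then
integrates phase by phase.  Phase-transition times are drawn by
multinomial allocation of the trajectory duration across zones — one
categorical draw per millisecond, weighted by relative dwell — giving
random dwell times with the correct means; the within-phase placement is
otherwise unspecified by the constraint structure.  Paths crossing a
boundary before their scheduled transition are discarded as inconsistent
with the observed zone sequence; at a transition, evidence already beyond
the incoming (collapsed) boundary registers as an immediate decision.
Model comparison uses BIC with k = 4 for the static model and
4 + 2·(phases − 1) for the dynamic one; the dynamic likelihood is
simulation-based (per-boundary Gaussian KDE with Silverman bandwidth over
retained paths, outcome-probability weighted), since the piecewise process
with discards has no closed-form density.

## Learning-effect statistics

Engagement or parameter time courses enter a long table
(network, trajectory type, learning stage, time bin, value).  The omnibus
model is a linear mixed model with a random intercept per network and
fixed effects time × learning × type (all interactions); a quadratic
variant adds time² and its interactions.  Both are fitted by maximum
likelihood (REML off, so BICs are comparable across fixed-effect
structures) and the lower BIC wins.  Because four decision classes are
tested independently, the omnibus threshold is α = 0.05/4 = 0.0125; the
per-bin follow-up, gated on a significant omnibus and restricted to the
terms it flagged, uses α = 0.05 and reports contiguous significant
windows.  Null simulations (500 replicates) put the omnibus type-I rate
within two binomial standard errors of the corrected level.

## Problem sizes and reproducibility

The acceptance script and default pipeline use 20 and 10 network
instances respectively, 50-trial baseline and post blocks, 30 training
trials, 1 ms integration, and 20 000–50 000 simulated diffusion paths for
model comparison; these sizes give sampling errors comfortably below the
calibration tolerances while keeping any single run in the minutes range
on one core.  Every random draw descends from one master seed through
fixed per-stage offsets, so identical configurations reproduce identical
outputs byte-for-byte.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the study's raw material —
channelized population rates, a thalamic threshold race, reward-dependent
weight asymmetry, and the resulting zone/class phenomenology — but it is a
rate-level caricature: no spiking statistics, no bursting or rebound
dynamics, no hyperdirect pathway, no tonic dopamine, and plasticity acts
once per trial rather than through spike-timing kinetics.  Passing tests
therefore demonstrate that the analysis stack (CLAW, control ensembles,
dynamic DDM, mixed models) behaves correctly and that the calibrated
behavioural endpoints are met; they do not validate the biological
parameters, and canonical loadings estimated from this circuit should not
be expected to match loadings estimated from spiking simulations or
recordings.  Known further limitations: the zone classifier is a
documented stand-in for a procedure whose original definition lives
outside this package; the choice of structure correlations (rather than
raw canonical weights) and the percent-engagement reference scale are
package conventions; and the dynamic-model likelihood is a KDE
approximation whose BIC should be read qualitatively.
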