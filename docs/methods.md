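# Model and methods

## The model

`comnet` implements a hierarchical attractor network of decision
updating in voluntary reaching.  An agent first forms an endogenous
intention (which of two colours to paint a dot cloud), then watches a
noisy random-dot motion stimulus and reaches to one of four targets —
two per colour, one per side in the standard layout — that jointly
satisfies the intention (colour) and the percept (motion direction).
Because evidence keeps arriving after movement onset, the network can
reverse its decision mid-flight: a change of mind.

Twelve nodes represent neural populations by their mean firing rate
(Hz):

* `I1, I2` — the two colour intentions;
* `S1, S2` — leftward / rightward motion evidence;
* `C1..C4` — the motor cost of each target, driven by the Euclidean
  distance from the current cursor position to that target;
* `A1..A4` — the four candidate actions, one per target.

Action nodes receive no direct input; they integrate excitation from
the intention sharing their target's colour and the sensory node
sharing its side, inhibition from their own cost node, and lateral
inhibition from the other actions.  Lateral inhibition also couples
the two intentions and the two sensory nodes; sensory nodes
self-excite, implementing temporal integration of motion evidence.
Competition between the two actions of the same colour (diagonally
opposite targets) is stronger than between actions of different
colours; the cross-colour inhibition is scaled by `kappa`.  Only the
ordering (`kappa < 1`), not the ratio, is constrained by the
underlying theory, so `kappa` is a calibrated constant like the
degree-to-pixel scale: it is set to 0.1, the regime in which the
horizontal-switch channel (perceptual + intentional changes of mind
and spontaneous vertical intention changes) carries the weight the
model's reported behaviour requires — at ratios near 0.5 the winning
action suppresses the other-colour actions so strongly that
intention reversals all but vanish.  It remains exposed in the task
configuration.  The cost→intention inhibition is fixed at
half the cost→action magnitude so that costs bias but cannot silence
intentions at trial start.  Cost nodes do not inhibit each other by
default (`cost_lateral = 0`): they encode four independent distances
rather than mutually exclusive hypotheses; a config switch enables the
coupling for exploration.

### Dynamics

Each 1 ms step computes, per node *i*:

1. total stimulation `stim_i = in_i + Σ_j r_j(t−1) · W[i,j]`;
2. Euler relaxation `r_i(t) = r_i(t−1) + (stim_i − r_i(t−1)) / τ`
   with `τ = 100 ms`;
3. additive Gaussian noise of variance `σ_i²`, then clamping to
   `[0, 100]` Hz.

The hierarchy enters through the noise term.  Non-action nodes keep
the baseline variance `σ0² = 2 Hz²`.  Each action node's variance
shrinks with the previous-step rate of its governing intention:

    σ_A² = σ0² − h · (r_I / 100) · σ0²,  floored at 0.

With `h = 1` an intention at half its maximum rate halves the noise of
the two actions serving it.  This is the model's mechanism of
top-down intentional control: strong intentions stabilise their
actions against noise-driven reversals.

Noise is added once per 1 ms step with variance σ² as written — the
per-step discrete formulation, with no √dt rescaling — and clamping is
applied after the noise so the stored state is always in range.

### Trial timeline

Rates start at 10 Hz.  Intention and cost drives are active from trial
start (intentions precede the stimulus, which is what makes early
responses possible); the stimulus appears 700–1000 ms into the trial
and reaches the sensory nodes 200 ms later (sensory delay).  The input
encoders are normalised: the sensory pair receives
`f_in(1 ± coh/100)`, the intention pair `f_in(1 ± col/100)` (each
summing to `2·f_in = 120 Hz`), and the four cost nodes receive
distance-proportional shares `4·f_in·d_k / Σ d_j` summing to 240 Hz.
The share form is our choice for the cost update rule: it is the
simplest form that (a) starts all cost inputs at 60 Hz in an
equidistant layout, (b) follows Euclidean distance during movement,
and (c) keeps total external input balanced.

An action is chosen when its rate reaches `θ = 40 Hz` *and* exceeds
every other action by at least 10 Hz (the mutual margin makes ties
impossible by construction).  Movement starts 180 ms later (motor
delay) at a constant 0.7 px/ms along a straight line, re-aimed from
the current position if another action crosses later.  Rates continue
updating for 380 ms after the first crossing (sensory 200 + motor
180 ms of non-decision time); within that window a crossing by a
*different* node redirects the movement, repeated crossings by the
same node are ignored.  After the window the rates freeze and the
movement completes ballistically; cost inputs track the moving cursor
every millisecond while rates still update.

Model RT is first crossing + 180 ms, measured from stimulus onset —
the analogue of the cursor leaving the behavioural home circle.  A
crossing before stimulus onset flags an early response; a trial whose
RT would exceed 1 s is aborted as a miss; both are excluded from
summary rates, as are trials with three or more distinct chosen
actions (double changes of mind).  A hard cap of 3 s of post-stimulus
simulation bounds any run.

### Geometry

Targets sit at (±6.0°, ±7.5°) — 9.6° eccentricity — in the standard
layout; the horizontal-distance manipulation uses (±18°, ±6°) (far)
and (±6°, ±18°) (close), both at √360° eccentricity so trial-start
costs stay equal across conditions.  Degrees map to screen pixels by a
single calibrated constant, 32.8 px/°, chosen so a straight reach to a
standard target lasts ≈450 ms at 0.7 px/ms, matching the observed
movement times; it is exposed in the task configuration.  In conflict
layouts both targets of a colour share a side (fixed as blue-right in
simulation; the wiring is mirror-equivariant, so the assignment is
immaterial).

### Classification

From threshold events: first vs final target — same target, no change
of mind; opposite side and same colour, a perceptual change of mind
(diagonal switch, intention pursued); opposite side and different
colour, a perceptual + intentional change of mind (horizontal switch);
same side and different colour, a vertical correction, interpreted as
fixing an initial colour-selection error.  The trajectory-based
classifier registers commitment to a target once the cursor has
covered 10 % of both that target's x- and y-distance in its direction,
then maps (first committed, final disc) the same way; it applies
unchanged to empirical 125 Hz cursor logs.  The two classifiers agree
whenever the first commitment had time to register kinematically
(redirections within ~45 ms of movement onset leave no trace — they
are rare at the operating point).

## Free parameters and fitting

Eight quantities are fitted; everything else is fixed.

| name | meaning | bounds | units |
|---|---|---|---|
| `w_ia` | intention → action excitation | [0, 2] | Hz/Hz |
| `w_sa` | sensory → action excitation | [0, 2] | Hz/Hz |
| `w_ca` | cost → action inhibition (cost → intention = half) | [0, 2] | Hz/Hz |
| `w_ss` | sensory self-excitation | [0, 2] | Hz/Hz |
| `w_lat` | lateral inhibition magnitude | [0, 2] | Hz/Hz |
| `coh` | test-trial motion coherence | [2, 40] | % |
| `col` | intention strength | [0, 100] | % |
| `h` | hierarchical noise control | [0, 1] | — |

The behavioural targets are the test-trial summary statistics: mean RT
570.5 ms, 56.6 % perceptual accuracy, 5.93 % perceptual changes of
mind, 1.71 % perceptual+intentional, 3.24 % vertical corrections.  The
loss is the sum of relative absolute discrepancies on those five
components plus penalties of 0.05 per percentage point of early
responses and misses and 0.01 per point of initial-colour inaccuracy.
The scalarised weighted sum (equal component weights) is the default;
the published optimisation was multi-objective with unspecified
weighting, so the scalarisation is our design choice and the weights
are configurable.

The optimiser is an in-package (μ/μ_w, λ) CMA-ES over the box bounds
(coordinates normalised to unit width, candidates projected onto the
box), followed by a Powell polish of the incumbent.  Every candidate
is evaluated on a simulation block with a fixed seed (common random
numbers), making the objective a deterministic function of the
parameters; the final incumbent is then re-scored on an independent
high-n campaign, which provides the reported loss, the pseudo
log-likelihood and the AIC.  Defaults: population 10, 40 generations,
2000 trials per evaluation — sized for a desk-scale fit.  The original
initial values and step sizes are not publicly available, so fitting
proceeds in two stages, mirroring the published procedure: an informal
exploration identifies a plausible operating region, and local CMA-ES
runs (smaller initial step size, several seeds) refine it; the shipped
reference fit is the lowest-loss such run (population 10, 40
generations, initial step 0.12 in normalised coordinates, Powell
polish, common high-n re-evaluation).  Mid-range initialisation within
the broad bounds is the API default and is what `fit` uses when no
start is given; unconstrained global runs can converge to degenerate
edge regimes (vanishing sensory self-excitation with saturated
sensory gain) whose auxiliary behaviour — zero-input steady state,
reversal decomposition — is implausible, which is why the staged
procedure is preferred.

Model comparison refits two ablations under the same budget — `h = 0`
(no hierarchical noise control, k = 7) and `w_ca = 0` (no action
costs; cost nodes fire but are disconnected, k = 7) — and compares
AIC = 2k − 2·logL under a Gaussian pseudo-likelihood over the
normalised discrepancy vector, `logL = −½ Σ d_c²`.  The likelihood
construction behind the published AIC values is not specified, so this
choice affects only de-novo comparisons; the evidence-ratio formula
`L = exp((AIC_full − AIC_alt)/2)` is checked directly against the two
published worked examples.

### Steady state

With every external input at zero, the fitted network must hold a
stable steady state whose background action-node activity stays far
below the action threshold.  `steady_state_check` reports the
time-averaged action rate after a 500 ms burn-in, the peak of the
across-run average trace (the background level the stability claim is
about), the raw per-node maximum and the fraction of runs containing
any threshold excursion.  The distinction matters: because the
baseline variance is injected every millisecond against a 100 ms time
constant, each node's stationary rate fluctuates with an SD near
10 Hz, so isolated single-node excursions to 40 Hz are a statistical
certainty in long simulations no matter the operating point —
stability is a property of the ensemble-average background, not of
every sample of every node.

## What the simulator does and does not emulate

The generator reproduces the task's trial structure: uniform random
motion direction, uniform random colour choice, stimulus onset uniform
in 700–1000 ms, conditions test (fitted coherence), easy (80 %
coherence) and conflict (80 % coherence, same-colour targets on one
side).  Intention strength is a single constant — no within- or
across-trial fluctuation — and sensory evidence is constant within a
trial, so all reversals are driven by neural noise inside the network,
not by stimulus fluctuations.  Movements are straight segments at
constant speed with no motor noise or curvature.  Early/late target
onset is not modelled: cost and intention inputs always begin at trial
start.  Consequently, passing tests show that the *network mechanism*
produces the observed reversal structure under idealised kinematics;
they say nothing about fluctuation-driven reversals or realistic
trajectory shapes.

## Numerical and design notes

* Integration is explicit Euler at dt = 1 ms, matching the model's
  discrete formulation; rates clamp to [0, 100] Hz after noise.
* Block seeds derive from the master seed by `SeedSequence` spawning;
  a campaign is reproducible as a whole, and any single trial is
  reproducible through `run_trial` with its own seed.
* Simulation stops integrating a trial at freeze time and computes the
  remaining straight-line flight analytically — exact for constant
  speed.
* The trial loop ends when every trial is frozen or missed; a 3 s
  post-stimulus cap bounds pathological parameter sets during fitting.
* Degenerate parameter sets that never decide simply produce misses
  and are penalised through the objective, not rejected.
* Problem sizes in the shipped tests: the reference campaign is
  30 × 1000 trials (the published prediction protocol); sweeps use
  1000-trial blocks with 2–10 repetitions per point, enough to resolve
  the directional effects they assert.

## Known limitations

* The cost-update rule and the degree-to-pixel scale are calibrated
  choices (documented above), not published constants.
* The AIC pseudo-likelihood is a package convention; published AIC
  values are only used through the evidence-ratio identity.
* CMA-ES here is single-objective by default; the published fit was
  multi-objective with a manual exploration stage.
* With one fitted constant per evidence stream, between-participant
  variability is outside the model's scope; all comparisons are to
  group-mean behaviour.
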