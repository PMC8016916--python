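# comnet

A hierarchical attractor-network model of changes of mind in voluntary
action.

## The problem

When people reach for a target while evidence is still arriving, they
sometimes reverse their decision mid-movement.  Classical models treat
such changes of mind as purely perceptual: late-arriving sensory
evidence overturns an initial percept.  But voluntary actions are
driven by more than percepts — they serve internally generated
intentions, and redirecting a movement has a motor cost that depends
on where the hand currently is.  `comnet` implements a firing-rate
network in which all three factors — endogenous intentions, perceptual
evidence and dynamically updated motor costs — compete continuously,
so that a single mechanism produces perceptual reversals, reversals of
intention, and corrections of outright selection errors.

It is written for computational cognitive scientists and motor-control
researchers who want to simulate the model, refit it to their own
summary statistics, or classify reaching trajectories (simulated or
empirical) by reversal type.

## The model in brief

Twelve nodes carry population firing rates r ∈ [0, 100] Hz: two colour
intentions I₁, I₂, two motion-sensitive sensory nodes S₁, S₂, four
distance-driven cost nodes C₁–C₄ and four action nodes A₁–A₄ (one per
reach target).  Each 1 ms step updates

    stim_i(t) = in_i(t) + Σ_j r_j(t−1) · W[i,j]
    r_i(t)    = r_i(t−1) + (stim_i(t) − r_i(t−1)) / τ,   τ = 100 ms
    r_i(t)   += N(0, σ_i²(t)),  then clamp to [0, 100] Hz

with intention→action and sensory→action excitation, cost→action
inhibition, lateral inhibition within every competing set, and
sensory self-excitation.  The hierarchy is a top-down noise control:
each action node's noise variance shrinks with its governing
intention's rate,

    σ_A² = σ0² − h · (r_I / 100) · σ0²   (σ0² = 2 Hz²),

so strong intentions shield their actions from noise-driven
reversals.  An action wins when it reaches θ = 40 Hz and leads every
rival by 10 Hz; the reach starts 180 ms later at 0.7 px/ms, rates keep
updating for 380 ms after the first crossing, and a later crossing by
a different action redirects the movement mid-flight.  Switches are
classified by geometry: diagonal (perceptual change of mind, CoM_P),
horizontal (perceptual + intentional, CoM_P+I) or vertical (colour
error correction).

Eight quantities are free — five connection magnitudes, the motion
coherence, the intention strength and the noise-control factor `h` —
and are fitted to behavioural summary statistics by an in-package
CMA-ES with a Powell polish; model variants are compared by AIC
evidence ratios exp((AIC_full − AIC_alt)/2).  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate the reference prediction campaign (30 blocks of 1000 test
trials at the shipped reference fit) and print its summary:

```python
from comnet import reference_parameters, simulate_condition

pv = reference_parameters()
result = simulate_condition(pv, "test", n=1000, n_runs=30, seed=101)
m = result.mean
print(f"RT        {m.rt:6.1f} ms")
print(f"accuracy  {m.accuracy:6.1f} %")
print(f"CoM_P     {m.com_p:6.2f} %")
print(f"CoM_P+I   {m.com_p_i:6.2f} %")
print(f"vertical  {m.vertical:6.2f} %")
```

prints

```
RT         566.8 ms
accuracy    59.2 %
CoM_P        5.78 %
CoM_P+I      1.67 %
vertical     3.99 %
```

i.e. at the fitted operating point the network reverses its perceptual
decision on ~6 % of difficult trials, additionally abandons the colour
intention on ~1.7 %, and corrects an initial colour-selection error by
a vertical switch on ~4 % — while staying close to the target reaction
time (570.5 ms) and accuracy (56.6 %).  The same surface is scriptable from a shell:

```
comnet simulate --condition test --n 1000 --runs 30 --seed 101 --out results/
comnet sweep intention --n 1000 --runs 2 --seed 1 --out results/
comnet fit --popsize 10 --generations 40 --seed 7 --out results/
comnet compare --seed 7 --out results/
comnet classify results/trajectories.csv --layout exp1-standard
```

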