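# Model and methods

## The model in brief

`lexigrow` simulates word-meaning acquisition in a twelve-area spiking model
of left-hemisphere cortex.  Six perisylvian areas implement the spoken
word form — an auditory stream (A1, AB, PB) and an articulatory stream
(PF_i, PM_i, M1_i) — and six extrasylvian areas implement referential
semantics: a ventral visual stream (V1, TO, AT) and a dorsolateral motor
stream (PF_L, PM_L, M1_L).  Within each stream adjacent areas are
reciprocally connected; the four multimodal hubs (PB, PF_i, AT, PF_L) are
fully interconnected; and eight second-order "jumping" bundles skip one
intermediate area — 22 reciprocal bundles in total.

Each area is a grid of excitatory cells, each paired with a graded
inhibitory twin.  An excitatory cell is a leaky integrator with
spike-frequency adaptation:

    tau · dV/dt   = −V + k1 · (V_in + k2 · eta)          membrane
    phi           = 1  iff  V − alpha · omega > thresh    spiking
    tauA · dw/dt  = −omega + phi                          adaptation

with `eta` uniform white noise on [−0.5, 0.5] and `k2 = sqrt(24/dt)`.  A
slower filter of the spike train (time constant `tau_favg`) provides each
cell's rate estimate `omega_E`; an area-wide filter of the spike count
(`tau_glob`) feeds back as subtractive global inhibition `k_G · omega_G` on
every excitatory cell of the area.  The inhibitory twin integrates the raw
pooled spike count of its 5×5 neighbourhood and subtracts its rectified
output from the twin excitatory cell's input (local competition).

Excitatory-to-excitatory links, within areas and along every bundle, are
drawn at random with a Gaussian distance profile clipped outside a square
neighbourhood (topographic, patchy connectivity), with initial weights
uniform on [0, 0.1].  They evolve under a discretised
Artola–Bröcher–Singer rule: a projection is *active* when its source's rate
estimate is at least `theta_pre`; an active projection onto a strongly
depolarised cell (`V ≥ theta_plus`) gains a fixed quantum `+delta` (LTP), an
active projection onto a moderately depolarised cell
(`theta_minus ≤ V < theta_plus`) loses `delta` (homosynaptic LTD), and an
inactive projection onto a strongly depolarised cell loses `delta`
(heterosynaptic LTD).  Weights are clipped to `[0, w_max]`.

## The learning protocol

A *word* is a set of fixed binary patterns over the primary areas: a word
form (A1 + M1_i) plus a semantic pattern — V1 for object words, M1_L for
action words — each pattern being `pattern_size` cells chosen at random.
A trial delivers the patterns for 16 steps (plasticity on), then runs
input-free until the global inhibition of the gateway hubs PB and PF_i has
decayed below a threshold, so consecutive trials do not blend.  In the
*sighted* regime the non-relevant fourth primary area receives a fresh
random pattern every trial (uncorrelated input); in the *congenitally
blind* regime V1 receives no pattern input whatsoever.  Contextual white
noise rides on all four primary areas in both regimes, during learning and
readout.  Each of the 12 words is presented `presentations_per_pattern`
times in randomised blocks.

Paired sighted/blind instances share every seed — connectivity, word
patterns, noise — so removing the V1 input channel is the *only*
difference within a pair, mirroring a within-subject deprivation design.

## Readout

*Production*: after training (plasticity frozen) the word form is presented
to A1 + M1_i for 15 steps and every excitatory cell's response is the peak
of its fast rate estimate (`tau_favg_readout = 5`), tracked through a
25-step post-stimulus window (a multi-area ignition cascade takes a few
membrane time constants per hop, so distant areas peak after stimulus
offset) and averaged over 5 independent repeats (trial averaging suppresses
spurious membership from sparse baseline spiking).  A cell joins the word's
cell assembly (CA) when its response reaches `gamma = 0.5` of its area's
maximal response; areas with an all-zero response contribute no members.

*Recognition*: only the auditory (A1) pattern is presented and the number
of spiking CA members per area is recorded per step.  The *total active
duration* is the last step at which at least 10% of the CA's members spike,
counted from stimulus onset; phases are annotated as stimulation (steps
1–16), ignition (first step with ≥ 50% of members active) and reverberation
(activity after stimulus offset).

*Statistics*: mean CA cells per area, per word type, per network feed
repeated-measures factorial ANOVAs with network instances as subjects (the
paired construction makes regime a within-subject factor).  Effects are
computed from orthonormal within-subject contrasts; sphericity is handled
with the Greenhouse–Geisser epsilon whenever an effect has more than one
numerator degree of freedom; effect size is partial eta squared
(0.01–0.06 small, 0.06–0.14 medium, > 0.14 large; below 0.01 we report
"negligible").  Planned per-area comparisons are paired t-tests at the
Bonferroni-corrected criterion 0.05/6 ≈ 0.0083.

## Parameters

Neuron and plasticity constants (defaults): `tau_e = 2.5`, `tau_i = 5`
(steps), `k1 = 0.01`, `k2 = sqrt(24/dt)`, `thresh = 0.18`, `alpha = 7`,
`tau_adapt = 10`, `tau_favg = 30` (learning) / `5` (readout),
`tau_glob = 12`, `theta_plus = 0.15`, `theta_minus = 0.14`,
`theta_pre = 0.05`.  Protocol constants: 19-cell patterns, 16-step trials,
15-step production readout, `gamma = 0.5`, 12 words (6 object + 6 action).

Quantities the model family leaves open were fixed by calibration on
training diagnostics (weight trajectories, evoked-response cascades,
stability of the interstimulus interval):

* `dt = 0.005` — the time-step entering the noise amplitude formula.  The
  uniform noise term is bounded by `k1·k2·0.5`; for any `dt > 0.019` that
  bound sits below the spiking threshold and the network is silent outside
  the stimulated cells, which kills Hebbian expansion entirely.  The
  default produces sparse spontaneous firing (~1% of cells per step).
* kernels: `sigma = 8` with peak probabilities 0.9 (within-area) and 0.8
  (between-area).  Much sparser kernels make the maximal attainable
  synaptic drive (fan-in × `w_max` × `k1`) smaller than the spiking
  threshold, so no assembly could ever re-ignite its members.
* `inhib_gain = 10` — the inhibitory twin's weight onto its excitatory
  cell, in raw input units.  The twin integrates the raw pooled spike
  count, so a gain of order ten makes local competition comparable to the
  other membrane-scale inputs.
* `contextual_amplitude` — peak-to-peak amplitude of the contextual noise
  on primary areas; default 50 raw units (10% of the stimulus drive),
  75 in the desk-scale preset (see below).
* `stimulus_amplitude = 500` raw units per active pattern cell, which
  drives a pattern cell across threshold within a step or two.
* interstimulus gate: 5% of the stimulation-phase peak of
  `omega_G(PB/PF_i)`, floored at 1.5× the spontaneous `omega_G` ceiling
  measured at training start.  Learning raises the spontaneous baseline, so
  the floor ratchets up whenever the gate times out; a trial aborts the run
  only if `omega_G` exceeds half the area's cell count (runaway).

## The desk-scale preset and what it can show

`SimConfig.scaled()` is the configuration actually exercised by the test
suite and the analysis scripts: 15×15-cell areas, 19-cell patterns,
11×11 kernel clipping, 300 presentations per pattern, 5 paired instances.
Standing in 225 cells for a cortical area requires compensations, chosen
once from scaling arguments and training diagnostics:

* `delta = 0.02` — the learning quantum scaled by the presentation ratio
  (3000/300 ≈ ×10, rounded up after inspecting weight trajectories), so the
  total plastic change available to a link over the protocol is preserved;
* `k_G = 2.5` — global inhibition scaled by the area-size ratio (625/225),
  preserving the firing set point `thresh/(k1·k_G·N)` ≈ 5% of an area,
  which is also where the plasticity rule balances (`theta_pre = 0.05` with
  `tau_favg = 30` corresponds to that same rate);
* `w_max = 6` — per-link efficacy upscaled so that a cell's maximal fan-in
  (≈ 10–19 co-active links after learning) can reach the spiking threshold
  `thresh/k1 = 18` raw units; with the conventional full-scale bound a
  225-cell area cannot drive any cell past threshold.

Extensive exploration of this preset's phase diagram found two robust
regimes.  In the *sub-ignition* regime (the default), word-selective link
bundles grow monotonically to a flux-limited plateau (~1.5–2 raw units per
link): during its word a circuit cell is depolarised into the LTP band and
fires at several times the baseline rate, word circuits are distinct
(pairwise CA overlap far below CA size), training is stable, and the
deprivation manipulation leaves its signature in the weight structure.  In
the *storm* regime (stronger coupling or faster learning) the first full
ignition potentiates links indiscriminately — during a network-wide burst
every projection is active and every cell strongly depolarised, so
heterosynaptic depression cannot prune — and a single word-unspecific
attractor absorbs the network.  The word-*selective full-ignition* regime
that the full-scale model occupies between these two phases was not
reachable at 225 cells per area.

Consequences, stated plainly: at desk scale the production readout shows
clear word-form assemblies and hub recruitment, but multi-hop ignition does
not reach the extrasylvian semantic areas, whose CA counts are therefore
dominated by a contextual-noise membership floor.  The category-specific
count dissociations across visual and motor areas, the blind model's V1
recruitment, and the prolonged blind reverberation — which all require
semantic-area ignition — do not emerge at this scale, and the corresponding
acceptance checks fail honestly rather than being weakened.  What the
passing tests do show: the exact per-step arithmetic of the neuron,
inhibition and plasticity rules; the architecture; bounded-versus-runaway
regulation by global inhibition; deterministic paired construction where
deprivation is the only difference; selective strengthening of
co-stimulated cell groups; and a statistics engine that matches a
brute-force general-linear-model oracle.

## What the synthetic stimuli do and do not capture

Word patterns are binary, fixed, and uniformly random; real sensorimotor
representations are graded, overlapping by similarity, and phonologically
structured.  The uncorrelated fourth-area input is a fresh random pattern
per trial — a stand-in for the variable percepts accompanying word use.
Contextual noise is i.i.d. uniform; real "context" is structured.  None of
these simplifications interact with the deprivation manipulation, which is
purely the removal of the V1 channel.

## Numerical choices

Explicit Euler with the simulation step as time unit; synchronous update
order: gather inputs from spikes at t → inhibitory potentials → excitatory
potentials → threshold to spikes at t+1 → adaptation/rate/global filters →
plasticity (using the new potentials and rate estimates).  The fused
network kernel is bit-identical to composing the single-area update over
areas (tested), and noise draws occur for every excitatory cell on every
step in a fixed order, independent of stimulus content, so paired runs
share identical noise histories.  Weight updates clip at 0 and `w_max`.
Ties in the CA threshold (`response == theta`) count as membership; an
area with an all-zero response map contributes no members.  Degenerate
ANOVA error terms (zero within-cell variance) are reported as NaN with a
diagnostic flag rather than as infinite F.

## Known limitations

Single-instance calibration at desk scale (the phase boundaries shift with
seed by a few percent); no axonal delays or conductance synapses; no
checkpoint/resume (the compiled kernel's RNG state is not exportable); the
full-scale configuration (25×25 areas, 3000 presentations, 13 pairs) is
supported by the same code paths but is not exercised by the test suite.
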