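# lexigrow

A spiking multi-area network model of how word meanings are learned — and of
why, in people blind from birth, "visual" cortex ends up doing language.

## The scientific problem

In congenitally blind individuals the occipital visual areas respond to
spoken language and are functionally relevant for semantic processing, yet
diffusion imaging finds no systematic anatomical rewiring relative to
sighted brains.  `lexigrow` implements the mechanistic hypothesis that three
ordinary ingredients suffice to explain this takeover: (i) Hebbian
correlation learning (LTP and both homo- and heterosynaptic LTD), (ii) the
fixed connectivity of fronto-temporo-occipital cortex, and (iii) the change
in the network's *activity balance* when the visual channel carries no
input.  Under normal learning, variable uncorrelated visual input actively
suppresses the expansion of word circuits into the visual stream; remove
that input and the same learning rule lets action-word circuits grow into
the deprived areas.

The model comprises 12 cortical areas (auditory A1–AB–PB and articulatory
PF_i–PM_i–M1_i perisylvian streams; ventral visual V1–TO–AT and dorsolateral
motor PF_L–PM_L–M1_L extrasylvian streams), each a grid of excitatory
leaky-integrate-and-fire cells with adaptation paired with graded inhibitory
twins, linked by 22 reciprocal topographic bundles (next-neighbour, hub–hub
among {PB, PF_i, AT, PF_L}, and second-order "jumping" links).  Membrane
dynamics follow

    tau dV/dt = −V + k1 (V_in + k2 eta),    spike iff V − alpha*omega > thresh

with uniform white noise `eta`, spike-frequency adaptation `omega`,
area-wide global inhibition `k_G omega_G`, and a discretised
Artola–Bröcher–Singer plasticity rule (±delta weight quanta gated by the
presynaptic rate estimate and the postsynaptic membrane potential).
"Words" are binary sensorimotor patterns over the primary areas; sighted
and congenitally blind training regimes differ *only* in whether V1
receives input.  After training, per-word cell assemblies are identified by
a word-production readout and compared across regimes, word types and areas
with repeated-measures ANOVAs and Bonferroni planned comparisons.
`docs/methods.md` has the full model description and every default.

## Layout

    src/lexigrow/        the library: config, stimuli, connectivity,
                         network_core, engine, plasticity, training,
                         readout, stats, pipeline
    analysis/01..04      numbered drivers: train pairs -> identify cell
                         assemblies -> recognition time courses -> statistics
    scripts/acceptance.py  recompute the headline quantity from scratch
    docs/methods.md      model, parameters, calibration, limitations

## Worked example

Train the desk-scale study (five paired sighted/blind instances, 15×15-cell
areas, 300 presentations per pattern — about 15 minutes on one CPU) and run
the readouts:

```
python analysis/01_train_pairs.py --seed 1
python analysis/02_cell_assemblies.py --seed 1
python analysis/03_recognition.py --seed 1
python analysis/04_statistics.py
```

`02_cell_assemblies.py` prints the mean number of CA cells per area
(instances × words averaged), e.g.:

```
regime     blind        sighted
word_type action object  action object
area
A1          19.0   19.0    19.0   19.0
AB          61.1   66.4    60.4   67.3
PB          60.6   68.7    60.0   68.0
PF_i        66.8   63.5    68.7   63.4
V1         107.0  106.2   113.6  114.1
M1_L       113.8  114.0   113.3  114.3
...
```

Reading it: the stimulated word-form cells (19 per pattern) are always
members in A1/M1_i; the auditory and hub areas carry word circuits of
~60–70 cells.  In the primary extrasylvian areas the counts are dominated
by a contextual-noise membership floor — at this reduced scale the
multi-hop ignition cascade does not reach the semantic areas, so the
category- and deprivation-specific count differences that the full-scale
model shows are not resolved here (see the scale discussion in
`docs/methods.md`).  `03_recognition.py` prints per-pair activity durations
for action-word recognition and the blind-vs-sighted percentage gain;
`04_statistics.py` prints the repeated-measures ANOVA tables
(Greenhouse–Geisser corrected, partial eta squared) and the per-area
planned comparisons at the corrected criterion p < 0.0083.  All tables are
also written under `results/`.

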