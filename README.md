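# gaitconn

Gait-phase-resolved functional connectivity for multichannel cortical EEG
recorded during locomotion — and a synthetic benchmark generator to
validate every stage of the analysis end to end.

## The scientific problem

When an animal walks over terrain it cannot see, the cortex has to fold
unexpected sensory events into an ongoing, rhythmic motor program.  A
static functional network computed over a whole session averages away
exactly the thing of interest: how the coupling between cortical areas
changes *within* the gait cycle and *across* terrain conditions.

`gaitconn` implements the time-varying analysis for this setting:
32-channel EEG over six cortical regions (left/right somatomotor LMO/RMO,
left/right somatosensory LSS/RSS, retrosplenial RSP, visual VIS), epochs
locked to gait events (RO/RC = right hind paw off/contacting the ground,
LO/LC = left; cycle LC→RO→RC→LO→LC with a 750-ms preparation phase LC→RO
and three 250-ms walking sub-phases), and three locomotion conditions
(FF flat→flat, FU flat→unexpected-uneven, UF uneven→flat).

## The statistic at the core

Connectivity is quantified by the phase-lag index (PLI).  With
instantaneous phases φ_x, φ_y from the analytic (Hilbert) signal and
Δφ(t_n) = φ_x(t_n) − φ_y(t_n) wrapped to (−π, π],

    PLI = | (1/N) Σ_n sign(Δφ(t_n)) |,   0 ≤ PLI ≤ 1,

with sign(0) = 0.  PLI is 0 for no coupling (or coupling at zero lag —
the volume-conduction confound) and 1 for complete phase locking at a
nonzero lag.  A 250-ms window with 50 % overlap scans each 2.5-s epoch
(19 windows); the preparation phase is summarized by the mean of its
three non-overlapping windows, each walking sub-phase by its exactly
coincident window, giving one 4 × 32 × 32 tensor slice per epoch.
Weighted graph metrics (global efficiency, transitivity, characteristic
path length; local efficiency, node strength, Onnela clustering,
eigenvector centrality; distances = 1/weight) describe the resulting
networks, one-way ANOVA with Tukey HSD compares conditions, and the
phase-resolved PLI matrices feed SVM / naive-Bayes / KNN classifiers
under stratified 5-fold cross-validation to decode the locomotion
condition.

## Worked example

```python
import gaitconn as gc

cfg = gc.SimConfig(n_epochs_per_condition=30, seed=0)
rec, events, truth = gc.simulate_recording(cfg)       # 32 ch @ 2 kHz
epochs = gc.preprocess_recording(rec, events)         # 3-50 Hz, CAR, 500 Hz
tensor = gc.sliding_pli(epochs)                       # 90 x 19 x 32 x 32
phases = gc.collapse_phases(tensor)                   # 90 x 4 x 32 x 32
avg, conds = gc.condition_average(phases)             # 3 x 4 x 32 x 32

table = gc.compare_families(
    {
        "whole_pli": gc.build_features("whole_pli", epochs=epochs),
        "tv_pli": gc.build_features("tv_pli", phase_conn=phases),
    },
    classifiers=("NB",), seed=42,
)
print(table[["family", "classifier", "dim", "accuracy", "f1"]].to_string(index=False))
```

prints (computed by this exact script):

```
   family classifier  dim  accuracy        f1
whole_pli         NB 1024 36.666667 34.964887
   tv_pli         NB 4096 91.111111 90.865579
```

The generator puts its condition differences only in the late walking
sub-phases, so the whole-cycle PLI (which averages over phases) is barely
above the 33 % chance level while the gait-phase-resolved PLI decodes the
condition at 91 % — the motivating point of the time-varying analysis.

The same stages are available from the shell:

```
gaitconn simulate --out-dir sim --seed 0
gaitconn run-all --out-dir run --seed 0
```

`run-all` writes the PLI tensors, metric and ANOVA tables, classification
report and a `log.json` with the config hash into the run directory.

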