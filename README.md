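# rgctwin

Digital-twin encoding models of retinal ganglion cells (RGCs), built as a
fully synthetic, self-verifying pipeline.

Mouse RGCs view the world through two spectral channels — green and UV —
whose statistics differ sharply between the sky (UV-dominant) and the
ground (green-dominant). A rare RGC type, the transient
suppressed-by-contrast (tSbC) cell, is selectively excited by UV-ON /
green-OFF stimuli, exactly the chromatic signature of a ground-to-sky
visual context change. Studying this computationally requires a "digital
twin": a convolutional neural network (CNN) trained to predict each
recorded cell's firing rate from a dichromatic movie, which can then be
probed with stimuli no experiment could present.

`rgctwin` implements that entire analysis chain over a ground-truth
simulator, so every stage can be tested against known answers without any
recordings:

* **synthetic data** — a clip-structured dichromatic movie (113 clips of
  150 frames at 30 Hz, 18×16 px, sky/ground chromatic labels), a
  ground-truth RGC population (ON, OFF, ON-OFF, slow-ON, and a nonlinearly
  colour-opponent suppressed-by-contrast family), and calcium-like traces
  at 7.8125 Hz with drift, noise and three test-sequence repeats;
* **preprocessing** — Savitzky–Golay detrending, percentile clipping, SD
  normalisation, calcium-kernel deconvolution to 30 Hz firing rates, and
  the quality/inclusion filter cascade (QI, confidence, test correlation,
  DoG-fit cost);
* **the encoding model** — a two-layer space-time-separable CNN core
  (16 kernels of 2×11×11×21 then 16×5×5×11, Fourier-parameterised temporal
  kernels with a per-recording time stretch, batch norm, ELU) with a
  per-neuron Gaussian readout and softplus output, trained with a Poisson
  objective, Adam, early stopping and restore-and-decay cycles; a
  linearised (LN) variant drops the activations;
* **MEIs** — maximally exciting inputs by constrained gradient ascent
  (`x ← x + λ ∂r̂/∂x`, joint L2 budget b = 30, per-channel range box),
  characterised by SVD decomposition, concentric anisotropic
  difference-of-Gaussians fits, centre size/mask, temporal frequency and
  the chromatic contrast pair (γ_green, γ_UV);
* **in-silico experiments** — rank-1 MEI stimuli on a 5×5 grid with
  Gaussian-readout-weighted responses and a selectivity index, chromatic
  tuning maps over an 11×11 contrast subspace, and ROC/AUC detection of
  ground-to-sky transitions, including a moving-window simulator at four
  angular velocities;
* **statistics** — permutation tests (100,000 shuffles), percentile
  bootstrap CIs, Cohen's d, Pearson correlation, Bonferroni correction.

The network, its backpropagation and the optimiser are implemented
directly in numpy; the gradients are validated against finite differences
in the test suite.

## Worked example

```python
import numpy as np
from rgctwin import (MovieConfig, PopulationConfig, RetinaTwin,
                     TrainingSchedule, generate_movie, generate_population,
                     simulate_recording)
from rgctwin.mei import MEIOptions, characterize_mei, synthesize_mei

movie = generate_movie(MovieConfig(n_clips=40), seed=0)
cells = generate_population(
    PopulationConfig(counts={"ON": 6, "opponent-SbC": 6}), seed=1)
pack = simulate_recording(cells, movie, seed=2)

schedule = TrainingSchedule(n_cycles=2, max_epochs_per_cycle=12,
                            batch_size=16, n_members=1, n_val_clips=5,
                            patience=6, spatial_decay=0.05)
results = RetinaTwin.from_recording(pack, movie).fit(schedule, seed=3)

rec = synthesize_mei(results, neuron=6, options=MEIOptions(seed=7))
props = characterize_mei(rec)
print(f"gamma = ({props.gamma['green']:+.2f}, {props.gamma['uv']:+.2f}), "
      f"opponent = {props.opponent}")
```

prints, for the first opponent-SbC cell of this population,

```
gamma = (-1.16, +1.85), opponent = True
```

— the synthesised MEI is green-dark / UV-bright, i.e. the model has
discovered the cell's colour opponency from movie responses alone, even
though the opponency is invisible to a linear fit (the same cell under the
LN variant yields `gamma = (+0.42, +3.35), opponent = False`). On the
simulated population, the opponent-SbC family attains the highest
ground-to-sky detection AUC of all families, at every simulated velocity.

A command-line interface mirrors the stages:

```bash
rgctwin run-all --seed 0 --out runs/demo
rgctwin validate --out runs/demo
```

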