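# emgsynergy

Muscle-synergy analysis of multi-channel lower-limb surface EMG (sEMG),
built around non-negative matrix factorization, for two clinical
questions: *which lower-limb motion is a subject performing?* and *does
the subject's muscle coordination show signs of knee pathology?*

The package is aimed at biomedical-signal researchers working with
thigh-muscle recordings — rectus femoris (RF), femoral biceps (FB),
vastus medialis (VM) and semitendinosus (SEM) — plus a knee goniometer,
during leg flexion while standing (STD), leg extension while sitting
(ST), and level walking (Gait).

## The model

An envelope matrix `A` (m muscles × n samples) is factored into a small
set of muscle synergies,

    A ≈ W H,   W ≥ 0, H ≥ 0,

where each column of `W (m × k)` is a fixed non-negative muscle weighting
recruited as a unit and each row of `H (k × n)` is its activation time
course.  The factorization minimizes the Euclidean cost `‖A − W H‖_F`
with Lee–Seung multiplicative updates, normalizes `W`'s columns every
iteration (compensating in `H`), and keeps the best of 20 random + 1
SVD-based restarts by the variability accounted for,

    VAF = 1 − ‖A − W H‖²_F / ‖A − Ā‖²_F .

The synergy count per motion is the smallest `k` with mean VAF > 0.85
across motion segments.  On top of the factorization the package
provides: max-correlation similarity of synergy sets (with intra/inter
group tables and 3σ outlier removal for representative synergies),
sliding-window feature extraction (synergy weights plus RMS / AR(4) /
IQR / waveform-length / MAV of the activations), two-stage feature
selection (Relief-F screening, then a floating wrapper search), and
imbalance-corrected random-forest classification with 10-fold
cross-validated F-measures (geometric-mean resampling: ADASYN
oversampling + random undersampling).

A synthetic-cohort generator (`emgsynergy.synthetic_data`) plants known
synergy structure — bell-shaped knee-angle trajectories, 1.32 s gait
cycles, amplitude-modulated band-limited carriers, controllable
between-group pattern shifts — so every stage is testable end to end
without any data download.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Generate one synthetic standing-flexion recording, preprocess it,
segment the movement repetitions from the knee angle, and extract the
synergies of the first repetition:

```python
import numpy as np
from emgsynergy import SynthSpec, generate_recording, nmf_decompose, max_cc
from emgsynergy.preprocess import (filter_and_rectify, normalize_and_envelope,
                                   segment_motion, attach_envelopes)

spec = SynthSpec(n_subjects=1, reps=2, seed=3)
rec, truth = generate_recording(spec, "CG01", "CG", "STD")
rect = np.vstack([filter_and_rectify(ch, rec.fs) for ch in rec.semg])
env = normalize_and_envelope(rect, rec.fs)
segs = segment_motion(rec.angle, rec.fs, "STD")
attach_envelopes(segs, env)
print(f"segments found: {len(segs)}")
dec = nmf_decompose(segs[0].envelope_resampled, k=2, rng=0)
print(f"VAF at k=2: {dec.vaf:.3f}  (init: {dec.init_kind}, {dec.iterations_run} iterations)")
print(f"synergy patterns W (muscles x synergies):\n{np.round(dec.W, 3)}")
print(f"recovery vs planted pattern, max CC: {max_cc(dec.W, truth['W_true']):.3f}")
```

prints

```
segments found: 2
VAF at k=2: 0.989  (init: random, 60 iterations)
synergy patterns W (muscles x synergies):
[[0.135 0.661]
 [0.741 0.104]
 [0.001 0.736]
 [0.658 0.106]]
recovery vs planted pattern, max CC: 0.986
```

Both planted repetitions are located from the angle trace; two synergies
explain 98.9% of the envelope variability.  Reading the columns of `W`
(rows are RF, FB, VM, SEM): the first synergy loads on the knee flexors
FB and SEM — the agonists of standing leg flexion — and the second on the
extensors RF and VM, the stabilizing co-contraction.  The extracted
patterns match the planted ground truth at a maximum correlation of
0.986.

## Command-line interface

```bash
emgsynergy simulate  --out cohort/ --subjects 3 --seed 1
emgsynergy synergy   --manifest cohort/manifest.yaml --out synergy.json
emgsynergy similarity --manifest cohort/manifest.yaml --out similarity.json
emgsynergy classify  --manifest cohort/manifest.yaml --task motion \
                     --k 2 --features fine --out report.json
```

`simulate` writes delimited-text recordings plus a YAML manifest;
the other subcommands read any manifest in that format, so the same
pipeline runs on real exported recordings (one CSV/TSV per recording,
columns mapped in the manifest's `layout`).

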