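# fnssir

Decoding **motor imagery of force-intensity variation** from EEG.

Most motor-imagery BCIs distinguish *which* limb is imagined; rehabilitation
robots also need to know *how forcefully*. In the paradigm this package
implements, each 12-s trial contains two 5-s imagery segments whose imagined
force changes within the trial, giving three classes: large→medium (LMF),
large→small (LSF), and medium→small (MSF). The discriminative EEG signatures
are graded: event-related desynchronization (ERD) of the sensorimotor alpha
(8–13 Hz) and beta (13–30 Hz) rhythms around C3 whose depth, duration and
spatial extent scale with imagined force, and a movement-related cortical
potential (MRCP) — a slow frontocentral negativity peaking ~1 s after each
imagery onset, more negative for larger force.

The package provides, end to end:

* **`fnssir.epochs`** — an epoch container (HDF5 on disk), EDF/GDF import,
  and the preprocessing chain (zero-phase FIR 0.1–30 Hz, common average
  reference, downsampling to 100 Hz, 12-s epoching, baseline correction);
* **`fnssir.simulate`** — a synthetic generator of the paradigm with
  force-scaled ERD/MRCP effects and known ground truth;
* **`fnssir.ersp`** — Morlet-based ERSP maps
  `ERSP(f,t) = 10 log₁₀(P(f,t)/P̄_base(f))`, band curves, scalp
  topographies, and trial-averaged MRCP waveforms;
* **`fnssir.plane`** — the electrode-plane representation: 10–20 electrodes
  snapped to an H×W scalp grid, vacant cells filled by distance-based
  interpolation, yielding the 3D tensor `X ∈ R^{1×H×W×T}`;
* **`fnssir.model` / `fnssir.nn`** — the FN-SSIR network: a multi-scale 3D
  convolutional branch (kernels (3,3,3), (5,5,5), (7,9,7), two units), a
  convolutional auto-encoder denoising six frontocentral electrodes, and an
  LSTM + self-attention fusion (40- and 80-unit LSTMs, d = 120 attention),
  implemented on a compact numpy layer library with hand-written,
  finite-difference-verified gradients;
* **`fnssir.training`** — Adam training (lr 0.001, batch 7, cross-entropy
  + 0.1·reconstruction-MSE), stratified k-fold and leave-one-subject-out
  cross-validation, confusion matrices, paired t-tests, label-shuffle
  controls, and the branch-ablation variants.

## Worked example

```python
import numpy as np
from fnssir.simulate import SyntheticConfig, generate_dataset
from fnssir.recovery import recover_erd_depths
from fnssir.benchmark import (benchmark_dataset, benchmark_model_config,
                              benchmark_train_config)
from fnssir.training import cv_experiment

cfg = SyntheticConfig(seed=7)            # 126 trials, 42 per class, 100 Hz
session = generate_dataset(cfg)

erd = recover_erd_depths(session, cfg)   # alpha ERD at C3, per class/segment
print(erd[["class_name", "segment", "force", "injected_db", "recovered_db"]])

report = cv_experiment(benchmark_dataset(1), benchmark_model_config(),
                       benchmark_train_config(1))
print(f"4-fold CV accuracy: {report.grand_mean:.1f}% "
      f"(folds {[round(a, 1) for a in report.per_fold_acc[0]]})")
```

prints (about 3 minutes on one CPU):

```
  class_name  segment   force  injected_db  recovered_db
0        LMF        0   large         -6.0     -5.337135
1        LMF        1  medium         -4.0     -3.650934
2        LSF        0   large         -6.0     -5.245331
3        LSF        1   small         -2.0     -1.793172
4        MSF        0  medium         -4.0     -3.495836
5        MSF        1   small         -2.0     -1.865132
4-fold CV accuracy: 85.8% (folds [75.0, 90.6, 93.5, 83.9])
```

The first table shows the analysis stack recovering the injected alpha ERD
depths at C3 to within 1 dB with the force ordering intact; the CV line is
the end-to-end FN-SSIR decoder on the desk-scale benchmark (126 trials
decimated to 25 Hz, reduced filter counts — see `docs/methods.md`), far
above the 33.3 % chance level of the three-class problem.

The same pipeline is scriptable from the shell:

```sh
fnssir simulate --seed 1 --out epochs.h5
fnssir ersp --epochs epochs.h5 --channel C3 --out c3.npz --png c3.png
fnssir mrcp --epochs epochs.h5 --channel FC3 --out mrcp.csv
fnssir cv --epochs epochs.h5 --train-config train.yaml --out report.json
```

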