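# Methods

This note documents the models, numerical choices, and open design decisions
behind `fnssir`: a pipeline for decoding motor imagery (MI) of *force-intensity
variation* from EEG, together with the synthetic data that makes every stage
testable without access to real recordings.

## The decoding problem

In the paradigm this package targets, a participant imagines a dynamic
right-upper-limb movement whose force changes *within* a single trial. Each
12-s trial contains two 5-s imagery segments separated by a 2-s preparation
gap, and each of the three classes is a force sequence:

| class | label | segment 1 | segment 2 |
|-------|-------|-----------|-----------|
| LMF   | 0     | large     | medium    |
| LSF   | 1     | large     | small     |
| MSF   | 2     | medium    | small     |

The neural signatures that separate these classes are graded rather than
categorical: deeper, longer, and spatially wider event-related
desynchronization (ERD) of the alpha (8–13 Hz) and beta (13–30 Hz)
sensorimotor rhythms over the contralateral cortex (around C3 for right-limb
imagery) for larger imagined force, and a more negative movement-related
cortical potential (MRCP) — a slow frontocentral deflection beginning about
0.5 s after each imagery onset and peaking near 1 s.

## Preprocessing (`fnssir.epochs`)

The chain is the standard offline MI pipeline: zero-phase Hamming-window FIR
bandpass (0.1–30 Hz), common average reference, polyphase decimation to
100 Hz, extraction of the 12-s trial window, and baseline correction against
the mean of the 1 s preceding the first imagery onset.

Numerical choices:

* FIR design is windowed-sinc (Hamming) with automatic order and a lower
  transition width equal to the low band edge, applied zero-phase.  A 0.1 Hz
  edge therefore implies a ~33 s impulse response: the bandpass is meant for
  continuous recordings, not for already-cut epochs.
* Time convention: t = 0 at the first imagery onset; windows are half-open;
  sample *i* covers `[t0 + i/fs, t0 + (i+1)/fs)`.
* Ocular-artifact removal is **not** implemented (no specific algorithm is
  prescribed for it, and the synthetic data contains no ocular activity);
  users with real recordings should pre-clean them.

## Synthetic data (`fnssir.simulate`)

The generator is a forward model of the paradigm, not a neural-mass
simulation. Per trial it sums:

1. **1/f background noise** — spectrally shaped Gaussian noise
   (exponent 1, 10 µV RMS per channel), independent across channels.
2. **Sensorimotor rhythms** — 10 Hz (20 µV at C3) and 24 Hz (10 µV)
   oscillations with random per-trial phase and a Gaussian spatial profile
   (σ = 2.5 grid cells) centred on C3.  During each imagery segment the
   rhythm amplitude is *multiplicatively* suppressed by the force-dependent
   ERD depth (−6 / −4 / −2 dB for large/medium/small) for a force-dependent
   fraction of the segment (1.0 / 0.8 / 0.6), with 0.25-s raised-cosine
   ramps.  The suppression depth falls off spatially as a Gaussian around
   C3 whose width scales with force (×1.2 / ×1.0 / ×0.8 of σ = 1.5 cells),
   so stronger imagined force also activates a wider area.
3. **MRCP transients** — a sin² negative bump from 0.5 s to 1.5 s after each
   segment onset (peak at 1 s), with force-scaled amplitude
   (−8 / −5 / −3 µV) and a broad Gaussian field (σ = 3.5 cells) centred
   between FCz and C3.  The breadth reflects the diffuse frontocentral
   topography of slow motor potentials; it also means FC3 — the electrode
   analysed throughout — sees ~90 % of the injected amplitude.
4. **Timing variability** — per-trial (and, for multi-subject data,
   per-subject) Gaussian jitter (SD 0.25 s) of ERD onset and duration.

Rationale for the signal-to-noise choices: a 20 µV idling mu rhythm over
10 µV broadband background is a strong but realistic resting sensorimotor
rhythm, and is the regime in which a −6 dB ERD measured from 42 trials is
recoverable to within ±1 dB — the recovery tolerance a study of this design
would need.  With weaker rhythms the 1/f noise inside the wavelet passband
biases recovered depths toward zero.

What the generator deliberately does *not* emulate: ocular/muscle artifacts,
volume-conduction correlations between channels, non-stationary background,
or any difference between imagery and execution phases.  Passing tests on
this data therefore validate the *machinery* (representation, network,
statistics), not decoding performance on real EEG.

ERD is multiplicative (not additive) because ERSP measures power *relative*
to baseline; an additive deflection would not produce a baseline-independent
dB change.

## Time-frequency analysis (`fnssir.ersp`)

Power is estimated with complex Morlet wavelets (cycles = max(3, f/2),
5σ support, admissibility-corrected zero-mean), computed per trial and
averaged:

    ERSP(f, t) = 10 log10( (1/n) Σ_k |F_k(f, t)|² / P̄_base(f) )

with the −2…0 s pre-onset window as baseline.  Raw mean power is available
via `db=False`.  Epochs are mirror-padded by 1 s before the transform; the
outer ~0.5 s of any map should still be treated as unreliable.  Band
summaries use alpha 8–13 Hz and beta 13–30 Hz; time-resolved curves may use
the narrower 22–27 Hz beta range conventional for this paradigm.  MRCP
waveforms are per-class trial averages, low-passed at 5 Hz and re-baselined.

## Electrode plane (`fnssir.plane`)

The montage CSV ships idealized 10–20/10–10 spherical coordinates
constructed from the canonical topographic grid layout via the inverse
azimuthal-equidistant map (18° per 10 % arc step).  `build_grid` projects
the montage, normalises each axis to the grid extent, and snaps electrodes
to cells (a collision is an error suggesting a larger grid).  Vacant cells
inside the electrode convex hull are filled by inverse-distance weighting
(power 1) over the 4 nearest placed electrodes; cells outside the hull are
zero and recorded in a mask.  Degenerate montages (< 3 or collinear
electrodes) fall back to bounding-box membership.  The default grid is 9×9,
which the two (3,3,·) pooling stages reduce to 1×1.

## The network (`fnssir.model`, `fnssir.nn`)

FN-SSIR fuses three branches:

* **MSSTCN** — two multi-scale 3D-convolution units over the electrode-plane
  tensor X ∈ R^{1×H×W×T}.  Each unit runs three parallel same-padded 3D
  convolutions with kernels (3,3,3), (5,5,5), (7,9,7), batch-normalises each
  per channel, concatenates, then ReLU → average pooling ((3,3,5), then
  (3,3,10)); dropout p = 0.5 after the second pooling.  Defaults of 8 and 16
  filters per kernel give a 48-channel, 24-step output on 9×9×1200 input.
* **CAE** — an auto-encoder over the min-max-scaled signals of FC3, FCz,
  FC4, C3, Cz, C4: two Conv(1,3)+ReLU+MaxPool(1,2) stages (time/4), then two
  transposed convolutions (kernel (1,4), stride (1,2), padding (0,1)) back
  to full length with a sigmoid.  Its role is denoising reconstruction of
  the low-frequency (MRCP-bearing) content; the reconstruction, cut into as
  many windows as the MSSTCN emits steps, is the second sequence.
* **LSTM-SA** — LSTM-A (40 units) over the MSSTCN sequence and LSTM-B (80
  units) over the CAE sequence; their per-step concatenation (120) passes
  through single-head scaled dot-product self-attention (softmax(QKᵀ/√d)V,
  d = 120), is flattened, and classified by one dense layer.

Design decisions where the architecture description left room:

* Filter counts per 3D convolution are configurable (8/16 defaults chosen to
  keep the model trainable on a desktop CPU while matching the published
  layer table's kernel shapes exactly).
* All 3D convolutions are same-padded so the three branch outputs
  concatenate; batch normalisation is per-convolution (equivalently,
  per-channel over the concatenation).
* One dropout layer (after the second pooling), following the layer table.
* The attention similarity is scaled by √d (the standard scaled dot
  product); the published divisor is ambiguous between d and √d.
* The CAE channel list contains a duplicated label in the source
  description; it is read as the symmetric pair FC3/FC4.
* LSTM-A is assigned to the MSSTCN branch and LSTM-B to the CAE branch; the
  CAE decoder output (not the bottleneck) feeds LSTM-B.
* Loss: cross-entropy plus λ·MSE between the CAE reconstruction and the
  ≤5 Hz low-passed, min-max-scaled input (λ = 0.1, λ = 0 supported).  The
  reconstruction term gives the auto-encoder its denoising interpretation;
  training remains end-to-end.
* Ablations: *w/o MSSTCN* feeds only the CAE sequence to LSTM-B+attention
  (d = 80); *w/o CAE* only the MSSTCN sequence (d = 40); *w/o LSTM-SA*
  flattens both sequences straight into the classifier.

### The numpy layer library

The network is implemented on a small layer library with hand-written
gradients (`fnssir.nn`): FFT-based same-padded 3D convolution (the three
kernels of a unit share one forward transform and batched inverses),
temporal 2D and transposed convolutions, batch norm, average/max pooling,
dropout, LSTM, self-attention, dense layers, Adam, and the two losses.
Float32 is the working precision; every backward pass is verified against
central finite differences in float64 in the test suite.  Inference uses
batch-norm running statistics and disables dropout; training is bitwise
reproducible given a seed.

## Training and evaluation (`fnssir.training`)

Defaults follow the study protocol: Adam, learning rate 0.001, batch size 7
(36 for the session-split style), 200 (400) epochs, stratified 4-fold
cross-validation repeated 5 times with repeat *r* seeded `seed + r`.  Both
the *highest* repeat mean (the protocol's headline convention) and the grand
mean are reported; the grand mean is the recommended summary.  No early
stopping, weight decay, or schedules.  Fold disjointness is asserted on
every run.  The paired t-test uses the closed form with a Shapiro–Wilk
normality *advisory* (a warning, never a gate).  Leave-one-subject-out
evaluation trains on all but one synthetic subject.

## The desk-scale benchmark (`fnssir.benchmark`)

End-to-end decoding and ablation checks run on a reduced instantiation
chosen to fit a single CPU: the default 126-trial session cropped to the
12-s task window and decimated to 25 Hz (keeping the alpha rhythm and the
MRCP, which carry the injected class information; the beta rhythm is
sacrificed), a model with 1 and 2 filters per 3D-convolution branch, batch
size 7, learning rate 0.001, and 50 training epochs — the point where the
training loss has plateaued at this scale.  Stratified 4-fold
cross-validation over this benchmark reaches fold-mean accuracies around
85–91 % across training seeds, with the label-shuffled control at chance.
Fold-level variance is large (individual folds range roughly 75–100 %, and
some seed/data combinations give lower means): with 31–32 test trials per
fold and a small, stochastically trained network this spread is expected,
and it mirrors the wide between-subject spread typical of force-imagery
decoding.  These numbers are properties of the synthetic benchmark, not
estimates of real-data accuracy.

### What the ablations show at this scale

Removing the MSSTCN branch collapses accuracy to near chance (25–44 %),
confirming that the 3D spatial-temporal convolution over the electrode
plane carries the ERD information that drives decoding.  Removing the
LSTM-SA fusion also hurts in most seeds.  Removing the CAE branch, however,
consistently *improves* accuracy on this synthetic benchmark: the injected
ERD is separable enough that the 80 of 120 attention dimensions fed by the
CAE sequence dilute the decision rather than complement it, and neither
longer training, dropping the reconstruction loss, nor reassigning LSTM
capacities changes that ordering.  The corresponding acceptance check is
therefore expected to fail on the CAE clause; the full three-branch
architecture earns its extra branch only on data where the slow-potential
features add information that the rhythm features lack — a property the
simplified generator does not reproduce at this problem size.

## Known limitations

* The synthetic generator's independence assumptions (no inter-channel
  noise correlation, sinusoidal rhythms) make decoding easier than real
  EEG; benchmark accuracies are not comparable to published real-data
  figures.
* The FFT convolution layer materialises full spectral grids; very large
  montages or sampling rates will be memory-hungry.
* The EDF/GDF import path expects an explicit events table
  (`onset_sample,label`); annotation-based event discovery is out of scope.
* The bandpass requires recordings long enough for its impulse response
  (~33 s at the default 0.1 Hz edge).
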