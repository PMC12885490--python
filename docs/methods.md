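# Methods

## Problem setting

`mispeed` is a testbed for decoding the *speed* of paced motor imagery (MI)
from EEG. Four conditions are modeled — rest and imagined grasping paced at
slow / medium / fast rates — following a cued protocol: a 1-s visual cue, a
beep marking the onset of a 5-s imagery period, and a 2-s break, organized
as three runs of 35 trials (10 per MI class + 5 rest per run; 30 per MI
class and 15 rest in total, so always-predict-majority accuracy is
30/105 = 0.2857).

Because no public recordings exist for this protocol, the package ships a
simulator that generates sessions with the statistical structure the
analysis pipeline assumes, with full ground truth. Every downstream claim in
the test suite is a *recovery* statement: the pipeline run on simulated data
must re-discover what the simulator injected.

## Signal model

Each trial is a sum of four components on a 14-channel 10-10 montage
(FC3, FCz, FC4, C3, Cz, C4, CP3, CPz, CP4, Pz, O1, O2, T7, Fz), in
microvolts at fs = 250 Hz:

1. **1/f background** — Gaussian noise shaped to |f|^(-β/2) in amplitude
   (β = 1 by default, configurable in [0, 2]), RMS `noise_scale` (default
   1 µV), independent per channel.
2. **Alpha and beta rhythms** — band-limited Gaussian noise (8–12 Hz at
   2 µV RMS, 13–30 Hz at 1 µV RMS), on all channels. During non-rest
   trials the rhythm envelope over motor channels is attenuated by the
   condition's ERD fractions (`erd_alpha`, `erd_beta`), from 1 s before
   the beep (anticipatory ERD) through the end of the MI period, with
   0.2-s raised-cosine edges so the envelope step does not inject
   broadband power. The attenuation scales with the motor topography
   weight, so the expected MI/rest alpha power ratio on a motor channel
   with weight 1 is exactly (1 − erd_alpha)².
3. **SSMRP** — sinusoids at the pacing fundamental f0 and harmonics
   h·f0, h = 1..4, with amplitude profile (0.6, 1.0, 0.5, 0.25) µV —
   strongest at the second harmonic, gradually attenuating above — with
   phases drawn once per trial, present only during the MI window and
   phase-locked to the beep. Harmonics above Nyquist are dropped with a
   warning. Weighted by a frontocentral topography.
4. **SSVEP** — the same harmonic shape on an occipital/parietal
   topography, scaled so its peak amplitude is `ssvep_amp` (default
   1.5 µV, i.e. 1.5× the SSMRP peak, reflecting that visual steady-state
   responses run larger than movement-related ones).

Pacing fundamentals default to 0.93 / 2.12 / 2.56 Hz. A grid-aligned
variant (0.9 / 2.1 / 2.6 Hz) is provided so all harmonics fall on exact
0.1-Hz spectral bins; spectral-recovery experiments use it.

Topographies are "max of Gaussian bumps" (σ = 3 cm of scalp distance)
centered on the named channel sets, using electrode positions from the
standard 10-10 montage shipped with MNE. This gives smooth, plausible — but
deliberately simple — spatial structure.

**What the simulator does not model:** ocular/muscle artifacts, electrode
drift, realistic volume conduction and channel covariance, inter-trial
non-stationarity, behavioral variability in pacing, or any participant
individuality. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and sensitive, *not* that comparable
decoding accuracy would be reached on real recordings.

### Separability presets

`default_conditions(separability=...)` offers two parameterizations:

* `"default"` — moderate ERD depths increasing with speed
  (0.2/0.35/0.5 alpha, 0.1/0.25/0.4 beta).
* `"high"` — a high-separability regime for decoder-recovery experiments:
  class-distinct ERD patterns (slow: deep alpha ERD only; medium: moderate
  alpha+beta; fast: deep beta ERD only), doubled steady-state amplitudes.
  This is the regime in which end-to-end recovery (accuracy, kernel bands,
  CAT topography) is asserted; with the default preset the problem is
  intentionally harder.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (`sosfiltfilt`), default
4–40 Hz: the low cut removes slow potentials and drift-like background, the
40-Hz cap keeps the decoder input compact. Epochs default to [−1, 5] s
around the beep, covering the anticipatory window and the full MI period.
Each channel of each epoch is z-scored over the epoch (constant channels
map to zeros); z-scoring is idempotent and makes the decoder scale-free.
The canonical evaluation scheme is leave-one-run-out (3 folds), which
respects run structure; a seeded stratified K-fold is available.

Note the 4-Hz high-pass removes the slow-condition harmonics (all below
3.8 Hz) from the *decoder's* input; steady-state spectral analysis is
therefore run on unfiltered epochs.

## Decoder

A conv-transformer in the EEGConformer family, implemented directly in
numpy with hand-derived gradients (verified against central finite
differences in the tests):

* temporal filter bank K (40 FIR kernels of 25 samples, applied per
  channel as correlation, i.e. convolution with the time-reversed kernel),
* spatial filter matrix W (40 × 14) projecting each filtered multichannel
  signal onto one source per feature,
* ELU, average pooling (75 samples, stride 15) producing ~94 tokens,
* a 2-layer pre-LayerNorm transformer encoder (4 heads, embed 40, GELU
  MLP of ratio 2, dropout 0.5 at the conv output and classifier head),
* LayerNorm → flatten → linear head → 4 class scores.

Because the temporal and spatial stages are both linear with no
nonlinearity between them, the implementation applies W first and the
kernels second (identical algebra, ~8× cheaper); parameters keep the
(K, W) layout so interpretation reads them directly. Batch normalization is
omitted: inputs are already z-scored per channel and trial, and removing
it keeps the backward pass lean. The ELU between the conv stage and
pooling is essential — pooled zero-mean oscillations would otherwise carry
no band-power information.

Training: Adam (lr 1e-3), batch 16, cross-entropy, early stopping on
validation loss (patience 20, max 100 passes), best-validation weights
restored. All randomness (init, batch order, dropout) derives from one
seed via `SeedSequence`; identical seeds give bit-identical training logs.
Non-finite loss aborts with a diagnostic rather than continuing.

The defaults are a desk-scale configuration chosen so that one session
trains in tens of seconds on a single CPU; recovery experiments in the
tests use further reduced variants (8–16 filters, 1 attention layer) where
the scientific question does not need capacity.

## Steady-state spectral analysis

* **CSD**: spherical-spline surface Laplacian (stiffness 4, λ = 1e-5) via
  MNE, for spatial sharpening; units µV/m².
* **PSD**: Welch with a Blackman window, averaged over trials and over the
  channels of the named set (`ssmrp` = FC3, FCz, FC4, C3, Cz, C4, CP3,
  CPz, CP4; `ssvep` = Pz, O1, O2), reported in dB (10·log10, floored at
  −300 dB for zero-power bins).
* **SNR**: power at each bin divided by the mean power of the ±5
  neighboring bins (the bin itself excluded); the 5 edge bins per side are
  flagged undefined. SNR is computed on linear power and is scale
  invariant by construction.
* **Harmonic readout**: SNR at the nearest grid bin to each h·f0 (ties
  toward the lower frequency), with a flag marking the harmonic that
  attains the global SNR maximum in 1–8 Hz.

### Resolving 0.1-Hz harmonics from 5-s trials

A single 5-s MI window gives only 0.2-Hz resolution, which cannot place
2.1-Hz multiples on bins. `steady_state_psd` therefore concatenates all
trials' MI spans into one record and uses 10-s Welch segments (0.1-Hz
grid, 75% overlap). Segments that straddle trial boundaries see a random
relative phase of the steady-state response, which makes harmonic-bin
power fluctuate with the (arbitrary) concatenation order; the estimator
removes that artifact by averaging the linear PSD over 4 seeded
permutations of trial order. With 30 trials per condition this places the
global 1–8 Hz SNR maximum at the second harmonic (4.2 / 5.2 Hz for
medium / fast) in ≥95% of seeded repetitions; the pipeline's `spectral`
stage and the acceptance script both use this estimator.

## Interpretation

* **Kernel spectra**: |FFT| of each temporal kernel on a ≥256-point grid
  to fs/2 (time reversal does not change the magnitude); the filter-bank
  mean is smoothed with a Savitzky–Golay filter (window 5, order 3).
* **Spatial patterns**: columns of W⁻¹ (exact inverse when W is square
  and condition number < 1e6, Moore–Penrose pseudo-inverse otherwise, with
  a logged warning), displayed as column-normalized absolute values —
  the sign of an oscillatory source's pattern is not meaningful.
* **CAM**: gradient-weighted class activation mapping with the feature
  hook at the conv-module output tokens. Weights α_k are token-time means
  of ∂score/∂A_k; the map Σ_k α_k A_k is **not** rectified — negative
  values are read as ERD-like evidence and positive as ERS-like, so the
  usual ReLU of the cited recipe would destroy exactly the quantity of
  interest. Token values are mapped back to input time by
  nearest-receptive-field-center assignment (ties to the earlier token),
  averaged over the target class's trials, and binned into non-overlapping
  0.5-s bins. With the default [−1, 5] s window the 12 bins partition the
  samples evenly, so the binned mean equals the sample mean exactly.
* **CAT**: per channel, the mean over trials and time of (z-scored EEG ×
  class CAM), giving one signed topography per class.

## Numerical and degenerate-input choices

* Prediction ties break toward the lower class index (argmax convention).
* Zero-variance channels normalize to zeros rather than raising.
* Constant (spatially uniform) fields map to ~0 under CSD, as the
  Laplacian of a constant should.
* The EDF+ writer stores 16-bit samples with per-channel physical scaling;
  round trips are exact up to half a quantization step. Sessions that do
  not fill the last 1-s record are zero-padded, with the true sample count
  kept in the JSON sidecar.
* Sampling rate, durations and epoch windows must be sample-aligned;
  misaligned combinations are rejected rather than rounded.

## Problem sizes

Recovery experiments are sized for a single CPU: one simulated session
(105 trials), leave-one-run-out folds, three training seeds for
seed-averaged claims, 100-repetition Monte-Carlo for the spectral
recovery statements, and reduced decoder variants where capacity is not
the question. These sizes are the package's operating points; all of them
are config fields, so larger replications are one YAML edit away.

## Known limitations

* The synthetic data's class structure is far cleaner than real MI-EEG;
  accuracy numbers on it say nothing quantitative about human decoding.
* The spatial model (Gaussian bumps, independent channel noise) ignores
  volume conduction; CSD and spatial-pattern results on simulated data
  are therefore qualitatively, not physiologically, interpretable.
* CAM's temporal resolution is limited by the pooling stride (token
  spacing 60 ms) and the 0.5-s bins.
* The numpy decoder is desk-scale; it is not intended to scale to large
  EEG corpora or GPU training.
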