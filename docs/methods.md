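# Methods

This note documents the models, the synthetic data they are validated on, the
numerical choices, and the limits of what the tests demonstrate.

## Paradigm and data model

A session consists of runs of guided center-out motor-imagery trials, two
guidance conditions (VtG: visual + vibrotactile; noVtG: visual only) and two
movement directions (right, up). Defaults follow the full experimental design: three
40-trial runs per condition, 7.5 s trials sampled at 1 kHz from 61 EEG
channels on the 10/10 grid plus 3 EOG channels. Within a trial (times
relative to the cue-movement onset): alert at −5.5 s, fixation cross at −4 s,
stationary cue at −2 s, cue movement at 0 s, imagery until +2 s. The
classification baseline window is −3.5 to −2.5 s, the imagery window 0.5 to
1.5 s; analyses epoch −4 to +2 s (6 s). Inter-trial gaps are drawn uniformly
from 0.25–0.75 s by the seeded generator.

## Synthetic generator

The generator is a sum of parametrized components over gaussian scalp
topographies (electrode coordinates from mne's standard 10/05 montage):

- **Background**: spatially correlated pink noise — per-channel 1/f-amplitude
  noise mixed through the Cholesky factor of an exponential distance
  covariance (length scale 5 cm). Default scale 4 μV (chosen as a realistic
  residual band-limited EEG amplitude).
- **MRCP**: a C1-smooth raised-cosine negativity from −0.3 s to the end of
  the imagery period, peaking at 0.77 s. Direction-specific gain vectors
  (right: centered near C3, contralateral to the imagined hand; up: near
  FCz) and amplitudes (−1.8 / −1.4 μV). The condition contrast is a depth
  scale (VtG 0.45 of noVtG, calibrated so the grand-average peaks sit near
  −0.60 vs −1.83 μV) plus a spatial broadening of the VtG topography.
- **Rhythms and ERD**: continuous band-limited noise carriers (μ 8–12 Hz at
  3 μV, β 15–32 Hz at 1.5 μV) over a centro-parietal topography; during each
  imagery window the carrier is attenuated by the per-band, per-condition ERD
  depth (defaults: μ −2.25 dB VtG / −2.04 dB noVtG as calibrated
  grand-average peaks; β values are invented at two thirds of μ) with 0.25 s
  cosine ramps and a condition-specific spatial modulation weight (unit at
  the topography core, spatially broader under VtG). At the core channel the
  mid-window power ratio is exactly the configured depth, which is the
  generator's spectral contract (verified by Welch and by the Morlet map
  within ±1 dB).
- **Evoked potentials**: a Gabor-like biphasic deflection over an occipital
  topography at fixation onset, cue appearance and movement onset (1.5 / 3 /
  3 μV), identical across classes.
- **Ocular activity**: blink bumps (150 μV, 0.3 s) and smoothed saccade steps
  (60 μV, 0.4 s) on the three EOG channels with deliberately asymmetric
  gains (a perfectly mirrored L/R pair would make the EOG regression
  singular), bleeding into EEG through a fixed frontal-decay mixing matrix.
  Calibration runs schedule both types densely on an even jittered grid with
  type markers.

With all class- and window-dependent amplitudes at zero (`EffectSpec.null`)
the recording carries no decodable structure; this is the null condition used
for calibration testing.

What the generator does **not** emulate: biophysical forward modeling,
non-stationary drifts, electrode artifacts other than the injected
transients, inter-channel rhythm phase structure, or any behavioral
dependence. Passing tests therefore demonstrate the correctness and honesty
of the pipeline, not expected accuracy levels on real recordings.

## Preprocessing

Feature-specific zero-phase 4th-order Butterworth band-passes (0.2–5 Hz for
amplitude features, 1–40 Hz for spectral features), polyphase downsampling to
10 Hz and 200 Hz respectively, and 6 s epoching. Marker indices are rescaled
with round-half-away-from-zero (stated to make tests bit-stable). Trial
rejection runs on a separate 1–60 Hz path with three rules (defaults 200 μV,
z = 5): absolute amplitude; per-trial excess kurtosis averaged over channels,
z-scored across trials; and a joint-probability score — the per-trial mean
negative log-likelihood of samples under channel-wise histograms pooled
across trials (50 bins, Laplace-smoothed), z-scored across trials. The
statistics pool channels per trial before z-scoring; this is one of two
defensible readings and the estimators are plain functions that can be
swapped. Rejection only returns a mask; data are never modified.

Eye artifacts are attenuated by a linear subspace subtraction trained on the
calibration runs: multivariate regression of EEG on the three EOG channels
over marked artifact segments, applied as the projection I − B(EOG→EEG). The
regression is ridge-regularized (1e-3 of the mean EOG eigenvalue) because
blink and saccade time courses excite only part of the EOG space. A hook
accepts an externally computed channel-space cleaning projection (e.g., from
an ICA workflow); no ICA is implemented here. Common-average referencing and
the 31-channel frontocentral-to-parietal subset (rows FC/C/CP/P from 5 to 6
plus PO3/POz/PO4 — the exact membership is a package default, configurable)
complete the chain.

## Features

**Amplitude features**: raw 10 Hz channel amplitudes over the preceding 1 s
(10 lags × 31 channels = 310 features), strictly causal, one sample every
100 ms.

**Morlet map**: complex Morlet wavelets in 1 Hz steps from 1 to 40 Hz with
the gaussian FWHM anchored at 3 s for 1 Hz and scaling as 1/f (a constant
≈ 8 cycles). Wavelets are energy-normalized (white-noise power flat across
frequency), truncated at ±3 envelope SDs or half the epoch, zero-meaned, and
applied by FFT convolution; power is trial-averaged and expressed in dB
relative to the baseline-window mean per channel and frequency. The
implementation agrees with mne's Morlet transform to < 0.2 dB on
baseline-relative power where both are defined; it is implemented here
because 1 Hz wavelets at this FWHM are longer than a 6 s epoch, which mne's
transform rejects.

**CSP band power**: per-trial covariances over the fit window (0.5–1.5 s)
are trace-normalized before class averaging (standard practice; scale-free
trials). Filters are sorted by descending eigenvalue with the sign convention
"first nonzero coefficient positive". Power is the squared filtered sample
(not an analytic envelope — the 1 s smoother removes carrier ripple; the
choice is localized in one function), log-transformed (natural log
internally, dB only for display), referenced to the trial-set baseline mean
per feature, smoothed causally (expanding window over the first second), and
decimated to the 100 ms classification grid.

## Decoding

Binary sLDA with Ledoit–Wolf shrinkage toward νI (deterministic, no inner
CV), equal priors. Cross-validation is stratified k-fold over trials,
repeated; the default scheme is 5 × 5 at the full protocol size, and 4 × 2 at
the reduced size where four folds keep 12/12 class splits exactly balanced —
unbalanced stratified folds bias null accuracy measurably below 50% at small
n. **Supervised feature extraction is refit inside every training fold**:
CSP fit on all trials before CV leaks label information and reaches 100%
"accuracy" on pure noise; the builder mechanism in `decode` exists to make
that impossible. The per-feature baseline reference is a constant shift
shared by train and test and provably does not affect predictions.
MI-vs-baseline classification takes one causal feature vector per trial at
the right edge of each window (the 1 s window then spans exactly the imagery
or baseline interval); folds split trials so a trial's two samples stay
together. Peak extraction breaks ties toward the earliest time.

## Patterns and statistics

The activation pattern is evaluated literally as a = Σx(Σx+λI)⁻¹(μ₁−μ₂)·Var{s}
with the model's shrinkage coefficient and empirical Var{s}; at λ = 0 this is
the classical forward-model identity up to scale. Lag collapsing for display
is per-channel RMS by default (mean and max-abs available). The CSP channel
power difference back-projects the selected components through the
pseudo-inverse (relative cutoff 1e-12) and references both classes to the
pooled baseline power, making P antisymmetric under class swap and equal to
the direct channel power difference when all filters are selected.

The chance threshold uses the one-sided adjusted-Wald bound with
z = Φ⁻¹(1−α), α = 0.05 by default; an exact-binomial mode exists and serves
as the test oracle (the two agree within 2 percentage points for n ≥ 30).
Wilcoxon signed-rank drops zero differences, uses the exact distribution for
n ≤ 25 without ties and the tie-corrected normal approximation otherwise.
No correction across time points is applied by default (a deliberate
omission, matching common practice for threshold lines; the stats module is
the place to add one).

## Problem sizes and determinism

Generator defaults are the full protocol conditions (3 × 40 trials per
condition at 1 kHz). Simulation-driven validation runs at a reduced size
chosen as the package's calibration configuration: one run of 24 trials per
condition at 160 Hz, 4 × 2 CV, 200 ms classification grid
(`desk_scale_config`). Null calibration uses 20 seeds and checks each
analysis's mean accuracy against the exact binomial 95% band around 50%
(and threshold exceedances against a conservative run-level binomial bound,
since time points within a run are correlated). Effect recovery sweeps five
MRCP-separation levels (0–6 × the default amplitudes) and five ERD depths
(0 to −10 dB) × 10 seeds, requiring monotone level means (Spearman ρ > 0.9)
and a top level above threshold. All stochastic stages descend from a single
seed; equal configuration and seed give bit-identical recordings and
byte-identical reports.

## Known limitations

- MI-vs-baseline accuracies at the reduced size with grand-average-calibrated
  effects sit close to chance: a −2.25 dB ERD is a weak single-trial effect
  at 24 trials, and CSP overfits small training folds (honestly — the full
  fit reaches 100%). Recovery tests use deeper sweeps precisely to separate
  pipeline correctness from effect strength.
- The EOG model is a dense regression; the original sparse subspace
  formulation is intentionally not reproduced (same train/apply contract).
- The 31-channel subset and the pattern display windows are conventions, not
  identifiable from the analysis itself; both are configuration.
- Condition effects (VtG vs noVtG) are injected as depth offsets and spatial
  broadening with free magnitudes; nothing calibrates them to a quantitative
  reference, so condition-analysis accuracies are qualitative only.
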