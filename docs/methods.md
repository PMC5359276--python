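# Methods notes

This note records the models behind `hybridnf`, the parameters that matter,
and the design choices made where several defensible options existed.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal models

### EEG

Clean EEG is broadband Gaussian noise (`noise_sd_eeg`, default 1 µV RMS per
channel) plus two sinusoidal oscillators at **9.7 Hz and 21.4 Hz**
(`osc_amp`, default 2 µV) on two "motor" channels (C3, C4).  During Task the
oscillator amplitude is scaled by 1 − `erd_depth`·s, where s ∈ [0, 1] is the
subject's regulation state — an event-related desynchronization (ERD) model.
The oscillator frequencies are deliberately non-integer: an integer-Hz tone
at a 250 Hz rate is exactly periodic in both a 2 s TR and a 1 s heartbeat
interval, so sliding artifact templates would coherently absorb it and
"remove" real signal.  The chosen frequencies are incommensurate with both
epoch grids, which is also the realistic situation (physiological rhythms
are not locked to the scanner).

The **gradient artifact** is one fixed band-limited pseudo-random waveform
repeated identically every TR and scaled so its RMS is `artifact_gain`
(default 100) times the RMS of the rest-state clean model.  Scaling against
the rest state rather than the realized (task-modulated) signal keeps
incremental generation causal and the ratio exactly reproducible.  The
**BCG artifact** is a 0.3 s damped sinusoid (7 Hz carrier, 0.12 s decay)
placed at each R peak with per-channel random weights around `bcg_amp`
(default 5 µV).  An ECG channel with monophasic ~800 µV R waves is appended;
a monophasic (Gaussian) R wave was chosen because a biphasic one has an
envelope null at the apex, which makes sub-sample peak alignment ambiguous.
The contaminated signal is *exactly* clean + gradient + BCG, so suppression
is measurable to machine precision.

The default heart rate is **66 bpm with zero jitter**.  60 bpm at TR = 2 s
makes every heartbeat TR-locked, in which case the gradient template absorbs
the whole BCG (and the ECG's QRS): a degenerate, unrealistically easy/hard
corner that the default avoids.  Both 60 and 66 bpm are exercised in tests.

### BOLD

Voxel time course = baseline (default 100) + β·(HRF ⊛ effective design) +
drift·k + Gaussian noise, where the effective design is the Task boxcar
multiplied by the subject state during each volume, and the HRF is the
canonical double-gamma (shape parameters 6 and 16, undershoot ratio 1/6)
normalized to unit peak and sampled on the TR grid.  A 3×3×1 voxel block in
a middle slice is active (β = `bold_beta`, default 1); the top slice never
carries task signal and serves as the background region.  The default grid
is 12×12×6 voxels at 2×2×4 mm — a deliberately scaled-down EPI matrix chosen
so a full session (calibration + feedback run) simulates in roughly a
second; all sizes scale up through `SimConfig`.

### Subject

The fast regulation state follows first-order dynamics: during Task it
relaxes toward 1 with rate (1 + gain·max(feedback, 0))/τ_task (τ_task = 6 s);
during Rest it decays with τ_rest = 4 s.  A slow **skill** term accumulates
at `learning_rate`·gain·feedback per second during Task, does not decay, and
adds to the effective regulation during Task only (capped at 0.6).  This
split is what makes the closed loop exhibit *across-block* learning when
gain > 0 while remaining exactly block-periodic at gain 0: the fast state
fully resets during a 20 s Rest block (e⁻⁵ carry-over), so any cross-block
trend is attributable to feedback, which is the property the learning tests
rely on.

## Pipeline choices

- **AAS template**: plain unweighted sliding mean; gradient buffer 10 TRs,
  BCG buffer 15 pulse intervals (inside the conventional 5–15 / 10–20
  ranges).  Warm-up: the very first epoch passes through unmodified and is
  flagged; later epochs are corrected with the partial mean.  No sub-sample
  realignment is performed — the synthetic artifact is phase-locked by
  construction, and replayed real data accepts this limitation.
- **Calibration windows start after the first TR.**  The flagged raw first
  epoch otherwise leaks ~100× artifact into whichever class owns the first
  block and corrupts CSP training; the online R-peak detector likewise
  ignores the first TR.
- **R-peak detection**: 5–15 Hz band-pass, rectified, thresholded at
  max(4×MAD scale, 0.4×median per-second envelope maximum) with a 0.3 s
  refractory period; the first threshold crossing of a burst is snapped to
  the envelope apex within 80 ms.  The amplitude-aware term keeps filter
  ringing side lobes subthreshold; the median-of-block-maxima statistic is
  robust to the uncorrected first TR.
- **CSP**: generalized eigenproblem of trace-normalized class-mean
  covariances; 3 filter pairs by default; eigenvalue ties break by index and
  filter signs are fixed by the largest coefficient.  The *feedback feature*
  uses only one eigenvalue end: CSP eigenvalues rank relative variance,
  but the feature is absolute log variance, so calibration picks the end
  with the larger absolute Task–Rest contrast on the calibration windows
  (under ERD this is the Task-variance-minimizing end) and records the
  contrast sign.
- **EEG feedback is a rest-referenced z-score** of the feature rather than
  a ratio-APSC (a ratio of log powers is scale-free nonsense) and both the
  rest mean and sd are replaced at every Rest-block end.  Self-calibrating
  the scale online absorbs the small systematic offset between offline
  calibration cleaning and the online cleaner; the display target is z = 2.
- **fMRI feedback** is the background-subtracted ROI mean referenced to its
  running Rest baseline and normalized against the calibration task
  response.  Linear (batch and causal) and EMA detrending are provided and
  tested, but the default loop relies on per-block baseline replacement to
  track drift — with 20 s blocks the baseline resets faster than scanner
  drift accumulates.
- **Rest-baseline lag**: features from the first 2 s (EEG) / 6 s (fMRI) of
  a Rest block are excluded from baseline updates, because ERD recovery and
  the hemodynamic tail of the preceding Task block would bias the reference
  toward the task state.
- **GLM design**: intercept + centered linear drift + HRF-convolved boxcar;
  t maps convert to z through the t CDF; activation clustering uses
  6-connectivity, threshold z > 3, minimum cluster 4 voxels (scaled to the
  small grid); ties between equal-peak clusters break by size, then lowest
  linear voxel index.  A near-singular XᵀX falls back to a tiny ridge with
  a log message, or names the collinear columns when the fallback is
  disabled.
- **Scheduler on a virtual clock**: all timing invariants (tick lattice,
  transition/tick coincidence, causality horizons) are exact and testable,
  instead of statistical claims about wall-clock threads.  Processing
  latencies are constant configurable delays (EEG path 200 ms, fMRI path
  150 ms, display 80 ms, marker 39 ms); every feedback sample only sees
  data time-stamped at least one latency before its tick.  Flexible task
  blocks end at the first update tick at which the normalized feedback
  reaches the target (with the minimum duration respected).  Desync
  tolerance defaults to 10 % of the TR; one re-synchronization attempt is
  made before the session aborts and flushes its logs.
- **File formats**: BrainVision is written as IEEE float32, multiplexed,
  with 1-based marker positions (the only place that convention exists);
  data is therefore exact for float32-representable values.  NIfTI-1 stores
  the TR in pixdim[4].  All writes are atomic (temp file + rename).

## What the generator does and does not emulate

It emulates: TR-locked gradient artifacts at realistic amplitude ratios,
heartbeat-locked BCG with rate jitter, ERD band-power modulation, HRF
dynamics, scanner drift, background/global signal structure, acquisition
timing (TTL markers, update lattices) and a learning subject.

It does **not** emulate: realistic scalp topographies or volume conduction,
respiration/ventilation artifacts, head motion (the motion/slice-time hooks
are pass-throughs), non-stationary artifact shapes within a session,
multi-subject variability, or spatially correlated BOLD noise.  Passing
tests therefore demonstrate algorithmic correctness under the stated model,
not clinical performance on real recordings.

## Problem sizes

Defaults were chosen so the complete test suite runs in well under a minute:
8 EEG channels + ECG at 250 Hz, 40–82 volumes per session, 12×12×6 voxel
grids, 10 seeds for stochastic claims, 20 seeds for estimator bias checks.
All of these are configuration values, not architectural limits.
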