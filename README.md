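# hybridnf

A desk-scale, fully synthetic, closed-loop **hybrid EEG–fMRI neurofeedback
platform**.  It simulates simultaneous EEG and BOLD acquisition inside an MR
scanner, performs real-time artifact correction and feature extraction for
both modalities, estimates unimodal or bimodal feedback values, and drives a
two-layer synchronization/protocol engine on a virtual clock — so every stage
of a hybrid neurofeedback pipeline can be developed and tested without
hardware, subjects, or recorded data.

It is aimed at researchers building or studying real-time EEG–fMRI systems:
every processing stage is an ordinary library function with known ground
truth behind it.

## What it computes

**EEG path.** Scanner gradient artifacts (amplitude ~100× clean EEG,
near-identical within each TR) and ballistocardiogram (BCG) artifacts
(heartbeat-locked electrode motion) are removed by *average artifact
subtraction*: the mean of the last N equally shaped epochs — 5–15 TRs for the
gradient, 10–20 pulse intervals for the BCG — is subtracted from each
incoming epoch, with R peaks detected on a dedicated ECG channel.  The
cleaned signal is band-passed to 8–30 Hz, projected through **common spatial
patterns** (CSP) filters trained on 2 s windows with 95 % overlap, and
summarized as log band power

&nbsp;&nbsp;&nbsp;&nbsp;*f* = mean over components of log var(*w*ᵀ*x*).

**fMRI path.** Volumes are Gaussian-smoothed, reduced to a region-of-interest
(ROI) mean with a top-slice background control region, and modelled with an
**incremental GLM**: only the sufficient statistics (XᵀX, Xᵀy, yᵀy, n) are
kept, so each new scan costs O(p²) and the estimates at any scan count equal
a batch least-squares fit,

&nbsp;&nbsp;&nbsp;&nbsp;β̂ = (XᵀX)⁻¹Xᵀy, σ̂² = (yᵀy − β̂ᵀXᵀy)/(n − p),
t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c).

Calibration converts the t map to z, thresholds it, and keeps the 6-connected
cluster with the highest peak as the feedback ROI.

**Feedback.** Each feature is referenced to its Rest baseline — average
percent signal change 100·(x−b)/|b| for BOLD, a rest-referenced z-score for
log-power EEG — normalized to [0, 1] against a calibration target, and
combined as a 2-vector [EEG, fMRI] or a scalar (mean/weighted).  Baselines
are replaced with the just-finished Rest block's mean at every Rest-block
end.  Display mappings (sun radius/brightness, bar height, 2-D disk) are pure
geometry.

**Synchronization.** The first TTL pulse anchors time zero; feedback is
emitted on the update-tick lattice t₀ + BEGIN + k·Δ (Δ = 0.5 s by default),
and block transitions are constrained to land exactly on update ticks (fixed
durations must be multiples of Δ; flexible task blocks snap to the first tick
after the target is reached).  Marker cross-checks detect TTL jitter, missed
pulses and clock drift; one re-synchronization is attempted before a session
aborts with its logs flushed.

A feedback-responsive subject model (fast regulation state + slow learning
term driven by positive feedback) closes the loop, so learning-curve
experiments run end-to-end in seconds.

## Worked example

```bash
cat > proto.yaml <<EOF
update_period: 0.5
repetitions: 4
blocks:
- {kind: BEGIN, duration: 4.0}
- {kind: REST, duration: 20.0}
- {kind: TASK, duration: 20.0}
EOF
hybridnf run --protocol proto.yaml --seed 3 --gain 0.5 --out session
```

prints

```
emitted 320 NFB samples; task-block mean feedback: 0.818, 0.835, 0.835, 0.848
```

— one feedback sample per 0.5 s update tick over the 164 s session, and the
mean normalized bimodal feedback of each of the four Task blocks.  The rising
sequence is the closed loop at work: with feedback gain 0.5 the subject
model's learning term accumulates, deepening the simulated 8–30 Hz
desynchronization and BOLD response block after block (at `--gain 0` the
means stay flat).  `session/nfb_log.csv` holds the tidy per-tick log
(time_s, block, modality, raw, baseline, normalized, combined) and
`session/events.tsv` the deterministic event log:

```
tick  time_s    event       detail
-1    0.000000  SESSION_START  t0=0.000000
0     4.000000  NFB_UPDATE  [0.000000]
...
```

Other subcommands: `hybridnf simulate` (write a ground-truthed BrainVision +
NIfTI recording), `hybridnf eeg-clean`, `hybridnf csp-train`,
`hybridnf fmri-calibrate`, `hybridnf replay`.

## Layout

```
src/hybridnf/
  synthetic.py    ground-truthed bimodal signal generator + subject model
  eeg.py          R peaks, template subtraction, band-pass, CSP, features
  fmri.py         smoothing, ROI, detrending, incremental GLM, activation map
  nfb.py          APSC, z-score, baselines, bimodal combination
  sync.py         two-layer scheduler, desync detection and recovery
  loop.py         calibration session + closed-loop runner
  presentation.py feedback-to-display geometry
  io_formats.py   BrainVision, NIfTI-1, YAML config, TSV/CSV logs
  cli.py          the `hybridnf` command
docs/methods.md   model and design notes
```
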