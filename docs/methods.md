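# Methods

`mesocage` re-implements, hardware-free, the software of a self-initiated
home-cage head-fixation rig for mesoscale widefield GCaMP imaging of mouse
cortex: the task controller that runs the cage, the image-processing chain
that turns raw fluorescence movies into ΔF/F₀ connectivity and
evoked-response maps, the behavioral analytics, and a synthetic-cortex
generator that stands in for animal data. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## The cage task model

A cage houses up to five RFID-tagged mice sharing one fixation tube.
The controller is a five-phase state machine (`idle`, `mouse_in_tube`,
`contact`, `fixed`, `releasing`) driven by sensor events (RFID entry/exit,
head-bar plate contact, power loss).

Reward economics (all volumes in µl, durations in s):

| parameter | default | meaning |
|---|---|---|
| `entrance_reward_ul` | 6.5 | drop for tube entry (hardware dispenses ~5–8) |
| `fix_reward_multiplier` | 30 | fixation-trial total ÷ entrance drop (deployed up to 30×) |
| `entrance_reward_cap` | 100 | entrance rewards per mouse per light-cycle day |
| `fix_probability` | 0.65 | chance a plate contact engages the solenoids |
| `trial_duration_s` | 30 | fixation trial length (configurable ≥156) |
| `reward_interval_s` / `valve_open_ms` | 10 / 400 | in-trial reward schedule |
| `stim_trial_fraction` | 0.65 | fraction of fixed trials carrying flashes |
| `flash_interval_s` | 5 | flash spacing; first flash 2 s after fixation |
| `lights_on_hour` | 7 | anchors diurnal bins and the reward-cap day boundary |

Choices that were open:

- **Per-trial water accounting.** The fixation-trial total
  (`entrance_reward_ul × fix_reward_multiplier`) is split equally over the
  scheduled in-trial rewards (0/10/20 s in a 30 s trial). A contact that
  does *not* engage fixation still dispenses the full trial value as one
  event, so probabilistic fixation is never punitive. Water conservation
  (`Σ event volumes = entrances×drop + (fix trials + contact rewards)×trial
  total`) is asserted per simulated colony.
- **Entrance-reward cap of 100/day.** The deployed software allowed
  100–500; 100 drops of 6.5 µl ≈ 0.65 ml, i.e. 50–75 % of the 1 ml minimum
  daily intake, which is the operating point the rig's designers describe.
- **Day boundary at lights-on (07:00), not midnight**, because every
  diurnal analysis is phrased in the light cycle.
- **Release latency is 0 s**; solenoid heating, habituation dummies and
  spout staging are configuration-documented but not simulated. A
  power-loss input releases the mouse immediately from any state
  (spring-driven release) and cancels all scheduled trial events.
- **First flash offset 2 s.** Only the 5 s spacing is fixed by the task;
  2 s lets 20 flashes fit a 97 s trial exactly.

The **virtual colony** replaces live mice with fixed-propensity agents
(mean entries/day, contact probability, nocturnal bias as a night/day rate
ratio, mean dwell). Entries are a diurnally modulated Poisson process
(thinning); tube occupancy is exclusive, so a colliding agent retries
after the occupant leaves. Every visit is driven through the same state
machine the real cage would use, which makes the log invariants (entry/
exit alternation, fix pairing, caps, conservation) hold by construction
and testable. Agents do not learn; training dynamics are out of scope.

## The synthetic cortex

No public recordings exist for this rig, so the imaging chain is
validated on generated movies in which every recoverable quantity is
injected and known. Per pixel and frame:

    F(x,t) = B(x) · bleach(t) · m(t) · (1 + g(t) + s_r(t) + e_r(t)) + n(x,t)

- `B`: baseline image — 10 000 counts inside the transcranial window,
  2 000 outside, 6 000 in the correction-ROI patch (16-bit headroom).
- `bleach`: single exponential, τ = 600 s (negligible within a 30 s
  trial; any residual is removed by the 0.3 Hz high-pass).
- `m`: multiplicative focus/motion artifact shared by the whole frame
  (off by default; used to validate the correction-ROI division).
- `g`: global component over the window, band-limited 0.3–3 Hz Gaussian,
  SD 0.01 ΔF/F₀ — the shared hemodynamic/illumination signal that global
  regression must remove.
- `s_r`: the latent trace of the region containing the pixel. Fourteen
  disk regions (V1, BC, HL, M1, M2, RS, AC per hemisphere, radius 0.5 mm)
  at schematic bregma-relative coordinates; latents are band-limited to
  the analysis band (so filtering cannot destroy ground truth), unit
  variance scaled to SD 0.02 ΔF/F₀, and correlated to target values by a
  Cholesky mixing of independent sources (`x = L·s` with `L·Lᵀ` the
  target correlation matrix) — expected pairwise Pearson r equals the
  target exactly. Homotopic pairs default to r = 0.8; other pairs to 0.
- `e_r`: evoked transients — the indicator impulse response
  `exp(−t/decay)` convolved with a boxcar burst lasting `latency`
  (default 0.5 s to peak, 1 s decay): fluorescence ramps while the burst
  lasts, peaks with a genuine kink at burst offset, then decays. A
  near-flat-topped kernel would make "time-to-peak" unidentifiable at
  realistic noise; measured GCaMP transients are kinked, not flat.
- `n`: white sensor noise, SD 50 counts (0.5 % of the window baseline).
- Motion: per-frame integer-pixel rigid translation (the rig drifts about
  one pixel between sessions; rotation is blocked by the tapered bar
  track). A settling helper puts random shifts of up to ±3 px in the
  first 1 s of a trial, emulating mechanical settling after solenoid
  engagement.

The GFP control zeroes `s` and `e` but keeps `g`, motion, bleach and
noise — the indicator-free animal.

What the generator does **not** emulate: optics (PSF, depth of field),
hemodynamic spectra, vascular structure, cellular resolution, sub-pixel
motion, and history-dependent behaviour. Recovery tests on these movies
therefore demonstrate the *algorithms* are correct and unbiased under the
stated statistical structure — not that the defaults match any particular
animal's noise budget.

## The processing chain

Order is fixed and recorded in provenance flags:

    align → discard settling → [correction-ROI division, raw domain]
          → ΔF/F₀ → band-pass 0.3–3 Hz → global-signal regression

- **Alignment**: one integer-pixel translation per 30 s session (within-
  session alignment is unnecessary once settling frames are discarded),
  estimated by zero-mean normalized cross-correlation — a direct
  argmax over ±10 px and an FFT route that must agree exactly (both are
  kept as mutual checks). Reference = mean frame of the first session.
  Edges exposed by the translation are replicate-padded and flagged
  invalid for all downstream statistics.
- **Settling discard**: first 1.0 s of each trial (the rig's observed
  settling window spans 0.3–3 s; configurable).
- **Correction-ROI division** (optional, raw domain — the artifact is
  multiplicative on measured intensity): divide each frame by the
  unit-mean trace of an off-window ROI (dental cement / fluorescent
  paint). Guarded twice: (a) the ROI trace SD must exceed 3× a robust
  frame-to-frame noise estimate (1.4826·MAD of first differences /√2),
  otherwise there is nothing to correct; (b) the division must reduce
  temporal RMS outside the window, otherwise it is rejected. The guard
  threshold is a package choice, stated and testable.
- **ΔF/F₀**: per-pixel `(F − F₀)/F₀`; `F₀` = trial mean by default
  (percentile alternative available). Non-positive `F₀` at a valid pixel
  is an error reporting the pixel count.
- **Band-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`) — zero phase so latencies are undistorted. Measured
  gain ≈ 0.99 at 1 Hz, < 10⁻⁶ at 0.05 Hz, DC removed exactly.
- **Global-signal regression**: per-pixel OLS of the trace on the
  window-mean trace with intercept, keeping the residual (a plain
  subtraction mode exists). After regression the window mean of every
  frame is zero to numerical precision, and the operation is idempotent
  (a numerically zero-variance global trace is skipped with a warning —
  this guard is what makes the second application a no-op).

**Evoked responses are measured on ΔF/F₀ *without* the band-pass.** The
zero-phase 0.3 Hz high-pass attenuates the peak of a 0.5 s-latency/1 s-
decay transient to ~0.6 of its value — a ~40 % amplitude bias. Slow
drift is handled instead by per-event baseline subtraction (mean of the
1 s immediately pre-event); global regression stays on. The band-pass
remains the default for correlation analyses, where amplitudes do not
matter but band-limiting does.

## Maps and statistics

- **Seed-pixel correlation maps**: zero-lag Pearson r of every valid
  pixel against one seed trace, over ≥900 frames (one 30 s trial) and
  typically nine concatenated trials (8 100 frames). Seeds can be placed
  in bregma-relative mm via the pixel pitch (fov·1000/frame_px ≈ 42 µm on
  the deployed 10.75 mm / 256 px rig).
- **Region matrices**: Pearson r between ROI-mean traces; symmetric,
  unit diagonal.
- **Composite thresholded maps**: per-seed masks `r ≥ threshold`
  rendered together; connected components ≥ `min_area` px are reported
  as islands with centroids, flagged `remote` when they do not contain
  the seed. The threshold is a required explicit parameter (no deployed
  value exists to default to).
- **Evoked averages**: event-locked mean ± SEM (SD/√n over events),
  baseline-subtracted; `peak_amp` = max of the post-event mean trace (in
  %), `peak_latency_s` its time. The p-value is a paired t-test of
  per-event post-window maxima against maxima of a pre-event window of
  the *same length*: maxima of unequal-length windows have different
  null distributions, and the matched design is what keeps the type-I
  rate at nominal level on indicator-free controls (measured ≤2 % at
  p<0.01 over 100 seeded nulls). Events without full window support are
  dropped with a warning and counted; a single event yields no SEM/p.
- **Concatenation** records session boundaries; zero-lag correlations
  are unaffected by boundaries, and a flag exists for lagged analyses to
  exclude cross-boundary pairs.

### Effective degrees of freedom

Band-limited traces are not independent samples: a 0.3–3 Hz signal
sampled at 30 Hz carries roughly `2·BW ≈ 5.4` independent samples per
second, so a 900-frame (30 s) correlation has ~160 effective samples and
a null r SD of ~0.08 — an order larger than the naïve `1/√900`. This is
why connectivity maps are made from concatenated trials: at 8 100 frames
the homotopic r = 0.8 target is recovered with median absolute error
≈ 0.02 (20 seeds), and GFP-control maps stay below |r| = 0.2 everywhere
off-seed from ~90 s of data. Per-pixel sensor noise additionally
attenuates seed-map r by the factor
`√(σ²_sig/(σ²_sig+σ²_noise))` per side (~2 % under the default
conditions after band-passing), a small negative bias visible in the
recovery numbers.

## Numerical conventions

- Pixel coordinates are 0-based `(row, col)`; anterior is the −row
  direction; bregma-relative positions are in mm converted via the pixel
  pitch. Timestamps are float seconds from session start, with an
  optional ISO wall-clock anchor; the session's start hour-of-day feeds
  diurnal binning.
- Display rates round halves away from zero at 1 decimal; internal
  computation keeps full precision. Cohort SDs use the sample (n−1)
  convention, and cohort means are means of per-mouse rates — both
  verified to reproduce the printed cohort summaries, which the
  population-SD convention does not.
- The unpaired trial-length interval comparison defaults to Student's
  equal-variance t-test (Welch by flag); two identical samples return
  p = 1 rather than NaN.
- Reproducibility: every stochastic component (generator, colony,
  schedulers) takes an explicit seed and is bit-identical across runs for
  the same inputs.

## Problem sizes in the shipped tests

Unit and acceptance tests run on 64-px frames (32 px for the type-I
null battery) — the pixel pitch scales with the field of view, and no
algorithm depends on the absolute frame size. The acceptance battery
uses the study-scale sizes: 100 registration fixtures at shifts ≤10 px,
recovery at 900 and 20×8 100 frames, evoked recovery at n = 60 events,
100 seeded null controls, 10⁴ contact draws, and an 8-day five-agent
colony.

## Known limitations

- Integer-pixel registration only; sub-pixel motion and rotation are out
  of scope (and below the rig's reported stability).
- The correction-ROI guard thresholds are package choices; on real data
  the ROI's brightness (fluorescent paint) determines their headroom.
- The virtual colony's agents have stationary propensities; training
  curves, social interaction and aggression are not modelled, so
  simulated inter-fix intervals reflect the configured rates, not learned
  behaviour.
- H264-compressed video is not read (lossy, decoder-heavy); raw RGB24 and
  TIFF cover the analysis path.
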