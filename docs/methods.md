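# Methods

## Scope and data model

`swacomp` analyzes one referenced EEG channel at a time (µV, uniform
sampling; EDF input) together with a fixed-epoch hypnogram over
{W, N1, N2, N3, REM, UNSCORABLE}. All event detection is restricted to
N2+N3 epochs; unknown stage tokens become UNSCORABLE and are excluded. The
pairing contract (hypnogram duration within one epoch of the recording) is
enforced at pairing time, not at file-read time, so either file can be
loaded and inspected independently.

## Preprocessing

* **Detrend.** The local linear trend seen by a *centered* 3-s sliding
  window is subtracted (order-1 Savitzky–Golay smooth; in the interior this
  equals removal of the centered 3-s moving average, at the edges the
  fitted line is extrapolated exactly). A centered window is essential:
  subtracting independent per-window line fits distorts a 1 Hz oscillation
  by roughly a quarter of its RMS, because a finite stretch of a sine has a
  genuinely nonzero least-squares slope, and each window then removes a
  real line and leaves seams. The centered form removes constants and
  ramps exactly and passes in-band oscillations essentially unchanged
  (< 1 % RMS at 1 Hz); `window_s` defaults to 3.0 s.
* **Gross artifacts.** Any sample whose detrended magnitude strictly
  exceeds 900 µV marks its whole 3-s window as excluded. Exclusions are
  combined with the hypnogram so that a sample is analyzable iff it is
  outside artifact windows and inside a kept stage. Masked samples never
  enter any percentile or SD estimate downstream.
* **Filters.** Slow band: 6th-order Butterworth 0.16–4 Hz; spindle bands:
  3rd-order Butterworth 10–13.5 Hz (late-fast) and 14.5–18 Hz (early-fast),
  all zero-phase (forward–backward) in second-order sections. 13.5–14.5 Hz
  lies outside both passbands by design: the two spindle subtypes share
  frequency content near 14 Hz and events there are not classifiable. The
  forward–backward pass uses reflective padding of 3 / f_lo seconds; the
  scipy default pad of a few filter lengths is orders of magnitude too
  short for a 0.16 Hz band edge and leaves a visible slow drift.
  One published figure caption gives the early-fast band as 14–18 Hz while
  the methods text of the same report gives 14.5–18 Hz; the band is
  configurable, and 14.5–18 Hz is the default.

## Slow-wave detection

Candidates are trough-first half-wave pairs: three consecutive zero
crossings of the slow-filtered signal (negative-going, positive-going,
negative-going) delimit a negative then a positive half-wave. The
full-wave duration must lie in [0.25, 2.5] s, i.e. 0.4–4 Hz; the band is
exposed as `sw.min_dur_s` / `sw.max_dur_s` because "approximately 0.4–4 Hz"
could also be read per half-wave. Candidates overlapping an excluded range
are dropped; a trailing incomplete half-wave never forms a candidate.

Selection happens in three fixed steps: (1) remove candidates whose trough
or peak magnitude exceeds 200 µV; (2) remove candidates whose trough or
peak lies more than 4 SD from the respective candidate-population mean
(mean/SD computed once over the night, separately for troughs and peaks,
no re-iteration); (3) keep candidates whose |trough| and peak are both at
or above the population medians ("top 50 %"). The median boundary is
inclusive, so ties survive and slightly more than half can be retained.
The top-50 % rule is computed per recording-channel over all N2+N3
candidates jointly; stages are only split afterwards, in the analysis.
Each retained wave is stamped with the stage of the epoch containing its
*trough* (all downstream timing is trough-locked). Selection is rank-based
and therefore invariant under a global amplitude rescaling that keeps all
waves inside the ceiling.

## Spindle detection

Per band: band-pass → upper envelope (analytic-signal magnitude) →
threshold = 75th percentile (linear-interpolation definition) of the
0.5-s moving RMS of the envelope over analyzable samples → contiguous
supra-threshold stretches of the envelope, with sub-threshold gaps shorter
than 0.1 s bridged (envelope ripple otherwise splits single bursts) →
duration gate 0.5–3.0 s → artifact gate: peak-to-trough range of the
band-passed signal within the event must not exceed 40 µV → outlier gate:
events whose peak envelope deviates more than 8 SD from the event
population mean are dropped. Events are stamped with the stage of their
onset epoch.

Two readings were genuinely open and are configurable, with these
defaults: the percentile threshold is *computed on* the moving-RMS trace
and *applied to* the envelope (`spindle.rms_window_s` = 0.5 s, the minimum
event length); and the 8-SD rule uses the *peak* envelope per event. An
important property of the percentile threshold is that it is relative: it
only separates bursts from background when spindles occupy somewhat less
than a quarter of analyzable time. That is the regime of real NREM sleep
(roughly ten spindles per minute of NREM, ~1 s each) and of the synthetic
generator's defaults; on inputs with almost no spindle activity the
threshold degenerates to the noise floor and short noise runs become
events.

## Coupling classification

A slow wave is coupled when at least one spindle's reference time falls in
[trough + 0.2 s, trough + 1.5 s]. The reference time is the spindle
*onset* by default (the 0.2 s buffer exists to exclude slow-spindle
activity immediately before the trough, which is an onset-timing
argument); an envelope-peak reference is config-switchable. Slow waves are
processed in trough order; each spindle can be claimed once (earliest
trough wins); a wave whose window contains unclaimed spindles of *both*
bands is left unclassified rather than double-counted. Consequently
coupled-LF + coupled-EF + unclassified always partitions the slow-wave
count, and the ambiguity rule structurally protects subtype accuracy: a
wrong-band capture requires the correct-band spindle to be absent from the
window while a wrong-band one is present.

## Time–frequency analysis

Troughs are centered in 5-s segments of the detrended, otherwise
unfiltered signal; each segment's baseline is the 5-s interval immediately
preceding it, discarded if it contains any detected slow-wave trough or
starts before the recording. An 8-cycle Morlet transform is evaluated at
4–20 Hz in 0.25 Hz steps (65 rows) as amplitude, not power. The mean
event map is divided per frequency by the baseline mean over time and
events; the normalization is therefore invariant to global amplitude
rescaling. ROI power is the mean normalized amplitude over a frequency ×
trough-relative-time rectangle with inclusive bounds. The default ROIs —
each spindle band crossed with the 0.2–1.5 s coupling window — are
placeholders mirroring the detection geometry; replication against
previously published ROI magnitudes must set the rectangles in config.
At high slow-wave densities most baseline candidates contain a trough, so
only a minority survive; the per-frequency baseline mean pools whatever
survives across events.

## Composition summaries

Two time axes are used and never mixed. Wall-clock histograms tile the
recording with 2-min left-closed right-open bins anchored at t = 0; an
event belongs to the bin containing its slow-wave trough. The ≥ 80 %
analysis concatenates the night's N2+N3 epochs into a normalized NREM axis
split into exactly 100 equal bins. In both, a bin with no coupled events
has an *undefined* (not 0 %) late-fast percentage, rendered as a gap and
never counted against a composition threshold; bins at exactly the
threshold are counted ("80 % or more").

## Statistics

* **Weighted Welch t-test** with frequency-weight semantics: weights are
  rescaled to sum to each group's n, so the weighted test with equal
  weights reduces exactly to the unweighted Welch test, and results are
  invariant to rescaling all weights in a group. (Whether the original
  analyses used frequency or precision weights is not documented;
  frequency semantics is the default.)
* **Negative-binomial GEE** for clustered counts: log link, exchangeable
  working correlation, robust (sandwich) standard errors; the NB dispersion
  is estimated once by method of moments (Var = µ + αµ²) and held fixed.
  The condition ratio is exp(coefficient); percent differences quoted from
  count models are 100·(ratio − 1). The working-correlation choice is a
  default to be reported with results, not a claim about the original
  software.
* **Repeated-measures ROI contrast**: paired within-subject differences
  with subject as the repeated factor, reported as a raw difference plus a
  percent-of-paired-mean parameterization.
* No multiple-testing correction is applied; every comparison is reported
  at face value. Degenerate zero-variance inputs return the exact estimate
  with p = 0 (p = 1 if the estimate is 0) and a logged warning instead of
  raising, so toy fixtures keep pipelines running.
* Null calibration: with ~100 clusters the NB-GEE rejection rate at
  α = 0.05 sits near 0.05–0.06; sandwich variance estimates are known to be
  mildly liberal at small cluster counts, so calibration checks use cluster
  numbers in the asymptotic regime.

## Synthetic polysomnography

The generator emulates the statistical structure the detectors consume:

* **Hypnogram**: a wake onset (~5 % of the night), then `n_nrem_cycles`
  cycles of N1→N2→N3→N2→REM with seeded ±15 % jitter on segment lengths.
* **Background**: 1/f^β Gaussian noise by FFT spectral shaping (β = 1,
  broadband RMS 15 µV).
* **Slow oscillations**: one-cycle biphasic waveforms (negative then
  positive half-sine; full-wave duration 0.8–1.6 s, trough depth
  80 ± 10 µV, peak 45–60 % of trough depth) placed sequentially with
  exponential gaps within N2/N3 runs at stage-dependent rates, default
  N3 = 33/min and N2 = 22/min. These densities follow the method's own
  accounting: slow-band NREM EEG is near-continuous oscillation, and
  zero-crossing detectors of this family select thousands of waves per
  night (~24 selected ≈ 48 candidate pairs per NREM minute), so sparse
  "textbook" slow-oscillation rates would not reproduce the regime the
  selection rules operate in.
* **Spindles**: Gaussian-phase sinusoids at 12 Hz (late-fast) or 16 Hz
  (early-fast) under a tapered-cosine envelope (quarter-duration ramps with
  a sustained core — spindles wax and wane but hold power mid-burst),
  duration 0.8–2.0 s, envelope peak 9–16 µV so the peak-to-peak range stays
  below the 40 µV artifact ceiling even with noise on top. A burst is
  attached to each slow wave with stage- and subtype-dependent probability
  (N3: LF 0.45 / EF 0.20; N2: LF 0.25 / EF 0.35) at a lag drawn uniformly
  from [0.25, 1.4] s — strictly inside the detector's [0.2, 1.5] s window
  so boundary effects cannot confound recovery tests — plus uncoupled
  bursts at 3/min per band over N2+N3, for a total near ten spindles per
  NREM minute. Same-band bursts never overlap (0.3 s guard).
* **Aging knob**: `lf_shift` adds to the late-fast coupling probability in
  every stage, raising the late-fast share and the number of ≥ 80 %
  late-fast bins.
* Ground truth records every injected wave, burst, and couple; generation
  is bitwise deterministic under the config seed, and `simulate_subject`
  writes standard EDF plus a plain-text hypnogram so tests exercise the
  real I/O path.

What the generator does **not** emulate: K-complexes and arousals, EMG/EOG
contamination, non-stationary noise floors, spindle frequency drift
(chirp), slow-wave travelling/propagation structure, or realistic
inter-subject variability beyond the seeded jitter. Passing recovery tests
therefore shows the pipeline is correct *under its stated model* —
detection thresholds separate events whose amplitudes clear the noise
floor, rank-based selection is stable, coupling bookkeeping is exact — not
that detection quality on clinical recordings will match synthetic
precision/recall.

## Numerical choices and degenerate inputs

16-bit EDF quantization uses a symmetric digital range (−32767..32767) so
written and read physical values agree to one least-significant bit;
sampling rates must be integer Hz and the final partial second is
zero-padded. Percentiles use the linear-interpolation definition
(documented so other implementations can agree). Zero-length inputs,
empty candidate sets, bands at or above Nyquist, zero baselines, all-zero
counts, and unpaired subjects raise immediately with specific messages;
zero-variance statistical inputs warn and return exact estimates rather
than raising. Detection is fully deterministic: identical input bytes
produce identical event lists.

## Test problem sizes

Synthetic nights in the test-suite and acceptance script are 15–60 min at
128 Hz with one or two NREM cycles, the generator's default amplitude,
noise, and coupling parameters, and seeds fixed in the tests; the
two-group study uses six subjects per group. These sizes give stable
detection statistics (hundreds to ~1200 ground-truth waves per night)
while keeping the whole suite fast.

## Known limitations

* The spindle-threshold reading ("75th percentile of the RMS value") is
  under-specified in the source description; the chosen reading is
  documented above and configurable, and numeric event counts shift by a
  few percent between readings.
* ROI rectangles for published power magnitudes live in an earlier report;
  defaults here mirror the detection geometry instead.
* Cross-channel coupling (slow waves on one channel, spindles on another)
  is supported, but no inter-channel lag correction is applied.
* The ≥ 80 % bin analysis treats empty bins as undefined; alternative
  conventions (counting them as 0 %) would lower bin counts and are a
  config choice, reported with results.
* Unclassified slow waves (no qualifying spindle, or spindles of both
  bands) are a substantial fraction of all detected waves by construction;
  the composition percentages describe the *classified* subset only.
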