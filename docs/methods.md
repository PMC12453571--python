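# Methods

This note documents the models, defaults and numerical choices behind
`stsbalance`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Recording model and conventions

A recording is a set of tri-axial channel arrays on a common time base
(seconds from the first sample) with metadata: user, trial type (`sts`,
`slb_left`, `slb_right`), start timestamp, nominal sample rate (100 Hz) and
device label. Canonical internal units are m/s² (accelerometer), rad/s
(gyroscope) and µT (magnetometer); files may declare `g` or `deg/s` in the
JSON sidecar and are converted on read, because phone APIs disagree on
native units and a single internal convention eliminates that bug class.
The magnetometer is stored and round-tripped but not analysed.

Axis convention for the chest-held portrait grip: the device long axis (`y`)
is vertical, the screen normal (`z`) is anterior-posterior, the remaining
axis (`x`) is medio-lateral; trunk pitch angular velocity is read from the
ML gyro axis. The mapping is a configurable `AxisConvention` — only the
grip orientation is fixed by the protocol, not the device axis labels.

Timestamps are accepted as-is while the median sample interval stays within
5% of nominal (consumer-phone jitter); otherwise the recording is rejected.
Non-exactly-uniform recordings are linearly resampled onto a uniform grid
before filtering. Resampling is idempotent and spans the original time
range.

The recording clock includes the 5-s countdown: the app samples from the
moment start is pressed, and the participant is still until the countdown
tone — which is precisely why the countdown segment can serve as the noise
baseline for both detectors.

## Sit-to-stand analysis

Pipeline: select pitch gyro → zero-phase low-pass (Butterworth order 4,
5 Hz; trunk motion in a chair rise lives below ~3 Hz) → subtract the mean
of the first still-window (1 s) of the countdown → prominence-based peak
detection on the filtered signal and on its negation → merge, enforce
alternation (same-sign runs keep the larger extremum, a leading sit is
dropped) → pair into (stand, sit) repetition events; a trailing unpaired
stand is not a repetition.

The prominence threshold is the maximum of two scale-free terms:

* `min_peak_prominence_frac` (0.3) × the robust signal range (0.1th–99.9th
  percentile span), which makes detection invariant to overall amplitude;
* `min_peak_snr` (8) × the MAD-based scale of the countdown still segment.

The second term is the noise floor: with only a range-relative threshold, a
recording containing nothing but sensor noise has a range proportional to
the noise itself, and noise peaks would be accepted as repetitions. Both
terms scale linearly with the signal, so multiplying a recording by any
k > 0 leaves the detected events unchanged. Same-sign peaks must be at
least `min_inter_peak_s` (0.8 s) apart. Ties between equal adjacent samples
resolve to the earliest index (the `scipy.signal.find_peaks` convention).

The time to n repetitions runs from the half-prominence crossing left of
the first stand peak to the half-prominence crossing right of the n-th sit
peak, approximating movement onset and offset rather than peak-to-peak
time. For the crossing reference height we use the peak's height above the
zero (still) baseline rather than the contour-line prominence estimate: on
noisy signals the contour estimate inflates with excursions elsewhere in
the record and shifts the crossing, while the baseline is pinned to zero by
the countdown-mean subtraction. Crossings are linearly interpolated between
samples. Repetitions beyond the required five are counted but the duration
uses the first five.

Validity requires a still countdown (filtered-signal variance in the first
still window below `still_var_threshold`, 0.05 (rad/s)²) and at least
`required_reps` detected events; failures are labelled `too_few_samples`,
`nonuniform_sampling`, `no_still_baseline` or `too_few_reps`.

## Single-leg balance analysis

Sway is the band-passed AP/ML acceleration. Two bands are used:

* **Sway metrics band** (0.1–3 Hz, Butterworth order 2, zero-phase): the
  conventional quiet-stance posturography band; the low corner removes
  gravity and slow postural drift.
* **Spike detection band** (8–25 Hz): a foot-strike impact is a broadband
  transient, while sway is confined below a few hertz. Detecting on a band
  above the sway spectrum means the detection baseline is sensor noise
  alone and sway excursions cannot trip the threshold — an absolute-band
  variant of detecting impacts on jerk.

Because forward-backward (`sosfiltfilt`) filtering applies the magnitude
response twice, the design corners are widened by the dual-pass correction
c = (√2 − 1)^(1/2·order) (Winter's correction) so the −3 dB points of the
combined filter land on the nominal band edges; without it the effective
band is narrower than specified and band-edge sway power is lost.

Foot contact: the resultant √(AP² + ML²) of the spike-band sway is
compared against `spike_threshold_k` (6) × the MAD-based scale
(1.4826 × MAD) of its first 5 s after the countdown (robust to a spike
falling inside the window on very short holds). An exceedance counts only
if sustained for `spike_min_duration_s` (50 ms, the impact's footprint);
because the band-passed impact rings and its resultant dips at ring zero
crossings, sub-20-ms dropouts are closed before run-length measurement. The
reported contact time is the resultant peak within the first sustained
exceedance event (merging sub-0.1-s gaps) — unlike the first threshold
crossing, the peak position does not move as the threshold changes.
Exceedances caused by the stop-button artifact occur after the activity
window and are clipped by the 30-s cap.

Balance duration is the contact time, else the 30-s protocol cap. The
validity gate is exact: `duration ≥ min_analysis_s` (11 s) is valid,
anything shorter fails with `insufficient_duration`. The 11-s figure is the
data-sufficiency requirement of the sway measures and is exposed as a
parameter rather than hard-coded, since it is an empirical working rule
rather than a physical constant. Sway metrics (RMS per axis, resultant RMS,
path length as the summed AP–ML plane increments) are computed over
[countdown end, countdown end + duration) on the metrics band.

## Synthetic data generator

The generator emulates the recording protocol, not human biomechanics:

* **Timeline** — 5-s countdown (still), activity window (≤ 30 s), 5-s still
  tail, 0.3-s stop-press artifact (windowed 25-Hz burst on all accel/gyro
  channels), 5-s still tail. Emitted length equals the segment sum within
  one sample.
* **StS** — per repetition cycle (Gaussian-distributed duration, default
  3.8 ± 0.3 s; five cycles ≈ 19 s) the pitch gyro carries a positive
  Gaussian pulse at 15% and a negative pulse at 85% of the cycle, σ =
  cycle/8, peak 1.5 rad/s, so the half-prominence onset/offset land at the
  cycle boundaries and the 5-rep time approximates the summed cycle
  durations. The vertical accelerometer carries derivative-of-Gaussian
  movement bursts on top of gravity. Ground-truth 5-rep time is the closed
  form: last sit peak + σ√(2 ln 2) minus first stand peak − σ√(2 ln 2).
* **SLB** — sway is white Gaussian noise low-pass filtered to the sway
  bandwidth (order 4, default 2 Hz — the steep rolloff keeps the emitted
  spectrum genuinely inside its nominal bandwidth) and rescaled so its RMS
  over the balance window equals the target exactly (defaults 0.05 AP /
  0.04 ML m/s²); a half-cosine 0.5-s ramp avoids a step edge at stance
  onset. Balance duration is drawn from a normal distribution truncated to
  (1, 30] s, mean 13.7 s (the neighbourhood of holds observed in older
  adults) and SD 6 s — the SD is a between-trial synthetic convention, as
  published cohort SDs describe per-participant means, not trials. If the
  hold ends before the cap, a 50-ms half-sine impact (default 0.5 m/s²,
  10× the AP sway RMS; 60% echoed on ML) starts at the contact instant,
  after which the signal is quiet standing (noise only).
* **Cohort** — participants follow a weekly schedule (default 17
  participants, 4 weeks, one session per week starting one week after
  onboarding, so a fully adherent participant has 4 sessions, 7-day gaps
  and a 21-day span). Session days jitter normally (SD 1.5 d); optional
  missed-session, extra-session and dropout probabilities generate
  non-compliant cohorts. Each session carries one StS recording and a
  left/right SLB pair, which count as a single balance session. Sensor
  noise defaults: 0.05 rad/s gyro and 0.02 m/s² accel white noise (an SNR
  of 5 — pulse peak over gyro noise SD — marks a stressed but plausible
  phone recording).

All randomness flows from the config seed; identical configs produce
bit-identical files.

What passing the synthetic tests shows: the detectors recover the
quantities the signal model encodes (repetition count and timing, balance
duration, contact time, sway RMS) under seeded noise, and the cohort
statistics track their generative values. What it does not show: robustness
to real-world artifacts the generator omits — device orientation error,
sensor bias and drift, non-Gaussian movement artifacts, hesitated or
partial repetitions, multi-touch ground contacts — and the simulator's
sway spectrum and repetition kinematics are synthetic conventions, not
fits to any cohort.

## Cohort statistics

Upload validity is 100 × n_valid/n_total, reported to one decimal
(round-half-up, matching how such percentages are conventionally printed).
Adherence summaries count sessions per activity from log rows (same-day
repeats count toward totals but collapse to one calendar day for gap and
span statistics); participants with a single session day have no defined
gap and are excluded, flagged, from gap aggregation. Cohort rows are
unweighted across participants. One-sample t-tests are computed from
summary statistics (mean, SD, n) so published cohort rows can be tested
without raw data; p-values are two-sided from Student's t with n − 1
degrees of freedom. No multiple-testing correction is applied across the
engagement rows, mirroring how such feasibility tables are reported. SUS
scores use Brooke's scheme (odd items score rating − 1, even items
5 − rating, total × 2.5); cohort SD uses the n − 1 denominator, and the
percentile interpretation interpolates linearly on the bundled Sauro–Lewis
anchor table (68 → 50th percentile, 80.8 → 90th).

## Problem sizes and determinism

Monte-Carlo checks in the test suite and acceptance script use 100 seeded
simulations per detector condition, 200 seeded cohorts for schedule
statistics, and 254 balance trials (the scale of a two-leg, 17-participant
study) for the validity-gate scenario; these sizes give the binomial and
standard-error tolerances quoted in the tests while keeping a full run in
tens of seconds. Per-trial seeds are drawn from a single master generator.
The gate-scenario check compares an observed invalid fraction against the
binomial 95% confidence interval of the scenario's analytic sub-11-s mass;
like any calibrated interval check it is expected to fail for about 5% of
master seeds.

## Known limitations

* Detector accuracy is validated against the synthetic signal model only;
  no motion-capture or force-plate ground truth is involved.
* The foot-contact detector assumes a single decisive impact; repeated
  hops or gentle toe-touches may be missed or mistimed.
* Sway metrics assume the phone stays fixed to the sternum; hand tremor or
  re-gripping contaminates the AP/ML channels.
* The adherence t-tests treat the cohort rows as independent summaries;
  with n = 17 they have limited power, so "no significant deviation" is a
  weak claim by construction.
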