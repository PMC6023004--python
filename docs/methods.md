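# Methods

## Signal model and data path

A wearable samples four sensors at a nominal 100 Hz and streams 20-byte
notification packets (little-endian: u16 sequence counter, u16 PPG, u16 EDA,
u16 EMG, i16 SKT in centi-°C, 10 reserved bytes). The EMG slot is carried
through the data model but no features are computed from it. Off-line
analysis works on `SessionRecording` objects: equal-length channel arrays on
the sample grid `index / sample_rate_hz`, 0-based, in seconds. Dropped
packets (sequence jumps, or empty CSV cells) are linearly interpolated when
a run lasts ≤ 0.5 s — short BLE dropouts are harmless for features whose
bandwidth is ≤ 0.25 Hz — and longer runs are filled too (downstream code
never sees NaN in a required channel) but flagged unusable in the load
report. Session CSVs are written with `%.17g` floats and read with the
round-trip parser, so write→read is bit-exact.

## HRV features

Beat detection smooths the PPG with a Gaussian matched roughly to the pulse
width, then keeps local maxima above an adaptive threshold (moving 75th
percentile over 2 s plus a quarter of the local peak-to-floor span) with a
0.33-s refractory period, capping detectable HR near 180 bpm. The interbeat
interval, attributed to the later beat of each pair, is interpolated onto
the sample grid with a cubic spline (held constant back to the first beat,
NaN outside beat coverage; linear fallback below four knots).

All rolling statistics use the centered, edge-truncated contract
`rolling(window, min_periods=1, center=True)` (sample std, ddof = 1); the
test suite checks them against a hand-written per-window recomputation.
Defaults: 10 s for time-domain features, 60 s for spectral features — one
LF cycle at the 0.04 Hz band edge alone takes 25 s, so anything shorter
than that triggers a warning.

Deliberate fidelity choices, each config-overridable:

* **Band edges** [0.04, 0.15] and [0.15, 0.40] Hz — contiguous, as computed
  (the prose "HF from 0.16 Hz" loses the 0.15–0.16 sliver).
* **Magnitude, not power.** The band "power" integrates the *magnitude*
  spectrum of the windowed IBI series (trapezoid over in-band bins, DFT
  scaled by window length); `power=True` switches to magnitude-squared.
* **HR is the formula, not the code line.** HR = 60000/IBI(ms) smoothed;
  the rolling mean of IBI itself is exposed separately as `mean_ibi`.
* **Difference order.** SDSD/RMSSD difference the beat-wise IBI first and
  interpolate the (absolute / squared) differences afterwards; squared
  differences are clipped at zero after interpolation because a cubic
  spline can overshoot below zero between knots.
* Spectral features are computed on a 1-s hop and linearly interpolated to
  the sample grid; order relations such as LF > HF survive linear
  interpolation, and per-sample FFTs would cost 100× for no information.

## Tonic features

EDA and SKT are low-passed with a 2nd-order Butterworth at a normalized
cutoff of 0.005 (fraction of Nyquist — 0.25 Hz at 100 Hz sampling; the
cutoff is kept normalized so the absolute frequency follows the session's
declared rate), applied forward and backward for zero phase. Odd-extension
padding is scaled to the filter's settling time (≈ `10/cutoff` samples,
capped by the signal length): at so low a cutoff the conventional
`3·max(len(b), len(a))` samples are far shorter than the impulse response
and leave visible boundary transients. Residual pass-band error at 20× the
cutoff is dominated by double-precision round-off in the IIR recursion
(~10⁻³ relative), well under the 1 % attenuation contract asserted in tests.

## Orienting-response detection

The EDA onset detector thresholds the derivative of the filtered signal at
`deriv_k` × its standard deviation over the relax period (unit-free, so raw
ADC counts work), requires the excursion to last ≥ 0.5 s, and enforces a
5-s refractory. Two non-obvious details:

* `deriv_k` defaults to 4. The filtered noise derivative is strongly
  autocorrelated (correlation time ≈ 2 s at a 0.25 Hz cutoff), so 3-σ
  excursions sustain half a second far more often than a white-noise
  intuition suggests; 4 σ brings the false-alarm rate to ~0.5 per 10 min at
  the generator's default noise while leaving SCR derivatives (tens of σ)
  untouched.
* The reported onset is the first sample of a supra-threshold run whose
  derivative reaches 60 % of the run's peak. A zero-phase filter smears a
  rising edge 1–2 s *backwards*, so the raw threshold crossing precedes the
  true onset by that much; the 60 %-of-peak point sits on the steep part of
  the rise and tracks ground-truth onsets to within ~0.4 s. Runs touching
  the first or last sample are discarded as filter edge transients.

Validation follows the cardiac-deceleration rule: least-squares HR slope
over the 2-s window starting 1 s before the onset; valid iff slope ≤
−`min_decel`, defensive iff ≥ +`min_decel` (mutually exclusive by
construction). Two choices matter:

* The HR series used here is smoothed with a **2-s** window, not the 10-s
  feature window — a 2-s slope test on a 10-s-smoothed series cannot
  resolve the deceleration at all.
* `min_decel` defaults to **0.5 bpm/s**. Because HR is beat-quantized, the
  check window observes only the first portion of a deceleration; measured
  on generated sessions, true orienting decelerations score −0.7 to −0.9
  bpm/s under this rule while baseline slope fluctuation at default noise
  stays within ±0.3 bpm/s, so 0.5 separates the two populations with margin
  on both sides.

## ANS-specificity classification

Baselines are channel means/stds of HR, EDA-mean and SKT-mean over the
relax interval (default first 180 s). A post-OR window's direction per
channel is +1/0/−1 against baseline with a deadband of `deadband_k = 0.5`
baseline standard deviations — without a dead zone, noise flips signs on
any channel whose true change is zero. Patterns score
matched/scored channels over their nonzero directions; all top scorers
above `min_score = 0.5` are returned, so the fear/disgust tie is explicit
rather than broken by table order. Only joy, disgust and fear ship as
defaults; anger and sadness directions are not anchored in the specificity
literature this package encodes and must be user-configured.

The match-rate statistic reports, per channel, the fraction of windows
matching the target direction and a one-sided exact binomial p-value
against chance 0.5 (`scipy.stats.binomtest`; the test suite cross-checks
the closed-form tail). "After" mode scores post-OR windows; "before" mode
scores blind consecutive 60-s segments of the whole recording.

## The synthetic generator

`generate_session` renders what the pipeline assumes real sessions look
like:

* **PPG** — Gaussian pulses (FWHM 80 ms, amplitude 1000 counts on a
  mid-scale 2048 baseline) at beat times integrated from the instantaneous
  HR profile; dicrotic morphology is not modelled.
* **HR profile** — baseline (default 70 bpm) plus, per episode, a linear
  deceleration ramp starting 1 s *before* the SCR onset (cardiac
  deceleration is immediate at the stimulus; the electrodermal onset lags),
  a recovery into a sustained level shift, and a 10-s release after the
  episode ends.
* **EDA** — tonic level plus bi-exponential SCRs (rise τ 1 s, decay τ 4 s,
  peak-normalized amplitude, default 150 counts).
* **SKT** — baseline plus per-episode linear trends (°C/min); after an
  episode the excursion relaxes exponentially (τ 90 s) toward the
  thermoregulated set point. An early version held SKT offsets forever,
  which is physiologically wrong and makes every late segment of a session
  read "warm".
* **Baseline wander** — each channel carries band-limited drift (periods
  50–120 s) at std 0.5 bpm / 5 counts / 0.02 °C. Two constraints set these
  numbers: the band is short enough that a 3-min relax window samples the
  full wander distribution (slower drift would bias every post-relax
  segment one way relative to the baseline), and the amplitudes sit a few
  times below the scripted effect sizes — the regime in which level
  comparison is a sensible method at all.
* **Noise** — white Gaussian per channel (σ 20 / 2 / 0.02 counts-or-°C).

Fixed seed ⇒ bit-identical output. Presets: `iaps_520` (3-min relax + the
20-picture 6 s/20 s schedule; unpleasant pictures script disgust episodes,
the first pleasant picture a joy episode, SCR latency 1.5 s) and
`film_joy_14` (14 joy scenes across a 30-min session).

What passing tests on this generator do **not** show: robustness to motion
artifacts, ectopic beats, electrode drift/detachment, respiration coupling,
or between-subject variability — none of which are modelled.

## Problem sizes and runtime choices

The detector sensitivity/false-alarm study uses twenty 10-minute sessions
(six scripted episodes each); label recovery uses two noiseless two-episode
sessions per emotion; the OR-locking contrast uses a 30-min session with
four transient joy episodes — sparse on purpose, since the advantage of
OR-locked averaging over blind segmentation exists precisely when most of
the runtime is emotionally neutral (a session saturated with responses
leaves fingertip temperature cumulatively elevated, and blind segments then
match the pattern legitimately). These sizes keep the full suite under a
minute while leaving every pass/fail margin wide.

## Known limitations

* The peak detector is tuned for clean optical pulses; heavy motion noise
  would need band-pass preprocessing it does not have.
* OR accuracy against *human* annotation is unknowable here; all recovery
  figures are against generator ground truth.
* The fear/disgust signature is genuinely degenerate in this channel set;
  disambiguation would need additional channels (e.g., facial EMG).
* `match_rate_test` assumes windows are independent Bernoulli trials;
  overlapping or adjacent windows violate that silently.
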