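# Methods

This note records the models implemented in burstkit, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## Baseline-noise model and detection threshold

Suction-electrode population signals are assumed already rectified and
RMS-smoothed by the recording chain (`rms_smooth` emulates that stage
for raw synthetic signals: moving root-mean-square of width τ, default
chosen per call). Baseline noise of the smoothed signal is modelled per
sliding window (`noise.window_s` = 120 s, hop = window/4) by a
least-squares Gaussian fit to the histogram of *all* samples in the
window — Freedman–Diaconis bins with a floor of 30. Fitting the
histogram mode rather than taking raw moments keeps the estimate
robust to the sparse event tail. The detection threshold is
μ(t) + k·σ(t) with k = 2 (the two-sided 95 % band of the baseline
distribution), linearly interpolated between window centers and held
constant beyond them.

Numerical fallbacks: a window of identical samples returns its value
with σ = 0 and is flagged; a failed curve fit falls back to the median
and 1.4826 × MAD (flagged), which—unlike the raw mean/SD—is not dragged
upward by events. An `exclude` mask supports an iterative refit after
masking detected events; it is off by default because the histogram fit
is already insensitive to the tail.

## Event detection

Suprathreshold excursions separated by < 150 ms are merged (refractory
merge; prevents double-counting a noisy peak). The peak is the merged
excursion's maximum (earliest sample on ties), the onset the last
upward threshold crossing before it, the offset the first downward
crossing after it. Excursions whose suprathreshold span is shorter
than 150 ms are discarded: burstlets last 310–400 ms in slices, and
even their suprathreshold portion exceeds ~200 ms, whereas correlated
baseline noise rarely stays above 2σ for more than a few correlation
times. This duration criterion, not the threshold, is what gives the
detector its precision on noisy recordings.

## Burst / burstlet / sigh classification

An event is a **burstlet** iff the XII channel shows negligible
activity in [onset − 0.1 s, offset + 0.1 s]; the pad covers the
preinspiratory lag between field onset and XII onset (~400 ms of the
event itself is already inside the window). "Negligible" is
operationalized as: no excursion above the XII channel's own μ + 2σ
threshold sustained for ≥ 100 ms. Genuine XII discharge stays
suprathreshold for the ~300-ms motor burst; sample-level exceedances of
correlated baseline noise do not persist that long. With a noise-free
XII channel the rule reduces to simple exceedance.

Sigh classification evaluates bursts left-to-right (burstlets never
enter the criteria): (i) area > mean + 1 SD of all burst areas, (ii)
interval since the previously *accepted* sigh (recording start for the
first candidate, which is flagged provisional) within [60 s, 240 s],
(iii) following inter-burst interval > 1.3 × the mean of the six
preceding inter-burst intervals (fewer available cycles are used and
flagged). A trailing candidate without a following interval cannot
satisfy (iii) and stays a burst. The sigh-period criterion uses
inter-sigh intervals rather than a per-candidate sliding estimate; the
choice is exposed through `SighCriteria`.

## Shape measurement

Rise, decay, and duration are defined from onset/peak/offset. Because
a k·σ threshold crossing clips the foot of an event by an
amplitude-dependent amount, `measure_shape` refines both edges by
default: it finds the last 25 % and 75 % amplitude crossings of each
flank (sub-sample, linear interpolation) and extrapolates that chord to
the baseline. For ramp-like flanks this recovers the true edge
independent of the event's amplitude-to-noise ratio; on simulated
burstlets the population mean rise/decay is recovered within a few
milliseconds of the planted 155.6/198.2 ms. Area is the trapezoidal
integral above the interpolated baseline mean between the refined
edges.

## Rhythm metrics

Instantaneous frequencies come from peak-to-peak intervals (peaks are
the most robustly located landmark; onset-to-onset is a caller choice by
passing onsets). CV is computed on the instantaneous frequencies with
population statistics (ddof = 0), so a single interval yields SD 0.
The collective cycle-period model for imaging uses the sample SD
(ddof = 1) of the peak-to-peak periods — the convention under which
periods {3.5, 4.0, 4.5} s give SD 0.5 and a 95 % CI of [3, 5] s.
The burstlet fraction excludes sighs from numerator and denominator.
Condition–response summaries use ordinary least squares with a
two-sided slope test (scipy); a constant response returns slope 0,
r² = 0 rather than an undefined correlation.

## Cycle-triggered averaging and depolarization rates

Windows of [−1 s, +1 s] around each trigger (XII onset for bursts; the
burstlet's own onset for burstlets) are averaged pointwise; windows that
do not fit are dropped and counted. Per-cycle baseline subtraction
(mean of the earliest quarter of the pre-trigger context) is on by
default so slow drift does not smear the average; it is exactly linear,
so CTA(a·x + b) = a·CTA(x) + b holds either way.

On the average, baseline = mean of [−pre, −0.8·pre] (far from the
preinspiratory ramp); the component peak is the post-trigger maximum.
Amplitudes: preinspiratory = |value at trigger − baseline|; burst =
peak − value at trigger (which omits the preinspiratory portion);
burstlet = peak − baseline. Times-to-peak: the preinspiratory onset is
the last pre-trigger time within 5 % of the preinspiratory amplitude
above baseline; burst and burstlet clocks start at the trigger.
Depolarization rate = amplitude / time-to-peak; a zero-amplitude
component has rate 0 and a non-positive time-to-peak is an error.

Whole-cell envelopes use a running median (50 ms default): it removes
2–5 ms spikes without attenuating the plateau, which a low-pass filter
would.

## Imaging ROI segmentation

The mean-frame trace is event-detected with the same operator as field
recordings; ≥ 3 collective peaks are required. The frequency band is
[1/(T + 2s), 1/(T − 2s)] for period mean T and SD s; a period SD of 0
(or any band narrower than one FFT bin) widens to the nearest nonzero
bin ± 1. Downsampling is by block means (2ⁿ, default n = 1; edge blocks
average their actual pixels; pitch scales by 2ⁿ). Per composite pixel
the temporal mean is subtracted and an unnormalized real FFT with a
rectangular window is taken; the map records the maximum in-band
magnitude. The map threshold (mean + 2 SD of all composite pixels) is
scale-free, so segmentation is invariant to global intensity rescaling;
the magnitude-vs-power convention is therefore isolated from the
result. Components are 8-connected; "diameter" is the equivalent
circular diameter 2·√(area/π)·pitch with a strict > 6 µm cut (below a
neuronal soma). ROI masks are back-projected to the original
resolution before ΔF/F₀ extraction; F₀ is the full-series ROI mean, so
the unsmoothed ΔF/F₀ has exactly zero mean — an identity the tests
assert to 10⁻¹⁰. The forward moving average (4 frames) includes the
current sample and averages the available remainder at the trailing
edge.

## Participation scoring

The per-cycle activity criterion is this package's own operational
definition (no field standard exists): ROI r is active in event e iff
its smoothed ΔF/F₀ stays above μ_r + 3σ_r for at least 0.1 s within
[onset − 0.2 s, offset + 0.5 s]. The asymmetric pad accommodates
indicator decay lag; (μ_r, σ_r) come from event-free frames, excluding
a 1.5-s trailing pad after each event so decay tails do not inflate the
baseline SD. The sustained-excursion requirement exists because the
maximum of ~20 smoothed frames crosses a 3σ line by chance ~2 % of the
time, which would bias pooled participation estimates upward by ~0.015;
GCaMP-like transients decay over ~0.5 s, so the requirement costs no
sensitivity. `act_k` is the key analyst-sensitive knob and is exposed
everywhere, including the CLI.

## Synthetic data: what it emulates, and what it does not

Field/XII generator: events at gamma-distributed intervals (shape 4,
interval CV 0.5 — mid-range for slice rhythms; mean rate 0.1 Hz).
Bursts carry a 400-ms linear preinspiratory ramp to 30 % amplitude,
then a rise/decay of 155.6/198.2 ms (the reported burstlet kinetics at
high excitability) to amplitude 1.0, with an XII partner starting at
the ramp-to-peak transition; burstlets are ramp-only events with
amplitude uniform in 15–65 % of burst amplitude and no XII partner;
optional sighs scale amplitude ×3 and force a prolonged following
interval. Flanks are linear with a Gaussian-rounded apex (10 ms), so
edge-refined shape measurements have a well-defined truth. Baseline
noise is correlated Gaussian (20-ms correlation time, SD 0.04 on a 0.2
baseline): the modeled signal is the *smoothed* recording, whose noise
is band-limited by construction — white noise at the sampling rate
would make threshold-crossing detection meaningless and corresponds to
no real recording chain.

Membrane generator: −60 mV baseline; bursts are >20-mV envelopes with
2-ms biphasic spikes; burstlets are summating alpha-function EPSP
staircases with envelope peaks uniform in 6–10 mV.

Imaging generator: 2-min, 32-Hz, 256×256 stacks over a 116-µm field;
~11-µm disk somata placed by rejection sampling with a minimum gap;
collective events every ~7 s (jittered); per-cell Bernoulli
participation (0.95 for bursts, 0.2 for burstlets); double-exponential
calcium kernel (rise 50 ms, decay 500 ms, GCaMP6f-like); transient
amplitude 40 on baseline 100 with Gaussian photon noise SD 10 (SNR 4);
an optional distractor cell oscillates sinusoidally at 3 × the
collective frequency and must never be segmented.

What passing these benchmarks does **not** show: the generators are
phenomenological — no recurrent-excitation network dynamics, no
bleaching, motion, or neuropil contamination in imaging, no
electrode-drift nonstationarity beyond what the sliding noise model
absorbs, and disk-shaped non-overlapping somata. Recovery on this data
validates the algorithms' correctness and calibration, not their
robustness to every artifact of real recordings.

## Problem sizes

The test suite and the acceptance script use the study-scale problem
sizes directly: 10–17 min field recordings (~60–100 events) at 2 kHz,
10⁶-sample noise fits, and full-scale 3840-frame 256×256 stacks for
segmentation; the participation benchmark uses a 144×144 field with 30
radius-6 cells because 30 soma-scale cells cannot pack into the 116-µm
field at the default radius. The full suite runs in about a minute on
one CPU.
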