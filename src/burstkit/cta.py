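"""Cycle-triggered averaging and event-amplitude / depolarization-rate
readouts.

A cycle-triggered average (CTA) aligns trace windows on a per-cycle
trigger — the onset of XII motor output for inspiratory bursts, or the
onset of the burstlet itself for burstlets — and takes the pointwise
mean. Three amplitude readouts are defined on the average:

* preinspiratory amplitude: |activity at XII onset - baseline|,
* burst amplitude: peak - activity at XII onset (which omits the
  portion attributable to the preinspiratory ramp),
* burstlet amplitude: peak - baseline at the burstlet onset.

The depolarization rate of a component is its amplitude divided by the
time that component takes to reach its peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .signal_io import Trace

__all__ = [
    "CTAResult",
    "EventAmplitudes",
    "cycle_triggered_average",
    "event_amplitudes",
    "depolarization_rate",
    "membrane_envelope",
]


@dataclass
class CTAResult:
    """Pointwise mean of trigger-aligned windows; trigger sits at t = 0."""

    mean_trace: Trace          # t0 = -pre_s
    n_cycles: int
    trigger_kind: str          # "xii_onset" | "burstlet_onset" | free label
    pre_s: float
    post_s: float
    n_dropped: int = 0         # triggers whose window fell outside the trace

    def value_at(self, t_rel: float) -> float:
        """Average value at time ``t_rel`` relative to the trigger."""
        return float(self.mean_trace.samples[self.mean_trace.index_at(t_rel)])


@dataclass
class EventAmplitudes:
    """Component amplitudes and times-to-peak measured on a CTA."""

    preinspiratory_amp: float
    burst_amp: float
    burstlet_amp: float
    preinspiratory_ttp_s: float
    burst_ttp_s: float
    burstlet_ttp_s: float
    baseline: float


def cycle_triggered_average(
    trace: Trace,
    triggers,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    baseline_subtract: bool = True,
    trigger_kind: str = "xii_onset",
) -> CTAResult:
    """Average trace windows aligned on the trigger times.

    Each window spans ``[t - pre_s, t + post_s]``; windows that do not
    fit inside the trace are dropped (counted in ``n_dropped``). With
    ``baseline_subtract`` each window first has the mean of its earliest
    quarter of the pre-trigger context removed, so slow baseline drift
    between cycles does not smear the average.

    The default 1-s context comfortably covers the ~400 ms
    preinspiratory ramp that precedes XII onset.
    """
    triggers = np.asarray(triggers, dtype=float)
    n_pre = int(round(pre_s * trace.rate))
    n_post = int(round(post_s * trace.rate))
    n = n_pre + n_post
    if n < 2:
        raise ValueError("window too short for this sampling rate")
    windows = []
    dropped = 0
    for t in triggers:
        i0 = int(round((t - trace.t0) * trace.rate)) - n_pre
        if i0 < 0 or i0 + n > len(trace):
            dropped += 1
            continue
        w = trace.samples[i0 : i0 + n].astype(float).copy()
        if baseline_subtract:
            nb = max(n_pre // 4, 1)
            w -= w[:nb].mean()
        windows.append(w)
    if not windows:
        raise ValueError("no trigger window fits inside the trace")
    mean = np.mean(windows, axis=0)
    return CTAResult(
        mean_trace=Trace(mean, rate=trace.rate, label=f"cta:{trace.label}", t0=-pre_s),
        n_cycles=len(windows),
        trigger_kind=trigger_kind,
        pre_s=pre_s,
        post_s=post_s,
        n_dropped=dropped,
    )


def event_amplitudes(avg: CTAResult, onset_frac: float = 0.05) -> EventAmplitudes:
    """Measure the three component amplitudes on a cycle-triggered average.

    The baseline is the mean of the early pre-trigger segment
    ``[-pre_s, -0.8*pre_s]`` (far from the preinspiratory ramp). The
    component peak is the maximum at or after the trigger. The
    preinspiratory onset is the last pre-trigger time at which the
    average sits within ``onset_frac`` of its preinspiratory amplitude
    above baseline; its time-to-peak runs from that onset to the
    trigger. Burst time-to-peak runs from the trigger to the peak;
    burstlet time-to-peak runs from the trigger (which *is* the burstlet
    onset for burstlet-triggered averages) to the peak.
    """
    tr = avg.mean_trace
    y = tr.samples
    t = tr.times
    n_base = max(int(round(0.2 * avg.pre_s * tr.rate)), 1)
    baseline = float(y[:n_base].mean())

    i_trig = tr.index_at(0.0)
    post = y[i_trig:]
    i_pk = i_trig + int(np.argmax(post))
    peak = float(y[i_pk])
    v_trig = float(y[i_trig])

    pre_amp = abs(v_trig - baseline)
    # preinspiratory onset: last pre-trigger sample still near baseline
    level = baseline + onset_frac * pre_amp
    below = np.flatnonzero(y[:i_trig] <= level)
    i_on = int(below[-1]) if below.size else 0
    pre_ttp = float(t[i_trig] - t[i_on])

    return EventAmplitudes(
        preinspiratory_amp=pre_amp,
        burst_amp=peak - v_trig,
        burstlet_amp=peak - baseline,
        preinspiratory_ttp_s=pre_ttp,
        burst_ttp_s=float(t[i_pk] - t[i_trig]),
        burstlet_ttp_s=float(t[i_pk] - t[i_trig]),
        baseline=baseline,
    )


def depolarization_rate(
    avg: CTAResult, amplitudes: EventAmplitudes, component: str
) -> float:
    """Amplitude / time-to-peak for a named component (units per second).

    ``component`` is one of ``"preinspiratory"``, ``"burst"``,
    ``"burstlet"``. A zero-amplitude component has rate 0; a
    non-positive time-to-peak is an error.
    """
    table = {
        "preinspiratory": (amplitudes.preinspiratory_amp, amplitudes.preinspiratory_ttp_s),
        "burst": (amplitudes.burst_amp, amplitudes.burst_ttp_s),
        "burstlet": (amplitudes.burstlet_amp, amplitudes.burstlet_ttp_s),
    }
    if component not in table:
        raise ValueError(f"unknown component {component!r}")
    amp, ttp = table[component]
    if amp == 0:
        return 0.0
    if ttp <= 0:
        raise ValueError("time-to-peak must be positive")
    return amp / ttp


def membrane_envelope(vm: Trace, width_s: float = 0.05) -> Trace:
    """Spike-free envelope of a whole-cell recording.

    A running median of width ``width_s`` removes action potentials
    (~2-5 ms) while preserving the slower envelope of depolarization
    (inspiratory drive potentials last hundreds of milliseconds) — a
    median, unlike a low-pass filter, does not smear spike charge into
    the envelope. The width must exceed a spike but stay well below a
    burst.
    """
    n = int(round(width_s * vm.rate))
    if n < 3:
        raise ValueError("envelope width must span at least 3 samples")
    if n % 2 == 0:
        n += 1
    out = median_filter(vm.samples, size=n, mode="nearest")
    return Trace(out, rate=vm.rate, label=f"env:{vm.label}", t0=vm.t0)
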