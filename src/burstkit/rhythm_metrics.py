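"""Summary statistics of event series: frequency, variability, composition.

Instantaneous frequencies are computed from peak-to-peak intervals (the
peak is the most robustly located landmark of a population event) and the
coefficient of variation (CV) is the ratio of the SD to the mean of those
instantaneous frequencies. The burstlet fraction is the share of
non-sigh events that are burstlets; it is the pipeline's readout of
network excitability (it falls sigmoidally as excitability rises).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .event_analysis import Event

__all__ = [
    "FrequencyStats",
    "RegressionSummary",
    "RhythmSummary",
    "frequency_cv",
    "burstlet_fraction",
    "regression_summary",
    "summarize_rhythm",
]


class FrequencyStats(NamedTuple):
    f_mean: float   # Hz
    f_sd: float     # Hz
    cv: float       # dimensionless, f_sd / f_mean
    n_intervals: int


class RegressionSummary(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class RhythmSummary:
    """Per-recording rhythm summary, optionally tagged with a condition."""

    f_mean: float
    f_sd: float
    cv: float
    n_events: int
    burstlet_fraction: float | None
    amp_mean: float
    amp_sd: float
    condition: dict | None = None

    def to_dict(self) -> dict:
        return {
            "f_mean_hz": self.f_mean,
            "f_sd_hz": self.f_sd,
            "cv": self.cv,
            "n_events": self.n_events,
            "burstlet_fraction": self.burstlet_fraction,
            "amp_mean": self.amp_mean,
            "amp_sd": self.amp_sd,
            "condition": self.condition,
        }


def _peak_times(events) -> np.ndarray:
    if len(events) and isinstance(events[0], Event):
        return np.array(sorted(e.peak_s for e in events))
    return np.sort(np.asarray(events, dtype=float))


def frequency_cv(events: Sequence) -> FrequencyStats | None:
    """Mean, SD, and CV of instantaneous event frequency.

    ``events`` may be a list of :class:`Event` or an array of peak times.
    Instantaneous frequencies are the reciprocals of successive
    peak-to-peak intervals. Returns ``None`` (flagged null) with fewer
    than two events. Population statistics (ddof=0) are used, so a
    single interval gives ``f_sd = 0``.
    """
    peaks = _peak_times(events)
    if peaks.size < 2:
        return None
    freqs = 1.0 / np.diff(peaks)
    f_mean = float(freqs.mean())
    f_sd = float(freqs.std())
    return FrequencyStats(f_mean, f_sd, f_sd / f_mean, freqs.size)


def burstlet_fraction(events: Sequence[Event]) -> float | None:
    """Fraction of classified, non-sigh events that are burstlets.

    Sighs are excluded from both numerator and denominator. Returns
    ``None`` when no bursts or burstlets are present.
    """
    n_burstlet = sum(1 for e in events if e.kind == "burstlet")
    n_burst = sum(1 for e in events if e.kind == "burst")
    total = n_burst + n_burstlet
    if total == 0:
        return None
    return n_burstlet / total


def regression_summary(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """Ordinary least squares of ``y`` on ``x`` with a two-sided slope test.

    Used for condition-response summaries such as frequency or amplitude
    versus excitability. Requires at least three points and non-constant
    ``x``; a constant ``y`` returns slope 0 with r-squared 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    if np.ptp(y) == 0:
        return RegressionSummary(0.0, float(y[0]), 0.0, 1.0)
    res = stats.linregress(x, y)
    return RegressionSummary(
        float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
    )


def summarize_rhythm(events: Sequence[Event], condition: dict | None = None) -> RhythmSummary:
    """Bundle the standard per-recording metrics into one summary."""
    fs = frequency_cv(events)
    amps = np.array([e.amplitude for e in events]) if events else np.zeros(0)
    return RhythmSummary(
        f_mean=fs.f_mean if fs else float("nan"),
        f_sd=fs.f_sd if fs else float("nan"),
        cv=fs.cv if fs else float("nan"),
        n_events=len(events),
        burstlet_fraction=burstlet_fraction(events),
        amp_mean=float(amps.mean()) if amps.size else float("nan"),
        amp_sd=float(amps.std()) if amps.size else float("nan"),
        condition=condition,
    )
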