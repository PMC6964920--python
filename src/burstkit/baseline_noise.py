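"""Baseline-noise modelling for smoothed population recordings.

Suction-electrode signals are rectified and RMS-smoothed by the recording
chain; all event detection operates on such smoothed traces. The detection
threshold is defined from a sliding-window Gaussian model of the baseline
noise: within each 120-s window every sample enters a histogram, the
histogram is fitted with a Gaussian, and the fitted mean + k*SD (k = 2 by
default, the two-sided 95% band of the baseline distribution) is the local
threshold. Thresholds are linearly interpolated between window centers and
held constant beyond the first/last center.

The Gaussian fit to the histogram mode, rather than raw sample statistics,
keeps the estimate robust to the sparse tail contributed by events
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .signal_io import Trace

__all__ = ["NoiseModel", "rms_smooth", "fit_noise_model", "threshold_at"]


@dataclass
class NoiseModel:
    """Per-window baseline statistics and the derived detection threshold.

    ``threshold(t) = mu(t) + k * sigma(t)`` with linear interpolation of
    mu and sigma between window centers and constant extrapolation at the
    ends.
    """

    centers: np.ndarray        # window-center times, seconds
    mu: np.ndarray             # fitted baseline mean per window
    sigma: np.ndarray          # fitted baseline SD per window (>= 0)
    k: float = 2.0             # threshold multiplier
    window_s: float = 120.0
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.flagged.size != self.centers.size:
            self.flagged = np.zeros(self.centers.size, dtype=bool)

    def mu_at(self, t):
        return np.interp(t, self.centers, self.mu)

    def sigma_at(self, t):
        return np.interp(t, self.centers, self.sigma)

    def threshold_at(self, t):
        """Detection threshold at absolute time(s) ``t``."""
        return np.interp(t, self.centers, self.mu + self.k * self.sigma)


def rms_smooth(raw: Trace, tau: float) -> Trace:
    """Moving root-mean-square of width ``tau`` seconds.

    Emulates the rectify-and-smooth stage of a differential amplifier:
    the output is the square root of the running mean of the squared
    signal, so it is non-negative and tracks the signal envelope. For a
    zero-mean sinusoid of amplitude A and ``tau`` much longer than the
    period, the output approaches A/sqrt(2).
    """
    n = int(round(tau * raw.rate))
    if n < 2:
        raise ValueError("tau must span at least 2 samples")
    power = uniform_filter1d(raw.samples**2, size=n, mode="nearest")
    # clip tiny negative round-off before the square root
    out = np.sqrt(np.maximum(power, 0.0))
    return Trace(out, rate=raw.rate, label=raw.label, t0=raw.t0)


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_window(samples: np.ndarray, min_bins: int = 30):
    """Least-squares Gaussian fit to the sample histogram.

    Returns ``(mu, sigma, flagged)``; falls back to robust sample
    statistics (median and scaled MAD, flagged) when the histogram is
    degenerate or the fit fails — unlike the raw mean/SD these are not
    dragged upward by the event tail.
    """
    s_mean = float(np.mean(samples))
    s_sd = float(np.std(samples))
    if s_sd == 0.0:
        return s_mean, 0.0, True
    # Freedman-Diaconis binning with a floor of `min_bins` bins
    edges = np.histogram_bin_edges(samples, bins="fd")
    if edges.size - 1 < min_bins:
        edges = np.histogram_bin_edges(samples, bins=min_bins)
    hist, edges = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gaussian,
            centers,
            hist,
            p0=(hist.max(), s_mean, s_sd),
            bounds=([0.0, centers[0], 1e-12 * s_sd], [np.inf, centers[-1], np.inf]),
            maxfev=5000,
        )
        mu, sigma = float(popt[1]), float(abs(popt[2]))
        if not np.isfinite(mu) or not np.isfinite(sigma) or sigma > 10 * s_sd:
            raise RuntimeError("implausible fit")
        return mu, sigma, False
    except Exception:
        med = float(np.median(samples))
        mad = float(np.median(np.abs(samples - med)))
        return med, 1.4826 * mad, True


def fit_noise_model(
    trace: Trace,
    window_s: float = 120.0,
    k: float = 2.0,
    hop_s: float | None = None,
    exclude: np.ndarray | None = None,
) -> NoiseModel:
    """Fit the sliding-window Gaussian noise model.

    Parameters
    ----------
    trace : Trace
        Smoothed recording to model.
    window_s : float
        Sliding-window length, seconds (default 120).
    k : float
        Threshold multiplier (default 2, the 95% band).
    hop_s : float, optional
        Window advance; defaults to ``window_s / 4``. Thresholds are
        interpolated between the resulting window centers.
    exclude : boolean array, optional
        Samples to leave out of the histograms (e.g. previously detected
        events, for an iterative refit). Same length as the trace.

    A trace shorter than one window is fitted with a single full-trace
    window.
    """
    if hop_s is None:
        hop_s = window_s / 4.0
    n = len(trace)
    win = int(round(window_s * trace.rate))
    hop = max(int(round(hop_s * trace.rate)), 1)
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.size != n:
            raise ValueError("exclude mask must match the trace length")

    if win >= n:
        starts = [0]
        win = n
    else:
        starts = list(range(0, n - win + 1, hop))
        if starts[-1] + win < n:
            starts.append(n - win)

    centers, mus, sigmas, flags = [], [], [], []
    for s in starts:
        seg = trace.samples[s : s + win]
        if exclude is not None:
            keep = ~exclude[s : s + win]
            if keep.sum() >= 10:
                seg = seg[keep]
        mu, sigma, flagged = _fit_window(seg)
        centers.append(trace.t0 + (s + win / 2.0) / trace.rate)
        mus.append(mu)
        sigmas.append(sigma)
        flags.append(flagged)
    return NoiseModel(
        centers=np.array(centers),
        mu=np.array(mus),
        sigma=np.array(sigmas),
        k=k,
        window_s=window_s,
        flagged=np.array(flags, dtype=bool),
    )


def threshold_at(model: NoiseModel, t):
    """Functional form of :meth:`NoiseModel.threshold_at`."""
    return model.threshold_at(t)
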