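"""Frequency-domain ROI detection on calcium-imaging stacks.

The segmentation exploits the fact that rhythmically active neurons
modulate their fluorescence at the slice's collective inspiratory
frequency. The steps are:

1. Average all pixels per frame to get the collective fluorescence
   trace; its peak-to-peak cycle periods define a 95% band
   (mean +/- 2*SD) and hence a frequency band of interest.
2. Downsample the stack planar resolution by 2**n (block means).
3. Per composite pixel, take the temporal FFT (mean-subtracted,
   rectangular window, magnitude convention) and record the maximum
   magnitude over bins inside the band — a 2-D "rhythm map".
4. Zero map pixels below mean + 2*SD of all map values; contiguous
   remaining sets (8-connected) whose equivalent circular diameter
   exceeds 6 um are the ROIs.
5. Back-project each ROI to the original resolution and extract
   dF/F0 = (F_i - F0)/F0, where F0 is the ROI's full-series mean,
   optionally smoothed with a 4-point forward moving average.

The magnitude convention and windowing are internal choices; the map
threshold is scale-free, so segmentation is invariant to an overall
intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .baseline_noise import NoiseModel, fit_noise_model
from .event_analysis import detect_events
from .signal_io import ImagingStack, Trace

__all__ = [
    "CyclePeriodModel",
    "RhythmMap",
    "ROI",
    "DFFTrace",
    "mean_frame_trace",
    "collective_cycle_model",
    "downsample_stack",
    "fft_rhythm_map",
    "segment_rois",
    "compute_dff",
    "forward_moving_average",
]


@dataclass
class CyclePeriodModel:
    """Collective-rhythm period statistics and the derived frequency band.

    ``ci`` is the 95% period interval (mean +/- 2*SD, seconds);
    ``band_hz`` is its reciprocal, ``[1/ci_high, 1/ci_low]``.
    """

    mean_period_s: float
    sd_period_s: float
    n_cycles: int

    @property
    def ci(self) -> tuple[float, float]:
        return (
            self.mean_period_s - 2.0 * self.sd_period_s,
            self.mean_period_s + 2.0 * self.sd_period_s,
        )

    @property
    def band_hz(self) -> tuple[float, float]:
        lo, hi = self.ci
        if lo <= 0:
            raise ValueError("period too variable: CI lower bound <= 0")
        return (1.0 / hi, 1.0 / lo)


@dataclass
class RhythmMap:
    """Per-composite-pixel in-band FFT magnitude and its threshold."""

    values: np.ndarray          # 2-D, non-negative
    downsample_n: int
    pixel_pitch_um: float       # pitch of the composite pixels
    band_hz: tuple[float, float]
    bin_hz: tuple[float, float]  # band actually used after bin snapping

    @property
    def threshold(self) -> float:
        """Mean + 2*SD over all composite pixels."""
        return float(self.values.mean() + 2.0 * self.values.std())


@dataclass
class ROI:
    """A contiguous suprathreshold region of the rhythm map."""

    roi_id: int
    mask: np.ndarray            # boolean, composite-pixel resolution
    mask_fullres: np.ndarray    # boolean, original resolution
    equivalent_diameter_um: float
    centroid: tuple[float, float]  # (row, col) in composite pixels

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class DFFTrace:
    """dF/F0 of one ROI; the unsmoothed series has exactly zero mean."""

    values: np.ndarray          # unsmoothed dF/F0 per frame
    smoothed: np.ndarray        # forward moving average
    roi_id: int
    frame_rate: float
    smooth_window: int = 4

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate


def mean_frame_trace(stack: ImagingStack) -> Trace:
    """Average fluorescence of all pixels, per frame."""
    return Trace(
        stack.frames.mean(axis=(1, 2)).astype(float),
        rate=stack.frame_rate,
        label="mean_frame",
    )


def collective_cycle_model(
    trace: Trace, model: NoiseModel | None = None
) -> CyclePeriodModel:
    """Estimate the collective cycle period from the mean-frame trace.

    Collective inspiratory peaks are detected with the same
    threshold-crossing operator used for field recordings (noise model
    fitted on the trace itself unless one is supplied). At least three
    peaks (two periods) are required.
    """
    if model is None:
        model = fit_noise_model(trace)
    events = detect_events(trace, model)
    if len(events) < 3:
        raise ValueError("need >= 3 collective peaks to model the cycle period")
    peaks = np.array([e.peak_s for e in events])
    periods = np.diff(peaks)
    return CyclePeriodModel(
        mean_period_s=float(periods.mean()),
        sd_period_s=float(periods.std(ddof=1)),
        n_cycles=periods.size,
    )


def downsample_stack(stack: ImagingStack, n: int = 1) -> ImagingStack:
    """Downsample planar resolution by 2**n via block means.

    Each 2**n x 2**n block becomes one composite pixel holding the mean
    of its constituent pixels; edge blocks average the pixels they
    actually contain. The pixel pitch scales by 2**n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    f = 2**n
    T, H, W = stack.frames.shape
    if f > H or f > W:
        raise ValueError("downsampling factor exceeds the image size")
    rows = np.arange(0, H, f)
    cols = np.arange(0, W, f)
    sums = np.add.reduceat(np.add.reduceat(stack.frames, rows, axis=1), cols, axis=2)
    row_counts = np.diff(np.append(rows, H))
    col_counts = np.diff(np.append(cols, W))
    counts = np.outer(row_counts, col_counts)[None, :, :]
    return ImagingStack(
        (sums / counts).astype(np.float32),
        frame_rate=stack.frame_rate,
        pixel_pitch=stack.pixel_pitch * f,
    )


def fft_rhythm_map(
    stack_ds: ImagingStack,
    band_hz: tuple[float, float],
    downsample_n: int = 1,
) -> RhythmMap:
    """Temporal FFT per composite pixel; max in-band magnitude as an image.

    Each composite pixel's time series is mean-subtracted and
    transformed with an unnormalized real FFT; the map records the
    maximum spectral magnitude over bins whose center frequency lies in
    ``band_hz`` (DC excluded). A band too narrow to contain a bin — for
    example when the cycle-period SD is zero — is widened to the nearest
    nonzero bin plus one bin on either side.
    """
    lo, hi = band_hz
    if not (0 <= lo <= hi):
        raise ValueError("invalid frequency band")
    T = stack_ds.frames.shape[0]
    freqs = np.fft.rfftfreq(T, d=1.0 / stack_ds.frame_rate)
    sel = np.flatnonzero((freqs >= lo) & (freqs <= hi) & (freqs > 0))
    if sel.size == 0:
        center = 0.5 * (lo + hi)
        nz = np.flatnonzero(freqs > 0)
        if nz.size == 0:
            raise ValueError("no nonzero FFT bins available")
        j = nz[np.argmin(np.abs(freqs[nz] - center))]
        sel = np.array(sorted({max(j - 1, 1), j, min(j + 1, freqs.size - 1)}))
    x = stack_ds.frames - stack_ds.frames.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=0)[sel])
    return RhythmMap(
        values=spec.max(axis=0),
        downsample_n=downsample_n,
        pixel_pitch_um=stack_ds.pixel_pitch,
        band_hz=(float(lo), float(hi)),
        bin_hz=(float(freqs[sel[0]]), float(freqs[sel[-1]])),
    )


def segment_rois(
    rmap: RhythmMap,
    full_shape: tuple[int, int] | None = None,
    min_diameter_um: float = 6.0,
) -> list[ROI]:
    """Threshold the rhythm map and extract contiguous regions as ROIs.

    Composite pixels at or below mean + 2*SD of all map values are
    zeroed; the survivors are labeled under 8-connectivity, and
    components whose equivalent circular diameter
    ``2*sqrt(area/pi) * pitch`` strictly exceeds ``min_diameter_um``
    (6 um — below a neuronal soma) are kept. Each ROI's
    full-resolution mask is the union of its composite pixels'
    constituent original pixels.
    """
    values = rmap.values
    binary = values > rmap.threshold
    labels = measure.label(binary, connectivity=2)
    f = 2**rmap.downsample_n
    if full_shape is None:
        full_shape = (values.shape[0] * f, values.shape[1] * f)
    rois = []
    for region in measure.regionprops(labels):
        d_um = 2.0 * np.sqrt(region.area / np.pi) * rmap.pixel_pitch_um
        if d_um <= min_diameter_um:
            continue
        mask = labels == region.label
        full = np.repeat(np.repeat(mask, f, axis=0), f, axis=1)[
            : full_shape[0], : full_shape[1]
        ]
        rois.append(
            ROI(
                roi_id=len(rois),
                mask=mask,
                mask_fullres=full,
                equivalent_diameter_um=float(d_um),
                centroid=tuple(float(c) for c in region.centroid),
            )
        )
    return rois


def forward_moving_average(x: np.ndarray, window: int = 4) -> np.ndarray:
    """Forward moving average: ``y[i] = mean(x[i : i + window])``.

    The trailing edge averages whatever samples remain, so the output
    has the input's length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    stop = np.minimum(np.arange(n) + window, n)
    counts = stop - np.arange(n)
    return (csum[stop] - csum[:n]) / counts


def compute_dff(stack: ImagingStack, roi: ROI, smooth_window: int = 4) -> DFFTrace:
    """dF/F0 trace of one ROI at the original stack resolution.

    F_i is the per-frame mean over the ROI's full-resolution pixels and
    F0 is the mean of F_i over the whole series, so the unsmoothed
    series has exactly zero mean by construction. The smoothed series
    applies a forward moving average (default 4 frames).
    """
    if not roi.mask_fullres.any():
        raise ValueError("ROI mask is empty")
    f_i = stack.frames[:, roi.mask_fullres].mean(axis=1).astype(float)
    f0 = f_i.mean()
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    dff = (f_i - f0) / f0
    return DFFTrace(
        values=dff,
        smoothed=forward_moving_average(dff, smooth_window),
        roi_id=roi.roi_id,
        frame_rate=stack.frame_rate,
        smooth_window=smooth_window,
    )
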