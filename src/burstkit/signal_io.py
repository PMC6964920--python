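"""Domain containers and file I/O for electrophysiology traces and imaging stacks.

Conventions
-----------
* Time is always in seconds; traces start at ``t0`` (0 by default) and event
  times are absolute seconds on that clock.
* Trace/event tables are plain CSV (comma separator, header row, ``.``
  decimal) so round trips are bit-exact for the printed precision.
* Imaging stacks are multi-page TIFFs; integer pixel data are promoted to
  float because downstream dF/F0 arithmetic needs reals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "AlignmentError",
    "Trace",
    "Recording",
    "ImagingStack",
    "DEFAULT_PIXEL_PITCH_UM",
    "load_recording",
    "save_recording",
    "load_stack",
    "save_stack",
    "save_events",
    "load_events",
]


class FormatError(ValueError):
    """A file or table does not have the expected layout or content."""


class AlignmentError(ValueError):
    """Two channels that must share a time base do not."""


#: Field of view of the two-photon rig emulated here: 256 x 256 pixels
#: spanning 116 x 116 um, i.e. ~0.4531 um per pixel.
DEFAULT_PIXEL_PITCH_UM = 116.0 / 256.0


@dataclass
class Trace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : array of float
        Signal values (volts, mV, or fluorescence a.u.).
    rate : float
        Sampling rate in samples per second; must be positive.
    label : str
        Channel name (e.g. ``"field"``, ``"xii"``, ``"vm"``).
    t0 : float
        Absolute time of the first sample, seconds.
    """

    samples: np.ndarray
    rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (``len / rate``)."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for absolute time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.samples.size - 1)


@dataclass
class Recording:
    """A named set of simultaneously acquired traces on one time base."""

    channels: dict[str, Trace]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        ref = next(iter(self.channels.values()))
        for name, tr in self.channels.items():
            if len(tr) != len(ref) or tr.rate != ref.rate or tr.t0 != ref.t0:
                raise AlignmentError(
                    f"channel {name!r} does not share the recording time base"
                )

    def __getitem__(self, name: str) -> Trace:
        return self.channels[name]

    @property
    def rate(self) -> float:
        return next(iter(self.channels.values())).rate

    @property
    def duration(self) -> float:
        return next(iter(self.channels.values())).duration


@dataclass
class ImagingStack:
    """A T x H x W fluorescence time series.

    ``pixel_pitch`` is the planar sampling in micrometres per pixel; the
    default matches a 116 um field of view scanned at 256 x 256.
    """

    frames: np.ndarray
    frame_rate: float = 32.0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.dtype.kind in "iub":
            self.frames = self.frames.astype(np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack must be T x H x W with T >= 2")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel pitch must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame rate must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate


def load_recording(
    path: str | Path,
    rate: float,
    column_map: dict[str, str] | None = None,
    t0: float = 0.0,
) -> Recording:
    """Load a multi-channel CSV as a :class:`Recording`.

    Parameters
    ----------
    path : file path
        CSV with a header row and one column per channel.
    rate : float
        Sampling rate of the file, samples per second.
    column_map : dict, optional
        Mapping ``channel name -> column name``. Defaults to every column
        under its own name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not rate > 0:
        raise ValueError("sampling rate must be positive")
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{path}: no data columns")
    if column_map is None:
        column_map = {c: c for c in df.columns}
    channels = {}
    for name, col in column_map.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            # pandas pads ragged columns with NaN, and non-numeric cells
            # coerce to NaN; both are format defects here.
            raise FormatError(f"{path}: column {col!r} is non-numeric or ragged")
        channels[name] = Trace(series.to_numpy(), rate=rate, label=name, t0=t0)
    return Recording(channels)


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to CSV, one column per channel."""
    df = pd.DataFrame({name: tr.samples for name, tr in rec.channels.items()})
    df.to_csv(path, index=False)


def load_stack(
    path: str | Path,
    frame_rate: float = 32.0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
) -> ImagingStack:
    """Load a multi-page TIFF as an :class:`ImagingStack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # corrupt / empty container
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise FormatError(f"{path}: single-page TIFF is not a time series")
    if frames.ndim != 3:
        raise FormatError(f"{path}: pages have mixed or non-planar shapes")
    return ImagingStack(frames, frame_rate=frame_rate, pixel_pitch=pixel_pitch)


def save_stack(stack: ImagingStack, path: str | Path) -> None:
    """Write a stack as a float32 multi-page TIFF."""
    tifffile.imwrite(path, stack.frames.astype(np.float32))


# Event-table serialization -------------------------------------------------

_EVENT_COLUMNS = [
    "onset_s",
    "peak_s",
    "offset_s",
    "amplitude",
    "area",
    "kind",
    "xii_concurrent",
]


def save_events(events, path: str | Path) -> None:
    """Write events to CSV, one row per event.

    Columns: onset_s, peak_s, offset_s, amplitude, area, kind,
    xii_concurrent. ``kind`` serializes as one of the strings
    ``burst`` / ``burstlet`` / ``sigh`` / ``unclassified``.
    """
    rows = []
    for ev in events:
        rows.append(
            {
                "onset_s": ev.onset_s,
                "peak_s": ev.peak_s,
                "offset_s": ev.offset_s,
                "amplitude": ev.amplitude,
                "area": ev.area,
                "kind": ev.kind,
                "xii_concurrent": ev.xii_concurrent,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def load_events(path: str | Path):
    """Read an event table written by :func:`save_events`."""
    from .event_analysis import Event  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        xii = row.xii_concurrent
        if pd.isna(xii):
            xii = None
        elif isinstance(xii, str):
            xii = xii.strip().lower() == "true"
        else:
            xii = bool(xii)
        events.append(
            Event(
                onset_s=float(row.onset_s),
                peak_s=float(row.peak_s),
                offset_s=float(row.offset_s),
                amplitude=float(row.amplitude),
                area=float(row.area),
                kind=str(row.kind),
                xii_concurrent=xii,
            )
        )
    return events
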