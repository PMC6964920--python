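"""Detection and classification of population events in field recordings.

An *event* is a suprathreshold excursion of the smoothed preBotC field
signal. Events are classified into three kinds:

* **burst** — field event with concurrent hypoglossal (XII) nerve
  discharge; drives motor output.
* **burstlet** — low-amplitude field event (empirically 15-65% of burst
  amplitude) with negligible concurrent XII activity; the putative
  rhythmogenic kernel.
* **sigh** — infrequent burst of larger area followed by a prolonged
  inter-event interval.

"Negligible" XII activity is operationalized as the XII channel never
exceeding its own baseline mean + 2*SD threshold anywhere in a padded
window around the field event.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .baseline_noise import NoiseModel
from .signal_io import AlignmentError, Trace

__all__ = [
    "Event",
    "SighCriteria",
    "detect_events",
    "classify_burst_burstlet",
    "classify_sighs",
    "measure_shape",
    "bilateral_synchrony",
    "match_events",
]


@dataclass
class Event:
    """One detected population event.

    Times are absolute seconds on the trace clock; ``amplitude`` is the
    peak value minus the local baseline mean, and ``area`` is the
    integral of the signal above the baseline mean between onset and
    offset (signal units x seconds).
    """

    onset_s: float
    peak_s: float
    offset_s: float
    amplitude: float
    area: float
    kind: str = "unclassified"
    xii_concurrent: bool | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ValueError("event requires onset <= peak <= offset")
        if self.kind not in ("burst", "burstlet", "sigh", "unclassified"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def rise_s(self) -> float:
        return self.peak_s - self.onset_s

    @property
    def decay_s(self) -> float:
        return self.offset_s - self.peak_s

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SighCriteria:
    """The three-part sigh test.

    A burst is reclassified as a sigh iff (i) its area exceeds the mean
    burst area by ``area_sd_mult`` SDs, (ii) the interval since the
    previous accepted sigh (or since recording start, for the first
    candidate) lies within ``[period_min_s, period_max_s]``, and (iii)
    the following inter-burst interval exceeds ``interval_mult`` times
    the mean cycle time of the ``lookback_cycles`` preceding cycles.
    """

    area_sd_mult: float = 1.0
    period_min_s: float = 60.0
    period_max_s: float = 240.0
    interval_mult: float = 1.3
    lookback_cycles: int = 6

    def __post_init__(self) -> None:
        if not (self.period_min_s < self.period_max_s):
            raise ValueError("period_min_s must be below period_max_s")
        for v in (self.area_sd_mult, self.period_min_s, self.interval_mult):
            if v <= 0:
                raise ValueError("sigh criteria must be positive")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_events(
    trace: Trace,
    model: NoiseModel,
    merge_gap_s: float = 0.15,
    min_duration_s: float = 0.15,
) -> list[Event]:
    """Detect suprathreshold events on a smoothed trace.

    Suprathreshold excursions separated by less than ``merge_gap_s`` are
    merged into one event (a refractory merge that prevents a noisy peak
    from being counted twice). Within each merged excursion the peak is
    the global maximum (earliest sample on ties), the onset is the last
    upward threshold crossing before the peak, and the offset is the
    first downward crossing after it. Excursions shorter than
    ``min_duration_s`` (default 150 ms, half the briefest burstlet
    durations reported in slices) are discarded: physiological events
    stay suprathreshold for hundreds of milliseconds, whereas threshold
    crossings of correlated baseline noise persist for at most a few
    noise correlation times.

    Returns time-ordered, non-overlapping events with amplitude and area
    measured against the interpolated baseline mean.
    """
    x = trace.samples
    t = trace.times
    thr = model.threshold_at(t)
    runs = _runs(x > thr)
    if not runs:
        return []

    gap = int(round(merge_gap_s * trace.rate))
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for r in runs[1:]:
        if r[0] - groups[-1][-1][1] < gap:
            groups[-1].append(r)
        else:
            groups.append([r])

    events = []
    for g in groups:
        lo, hi = g[0][0], g[-1][1]
        pk = lo + int(np.argmax(x[lo:hi]))
        onset = max(s for s, e in g if s <= pk)
        offset = min(e for s, e in g if e > pk)
        flags = ()
        if offset >= len(x):
            offset = len(x) - 1
            flags = ("offset_clamped",)
        if (offset - onset) / trace.rate < min_duration_s:
            continue
        seg_t = t[onset : offset + 1]
        baseline = model.mu_at(seg_t)
        area = float(np.trapezoid(x[onset : offset + 1] - baseline, seg_t))
        events.append(
            Event(
                onset_s=float(t[onset]),
                peak_s=float(t[pk]),
                offset_s=float(t[min(offset, len(x) - 1)]),
                amplitude=float(x[pk] - model.mu_at(t[pk])),
                area=area,
                flags=flags,
            )
        )
    return events


def classify_burst_burstlet(
    events: list[Event],
    xii: Trace,
    xii_model: NoiseModel,
    window_pad_s: float = 0.1,
    min_excursion_s: float = 0.1,
) -> list[Event]:
    """Split events into bursts and burstlets by XII concurrency.

    An event is a burstlet iff the XII trace shows negligible activity
    within ``[onset - pad, offset + pad]``; otherwise it is a burst
    (pending sigh reclassification). "Negligible" means the XII signal
    never sustains an excursion above its own noise threshold
    (mu + k*sigma) for ``min_excursion_s`` (100 ms) or longer: genuine
    XII discharge stays suprathreshold for the ~300-ms duration of the
    motor burst, whereas correlated baseline noise only pokes above the
    2*SD line for a few tens of milliseconds at a time. The pad absorbs the
    preinspiratory lag between field onset and XII onset.
    """
    out = []
    t_lo, t_hi = xii.t0, xii.t0 + xii.duration
    min_run = max(int(round(min_excursion_s * xii.rate)), 1)
    for ev in events:
        a = ev.onset_s - window_pad_s
        b = ev.offset_s + window_pad_s
        if b < t_lo or a > t_hi:
            raise AlignmentError(
                f"event at {ev.peak_s:.3f}s lies outside the XII trace span"
            )
        i0 = xii.index_at(a)
        i1 = xii.index_at(b) + 1
        seg = xii.samples[i0:i1]
        seg_t = xii.times[i0:i1]
        above = seg > xii_model.threshold_at(seg_t)
        concurrent = bool(any(e - s >= min_run for s, e in _runs(above)))
        out.append(
            dataclasses.replace(
                ev,
                kind="burst" if concurrent else "burstlet",
                xii_concurrent=concurrent,
            )
        )
    return out


def classify_sighs(
    events: list[Event],
    criteria: SighCriteria | None = None,
    t_start: float = 0.0,
) -> list[Event]:
    """Reclassify qualifying bursts as sighs.

    Only bursts are candidates; burstlets never affect the criteria
    (cycle times and areas are computed on the burst subsequence alone).
    Candidates are evaluated left to right so that criterion (ii) — the
    sigh-to-sigh period — refers to the previously *accepted* sigh. For
    the first candidate the interval is measured from ``t_start``
    (recording start) and the event is flagged ``first_sigh_provisional``.
    A trailing burst with no following interval cannot satisfy criterion
    (iii) and is left as a burst.
    """
    if criteria is None:
        criteria = SighCriteria()
    events = sorted(events, key=lambda e: e.peak_s)
    burst_idx = [i for i, e in enumerate(events) if e.kind in ("burst", "sigh")]
    if len(burst_idx) < 2:
        return events

    areas = np.array([events[i].area for i in burst_idx])
    area_thr = areas.mean() + criteria.area_sd_mult * areas.std()
    peaks = np.array([events[i].peak_s for i in burst_idx])
    intervals = np.diff(peaks)  # intervals[j] separates burst j and j+1

    out = list(events)
    last_sigh_t: float | None = None
    for j, i in enumerate(burst_idx):
        ev = events[i]
        if ev.area <= area_thr:
            continue
        # (ii) sigh period 1-4 min, from recording start for the first
        ref = t_start if last_sigh_t is None else last_sigh_t
        period = ev.peak_s - ref
        if not (criteria.period_min_s <= period <= criteria.period_max_s):
            continue
        # (iii) prolonged following interval vs preceding cycle time
        if j >= len(intervals):
            continue
        following = intervals[j]
        lb = criteria.lookback_cycles
        preceding = intervals[max(j - lb, 0) : j]
        flags = list(ev.flags)
        if preceding.size == 0:
            continue
        if preceding.size < lb:
            flags.append("short_lookback")
        if following <= criteria.interval_mult * preceding.mean():
            continue
        if last_sigh_t is None:
            flags.append("first_sigh_provisional")
        out[i] = dataclasses.replace(ev, kind="sigh", flags=tuple(flags))
        last_sigh_t = ev.peak_s
    return out


def _chord_edge(trace: Trace, model: NoiseModel, pk: int, amp: float, direction: int):
    """Extrapolated baseline intercept of one event flank.

    Walks from the peak in ``direction`` (-1 rising, +1 falling) down to
    the baseline, locates the last 25% and 75% amplitude crossings
    (sub-sample, by linear interpolation), and extrapolates the chord
    through them to the baseline. A detection threshold at k*SD clips
    the foot of an event; the chord intercept recovers the true edge of
    a ramp-like flank independent of the event's amplitude-to-noise
    ratio.
    """
    x = trace.samples
    t = trace.times
    base = model.mu_at(t[pk])
    # walk until the signal returns to baseline (or the trace ends)
    i = pk
    limit = len(x) - 1 if direction > 0 else 0
    while i != limit and x[i + direction] - base > 0:
        i += direction
    lo, hi = (i, pk) if direction < 0 else (pk, i)
    seg = x[lo : hi + 1] - base
    if seg.size < 3:
        return float(t[i]), False
    crossings = []
    for frac in (0.25, 0.75):
        level = frac * amp
        below = seg <= level
        if direction < 0:
            idx = np.flatnonzero(below[:-1] & ~below[1:])   # upward crossings
            if idx.size == 0:
                return float(t[i]), False
            j = idx[-1]
        else:
            idx = np.flatnonzero(~below[:-1] & below[1:])   # downward crossings
            if idx.size == 0:
                return float(t[i]), False
            j = idx[0] if frac == 0.75 else idx[-1]
        # sub-sample time of the crossing
        y0, y1 = seg[j], seg[j + 1]
        f = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
        crossings.append((t[lo + j] + f / trace.rate, level))
    (t25, v25), (t75, v75) = sorted(crossings, key=lambda c: c[1])
    if t75 == t25:
        return float(t[i]), False
    slope = (v75 - v25) / (t75 - t25)
    return float(t25 - v25 / slope), True


def measure_shape(
    event: Event, trace: Trace, model: NoiseModel, refine_edges: bool = True
) -> Event:
    """Re-measure an event's shape on a trace.

    With ``refine_edges`` (the default) the onset and offset are the
    baseline intercepts of the 25-75% amplitude chords of the rising
    and falling flanks, so rise, decay, and duration describe the full
    event rather than only its suprathreshold part. Amplitude is the
    peak value minus the local baseline mean and the area is the
    trapezoidal integral above the baseline between onset and offset.
    An offset beyond the trace end is clamped and flagged.
    """
    flags = [f for f in event.flags]
    pk = trace.index_at(event.peak_s)
    amp = float(trace.samples[pk] - model.mu_at(event.peak_s))

    onset_s, offset_s = event.onset_s, event.offset_s
    if refine_edges and amp > 0:
        on, ok_on = _chord_edge(trace, model, pk, amp, -1)
        off, ok_off = _chord_edge(trace, model, pk, amp, +1)
        if ok_on and on < event.peak_s:
            onset_s = on
        if ok_off and off > event.peak_s:
            offset_s = off

    end_t = trace.t0 + (len(trace) - 1) / trace.rate
    if offset_s > end_t:
        offset_s = end_t
        if "offset_clamped" not in flags:
            flags.append("offset_clamped")
    onset_s = max(onset_s, trace.t0)
    i0 = trace.index_at(onset_s)
    i1 = trace.index_at(offset_s)
    if i1 <= i0:
        raise ValueError("event indices collapse on this trace")
    seg_t = trace.times[i0 : i1 + 1]
    seg = trace.samples[i0 : i1 + 1]
    baseline = model.mu_at(seg_t)
    return dataclasses.replace(
        event,
        onset_s=float(onset_s),
        offset_s=float(offset_s),
        amplitude=amp,
        area=float(np.trapezoid(seg - baseline, seg_t)),
        flags=tuple(flags),
    )


def match_events(
    times_a: np.ndarray, times_b: np.ndarray, tol_s: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of two sorted event-time lists.

    Candidate pairs within ``tol_s`` are accepted in order of increasing
    time difference; each event is used at most once. Returns index
    pairs ``(i_a, i_b)``.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    pairs = [
        (abs(ta - tb), i, j)
        for i, ta in enumerate(times_a)
        for j, tb in enumerate(times_b)
        if abs(ta - tb) <= tol_s
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def bilateral_synchrony(
    events_left: list[Event],
    events_right: list[Event],
    tol_s: float = 0.25,
) -> float | None:
    """Fraction of left-channel events with a synchronous right partner.

    Matching is greedy nearest-neighbour on peak times with each right
    event used at most once. Returns ``None`` (flagged null) for an
    empty left list; an empty right list gives 0.0.
    """
    if not events_left:
        return None
    if not events_right:
        return 0.0
    left = np.array([e.peak_s for e in events_left])
    right = np.array([e.peak_s for e in events_right])
    matches = match_events(left, right, tol_s)
    return len(matches) / len(events_left)
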