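"""Per-cycle participation of imaged neurons in bursts and burstlets.

Given dF/F0 traces for a set of ROIs and an event table (bursts and
burstlets in imaging time), this module decides for each ROI x event
pair whether the neuron emitted a calcium transient during that cycle,
and summarizes the per-kind participation fractions.

The activity criterion is a threshold on the smoothed dF/F0: ROI r is
active in event e iff its maximum within ``[onset - 0.2 s,
offset + 0.5 s]`` exceeds ``mu_r + act_k * sigma_r``, where (mu_r,
sigma_r) are the ROI's statistics over event-free frames. The window is
padded asymmetrically because calcium-indicator decay outlasts the
electrical event. This criterion (and ``act_k = 3``) is the key
analyst-sensitive knob of the analysis and is deliberately exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .event_analysis import Event
from .imaging_roi import DFFTrace

__all__ = ["ParticipationMatrix", "score_participation", "participation_summary"]


@dataclass
class ParticipationMatrix:
    """Boolean (ROIs x events) activity matrix with per-event kinds."""

    active: np.ndarray          # bool, shape (n_rois, n_events)
    event_kinds: list[str]
    roi_ids: list[int]
    n_dropped_events: int = 0

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (len(self.roi_ids), len(self.event_kinds)):
            raise ValueError("matrix shape inconsistent with labels")


def score_participation(
    dff_traces: list[DFFTrace],
    events: list[Event],
    act_k: float = 3.0,
    pre_pad_s: float = 0.2,
    post_pad_s: float = 0.5,
    baseline_pad_s: float = 1.5,
    min_active_s: float = 0.1,
) -> ParticipationMatrix:
    """Score each ROI as active/inactive in each event.

    Baseline statistics use frames outside ``[onset - pre_pad_s,
    offset + baseline_pad_s]`` of every event; the wide trailing pad
    keeps the tail of slow indicator decay out of the baseline. The
    suprathreshold excursion must persist for ``min_active_s`` within
    the window: indicator transients decay over hundreds of
    milliseconds, so a single-frame exceedance is noise, not activity.
    Events whose activity window lies outside the imaging span are
    dropped.
    """
    if not dff_traces:
        raise ValueError("no dF/F0 traces supplied")
    rate = dff_traces[0].frame_rate
    n_frames = dff_traces[0].values.size
    t = np.arange(n_frames) / rate

    kept_events = []
    windows = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        lo, hi = ev.onset_s - pre_pad_s, ev.offset_s + post_pad_s
        idx = np.flatnonzero((t >= lo) & (t <= hi))
        if idx.size == 0:
            continue
        kept_events.append(ev)
        windows.append(idx)
    n_dropped = len(events) - len(kept_events)

    baseline_mask = np.ones(n_frames, dtype=bool)
    for ev in kept_events:
        lo, hi = ev.onset_s - pre_pad_s, ev.offset_s + baseline_pad_s
        baseline_mask &= ~((t >= lo) & (t <= hi))
    if baseline_mask.sum() < 10:
        raise ValueError("too few event-free frames for baseline statistics")

    min_run = max(int(round(min_active_s * rate)), 1)
    active = np.zeros((len(dff_traces), len(kept_events)), dtype=bool)
    for r, dff in enumerate(dff_traces):
        s = dff.smoothed
        if s.size != n_frames:
            raise ValueError("dF/F0 traces must share one time base")
        mu = s[baseline_mask].mean()
        sd = s[baseline_mask].std()
        thr = mu + act_k * sd
        for c, idx in enumerate(windows):
            above = s[idx] > thr
            if above.sum() < min_run:
                continue
            # longest consecutive suprathreshold run in the window
            run = best = 0
            for flag in above:
                run = run + 1 if flag else 0
                best = max(best, run)
            active[r, c] = best >= min_run

    return ParticipationMatrix(
        active=active,
        event_kinds=[ev.kind for ev in kept_events],
        roi_ids=[dff.roi_id for dff in dff_traces],
        n_dropped_events=n_dropped,
    )


def participation_summary(matrix: ParticipationMatrix) -> dict:
    """Per-kind participation fractions and per-ROI rates.

    For each event kind, the per-event fraction of active ROIs is
    averaged over events (mean and SD); kinds without events report
    ``None``. Also returns each ROI's per-kind participation rate and
    the pooled fraction of active (ROI, event) pairs.
    """
    kinds = np.asarray(matrix.event_kinds)
    out: dict = {"per_kind": {}, "per_roi": {}, "pooled": {}}
    for kind in ("burst", "burstlet"):
        cols = np.flatnonzero(kinds == kind)
        if cols.size == 0:
            out["per_kind"][kind] = None
            out["per_roi"][kind] = None
            out["pooled"][kind] = None
            continue
        sub = matrix.active[:, cols]
        per_event = sub.mean(axis=0)
        out["per_kind"][kind] = {
            "mean": float(per_event.mean()),
            "sd": float(per_event.std()),
            "n_events": int(cols.size),
        }
        out["per_roi"][kind] = sub.mean(axis=1)
        out["pooled"][kind] = float(sub.mean())
    return out
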