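"""Synthetic recordings and imaging stacks with full ground truth.

Every pipeline stage in this package can be exercised without real data:
this module generates (a) preBotC field + XII nerve recordings containing
bursts, burstlets, and sighs on a noisy baseline, (b) whole-cell membrane
traces with spiking bursts and EPSP-staircase burstlets, and (c)
two-photon stacks of disk-shaped neurons with calcium transients and
heterogeneous per-cycle participation. Each generator also returns a
:class:`GroundTruth` record (planted event times and kinds, ROI masks,
participation matrix) that tests use as the oracle.

Default parameters emulate the conditions of slice experiments at
moderate-to-high excitability: ~0.1 Hz composite rhythm with gamma-
distributed cycle intervals, burstlet amplitudes drawn from 15-65% of the
burst amplitude, burstlet rise/decay around 155/198 ms, 32-Hz imaging of
a 116-um field at 256 x 256 pixels with a ~7-s collective period, near-
complete burst participation and ~20% burstlet participation. The
generators are phenomenological: they plant waveforms, not a biophysical
network model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal_io import DEFAULT_PIXEL_PITCH_UM, ImagingStack, Recording, Trace

__all__ = [
    "FieldSimConfig",
    "MembraneSimConfig",
    "ImagingSimConfig",
    "TruthEvent",
    "GroundTruth",
    "simulate_field_recording",
    "simulate_membrane_trace",
    "simulate_imaging_stack",
]


@dataclass
class TruthEvent:
    """One planted event, in absolute seconds."""

    onset_s: float
    peak_s: float
    offset_s: float
    kind: str                      # burst | burstlet | sigh
    amplitude: float
    xii_onset_s: float | None = None


@dataclass
class GroundTruth:
    """The generator's record of everything it planted."""

    events: list[TruthEvent] = field(default_factory=list)
    roi_masks: np.ndarray | None = None        # (n_cells, H, W) bool
    distractor_masks: np.ndarray | None = None
    participation: np.ndarray | None = None    # (n_cells, n_events) bool
    params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        """Internal-consistency checks of the planted record."""
        dur = self.params.get("duration_s")
        if dur is not None:
            for ev in self.events:
                if not (0 <= ev.onset_s <= ev.offset_s <= dur + 1e-9):
                    raise AssertionError("planted event outside the recording")
        if self.participation is not None and self.roi_masks is not None:
            if self.participation.shape != (
                self.roi_masks.shape[0],
                len(self.events),
            ):
                raise AssertionError("participation matrix shape mismatch")


# --------------------------------------------------------------------------
# field + XII recordings


@dataclass
class FieldSimConfig:
    """Parameters for the field/XII generator.

    Amplitudes are in arbitrary units of the smoothed recording; burst
    amplitude 1.0 with baseline noise SD 0.04 puts even the smallest
    burstlet (15% of a burst) at ~4 noise SDs. Cycle intervals are
    gamma-distributed with shape 4 (interval CV 0.5, in the range seen
    in slices at moderate excitability).
    """

    duration_s: float = 600.0
    rate: float = 2000.0
    burst_rate_hz: float = 0.1
    burstlet_prob: float = 0.3
    burst_amp: float = 1.0
    burstlet_amp_frac: tuple[float, float] = (0.15, 0.65)
    rise_ms: float = 155.6          # burstlet rise time
    decay_ms: float = 198.2         # burstlet decay time
    preinsp_ms: float = 400.0       # preinspiratory ramp of bursts
    preinsp_frac: float = 0.3       # ramp height as a fraction of burst amp
    interval_shape: float = 4.0     # gamma shape of cycle intervals
    noise_sd: float = 0.04
    noise_tau_s: float = 0.02       # correlation time of the smoothed noise
    baseline: float = 0.2
    xii_amp: float = 1.0
    xii_rise_ms: float = 100.0
    xii_decay_ms: float = 250.0
    xii_noise_sd: float | None = None   # defaults to noise_sd
    sigh_every_s: float | None = None
    sigh_area_mult: float = 3.0
    post_sigh_interval_mult: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.burstlet_amp_frac
        if not (0 < lo <= hi <= 1):
            raise ValueError("burstlet_amp_frac must be a range within (0, 1]")
        if not (0 <= self.burstlet_prob <= 1):
            raise ValueError("burstlet_prob must lie in [0, 1]")
        event_dur = (self.preinsp_ms + self.rise_ms + self.decay_ms) / 1000.0
        if 1.0 / self.burst_rate_hz < 2.0 * event_dur:
            raise ValueError("event rate too high for the event duration")


def _smoothstep(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, max(n, 2))
    return u * u * (3.0 - 2.0 * u)


def _ramp_peak_wave(
    rate, rise_s, decay_s, amp, preinsp_s=0.0, preinsp_frac=0.0, round_s=0.01
):
    """Piecewise-linear event waveform with a rounded peak.

    Flanks are linear ramps (so onset, peak, and offset are geometrically
    well defined); a light Gaussian smoothing of width ``round_s`` rounds
    the apex, as in recorded population events. Returns
    ``(wave, peak_index, pad)`` where ``pad`` is the number of leading
    zero samples added for the smoothing support.
    """
    parts = []
    if preinsp_s > 0:
        n_p = max(int(round(preinsp_s * rate)), 2)
        parts.append(np.linspace(0.0, preinsp_frac * amp, n_p, endpoint=False))
        start = preinsp_frac * amp
    else:
        start = 0.0
    n_r = max(int(round(rise_s * rate)), 2)
    parts.append(np.linspace(start, amp, n_r, endpoint=False))
    n_d = max(int(round(decay_s * rate)), 2)
    parts.append(np.linspace(amp, 0.0, n_d))
    wave = np.concatenate(parts)
    sigma = round_s * rate
    if sigma >= 1:
        pad = int(round(4 * sigma))
        wave = np.concatenate([np.zeros(pad), wave, np.zeros(pad)])
        wave = gaussian_filter1d(wave, sigma=sigma)
    else:
        pad = 0
    return wave, int(np.argmax(wave)), pad


def _colored_noise(rng, n, sd, tau_samples):
    """Gaussian noise with ~tau_samples correlation time and exact SD."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if tau_samples >= 1:
        w = gaussian_filter1d(w, sigma=tau_samples, mode="wrap")
    s = w.std()
    return w * (sd / s) if s > 0 else w


def _event_schedule(rng, cfg: FieldSimConfig):
    """Gamma-interval event times with optional sigh insertions."""
    mean_iv = 1.0 / cfg.burst_rate_hz
    scale = mean_iv / cfg.interval_shape
    times, kinds = [], []
    t = float(rng.gamma(cfg.interval_shape, scale))
    next_sigh = cfg.sigh_every_s
    margin = (cfg.preinsp_ms + cfg.rise_ms + cfg.decay_ms) / 1000.0 + 0.5
    while t < cfg.duration_s - margin:
        if next_sigh is not None and t >= next_sigh:
            kinds.append("sigh")
            next_sigh += cfg.sigh_every_s
            iv = max(
                float(rng.gamma(cfg.interval_shape, scale)),
                cfg.post_sigh_interval_mult * mean_iv,
            )
        else:
            kinds.append("burstlet" if rng.random() < cfg.burstlet_prob else "burst")
            iv = float(rng.gamma(cfg.interval_shape, scale))
        times.append(t)
        t += max(iv, 1.5 * margin)
    return times, kinds


def simulate_field_recording(cfg: FieldSimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a field + XII recording pair with planted events.

    Bursts carry a preinspiratory ramp followed by a full-amplitude peak
    and an XII discharge that starts at the ramp-to-peak transition.
    Burstlets are ramp-only events with amplitude drawn uniformly from
    ``burstlet_amp_frac`` times the burst amplitude and no XII partner.
    Sighs (if scheduled) are bursts whose amplitude is scaled by
    ``sigh_area_mult`` and which are followed by a prolonged interval.
    Correlated Gaussian noise rides on a constant baseline, emulating
    the residual fluctuation of an RMS-smoothed recording.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    xii_sd = cfg.noise_sd if cfg.xii_noise_sd is None else cfg.xii_noise_sd

    field_sig = np.zeros(n)
    xii_sig = np.zeros(n)
    times, kinds = _event_schedule(rng, cfg)

    truth_events = []
    for t_on, kind in zip(times, kinds):
        if kind == "burstlet":
            frac = rng.uniform(*cfg.burstlet_amp_frac)
            amp = frac * cfg.burst_amp
            wave, pk, pad = _ramp_peak_wave(
                cfg.rate, cfg.rise_ms / 1e3, cfg.decay_ms / 1e3, amp
            )
            xii_onset = None
        else:
            amp = cfg.burst_amp * (cfg.sigh_area_mult if kind == "sigh" else 1.0)
            wave, pk, pad = _ramp_peak_wave(
                cfg.rate,
                cfg.rise_ms / 1e3,
                cfg.decay_ms / 1e3,
                amp,
                preinsp_s=cfg.preinsp_ms / 1e3,
                preinsp_frac=cfg.preinsp_frac,
            )
            xii_onset = t_on + cfg.preinsp_ms / 1e3
            xw, _, xpad = _ramp_peak_wave(
                cfg.rate, cfg.xii_rise_ms / 1e3, cfg.xii_decay_ms / 1e3, cfg.xii_amp
            )
            j = max(int(round(xii_onset * cfg.rate)) - xpad, 0)
            stop = min(j + xw.size, n)
            xii_sig[j:stop] += xw[: stop - j]
        # the smoothing pad sits before the nominal onset corner
        i0 = max(int(round(t_on * cfg.rate)) - pad, 0)
        stop = min(i0 + wave.size, n)
        field_sig[i0:stop] += wave[: stop - i0]
        truth_events.append(
            TruthEvent(
                onset_s=t_on,
                peak_s=(i0 + pk) / cfg.rate,
                offset_s=t_on + (wave.size - 2 * pad) / cfg.rate,
                kind=kind,
                amplitude=float(wave.max()),
                xii_onset_s=xii_onset,
            )
        )

    tau = cfg.noise_tau_s * cfg.rate
    field_sig += cfg.baseline + _colored_noise(rng, n, cfg.noise_sd, tau)
    xii_sig += cfg.baseline + _colored_noise(rng, n, xii_sd, tau)

    rec = Recording(
        {
            "field": Trace(field_sig, rate=cfg.rate, label="field"),
            "xii": Trace(xii_sig, rate=cfg.rate, label="xii"),
        }
    )
    truth = GroundTruth(
        events=truth_events,
        params={"duration_s": cfg.duration_s, "noise_sd": cfg.noise_sd,
                "baseline": cfg.baseline, "rate": cfg.rate},
        seed=cfg.seed,
    )
    truth.validate()
    return rec, truth


# --------------------------------------------------------------------------
# whole-cell membrane traces


@dataclass
class MembraneSimConfig:
    """Parameters for the whole-cell membrane-potential generator.

    The baseline sits at -60 mV. Bursts are >20-mV drive-potential
    envelopes carrying brief biphasic spikes; burstlets are summating
    EPSP staircases whose envelope peaks between 6 and 10 mV.
    """

    duration_s: float = 120.0
    rate: float = 4000.0
    event_rate_hz: float = 0.15
    burstlet_prob: float = 0.5
    baseline_mv: float = -60.0
    burst_amp_mv: float = 22.0
    burstlet_amp_range: tuple[float, float] = (6.0, 10.0)
    envelope_rise_ms: float = 150.0
    envelope_decay_ms: float = 250.0
    spike_amp_mv: float = 40.0
    spike_ms: float = 2.0
    spike_rate_hz: float = 30.0
    epsp_tau_ms: float = 25.0
    epsp_spacing_ms: float = 25.0
    noise_sd_mv: float = 0.3
    noise_tau_s: float = 0.005
    interval_shape: float = 4.0
    seed: int = 0


def _alpha_kernel(rate, tau_s, length_s):
    t = np.arange(0, length_s, 1.0 / rate)
    k = (t / tau_s) * np.exp(1.0 - t / tau_s)
    return k


def simulate_membrane_trace(cfg: MembraneSimConfig) -> tuple[Trace, GroundTruth]:
    """Generate a whole-cell V_m trace with bursts and burstlet staircases."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    vm = np.zeros(n)

    mean_iv = 1.0 / cfg.event_rate_hz
    scale = mean_iv / cfg.interval_shape
    t = float(rng.gamma(cfg.interval_shape, scale)) + 1.0
    truth_events = []
    while t < cfg.duration_s - 2.0:
        i_on = int(round(t * cfg.rate))
        if rng.random() < cfg.burstlet_prob:
            # burstlet: summating EPSPs, envelope peak in 6-10 mV
            target = rng.uniform(*cfg.burstlet_amp_range)
            n_epsp = int(rng.integers(6, 10))
            kern = _alpha_kernel(cfg.rate, cfg.epsp_tau_ms / 1e3, 0.4)
            wave = np.zeros(int(0.9 * cfg.rate))
            for j in range(n_epsp):
                off = int(round(j * cfg.epsp_spacing_ms / 1e3 * cfg.rate))
                seg = wave[off : off + kern.size]
                seg += kern[: seg.size]
            wave *= target / wave.max()
            kind, amp = "burstlet", target
        else:
            wave, _, _ = _ramp_peak_wave(
                cfg.rate,
                cfg.envelope_rise_ms / 1e3,
                cfg.envelope_decay_ms / 1e3,
                cfg.burst_amp_mv,
            )
            wave = wave.copy()
            env_peak = float(wave.max())
            # biphasic spikes while the envelope is high
            hot = np.flatnonzero(wave > 0.4 * cfg.burst_amp_mv)
            if hot.size:
                n_sp = int(round(hot.size / cfg.rate * cfg.spike_rate_hz))
                sp_len = max(int(round(cfg.spike_ms / 1e3 * cfg.rate)), 4)
                spike = np.sin(np.linspace(0, 2 * np.pi, sp_len)) * cfg.spike_amp_mv
                for st in rng.choice(hot[:-sp_len], size=max(n_sp, 1), replace=False):
                    wave[st : st + sp_len] += spike
            kind, amp = "burst", env_peak
        stop = min(i_on + wave.size, n)
        vm[i_on:stop] += wave[: stop - i_on]
        pk = i_on + int(np.argmax(wave[: stop - i_on]))
        truth_events.append(
            TruthEvent(
                onset_s=t,
                peak_s=pk / cfg.rate,
                offset_s=(stop - 1) / cfg.rate,
                kind=kind,
                amplitude=amp,
            )
        )
        t += max(float(rng.gamma(cfg.interval_shape, scale)), 1.5)

    vm += cfg.baseline_mv + _colored_noise(
        rng, n, cfg.noise_sd_mv, cfg.noise_tau_s * cfg.rate
    )
    trace = Trace(vm, rate=cfg.rate, label="vm")
    truth = GroundTruth(
        events=truth_events,
        params={"duration_s": cfg.duration_s, "baseline_mv": cfg.baseline_mv},
        seed=cfg.seed,
    )
    truth.validate()
    return trace, truth


# --------------------------------------------------------------------------
# imaging stacks


@dataclass
class ImagingSimConfig:
    """Parameters for the two-photon stack generator.

    Defaults emulate a 2-min series at 32 Hz over a 116-um field
    (256 x 256 pixels): disk-shaped somata of ~11 um diameter, a ~7-s
    collective period, near-complete participation in bursts and ~20%
    participation in burstlets, GCaMP6f-like transient kinetics, and a
    transient-to-noise ratio of 4. One optional distractor cell
    oscillates sinusoidally at a multiple of the collective frequency
    and must never be segmented.
    """

    shape: tuple[int, int, int] = (3840, 256, 256)
    frame_rate: float = 32.0
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    n_cells: int = 12
    cell_radius_px: int = 12
    min_gap_px: int = 12
    collective_period_s: float = 7.0
    period_jitter_s: float = 0.7
    burstlet_prob: float = 0.25
    participation_p_burst: float = 0.95
    participation_p_burstlet: float = 0.2
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5
    cell_baseline: float = 100.0
    transient_amp: float = 40.0
    background: float = 20.0
    photon_noise_sd: float = 10.0
    n_distractors: int = 1
    distractor_freq_mult: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.burstlet_prob, self.participation_p_burst,
                  self.participation_p_burstlet):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def _place_disks(rng, n_disks, hw, radius, min_gap, max_tries=20000):
    """Non-overlapping disk centers by rejection sampling."""
    H, W = hw
    margin = radius + 2
    min_d2 = (2 * radius + min_gap) ** 2
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_disks:
        tries += 1
        if tries > max_tries:
            raise ValueError("infeasible cell packing for this field size")
        r = int(rng.integers(margin, H - margin))
        c = int(rng.integers(margin, W - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def _disk_mask(hw, center, radius):
    H, W = hw
    rr, cc = np.ogrid[:H, :W]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _calcium_kernel(rate, rise_s, decay_s):
    t = np.arange(0, rise_s + 6.0 * decay_s, 1.0 / rate)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def simulate_imaging_stack(cfg: ImagingSimConfig) -> tuple[ImagingStack, GroundTruth]:
    """Generate a fluorescence stack of rhythmically active disk neurons.

    Each cell adds a calcium-kernel transient for every collective event
    it participates in (Bernoulli per cell and event, with separate
    probabilities for bursts and burstlets); distractor cells modulate
    sinusoidally at ``distractor_freq_mult`` times the collective
    frequency. Gaussian photon noise is added per pixel and frame and
    the result is clipped at zero.
    """
    rng = np.random.default_rng(cfg.seed)
    T, H, W = cfg.shape
    dt = 1.0 / cfg.frame_rate
    duration = T * dt

    centers = _place_disks(
        rng, cfg.n_cells + cfg.n_distractors, (H, W), cfg.cell_radius_px,
        cfg.min_gap_px,
    )
    cell_centers = centers[: cfg.n_cells]
    distractor_centers = centers[cfg.n_cells :]
    roi_masks = np.stack(
        [_disk_mask((H, W), c, cfg.cell_radius_px) for c in cell_centers]
    )
    distractor_masks = (
        np.stack([_disk_mask((H, W), c, cfg.cell_radius_px) for c in distractor_centers])
        if distractor_centers
        else None
    )

    # collective event schedule: jittered periodic
    times, kinds = [], []
    t = cfg.collective_period_s
    while t < duration - 2.0 * cfg.kernel_decay_s:
        times.append(t)
        kinds.append("burstlet" if rng.random() < cfg.burstlet_prob else "burst")
        t += max(
            cfg.collective_period_s + cfg.period_jitter_s * rng.standard_normal(),
            0.3 * cfg.collective_period_s,
        )
    n_events = len(times)

    participation = np.zeros((cfg.n_cells, n_events), dtype=bool)
    for e, kind in enumerate(kinds):
        p = (
            cfg.participation_p_burst
            if kind == "burst"
            else cfg.participation_p_burstlet
        )
        participation[:, e] = rng.random(cfg.n_cells) < p

    frames = np.full((T, H, W), cfg.background, dtype=np.float32)
    kernel = _calcium_kernel(cfg.frame_rate, cfg.kernel_rise_s, cfg.kernel_decay_s)
    frame_t = np.arange(T) * dt

    for c in range(cfg.n_cells):
        sig = np.zeros(T, dtype=np.float32)
        for e, t_ev in enumerate(times):
            if not participation[c, e]:
                continue
            i0 = int(round(t_ev * cfg.frame_rate))
            stop = min(i0 + kernel.size, T)
            sig[i0:stop] += kernel[: stop - i0]
        mask = roi_masks[c]
        frames[:, mask] += (
            cfg.cell_baseline + cfg.transient_amp * sig[:, None]
        ).astype(np.float32)

    f_collective = 1.0 / cfg.collective_period_s
    for d, mask in enumerate(distractor_masks if distractor_masks is not None else []):
        f_d = cfg.distractor_freq_mult * f_collective
        phase = rng.uniform(0, 2 * np.pi)
        sig = 0.5 * (1.0 + np.sin(2 * np.pi * f_d * frame_t + phase))
        frames[:, mask] += (
            cfg.cell_baseline + cfg.transient_amp * sig[:, None]
        ).astype(np.float32)

    # chunked noise keeps the transient allocation bounded
    if cfg.photon_noise_sd > 0:
        chunk = max(1, int(2e8 // (H * W * 4)))
        for s in range(0, T, chunk):
            e = min(s + chunk, T)
            frames[s:e] += cfg.photon_noise_sd * rng.standard_normal(
                (e - s, H, W), dtype=np.float32
            )
    np.maximum(frames, 0.0, out=frames)

    event_len = cfg.kernel_rise_s + cfg.kernel_decay_s
    truth = GroundTruth(
        events=[
            TruthEvent(
                onset_s=t_ev,
                peak_s=t_ev + cfg.kernel_rise_s,
                offset_s=t_ev + event_len,
                kind=kind,
                amplitude=cfg.transient_amp,
            )
            for t_ev, kind in zip(times, kinds)
        ],
        roi_masks=roi_masks,
        distractor_masks=distractor_masks,
        participation=participation,
        params={"duration_s": duration, "frame_rate": cfg.frame_rate,
                "collective_period_s": cfg.collective_period_s},
        seed=cfg.seed,
    )
    truth.validate()
    stack = ImagingStack(
        frames, frame_rate=cfg.frame_rate, pixel_pitch=cfg.pixel_pitch
    )
    return stack, truth
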