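import dataclasses

import numpy as np
import pytest

import burstkit as bk
from tests.conftest import make_trace


def triangle(n_rise, n_decay, amp):
    return np.concatenate(
        [np.linspace(0, amp, n_rise, endpoint=False), np.linspace(amp, 0, n_decay)]
    )


class TestDetect:
    def test_subthreshold_trace_gives_no_events(self, flat_model):
        rng = np.random.default_rng(0)
        tr = make_trace(0.02 * np.sin(np.linspace(0, 20, 2000)), rate=1000.0)
        assert bk.detect_events(tr, flat_model) == []

    def test_single_planted_event_located(self, flat_model):
        # triangular event peaking at 6 sigma at t = 5.0 s in Gaussian noise
        rng = np.random.default_rng(1)
        rate = 1000.0
        x = rng.normal(0, 0.05, 10_000)
        wave = triangle(200, 200, 0.30)
        x[4800:4800 + wave.size] += wave
        events = bk.detect_events(make_trace(x, rate=rate), flat_model)
        assert len(events) == 1
        assert events[0].peak_s == pytest.approx(5.0, abs=0.05)

    def test_events_ordered_disjoint_and_suprathreshold(self, classified_field):
        rec, _, events, model, _ = classified_field
        assert len(events) > 10
        for prev, nxt in zip(events, events[1:]):
            assert prev.offset_s <= nxt.onset_s
        for ev in events:
            peak_val = rec["field"].samples[rec["field"].index_at(ev.peak_s)]
            assert peak_val > model.threshold_at(ev.peak_s)

    def test_recall_and_precision_on_planted_events(self, classified_field):
        _, truth, events, _, _ = classified_field
        truth_peaks = [e.peak_s for e in truth.events]
        det_peaks = [e.peak_s for e in events]
        matches = bk.match_events(truth_peaks, det_peaks, tol_s=0.2)
        assert len(matches) / len(truth_peaks) >= 0.95
        assert len(matches) / len(det_peaks) >= 0.95


class TestBurstBurstletClassification:
    def test_coincident_xii_deflection_makes_burst(self, flat_model):
        ev = bk.Event(1.0, 1.2, 1.4, amplitude=0.3, area=0.05)
        xii = np.zeros(3000)
        xii[1000:1400] = 0.25  # 5 sigma on the XII channel
        [out] = bk.classify_burst_burstlet(
            [ev], make_trace(xii), flat_model
        )
        assert out.kind == "burst" and out.xii_concurrent

    def test_flat_xii_makes_burstlet(self, flat_model):
        ev = bk.Event(1.0, 1.2, 1.4, amplitude=0.3, area=0.05)
        [out] = bk.classify_burst_burstlet(
            [ev], make_trace(np.zeros(3000)), flat_model
        )
        assert out.kind == "burstlet" and not out.xii_concurrent

    def test_planted_labels_recovered(self, classified_field):
        _, truth, events, _, _ = classified_field
        matches = bk.match_events(
            [e.peak_s for e in truth.events], [e.peak_s for e in events], 0.2
        )
        agree = sum(
            (truth.events[i].kind == "burstlet") == (events[j].kind == "burstlet")
            for i, j in matches
        )
        assert agree / len(matches) >= 0.95

    def test_relabeling_is_idempotent(self, classified_field):
        rec, _, events, _, xii_model = classified_field
        again = bk.classify_burst_burstlet(events, rec["xii"], xii_model)
        assert [e.kind for e in again] == [e.kind for e in events]


def _burst(t, area):
    return bk.Event(t - 0.2, t, t + 0.2, amplitude=area, area=area, kind="burst",
                    xii_concurrent=True)


def sigh_schedule():
    """Bursts every 10 s (area 1) with two area-3 events 120 s apart,
    each followed by a 20-s gap."""
    events = []
    t = 10.0
    while t < 120.0:
        events.append(_burst(t, 1.0))
        t += 10.0
    events.append(_burst(120.0, 3.0))
    t = 140.0
    while t < 240.0:
        events.append(_burst(t, 1.0))
        t += 10.0
    events.append(_burst(240.0, 3.0))
    t = 260.0
    while t <= 350.0:
        events.append(_burst(t, 1.0))
        t += 10.0
    return events


class TestSighs:
    def test_identical_areas_never_sigh(self):
        events = [_burst(10.0 * k, 1.0) for k in range(1, 30)]
        out = bk.classify_sighs(events)
        assert all(e.kind == "burst" for e in out)

    def test_planted_schedule_flags_exactly_two(self):
        out = bk.classify_sighs(sigh_schedule())
        sighs = [e.peak_s for e in out if e.kind == "sigh"]
        assert sighs == [120.0, 240.0]

    def test_large_area_without_prolonged_interval_rejected(self):
        # a big event followed by a normal 10-s cycle fails criterion (iii)
        events = [_burst(10.0 * k, 1.0) for k in range(1, 12)]
        events.append(_burst(120.0, 3.0))
        events.append(_burst(130.0, 1.0))
        out = bk.classify_sighs(events)
        assert all(e.kind != "sigh" for e in out)

    def test_flags_invariant_to_added_burstlets(self):
        base = sigh_schedule()
        with_burstlets = sorted(
            base
            + [
                bk.Event(t - 0.1, t, t + 0.1, amplitude=0.3, area=0.2,
                         kind="burstlet", xii_concurrent=False)
                for t in np.arange(15.0, 340.0, 30.0)
            ],
            key=lambda e: e.peak_s,
        )
        out_a = {e.peak_s for e in bk.classify_sighs(base) if e.kind == "sigh"}
        out_b = {
            e.peak_s for e in bk.classify_sighs(with_burstlets) if e.kind == "sigh"
        }
        assert out_a == out_b == {120.0, 240.0}


class TestShape:
    def test_symmetric_triangle(self, flat_model):
        rate = 1000.0
        x = np.zeros(3000)
        wave = triangle(200, 201, 1.0)  # base 0.4 s
        x[1000:1000 + wave.size] += wave
        tr = make_trace(x, rate=rate)
        model = bk.NoiseModel(centers=[0.0], mu=[0.0], sigma=[0.01], k=2.0)
        [ev] = bk.detect_events(tr, model)
        ev = bk.measure_shape(ev, tr, model)
        assert ev.rise_s == pytest.approx(0.2, abs=0.01)
        assert ev.decay_s == pytest.approx(0.2, abs=0.01)
        assert ev.duration_s == pytest.approx(0.4, abs=0.02)
        # triangle area = A * b / 2
        assert ev.area == pytest.approx(1.0 * 0.4 / 2, rel=0.03)

    def test_burstlet_kinetics_recovered_from_simulation(self):
        # generator plants rise 155.6 ms / decay 198.2 ms burstlets
        cfg = bk.FieldSimConfig(
            duration_s=600.0, burstlet_prob=1.0, burstlet_amp_frac=(0.2, 0.65),
            seed=5,
        )
        rec, truth = bk.simulate_field_recording(cfg)
        model = bk.fit_noise_model(rec["field"])
        events = [
            bk.measure_shape(e, rec["field"], model)
            for e in bk.detect_events(rec["field"], model)
        ]
        assert len(events) >= 30
        rise = np.mean([e.rise_s for e in events])
        decay = np.mean([e.decay_s for e in events])
        assert rise == pytest.approx(cfg.rise_ms / 1e3, abs=0.020)
        assert decay == pytest.approx(cfg.decay_ms / 1e3, abs=0.020)


class TestBilateralSynchrony:
    def _ev(self, t):
        return bk.Event(t - 0.1, t, t + 0.1, amplitude=0.3, area=0.05,
                        kind="burstlet")

    def test_identical_lists_fully_synchronous(self):
        left = [self._ev(5.0 * k) for k in range(1, 10)]
        assert bk.bilateral_synchrony(left, list(left)) == 1.0

    def test_empty_right_gives_zero(self):
        assert bk.bilateral_synchrony([self._ev(1.0)], []) == 0.0

    def test_empty_left_is_null(self):
        assert bk.bilateral_synchrony([], [self._ev(1.0)]) is None

    def test_partial_matching_fraction(self):
        # 20 synchronous pairs plus 5 unmatched left events -> 20/25
        left = [self._ev(5.0 * k) for k in range(1, 26)]
        right = [self._ev(5.0 * k + 0.05) for k in range(1, 21)]
        assert bk.bilateral_synchrony(left, right, tol_s=0.25) == pytest.approx(0.8)
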