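import numpy as np
import pytest

import burstkit as bk


@pytest.fixture(scope="session")
def classified_field():
    """A 10-min mixed burst/burstlet recording run through the pipeline.

    Returns (recording, truth, events, field_model, xii_model) with
    events already burst/burstlet-classified.
    """
    cfg = bk.FieldSimConfig(
        duration_s=600.0,
        burstlet_prob=0.5,
        burstlet_amp_frac=(0.2, 0.65),
        seed=11,
    )
    rec, truth = bk.simulate_field_recording(cfg)
    model = bk.fit_noise_model(rec["field"])
    xii_model = bk.fit_noise_model(rec["xii"])
    events = bk.detect_events(rec["field"], model)
    events = bk.classify_burst_burstlet(events, rec["xii"], xii_model)
    return rec, truth, events, model, xii_model


@pytest.fixture(scope="session")
def small_imaging():
    """A small imaging stack (64 x 64, ~40 s) with three planted cells."""
    cfg = bk.ImagingSimConfig(
        shape=(1280, 64, 64),
        n_cells=3,
        cell_radius_px=8,
        min_gap_px=8,
        collective_period_s=4.0,
        period_jitter_s=0.2,
        burstlet_prob=0.0,
        participation_p_burst=1.0,
        n_distractors=0,
        seed=7,
    )
    stack, truth = bk.simulate_imaging_stack(cfg)
    return cfg, stack, truth


def make_trace(samples, rate=1000.0, **kw):
    return bk.Trace(np.asarray(samples, dtype=float), rate=rate, **kw)


@pytest.fixture
def flat_model():
    """A constant noise model: mu 0, sigma 0.05, threshold 0.10."""
    return bk.NoiseModel(centers=[0.0], mu=[0.0], sigma=[0.05], k=2.0)
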