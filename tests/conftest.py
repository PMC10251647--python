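from __future__ import annotations

import warnings

import numpy as np
import pytest

import divebuzz as db


def random_segment(rng: np.random.Generator, n: int | None = None):
    """A random but realistic-ish segment: quantized random-walk depths."""
    if n is None:
        n = int(rng.integers(5, 200))
    kind = rng.integers(0, 3)
    if kind == 0:  # bottom-like jitter
        d = 600 + np.cumsum(rng.normal(0, 3, n))
    elif kind == 1:  # transit-like ramp with noise
        d = 100 + 1.4 * np.arange(n) + rng.normal(0, 1, n)
    else:  # coarse steps, exercises steady points and ties
        d = 500 + np.round(np.cumsum(rng.choice([-1.0, 0.0, 0.0, 1.0], n)))
    d = np.round(np.clip(d, 0, None), 1)  # TDR-like 0.1 m resolution
    return d


def make_segment(depths, dive_max_depth=None, **kw):
    depths = np.asarray(depths, dtype=float)
    return db.SegmentRecord(
        individual_id=kw.get("individual_id", "w1"),
        dive_id=kw.get("dive_id", 0),
        segment_duration=len(depths),
        start_s=kw.get("start_s", 0.0),
        depths=depths,
        phase=kw.get("phase", "bottom"),
        buzz_count=kw.get("buzz_count", 0),
        dive_max_depth=float(dive_max_depth if dive_max_depth is not None else depths.max()),
    )


@pytest.fixture(scope="session")
def small_deployment():
    """A 6-individual synthetic deployment shared across tests."""
    return db.simulate_deployment(
        db.SimulationConfig(n_individuals=6, dives_per_individual_mean=6, seed=11)
    )


def deployment_segments(deployment, duration=180):
    segs = []
    for ind, s in deployment.depth_series.items():
        dives = db.detect_dives(s, deployment.buzz_events)
        segs.extend(
            db.segment_dives(
                [d for d in dives if d.is_foraging], s, deployment.buzz_events, duration
            )
        )
    return segs


@pytest.fixture(scope="session")
def small_metric_table(small_deployment):
    return db.metric_table(deployment_segments(small_deployment, 180))


@pytest.fixture()
def quiet_fit():
    """Suppress the small-group warnings that tiny test tables trigger."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
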