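"""Per-segment dive metrics and collinearity screening.

Each fixed-duration segment of 1 Hz depths yields a vector of candidate
predictors of foraging: depth statistics (average, maximum, variance,
start-to-end difference), time spent near the dive's maximum depth
(>60/70/80/90% of max depth, as ratios), vertical kinematics (signed
per-second velocity and its average/variance; absolute per-second
acceleration and its average/variance), trace-shape counts (inflections,
wiggles = inflections >20 m apart in depth, steady points at equal depth)
and vertical sinuosity (net over gross vertical displacement, 1 = straight
path).  Candidates are screened pairwise for collinearity (|Pearson r| >=
0.7) keeping the ecologically higher-priority metric of each correlated
pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from divebuzz.dives import SegmentRecord

logger = logging.getLogger(__name__)

#: depth quantization used for the steady-point equality test (typical TDR
#: resolution, m); raw float equality would be meaningless.
STEADY_QUANTUM_M = 0.1

#: minimum depth excursion between successive inflections for a wiggle (m)
WIGGLE_DEPTH_M = 20.0

#: segment-level metric columns, in the documented CSV order
METRIC_NAMES = [
    "average_depth",
    "maximum_depth",
    "variance_depth",
    "depth_difference",
    "time_gt_60pct_max_depth",
    "time_gt_70pct_max_depth",
    "time_gt_80pct_max_depth",
    "time_gt_90pct_max_depth",
    "average_vertical_velocity",
    "variance_vertical_velocity",
    "average_vertical_acceleration",
    "variance_vertical_acceleration",
    "inflections",
    "wiggles",
    "steady_points",
    "sinuosity",
]

#: default ecological priority for collinearity screening: depth-use and
#: manoeuvring metrics believed to track buzz production come first.
DEFAULT_PRIORITY = [
    "average_depth",
    "variance_depth",
    "variance_vertical_velocity",
    "sinuosity",
    "wiggles",
    "inflections",
    "steady_points",
    "depth_difference",
    "average_vertical_velocity",
    "average_vertical_acceleration",
    "variance_vertical_acceleration",
    "maximum_depth",
    "time_gt_60pct_max_depth",
    "time_gt_70pct_max_depth",
    "time_gt_80pct_max_depth",
    "time_gt_90pct_max_depth",
]


@dataclass(frozen=True)
class MetricVector:
    average_depth: float
    maximum_depth: float
    variance_depth: float
    depth_difference: float
    time_gt_60pct_max_depth: float
    time_gt_70pct_max_depth: float
    time_gt_80pct_max_depth: float
    time_gt_90pct_max_depth: float
    average_vertical_velocity: float
    variance_vertical_velocity: float
    average_vertical_acceleration: float
    variance_vertical_acceleration: float
    inflections: int
    wiggles: int
    steady_points: int
    sinuosity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def vertical_velocity(depths: np.ndarray) -> np.ndarray:
    """Signed per-second depth rate (m/s at 1 Hz): depth(t1) - depth(t0).

    Positive while descending (depth increasing).  Length n-1.
    """
    d = np.asarray(depths, dtype=float)
    if d.size < 2:
        raise ValueError("vertical velocity needs at least 2 samples")
    return np.diff(d)


def compute_metrics(
    segment: SegmentRecord, absolute_velocity: bool = False
) -> MetricVector:
    """Compute the full segment-level metric vector for one segment.

    Velocity is kept signed for its average/variance (the sign carries
    descent-vs-ascent information); ``absolute_velocity=True`` switches the
    velocity moments to |v| for sensitivity checks of that convention.
    Acceleration is the absolute difference of successive velocities.  Sample variances use the n-1 denominator.
    Inflections are interior samples that are strict local depth extrema;
    a wiggle is an inflection differing by more than 20 m in depth from the
    immediately preceding inflection (the first inflection of a segment can
    never be a wiggle).  Steady points compare successive depths after
    quantizing to 0.1 m.  Sinuosity is |net depth change| / total absolute
    depth change, defined as 1 on an all-constant segment.  The time-at-depth
    ratios are measured against the parent dive's maximum depth.
    """
    d = np.asarray(segment.depths, dtype=float)
    if d.size == 0:
        raise ValueError("empty segment")
    if not segment.dive_max_depth > 0:
        raise ValueError("dive_max_depth must be positive")

    vv = vertical_velocity(d)
    va = np.abs(np.diff(vv))
    vv_m = np.abs(vv) if absolute_velocity else vv

    max_dive = segment.dive_max_depth
    time_ratios = {
        pct: float(np.mean(d > (pct / 100.0) * max_dive)) for pct in (60, 70, 80, 90)
    }

    prev = d[:-2] if d.size >= 3 else np.empty(0)
    cur = d[1:-1] if d.size >= 3 else np.empty(0)
    nxt = d[2:] if d.size >= 3 else np.empty(0)
    is_inflection = ((cur - prev > 0) & (nxt - cur < 0)) | (
        (cur - prev < 0) & (nxt - cur > 0)
    )
    inflection_depths = cur[is_inflection]
    wiggles = (
        int(np.sum(np.abs(np.diff(inflection_depths)) > WIGGLE_DEPTH_M))
        if inflection_depths.size >= 2
        else 0
    )

    q = np.round(d / STEADY_QUANTUM_M)
    steady = int(np.sum(q[1:] == q[:-1]))

    gross = float(np.sum(np.abs(vv)))
    net = float(abs(d[-1] - d[0]))
    sinuosity = 1.0 if gross == 0.0 else net / gross

    return MetricVector(
        average_depth=float(np.mean(d)),
        maximum_depth=float(np.max(d)),
        variance_depth=float(np.var(d, ddof=1)) if d.size > 1 else 0.0,
        depth_difference=net,
        time_gt_60pct_max_depth=time_ratios[60],
        time_gt_70pct_max_depth=time_ratios[70],
        time_gt_80pct_max_depth=time_ratios[80],
        time_gt_90pct_max_depth=time_ratios[90],
        average_vertical_velocity=float(np.mean(vv_m)),
        variance_vertical_velocity=float(np.var(vv_m, ddof=1))
        if vv_m.size > 1
        else 0.0,
        average_vertical_acceleration=float(np.mean(va)) if va.size else 0.0,
        variance_vertical_acceleration=float(np.var(va, ddof=1))
        if va.size > 1
        else 0.0,
        inflections=int(np.sum(is_inflection)),
        wiggles=wiggles,
        steady_points=steady,
        sinuosity=sinuosity,
    )


def metric_table(segments: list[SegmentRecord]) -> pd.DataFrame:
    """Long-format table: one row per segment with identifiers, phase, buzz
    count and all segment-level metrics (the pipeline interchange format)."""
    rows = []
    for seg in segments:
        row = {
            "individual_id": seg.individual_id,
            "dive_id": seg.dive_id,
            "segment_duration": seg.segment_duration,
            "start_s": seg.start_s,
            "phase": seg.phase,
            "buzz_count": seg.buzz_count,
            "dive_max_depth": seg.dive_max_depth,
        }
        row.update(compute_metrics(seg).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def screen_collinearity(
    table: pd.DataFrame,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate metrics pairwise for collinearity.

    Walks the priority list in order, retaining a metric only when its
    absolute Pearson correlation with every already-retained metric is
    below ``threshold``; the output order (and therefore the survivor of
    each correlated pair) is deterministic.  Zero-variance metrics are
    excluded with a warning.  Returns the retained names and the full
    correlation matrix of the non-degenerate candidates.
    """
    if priority is None:
        priority = [m for m in DEFAULT_PRIORITY if m in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 segments to screen collinearity")

    usable: list[str] = []
    for name in priority:
        col = table[name].to_numpy(dtype=float)
        if np.std(col) == 0.0:
            msg = f"metric {name!r} has zero variance; excluded from screening"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        usable.append(name)

    corr = table[usable].corr(method="pearson")
    retained: list[str] = []
    for name in usable:
        if all(abs(corr.loc[name, kept]) < threshold for kept in retained):
            retained.append(name)
    return retained, corr
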