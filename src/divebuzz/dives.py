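"""Dive detection, phase labelling and fixed-duration segmentation.

Turns raw 1 Hz depth series into foraging dives (excursions deeper than the
25 m threshold containing at least one buzz) with per-sample phase labels
(descent / bottom / ascent) and contiguous, non-overlapping fixed-duration
segments, each carrying its observed buzz count.  Segments are the unit of
analysis for the buzz-count model.

Conventions used throughout: 0-based sample indices, half-open intervals,
seconds as the only time unit, depth positive downward in metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DESCENT = "descent"
BOTTOM = "bottom"
ASCENT = "ascent"

#: Depth below which an excursion counts as a dive (m).
DIVE_THRESHOLD_M = 25.0


@dataclass
class DepthSeries:
    """A per-individual, uniformly sampled depth record.

    Depths are metres, positive downward.  Small negative readings from
    surface sensor noise (down to -1 m) are clipped to 0 on construction;
    anything more negative raises.
    """

    individual_id: str
    times: np.ndarray
    depths: np.ndarray
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape:
            raise ValueError("times and depths must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-6):
                raise ValueError(
                    f"non-uniform sampling: expected dt={1.0 / self.rate_hz}s"
                )
        if not np.all(np.isfinite(self.depths)):
            raise ValueError("depths must be finite")
        if np.any(self.depths < -1.0):
            raise ValueError("depths below -1 m are not sensor noise")
        self.depths = np.clip(self.depths, 0.0, None)

    def __len__(self) -> int:
        return self.depths.size


@dataclass(frozen=True)
class BuzzEvent:
    """An annotated prey-capture attempt (terminal echolocation buzz)."""

    individual_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("buzz end must be after start")


@dataclass
class Dive:
    """A detected dive: indices into the 1 Hz series, phases, foraging flag.

    ``start_index``/``end_index`` are half-open and include the boundary
    crossing samples (depth <= threshold) on each side when present; the
    interior indices delimit the samples strictly deeper than the threshold,
    on which durations, segmentation and max depth are measured.
    """

    individual_id: str
    dive_id: int
    start_index: int
    end_index: int
    interior_start: int
    interior_end: int
    max_depth: float
    phase_labels: np.ndarray
    is_foraging: bool

    @property
    def duration_s(self) -> int:
        return self.interior_end - self.interior_start


@dataclass
class SegmentRecord:
    """One fixed-duration window of a dive: depths, phase and buzz count."""

    individual_id: str
    dive_id: int
    segment_duration: int
    start_s: float
    depths: np.ndarray
    phase: str
    buzz_count: int
    dive_max_depth: float


def downsample(series: DepthSeries, target_hz: float = 1.0) -> DepthSeries:
    """Decimate a depth series to ``target_hz`` by keeping the first sample
    of each block.

    TDRs record instantaneous pressure, so decimation (not block averaging)
    is the faithful emulation of a low-rate tag.  The source rate must be an
    integer multiple of the target rate.  Output length is
    ``floor(n / ratio)``; a 1 Hz input is returned unchanged.
    """
    ratio = series.rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"cannot downsample {series.rate_hz} Hz to {target_hz} Hz: "
            "rate must be an integer multiple of the target"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return series
    n_out = len(series) // ratio
    sl = slice(0, n_out * ratio, ratio)
    return DepthSeries(
        individual_id=series.individual_id,
        times=series.times[sl],
        depths=series.depths[sl],
        rate_hz=target_hz,
    )


def label_phases(
    dive_depths: np.ndarray, reversal_tolerance_s: int = 10
) -> np.ndarray:
    """Label each 1 Hz sample of a dive as descent, bottom or ascent.

    Descent and ascent are defined by sustained depth-rate sign; brief
    reversals (negligible relative to the phase duration) are ignored.
    Operationally the descent is the longest prefix over which the running
    depth maximum keeps advancing, allowing at most ``reversal_tolerance_s``
    seconds between successive record-setting samples; the ascent is the
    symmetric suffix on the running maximum of the time-reversed trace.  A
    pure run-length rule on the depth-rate sign cannot separate a jittery
    bottom phase (whose reversals are also brief) from a genuinely
    interrupted descent; requiring net progress does.  The bottom phase is
    whatever lies between; on a V-shaped dive it is empty and the deepest
    sample belongs to the descent.
    """
    d = np.asarray(dive_depths, dtype=float)
    n = d.size
    if n < 3:
        raise ValueError("a dive must have at least 3 samples to label phases")

    descent_end = _progress_end(d, reversal_tolerance_s)
    ascent_start = n - 1 - _progress_end(d[::-1], reversal_tolerance_s)
    if ascent_start <= descent_end:  # V-dive: phases meet at the apex
        ascent_start = descent_end + 1

    labels = np.full(n, BOTTOM, dtype=object)
    labels[: descent_end + 1] = DESCENT
    labels[ascent_start:] = ASCENT
    return labels


def _progress_end(d: np.ndarray, tol: int) -> int:
    """Index of the last running-max record reachable with gaps <= tol."""
    last_record = 0
    running_max = d[0]
    for i in range(1, d.size):
        if i - last_record > tol:
            break
        if d[i] > running_max:
            running_max = d[i]
            last_record = i
    return last_record


def detect_dives(
    series: DepthSeries,
    buzzes: list[BuzzEvent],
    threshold: float = DIVE_THRESHOLD_M,
    drop_first: bool = True,
    reversal_tolerance_s: int = 10,
) -> list[Dive]:
    """Detect dives as maximal runs deeper than ``threshold`` and flag
    foraging dives (those in which at least one buzz starts).

    The chronologically first dive of each individual is excluded when
    ``drop_first`` (a tagging-effect precaution).  Non-foraging dives are
    returned too, flagged, so callers can report on them; only foraging
    dives feed the model.
    """
    if series.rate_hz != 1.0:
        raise ValueError("detect_dives expects a 1 Hz series; downsample first")
    deep = series.depths > threshold
    if not deep.any():
        return []

    # maximal runs of deep samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], deep.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]

    own_buzz_starts = np.array(
        [b.start_s for b in buzzes if b.individual_id == series.individual_id]
    )

    dives: list[Dive] = []
    first = True
    dive_id = 0
    n = len(series)
    for i0, i1 in zip(starts, stops):
        if first and drop_first:
            first = False
            continue
        first = False
        if i1 - i0 < 3:
            continue  # too short to carry phases; spurious crossing
        start = max(i0 - 1, 0)
        end = min(i1 + 1, n)
        t_in = series.times[i0]
        t_out = t_in + (i1 - i0)  # half-open interior time span at 1 Hz
        n_buzzes = (
            int(np.sum((own_buzz_starts >= t_in) & (own_buzz_starts < t_out)))
            if own_buzz_starts.size
            else 0
        )
        dives.append(
            Dive(
                individual_id=series.individual_id,
                dive_id=dive_id,
                start_index=start,
                end_index=end,
                interior_start=i0,
                interior_end=i1,
                max_depth=float(series.depths[i0:i1].max()),
                phase_labels=label_phases(
                    series.depths[start:end], reversal_tolerance_s
                ),
                is_foraging=n_buzzes > 0,
            )
        )
        dive_id += 1
    return dives


def segment_dives(
    dives: list[Dive],
    series: DepthSeries,
    buzzes: list[BuzzEvent],
    segment_duration: int,
) -> list[SegmentRecord]:
    """Cut each dive into contiguous, non-overlapping windows of
    ``segment_duration`` seconds, from the dive's first interior sample.

    The trailing incomplete window is discarded.  A segment's buzz count is
    the number of buzzes *starting* in its half-open time window (a buzz on
    a boundary belongs to the later window), its phase is the phase of its
    first second, so segments per dive = floor(dive duration / duration).
    """
    if segment_duration <= 0:
        raise ValueError("segment_duration must be positive")
    if series.rate_hz != 1.0:
        raise ValueError("segment_dives expects a 1 Hz series")

    records: list[SegmentRecord] = []
    for dive in dives:
        own_starts = np.array(
            [b.start_s for b in buzzes if b.individual_id == dive.individual_id]
        )
        n_seg = dive.duration_s // segment_duration
        for k in range(n_seg):
            ws = dive.interior_start + k * segment_duration
            we = ws + segment_duration
            t0 = series.times[ws]
            t1 = t0 + segment_duration
            count = (
                int(np.sum((own_starts >= t0) & (own_starts < t1)))
                if own_starts.size
                else 0
            )
            records.append(
                SegmentRecord(
                    individual_id=dive.individual_id,
                    dive_id=dive.dive_id,
                    segment_duration=segment_duration,
                    start_s=float(t0),
                    depths=series.depths[ws:we].copy(),
                    phase=str(dive.phase_labels[ws - dive.start_index]),
                    buzz_count=count,
                    dive_max_depth=dive.max_depth,
                )
            )
    return records
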