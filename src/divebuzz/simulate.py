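"""Seeded synthetic biologging deployments with known ground truth.

Emulates deep-diver (sperm-whale-like) time-depth data: per individual, a
sequence of foraging dives separated by >= 60 s surface intervals.  Each
dive descends at a speed drawn from N(1.35, 0.21) m/s, holds a bottom phase
simulated as a bounded (reflected) random walk around a bottom depth drawn
from 500-900 m, and ascends at a speed drawn from N(1.60, 0.19) m/s; the
surface sits at 0 m with small uniform jitter so the 25 m dive threshold is
exercised robustly.  Defaults target the field scale: 12 individuals, ~9
dives each, ~12 buzzes per dive.

Buzz (prey-capture-attempt) events are generated from the same model the
analysis fits: each dive is partitioned into fixed windows (default 180 s),
the three driving covariates (average depth, variance of depth, variance of
vertical velocity) are computed per window, standardized deployment-wide,
and the window's buzz count is drawn Poisson with
log lambda = intercept + alpha_i + beta . x, alpha_i ~ N(0, sd).  That many
non-overlapping 5-10 s buzzes are placed uniformly within the window.  The
realized ground truth (random intercepts, per-window lambda and counts) is
retained so parameter-recovery tests can compare fitted against true
values.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from divebuzz.dives import BuzzEvent, DepthSeries, DIVE_THRESHOLD_M

#: default ground-truth coefficients on the standardized log-link scale;
#: signs follow the established buzz-count relationships (deeper segments
#: and higher vertical-velocity variance -> more buzzes; higher depth
#: variance, i.e. transit-like movement -> fewer).  The intercept is set so
#: a deployment averages roughly 12 buzzes per dive at the 180 s generation
#: scale.
DEFAULT_TRUE_COEFFICIENTS = {
    "intercept": -0.45,
    "average_depth": 0.955,
    "variance_depth": -0.356,
    "variance_vertical_velocity": 0.187,
}

_GENERATION_PREDICTORS = (
    "average_depth",
    "variance_depth",
    "variance_vertical_velocity",
)


@dataclass
class SimulationConfig:
    n_individuals: int = 12
    dives_per_individual_mean: float = 9.0
    descent_speed_mean_sd: tuple[float, float] = (1.35, 0.21)
    ascent_speed_mean_sd: tuple[float, float] = (1.60, 0.19)
    bottom_depth_range: tuple[float, float] = (500.0, 900.0)
    bottom_duration_range: tuple[float, float] = (600.0, 1200.0)
    bottom_walk_sd: float = 3.0
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    random_intercept_sd: float = 0.3
    segment_duration_for_generation: int = 180
    high_rate_hz: int | None = None
    seed: int = 0
    surface_gap_range: tuple[float, float] = (60.0, 180.0)
    max_dive_duration_s: float = 3600.0

    def __post_init__(self) -> None:
        lo, hi = self.bottom_depth_range
        if not (DIVE_THRESHOLD_M < lo < hi < 2000.0):
            raise ValueError("bottom_depth_range must lie within (25, 2000) m, min < max")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        for name in ("descent_speed_mean_sd", "ascent_speed_mean_sd"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.random_intercept_sd < 0 or self.bottom_walk_sd < 0:
            raise ValueError("SD fields must be >= 0")
        if self.surface_gap_range[0] < 60.0:
            raise ValueError("surface gaps must be at least 60 s")
        # reject configs whose slowest-plausible dive would exceed the cap
        v_desc = max(self.descent_speed_mean_sd[0] - 2 * self.descent_speed_mean_sd[1], 0.1)
        v_asc = max(self.ascent_speed_mean_sd[0] - 2 * self.ascent_speed_mean_sd[1], 0.1)
        worst = hi / v_desc + self.bottom_duration_range[1] + hi / v_asc
        if worst > self.max_dive_duration_s:
            raise ValueError(
                f"implied dive duration up to {worst:.0f} s exceeds the "
                f"{self.max_dive_duration_s:.0f} s cap: inconsistent speed/depth settings"
            )


@dataclass
class SyntheticDeployment:
    """A generated deployment plus its realized ground truth."""

    config: SimulationConfig
    depth_series: dict[str, DepthSeries]
    buzz_events: list[BuzzEvent]
    random_intercepts: pd.Series
    truth_windows: pd.DataFrame  # per generation window: covariates, lambda, count
    high_rate_series: dict[str, DepthSeries] = field(default_factory=dict)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Speed draw truncated to mean +/- 2 SD (and > 0.1 m/s)."""
    if sd == 0:
        return max(mean, 0.1)
    x = float(np.clip(rng.normal(mean, sd), mean - 2 * sd, mean + 2 * sd))
    return max(x, 0.1)


def _dive_profile(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """One dive's 1 Hz depth run from surface back to surface."""
    v_desc = _truncnorm(rng, *cfg.descent_speed_mean_sd)
    v_asc = _truncnorm(rng, *cfg.ascent_speed_mean_sd)
    depth = float(rng.uniform(*cfg.bottom_depth_range))
    t_bottom = int(rng.uniform(*cfg.bottom_duration_range))

    n_desc = int(np.ceil(depth / v_desc))
    descent = np.minimum(np.arange(1, n_desc + 1) * v_desc, depth)

    lo, hi = depth - 80.0, depth + 80.0
    steps = rng.normal(0.0, cfg.bottom_walk_sd, size=t_bottom)
    walk = depth + np.cumsum(steps)
    # reflect the walk into [lo, hi]
    span = hi - lo
    walk = lo + np.abs((walk - lo) % (2 * span) - span)

    start_asc = walk[-1] if t_bottom > 0 else depth
    n_asc = int(np.ceil(start_asc / v_asc))
    ascent = np.maximum(start_asc - np.arange(1, n_asc + 1) * v_asc, 0.0)

    profile = np.concatenate([descent, walk, ascent])
    if profile.size > cfg.max_dive_duration_s:
        raise ValueError("generated dive exceeds the duration cap")
    return profile


def _place_buzzes(
    rng: np.random.Generator, individual: str, t0: float, window_s: int, k: int
) -> list[BuzzEvent]:
    """k non-overlapping 5-10 s buzzes placed uniformly in [t0, t0+window)."""
    if k <= 0:
        return []
    durations = rng.uniform(5.0, 10.0, size=k)
    if durations.sum() >= window_s:
        durations = np.full(k, 5.0)
        k_max = max(int(window_s // 5) - 1, 0)
        if k > k_max:  # physically cannot fit; truncate (rare, tiny windows)
            k = k_max
            durations = durations[:k]
            if k == 0:
                return []
    free = window_s - durations.sum()
    gaps = np.sort(rng.uniform(0.0, free, size=k))
    starts = t0 + gaps + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    return [
        BuzzEvent(individual_id=individual, start_s=float(s), end_s=float(s + d))
        for s, d in zip(starts, durations)
    ]


def simulate_deployment(config: SimulationConfig) -> SyntheticDeployment:
    """Generate a full deployment (depth series, buzz events, ground truth).

    Deterministic given ``config.seed``.  Dive counts per individual are
    Poisson around the configured mean; a zero mean yields an empty
    deployment (surface-only records, no buzzes).
    """
    rng = np.random.default_rng(config.seed)
    W = int(config.segment_duration_for_generation)

    alphas = (
        rng.normal(0.0, config.random_intercept_sd, size=config.n_individuals)
        if config.random_intercept_sd > 0
        else np.zeros(config.n_individuals)
    )
    ids = [f"whale_{i + 1:02d}" for i in range(config.n_individuals)]

    depth_series: dict[str, DepthSeries] = {}
    # per individual: list of (dive_interior_start_index, profile_len_interior)
    window_meta: list[dict] = []
    for idx, ind in enumerate(ids):
        n_dives = int(rng.poisson(config.dives_per_individual_mean))
        chunks = []
        pos = 0
        gap0 = int(rng.uniform(*config.surface_gap_range))
        chunks.append(np.clip(rng.uniform(-0.5, 0.5, size=gap0), 0.0, None))
        pos += gap0
        for d in range(n_dives):
            profile = _dive_profile(rng, config)
            interior = np.flatnonzero(profile > DIVE_THRESHOLD_M)
            i0, i1 = int(interior[0]), int(interior[-1]) + 1
            for k in range((i1 - i0) // W):
                ws = pos + i0 + k * W
                window_meta.append(
                    {
                        "individual_id": ind,
                        "alpha_index": idx,
                        "dive_ordinal": d,
                        "window_start_s": float(ws),
                        "depths_slice": (ws, ws + W),
                    }
                )
            chunks.append(profile)
            pos += profile.size
            gap = int(rng.uniform(*config.surface_gap_range))
            chunks.append(np.clip(rng.uniform(-0.5, 0.5, size=gap), 0.0, None))
            pos += gap
        depths = np.concatenate(chunks)
        depth_series[ind] = DepthSeries(
            individual_id=ind,
            times=np.arange(depths.size, dtype=float),
            depths=depths,
            rate_hz=1.0,
        )

    # covariates on every generation window, standardized deployment-wide
    rows = []
    for meta in window_meta:
        ws, we = meta["depths_slice"]
        d = depth_series[meta["individual_id"]].depths[ws:we]
        vv = np.diff(d)
        rows.append(
            {
                **{k: meta[k] for k in
                   ("individual_id", "alpha_index", "dive_ordinal", "window_start_s")},
                "average_depth": float(np.mean(d)),
                "variance_depth": float(np.var(d, ddof=1)),
                "variance_vertical_velocity": float(np.var(vv, ddof=1)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "individual_id", "alpha_index", "dive_ordinal", "window_start_s",
            *_GENERATION_PREDICTORS,
        ],
    )

    buzz_events: list[BuzzEvent] = []
    if len(truth):
        beta0 = config.true_coefficients.get("intercept", 0.0)
        eta = np.full(len(truth), beta0) + alphas[truth["alpha_index"].to_numpy()]
        for name in _GENERATION_PREDICTORS:
            coef = config.true_coefficients.get(name, 0.0)
            if coef != 0.0:
                col = truth[name].to_numpy()
                sd = col.std(ddof=0)
                z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
                eta = eta + coef * z
        lam = np.exp(eta)
        counts = rng.poisson(lam)
        truth["lambda"] = lam
        truth["buzz_count"] = counts
        for row, k in zip(truth.itertuples(), counts):
            buzz_events.extend(
                _place_buzzes(rng, row.individual_id, row.window_start_s, W, int(k))
            )
    else:
        truth["lambda"] = pd.Series(dtype=float)
        truth["buzz_count"] = pd.Series(dtype=int)

    buzz_events.sort(key=lambda b: (b.individual_id, b.start_s))

    high_rate: dict[str, DepthSeries] = {}
    if config.high_rate_hz:
        R = int(config.high_rate_hz)
        for ind, series in depth_series.items():
            n = len(series)
            t_hi = np.arange(n * R, dtype=float) / R
            d_hi = np.interp(t_hi, series.times, series.depths)
            high_rate[ind] = DepthSeries(
                individual_id=ind, times=t_hi, depths=d_hi, rate_hz=float(R)
            )

    return SyntheticDeployment(
        config=config,
        depth_series=depth_series,
        buzz_events=buzz_events,
        random_intercepts=pd.Series(alphas, index=ids),
        truth_windows=truth,
        high_rate_series=high_rate,
    )


def export_tdr_csv(deployment: SyntheticDeployment, path: str | Path) -> list[Path]:
    """Write the deployment as plain CSV: one 1 Hz depth file per individual
    (``depth_<id>.csv``: time_s, depth_m), optional high-rate files
    (``depth_<id>_hr.csv``) and one buzz table (``buzzes.csv``: individual,
    start_s, end_s).  Values are written to 3 decimals so files round-trip
    byte-identically; an empty deployment yields header-only files."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for ind, series in sorted(deployment.depth_series.items()):
        f = out / f"depth_{ind}.csv"
        pd.DataFrame({"time_s": series.times, "depth_m": series.depths}).to_csv(
            f, index=False, float_format="%.3f"
        )
        written.append(f)
    for ind, series in sorted(deployment.high_rate_series.items()):
        f = out / f"depth_{ind}_hr.csv"
        pd.DataFrame({"time_s": series.times, "depth_m": series.depths}).to_csv(
            f, index=False, float_format="%.3f"
        )
        written.append(f)
    f = out / "buzzes.csv"
    pd.DataFrame(
        [
            {"individual": b.individual_id, "start_s": b.start_s, "end_s": b.end_s}
            for b in deployment.buzz_events
        ],
        columns=["individual", "start_s", "end_s"],
    ).to_csv(f, index=False, float_format="%.3f")
    written.append(f)
    return written
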