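"""Reading and writing the pipeline's plain-CSV interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from divebuzz.dives import BuzzEvent, DepthSeries


def read_depth_csv(
    path: str | Path, individual_id: str | None = None, rate_hz: float = 1.0
) -> DepthSeries:
    """Read a per-individual depth file (columns time_s, depth_m).

    The individual id defaults to the ``depth_<id>[.suffix].csv`` filename
    convention used by the exporter.
    """
    path = Path(path)
    if individual_id is None:
        stem = path.stem
        individual_id = stem.removeprefix("depth_").removesuffix("_hr")
    df = pd.read_csv(path)
    return DepthSeries(
        individual_id=individual_id,
        times=df["time_s"].to_numpy(float),
        depths=df["depth_m"].to_numpy(float),
        rate_hz=rate_hz,
    )


def read_buzz_csv(path: str | Path) -> list[BuzzEvent]:
    """Read the buzz table (columns individual, start_s, end_s)."""
    df = pd.read_csv(path)
    return [
        BuzzEvent(
            individual_id=str(r.individual), start_s=float(r.start_s), end_s=float(r.end_s)
        )
        for r in df.itertuples()
    ]


def load_deployment_dir(
    path: str | Path, rate_hz: float = 1.0
) -> tuple[dict[str, DepthSeries], list[BuzzEvent]]:
    """Load every ``depth_<id>.csv`` (1 Hz) plus ``buzzes.csv`` from a
    directory, as written by :func:`divebuzz.simulate.export_tdr_csv`."""
    path = Path(path)
    series = {}
    for f in sorted(path.glob("depth_*.csv")):
        if f.stem.endswith("_hr"):
            continue
        s = read_depth_csv(f, rate_hz=rate_hz)
        series[s.individual_id] = s
    buzzes = read_buzz_csv(path / "buzzes.csv") if (path / "buzzes.csv").exists() else []
    return series, buzzes


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a report table deterministically (fixed float formatting, no
    index) so reruns with the same seed are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path
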