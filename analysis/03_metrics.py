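"""Segment foraging dives at 30/60/180/300 s and compute the metric suite.

Writes one metric table per segment duration to results/ and reports the
collinearity screening outcome (which candidate predictors survive the
|Pearson r| < 0.7 rule under the ecological priority ordering).
"""

from pathlib import Path

import divebuzz as db
from divebuzz.io import load_deployment_dir, write_table

ROOT = Path(__file__).resolve().parents[1] / "results"
DURATIONS = (30, 60, 180, 300)


def main() -> None:
    series, buzzes = load_deployment_dir(ROOT / "data")
    dives = {ind: db.detect_dives(s, buzzes) for ind, s in sorted(series.items())}

    for dur in DURATIONS:
        segments = []
        for ind, dl in sorted(dives.items()):
            foraging = [d for d in dl if d.is_foraging]
            segments.extend(db.segment_dives(foraging, series[ind], buzzes, dur))
        table = db.metric_table(segments)
        write_table(table, ROOT / f"metrics_{dur}.csv")
        with_buzz = 100 * (table["buzz_count"] >= 1).mean()
        print(f"{dur:>4} s: {len(table):>5} segments, "
              f"{with_buzz:4.0f}% contain at least one buzz")
        retained, corr = db.screen_collinearity(table)
        corr.round(6).to_csv(ROOT / f"correlations_{dur}.csv")
        print(f"       retained after collinearity screen: {', '.join(retained)}")


if __name__ == "__main__":
    main()
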