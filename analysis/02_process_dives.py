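"""Detect foraging dives and label descent/bottom/ascent phases.

Reads the exported deployment from results/data/ (run 01_simulate.py first),
drops each whale's first dive, flags foraging dives (those containing at
least one buzz) and writes the per-dive summary to results/dives.csv.
"""

from pathlib import Path

import divebuzz as db
from divebuzz.io import load_deployment_dir, write_table
from divebuzz.pipeline import dive_summary

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series, buzzes = load_deployment_dir(ROOT / "data")
    dives = {
        ind: db.detect_dives(s, buzzes) for ind, s in sorted(series.items())
    }
    summary = dive_summary(dives)
    write_table(summary, ROOT / "dives.csv")

    foraging = summary[summary["is_foraging"]]
    print(f"candidate dives: {len(summary)}; foraging dives: {len(foraging)}")
    print(f"max depth range: {foraging['max_depth'].min():.0f}-"
          f"{foraging['max_depth'].max():.0f} m")
    tot = foraging[["descent_s", "bottom_s", "ascent_s"]].sum()
    frac = 100 * tot / tot.sum()
    print("time in phase: "
          f"descent {frac['descent_s']:.0f}%, bottom {frac['bottom_s']:.0f}%, "
          f"ascent {frac['ascent_s']:.0f}%")
    print(f"wrote {ROOT / 'dives.csv'}")


if __name__ == "__main__":
    main()
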