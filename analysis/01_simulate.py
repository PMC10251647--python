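"""Generate the reference synthetic deployment and export it as TDR-style CSV.

Emulates a field deployment of 12 tagged whales (~9 foraging dives each,
~12 buzzes per dive, bottom depths 500-900 m) and writes 1 Hz depth files
plus the buzz table to results/data/.  Prints the realized scale so it can
be eyeballed against the deployment the generator is calibrated to.
"""

from pathlib import Path

import numpy as np

import divebuzz as db

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20260918


def main() -> None:
    cfg = db.SimulationConfig(seed=SEED)
    dep = db.simulate_deployment(cfg)
    files = db.export_tdr_csv(dep, OUT)

    per_dive = dep.truth_windows.groupby(["individual_id", "dive_ordinal"])[
        "buzz_count"
    ].sum()
    dives_per_ind = per_dive.groupby("individual_id").size()
    print(f"wrote {len(files)} files to {OUT}")
    print(f"individuals: {cfg.n_individuals}")
    print(
        f"dives per individual: mean {dives_per_ind.mean():.1f} "
        f"(SD {dives_per_ind.std():.1f})"
    )
    print(
        f"buzzes per dive: mean {per_dive.mean():.1f} (SD {per_dive.std():.1f}); "
        f"total buzzes {len(dep.buzz_events)}"
    )
    depths = np.concatenate([s.depths for s in dep.depth_series.values()])
    deep = depths[depths > 25]
    print(
        f"dive-depth interquartile range: "
        f"{np.percentile(deep, 25):.0f}-{np.percentile(deep, 75):.0f} m"
    )


if __name__ == "__main__":
    main()
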