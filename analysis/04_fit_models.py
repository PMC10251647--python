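"""Fit the buzz-count GLMM per segment duration with AIC backward selection.

For each duration's metric table: screen collinearity, fit the Poisson
random-intercept model on the survivors, backward-select by AIC, and write
the coefficient summary (estimate, SE, z, marginal/conditional R2) to
results/model_summary.csv — one block per duration, mirroring how such
model outputs are usually tabulated.
"""

import warnings
from pathlib import Path

import pandas as pd

import divebuzz as db
from divebuzz.io import write_table
from divebuzz.model import ModelSpec, backward_select, standardize

ROOT = Path(__file__).resolve().parents[1] / "results"
DURATIONS = (30, 60, 180, 300)


def main() -> None:
    rows = []
    for dur in DURATIONS:
        table = pd.read_csv(ROOT / f"metrics_{dur}.csv")
        retained, _ = db.screen_collinearity(table)
        _, std = standardize(table, retained)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, trace = backward_select(
                ModelSpec(predictors=tuple(retained)), table, standardization=std
            )
        write_table(trace, ROOT / f"selection_{dur}.csv")
        print(f"{dur} s: selected {', '.join(best.spec.predictors)}; "
              f"AIC {best.aic:.1f}; R2m {best.r2_marginal:.2f} "
              f"R2c {best.r2_conditional:.2f}")
        for name, c in best.coefficients.iterrows():
            rows.append(
                {
                    "segment_duration": dur,
                    "dive_metric": name,
                    "estimate": c["estimate"],
                    "std_error": c["std_error"],
                    "z_value": c["z_value"],
                    "p_value": c["p_value"],
                    "r2_marginal": best.r2_marginal,
                    "r2_conditional": best.r2_conditional,
                    "aic": best.aic,
                }
            )
    write_table(pd.DataFrame(rows), ROOT / "model_summary.csv")
    print(f"wrote {ROOT / 'model_summary.csv'}")


if __name__ == "__main__":
    main()
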