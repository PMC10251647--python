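"""Cross-validated evaluation of the buzz-count model.

Validation is leave-individuals-out: each run trains on a random subset of
individuals (8 of 12 by default) and tests on the rest, so accuracy reflects
transfer to unseen whales.  Per run the model is refitted on the training
individuals, segments are scored with the probability of containing at
least one buzz, p(y >= 1) = 1 - exp(-lambda_hat), and four measures are
computed on the pooled test segments: ROC AUC, and sensitivity /
specificity / precision at a single operating threshold chosen on the
training data (Youden's J by default, fixed 0.5 optionally).  The
sensitivity analysis repeats this over many runs (100 by default) and
reports medians/SDs plus, per retained predictor, the number of runs with
p < 0.01.  Dive-level accounting compares observed and predicted buzz
totals per dive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from divebuzz.model import (
    FittedPCAModel,
    GLMMConvergenceError,
    ModelSpec,
    fit_glmm,
    predict_counts,
    standardize,
)

logger = logging.getLogger(__name__)

MEASURES = ("auc", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class SplitPlan:
    """One cross-validation run: which individuals train, which test."""

    run_id: int
    train_individuals: tuple[str, ...]
    test_individuals: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_individuals) & set(self.test_individuals):
            raise ValueError("train and test individuals must be disjoint")


@dataclass
class AccuracyReport:
    """Per-run accuracy measures and their across-run summaries."""

    per_run: pd.DataFrame  # run_id, auc, sensitivity, specificity, precision, ...
    summary: pd.DataFrame  # index: measure; columns: median, sd
    significance_counts: pd.Series  # per predictor: runs with p < alpha
    n_runs: int
    n_failed: int
    threshold_rule: str
    p_alpha: float = 0.01


def make_splits(
    individuals: list[str],
    n_train: int = 8,
    n_runs: int = 100,
    seed: int = 0,
) -> list[SplitPlan]:
    """Draw ``n_runs`` random train/test partitions of the individuals.

    Sampling is without replacement within a run; runs are independent (and
    may repeat — with 12 choose 8 = 495 partitions collisions are possible).
    Deterministic given the seed.
    """
    individuals = sorted(individuals)
    if n_train >= len(individuals):
        raise ValueError(
            f"n_train={n_train} must be smaller than the {len(individuals)} individuals"
        )
    rng = np.random.default_rng(seed)
    plans = []
    for run in range(n_runs):
        train = rng.choice(individuals, size=n_train, replace=False)
        train_set = set(train)
        plans.append(
            SplitPlan(
                run_id=run,
                train_individuals=tuple(sorted(train_set)),
                test_individuals=tuple(i for i in individuals if i not in train_set),
                seed=seed,
            )
        )
    return plans


def buzz_probability(lam: np.ndarray) -> np.ndarray:
    """p(at least one buzz) under Poisson(lambda)."""
    return -np.expm1(-np.asarray(lam, dtype=float))


def choose_threshold(
    labels: np.ndarray, scores: np.ndarray, rule: str = "youden"
) -> float:
    """Operating threshold on the score scale, chosen on training data.

    ``youden`` maximizes sensitivity + specificity - 1 along the ROC curve;
    ``fixed`` uses probability 0.5.
    """
    if rule == "fixed":
        return 0.5
    if rule != "youden":
        raise ValueError(f"unknown threshold rule {rule!r}")
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return 0.5  # degenerate training labels: fall back to fixed
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def accuracy_measures(
    observed_counts: np.ndarray,
    scores: np.ndarray,
    threshold: float,
) -> dict[str, float]:
    """AUC plus threshold-based sensitivity, specificity and precision.

    Labels are presence of at least one buzz; a segment is predicted
    present when its score >= threshold.  With single-class labels the AUC
    is undefined and reported as NaN with a warning; ratios with empty
    denominators are NaN as well.
    """
    observed_counts = np.asarray(observed_counts)
    scores = np.asarray(scores, dtype=float)
    if observed_counts.shape != scores.shape:
        raise ValueError("observed counts and scores must have equal length")
    labels = observed_counts >= 1
    if labels.all() or not labels.any():
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        auc = np.nan
    else:
        auc = float(roc_auc_score(labels, scores))
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    return {
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "threshold": float(threshold),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def _summarize(per_run: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for m in MEASURES:
        vals = per_run[m].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN runs
            rows[m] = {"median": np.nanmedian(vals), "sd": np.nanstd(vals, ddof=1)}
    return pd.DataFrame(rows).T


def sensitivity_analysis(
    table: pd.DataFrame,
    spec: ModelSpec,
    splits: list[SplitPlan],
    threshold_rule: str = "youden",
    p_alpha: float = 0.01,
) -> AccuracyReport:
    """Refit the (already selected) model on each run's training individuals
    and evaluate on the pooled test individuals.

    Per run the standardization is recomputed on the training segments, the
    operating threshold is chosen on training scores, and the four accuracy
    measures plus per-segment exact/over/under prediction fractions are
    computed on the test segments.  Failed fits are excluded from the
    medians and counted.  Also tallies, per predictor, the runs in which
    its Wald p value is below ``p_alpha``.
    """
    rows = []
    sig = {name: 0 for name in spec.predictors}
    n_failed = 0
    for plan in splits:
        train = table[table["individual_id"].isin(plan.train_individuals)]
        test = table[table["individual_id"].isin(plan.test_individuals)]
        if len(train) == 0 or len(test) == 0:
            n_failed += 1
            logger.warning("run %d: empty train or test set; skipped", plan.run_id)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, std = standardize(train, list(spec.predictors))
                if set(std.means) != set(spec.predictors):
                    raise GLMMConvergenceError(
                        "zero-SD predictor on this training split"
                    )
                fit = fit_glmm(spec, train, standardization=std, compute_r2=False)
        except GLMMConvergenceError as err:
            n_failed += 1
            logger.warning("run %d: fit failed (%s); excluded", plan.run_id, err)
            continue
        lam_train, _ = predict_counts(fit, train)
        lam_test, pred_counts_test = predict_counts(fit, test)
        thr = choose_threshold(
            train["buzz_count"].to_numpy() >= 1,
            buzz_probability(lam_train),
            rule=threshold_rule,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            meas = accuracy_measures(
                test["buzz_count"].to_numpy(), buzz_probability(lam_test), thr
            )
        obs = test["buzz_count"].to_numpy()
        meas.update(
            run_id=plan.run_id,
            frac_exact=float(np.mean(pred_counts_test == obs)),
            frac_over=float(np.mean(pred_counts_test > obs)),
            frac_under=float(np.mean(pred_counts_test < obs)),
        )
        for name in spec.predictors:
            if fit.coefficients.loc[name, "p_value"] < p_alpha:
                sig[name] += 1
        rows.append(meas)
    per_run = pd.DataFrame(rows)
    if len(per_run) == 0:
        per_run = pd.DataFrame(columns=["run_id", *MEASURES])
    summary = _summarize(per_run) if len(per_run) else pd.DataFrame(
        index=list(MEASURES), columns=["median", "sd"], dtype=float
    )
    return AccuracyReport(
        per_run=per_run,
        summary=summary,
        significance_counts=pd.Series(sig),
        n_runs=len(splits),
        n_failed=n_failed,
        threshold_rule=threshold_rule,
        p_alpha=p_alpha,
    )


def dive_level_accounting(
    predicted_counts: np.ndarray, segment_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-vs-predicted buzz totals per dive.

    ``predicted_counts`` are rounded per-segment predictions aligned with
    ``segment_table`` rows.  Per dive: observed total over complete
    segments, predicted total, absolute difference, percentage difference
    100*|obs - pred|/obs (NaN when no buzz was observed) and segment count.
    Returns (per-dive table, summary of medians/SDs across dives).
    """
    df = segment_table[["individual_id", "dive_id", "buzz_count"]].copy()
    df["predicted"] = np.asarray(predicted_counts)
    per_dive = (
        df.groupby(["individual_id", "dive_id"], sort=True)
        .agg(
            observed=("buzz_count", "sum"),
            predicted=("predicted", "sum"),
            n_segments=("buzz_count", "size"),
        )
        .reset_index()
    )
    per_dive["abs_difference"] = (per_dive["observed"] - per_dive["predicted"]).abs()
    per_dive["pct_abs_difference"] = np.where(
        per_dive["observed"] > 0,
        100.0 * per_dive["abs_difference"] / per_dive["observed"],
        np.nan,
    )
    cols = ["abs_difference", "pct_abs_difference", "observed", "n_segments"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        summary = pd.DataFrame(
            {
                "median": [np.nanmedian(per_dive[c].to_numpy(float)) for c in cols],
                "sd": [np.nanstd(per_dive[c].to_numpy(float), ddof=1) for c in cols],
            },
            index=cols,
        )
    return per_dive, summary


def bottom_phase_comparison(
    table: pd.DataFrame,
    spec: ModelSpec,
    splits: list[SplitPlan],
    threshold_rule: str = "youden",
    min_bottom_segments: int = 30,
) -> dict[str, AccuracyReport]:
    """Run the sensitivity analysis on all segments and again restricted to
    bottom-phase segments, with the same splits for paired comparability.

    Returns ``{"all": ..., "bottom": ...}``; runs with too few bottom
    segments fail their fit and are excluded (counted in ``n_failed``).
    """
    all_report = sensitivity_analysis(table, spec, splits, threshold_rule)
    bottom = table[table["phase"] == "bottom"]
    if len(bottom) < min_bottom_segments:
        logger.warning(
            "only %d bottom-phase segments (< %d); bottom-only analysis skipped",
            len(bottom),
            min_bottom_segments,
        )
        empty = AccuracyReport(
            per_run=pd.DataFrame(columns=["run_id", *MEASURES]),
            summary=pd.DataFrame(index=list(MEASURES), columns=["median", "sd"], dtype=float),
            significance_counts=pd.Series({n: 0 for n in spec.predictors}),
            n_runs=len(splits),
            n_failed=len(splits),
            threshold_rule=threshold_rule,
        )
        return {"all": all_report, "bottom": empty}
    bottom_report = sensitivity_analysis(bottom, spec, splits, threshold_rule)
    return {"all": all_report, "bottom": bottom_report}
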