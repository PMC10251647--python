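"""Independent oracles: naive per-definition implementations used only to
check the package's vectorized code.  Deliberately written as plain Python
loops, sharing nothing with the implementation under test."""

from __future__ import annotations

import math

import numpy as np


def naive_metrics(depths, dive_max_depth: float) -> dict[str, float]:
    """All segment-level metrics by direct per-definition loops."""
    d = [float(x) for x in depths]
    n = len(d)
    avg = sum(d) / n
    mx = max(d)
    var_d = sum((x - avg) ** 2 for x in d) / (n - 1) if n > 1 else 0.0
    dd = abs(d[-1] - d[0])

    ratios = {}
    for pct in (60, 70, 80, 90):
        cut = pct / 100.0 * dive_max_depth
        ratios[pct] = sum(1 for x in d if x > cut) / n

    vv = [d[i + 1] - d[i] for i in range(n - 1)]
    avg_vv = sum(vv) / len(vv)
    var_vv = (
        sum((x - avg_vv) ** 2 for x in vv) / (len(vv) - 1) if len(vv) > 1 else 0.0
    )
    va = [abs(vv[i + 1] - vv[i]) for i in range(len(vv) - 1)]
    avg_va = sum(va) / len(va) if va else 0.0
    var_va = sum((x - avg_va) ** 2 for x in va) / (len(va) - 1) if len(va) > 1 else 0.0

    inflections = 0
    wiggles = 0
    prev_inflection_depth = None
    for t in range(1, n - 1):
        up_down = d[t] - d[t - 1] > 0 and d[t + 1] - d[t] < 0
        down_up = d[t] - d[t - 1] < 0 and d[t + 1] - d[t] > 0
        if up_down or down_up:
            inflections += 1
            if (
                prev_inflection_depth is not None
                and abs(d[t] - prev_inflection_depth) > 20.0
            ):
                wiggles += 1
            prev_inflection_depth = d[t]

    steady = 0
    for t in range(1, n):
        if round(d[t] / 0.1) == round(d[t - 1] / 0.1):
            steady += 1

    gross = sum(abs(x) for x in vv)
    sinuosity = 1.0 if gross == 0.0 else dd / gross

    return {
        "average_depth": avg,
        "maximum_depth": mx,
        "variance_depth": var_d,
        "depth_difference": dd,
        "time_gt_60pct_max_depth": ratios[60],
        "time_gt_70pct_max_depth": ratios[70],
        "time_gt_80pct_max_depth": ratios[80],
        "time_gt_90pct_max_depth": ratios[90],
        "average_vertical_velocity": avg_vv,
        "variance_vertical_velocity": var_vv,
        "average_vertical_acceleration": avg_va,
        "variance_vertical_acceleration": var_va,
        "inflections": inflections,
        "wiggles": wiggles,
        "steady_points": steady,
        "sinuosity": sinuosity,
    }


def irls_poisson(y, X, n_iter: int = 100, tol: float = 1e-12):
    """Plain Poisson log-link regression by iteratively reweighted least
    squares; returns (coefficients, log-likelihood)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = math.log(max(y.mean(), 1e-8))
    for _ in range(n_iter):
        eta = X @ beta
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = X @ beta
    ll = float(np.sum(y * eta - np.exp(eta) - [math.lgamma(v + 1) for v in y]))
    return beta, ll


def pairwise_auc(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney pairwise statistic, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
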