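"""Poisson mixed-effects model of buzz counts per dive segment.

The response is the number of buzzes in a fixed-duration segment; predictors
are z-scored segment metrics; a single random intercept per individual
absorbs between-whale differences in buzz rate:

    y_ij ~ Poisson(lambda_ij),   log lambda_ij = beta0 + x_ij' beta + alpha_i,
    alpha_i ~ N(0, sigma_alpha^2)

The marginal likelihood integrates the random intercept out per individual.
Because the group contribution depends on alpha_i only through
S_i = sum_j y_ij and E_i(beta) = sum_j exp(x_ij' beta), the integral is
one-dimensional with a closed-form integrand; it is evaluated by adaptive
Gauss-Hermite quadrature centred on the per-group mode (found by Newton
steps with analytic first and second derivatives).  No maximum-likelihood
Poisson GLMM exists in the installed Python stack, so the likelihood code
here is self-contained; an ordinary Poisson GLM (statsmodels) provides
starting values and the degenerate sigma_alpha = 0 path.

Model comparison uses AIC = -2 log L + 2 (n_fixed + 1), the +1 counting the
variance parameter; backward selection drops one predictor at a time while
AIC improves.  Variance explained is summarized with marginal/conditional
R2 for log-link Poisson mixed models (fixed-effect linear-predictor
variance over total latent variance, with a log-normal — or, optionally,
trigamma — observation-level variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_GH_NODES = 15
_SIGMA_FLOOR = 1e-4  # below this the random intercept is reported as zero
_LOG2PI = float(np.log(2.0 * np.pi))


class GLMMConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimizer fails; carries the
    optimizer diagnostics so failures are never silent."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response counts, candidate predictors, grouping factor."""

    predictors: tuple[str, ...]
    response: str = "buzz_count"
    grouping: str = "individual_id"

    def __post_init__(self) -> None:
        if len(self.predictors) == 0:
            raise ValueError("candidate predictor set must be non-empty")

    def drop(self, name: str) -> "ModelSpec":
        return ModelSpec(
            predictors=tuple(p for p in self.predictors if p != name),
            response=self.response,
            grouping=self.grouping,
        )


@dataclass(frozen=True)
class Standardization:
    """Per-predictor mean/SD computed on a training set; applied unchanged
    to any later table so train and test live on the same scale."""

    means: dict[str, float]
    sds: dict[str, float]

    def apply(self, table: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
        cols = []
        for name in predictors:
            if name not in table.columns:
                raise KeyError(f"predictor {name!r} missing from table")
            cols.append(
                (table[name].to_numpy(dtype=float) - self.means[name])
                / self.sds[name]
            )
        return np.column_stack(cols) if cols else np.empty((len(table), 0))


def standardize(
    table: pd.DataFrame, predictors: list[str] | tuple[str, ...]
) -> tuple[pd.DataFrame, Standardization]:
    """z-score predictors using this table's statistics.

    Returns the transformed copy and the Standardization record; predictors
    with zero SD are dropped from both with a warning.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    out = table.copy()
    kept = []
    for name in predictors:
        col = table[name].to_numpy(dtype=float)
        mu, sd = float(np.mean(col)), float(np.std(col, ddof=0))
        if sd == 0.0:
            msg = f"predictor {name!r} has zero SD on the training set; excluded"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        means[name], sds[name] = mu, sd
        out[name] = (col - mu) / sd
        kept.append(name)
    out.attrs["standardized_predictors"] = kept
    return out, Standardization(means=means, sds=sds)


@dataclass
class FittedPCAModel:
    """A fitted prey-capture-attempt model: coefficients on the standardized
    scale, random-intercept variance, information criteria and R2."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index: 'intercept' + predictors; cols estimate/se/z/p
    random_intercept_variance: float
    log_likelihood: float
    aic: float
    standardization: Standardization
    n_obs: int
    n_groups: int
    converged: bool
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    random_effects: pd.Series | None = None  # per-group modal intercepts

    @property
    def intercept(self) -> float:
        return float(self.coefficients.loc["intercept", "estimate"])

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients.loc[list(self.spec.predictors), "estimate"].to_numpy()

    def summary_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out["r2_marginal"] = self.r2_marginal
        out["r2_conditional"] = self.r2_conditional
        out["aic"] = self.aic
        return out


# ---------------------------------------------------------------------------
# marginal log-likelihood


def _group_stats(y, eta_fixed, codes, n_groups):
    """Per-group sufficient pieces: S_i = sum y, E_i = sum exp(eta),
    C_i = sum (y*eta - log y!)."""
    S = np.bincount(codes, weights=y, minlength=n_groups)
    E = np.bincount(codes, weights=np.exp(eta_fixed), minlength=n_groups)
    C = np.bincount(
        codes, weights=y * eta_fixed - special.gammaln(y + 1.0), minlength=n_groups
    )
    return S, E, C


def _group_modes(S, E, sigma2, n_iter=50, tol=1e-10):
    """Newton solve for the per-group conditional mode of the random effect:
    maximize S*b - E*exp(b) - b^2/(2 sigma2)."""
    b = np.zeros_like(S)
    for _ in range(n_iter):
        Eb = E * np.exp(b)
        g = S - Eb - b / sigma2
        h = -Eb - 1.0 / sigma2
        step = g / h
        b = b - step
        if np.max(np.abs(step)) < tol:
            break
    return b


def _marginal_loglik(theta, y, X, codes, n_groups, gh_x, gh_logw):
    """Marginal log-likelihood at theta = (beta..., log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    S, E, C = _group_stats(y, eta, codes, n_groups)
    if sigma < _SIGMA_FLOOR:
        return float(np.sum(C) - np.sum(E))
    sigma2 = sigma * sigma
    b_hat = _group_modes(S, E, sigma2)
    tau = 1.0 / np.sqrt(E * np.exp(b_hat) + 1.0 / sigma2)
    nodes = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * gh_x[None, :]
    f = (
        S[:, None] * nodes
        - E[:, None] * np.exp(nodes)
        - nodes**2 / (2.0 * sigma2)
        - log_sigma
        - 0.5 * _LOG2PI
    )
    ll_g = special.logsumexp(f + gh_x[None, :] ** 2 + gh_logw[None, :], axis=1)
    ll_g += np.log(np.sqrt(2.0) * tau)
    return float(np.sum(ll_g + C))


def _numeric_hessian(fun, theta, rel_step=1e-4):
    p = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((p, p))
    f0 = fun(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej)
                    - fun(theta + ei - ej)
                    - fun(theta - ei + ej)
                    + fun(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_glmm(
    spec: ModelSpec,
    table: pd.DataFrame,
    standardization: Standardization | None = None,
    compute_r2: bool = True,
    r2_variant: str = "lognormal",
) -> FittedPCAModel:
    """Fit the Poisson random-intercept model by maximum marginal likelihood.

    Predictors are z-scored (using ``standardization`` if given, else this
    table's statistics).  With fewer than 2 groups the random-intercept
    variance is unidentifiable and the model collapses to an ordinary
    Poisson regression with sigma_alpha^2 = 0 (a warning is emitted, as for
    groups with fewer than 10 segments).  Non-convergence raises
    :class:`GLMMConvergenceError` with the optimizer's diagnostics.
    """
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    group_labels, codes = np.unique(table[spec.grouping].to_numpy(), return_inverse=True)
    n_groups = group_labels.size
    if n_groups < 2:
        warnings.warn(
            "fewer than 2 groups: random-intercept variance unidentifiable, "
            "fitting ordinary Poisson regression",
            stacklevel=2,
        )
    counts = np.bincount(codes, minlength=n_groups)
    if np.any(counts < 10):
        warnings.warn("some groups have fewer than 10 segments", stacklevel=2)

    if standardization is None:
        _, standardization = standardize(table, list(spec.predictors))
        missing = [p for p in spec.predictors if p not in standardization.means]
        if missing:
            raise ValueError(f"predictors with zero SD cannot be fitted: {missing}")
    Xz = standardization.apply(table, spec.predictors)
    X = np.column_stack([np.ones(len(table)), Xz])
    p_fixed = X.shape[1]

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(glm.params, dtype=float)

    if n_groups < 2:
        theta_hat = np.concatenate([beta0, [np.log(_SIGMA_FLOOR / 2)]])
        ll = float(glm.llf)
        se = np.asarray(glm.bse, dtype=float)
        sigma = 0.0
        cov_ok = True
        b_modes = np.zeros(n_groups)
    else:
        gh_x, gh_w = hermgauss(_GH_NODES)
        gh_logw = np.log(gh_w)
        args = (y, X, codes, n_groups, gh_x, gh_logw)

        def nll(theta):
            return -_marginal_loglik(theta, *args)

        best = None
        for s0 in (np.log(0.5), np.log(0.05)):
            res = optimize.minimize(
                nll,
                np.concatenate([beta0, [s0]]),
                method="L-BFGS-B",
                bounds=[(None, None)] * p_fixed + [(np.log(1e-6), np.log(10.0))],
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise GLMMConvergenceError(
                f"GLMM optimizer failed: {best.message!r} (nit={best.nit})"
            )
        if not best.success:
            # L-BFGS-B sometimes reports line-search breakdown at a usable
            # optimum; accept only if the gradient is essentially flat.
            grad_inf = float(np.max(np.abs(best.jac)))
            if grad_inf > 1e-3 * max(1.0, abs(best.fun)):
                raise GLMMConvergenceError(
                    f"GLMM optimizer failed: {best.message!r} "
                    f"(|grad|_inf={grad_inf:.3g}, nit={best.nit})"
                )
        theta_hat = best.x
        sigma = float(np.exp(theta_hat[-1]))
        if sigma < _SIGMA_FLOOR:
            sigma = 0.0
        ll = float(-best.fun)

        H = _numeric_hessian(nll, theta_hat)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)[:p_fixed]
            cov_ok = bool(np.all(diag > 0))
            se = np.sqrt(np.clip(diag, 0.0, None))
        except np.linalg.LinAlgError:
            cov_ok = False
            se = np.full(p_fixed, np.nan)
        if not cov_ok:
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov)[:p_fixed], 0.0, None))
        S, E, _ = _group_stats(y, X @ theta_hat[:p_fixed], codes, n_groups)
        b_modes = (
            _group_modes(S, E, sigma**2) if sigma > 0 else np.zeros(n_groups)
        )

    beta_hat = theta_hat[:p_fixed]
    z = np.divide(beta_hat, se, out=np.full(p_fixed, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {"estimate": beta_hat, "std_error": se, "z_value": z, "p_value": pvals},
        index=["intercept"] + list(spec.predictors),
    )
    aic = -2.0 * ll + 2.0 * (p_fixed + 1)

    model = FittedPCAModel(
        spec=spec,
        coefficients=coef,
        random_intercept_variance=float(sigma**2),
        log_likelihood=ll,
        aic=aic,
        standardization=standardization,
        n_obs=len(table),
        n_groups=int(n_groups),
        converged=True,
        random_effects=pd.Series(b_modes, index=group_labels),
    )
    if compute_r2:
        model.r2_marginal, model.r2_conditional = r_squared(
            model, table, variant=r2_variant
        )
    return model


def backward_select(
    full_spec: ModelSpec,
    table: pd.DataFrame,
    standardization: Standardization | None = None,
) -> tuple[FittedPCAModel, pd.DataFrame]:
    """AIC backward selection: repeatedly drop the single predictor whose
    removal lowers AIC most; stop when no removal improves.

    Returns the best model and a trace (one row per step: candidate
    removed, AIC before/after).  Standardization is computed once from the
    full table so nested models share a scale.
    """
    if standardization is None:
        _, standardization = standardize(table, list(full_spec.predictors))
        full_spec = ModelSpec(
            predictors=tuple(
                p for p in full_spec.predictors if p in standardization.means
            ),
            response=full_spec.response,
            grouping=full_spec.grouping,
        )
    current = fit_glmm(full_spec, table, standardization=standardization)
    trace_rows = [
        {"step": 0, "action": "full", "removed": "", "aic": current.aic,
         "predictors": ",".join(current.spec.predictors)}
    ]
    step = 0
    while len(current.spec.predictors) > 1:
        step += 1
        candidates = []
        for name in current.spec.predictors:
            sub = current.spec.drop(name)
            try:
                fit = fit_glmm(sub, table, standardization=standardization)
            except GLMMConvergenceError as err:
                raise GLMMConvergenceError(
                    f"sub-model without {name!r} failed: {err}"
                ) from err
            candidates.append((fit.aic, name, fit))
        candidates.sort(key=lambda t: (t[0], t[1]))
        best_aic, best_name, best_fit = candidates[0]
        if best_aic < current.aic:
            current = best_fit
            trace_rows.append(
                {"step": step, "action": "drop", "removed": best_name,
                 "aic": best_aic, "predictors": ",".join(current.spec.predictors)}
            )
        else:
            break
    return current, pd.DataFrame(trace_rows)


def r_squared(
    model: FittedPCAModel, table: pd.DataFrame, variant: str = "lognormal"
) -> tuple[float, float]:
    """Marginal and conditional R2 for the log-link Poisson mixed model.

    R2_marginal = var_f / (var_f + var_alpha + var_d) and R2_conditional =
    (var_f + var_alpha) / (same denominator), where var_f is the population
    variance of the fixed-effect linear predictor on the training data,
    var_alpha the random-intercept variance, and var_d the observation-level
    (distribution-specific) variance: ln(1 + 1/lambda_bar) for the
    log-normal approximation (default) or trigamma(lambda_bar) with
    lambda_bar = exp(intercept + var_alpha / 2).
    """
    X = model.standardization.apply(table, model.spec.predictors)
    eta_fixed = X @ model.beta if X.size else np.zeros(len(table))
    var_f = float(np.var(eta_fixed, ddof=0))
    var_a = model.random_intercept_variance
    lam_bar = float(np.exp(model.intercept + var_a / 2.0))
    if variant == "lognormal":
        var_d = float(np.log1p(1.0 / lam_bar))
    elif variant == "trigamma":
        var_d = float(special.polygamma(1, lam_bar))
    else:
        raise ValueError(f"unknown r2 variant {variant!r}")
    denom = var_f + var_a + var_d
    if denom == 0.0 or var_f == 0.0:
        r2m = 0.0
    else:
        r2m = var_f / denom
    r2c = (var_f + var_a) / denom if denom > 0 else 0.0
    return r2m, r2c


def predict_counts(
    model: FittedPCAModel, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Population-level predictions for (possibly unseen) individuals.

    The random effect of an individual absent from training is set to its
    population mean 0, so lambda_hat = exp(intercept + x' beta) using the
    training standardization.  Returns (lambda_hat, rounded counts); the
    rounding is nearest integer with ties to even.
    """
    X = model.standardization.apply(table, model.spec.predictors)
    lam = np.exp(model.intercept + (X @ model.beta if X.size else 0.0))
    return lam, np.rint(lam).astype(int)
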