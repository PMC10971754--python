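"""Proportional-odds logistic regression, subset selection and odds-ratio
interpretation.

The model is ``logit P(Y <= j | x) = theta_j - x . beta`` with strictly
increasing cutpoints.  Fitting maximizes the likelihood by quasi-Newton
iteration from ``beta = 0`` and the empirical cumulative logits; standard
errors come from the inverse observed information.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .datatypes import OrdinalFit

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Perfect separation: the likelihood is unbounded."""


class FitError(RuntimeError):
    pass


def _encode_labels(y) -> tuple[np.ndarray, list]:
    """Map ordinal labels to 0..J-1 preserving sort order."""
    y = np.asarray(y)
    cats = np.unique(y)
    codes = np.searchsorted(cats, y)
    return codes.astype(np.int64), cats.tolist()


def _nll_grad(params: np.ndarray, X: np.ndarray, codes: np.ndarray, n_cut: int):
    """Negative log-likelihood and gradient in (theta, beta) coordinates."""
    theta = params[:n_cut]
    beta = params[n_cut:]
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    # z_upper = theta_{y} - eta (z=+inf for top class), z_lower for y-1
    upper = np.where(codes < n_cut, theta[np.minimum(codes, n_cut - 1)] - eta, np.inf)
    lower = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    F_up = special.expit(upper)
    F_lo = special.expit(lower)
    prob = F_up - F_lo
    if np.any(prob <= 0):
        return np.inf, np.zeros_like(params)
    nll = -np.log(prob).sum()
    f_up = np.where(np.isfinite(upper), F_up * (1 - F_up), 0.0)
    f_lo = np.where(np.isfinite(lower), F_lo * (1 - F_lo), 0.0)
    inv = 1.0 / prob
    grad_theta = np.zeros(n_cut)
    np.add.at(grad_theta, np.minimum(codes, n_cut - 1), -np.where(codes < n_cut, f_up * inv, 0.0))
    np.add.at(grad_theta, np.maximum(codes - 1, 0), np.where(codes > 0, f_lo * inv, 0.0))
    dl_deta = (f_up - f_lo) * inv  # d(nll)/d(eta)
    grad_beta = X.T @ dl_deta if X.shape[1] else np.zeros(0)
    return nll, np.concatenate([grad_theta, grad_beta])


def _to_unconstrained(theta: np.ndarray) -> np.ndarray:
    a = np.empty_like(theta)
    a[0] = theta[0]
    if len(theta) > 1:
        a[1:] = np.log(np.diff(theta))
    return a


def _from_unconstrained(a: np.ndarray) -> np.ndarray:
    theta = np.empty_like(a)
    theta[0] = a[0]
    for j in range(1, len(a)):
        theta[j] = theta[j - 1] + math.exp(a[j])
    return theta


def polr_fit(X, y, feature_names=None, max_abs_coef: float = 30.0) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit.

    Rows with missing values are dropped (and counted in ``n_dropped``).
    Raises :class:`SeparationError` when the likelihood appears unbounded
    and :class:`FitError` on optimizer failure.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise FitError("X and y length mismatch")
    if feature_names is None:
        feature_names = [f"x{k}" for k in range(X.shape[1])]
    feature_names = list(feature_names)

    ok = ~np.any(np.isnan(X), axis=1)
    if y.dtype.kind == "f":
        ok &= ~np.isnan(y.astype(float))
    n_dropped = int((~ok).sum())
    X, y = X[ok], y[ok]
    codes, cats = _encode_labels(y)
    J = len(cats)
    if J < 2:
        raise FitError("need at least 2 categories with observations")
    n = len(codes)
    n_cut = J - 1

    # start: beta = 0, theta at empirical cumulative logits
    cum = np.cumsum(np.bincount(codes, minlength=J))[:-1] / n
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    theta0 = special.logit(cum)
    start_nll, _ = _nll_grad(
        np.concatenate([theta0, np.zeros(X.shape[1])]), X, codes, n_cut
    )

    def obj(p):
        theta = _from_unconstrained(p[:n_cut])
        nll, grad = _nll_grad(
            np.concatenate([theta, p[n_cut:]]), X, codes, n_cut
        )
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(p)
        # chain rule for the log-difference cutpoint parameterization
        g = grad.copy()
        gt = grad[:n_cut]
        for k in range(n_cut):
            if k == 0:
                g[0] = gt.sum()
            else:
                g[k] = gt[k:].sum() * math.exp(p[k])
        return nll, g

    p0 = np.concatenate([_to_unconstrained(theta0), np.zeros(X.shape[1])])
    res = optimize.minimize(
        obj, p0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    theta = _from_unconstrained(res.x[:n_cut])
    beta = res.x[n_cut:]
    if np.any(np.abs(beta) > max_abs_coef) or np.any(np.abs(theta) > 2 * max_abs_coef):
        raise SeparationError(
            "coefficients diverged; data are likely perfectly separated "
            f"(max |beta| = {np.abs(beta).max() if beta.size else 0:.2f})"
        )
    if not res.success and res.status != 2:  # 2: precision loss at optimum
        raise FitError(f"optimizer failed: {res.message}")

    nll, _ = _nll_grad(np.concatenate([theta, beta]), X, codes, n_cut)
    if nll > start_nll + 1e-8:
        raise FitError("optimizer did not improve on the starting value")

    hess = approx_hess1(
        np.concatenate([theta, beta]),
        lambda p: _nll_grad(p, X, codes, n_cut)[0],
    )
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_cut + len(beta), np.nan)
    se_theta, se_beta = se[:n_cut], se[n_cut:]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se_beta
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    loglik = -float(nll)
    k_params = n_cut + len(beta)
    return OrdinalFit(
        feature_names=feature_names,
        beta=beta,
        theta=theta,
        se_beta=se_beta,
        se_theta=se_theta,
        z_values=z,
        p_values=p_values,
        log_likelihood=loglik,
        aic=2.0 * k_params - 2.0 * loglik,
        n_obs=n,
        n_dropped=n_dropped,
    )


def cell_probabilities(fit: OrdinalFit, X) -> np.ndarray:
    """P(Y = j | x) for every row of X, from adjacent cumulative differences."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ fit.beta if len(fit.beta) else np.zeros(X.shape[0])
    cum = special.expit(fit.theta[None, :] - eta[:, None])
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    return np.diff(cum, axis=1)


#: derived counts excluded from the candidate set a priori: positive and
#: negative edge counts determine total_edges and the edge ratio
EXCLUDED_FEATURES = ("positive_edges", "negative_edges")

CANDIDATE_FEATURES = (
    "total_nodes",
    "total_edges",
    "pos_neg_ratio",
    "average_path_length",
    "modularity",
    "average_degree",
    "heterogeneity",
    "clustering_coefficient",
)


def multicollinearity_screen(
    features: pd.DataFrame, r_max: float = 0.9
) -> list:
    """Greedy collinearity filter in fixed column order.

    For any pair with |Pearson r| > ``r_max`` the later column is dropped;
    constant columns are dropped and logged.
    """
    if features.shape[1] < 2:
        raise FitError("need at least 2 features to screen")
    cols = [c for c in features.columns if c not in EXCLUDED_FEATURES]
    retained: list = []
    for col in cols:
        vals = features[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size == 0 or np.all(finite == finite[0]):
            logger.info("dropping constant feature %r", col)
            continue
        collinear = False
        for kept in retained:
            pair = features[[kept, col]].dropna()
            if len(pair) < 3:
                continue
            r = np.corrcoef(pair[kept], pair[col])[0, 1]
            if abs(r) > r_max:
                logger.info(
                    "dropping %r (|r| = %.3f with %r)", col, abs(r), kept
                )
                collinear = True
                break
        if not collinear:
            retained.append(col)
    return retained


def _fit_subset(X_df: pd.DataFrame, y, subset):
    sub = X_df[list(subset)] if subset else X_df[[]]
    return polr_fit(sub.to_numpy(dtype=float), y, feature_names=list(subset))


def best_subset(X: pd.DataFrame, y, max_features: int | None = None):
    """Exhaustive AIC-minimizing subset search (<= 12 candidates).

    The intercept-only model is a candidate, so the selected set may be
    empty.  Subsets whose fit fails are skipped and logged.
    """
    cols = list(X.columns)
    if len(cols) > 12:
        raise FitError("exhaustive search limited to 12 candidate features")
    if max_features is None:
        max_features = len(cols)
    best: tuple | None = None
    for size in range(0, max_features + 1):
        for subset in itertools.combinations(cols, size):
            try:
                fit = _fit_subset(X, y, subset)
            except (SeparationError, FitError) as exc:
                logger.info("subset %s skipped: %s", subset, exc)
                continue
            if best is None or fit.aic < best[1]:
                best = (set(subset), fit.aic)
    if best is None:
        raise FitError("every candidate subset failed to fit")
    return best[0]


def stepwise_aic(X: pd.DataFrame, y):
    """Bidirectional stepwise search from the full model; deterministic."""
    cols = list(X.columns)
    current = set(cols)

    def aic_of(subset):
        try:
            return _fit_subset(X, y, sorted(subset)).aic
        except (SeparationError, FitError):
            return np.inf

    current_aic = aic_of(current)
    while True:
        moves = []
        for col in sorted(current):
            moves.append((current - {col}, f"-{col}"))
        for col in sorted(set(cols) - current):
            moves.append((current | {col}, f"+{col}"))
        scored = [(aic_of(s), s, label) for s, label in moves]
        scored.sort(key=lambda t: (t[0], t[2]))
        if not scored or scored[0][0] >= current_aic - 1e-10:
            return current
        current_aic, current, _ = scored[0]


def reconcile(set_a: set, set_b: set, X: pd.DataFrame | None = None, y=None) -> set:
    """Pick between two selected feature sets: agreement wins; otherwise
    the smaller set; a size tie goes to the lower-AIC set."""
    set_a, set_b = set(set_a), set(set_b)
    if set_a == set_b:
        return set_a
    if len(set_a) != len(set_b):
        chosen = set_a if len(set_a) < len(set_b) else set_b
        logger.info("set mismatch: choosing the simpler model %s", sorted(chosen))
        return chosen
    if X is None or y is None:
        raise FitError("size tie needs X and y to compare AICs")
    aic_a = _fit_subset(X, y, sorted(set_a)).aic
    aic_b = _fit_subset(X, y, sorted(set_b)).aic
    chosen = set_a if aic_a <= aic_b else set_b
    logger.info("size tie: choosing lower-AIC set %s", sorted(chosen))
    return chosen


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def interpret_odds_ratio(or_value: float) -> dict:
    """Reciprocal interpretation of an odds ratio.

    OR >= 1 -> that many times *more* likely; OR < 1 -> ``1/OR`` times
    *less* likely.  The fold change is reported to 3 significant figures.
    """
    if not (or_value > 0):
        raise ValueError("odds ratio must be positive")
    if or_value >= 1.0:
        return {"direction": "more", "fold": _round_sig(or_value)}
    return {"direction": "less", "fold": _round_sig(1.0 / or_value)}


def regression_report(
    features: pd.DataFrame,
    y,
    r_max: float = 0.9,
    p_threshold: float = 0.01,
) -> dict:
    """Screen -> best-subset -> stepwise -> reconcile -> final fit + ORs."""
    retained = multicollinearity_screen(features, r_max=r_max)
    X = features[retained].dropna()
    y_arr = pd.Series(np.asarray(y), index=features.index).loc[X.index]
    n_dropped = len(features) - len(X)
    sel_best = best_subset(X, y_arr)
    sel_step = stepwise_aic(X, y_arr)
    chosen = reconcile(sel_best, sel_step, X, y_arr)
    fit = _fit_subset(X, y_arr, sorted(chosen))
    rows = []
    for name, b, se, p in zip(fit.feature_names, fit.beta, fit.se_beta, fit.p_values):
        orv = math.exp(b)
        interp = interpret_odds_ratio(orv)
        rows.append(
            {
                "feature": name,
                "beta": b,
                "se": se,
                "p": p,
                "odds_ratio": orv,
                "direction": interp["direction"],
                "fold": interp["fold"],
                "significant": bool(p < p_threshold),
            }
        )
    return {
        "screened_features": retained,
        "best_subset": sorted(sel_best),
        "stepwise": sorted(sel_step),
        "selected": sorted(chosen),
        "fit": fit,
        "odds_table": pd.DataFrame(rows),
        "n_rows_dropped": n_dropped,
        "p_threshold": p_threshold,
    }
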