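"""Two-step ordinary-least-squares Finlay-Wilkinson estimator.

Step 1 fits the additive main-effects model ``y = mu + g_i + h_j + e`` by
least squares under the sum-to-zero constraints ``sum_i g_i = 0`` and
``sum_j h_j = 0``; this yields environment-effect estimates ``h_hat`` that,
unlike raw environment means, account for which varieties happen to be
present in each environment.  Step 2 regresses, separately within each
line, the observed phenotypes on ``h_hat`` (with an intercept but no
separate overall mean): the intercept estimates ``mu + g_i`` and the slope
estimates ``1 + b_i``.  The residual variances of the within-line
regressions are pooled, weighting each line by its residual degrees of
freedom.

Both steps treat effects as fixed and use only non-missing records; the
Bayesian estimator in :mod:`fwreg.gibbs` is the shrinkage alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .datamodel import (
    CovarianceSpec,
    FWFit,
    ModelFrame,
    PhenotypeTable,
    validate_and_align,
)

__all__ = ["OLSStepOneResult", "fit_main_effects", "fit_within_line", "fit_ols"]


@dataclass
class OLSStepOneResult:
    """Constrained main-effects least-squares solution.

    ``g_hat`` and ``h_hat`` each sum to zero (within numerical tolerance).
    """

    mu_hat: float
    g_hat: np.ndarray
    h_hat: np.ndarray


def _check_design(frame: ModelFrame) -> None:
    """Reject designs the constrained OLS normal equations cannot identify."""
    obs = frame.observed
    q, p = frame.n_varieties, frame.n_environments
    env_counts = np.bincount(frame.env_idx[obs], minlength=p)
    empty = [frame.environments[j] for j in np.flatnonzero(env_counts == 0)]
    if empty:
        raise ValueError(
            f"environment(s) {empty} have no observed records; the OLS "
            "estimator cannot estimate their effects (the Gibbs method can, "
            "given a covariance structure)"
        )
    var_counts = np.bincount(frame.variety_idx[obs], minlength=q)
    empty_v = [frame.varieties[i] for i in np.flatnonzero(var_counts == 0)]
    if empty_v:
        raise ValueError(f"variety(ies) {empty_v} have no observed records")
    # bipartite variety/environment incidence graph must be connected
    rows = frame.variety_idx[obs]
    cols = frame.env_idx[obs] + q
    n = q + p
    adj = scipy.sparse.coo_matrix(
        (np.ones(2 * len(rows)), (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(n, n),
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comp0 = [frame.varieties[i] for i in range(q) if labels[i] == labels[0]]
        comp0 += [
            frame.environments[j] for j in range(p) if labels[q + j] == labels[0]
        ]
        raise ValueError(
            "variety/environment incidence is disconnected; the constrained "
            f"main-effects model is not identified (one component: {comp0})"
        )


def fit_main_effects(frame: ModelFrame) -> OLSStepOneResult:
    """Step 1: constrained least squares for ``y = mu + g_i + h_j + e``.

    Solves the bordered (Lagrange) normal equations of the additive model
    under ``sum(g) = 0`` and ``sum(h) = 0``, using non-missing records only.
    On a complete balanced design this reduces to ``h_hat_j`` = environment
    mean minus grand mean and ``g_hat_i`` = line mean minus grand mean.
    """
    if frame.n_obs == 0:
        raise ValueError("no observed records")
    _check_design(frame)
    obs = frame.observed
    y = frame.y[obs]
    vi = frame.variety_idx[obs]
    ei = frame.env_idx[obs]
    q, p = frame.n_varieties, frame.n_environments
    m = 1 + q + p  # mu, g block, h block

    # normal equations X'X beta = X'y assembled from counts
    xtx = np.zeros((m, m))
    xty = np.zeros(m)
    n = len(y)
    cnt_v = np.bincount(vi, minlength=q).astype(float)
    cnt_e = np.bincount(ei, minlength=p).astype(float)
    cross = scipy.sparse.coo_matrix(
        (np.ones(n), (vi, ei)), shape=(q, p)
    ).toarray()
    xtx[0, 0] = n
    xtx[0, 1 : 1 + q] = xtx[1 : 1 + q, 0] = cnt_v
    xtx[0, 1 + q :] = xtx[1 + q :, 0] = cnt_e
    xtx[1 : 1 + q, 1 : 1 + q] = np.diag(cnt_v)
    xtx[1 + q :, 1 + q :] = np.diag(cnt_e)
    xtx[1 : 1 + q, 1 + q :] = cross
    xtx[1 + q :, 1 : 1 + q] = cross.T
    xty[0] = y.sum()
    xty[1 : 1 + q] = np.bincount(vi, weights=y, minlength=q)
    xty[1 + q :] = np.bincount(ei, weights=y, minlength=p)

    # border with the two sum-to-zero constraints
    C = np.zeros((2, m))
    C[0, 1 : 1 + q] = 1.0
    C[1, 1 + q :] = 1.0
    bordered = np.block([[xtx, C.T], [C, np.zeros((2, 2))]])
    rhs = np.r_[xty, 0.0, 0.0]
    try:
        sol = scipy.linalg.solve(bordered, rhs, assume_a="sym")
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise ValueError(f"constrained normal equations are singular: {err}")
    if not np.all(np.isfinite(sol)):
        raise ValueError("constrained normal equations are singular")
    return OLSStepOneResult(
        mu_hat=float(sol[0]), g_hat=sol[1 : 1 + q], h_hat=sol[1 + q : 1 + q + p]
    )


def fit_within_line(
    frame: ModelFrame, h_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Step 2: per-line simple regression of y on the estimated h.

    For each line the intercept estimates ``mu + g_i`` and the slope
    ``1 + b_i``, so ``b_hat_i`` = slope - 1.  Returns
    ``(intercepts, b_hat, pooled_resid_var, estimable)`` where
    ``pooled_resid_var = sum_i RSS_i / sum_i (n_i - 2)`` pools the
    within-line residual variances by their residual degrees of freedom.

    Lines observed at fewer than two distinct values of ``h_hat`` cannot
    support a slope: they get ``b_hat = 0``, an intercept equal to the line
    mean minus the mean ``h_hat`` at their records, contribute no degrees
    of freedom to the pooled variance, and are flagged ``False`` in
    ``estimable``.
    """
    obs = frame.observed
    y = frame.y[obs]
    vi = frame.variety_idx[obs]
    x = np.asarray(h_hat, dtype=float)[frame.env_idx[obs]]
    q = frame.n_varieties

    n_i = np.bincount(vi, minlength=q).astype(float)
    sx = np.bincount(vi, weights=x, minlength=q)
    sy = np.bincount(vi, weights=y, minlength=q)
    sxx = np.bincount(vi, weights=x * x, minlength=q)
    sxy = np.bincount(vi, weights=x * y, minlength=q)
    syy = np.bincount(vi, weights=y * y, minlength=q)

    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx * sx / n_i           # sum (x - xbar)^2 per line
        spxy = sxy - sx * sy / n_i
        ssy = syy - sy * sy / n_i
    scale = np.maximum(sxx, 1.0)
    estimable = (n_i >= 2) & (ssx > 1e-12 * scale)

    slope = np.ones(q)
    np.divide(spxy, ssx, out=slope, where=estimable)
    with np.errstate(invalid="ignore"):
        intercept = np.where(n_i > 0, (sy - slope * sx) / n_i, np.nan)
    b_hat = slope - 1.0

    rss = np.where(estimable, ssy - slope * spxy, 0.0)
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    df = np.where(estimable, np.maximum(n_i - 2.0, 0.0), 0.0)
    total_df = df.sum()
    pooled = float(rss.sum() / total_df) if total_df > 0 else 0.0
    return intercept, b_hat, pooled, estimable


def fit_ols(
    table: PhenotypeTable,
    A: CovarianceSpec | None = None,
    H: CovarianceSpec | None = None,
) -> FWFit:
    """Fit the full two-step OLS Finlay-Wilkinson regression.

    ``A``/``H`` are accepted for interface symmetry with the Gibbs method
    and validated against the table's labels, but the OLS estimator ignores
    them.  The returned fit has exactly one column per estimate; ``yhat``
    is the predictor identity evaluated at every record, including records
    with a missing phenotype.
    """
    frame = validate_and_align(table, A, H)
    step1 = fit_main_effects(frame)
    intercept, b_hat, pooled, estimable = fit_within_line(frame, step1.h_hat)
    mu = step1.mu_hat
    g_hat = intercept - mu
    h_hat = step1.h_hat
    yhat = (
        mu
        + g_hat[frame.variety_idx]
        + (1.0 + b_hat[frame.variety_idx]) * h_hat[frame.env_idx]
    )
    col = lambda v: np.asarray(v, dtype=float).reshape(-1, 1)
    return FWFit(
        method="OLS",
        varieties=frame.varieties,
        environments=frame.environments,
        mu=np.array([mu]),
        g=col(g_hat),
        b=col(b_hat),
        h=col(h_hat),
        yhat=col(yhat),
        which_missing=frame.table.which_missing,
        pooled_resid_var=pooled,
        line_status=estimable,
    )
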