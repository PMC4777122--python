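"""Posterior summaries, MCMC diagnostics, prediction scoring and plot data.

Operates on the thinned draws collected by the Gibbs sampler and on fitted
models from either estimator: shortest (highest-posterior-density)
intervals, autocorrelation, batch-means Monte Carlo standard errors,
training/validation correlations for masked designs, the cross-validation
loop, and the per-variety intercept/slope data needed to draw classical
Finlay-Wilkinson reaction-norm plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datamodel import FWFit, PhenotypeTable
from .simulate import mask_one_env_per_line

__all__ = [
    "HPDInterval",
    "hpd",
    "autocorr",
    "timeseries_se",
    "score_predictions",
    "crossvalidate",
    "fitted_lines",
]


@dataclass
class HPDInterval:
    """Shortest interval containing a given mass of the empirical draws."""

    lower: float
    upper: float
    mass: float = 0.95

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hpd(draws, mass: float = 0.95) -> HPDInterval:
    """Empirical highest-posterior-density interval.

    Returns the shortest contiguous window over the sorted draws that
    contains at least ``ceil(mass * n)`` points; ties are broken by the
    lowest-index window.  Requires at least 10 draws.
    """
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HPDInterval(lower=float(x[i]), upper=float(x[i + k - 1]), mass=mass)


def autocorr(draws, lag: int) -> float:
    """Empirical lag-k autocorrelation (biased normalization, lag 0 = 1)."""
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n <= lag:
        raise ValueError("need more draws than the requested lag")
    if lag == 0:
        return 1.0
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0  # constant chain
    return float(x[:-lag] @ x[lag:]) / denom


def timeseries_se(draws) -> float:
    """Monte Carlo standard error of the chain mean via batch means.

    Splits the chain into about sqrt(n) consecutive batches and uses the
    variance of batch means; this accounts for autocorrelation without a
    spectral estimate.  Requires at least 100 draws.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws")
    n_batches = int(np.floor(np.sqrt(n)))
    batch = n // n_batches
    means = x[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    if np.allclose(means, means[0]):
        return 0.0
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))


def score_predictions(y_true, yhat, indices=None) -> float:
    """Pearson correlation between observed and predicted values.

    ``indices`` restricts scoring to a subset of records (training =
    unmasked indices, validation = masked indices).  Pairs with a
    non-finite member are dropped; fewer than 3 finite pairs is an error
    and a zero-variance vector yields ``nan`` (correlation undefined).
    """
    y_true = np.asarray(y_true, dtype=float)
    yhat = np.asarray(yhat, dtype=float).reshape(len(y_true), -1)[:, 0]
    if indices is not None:
        idx = np.asarray(indices, dtype=int)
        y_true, yhat = y_true[idx], yhat[idx]
    ok = np.isfinite(y_true) & np.isfinite(yhat)
    y_true, yhat = y_true[ok], yhat[ok]
    if len(y_true) < 3:
        raise ValueError("need at least 3 finite pairs to correlate")
    if np.std(y_true) == 0 or np.std(yhat) == 0:
        return float("nan")
    return float(np.corrcoef(y_true, yhat)[0, 1])


def crossvalidate(
    table: PhenotypeTable,
    fitters: Mapping[str, Callable[[PhenotypeTable], FWFit]],
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Masked-phenotype cross-validation of one or more fitting methods.

    For each replicate, one environment per line is masked, each fitter is
    run on the masked table, and the predictions are correlated with the
    held-back truth on both the training (unmasked) and validation
    (masked) records.  Returns a tidy frame with one row per
    (replicate, method) and columns ``cor_train``/``cor_validation``; mask
    seeds are derived from ``seed`` so the partition sequence is
    reproducible.
    """
    y_full = np.asarray(table.y, dtype=float)
    rows = []
    for rep in range(n_replicates):
        masked, idx = mask_one_env_per_line(table, seed=seed + rep)
        train_idx = np.setdiff1d(np.arange(len(y_full)), idx)
        assert len(np.intersect1d(train_idx, idx)) == 0
        for name, fitter in fitters.items():
            fit = fitter(masked)
            rows.append(
                {
                    "replicate": rep,
                    "method": name,
                    "cor_train": score_predictions(y_full, fit.yhat, train_idx),
                    "cor_validation": score_predictions(y_full, fit.yhat, idx),
                    "n_train": len(train_idx),
                    "n_validation": len(idx),
                }
            )
    return pd.DataFrame(rows)


def fitted_lines(
    fit: FWFit, table: PhenotypeTable, chain: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data for the classical reaction-norm plot.

    Returns ``(lines, cells)``: per variety the fitted intercept
    ``mu + g_i`` and slope ``1 + b_i`` (so a variety with average
    responsiveness has slope exactly 1), and per (variety, environment)
    cell the mean observed phenotype together with the estimated
    environment effect on the horizontal axis.
    """
    mu = float(fit.mu[chain])
    lines = pd.DataFrame(
        {
            "VAR": fit.varieties,
            "intercept": mu + fit.g[:, chain],
            "slope": 1.0 + fit.b[:, chain],
        }
    )
    h_of = dict(zip(fit.environments, fit.h[:, chain]))
    df = table.to_frame()
    cells = (
        df.dropna(subset=["y"])
        .groupby(["VAR", "ENV"], sort=False)["y"]
        .mean()
        .reset_index()
        .rename(columns={"y": "cell_mean"})
    )
    cells["h"] = cells["ENV"].map(h_of)
    return lines, cells
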