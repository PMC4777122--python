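"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

from fwreg import PhenotypeTable, validate_and_align


@pytest.fixture
def toy_2x2() -> PhenotypeTable:
    """Balanced 2 varieties x 2 environments, y = (1, 2, 3, 4)."""
    return PhenotypeTable(
        ["L1", "L1", "L2", "L2"], ["E1", "E2", "E1", "E2"], [1.0, 2.0, 3.0, 4.0]
    )


def random_small_table(rng: np.random.Generator, allow_missing: bool = True,
                       allow_replicates: bool = True) -> PhenotypeTable:
    """A random small trial (<=10 lines x <=6 envs) that stays connected.

    Cells are deleted at random but every line keeps >=2 cells and every
    environment >=1, and the full-factorial base guarantees connectivity.
    """
    n_l = rng.integers(3, 11)
    n_e = rng.integers(2, 7)
    reps = rng.integers(1, 3) if allow_replicates else 1
    var, env, y = [], [], []
    keep = np.ones((n_l, n_e), dtype=bool)
    if allow_missing:
        for i in range(n_l):
            if n_e > 2 and rng.random() < 0.5:
                keep[i, rng.integers(n_e)] = False
    # every environment must retain at least one cell
    for j in range(n_e):
        if not keep[:, j].any():
            keep[rng.integers(n_l), j] = True
    for i in range(n_l):
        for j in range(n_e):
            if not keep[i, j]:
                continue
            for _ in range(reps):
                var.append(f"L{i + 1}")
                env.append(f"E{j + 1}")
                y.append(float(rng.normal(4.0, 1.0)))
    return PhenotypeTable(var, env, y)


def constrained_ls_oracle(table: PhenotypeTable):
    """Brute-force constrained least squares for the main-effects model.

    Builds the dense design matrix for y = mu + g_i + h_j on observed
    records, parameterizes the two sum-to-zero constraints through a
    null-space basis, and solves by ordinary lstsq.  Entirely independent
    of the bordered-system solver under test.
    """
    frame = validate_and_align(table)
    obs = frame.observed
    y = frame.y[obs]
    vi = frame.variety_idx[obs]
    ei = frame.env_idx[obs]
    q, p = frame.n_varieties, frame.n_environments
    n = len(y)
    X = np.zeros((n, 1 + q + p))
    X[:, 0] = 1.0
    X[np.arange(n), 1 + vi] = 1.0
    X[np.arange(n), 1 + q + ei] = 1.0
    C = np.zeros((2, 1 + q + p))
    C[0, 1 : 1 + q] = 1.0
    C[1, 1 + q :] = 1.0
    N = scipy.linalg.null_space(C)
    coef, *_ = np.linalg.lstsq(X @ N, y, rcond=None)
    beta = N @ coef
    return float(beta[0]), beta[1 : 1 + q], beta[1 + q :]


def per_line_regression_oracle(table: PhenotypeTable, h_hat: np.ndarray):
    """Closed-form per-line simple regression of y on h_hat (slope, intercept)."""
    frame = validate_and_align(table)
    obs = frame.observed
    y = frame.y[obs]
    vi = frame.variety_idx[obs]
    x = np.asarray(h_hat)[frame.env_idx[obs]]
    out = {}
    for i, lab in enumerate(frame.varieties):
        sel = vi == i
        xi, yi = x[sel], y[sel]
        if len(xi) < 2 or np.ptp(xi) == 0:
            out[lab] = None
            continue
        slope = np.cov(xi, yi, ddof=1)[0, 1] / np.var(xi, ddof=1)
        intercept = yi.mean() - slope * xi.mean()
        rss = float(np.sum((yi - intercept - slope * xi) ** 2))
        out[lab] = (intercept, slope, rss, len(xi) - 2)
    return out
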