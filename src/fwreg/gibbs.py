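"""Single-step Bayesian Finlay-Wilkinson regression fitted by Gibbs sampling.

Model.  Observed phenotypes follow ``y_ijk ~ N(mu + g_i + h_j + b_i*h_j,
var_e)``.  The prior is ``g ~ N(0, A*var_g)``, ``b ~ N(0, A*var_b)``,
``h ~ N(0, H*var_h)`` with A a variety relationship matrix (pedigree- or
marker-derived) and H an environment covariance structure; identity
matrices recover independent effects.  The overall mean gets a flat prior
and each variance a scaled-inverse-chi-square prior with degrees of
freedom ``df`` and scale ``S2`` (prior mean ``df*S2/(df-2)`` when
``df > 2``).

Sampling.  All full conditionals are available in closed form, so a plain
Gibbs sampler applies.  Each cycle updates, in a fixed scan order, mu, the
g block, the b block, the h block, and the four variances.  Given the
other parameters the model is linear in each coefficient block, so each
block has a multivariate-normal conditional with precision
``diag(D)/var_e + K^-1/var_u``; when K is the identity that precision is
diagonal and the block update costs O(n_obs).  Variances are drawn from
scaled-inverse-chi-square conditionals.  Records with a missing phenotype
contribute to no likelihood sum -- they are predicted through the
parameters rather than imputed -- which is also what lets an environment
with no data at all be inferred through H.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .datamodel import (
    CovarianceSpec,
    FWFit,
    FWParams,
    ModelFrame,
    PhenotypeTable,
    validate_and_align,
)

__all__ = [
    "Hyperparameters",
    "GibbsConfig",
    "SampleStore",
    "default_hyperparameters",
    "gibbs_cycle",
    "run_gibbs",
    "draw_mu",
    "draw_coefficient_block",
    "draw_variance",
]

logger = logging.getLogger(__name__)

#: block names a Gibbs scan can update
_ALL_BLOCKS = frozenset(
    {"mu", "g", "b", "h", "var_e", "var_g", "var_b", "var_h"}
)


@dataclass
class Hyperparameters:
    """Degrees of freedom and scale of the four variance priors.

    Each variance u in {e, g, b, h} has prior ``var_u ~ ScaledInv-chi2(df_u,
    S2_u)`` whose mean is ``df_u*S2_u/(df_u - 2)`` for ``df_u > 2``.
    """

    df_e: float
    S2_e: float
    df_g: float
    S2_g: float
    df_b: float
    S2_b: float
    df_h: float
    S2_h: float

    def __post_init__(self):
        for name in ("e", "g", "b", "h"):
            df = getattr(self, f"df_{name}")
            s2 = getattr(self, f"S2_{name}")
            if not (df > 0 and s2 > 0):
                raise ValueError(
                    f"df_{name} and S2_{name} must be strictly positive"
                )
            if df <= 2:
                warnings.warn(
                    f"df_{name}={df} <= 2: the prior for var_{name} has no "
                    "finite mean (the sampler remains proper)",
                    stacklevel=2,
                )

    def prior_mean(self, name: str) -> float:
        """Prior expectation of a variance; ``inf`` when df <= 2."""
        df = getattr(self, f"df_{name}")
        s2 = getattr(self, f"S2_{name}")
        return df * s2 / (df - 2.0) if df > 2 else math.inf


#: fraction of Var(y) assigned, a priori, to each variance component
_R2_SPLIT = {"e": 0.5, "g": 0.25, "b": 0.25, "h": 0.5}
_DEFAULT_DF = 5.0


def default_hyperparameters(
    y_observed: np.ndarray, frame: ModelFrame | None = None
) -> Hyperparameters:
    """Default variance-prior hyperparameters from the phenotypic variance.

    All four priors use df = 5.  Scales are set so the prior expectations
    partition the sample variance of the observed phenotypes: half to the
    residual, a quarter each to the variety intercepts and slopes, and --
    deliberately generously, because the number of environments is usually
    tiny and its posterior accordingly wide -- half to the environment
    effects.  Hence ``S2 = E[var] * (df - 2) / df``.
    """
    y = np.asarray(y_observed, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 2:
        raise ValueError("need at least 2 observed phenotypes")
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("observed phenotypes have zero variance")
    kw = {}
    for name, r2 in _R2_SPLIT.items():
        kw[f"df_{name}"] = _DEFAULT_DF
        kw[f"S2_{name}"] = r2 * vy * (_DEFAULT_DF - 2.0) / _DEFAULT_DF
    return Hyperparameters(**kw)


@dataclass
class GibbsConfig:
    """Run-length, thinning, chain and persistence settings.

    Defaults are a single chain of 5000 cycles with the first 3000
    discarded as burn-in and a thinning of 5, so 400 draws remain for
    inference; longer chains are advisable for final analyses because the
    intercept and environment effects mix slowly in multiplicative models.
    """

    n_iter: int = 5000
    burn_in: int = 3000
    thin: int = 5
    n_chains: int = 1
    seed: int = 12345
    save_varieties: list | None = None  # None -> first two varieties
    save_envs: list | None = None       # None -> first two environments
    save_at: str | None = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class SampleStore:
    """Thinned post-burn-in draws of the monitored scalars, one block per chain.

    Every chain is a DataFrame with columns ``var_e, var_g, var_b, var_h,
    mu`` plus ``g[label]``/``b[label]`` for each monitored variety and
    ``h[label]`` for each monitored environment.
    """

    chains: list[pd.DataFrame]
    config: GibbsConfig

    def __getitem__(self, chain: int) -> pd.DataFrame:
        return self.chains[chain]

    def __len__(self) -> int:
        return len(self.chains)

    def write(self, prefix: str | None = None) -> list[str]:
        """Persist as one CSV per chain plus a JSON config sidecar."""
        prefix = prefix if prefix is not None else (self.config.save_at or "fw")
        paths = []
        for c, df in enumerate(self.chains):
            path = f"{prefix}samples_chain{c + 1}.csv"
            df.to_csv(path, index=False)
            paths.append(path)
        meta = {
            "n_iter": self.config.n_iter,
            "burn_in": self.config.burn_in,
            "thin": self.config.thin,
            "n_chains": self.config.n_chains,
            "seed": self.config.seed,
        }
        with open(f"{prefix}samples_config.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        return paths

    @classmethod
    def read(cls, prefix: str) -> "SampleStore":
        with open(f"{prefix}samples_config.json") as fh:
            meta = json.load(fh)
        cfg = GibbsConfig(**meta)
        chains = [
            pd.read_csv(f"{prefix}samples_chain{c + 1}.csv")
            for c in range(cfg.n_chains)
        ]
        return cls(chains=chains, config=cfg)


# ----------------------------------------------------------------------
# full-conditional draws (shared by the cycle and directly testable)

def draw_mu(resid_plus_mu_sum: float, n_obs: int, var_e: float,
            rng: np.random.Generator) -> float:
    """Draw mu | rest ~ N(mean of (y - g_i - (1+b_i)h_j), var_e/n_obs).

    ``resid_plus_mu_sum`` is the sum over observed records of
    ``y - g_i - (1+b_i)*h_j``; the flat prior on mu leaves the
    least-squares mean untouched.
    """
    return rng.normal(resid_plus_mu_sum / n_obs, math.sqrt(var_e / n_obs))


def draw_coefficient_block(
    r: np.ndarray,
    D: np.ndarray,
    K_inv: np.ndarray | None,
    var_u: float,
    var_e: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a coefficient block u | rest ~ N(P^-1 r/var_e, P^-1).

    ``P = diag(D)/var_e + K^-1/var_u`` is the conditional precision; ``r``
    collects, per level, the covariate-weighted partial residuals.  With
    ``K_inv=None`` (identity prior covariance) the precision is diagonal
    and the draw is elementwise; otherwise the dense system is solved
    through a Cholesky factorization.
    """
    if K_inv is None:
        prec = D / var_e + 1.0 / var_u
        mean = (r / var_e) / prec
        return mean + rng.standard_normal(len(r)) / np.sqrt(prec)
    P = K_inv / var_u
    P = P + np.diag(D / var_e)
    L = np.linalg.cholesky(P)
    mean = scipy.linalg.cho_solve((L, True), r / var_e)
    z = rng.standard_normal(len(r))
    return mean + scipy.linalg.solve_triangular(L, z, trans="T", lower=True)


def draw_variance(quad: float, q: int, df: float, S2: float,
                  rng: np.random.Generator) -> float:
    """Draw var | u ~ ScaledInv-chi2(df + q, (quad + df*S2)/(df + q)).

    ``quad`` is ``u' K^-1 u`` for a coefficient block of length q (or the
    residual sum of squares with q = n_obs for the residual variance).
    """
    return (quad + df * S2) / rng.chisquare(df + q)


def _obs_arrays(frame: ModelFrame):
    """Cached (y, variety_idx, env_idx) over observed records plus counts."""
    cache = frame.__dict__.get("_gibbs_obs")
    if cache is None:
        obs = frame.observed
        cache = (
            frame.y[obs],
            frame.variety_idx[obs],
            frame.env_idx[obs],
            np.bincount(frame.variety_idx[obs], minlength=frame.n_varieties).astype(float),
        )
        frame.__dict__["_gibbs_obs"] = cache
    return cache


def gibbs_cycle(
    state: FWParams,
    frame: ModelFrame,
    A_inv: np.ndarray | None,
    H_inv: np.ndarray | None,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    cycle: int | None = None,
    update: frozenset[str] | set[str] | None = None,
) -> FWParams:
    """One full Gibbs scan: mu, g, b, h, then the four variances.

    Covariance inverses are passed precomputed (``None`` means identity).
    Only observed records enter any sum.  ``update`` restricts the scan to
    a subset of {"mu", "g", "b", "h", "var_e", "var_g", "var_b", "var_h"},
    leaving the other blocks clamped at their current values -- useful for
    conditional runs and for checking a single full conditional in
    isolation.  Raises ``FloatingPointError`` (tagged with the cycle
    number when given) if any draw is non-finite.
    """
    if update is None:
        update = _ALL_BLOCKS
    elif not update <= _ALL_BLOCKS:
        raise ValueError(f"unknown block(s) {set(update) - _ALL_BLOCKS}")
    yo, vi, ei, cnt_g = _obs_arrays(frame)
    n_obs = len(yo)
    q_g = frame.n_varieties
    q_h = frame.n_environments
    mu = state.mu
    g, b, h = state.g.copy(), state.b.copy(), state.h.copy()
    var_e, var_g = state.var_e, state.var_g
    var_b, var_h = state.var_b, state.var_h

    # mu | rest (flat prior: with no data the conditional is improper, so
    # mu is left at its current value and everything else reduces to the prior)
    if "mu" in update and n_obs > 0:
        slope = 1.0 + b[vi]
        mu = draw_mu(float(np.sum(yo - g[vi] - slope * h[ei])), n_obs, var_e, rng)

    if "g" in update:
        r_g = np.bincount(
            vi, weights=yo - mu - (1.0 + b[vi]) * h[ei], minlength=q_g
        )
        g = draw_coefficient_block(r_g, cnt_g, A_inv, var_g, var_e, rng)

    if "b" in update:  # covariate h_j within each line
        x = h[ei]
        D_b = np.bincount(vi, weights=x * x, minlength=q_g)
        r_b = np.bincount(vi, weights=x * (yo - mu - g[vi] - x), minlength=q_g)
        b = draw_coefficient_block(r_b, D_b, A_inv, var_b, var_e, rng)

    if "h" in update:  # covariate 1 + b_i within each environment
        w = 1.0 + b[vi]
        D_h = np.bincount(ei, weights=w * w, minlength=q_h)
        r_h = np.bincount(ei, weights=w * (yo - mu - g[vi]), minlength=q_h)
        h = draw_coefficient_block(r_h, D_h, H_inv, var_h, var_e, rng)

    if "var_e" in update:
        resid = yo - mu - g[vi] - (1.0 + b[vi]) * h[ei]
        var_e = draw_variance(
            float(resid @ resid), n_obs, hyper.df_e, hyper.S2_e, rng
        )
    if "var_g" in update:
        quad_g = float(g @ (A_inv @ g)) if A_inv is not None else float(g @ g)
        var_g = draw_variance(quad_g, q_g, hyper.df_g, hyper.S2_g, rng)
    if "var_b" in update:
        quad_b = float(b @ (A_inv @ b)) if A_inv is not None else float(b @ b)
        var_b = draw_variance(quad_b, q_g, hyper.df_b, hyper.S2_b, rng)
    if "var_h" in update:
        quad_h = float(h @ (H_inv @ h)) if H_inv is not None else float(h @ h)
        var_h = draw_variance(quad_h, q_h, hyper.df_h, hyper.S2_h, rng)

    if not (
        math.isfinite(mu)
        and math.isfinite(var_e + var_g + var_b + var_h)
        and np.isfinite(g).all()
        and np.isfinite(b).all()
        and np.isfinite(h).all()
    ):
        where = f" at cycle {cycle}" if cycle is not None else ""
        raise FloatingPointError(f"non-finite Gibbs draw{where}")
    return dataclasses.replace(
        state, mu=mu, g=g, b=b, h=h,
        var_e=var_e, var_g=var_g, var_b=var_b, var_h=var_h,
    )


def _inverse_with_jitter(K: np.ndarray, name: str) -> np.ndarray:
    """Invert a covariance matrix, adding one round of diagonal jitter if
    the Cholesky factorization fails (marker-derived kinships are often
    numerically singular)."""
    try:
        c = scipy.linalg.cho_factor(K)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(K)))
        logger.warning(
            "factorization of %s failed; retrying with jitter %.3e", name, jitter
        )
        c = scipy.linalg.cho_factor(K + jitter * np.eye(K.shape[0]))
    return scipy.linalg.cho_solve(c, np.eye(K.shape[0]))


def _initial_state(frame: ModelFrame, hyper: Hyperparameters) -> FWParams:
    """Cheap starting values: mu at the data mean, g=b=0, h at centered
    environment means (0 where an environment has no data), variances at
    their prior expectations (prior scale when the mean is infinite)."""
    yo, _, ei, _ = _obs_arrays(frame)
    mu0 = float(np.mean(yo)) if len(yo) else 0.0
    cnt_e = np.bincount(ei, minlength=frame.n_environments).astype(float)
    sum_e = np.bincount(ei, weights=yo, minlength=frame.n_environments)
    with np.errstate(invalid="ignore"):
        h0 = np.where(cnt_e > 0, sum_e / np.maximum(cnt_e, 1.0) - mu0, 0.0)
    var0 = {
        name: (hyper.prior_mean(name) if getattr(hyper, f"df_{name}") > 2
               else getattr(hyper, f"S2_{name}"))
        for name in ("e", "g", "b", "h")
    }
    return FWParams(
        mu=mu0,
        g=np.zeros(frame.n_varieties),
        b=np.zeros(frame.n_varieties),
        h=h0,
        varieties=frame.varieties,
        environments=frame.environments,
        var_e=var0["e"], var_g=var0["g"], var_b=var0["b"], var_h=var0["h"],
    )


def _monitored(labels: list, requested: list | None) -> list:
    if requested is None:
        return labels[:2]
    requested = [str(l) for l in requested]
    unknown = [l for l in requested if l not in labels]
    if unknown:
        raise ValueError(f"monitored label(s) {unknown} not present in the table")
    return requested


class _Accumulator:
    """Streaming mean/SD over kept draws for an array-valued quantity."""

    def __init__(self, shape):
        self.n = 0
        self.s = np.zeros(shape)
        self.s2 = np.zeros(shape)

    def add(self, x):
        self.n += 1
        self.s += x
        self.s2 += np.square(x)

    def mean(self):
        return self.s / self.n

    def sd(self):
        if self.n < 2:
            return np.zeros_like(self.s)
        v = (self.s2 - self.s * self.s / self.n) / (self.n - 1)
        return np.sqrt(np.maximum(v, 0.0))


def run_gibbs(
    table: PhenotypeTable,
    A: CovarianceSpec | None = None,
    H: CovarianceSpec | None = None,
    hyper: Hyperparameters | None = None,
    config: GibbsConfig | None = None,
) -> tuple[FWFit, SampleStore]:
    """Fit the Bayesian Finlay-Wilkinson regression.

    Runs ``config.n_chains`` independent chains; chain c is seeded with a
    deterministic child of ``(config.seed, c)``, so identical inputs and
    configuration reproduce the run bit for bit.  Posterior means and SDs
    are computed from the thinned post-burn-in draws of every parameter
    and of the predictor at every record (missing-phenotype records
    included).  Returns the fit plus the thinned draws of the monitored
    scalars; the store is also written to ``config.save_at`` when set.
    """
    config = config if config is not None else GibbsConfig()
    frame = validate_and_align(table, A, H)
    if frame.n_obs < 2:
        raise ValueError("need at least 2 observed phenotypes")
    if hyper is None:
        hyper = default_hyperparameters(frame.y[frame.observed], frame)

    A_inv = _inverse_with_jitter(frame.A, "A") if frame.A is not None else None
    H_inv = _inverse_with_jitter(frame.H, "H") if frame.H is not None else None

    mon_v = _monitored(frame.varieties, config.save_varieties)
    mon_e = _monitored(frame.environments, config.save_envs)
    mon_vi = [frame.varieties.index(l) for l in mon_v]
    mon_ei = [frame.environments.index(l) for l in mon_e]
    columns = (
        ["var_e", "var_g", "var_b", "var_h", "mu"]
        + [f"g[{l}]" for l in mon_v]
        + [f"b[{l}]" for l in mon_v]
        + [f"h[{l}]" for l in mon_e]
    )

    n_kept = config.n_kept
    vi_all, ei_all = frame.variety_idx, frame.env_idx
    chains = []
    chain_results = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(c,))
        )
        state = _initial_state(frame, hyper)
        acc = {
            "mu": _Accumulator(()),
            "g": _Accumulator(frame.n_varieties),
            "b": _Accumulator(frame.n_varieties),
            "h": _Accumulator(frame.n_environments),
            "yhat": _Accumulator(frame.n_records),
            "var_e": _Accumulator(()),
            "var_g": _Accumulator(()),
            "var_b": _Accumulator(()),
            "var_h": _Accumulator(()),
        }
        draws = np.empty((n_kept, len(columns)))
        kept = 0
        for cycle in range(1, config.n_iter + 1):
            state = gibbs_cycle(state, frame, A_inv, H_inv, hyper, rng, cycle)
            if cycle % 1000 == 0:
                logger.info("chain %d: cycle %d/%d", c + 1, cycle, config.n_iter)
            past = cycle - config.burn_in
            if past <= 0 or past % config.thin != 0:
                continue
            if kept < n_kept:
                draws[kept] = (
                    [state.var_e, state.var_g, state.var_b, state.var_h, state.mu]
                    + [state.g[i] for i in mon_vi]
                    + [state.b[i] for i in mon_vi]
                    + [state.h[j] for j in mon_ei]
                )
                kept += 1
            yhat = (
                state.mu
                + state.g[vi_all]
                + (1.0 + state.b[vi_all]) * state.h[ei_all]
            )
            acc["mu"].add(state.mu)
            acc["g"].add(state.g)
            acc["b"].add(state.b)
            acc["h"].add(state.h)
            acc["yhat"].add(yhat)
            for name in ("var_e", "var_g", "var_b", "var_h"):
                acc[name].add(getattr(state, name))
        chains.append(pd.DataFrame(draws[:kept], columns=columns))
        chain_results.append(acc)

    def stack(name, fn):
        return np.column_stack([fn(acc[name]) for acc in chain_results])

    def scalar(name, fn):
        return np.array([float(fn(acc[name])) for acc in chain_results])

    fit = FWFit(
        method="Gibbs",
        varieties=frame.varieties,
        environments=frame.environments,
        mu=scalar("mu", _Accumulator.mean),
        sd_mu=scalar("mu", _Accumulator.sd),
        g=stack("g", _Accumulator.mean),
        sd_g=stack("g", _Accumulator.sd),
        b=stack("b", _Accumulator.mean),
        sd_b=stack("b", _Accumulator.sd),
        h=stack("h", _Accumulator.mean),
        sd_h=stack("h", _Accumulator.sd),
        yhat=stack("yhat", _Accumulator.mean),
        sd_yhat=stack("yhat", _Accumulator.sd),
        var_e=scalar("var_e", _Accumulator.mean),
        sd_var_e=scalar("var_e", _Accumulator.sd),
        var_g=scalar("var_g", _Accumulator.mean),
        sd_var_g=scalar("var_g", _Accumulator.sd),
        var_b=scalar("var_b", _Accumulator.mean),
        sd_var_b=scalar("var_b", _Accumulator.sd),
        var_h=scalar("var_h", _Accumulator.mean),
        sd_var_h=scalar("var_h", _Accumulator.sd),
        which_missing=frame.table.which_missing,
    )
    store = SampleStore(chains=chains, config=config)
    if config.save_at is not None:
        store.write(config.save_at)
    return fit, store
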