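"""Synthetic multi-environment trial data with exact reaction-norm structure.

Generates phenotype tables from ``y = mu + g_i + (1 + b_i) * h_j + e`` with
variety effects optionally drawn under a marker-derived kinship and
environment effects optionally drawn under an environment covariance, plus
the masking design used for cross-validation (one environment hidden per
line).  Every generator is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .datamodel import CovarianceSpec, FWParams, PhenotypeTable

__all__ = [
    "SimTruth",
    "kinship_from_dosages",
    "simulate_kinship",
    "simulate_fw_table",
    "mask_one_env_per_line",
]


def kinship_from_dosages(W: np.ndarray, p: np.ndarray) -> np.ndarray:
    """VanRaden-style genomic relationship matrix from 0/1/2 dosages.

    Dosages are centered by the expected value ``2p`` and scaled by the
    binomial standard deviation ``sqrt(2p(1-p))`` per marker, then
    cross-multiplied and divided by the marker count, so identical marker
    rows yield an off-diagonal equal to both diagonals and unrelated lines
    have off-diagonals near zero.
    """
    W = np.asarray(W, dtype=float)
    p = np.asarray(p, dtype=float)
    Z = (W - 2 * p) / np.sqrt(2 * p * (1 - p))
    G = Z @ Z.T / W.shape[1]
    return (G + G.T) / 2.0


@dataclass
class SimTruth:
    """The parameters actually used to generate a synthetic table."""

    params: FWParams
    n_lines: int
    n_envs: int
    replicates: int
    seed: int
    n_markers: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "mu": self.params.mu,
            "g": self.params.g.tolist(),
            "b": self.params.b.tolist(),
            "h": self.params.h.tolist(),
            "varieties": self.params.varieties,
            "environments": self.params.environments,
            "var_e": self.params.var_e,
            "var_g": self.params.var_g,
            "var_b": self.params.var_b,
            "var_h": self.params.var_h,
            "n_lines": self.n_lines,
            "n_envs": self.n_envs,
            "replicates": self.replicates,
            "seed": self.seed,
            "n_markers": self.n_markers,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_kinship(
    n_lines: int,
    n_markers: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_families: int | None = None,
    labels: list | None = None,
) -> CovarianceSpec:
    """Simulate a genomic relationship matrix from biallelic dosages.

    Markers are iid binomial(2, p) dosages with per-marker allele frequency
    p uniform on ``maf_range`` (no linkage disequilibrium -- sufficient to
    produce valid positive-semidefinite kinships).  The matrix is the
    VanRaden-style cross-product of centered, scaled dosages divided by the
    marker count, so unrelated lines have near-zero off-diagonals and the
    mean diagonal is close to 1.

    With ``n_families`` set, lines are grouped into that many full-sib
    families: each family has two binomial parents and every line inherits
    one allele from each parent per marker, giving expected within-family
    relatedness of about one half -- useful when a test needs genuinely
    structured kinship rather than a near-identity matrix.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi < 1):
        raise ValueError("maf_range must satisfy 0 < low <= high < 1")
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    if n_families is None:
        W = rng.binomial(2, p, size=(n_lines, n_markers)).astype(float)
    else:
        fam = np.repeat(np.arange(n_families), -(-n_lines // n_families))[:n_lines]
        W = np.empty((n_lines, n_markers))
        for f in range(n_families):
            parents = rng.binomial(1, p, size=(4, n_markers))  # 2 parents x 2 alleles
            members = np.flatnonzero(fam == f)
            gam1 = parents[rng.integers(0, 2, size=(len(members), n_markers)), np.arange(n_markers)]
            gam2 = parents[2 + rng.integers(0, 2, size=(len(members), n_markers)), np.arange(n_markers)]
            W[members] = gam1 + gam2
    G = kinship_from_dosages(W, p)
    if labels is None:
        labels = [f"L{i + 1}" for i in range(n_lines)]
    return CovarianceSpec(labels=labels, K=G, kind="lines")


def _mvn(rng: np.random.Generator, cov: np.ndarray | None, var: float,
         n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    if cov is None:
        return np.sqrt(var) * z
    # eigendecomposition tolerates the PSD (possibly singular) kinships
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, 0.0)
    return V @ (np.sqrt(w * var) * z)


def simulate_fw_table(
    n_lines: int = 300,
    n_envs: int = 8,
    mu: float = 4.0,
    var_e: float = 0.3,
    var_g: float = 0.09,
    var_b: float = 0.10,
    var_h: float = 0.9,
    A: CovarianceSpec | None = None,
    H: CovarianceSpec | None = None,
    env_effects: np.ndarray | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate a full-factorial trial under the reaction-norm model.

    ``g ~ N(0, A*var_g)``, ``b ~ N(0, A*var_b)`` and, unless fixed
    ``env_effects`` are supplied, ``h ~ N(0, H*var_h)``; then
    ``y = mu + g_i + (1 + b_i)*h_j + e`` with iid ``N(0, var_e)`` errors
    (``var_e = 0`` yields noise-free data satisfying the predictor
    identity exactly).  The default sizes and variances mirror a typical
    several-hundred-line wheat trial in a handful of environments.
    Returns the table together with the :class:`SimTruth` that generated
    it.
    """
    for name, v in (("var_e", var_e), ("var_g", var_g), ("var_b", var_b)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if A is not None and len(A.labels) != n_lines:
        raise ValueError("A dimension does not match n_lines")
    rng = np.random.default_rng(seed)
    A_mat = A.K if A is not None else None
    g = _mvn(rng, A_mat, var_g, n_lines)
    b = _mvn(rng, A_mat, var_b, n_lines)
    if env_effects is not None:
        h = np.asarray(env_effects, dtype=float)
        if len(h) != n_envs:
            raise ValueError("env_effects length does not match n_envs")
    else:
        if var_h < 0:
            raise ValueError("var_h must be non-negative")
        if H is not None and len(H.labels) != n_envs:
            raise ValueError("H dimension does not match n_envs")
        h = _mvn(rng, H.K if H is not None else None, var_h, n_envs)

    varieties = A.labels if A is not None else [f"L{i + 1}" for i in range(n_lines)]
    environments = H.labels if H is not None else [f"E{j + 1}" for j in range(n_envs)]
    vi = np.repeat(np.arange(n_lines), n_envs * replicates)
    ei = np.tile(np.repeat(np.arange(n_envs), replicates), n_lines)
    eps = (
        np.sqrt(var_e) * rng.standard_normal(len(vi)) if var_e > 0
        else np.zeros(len(vi))
    )
    y = mu + g[vi] + (1.0 + b[vi]) * h[ei] + eps
    table = PhenotypeTable(
        [varieties[i] for i in vi], [environments[j] for j in ei], y
    )
    params = FWParams(
        mu=mu, g=g, b=b, h=h,
        varieties=varieties, environments=environments,
        var_e=var_e, var_g=var_g, var_b=var_b, var_h=var_h,
    )
    truth = SimTruth(
        params=params, n_lines=n_lines, n_envs=n_envs,
        replicates=replicates, seed=seed,
        n_markers=None,
    )
    return table, truth


def mask_one_env_per_line(
    table: PhenotypeTable, seed: int = 0
) -> tuple[PhenotypeTable, np.ndarray]:
    """Hide exactly one environment's record per line (cross-validation mask).

    For every variety one of its observed environments is chosen uniformly
    at random and all of that variety's records in it are set missing.
    Requires every line to be observed in at least two environments.
    Returns the masked table and the masked record indices.
    """
    rng = np.random.default_rng(seed)
    masked_idx: list[int] = []
    var = np.asarray(table.var)
    env = np.asarray(table.env)
    observed = ~np.isnan(table.y)
    for v in table.varieties:
        rows = np.flatnonzero((var == v) & observed)
        envs = list(dict.fromkeys(env[rows]))  # first-appearance order
        if len(envs) < 2:
            raise ValueError(
                f"variety {v!r} is observed in fewer than 2 environments; "
                "masking would leave it without training data"
            )
        drop = envs[rng.integers(len(envs))]
        masked_idx.extend(rows[env[rows] == drop].tolist())
    idx = np.array(sorted(masked_idx), dtype=int)
    return table.masked(idx), idx
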