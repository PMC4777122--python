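"""Shared data structures for Finlay-Wilkinson regression.

The reaction-norm model underlying everything in this package is

    y_ijk = mu + g_i + h_j + b_i * h_j + e_ijk

where ``g_i`` is the main effect of variety *i*, ``h_j`` the main effect of
environment *j*, ``b_i`` the deviation of variety *i*'s responsiveness from
the average (the expected response per unit of environment effect is
``1 + b_i``), and ``e_ijk`` an iid normal error over replicates *k*.

This module defines the phenotype table, the labeled covariance matrices for
varieties (A, pedigree- or marker-derived) and environments (H), the
parameter and fit containers, and the label-alignment step that turns a
long-format table plus optional covariance matrices into an integer-indexed
model frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "CovarianceSpec",
    "FWParams",
    "FWFit",
    "ModelFrame",
    "validate_and_align",
    "predictor",
]

#: relative tolerance for symmetry and positive-semidefiniteness checks
PSD_RTOL = 1e-8

#: strings that parse as a missing trait value (besides an empty field)
NA_STRINGS = ("NA",)


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


class PhenotypeTable:
    """Long-format phenotype records: one row per (variety, environment, value).

    Variety and environment identifiers are treated as opaque labels and are
    never missing; the trait value may be missing (``NaN``).  Replicate
    records (same variety and environment) are allowed.  Varieties and
    environments are ordered by first appearance in the table, which fixes
    the output ordering of every downstream estimate.

    Parameters
    ----------
    var : sequence of labels
        Variety identifier per record.
    env : sequence of labels
        Environment identifier per record.
    y : sequence of float
        Trait value per record; ``NaN`` marks a missing phenotype.
    """

    def __init__(self, var: Sequence, env: Sequence, y: Sequence[float]):
        var = np.asarray([str(v) for v in var], dtype=object)
        env = np.asarray([str(e) for e in env], dtype=object)
        y = np.asarray(y, dtype=float)
        if not (len(var) == len(env) == len(y)):
            raise ValueError("VAR, ENV and y must have equal length")
        if len(var) == 0:
            raise ValueError("phenotype table is empty")
        for lab, name in ((var, "VAR"), (env, "ENV")):
            if any(v in ("nan", "None", "") for v in lab):
                raise ValueError(f"{name} labels must not be missing")
        self.var = var
        self.env = env
        self.y = y
        self.varieties: list[str] = list(pd.unique(var))
        self.environments: list[str] = list(pd.unique(env))

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_obs(self) -> int:
        """Number of records with a non-missing trait value."""
        return int(np.sum(~np.isnan(self.y)))

    @property
    def which_missing(self) -> np.ndarray:
        """Indices of records whose trait value is missing."""
        return np.flatnonzero(np.isnan(self.y))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"VAR": self.var, "ENV": self.env, "y": self.y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        """Build from a DataFrame with columns VAR, ENV, y (extras ignored)."""
        missing = {"VAR", "ENV", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table lacks column(s): {sorted(missing)}")
        return cls(df["VAR"].to_numpy(), df["ENV"].to_numpy(), df["y"].to_numpy())

    @classmethod
    def read(cls, path) -> "PhenotypeTable":
        """Read a CSV/TSV phenotype file with header columns VAR, ENV, y.

        The literal string ``NA`` (case-sensitive) and an empty field both
        parse as a missing trait value.
        """
        df = pd.read_csv(
            path,
            sep=_delimiter_for(path),
            dtype={"VAR": str, "ENV": str},
            na_values=list(NA_STRINGS),
            keep_default_na=False,
        )
        df["y"] = pd.to_numeric(df["y"], errors="raise")
        return cls.from_frame(df)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep=_delimiter_for(path), index=False, na_rep="NA")

    def masked(self, indices: Iterable[int]) -> "PhenotypeTable":
        """Return a copy with the trait value at ``indices`` set missing."""
        y = self.y.copy()
        y[np.asarray(list(indices), dtype=int)] = np.nan
        return PhenotypeTable(self.var, self.env, y)


@dataclass
class CovarianceSpec:
    """A labeled symmetric positive-semidefinite covariance/relationship matrix.

    ``kind`` is ``"lines"`` for a variety matrix (A) or ``"environments"``
    for an environment matrix (H).  Symmetry is required within a relative
    tolerance of 1e-8 and eigenvalues must be >= -1e-8 times the largest
    eigenvalue; matrices failing this are rejected at construction (no
    silent jitter here -- regularization happens only at inversion inside
    the Gibbs sampler).
    """

    labels: list
    K: np.ndarray
    kind: str = "lines"

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.K = np.asarray(self.K, dtype=float)
        if self.kind not in ("lines", "environments"):
            raise ValueError("kind must be 'lines' or 'environments'")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("covariance labels must be unique")
        n = len(self.labels)
        if self.K.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.K.shape} does not match {n} labels"
            )
        scale = float(np.max(np.abs(self.K))) or 1.0
        if not np.allclose(self.K, self.K.T, atol=PSD_RTOL * scale, rtol=0):
            raise ValueError("covariance matrix is not symmetric within tolerance")
        w = np.linalg.eigvalsh((self.K + self.K.T) / 2.0)
        if w[0] < -PSD_RTOL * max(w[-1], 0.0):
            raise ValueError(
                f"covariance matrix is not positive semi-definite "
                f"(min eigenvalue {w[0]:.3e})"
            )

    def aligned_to(self, labels: Sequence[str]) -> np.ndarray:
        """Return K reordered/subset to ``labels``.

        Labels present in the matrix but absent from ``labels`` are dropped;
        a label in ``labels`` missing from the matrix is a hard error.
        """
        pos = {l: i for i, l in enumerate(self.labels)}
        try:
            idx = np.array([pos[str(l)] for l in labels], dtype=int)
        except KeyError as err:
            raise KeyError(
                f"label {err.args[0]!r} in the phenotype table is absent from "
                f"the {self.kind} covariance matrix"
            ) from None
        return self.K[np.ix_(idx, idx)]

    @classmethod
    def read(cls, path, kind: str = "lines") -> "CovarianceSpec":
        """Read a CSV/TSV matrix whose first row and column hold the labels."""
        df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
        labels = [str(l) for l in df.index]
        if labels != [str(c) for c in df.columns]:
            raise ValueError("row and column labels of covariance file differ")
        return cls(labels=labels, K=df.to_numpy(dtype=float), kind=kind)

    def write(self, path) -> None:
        pd.DataFrame(self.K, index=self.labels, columns=self.labels).to_csv(
            path, sep=_delimiter_for(path)
        )


@dataclass
class FWParams:
    """One complete set of reaction-norm parameters.

    ``g`` and ``b`` are indexed by ``varieties``, ``h`` by ``environments``.
    The variance components are present only for parameter sets produced by
    (or fed to) the Gibbs sampler; the two-step OLS estimator does not
    define them.
    """

    mu: float
    g: np.ndarray
    b: np.ndarray
    h: np.ndarray
    varieties: list
    environments: list
    var_e: float | None = None
    var_g: float | None = None
    var_b: float | None = None
    var_h: float | None = None

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.varieties = [str(v) for v in self.varieties]
        self.environments = [str(e) for e in self.environments]
        if len(self.g) != len(self.varieties) or len(self.b) != len(self.varieties):
            raise ValueError("g/b length must match number of varieties")
        if len(self.h) != len(self.environments):
            raise ValueError("h length must match number of environments")

    def copy(self) -> "FWParams":
        return dataclasses.replace(
            self, g=self.g.copy(), b=self.b.copy(), h=self.h.copy()
        )


def predictor(params: FWParams, variety, env) -> float:
    """Evaluate the reaction-norm predictor mu + g_i + h_j + b_i*h_j.

    Raises ``KeyError`` for a variety or environment unknown to ``params``.
    """
    try:
        i = params.varieties.index(str(variety))
    except ValueError:
        raise KeyError(f"unknown variety {variety!r}") from None
    try:
        j = params.environments.index(str(env))
    except ValueError:
        raise KeyError(f"unknown environment {env!r}") from None
    return float(params.mu + params.g[i] + params.h[j] + params.b[i] * params.h[j])


@dataclass
class ModelFrame:
    """Integer-indexed design extracted from a PhenotypeTable.

    ``variety_idx``/``env_idx`` give, per record, the position of its labels
    in first-appearance order.  ``A``/``H`` are the covariance matrices
    aligned to that order, or ``None`` when an identity covariance is
    assumed.
    """

    table: PhenotypeTable
    variety_idx: np.ndarray
    env_idx: np.ndarray
    y: np.ndarray
    observed: np.ndarray
    varieties: list
    environments: list
    A: np.ndarray | None = None
    H: np.ndarray | None = None

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_obs(self) -> int:
        return int(self.observed.sum())

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_environments(self) -> int:
        return len(self.environments)


def validate_and_align(
    table: PhenotypeTable,
    A: CovarianceSpec | None = None,
    H: CovarianceSpec | None = None,
) -> ModelFrame:
    """Validate a phenotype table against optional covariance matrices.

    Returns a :class:`ModelFrame` with integer variety/environment indices,
    an observed mask, and A reordered to variety order and H to environment
    order.  A missing covariance matrix means identity (independent
    effects).  Covariance labels not present in the table are dropped after
    subsetting; a table label missing from a supplied matrix is an error.
    """
    vpos = {v: i for i, v in enumerate(table.varieties)}
    epos = {e: j for j, e in enumerate(table.environments)}
    variety_idx = np.array([vpos[v] for v in table.var], dtype=np.intp)
    env_idx = np.array([epos[e] for e in table.env], dtype=np.intp)
    A_mat = H_mat = None
    if A is not None:
        if A.kind != "lines":
            raise ValueError("A must have kind='lines'")
        A_mat = A.aligned_to(table.varieties)
    if H is not None:
        if H.kind != "environments":
            raise ValueError("H must have kind='environments'")
        H_mat = H.aligned_to(table.environments)
    return ModelFrame(
        table=table,
        variety_idx=variety_idx,
        env_idx=env_idx,
        y=table.y.copy(),
        observed=~np.isnan(table.y),
        varieties=list(table.varieties),
        environments=list(table.environments),
        A=A_mat,
        H=H_mat,
    )


@dataclass
class FWFit:
    """Fitted Finlay-Wilkinson regression (either estimator).

    Vector estimates are stored as matrices with one column per chain
    (exactly one column for OLS).  ``yhat`` holds the predictor
    ``mu + g_i + h_j + b_i*h_j`` evaluated at every record of the input
    table -- including records whose phenotype was missing, which is what
    makes cross-validation by masking possible.  For the Gibbs method the
    ``sd_*`` fields are posterior standard deviations and ``var_*`` the
    posterior means/SDs of the variance components; for OLS only
    ``pooled_resid_var`` (the degree-of-freedom-weighted mean of the
    within-line residual variances) is defined.
    """

    method: str
    varieties: list
    environments: list
    mu: np.ndarray                      # (n_chains,)
    g: np.ndarray                       # (n_varieties, n_chains)
    b: np.ndarray
    h: np.ndarray                       # (n_environments, n_chains)
    yhat: np.ndarray                    # (n_records, n_chains)
    which_missing: np.ndarray
    sd_mu: np.ndarray | None = None
    sd_g: np.ndarray | None = None
    sd_b: np.ndarray | None = None
    sd_h: np.ndarray | None = None
    sd_yhat: np.ndarray | None = None
    var_e: np.ndarray | None = None     # (n_chains,) posterior means
    var_g: np.ndarray | None = None
    var_b: np.ndarray | None = None
    var_h: np.ndarray | None = None
    sd_var_e: np.ndarray | None = None
    sd_var_g: np.ndarray | None = None
    sd_var_b: np.ndarray | None = None
    sd_var_h: np.ndarray | None = None
    pooled_resid_var: float | None = None
    line_status: np.ndarray | None = None  # OLS: True where b was estimable

    @property
    def n_chains(self) -> int:
        return self.g.shape[1]

    def params(self, chain: int = 0) -> FWParams:
        """Point-estimate parameters for one chain as an :class:`FWParams`."""
        kw = {}
        if self.var_e is not None:
            kw = dict(
                var_e=float(self.var_e[chain]),
                var_g=float(self.var_g[chain]),
                var_b=float(self.var_b[chain]),
                var_h=float(self.var_h[chain]),
            )
        return FWParams(
            mu=float(self.mu[chain]),
            g=self.g[:, chain],
            b=self.b[:, chain],
            h=self.h[:, chain],
            varieties=self.varieties,
            environments=self.environments,
            **kw,
        )

    def estimates_frame(self, table: PhenotypeTable) -> pd.DataFrame:
        """Per-record table of y and yhat (with SDs when available)."""
        df = table.to_frame()
        for c in range(self.n_chains):
            suffix = "" if self.n_chains == 1 else f"_chain{c + 1}"
            df[f"yhat{suffix}"] = self.yhat[:, c]
            if self.sd_yhat is not None:
                df[f"SD.yhat{suffix}"] = self.sd_yhat[:, c]
        return df

    def effects_frame(self) -> pd.DataFrame:
        """Per-variety g and b estimates, one row per variety."""
        cols = {"VAR": self.varieties}
        for c in range(self.n_chains):
            suffix = "" if self.n_chains == 1 else f"_chain{c + 1}"
            cols[f"g{suffix}"] = self.g[:, c]
            cols[f"b{suffix}"] = self.b[:, c]
            if self.sd_g is not None:
                cols[f"SD.g{suffix}"] = self.sd_g[:, c]
                cols[f"SD.b{suffix}"] = self.sd_b[:, c]
        return pd.DataFrame(cols)

    def env_frame(self) -> pd.DataFrame:
        cols = {"ENV": self.environments}
        for c in range(self.n_chains):
            suffix = "" if self.n_chains == 1 else f"_chain{c + 1}"
            cols[f"h{suffix}"] = self.h[:, c]
            if self.sd_h is not None:
                cols[f"SD.h{suffix}"] = self.sd_h[:, c]
        return pd.DataFrame(cols)
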