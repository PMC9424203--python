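"""Covariate-adjusted polygenic-score association.

Fits ``y ~ PGS + sex + age + PC1..PCk`` by least squares, computes
cluster-robust (sandwich) standard errors to account for the family
clustering of twins, and quantifies the incremental variance explained by
the PGS as the R-squared difference between the full model and the model
without the PGS column.

The sandwich estimator is::

    (X'X)^-1 ( sum_g X_g' e_g e_g' X_g ) (X'X)^-1

scaled by the small-sample factor ``G/(G-1) * (n-1)/(n-k)`` with G
clusters, so that with every observation in its own cluster it reduces to
the heteroskedasticity-robust HC1 estimator. Test statistics use a t
distribution with G-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """Least-squares fit with the pieces downstream inference needs."""

    params: np.ndarray
    names: list[str]
    fitted: np.ndarray
    resid: np.ndarray
    r2: float
    n: int
    k: int
    X: np.ndarray
    y: np.ndarray
    xtx_inv: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


@dataclass
class RobustInference:
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    cov: np.ndarray
    names: list[str]

    def for_term(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.se[i]), float(self.p[i])


@dataclass
class AssociationResult:
    """Covariate-adjusted PGS effect with cluster-robust inference."""

    beta: float
    se: float
    p: float
    delta_r2: float
    n: int
    n_clusters: int
    covariates: list[str]

    def __post_init__(self) -> None:
        if not 0 <= self.delta_r2 <= 1:
            raise ValueError(f"delta_r2 outside [0, 1]: {self.delta_r2}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p outside [0, 1]: {self.p}")
        if self.n_clusters > self.n:
            raise ValueError("more clusters than observations")


def fit_linear(y, X, names: list[str] | None = None) -> LinearFit:
    """Ordinary least squares with an explicit full-rank check.

    ``X`` must include the intercept column. Rank deficiency raises an
    error naming the collinear columns (identified from the QR diagonal).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} rows, X has {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in design or response; drop rows upstream")
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    tol = r_diag.max() * max(n, k) * np.finfo(float).eps
    if (r_diag <= tol).any():
        bad = [names[i] for i in np.where(r_diag <= tol)[0]]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ params
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearFit(
        params=params, names=names, fitted=fitted, resid=resid, r2=r2,
        n=n, k=k, X=X, y=y, xtx_inv=np.linalg.inv(X.T @ X),
    )


def cluster_robust_se(fit: LinearFit, cluster_ids) -> RobustInference:
    """Cluster-robust sandwich standard errors and t-tests (G-1 df)."""
    ids = np.asarray(cluster_ids)
    if ids.size != fit.n:
        raise ValueError("one cluster id per observation required")
    _, inverse = np.unique(ids, return_inverse=True)
    n_clusters = int(inverse.max()) + 1
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    xe = fit.X * fit.resid[:, None]
    sums = np.zeros((n_clusters, fit.k))
    np.add.at(sums, inverse, xe)
    meat = sums.T @ sums
    c = (n_clusters / (n_clusters - 1)) * ((fit.n - 1) / (fit.n - fit.k))
    cov = c * fit.xtx_inv @ meat @ fit.xtx_inv
    se = np.sqrt(np.diag(cov))
    tvals = fit.params / se
    df = n_clusters - 1
    p = 2 * stats.t.sf(np.abs(tvals), df)
    return RobustInference(se=se, t=tvals, p=p, df=df, cov=cov, names=fit.names)


def delta_r2(full_fit: LinearFit, reduced_fit: LinearFit) -> float:
    """R-squared increment of the full over the nested reduced model."""
    if full_fit.n != reduced_fit.n or not np.array_equal(full_fit.y, reduced_fit.y):
        raise ValueError("full and reduced fits must use the same rows")
    if reduced_fit.k != full_fit.k - 1:
        raise ValueError("reduced design must drop exactly the PGS column")
    return max(full_fit.r2 - reduced_fit.r2, 0.0)


def pgs_association(
    phenotype: pd.Series,
    pgs: pd.Series,
    covariates: pd.DataFrame,
    cluster_ids: pd.Series,
    pgs_name: str = "pgs",
) -> AssociationResult:
    """One-stop covariate-adjusted PGS association for one outcome.

    Aligns inputs on their index, drops incomplete rows (logged), fits the
    full and PGS-free models, and returns the standardized PGS
    coefficient with cluster-robust inference and the R-squared increment.
    """
    df = pd.DataFrame({"_y": phenotype, pgs_name: pgs})
    df = df.join(covariates, how="inner")
    df["_cluster"] = cluster_ids
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if dropped:
        logger.info("pgs_association: dropped %d incomplete rows", dropped)
    cov_names = list(covariates.columns)
    X_full = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"), df[[pgs_name] + cov_names]], axis=1
    )
    full = fit_linear(df["_y"], X_full)
    reduced = fit_linear(df["_y"], X_full.drop(columns=pgs_name))
    robust = cluster_robust_se(full, df["_cluster"].to_numpy())
    se, p = robust.for_term(pgs_name)
    return AssociationResult(
        beta=full.coef(pgs_name),
        se=se,
        p=p,
        delta_r2=delta_r2(full, reduced),
        n=full.n,
        n_clusters=robust.df + 1,
        covariates=cov_names,
    )
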