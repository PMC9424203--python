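"""Within/between-family decomposition of polygenic-score effects.

For complete dizygotic twin pairs the polygenic score is split exactly
into a family mean and the individual deviation from it, and both enter a
random-intercept model as fixed effects::

    Y_ij = a0 + bW (PGS_ij - mean PGS_j) + bB mean PGS_j + gamma_j + e_ij

with ``gamma_j ~ N(0, var_family)`` shared by co-twins and
``e_ij ~ N(0, var_resid)``. Equal within- and between-family coefficients
indicate direct genetic effects; an excess between-family coefficient
indicates indirect (genetic nurture) or confounded (stratification,
assortative mating) pathways, because Mendelian segregation randomizes
the within-pair contrast with respect to those channels.

Estimation is restricted maximum likelihood, profiled over the variance
ratio ``theta = var_family / var_resid``: for a given theta the fixed
effects are generalized least squares (closed form for balanced pairs),
the residual variance is the REML estimate ``y' P y / (n - k)``, and a
one-dimensional bounded search minimizes the restricted criterion in
theta. The boundary ``theta = 0`` (no family variance) is allowed and
then reproduces OLS exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


def decompose_pgs(scores: pd.Series, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Exact within/between split of PGS for complete DZ twin pairs.

    Returns a DataFrame indexed by sample id with columns ``family_id``,
    ``pgs``, ``within`` (deviation from the family mean) and ``between``
    (family mean); ``within + between`` reconstructs the score exactly and
    within components sum to zero inside each family. MZ pairs are
    excluded; pairs with a missing score are dropped with a logged count.
    """
    dz = pedigree[pedigree["zygosity"] == "DZ"]
    rows = []
    dropped = 0
    for _, fam in dz.iterrows():
        t1, t2 = fam["twin1_id"], fam["twin2_id"]
        s1 = scores.get(t1, np.nan)
        s2 = scores.get(t2, np.nan)
        if pd.isna(s1) or pd.isna(s2):
            dropped += 1
            continue
        mean = (s1 + s2) / 2.0
        rows.append((t1, fam["family_id"], s1, s1 - mean, mean))
        rows.append((t2, fam["family_id"], s2, s2 - mean, mean))
    if dropped:
        logger.info("decompose_pgs: dropped %d incomplete DZ pairs", dropped)
    out = pd.DataFrame(rows, columns=["sample_id", "family_id", "pgs", "within", "between"])
    return out.set_index("sample_id")


@dataclass
class DecompositionResult:
    """Fixed and random effects of the within/between random-intercept fit."""

    beta_within: float
    beta_between: float
    intercept: float
    var_family: float
    var_resid: float
    se_within: float
    se_between: float
    ci95_within: tuple
    ci95_between: tuple
    cov_within_between: float
    n_pairs: int
    converged: bool
    params: pd.Series          # all fixed effects
    cov_fixed: pd.DataFrame    # GLS covariance of all fixed effects
    theta: float               # var_family / var_resid at the optimum

    def __post_init__(self) -> None:
        if self.var_family < 0 or self.var_resid < 0:
            raise ValueError("variance components must be non-negative")

    def table_rows(self, outcome: str = "outcome") -> pd.DataFrame:
        """Two rows (between, within) shaped like a results table."""
        return pd.DataFrame(
            {
                "outcome": outcome,
                "effect": ["between", "within"],
                "beta": [self.beta_between, self.beta_within],
                "se": [self.se_between, self.se_within],
                "p": [
                    2 * stats.norm.sf(abs(self.beta_between / self.se_between)),
                    2 * stats.norm.sf(abs(self.beta_within / self.se_within)),
                ],
                "ci_low": [self.ci95_between[0], self.ci95_within[0]],
                "ci_high": [self.ci95_between[1], self.ci95_within[1]],
                "n_pairs": self.n_pairs,
            }
        )


def _family_sums(a: np.ndarray, fam_index: np.ndarray, n_fam: int) -> np.ndarray:
    out = np.zeros((n_fam,) + a.shape[1:])
    np.add.at(out, fam_index, a)
    return out


def reml_criterion(theta: float, y: np.ndarray, X: np.ndarray, fam_index: np.ndarray):
    """Profiled REML criterion (-2 restricted log-likelihood, up to a constant).

    Families are pairs, so ``V_j = I + theta * J`` per family and
    ``V_j^-1 = I - theta/(1+2 theta) J``; all GLS quantities reduce to
    whole-sample and family-sum cross products. Returns
    ``(criterion, beta, cov_unscaled, sigma2)`` where the fixed-effect
    covariance is ``sigma2 * cov_unscaled``.
    """
    n, k = X.shape
    n_fam = int(fam_index.max()) + 1
    a = theta / (1.0 + 2.0 * theta)
    S = _family_sums(X, fam_index, n_fam)
    sy = _family_sums(y[:, None], fam_index, n_fam)[:, 0]
    A = X.T @ X - a * S.T @ S            # X' V^-1 X
    b = X.T @ y - a * S.T @ sy           # X' V^-1 y
    yvy = y @ y - a * sy @ sy
    beta = np.linalg.solve(A, b)
    quad = yvy - beta @ b                # y' P y
    sigma2 = quad / (n - k)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or sigma2 <= 0:
        return np.inf, beta, np.linalg.inv(A), max(sigma2, 1e-300)
    logdet_v = n_fam * np.log1p(2.0 * theta)
    crit = (n - k) * np.log(sigma2) + logdet_v + logdet_a
    return crit, beta, np.linalg.inv(A), sigma2


def fit_random_intercept(
    y: pd.Series,
    decomposed: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_pairs: int = 10,
) -> DecompositionResult:
    """REML fit of the within/between random-intercept model on DZ pairs.

    Parameters
    ----------
    y
        Outcome per sample (indexed by sample id).
    decomposed
        Output of :func:`decompose_pgs`.
    covariates
        Optional additional fixed effects (conventionally sex and the top
        PCs; age is collinear with the family intercept for twins and is
        not included).
    min_pairs
        Minimum number of complete pairs required.
    """
    df = decomposed.join(y.rename("_y"), how="inner")
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    # keep only families still complete after missing-data removal
    sizes = df.groupby("family_id")["_y"].transform("size")
    incomplete = int((sizes != 2).sum())
    if incomplete:
        logger.info("fit_random_intercept: dropped %d members of incomplete pairs", incomplete)
    df = df[sizes == 2].sort_values(["family_id"]).copy()
    n_pairs = len(df) // 2
    if n_pairs < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, have {n_pairs}")

    cov_names = list(covariates.columns) if covariates is not None else []
    names = ["const", "within", "between"] + cov_names
    X = np.column_stack(
        [np.ones(len(df)), df["within"].to_numpy(), df["between"].to_numpy()]
        + [df[c].to_numpy(dtype=float) for c in cov_names]
    )
    yv = df["_y"].to_numpy(dtype=float)
    fam_codes = pd.factorize(df["family_id"])[0]

    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    tol = r_diag.max() * X.shape[0] * np.finfo(float).eps
    if (r_diag <= tol).any():
        bad = [names[i] for i in np.where(r_diag <= tol)[0]]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")

    def objective(log_theta: float) -> float:
        return reml_criterion(np.exp(log_theta), yv, X, fam_codes)[0]

    res = optimize.minimize_scalar(objective, bounds=(-12.0, 6.0), method="bounded",
                                   options={"xatol": 1e-10})
    crit_opt = res.fun
    theta = float(np.exp(res.x))
    crit_zero = reml_criterion(0.0, yv, X, fam_codes)[0]
    converged = bool(res.success)
    if crit_zero <= crit_opt:
        theta = 0.0  # boundary estimate: no family variance
    crit, beta, cov_unscaled, sigma2 = reml_criterion(theta, yv, X, fam_codes)
    cov_fixed = sigma2 * cov_unscaled
    se = np.sqrt(np.diag(cov_fixed))
    params = pd.Series(beta, index=names)
    cov_df = pd.DataFrame(cov_fixed, index=names, columns=names)

    iw, ib = names.index("within"), names.index("between")
    z = stats.norm.ppf(0.975)
    return DecompositionResult(
        beta_within=float(beta[iw]),
        beta_between=float(beta[ib]),
        intercept=float(beta[0]),
        var_family=float(theta * sigma2),
        var_resid=float(sigma2),
        se_within=float(se[iw]),
        se_between=float(se[ib]),
        ci95_within=(float(beta[iw] - z * se[iw]), float(beta[iw] + z * se[iw])),
        ci95_between=(float(beta[ib] - z * se[ib]), float(beta[ib] + z * se[ib])),
        cov_within_between=float(cov_fixed[iw, ib]),
        n_pairs=n_pairs,
        converged=converged,
        params=params,
        cov_fixed=cov_df,
        theta=theta,
    )


@dataclass
class WithinBetweenComparison:
    difference: float   # beta_between - beta_within
    z: float
    p: float
    ci_overlap: bool


def compare_within_between(result: DecompositionResult) -> WithinBetweenComparison:
    """Wald test of beta_between - beta_within, plus the CI-overlap indicator.

    The Wald z uses the joint GLS covariance of the two fixed effects
    (for balanced pairs the within and between regressors are orthogonal,
    so the covariance term is typically near zero). The confidence-interval
    overlap flag is the cruder eyeball comparison sometimes reported
    alongside.
    """
    if not result.converged:
        logger.warning("compare_within_between: comparing a non-converged fit")
    diff = result.beta_between - result.beta_within
    var = result.se_between**2 + result.se_within**2 - 2.0 * result.cov_within_between
    if var <= 0:
        raise ValueError("non-positive variance of the contrast")
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    lo_w, hi_w = result.ci95_within
    lo_b, hi_b = result.ci95_between
    overlap = (lo_w <= hi_b) and (lo_b <= hi_w)
    return WithinBetweenComparison(difference=float(diff), z=float(z), p=float(p), ci_overlap=bool(overlap))


def decomposition_table(results: dict[str, DecompositionResult]) -> pd.DataFrame:
    """Stack per-outcome results into one between/within table."""
    return pd.concat(
        [r.table_rows(outcome) for outcome, r in results.items()], ignore_index=True
    )
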