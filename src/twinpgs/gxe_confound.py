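"""Gene-environment correlation and confounding diagnostics.

Three complementary checks on whether a polygenic score's association is
inflated by non-direct pathways:

* a family-environment enrichment index (first principal component of
  four environment items) correlated with individuals' PGS — a nonzero
  correlation is evidence of gene-environment correlation;
* the co-twin PGS correlation in dizygotic pairs, whose Mendelian
  expectation under random mating in a homogeneous population is 0.50 —
  a confidence interval excluding 0.50 suggests assortative mating or
  residual population structure;
* the expected out-of-sample predictive accuracy of a score,
  ``r2 = h2_snp / (1 + (M/N) h2_snp)``, from discovery-GWAS metadata.

Correlation confidence intervals use the Fisher z transform
(``atanh(r)``, SE ``1/sqrt(n-3)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pgs import GwasSummaryMeta

logger = logging.getLogger(__name__)

ENVIRONMENT_ITEMS = ("n_records", "n_players", "concert_freq", "music_edu_before12")


@dataclass
class CorrelationResult:
    """Pearson correlation with a Fisher-transform confidence interval."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    pairing: str = "individual"     # "individual" | "twin_pair"
    contains_half: bool | None = None

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError(f"correlation outside [-1, 1]: {self.r}")
        if not self.ci_low <= self.r <= self.ci_high:
            raise ValueError("confidence interval does not contain the estimate")


@dataclass
class EnvironmentIndex:
    """First principal component of the family-environment items."""

    scores: pd.Series       # per family
    loadings: pd.Series     # per item
    eigenvalue: float


def environment_index(items: pd.DataFrame) -> EnvironmentIndex:
    """Enrichment index: PC1 of the standardized environment items.

    The four items are column-standardized and the leading eigenvector of
    their correlation matrix defines the index; the sign is oriented so
    the music-education item loads positively (higher index = more
    musically enriched childhood environment). Constant items are dropped
    with a warning. The index variance equals the leading eigenvalue.
    """
    cols = [c for c in ENVIRONMENT_ITEMS if c in items.columns]
    missing_cols = set(ENVIRONMENT_ITEMS) - set(cols)
    if missing_cols:
        raise ValueError(f"environment items missing columns: {sorted(missing_cols)}")
    if len(items) < 2:
        raise ValueError("need at least 2 families")
    x = items[list(cols)].astype(float)
    keep = [c for c in cols if x[c].std(ddof=1) > 0]
    for c in set(cols) - set(keep):
        logger.warning("environment_index: dropping constant item %r", c)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant environment items")
    z = (x[keep] - x[keep].mean()) / x[keep].std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    loadings = pd.Series(lead, index=keep)
    anchor = "music_edu_before12" if "music_edu_before12" in keep else keep[0]
    if loadings[anchor] < 0:
        loadings = -loadings
    scores = pd.Series(z.to_numpy() @ loadings.to_numpy(), index=items.index, name="environment_index")
    if "family_id" in items.columns:
        scores.index = items["family_id"]
    return EnvironmentIndex(scores=scores, loadings=loadings, eigenvalue=float(evals[-1]))


def pearson_r_ci(x, y, pairing: str = "individual") -> CorrelationResult:
    """Pearson correlation with 95% Fisher-transform CI and two-sided p.

    In ``twin_pair`` mode ``x`` and ``y`` are the twin-1 and twin-2 score
    vectors under a deterministic twin ordering, ``n`` is the number of
    pairs, and ``contains_half`` records whether 0.50 falls inside the CI
    (bounds inclusive).
    """
    if pairing not in ("individual", "twin_pair"):
        raise ValueError(f"unknown pairing {pairing!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete observation pairs, have {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the correlated vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return fisher_ci(r, n, pairing=pairing)


def fisher_ci(r: float, n: int, pairing: str = "individual") -> CorrelationResult:
    """Build a :class:`CorrelationResult` from a correlation and sample size."""
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    p = 2 * stats.norm.sf(abs(z) / se)
    contains = bool(lo <= 0.5 <= hi) if pairing == "twin_pair" else None
    return CorrelationResult(
        r=float(r), n=int(n), ci_low=float(lo), ci_high=float(hi),
        p=float(p), pairing=pairing, contains_half=contains,
    )


def dz_pgs_correlation(scores: pd.Series, pedigree: pd.DataFrame) -> CorrelationResult:
    """Co-twin PGS correlation over complete DZ pairs.

    Twins within each pair are ordered lexicographically by sample id so
    the statistic is deterministic; swapping every pair's labels
    simultaneously leaves the Pearson correlation unchanged.
    """
    dz = pedigree[pedigree["zygosity"] == "DZ"]
    first, second = [], []
    for _, fam in dz.iterrows():
        a, b = sorted([fam["twin1_id"], fam["twin2_id"]])
        sa, sb = scores.get(a, np.nan), scores.get(b, np.nan)
        if pd.isna(sa) or pd.isna(sb):
            continue
        first.append(sa)
        second.append(sb)
    return pearson_r_ci(np.array(first), np.array(second), pairing="twin_pair")


def test_expected_half(result: CorrelationResult) -> str:
    """Verdict on the DZ co-twin correlation against its 0.50 expectation.

    A CI containing 0.50 (bounds inclusive) is "consistent with 0.50";
    otherwise the verdict reports the direction of departure, which points
    to confounding (assortative mating / population structure) when above.
    """
    if result.pairing != "twin_pair":
        raise ValueError("verdict requires a twin_pair-mode correlation")
    if result.ci_low <= 0.5 <= result.ci_high:
        return "consistent with 0.50"
    if result.ci_low > 0.5:
        return "exceeds 0.50"
    return "below 0.50"


def expected_r2(meta: GwasSummaryMeta) -> float:
    """Expected predictive accuracy r2 = h2_snp / (1 + (M/N) h2_snp).

    Increases with the discovery sample size N and is bounded above by
    the SNP heritability (the infinite-GWAS limit).
    """
    ratio = meta.n_variants / meta.n_discovery
    return meta.h2_snp / (1.0 + ratio * meta.h2_snp)
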