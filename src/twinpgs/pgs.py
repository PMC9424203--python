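"""Polygenic-score weights and scoring.

A polygenic score is a weighted sum of effect-allele dosages,
``score_i = sum_v w_v d_iv``. This module holds the weight container
(:class:`WeightSet`), the summary-statistic BLUP re-estimation of marginal
GWAS effects that accounts for LD between variants, the scoring routine
with allele matching (exact / swapped / strand-ambiguous), monozygotic
co-twin score imputation, and the variable standardization used before
all downstream models.

SBLUP
-----
Marginal GWAS effects beta are jointly re-estimated per LD block by
solving ``(R + kappa I) b = beta`` where ``R`` is the block's variant
correlation matrix and the ridge shrinkage is ``kappa = lambda / N`` with
``lambda = M (1/h2_snp - 1)`` — ``M`` the number of independent variants,
``N`` the discovery sample size, and ``h2_snp`` the SNP heritability.
With no LD (``R = I``) this uniformly shrinks each effect by
``1/(1 + kappa)``; with individual-level data it is equivalent to ridge
regression with penalty ``lambda``, which is how the implementation is
validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

#: PGS-Catalog-compatible weight table columns
WEIGHT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "effect_weight")

_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class GwasSummaryMeta:
    """Summary-level metadata of a discovery GWAS.

    h2_snp : SNP heritability captured by the GWAS, in (0, 1).
    n_variants : number of independent variants M.
    n_discovery : discovery sample size N.
    """

    h2_snp: float
    n_variants: int
    n_discovery: int

    def __post_init__(self) -> None:
        if not 0 < self.h2_snp < 1:
            raise ValueError(f"h2_snp must be in (0, 1), got {self.h2_snp}")
        if self.n_variants <= 0 or self.n_discovery <= 0:
            raise ValueError("n_variants and n_discovery must be positive")

    @property
    def shrinkage(self) -> float:
        """Ridge shrinkage kappa = M (1/h2_snp - 1) / N."""
        return self.n_variants * (1.0 / self.h2_snp - 1.0) / self.n_discovery


@dataclass
class WeightSet:
    """Per-variant effect-allele weights (marginal GWAS or SBLUP)."""

    table: pd.DataFrame
    provenance: str = "marginal"

    def __post_init__(self) -> None:
        for col in WEIGHT_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"weight table missing column {col!r}")
        if self.table["variant_id"].duplicated().any():
            raise ValueError("duplicated variant ids in weight table")
        w = self.table["effect_weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        if self.provenance not in ("marginal", "sblup"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def weights(self) -> pd.Series:
        return pd.Series(
            self.table["effect_weight"].to_numpy(dtype=float),
            index=self.table["variant_id"],
        )


def read_weights(path: str, provenance: str = "marginal") -> WeightSet:
    return WeightSet(pd.read_csv(path, sep="\t"), provenance=provenance)


def write_weights(ws: WeightSet, path: str) -> None:
    ws.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# SBLUP
# ---------------------------------------------------------------------------

def sblup_reweight(
    marginal: WeightSet,
    ld_blocks: list[tuple[list[str], np.ndarray]],
    meta: GwasSummaryMeta,
) -> WeightSet:
    """Re-estimate marginal effects jointly within LD blocks (SBLUP).

    Parameters
    ----------
    marginal
        Marginal (per-variant) GWAS effect sizes.
    ld_blocks
        List of ``(variant_ids, R)`` pairs; every weighted variant must
        appear in exactly one block and each ``R`` must be a symmetric
        positive semi-definite correlation matrix.
    meta
        Discovery-GWAS metadata supplying the shrinkage
        ``kappa = M (1/h2_snp - 1) / N``.
    """
    beta = marginal.weights()
    assigned: dict[str, int] = {}
    for bi, (ids, r) in enumerate(ld_blocks):
        r = np.asarray(r, dtype=float)
        if r.shape != (len(ids), len(ids)):
            raise ValueError(f"block {bi}: correlation matrix shape {r.shape} != {len(ids)} variants")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError(f"block {bi}: correlation matrix not symmetric")
        for v in ids:
            if v in assigned:
                raise ValueError(f"variant {v} assigned to more than one LD block")
            assigned[v] = bi
    missing = [v for v in beta.index if v not in assigned]
    if missing:
        raise ValueError(f"{len(missing)} weighted variants not assigned to any LD block (e.g. {missing[:3]})")

    kappa = meta.shrinkage
    new = beta.copy()
    for ids, r in ld_blocks:
        in_set = [v for v in ids if v in beta.index]
        if not in_set:
            continue
        pos = [ids.index(v) for v in in_set]
        r_sub = np.asarray(r, dtype=float)[np.ix_(pos, pos)]
        lhs = r_sub + kappa * np.eye(len(in_set))
        if kappa == 0:
            # kappa = 0 only solvable for a non-singular block
            if np.linalg.matrix_rank(r_sub) < len(in_set):
                raise np.linalg.LinAlgError("singular LD block with zero shrinkage (kappa = 0)")
        new.loc[in_set] = scipy.linalg.solve(lhs, beta.loc[in_set].to_numpy(), assume_a="sym")
    table = marginal.table.copy()
    table["effect_weight"] = new.loc[table["variant_id"]].to_numpy()
    logger.info("sblup_reweight: kappa = %.6g over %d blocks", kappa, len(ld_blocks))
    return WeightSet(table, provenance="sblup")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS_PAIRS


def compute_pgs(gm, weights: WeightSet) -> pd.Series:
    """Score samples as the weighted sum of effect-allele dosages.

    Allele matching per variant: exact match keeps the dosage; swapped
    alleles (weight effect allele equals the matrix's other allele) flip
    the dosage to ``2 - d``; strand-ambiguous pairs (A/T, C/G) are excluded
    with a logged count, as are variants whose allele sets disagree.
    Missing dosages are replaced by ``2 x frequency`` of the effect allele.

    Raises
    ------
    ValueError
        If no variant survives matching; the message reports per-cause
        exclusion counts.
    """
    meta = gm.variants.set_index("variant_id")
    counts = {"not_in_genotypes": 0, "ambiguous": 0, "allele_mismatch": 0, "matched": 0, "flipped": 0}
    cols: list[int] = []
    signs: list[int] = []
    w_used: list[float] = []
    colpos = {v: j for j, v in enumerate(gm.variants["variant_id"])}
    for _, row in weights.table.iterrows():
        vid = row["variant_id"]
        if vid not in colpos:
            counts["not_in_genotypes"] += 1
            continue
        if _is_ambiguous(row["effect_allele"], row["other_allele"]):
            counts["ambiguous"] += 1
            continue
        g_eff = meta.at[vid, "effect_allele"]
        g_oth = meta.at[vid, "other_allele"]
        if row["effect_allele"] == g_eff and row["other_allele"] == g_oth:
            counts["matched"] += 1
            sign = 1
        elif row["effect_allele"] == g_oth and row["other_allele"] == g_eff:
            counts["flipped"] += 1
            sign = -1
        else:
            counts["allele_mismatch"] += 1
            continue
        cols.append(colpos[vid])
        signs.append(sign)
        w_used.append(float(row["effect_weight"]))
    if not cols:
        raise ValueError(f"no overlapping variants after allele matching: {counts}")
    logger.info("compute_pgs: %s", counts)

    j = np.array(cols)
    sgn = np.array(signs, dtype=float)
    w = np.array(w_used)
    d = gm.dosages[:, j].astype(float)
    miss = gm.missing[:, j]
    if miss.any():
        freq = gm.variants.iloc[j]["frequency"].to_numpy(dtype=float)
        obs = gm.observed_frequencies()[j]
        freq = np.where(np.isfinite(freq), freq, obs)
        fill = 2.0 * freq
        d = np.where(miss, fill[None, :], d)
        logger.info("compute_pgs: %d missing dosages imputed as 2 x frequency", int(miss.sum()))
    # swapped alleles: dosage of the weight's effect allele is 2 - d
    d_eff = np.where(sgn[None, :] > 0, d, 2.0 - d)
    scores = d_eff @ w
    return pd.Series(scores, index=gm.sample_ids, name="pgs")


def impute_mz_pgs(scores: pd.Series, pedigree: pd.DataFrame) -> pd.Series:
    """Fill a monozygotic twin's missing score with the co-twin's score.

    ``pedigree`` must carry ``twin1_id``, ``twin2_id`` and ``zygosity``
    columns. Dizygotic twins are never imputed; MZ pairs with both scores
    missing remain missing (warning logged), as do pairs with unknown
    zygosity.
    """
    out = scores.copy()
    n_imputed = 0
    for _, row in pedigree.iterrows():
        zyg = row.get("zygosity")
        if pd.isna(zyg) or zyg not in ("MZ", "DZ"):
            logger.warning("impute_mz_pgs: pair %s/%s skipped (zygosity missing)", row["twin1_id"], row["twin2_id"])
            continue
        if zyg != "MZ":
            continue
        t1, t2 = row["twin1_id"], row["twin2_id"]
        s1 = out.get(t1, np.nan)
        s2 = out.get(t2, np.nan)
        if pd.isna(s1) and pd.isna(s2):
            logger.warning("impute_mz_pgs: MZ pair %s/%s both missing", t1, t2)
            continue
        if pd.isna(s1):
            out.loc[t1] = s2
            n_imputed += 1
        elif pd.isna(s2):
            out.loc[t2] = s1
            n_imputed += 1
    logger.info("impute_mz_pgs: imputed %d MZ co-twin scores", n_imputed)
    return out


def standardize(table: pd.DataFrame, exempt_columns: list[str] = ()) -> pd.DataFrame:
    """Z-score every non-exempt column to mean 0 and SD 1 (denominator n-1).

    Exempt columns (conventionally sex, age and the PCs) are returned
    byte-identical. Missing values are preserved; means and SDs are
    computed over observed entries. A zero-variance non-exempt column is
    an error naming the column. The operation is idempotent.
    """
    out = table.copy()
    for col in table.columns:
        if col in exempt_columns:
            continue
        x = table[col]
        if not pd.api.types.is_numeric_dtype(x):
            raise ValueError(f"cannot standardize non-numeric column {col!r}")
        sd = x.std(ddof=1, skipna=True)
        if not sd > 0:
            raise ValueError(f"zero-variance column {col!r}")
        out[col] = (x - x.mean(skipna=True)) / sd
    return out
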