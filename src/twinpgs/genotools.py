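"""Genotype containers, file I/O, and the ancestry-covariate pipeline.

The central container is :class:`GenotypeMatrix`: an effect-allele dosage
matrix (samples x variants) with per-variant metadata. Genotypes are read
from VCF (via pysam) or a plain dosage TSV, filtered on minor allele
frequency, LD-pruned with a greedy sliding-window scan, and summarised into
principal components that downstream association models use as ancestry
covariates.

Conventions
-----------
* Dosages count copies of the variant's *effect allele* (the VCF ALT
  allele on read/write); values are 0, 1, 2 or missing.
* The MAF filter keeps variants with min(f, 1-f) strictly greater than the
  threshold, computed from observed dosages.
* LD pruning is a deterministic left-to-right scan: within each window the
  later variant of any pair with squared Pearson dosage correlation at or
  above the threshold is dropped.
* PCA standardizes variants (mean 0, unit variance), orders components by
  decreasing eigenvalue, and fixes each component's sign by making its
  largest-magnitude loading positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: required columns of ``GenotypeMatrix.variants``
VARIANT_COLUMNS = ("variant_id", "effect_allele", "other_allele", "frequency", "block_id")

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class VariantInfo:
    """Metadata for a single biallelic variant."""

    variant_id: str
    effect_allele: str
    other_allele: str
    frequency: float = np.nan
    block_id: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")
        for a in (self.effect_allele, self.other_allele):
            if a not in _VALID_ALLELES:
                raise ValueError(f"{self.variant_id}: invalid allele {a!r}")


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (rows of ``dosages``).
    variants
        DataFrame with columns :data:`VARIANT_COLUMNS`, one row per column
        of ``dosages``.
    dosages
        Float array of shape (n_samples, n_variants); entries in [0, 2].
        Entries under the missing mask are ignored.
    missing
        Boolean array, same shape as ``dosages``; True marks a missing
        genotype call.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.dosages.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} dosage columns")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants table missing column {col!r}")
        if self.variants["variant_id"].duplicated().any():
            dups = self.variants["variant_id"][self.variants["variant_id"].duplicated()]
            raise ValueError(f"duplicated variant ids: {list(dups)[:5]}")
        observed = self.dosages[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages outside [0, 2]")
        if self.missing.shape != self.dosages.shape:
            raise ValueError("missing mask shape mismatch")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def observed_frequencies(self) -> np.ndarray:
        """Effect-allele frequency per variant from non-missing dosages."""
        d = np.where(self.missing, np.nan, self.dosages)
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index].copy(),
            missing=self.missing[:, index].copy(),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = np.array([pos[s] for s in ids])
        except KeyError as exc:
            raise KeyError(f"sample not in genotype matrix: {exc.args[0]}") from None
        return GenotypeMatrix(
            sample_ids=list(ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows].copy(),
            missing=self.missing[rows].copy(),
        )

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        d = np.where(self.missing, np.nan, self.dosages)
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        return np.where(np.isnan(d), col_mean[None, :], d)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file.

    The effect allele is written as ALT and the other allele as REF, so
    that the ALT-dosage read convention round-trips. Variants are placed at
    consecutive positions on a synthetic contig "1".
    """
    header = pysam.VariantHeader()
    header.contigs.add("1", length=max(gm.n_variants + 1, 2))
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.sample_ids:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, row in gm.variants.iterrows():
            rec = out.new_record(
                contig="1",
                start=j,
                stop=j + 1,
                alleles=(row["other_allele"], row["effect_allele"]),
                id=row["variant_id"],
            )
            for i, s in enumerate(gm.sample_ids):
                if gm.missing[i, j]:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = gt_codes[int(round(gm.dosages[i, j]))]
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; ALT is taken as the effect allele."""
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample ids in VCF header")
        dosage_cols: list[np.ndarray] = []
        missing_cols: list[np.ndarray] = []
        meta: list[dict] = []
        for rec_no, rec in enumerate(vf, start=1):
            try:
                if rec.alts is None or len(rec.alts) != 1:
                    raise ValueError("expected exactly one ALT allele")
                dos = np.zeros(len(samples))
                miss = np.zeros(len(samples), dtype=bool)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        miss[i] = True
                    else:
                        dos[i] = sum(int(a > 0) for a in gt)
                meta.append(
                    {
                        "variant_id": rec.id or f"{rec.contig}:{rec.pos}",
                        "effect_allele": rec.alts[0],
                        "other_allele": rec.ref,
                        "frequency": np.nan,
                        "block_id": None,
                    }
                )
                dosage_cols.append(dos)
                missing_cols.append(miss)
            except Exception as exc:
                raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
    if not meta:
        raise ValueError(f"no variant records in {path}")
    gm = GenotypeMatrix(
        sample_ids=samples,
        variants=pd.DataFrame(meta),
        dosages=np.column_stack(dosage_cols),
        missing=np.column_stack(missing_cols),
    )
    gm.variants["frequency"] = gm.observed_frequencies()
    return gm


def write_dosage_tsv(gm: GenotypeMatrix, path: str, variants_path: str | None = None) -> None:
    """Write dosages as a samples x variants TSV (header = variant ids).

    Missing genotypes are written as empty cells. If ``variants_path`` is
    given, the variant metadata table is written alongside so a round trip
    preserves allele labels.
    """
    d = np.where(gm.missing, np.nan, gm.dosages)
    df = pd.DataFrame(d, index=gm.sample_ids, columns=gm.variants["variant_id"])
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%g")
    if variants_path is not None:
        gm.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(path: str, variants_path: str | None = None) -> GenotypeMatrix:
    """Read a samples x variants dosage TSV.

    Without a variant metadata sidecar the allele labels are unknown; they
    are filled with placeholder A (effect) / C (other) and a warning is
    logged, which is sufficient for analyses that never match alleles.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicated sample ids in {path}")
    dosages = df.to_numpy(dtype=float)
    missing = np.isnan(dosages)
    dosages = np.where(missing, 0.0, dosages)
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t")
        if list(variants["variant_id"]) != list(df.columns):
            raise ValueError("variant metadata does not match dosage TSV columns")
        if "block_id" in variants.columns:
            variants["block_id"] = variants["block_id"].astype("object").where(variants["block_id"].notna(), None)
    else:
        logger.warning("no variant metadata for %s; using placeholder alleles", path)
        variants = pd.DataFrame(
            {
                "variant_id": df.columns,
                "effect_allele": "A",
                "other_allele": "C",
                "frequency": np.nan,
                "block_id": None,
            }
        )
    gm = GenotypeMatrix(list(df.index.astype(str)), variants, dosages, missing)
    if gm.variants["frequency"].isna().all():
        gm.variants["frequency"] = gm.observed_frequencies()
    return gm


def read_genotypes(path: str, format: str = "vcf", variants_path: str | None = None) -> GenotypeMatrix:
    """Dispatch to :func:`read_vcf` or :func:`read_dosage_tsv`."""
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_dosage_tsv(path, variants_path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'vcf' or 'tsv')")


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def maf_filter(gm: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep variants with minor allele frequency strictly above ``threshold``.

    Frequencies are computed from observed dosages; the boundary value is
    excluded (a variant with MAF exactly equal to the threshold is removed).
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    f = gm.observed_frequencies()
    maf = np.minimum(f, 1 - f)
    # strict inequality, robust to float round-off at the boundary
    at_boundary = np.isclose(maf, threshold, rtol=0, atol=1e-12)
    keep = np.where((maf > threshold) & ~at_boundary)[0]
    logger.info("maf_filter: kept %d/%d variants at MAF > %g", len(keep), gm.n_variants, threshold)
    return gm.subset_variants(keep)


def ld_prune(gm: GenotypeMatrix, r2_threshold: float = 0.1, window: int = 50, step: int = 5) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on squared dosage correlation.

    Zero-variance variants are dropped first (with a logged warning). The
    scan then moves left to right in windows of ``window`` variants
    advancing by ``step``; within a window, for every pair with r-squared at
    or above the threshold the later variant is dropped. The result is
    deterministic for a fixed variant order and itself passes the threshold
    check within any window.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError(f"r2 threshold must be in (0, 1], got {r2_threshold}")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    d = gm.imputed_dosages()
    variances = d.var(axis=0)
    keep = variances > 0
    if (~keep).any():
        logger.warning("ld_prune: dropping %d zero-variance variants", int((~keep).sum()))
    m = gm.n_variants
    centred = d - d.mean(axis=0)
    norms = np.sqrt((centred**2).sum(axis=0))
    for start in range(0, m, step):
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        if len(idx) < 2:
            continue
        block = centred[:, idx] / norms[idx]
        r2 = (block.T @ block) ** 2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] >= r2_threshold:
                    keep[idx[b]] = False
    kept = np.where(keep)[0]
    logger.info(
        "ld_prune: kept %d/%d variants (r2 < %g, window=%d, step=%d)",
        len(kept), m, r2_threshold, window, step,
    )
    return gm.subset_variants(kept)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Principal-component scores and spectrum of a genotype matrix."""

    scores: pd.DataFrame           # samples x components, columns PC1..PCk
    explained_variance: np.ndarray  # eigenvalues of the standardized covariance
    loadings: pd.DataFrame          # variants x components


def pca_components(gm: GenotypeMatrix, n_components: int = 20) -> PCAResult:
    """Principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant before standardization
    (used for PCA only). Components are ordered by decreasing eigenvalue;
    scores have zero mean, and the sign of each component is fixed by
    making its largest-magnitude variant loading positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    d = gm.imputed_dosages()
    mean = d.mean(axis=0)
    sd = d.std(axis=0)
    nonconst = sd > 0
    if (~nonconst).any():
        logger.warning("pca_components: dropping %d constant variants", int((~nonconst).sum()))
    x = (d[:, nonconst] - mean[nonconst]) / sd[nonconst]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    k = n_components
    scores = u[:, :k] * s[:k]
    load = np.zeros((gm.n_variants, k))
    load[nonconst] = vt[:k].T
    # deterministic sign: largest-magnitude loading positive
    for c in range(k):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    explained = s[:k] ** 2 / (gm.n_samples - 1)
    return PCAResult(
        scores=pd.DataFrame(scores, index=gm.sample_ids, columns=cols),
        explained_variance=explained,
        loadings=pd.DataFrame(load, index=gm.variants["variant_id"], columns=cols),
    )


def ld_block_correlations(gm: GenotypeMatrix) -> list[tuple[list[str], np.ndarray]]:
    """Per-block dosage correlation matrices keyed by the ``block_id`` column.

    Variants without a block id are treated as singleton blocks. Used to
    feed LD information to the SBLUP reweighting step.
    """
    d = gm.imputed_dosages()
    sd = d.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant variants present; filter before computing LD blocks")
    z = (d - d.mean(axis=0)) / sd
    blocks: list[tuple[list[str], np.ndarray]] = []
    ids = gm.variants["variant_id"].to_numpy()
    raw = gm.variants["block_id"]
    labels = raw.to_numpy(dtype=object)
    if raw.isna().all():
        labels = np.array([f"_singleton_{i}" for i in range(len(ids))], dtype=object)
    seen: dict[object, list[int]] = {}
    for j, b in enumerate(labels):
        seen.setdefault(b, []).append(j)
    for b, idx in seen.items():
        cols = np.array(idx)
        r = z[:, cols].T @ z[:, cols] / gm.n_samples
        np.fill_diagonal(r, 1.0)
        blocks.append((list(ids[cols]), r))
    return blocks
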