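"""Generative model for twin-family polygenic-score studies.

The simulator produces the data structure that family-based PGS inference
assumes: DZ/MZ twin pairs nested in families, parental genotypes drawn
under Hardy-Weinberg (optionally with block LD and Balding-Nichols
subpopulation allele-frequency divergence), phenotypes built from four
channels that the analysis modules are designed to separate, and
item-level phenotype inputs for the composite scorers.

Phenotype model (per twin i in family j)::

    y_ij = delta * g_ij  +  eta * gbar_j  +  s(subpop_j)  +  c_j  +  e_ij

where ``g`` is the twin's true standardized polygenic value, ``gbar`` the
mid-parent polygenic value (the genetic-nurture / passive rGE channel:
parents with higher genetic propensity create a more enriching
environment), ``s`` a per-subpopulation shift (population stratification),
``c_j ~ N(0, sigma_c^2)`` a shared family environment and ``e`` residual
noise scaled so the total phenotype variance is 1. Assortative mating is
phenotypic: spouses are rank-matched against a latent Gaussian couple with
correlation ``rho_mate``, so the spousal *PGS* correlation is an emergent
quantity.

"GWAS" weights are emulated rather than estimated: true per-variant
effects are drawn N(0, 1/M) on standardized genotypes and observed with
independent Gaussian estimation noise (``gwas_noise_sd``).

Loci are unlinked by default (meiosis is exact and fast); optional block
LD uses a Gaussian-threshold haplotype copula and exists to exercise the
SBLUP step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import genotools
from .genotools import GenotypeMatrix
from .pgs import WeightSet

logger = logging.getLogger(__name__)

_NONAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                       ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters of the twin-family generative model.

    Defaults emulate a registry-scale twin cohort: ~2500 complete twin
    pairs with ~40% monozygotic, a direct genetic effect whose variance
    share (delta^2 ~ 0.145) sits in the usual SNP-heritability band for a
    behavioural trait, no genetic nurture, a moderate shared family
    environment, modest phenotypic assortment and a single homogeneous
    population.
    """

    n_families: int = 2500
    n_snps: int = 500
    n_blocks: int = 10            # LD blocks (only matters when rho_ld > 0)
    rho_ld: float = 0.0           # adjacent-variant haplotype correlation in [0, 1)
    n_subpops: int = 1
    fst: float = 0.0              # Wright's F_ST in [0, 1)
    maf_range: tuple = (0.1, 0.5)
    delta: float = 0.38           # direct effect of the twin's true standardized PGS
    eta: float = 0.0              # nurture effect of the mid-parent standardized PGS
    sigma_c: float = 0.4          # shared-family-environment SD
    stratum_effect: float = 0.0   # per-subpopulation phenotype shift (scale of a unit step)
    rho_mate: float = 0.2         # target spousal *phenotype* correlation
    gwas_noise_sd: float = 0.1    # SD of estimation noise on true per-variant effects
    prop_mz: float = 0.4
    enrichment_loading: float = 0.3  # loading of mid-parent PGS on the family-environment latent
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.n_snps < 1 or self.n_blocks < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.rho_ld < 1:
            raise ValueError(f"rho_ld must be in [0, 1), got {self.rho_ld}")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"maf_range must satisfy 0 < low <= high < 1, got {self.maf_range}")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if not -1 <= self.rho_mate <= 1:
            raise ValueError(f"rho_mate must be in [-1, 1], got {self.rho_mate}")
        if not 0 <= self.prop_mz <= 1:
            raise ValueError(f"prop_mz must be in [0, 1], got {self.prop_mz}")
        if not 0 <= self.enrichment_loading <= 1:
            raise ValueError("enrichment_loading must be in [0, 1]")
        if self.gwas_noise_sd < 0:
            raise ValueError("gwas_noise_sd must be >= 0")


@dataclass
class TransmissionRecord:
    """Which parental allele slot each twin received, per locus.

    Slots index the two (arbitrary but fixed) allele copies of a parent;
    identity of slots between co-twins is identity by descent regardless
    of the allele state carried.
    """

    zygosity: str
    pat1: np.ndarray
    mat1: np.ndarray
    pat2: np.ndarray
    mat2: np.ndarray


@dataclass
class TwinFamily:
    family_id: str
    father_id: str
    mother_id: str
    twin1_id: str
    twin2_id: str
    zygosity: str
    subpop: int
    transmission_record: TransmissionRecord | None = None


# ---------------------------------------------------------------------------
# Elementary generative operations
# ---------------------------------------------------------------------------

def draw_subpop_frequencies(ancestral_freqs, fst: float, n_subpops: int, seed=None) -> np.ndarray:
    """Balding-Nichols subpopulation allele frequencies.

    Each subpopulation frequency is drawn from
    Beta(p (1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, so
    E[f] = p and Var[f] = F p (1-p). For F = 0 the ancestral frequencies
    are returned exactly. Outputs are clipped to (0.001, 0.999).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty ancestral frequency vector")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    if not 0 <= fst < 1:
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if fst == 0:
        return np.tile(p, (n_subpops, 1))
    rng = _as_rng(seed)
    scale = (1.0 - fst) / fst
    draws = rng.beta(p * scale, (1.0 - p) * scale, size=(n_subpops, p.size))
    return np.clip(draws, 0.001, 0.999)


def sample_parent_genotypes(freqs, n: int, rho_ld: float = 0.0, n_blocks: int = 1, seed=None) -> np.ndarray:
    """Draw n unrelated genotypes (dosage matrix in {0,1,2}) at HWE.

    With ``rho_ld = 0`` every variant is an independent Binomial(2, p).
    With ``rho_ld > 0`` each haplotype follows a Gaussian-threshold copula:
    a first-order autoregressive latent Gaussian within each of
    ``n_blocks`` contiguous blocks (adjacent correlation ``rho_ld``) is
    thresholded at the allele-frequency quantile; the two haplotypes are
    independent, so HWE still holds marginally.
    """
    p = np.asarray(freqs, dtype=float)
    if n <= 0:
        raise ValueError("n must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    rng = _as_rng(seed)
    m = p.size
    if rho_ld == 0:
        return rng.binomial(2, p, size=(n, m)).astype(np.int8)
    bounds = np.array_split(np.arange(m), n_blocks)
    thresh = norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))
    hap_sum = np.zeros((n, m), dtype=np.int8)
    for _ in range(2):
        z = np.empty((n, m))
        for block in bounds:
            if block.size == 0:
                continue
            e = rng.standard_normal((n, block.size))
            zb = np.empty((n, block.size))
            zb[:, 0] = e[:, 0]
            for j in range(1, block.size):
                zb[:, j] = rho_ld * zb[:, j - 1] + np.sqrt(1 - rho_ld**2) * e[:, j]
            z[:, block] = zb
        hap_sum += (z < thresh[None, :]).astype(np.int8)
    return hap_sum


def mate_assortatively(male_phenotypes, female_phenotypes, rho_mate: float, seed=None) -> np.ndarray:
    """Pair males with females so spousal phenotypes correlate ~rho_mate.

    Couples are formed by rank-matching each sex's phenotype against one
    margin of a shared latent bivariate Gaussian with correlation
    ``rho_mate``. Returns ``wife_of``: the female index paired with each
    male. For Gaussian phenotypes the realized spousal Pearson correlation
    approaches ``rho_mate`` as n grows; ``rho_mate = 1`` reduces to exact
    rank-sorted matching.
    """
    ym = np.asarray(male_phenotypes, dtype=float)
    yf = np.asarray(female_phenotypes, dtype=float)
    if ym.size != yf.size:
        raise ValueError(f"unequal pool sizes: {ym.size} males vs {yf.size} females")
    if not -1 <= rho_mate <= 1:
        raise ValueError(f"rho_mate must be in [-1, 1], got {rho_mate}")
    rng = _as_rng(seed)
    n = ym.size
    u = rng.standard_normal(n)
    v = rho_mate * u + np.sqrt(max(0.0, 1 - rho_mate**2)) * rng.standard_normal(n)
    # couple k gets the male whose phenotype rank equals u_k's rank, etc.
    male_of_couple = np.argsort(ym, kind="stable")[np.argsort(np.argsort(u, kind="stable"), kind="stable")]
    female_of_couple = np.argsort(yf, kind="stable")[np.argsort(np.argsort(v, kind="stable"), kind="stable")]
    wife_of = np.empty(n, dtype=int)
    wife_of[male_of_couple] = female_of_couple
    return wife_of


def _parent_slot_alleles(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # slot 0 carries the effect allele when dosage >= 1, slot 1 when dosage == 2
    return (dosage >= 1).astype(np.int8), (dosage == 2).astype(np.int8)


def meiosis(father_genotype, mother_genotype, zygosity: str, seed=None):
    """One twin pair from two parental genotypes at unlinked loci.

    Each twin receives one allele per parent per locus, the transmitting
    parental slot chosen uniformly and independently across loci. MZ twins
    are one meiosis duplicated; DZ twins are two independent meioses.

    Returns ``(twin1, twin2, TransmissionRecord)``.
    """
    f = np.asarray(father_genotype)
    m = np.asarray(mother_genotype)
    if f.shape != m.shape:
        raise ValueError("parental genotypes differ in length")
    for g in (f, m):
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("parental dosages must be in {0, 1, 2}")
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    rng = _as_rng(seed)
    nloci = f.size
    fa0, fa1 = _parent_slot_alleles(f)
    ma0, ma1 = _parent_slot_alleles(m)
    pat1 = rng.integers(0, 2, nloci).astype(np.int8)
    mat1 = rng.integers(0, 2, nloci).astype(np.int8)
    if zygosity == "MZ":
        pat2, mat2 = pat1.copy(), mat1.copy()
    else:
        pat2 = rng.integers(0, 2, nloci).astype(np.int8)
        mat2 = rng.integers(0, 2, nloci).astype(np.int8)
    twin1 = np.where(pat1 == 0, fa0, fa1) + np.where(mat1 == 0, ma0, ma1)
    twin2 = np.where(pat2 == 0, fa0, fa1) + np.where(mat2 == 0, ma0, ma1)
    return twin1.astype(np.int8), twin2.astype(np.int8), TransmissionRecord(zygosity, pat1, mat1, pat2, mat2)


def ibd_share(record: TransmissionRecord) -> float:
    """Proportion of parental transmissions identical between co-twins.

    Per locus the share is (matching transmissions) / 2, averaged over
    loci; the Mendelian expectation for DZ twins is 0.5 and MZ pairs
    return 1.0 by construction.
    """
    if record.pat1.size == 0:
        raise ValueError("empty transmission record")
    same = (record.pat1 == record.pat2).astype(float) + (record.mat1 == record.mat2)
    return float(same.mean() / 2.0)


def simulate_phenotype(child_true_pgs, midparent_true_pgs, subpop, family_shared_env, config: SimConfig, seed=None) -> np.ndarray:
    """Phenotypes from the direct + nurture + stratification + family model.

    ``family_shared_env`` must already be expanded per individual (co-twins
    share the same value). The residual SD is chosen so the total
    phenotype variance is 1; if the systematic components already exceed
    unit variance the call fails, reporting the component budget.
    """
    g = np.asarray(child_true_pgs, dtype=float)
    gp = np.asarray(midparent_true_pgs, dtype=float)
    sp = np.asarray(subpop, dtype=int)
    c = np.asarray(family_shared_env, dtype=float)
    rng = _as_rng(seed)
    shifts = _stratum_shifts(config)
    systematic = config.delta * g + config.eta * gp + shifts[sp]
    var_sys = float(np.var(systematic)) if systematic.size > 1 else 0.0
    var_resid = 1.0 - var_sys - config.sigma_c**2
    if var_resid < 0:
        raise ValueError(
            "negative implied residual variance: systematic components use "
            f"{var_sys:.3f} (delta/eta/stratum) + {config.sigma_c**2:.3f} (shared env) > 1"
        )
    return systematic + c + rng.normal(0.0, np.sqrt(var_resid), size=g.shape)


def _stratum_shifts(config: SimConfig) -> np.ndarray:
    """Mean-centred per-subpopulation phenotype shifts in steps of ``stratum_effect``."""
    k = np.arange(config.n_subpops, dtype=float)
    shifts = config.stratum_effect * k
    return shifts - shifts.mean()


def simulate_environment_items(midparent_true_pgs, enrichment_loading: float, seed=None) -> pd.DataFrame:
    """Family-environment items driven by a latent enrichment score.

    The latent score is ``loading * z(midparent PGS) + sqrt(1-loading^2) *
    noise`` and maps to four items: two Poisson counts (records in the
    home, players in the environment), an ordinal 0-4 concert-frequency
    item and a binary music-education-before-12 item. One row per family;
    both co-twins share the row.
    """
    if not 0 <= enrichment_loading <= 1:
        raise ValueError("enrichment_loading must be in [0, 1]")
    gp = np.asarray(midparent_true_pgs, dtype=float)
    rng = _as_rng(seed)
    z = (gp - gp.mean()) / gp.std() if gp.size > 1 and gp.std() > 0 else np.zeros_like(gp)
    latent = enrichment_loading * z + np.sqrt(1 - enrichment_loading**2) * rng.standard_normal(gp.size)
    n_records = rng.poisson(np.exp(np.log(15.0) + 0.3 * latent))
    n_players = rng.poisson(np.exp(np.log(2.0) + 0.3 * latent))
    noisy = latent + rng.normal(0, 0.6, gp.size)
    cuts = norm.ppf([0.3, 0.6, 0.85, 0.95]) * np.sqrt(1 + 0.36)
    concert_freq = np.digitize(noisy, cuts)
    music_edu = (latent + rng.normal(0, 0.8, gp.size) > norm.ppf(0.65) * np.sqrt(1 + 0.64)).astype(int)
    return pd.DataFrame(
        {
            "latent_enrichment": latent,
            "n_records": n_records,
            "n_players": n_players,
            "concert_freq": concert_freq,
            "music_edu_before12": music_edu,
        }
    )


# ---------------------------------------------------------------------------
# Item-level phenotype inputs
# ---------------------------------------------------------------------------

_SUBTEST_SPECS = {  # (loading on the musicality phenotype, mean, sd, max raw score)
    "pitch": (0.60, 16.0, 4.5, 27),
    "melody": (0.62, 11.0, 3.0, 18),
    "rhythm": (0.58, 12.0, 3.0, 18),
}
_ISIP_TARGETS_MS = (524, 819, 655, 1024, 655, 524)


def simulate_item_phenotypes(sample_ids, phenotype, rng, n_isip_intervals: int = 12):
    """Item-level inputs (discrimination subtests, tapping trials, flow).

    All items load on the simulated musicality phenotype with independent
    item noise, so the composite scorers recover phenotypes correlated
    with — but not identical to — the latent outcome.

    Returns ``(subtests, isip_trials, flow)`` DataFrames.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    sub = {"sample_id": list(sample_ids)}
    for name, (load, mean, sd, max_raw) in _SUBTEST_SPECS.items():
        latent = load * y + np.sqrt(1 - load**2) * rng.standard_normal(n)
        raw = np.clip(np.round(mean + sd * latent), 0, max_raw)
        sub[name] = raw.astype(int)
    subtests = pd.DataFrame(sub)

    # per-person tapping variability: log CV decreases with the phenotype
    isip_latent = 0.5 * y + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    cv = np.exp(np.log(0.045) - 0.35 * isip_latent)
    n_trials = len(_ISIP_TARGETS_MS)
    targets = np.asarray(_ISIP_TARGETS_MS, dtype=float)
    # (samples, trials, intervals)
    noise = rng.standard_normal((n, n_trials, n_isip_intervals))
    intervals = targets[None, :, None] * (1.0 + cv[:, None, None] * noise)
    isip_trials = pd.DataFrame(
        {
            "sample_id": np.repeat(list(sample_ids), n_trials * n_isip_intervals),
            "trial": np.tile(np.repeat(np.arange(1, n_trials + 1), n_isip_intervals), n),
            "target_ms": np.tile(np.repeat(targets, n_isip_intervals), n),
            "interval_ms": np.maximum(intervals, 1.0).ravel(),
        }
    )

    flow = pd.DataFrame({"sample_id": list(sample_ids)})
    for domain, load in (("work", 0.10), ("leisure", 0.15), ("maintenance", 0.10), ("music", 0.55)):
        latent = load * y + np.sqrt(1 - load**2) * rng.standard_normal(n)
        flow[domain] = np.clip(3.0 + 0.8 * latent, 1.0, 5.0).round(2)
    return subtests, isip_trials, flow


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    genotypes: GenotypeMatrix          # parents + twins
    pedigree: pd.DataFrame             # family_id, father_id, mother_id, twin ids, zygosity, subpop
    phenotypes: pd.DataFrame           # sample_id, family_id, zygosity, sex, age, musicality
    env_items: pd.DataFrame            # per family
    subtests: pd.DataFrame             # twins only
    isip_trials: pd.DataFrame          # twins only, long format
    flow: pd.DataFrame                 # twins only
    true_weights: WeightSet            # dosage-scale true effects
    gwas_weights: WeightSet            # noisy "GWAS" effects
    true_pgs: pd.Series                # standardized within generation
    midparent_pgs: pd.Series           # per family, from parents' standardized values
    transmissions: dict                # family_id -> TransmissionRecord

    def family(self, family_id: str) -> TwinFamily:
        row = self.pedigree.set_index("family_id").loc[family_id]
        return TwinFamily(
            family_id=family_id,
            father_id=row["father_id"],
            mother_id=row["mother_id"],
            twin1_id=row["twin1_id"],
            twin2_id=row["twin2_id"],
            zygosity=row["zygosity"],
            subpop=int(row["subpop"]),
            transmission_record=self.transmissions[family_id],
        )

    def ibd_shares(self) -> pd.Series:
        """IBD-shared proportion per family (DZ families informative)."""
        return pd.Series({fid: ibd_share(rec) for fid, rec in self.transmissions.items()})


def simulate_study(config: SimConfig, items: bool = True) -> SimulatedStudy:
    """Run the full generative model for one study.

    Deterministic given the config (including its seed): two calls with an
    identical config produce identical outputs. ``items=False`` skips the
    item-level phenotype and environment tables (empty DataFrames), which
    speeds up replicate studies that only need genotypes, scores and the
    latent outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    F, M, K = config.n_families, config.n_snps, config.n_subpops

    # variants
    ancestral = rng.uniform(config.maf_range[0], config.maf_range[1], M)
    allele_idx = rng.integers(0, len(_NONAMBIGUOUS_PAIRS), M)
    freqs_by_pop = draw_subpop_frequencies(ancestral, config.fst, K, rng)
    block_size = int(np.ceil(M / config.n_blocks))
    block_ids = np.arange(M) // block_size

    # families assigned to subpops in (deterministic) round-robin
    subpop = np.arange(F) % K

    fathers = np.zeros((F, M), dtype=np.int8)
    mothers = np.zeros((F, M), dtype=np.int8)
    for k in range(K):
        idx = np.where(subpop == k)[0]
        fathers[idx] = sample_parent_genotypes(freqs_by_pop[k], idx.size, config.rho_ld, config.n_blocks, rng)
        mothers[idx] = sample_parent_genotypes(freqs_by_pop[k], idx.size, config.rho_ld, config.n_blocks, rng)

    # true and observed ("GWAS") per-variant effects on standardized genotypes
    b_std = rng.normal(0.0, np.sqrt(1.0 / M), M)
    b_obs = b_std + rng.normal(0.0, config.gwas_noise_sd, M)
    scale = np.sqrt(2.0 * ancestral * (1.0 - ancestral))
    w_true = b_std / scale   # dosage-scale weights
    w_obs = b_obs / scale

    def genetic_value(dosages: np.ndarray) -> np.ndarray:
        return dosages.astype(float) @ w_true

    g_par_raw = np.concatenate([genetic_value(fathers), genetic_value(mothers)])
    g_par = (g_par_raw - g_par_raw.mean()) / g_par_raw.std(ddof=1)
    g_f, g_m = g_par[:F], g_par[F:]

    # parent phenotypes for phenotypic assortment
    shifts = _stratum_shifts(config)
    sys_par = config.delta * g_par + np.concatenate([shifts[subpop], shifts[subpop]])
    resid_par = 1.0 - float(np.var(sys_par))
    if resid_par < 0:
        raise ValueError("parental phenotype variance budget exceeds 1; reduce delta/stratum_effect")
    y_par = sys_par + rng.normal(0.0, np.sqrt(resid_par), 2 * F)
    y_f, y_m = y_par[:F], y_par[F:]

    # assortative mating within each subpopulation: reorder mothers
    wife_of = np.empty(F, dtype=int)
    for k in range(K):
        idx = np.where(subpop == k)[0]
        local = mate_assortatively(y_f[idx], y_m[idx], config.rho_mate, rng)
        wife_of[idx] = idx[local]
    mothers = mothers[wife_of]
    g_m = g_m[wife_of]
    midparent = (g_f + g_m) / 2.0

    # meiosis, vectorized over families
    zyg = np.where(rng.random(F) < config.prop_mz, "MZ", "DZ")
    fa0, fa1 = _parent_slot_alleles(fathers)
    ma0, ma1 = _parent_slot_alleles(mothers)
    pat1 = rng.integers(0, 2, (F, M), dtype=np.int8)
    mat1 = rng.integers(0, 2, (F, M), dtype=np.int8)
    pat2 = rng.integers(0, 2, (F, M), dtype=np.int8)
    mat2 = rng.integers(0, 2, (F, M), dtype=np.int8)
    mz = zyg == "MZ"
    pat2[mz] = pat1[mz]
    mat2[mz] = mat1[mz]
    twin1 = np.where(pat1 == 0, fa0, fa1) + np.where(mat1 == 0, ma0, ma1)
    twin2 = np.where(pat2 == 0, fa0, fa1) + np.where(mat2 == 0, ma0, ma1)

    g_tw_raw = np.concatenate([genetic_value(twin1), genetic_value(twin2)])
    g_tw = (g_tw_raw - g_tw_raw.mean()) / g_tw_raw.std(ddof=1)
    g_t1, g_t2 = g_tw[:F], g_tw[F:]

    # twin phenotypes
    c_fam = rng.normal(0.0, config.sigma_c, F)
    y_tw = simulate_phenotype(
        np.concatenate([g_t1, g_t2]),
        np.concatenate([midparent, midparent]),
        np.concatenate([subpop, subpop]),
        np.concatenate([c_fam, c_fam]),
        config,
        rng,
    )
    y_t1, y_t2 = y_tw[:F], y_tw[F:]

    # demographics: MZ twins share sex; twins share age
    sex1 = rng.integers(0, 2, F)
    sex2 = np.where(mz, sex1, rng.integers(0, 2, F))
    age = rng.integers(27, 55, F)

    width = len(str(F))
    fam_ids = [f"F{i + 1:0{width}d}" for i in range(F)]
    father_ids = [f"{f}_FA" for f in fam_ids]
    mother_ids = [f"{f}_MO" for f in fam_ids]
    t1_ids = [f"{f}_T1" for f in fam_ids]
    t2_ids = [f"{f}_T2" for f in fam_ids]

    pedigree = pd.DataFrame(
        {
            "family_id": fam_ids,
            "father_id": father_ids,
            "mother_id": mother_ids,
            "twin1_id": t1_ids,
            "twin2_id": t2_ids,
            "zygosity": zyg,
            "subpop": subpop,
        }
    )

    sample_ids = father_ids + mother_ids + t1_ids + t2_ids
    dosages = np.vstack([fathers, mothers, twin1, twin2]).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j + 1:05d}" for j in range(M)],
            "effect_allele": [_NONAMBIGUOUS_PAIRS[i][0] for i in allele_idx],
            "other_allele": [_NONAMBIGUOUS_PAIRS[i][1] for i in allele_idx],
            "frequency": ancestral,
            "block_id": block_ids,
        }
    )
    genotypes = GenotypeMatrix(sample_ids, variants, dosages)
    genotypes.variants["frequency"] = genotypes.observed_frequencies()

    phenotypes = pd.DataFrame(
        {
            "sample_id": t1_ids + t2_ids,
            "family_id": fam_ids + fam_ids,
            "zygosity": np.concatenate([zyg, zyg]),
            "subpop": np.concatenate([subpop, subpop]),
            "sex": np.concatenate([sex1, sex2]),
            "age": np.concatenate([age, age]),
            "musicality": y_tw,
        }
    )

    if items:
        env = simulate_environment_items(midparent, config.enrichment_loading, rng)
        env.insert(0, "family_id", fam_ids)
        subtests, isip_trials, flow = simulate_item_phenotypes(t1_ids + t2_ids, y_tw, rng)
    else:
        env = pd.DataFrame()
        subtests, isip_trials, flow = pd.DataFrame(), pd.DataFrame(), pd.DataFrame()

    weight_cols = {
        "variant_id": variants["variant_id"],
        "effect_allele": variants["effect_allele"],
        "other_allele": variants["other_allele"],
    }
    true_weights = WeightSet(pd.DataFrame({**weight_cols, "effect_weight": w_true}), provenance="marginal")
    gwas_weights = WeightSet(pd.DataFrame({**weight_cols, "effect_weight": w_obs}), provenance="marginal")

    transmissions = {
        fid: TransmissionRecord(zyg[i], pat1[i], mat1[i], pat2[i], mat2[i])
        for i, fid in enumerate(fam_ids)
    }
    true_pgs = pd.Series(
        np.concatenate([g_f, g_m, g_t1, g_t2]), index=sample_ids, name="true_pgs"
    )
    logger.info(
        "simulate_study: %d families (%d MZ), %d variants, %d subpops",
        F, int(mz.sum()), M, K,
    )
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        pedigree=pedigree,
        phenotypes=phenotypes,
        env_items=env,
        subtests=subtests,
        isip_trials=isip_trials,
        flow=flow,
        true_weights=true_weights,
        gwas_weights=gwas_weights,
        true_pgs=true_pgs,
        midparent_pgs=pd.Series(midparent, index=fam_ids, name="midparent_pgs"),
        transmissions=transmissions,
    )
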