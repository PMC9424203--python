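"""Composite phenotype scorers for item-level music-study measures.

Deterministic, missing-data-transparent scorers:

* musical aptitude: mean of the standardized pitch (0-27), melody (0-18)
  and rhythm (0-18) discrimination subtests;
* motor timing: reversed mean coefficient of variation of self-paced
  inter-tap intervals across tapping trials (higher = more accurate);
* global flow proneness: mean of the work, leisure and maintenance
  subscales;
* lifetime music practice: weekly-hours category midpoints integrated
  over the years played within four age intervals.

Missing inputs propagate to missing outputs; scorers never silently
substitute zeros.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTEST_MAXIMA = {"pitch": 27, "melody": 18, "rhythm": 18}

#: practice age intervals, keyed by the column/category label
PRACTICE_INTERVALS = {"0-5": (0, 5), "6-11": (6, 11), "12-17": (12, 17), "18+": (18, None)}

#: weekly-hours midpoints of the ten practice-frequency categories
#: (category 0 = never practiced). The survey categories have no printed
#: midpoints; this table is a declared, configurable approximation.
DEFAULT_PRACTICE_MIDPOINTS = (0.0, 0.5, 1.5, 3.0, 5.0, 7.5, 10.5, 15.0, 25.0, 40.0)


def aptitude_composite(scores: pd.DataFrame) -> pd.Series:
    """Mean of z-scored pitch, melody and rhythm subtest scores.

    Each subtest is standardized across samples (denominator n-1) before
    averaging, so the composite is invariant to affine rescaling of any
    subtest. Rows with a missing subtest yield a missing composite.
    """
    for col, maxi in SUBTEST_MAXIMA.items():
        if col not in scores.columns:
            raise ValueError(f"missing subtest column {col!r}")
        observed = scores[col].dropna()
        if ((observed < 0) | (observed > maxi)).any():
            raise ValueError(f"{col} scores outside [0, {maxi}]")
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to standardize subtests")
    zs = []
    for col in SUBTEST_MAXIMA:
        sd = scores[col].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero-variance subtest {col!r}")
        zs.append((scores[col] - scores[col].mean()) / sd)
    composite = pd.concat(zs, axis=1).mean(axis=1, skipna=False)
    return composite.rename("aptitude")


def isip_score(trials: pd.DataFrame, interval_col: str = "interval_ms", trial_col: str = "trial") -> float:
    """Reversed mean coefficient of variation of self-paced tap intervals.

    Per trial the CV is SD/mean of the inter-tap intervals; the score is
    the negative of the mean CV across trials, so perfectly regular
    tapping scores 0 (the maximum) and noisier tapping scores lower.
    """
    if trials.empty:
        return np.nan
    cvs = []
    for _, grp in trials.groupby(trial_col):
        x = grp[interval_col].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"trial with {x.size} intervals; need >= 3")
        mean = x.mean()
        if mean <= 0:
            raise ValueError("non-positive mean inter-tap interval")
        cvs.append(x.std(ddof=1) / mean)
    return float(-np.mean(cvs))


def isip_scores(trials: pd.DataFrame, sample_col: str = "sample_id") -> pd.Series:
    """Per-sample motor-timing scores from a long trial table."""
    out = {sid: isip_score(grp) for sid, grp in trials.groupby(sample_col, sort=True)}
    return pd.Series(out, name="motor_timing")


def global_flow(work, leisure, maintenance) -> float | pd.Series:
    """Mean of the work, leisure and maintenance flow subscale scores.

    Accepts scalars or aligned Series. A missing subscale yields a
    missing result with a warning (never a partial mean).
    """
    if isinstance(work, pd.Series) or isinstance(leisure, pd.Series) or isinstance(maintenance, pd.Series):
        df = pd.DataFrame({"work": work, "leisure": leisure, "maintenance": maintenance})
        n_missing = int(df.isna().any(axis=1).sum())
        if n_missing:
            logger.warning("global_flow: %d samples with a missing subscale -> missing", n_missing)
        return df.mean(axis=1, skipna=False).rename("global_flow")
    vals = (work, leisure, maintenance)
    if any(pd.isna(v) for v in vals):
        logger.warning("global_flow: missing subscale -> missing result")
        return np.nan
    return float(np.mean(vals))


def lifetime_practice(
    start_age,
    end_age,
    weekly_category: dict,
    age_at_measurement,
    midpoints=DEFAULT_PRACTICE_MIDPOINTS,
) -> float:
    """Estimated total lifetime hours of music practice.

    Each year of age from ``start_age`` to ``end_age`` (inclusive) falls
    into one of the four intervals 0-5, 6-11, 12-17, 18+; the year
    contributes 52 times the weekly-hours midpoint of the category
    reported for that interval. Category 0 contributes nothing. Both ages
    missing means the respondent never played (0 hours, the survey skip
    pattern); a missing category for an interval actually played
    propagates to a missing total.
    """
    if pd.isna(start_age) and pd.isna(end_age):
        return 0.0
    if pd.isna(start_age) or pd.isna(end_age):
        return np.nan
    start_age, end_age = int(start_age), int(end_age)
    if not start_age <= end_age <= age_at_measurement:
        raise ValueError(
            f"inconsistent ages: start {start_age} <= end {end_age} <= measurement {age_at_measurement} required"
        )
    total = 0.0
    for label, (lo, hi) in PRACTICE_INTERVALS.items():
        hi_eff = age_at_measurement if hi is None else hi
        overlap = min(end_age, hi_eff) - max(start_age, lo) + 1
        if overlap <= 0:
            continue
        cat = weekly_category.get(label, np.nan)
        if pd.isna(cat):
            logger.warning("lifetime_practice: missing category for played interval %s", label)
            return np.nan
        cat = int(cat)
        if not 0 <= cat < len(midpoints):
            raise ValueError(f"practice category {cat} outside 0..{len(midpoints) - 1}")
        total += midpoints[cat] * 52.0 * overlap
    return total
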