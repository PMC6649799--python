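"""Per-woman aggregation of per-mammogram feature vectors.

A woman typically contributes several usable mammograms (left and right
breasts, multiple visits).  Her feature vector is the featurewise median
over all of them — the median, not the mean, so that a single unusual
film does not dominate.  A single-mammogram mode (earliest visit) is
provided for sensitivity analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .texture import FEATURE_NAMES

ID_COLUMNS = ("image_id", "woman_id", "visit_index")


def aggregate_median(per_mammogram: pd.DataFrame,
                     feature_cols: list[str] | None = None) -> pd.DataFrame:
    """Collapse per-mammogram rows to one row per woman.

    Each feature is aggregated independently as the median over the
    woman's mammograms (even counts: mean of the two central values);
    NaN sentinels from degenerate images are excluded per feature.
    Women whose rows are all-NaN for some feature keep NaN there; women
    with zero rows cannot appear (there is nothing to group).

    Returns a DataFrame indexed by woman_id with the feature columns plus
    ``n_mammograms``.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_NAMES if c in per_mammogram.columns]
    if not feature_cols:
        raise ValueError("no feature columns found")
    if "woman_id" not in per_mammogram.columns:
        raise ValueError("per-mammogram table must have a woman_id column")
    grouped = per_mammogram.groupby("woman_id", sort=True)
    agg = grouped[feature_cols].median()  # skips NaN per feature
    agg["n_mammograms"] = grouped.size()
    all_nan = agg[feature_cols].isna().all(axis=1)
    if all_nan.any():
        warnings.warn(
            f"{int(all_nan.sum())} women had no valid feature values and were excluded"
        )
        agg = agg[~all_nan]
    return agg


def select_earliest(per_mammogram: pd.DataFrame) -> pd.DataFrame:
    """Single-mammogram mode: keep each woman's earliest-visit mammogram.

    Ties within the earliest visit are broken by image_id for determinism.
    """
    df = per_mammogram.copy()
    sort_cols = [c for c in ("woman_id", "visit_index", "image_id") if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort")
    return df.groupby("woman_id", sort=True).head(1)


def build_woman_table(per_mammogram: pd.DataFrame, cohort: pd.DataFrame,
                      single_mammogram: bool = False) -> pd.DataFrame:
    """Join aggregated features with cohort covariates.

    cohort must carry woman_id, status (1 = case, 0 = control), age, bmi,
    and optionally absolute_density / percent_density.  Women missing from
    either table are dropped with a warning.
    """
    if single_mammogram:
        per_mammogram = select_earliest(per_mammogram)
    agg = aggregate_median(per_mammogram)
    cohort = cohort.set_index("woman_id") if "woman_id" in cohort.columns else cohort
    merged = cohort.join(agg, how="inner")
    n_lost = len(cohort) - len(merged)
    if n_lost:
        warnings.warn(f"{n_lost} women in the cohort table had no usable mammograms")
    if (merged["n_mammograms"] < 1).any():
        raise ValueError("aggregation produced a woman with no mammograms")
    return merged
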