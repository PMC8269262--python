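"""Normalization: volume/biovolume scaling, B-MIS, and standardizations.

B-MIS (best-matched internal standard) removes non-biological run-to-run
variability: for every feature, each spiked internal standard is tried as a
normalizer (area × mean IS area over the pooled QC injections / IS area in
that injection) and the one minimizing the pooled-sample CV is kept —
but only if it improves on the un-normalized pooled CV by at least a
relative ``min_improvement`` (default 40%); otherwise the feature keeps its
raw areas.  Candidates are judged on pooled injections only and applied to
every column.

Two standardizations feed the multivariate stages: environmental tables
are expressed per feature as fractions of that feature's total area across
the biological samples; culture tables are log10-transformed and scaled to
the per-feature maximum across organisms (so only large differences count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_tables import PeakTable, ValidationError
from .qc_filters import _row_cv

__all__ = ["BmisResult", "volume_normalize", "bmis_normalize",
           "standardize_to_total", "standardize_culture"]


def volume_normalize(table: PeakTable) -> PeakTable:
    """Divide each biological sample's areas by its volume filtered (L) or
    biovolume (µm³).  Pooled and blank columns are left untouched (they
    have no sampled volume).  A ``role=sample`` column with no volume is an
    error naming the sample."""
    areas = table.areas.copy()
    for sid in table.sample_ids("sample"):
        row = table.samples.loc[sid]
        vol = row["vol_filtered_L"]
        if pd.isna(vol):
            vol = row["biovolume_um3"]
        if pd.isna(vol):
            raise ValidationError(
                f"sample {sid} has neither vol_filtered_L nor biovolume_um3")
        if vol <= 0:
            raise ValidationError(f"sample {sid} has non-positive volume {vol}")
        areas[sid] = areas[sid] / vol
    return table.with_areas(areas, units="area per volume")


@dataclass
class BmisResult:
    """Per-feature chosen normalizer and the pooled CVs behind the choice."""

    chosen: pd.Series                 # feature -> IS id or "none"
    cv_baseline: pd.Series            # pooled CV without normalization
    cv_chosen: pd.Series              # pooled CV with the chosen normalizer
    candidate_cvs: pd.DataFrame       # features x candidate IS
    accepted_candidates: list[str]
    min_improvement: float


def bmis_normalize(table: PeakTable,
                   internal_standards: list[str] | None = None,
                   pooled_ids: list[str] | None = None,
                   min_improvement: float = 0.4,
                   ) -> tuple[PeakTable, BmisResult]:
    """Best-matched internal-standard normalization.

    Parameters
    ----------
    internal_standards
        Feature IDs of the spiked standards (default: the table's
        ``meta['internal_standards']``).  A standard with a zero or missing
        area in any column is excluded with a warning; if all are excluded,
        every feature keeps its raw areas.
    pooled_ids
        Pooled QC columns used to judge candidates (default: all
        ``role=pooled`` samples; at least two are required).
    min_improvement
        Minimum relative reduction of the pooled CV, versus no
        normalization, for a candidate to be accepted.
    """
    internal_standards = internal_standards or table.meta.get("internal_standards")
    if not internal_standards:
        raise ValidationError("no internal standards given or recorded in meta")
    missing = set(internal_standards) - set(table.features.index)
    if missing:
        raise ValidationError(f"internal standards not in table: {sorted(missing)}")
    pooled_ids = pooled_ids or table.sample_ids("pooled")
    if len(pooled_ids) < 2:
        raise ValidationError("B-MIS needs >= 2 pooled QC injections")

    accepted = []
    for is_id in internal_standards:
        is_areas = table.areas.loc[is_id]
        if is_areas.isna().any() or (is_areas <= 0).any():
            warnings.warn(f"internal standard {is_id} has zero/missing areas; excluded")
            continue
        accepted.append(is_id)

    pooled = table.areas[pooled_ids]
    cv_baseline = _row_cv(pooled)
    candidate_cvs = pd.DataFrame(index=table.areas.index, columns=accepted,
                                 dtype=float)
    factors = {}
    for is_id in accepted:
        is_all = table.areas.loc[is_id]
        factor = is_all[pooled_ids].mean() / is_all      # per-column multiplier
        factors[is_id] = factor
        candidate_cvs[is_id] = _row_cv(pooled.mul(factor[pooled_ids], axis=1))

    chosen = pd.Series("none", index=table.areas.index)
    cv_chosen = cv_baseline.copy()
    if accepted:
        best_is = candidate_cvs.idxmin(axis=1)
        best_cv = candidate_cvs.min(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            improvement = (cv_baseline - best_cv) / cv_baseline
        take = improvement.ge(min_improvement) & best_cv.notna() & cv_baseline.notna()
        chosen[take] = best_is[take]
        cv_chosen[take] = best_cv[take]

    areas = table.areas.copy()
    for is_id in accepted:
        rows = chosen.index[chosen == is_id]
        if len(rows):
            areas.loc[rows] = areas.loc[rows].mul(factors[is_id], axis=1)
    result = BmisResult(chosen=chosen, cv_baseline=cv_baseline,
                        cv_chosen=cv_chosen, candidate_cvs=candidate_cvs,
                        accepted_candidates=accepted,
                        min_improvement=min_improvement)
    out = table.with_areas(areas, bmis="applied")
    return out, result


def standardize_to_total(table: PeakTable) -> pd.DataFrame:
    """Per-feature fractions of the total area across biological samples.

    Entry (j, s) = area_js / Σ_s' area_js' over ``role=sample`` columns;
    missing areas contribute 0 and become 0.  Rows sum to 1.  A feature
    with no positive area is an error (it has no pattern to standardize).
    """
    sample_ids = table.sample_ids("sample")
    sub = table.areas[sample_ids].fillna(0.0)
    totals = sub.sum(axis=1)
    dead = totals.index[totals <= 0].tolist()
    if dead:
        raise ValidationError(f"all-zero features cannot be standardized: {dead}")
    return sub.div(totals, axis=0)


def standardize_culture(table: PeakTable) -> pd.DataFrame:
    """log10 areas scaled to the per-feature maximum across organisms.

    Non-positive areas are treated as missing (and logged); missing values
    stay NaN here — the clustering front-end renders them as 0 and sends
    all-missing features to the "not observed" pseudo-mode.  The maximum
    entry of every observed row is 1.  A feature whose largest area is
    still <= 1 (log10 <= 0) has no usable dynamic range on this scale and
    is likewise returned all-missing, with a warning.
    """
    sample_ids = table.sample_ids("sample")
    sub = table.areas[sample_ids]
    nonpos = (sub <= 0)
    if nonpos.any().any():
        n = int(nonpos.sum().sum())
        warnings.warn(f"{n} non-positive culture areas treated as missing")
    logged = np.log10(sub.where(~nonpos))
    maxes = logged.max(axis=1)
    unscalable = maxes.notna() & (maxes <= 0)
    if unscalable.any():
        warnings.warn(f"{int(unscalable.sum())} features with max log10 area "
                      "<= 0 returned as missing")
        logged.loc[unscalable] = np.nan
        maxes[unscalable] = np.nan
    return logged.div(maxes, axis=0)
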