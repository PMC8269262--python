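"""Feature-quality filters for untargeted feature tables.

Four filters, applied in order:

1. pooled-CV filter — drop features whose coefficient of variation across
   repeated injections of the pooled QC sample exceeds 30% (strict >);
2. replicate-variability filter — drop features whose mean within-replicate
   CV exceeds the CV over the whole sample set;
3. presence filter — drop features detected in fewer than 50% of the
   biological samples ("at least" is inclusive);
4. blank filter — drop features whose mean sample area is not at least
   three times the mean blank area.

The pooled CV measures instrument noise only, so a high value means the
peak integration is unreliable regardless of biology.  Missing areas count
as "not detected" for presence and as 0 in the blank-filter means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_tables import PeakTable

__all__ = ["QcError", "QcReport", "compute_cv", "pooled_cv_filter",
           "replicate_variability_filter", "presence_filter", "blank_filter",
           "apply_qc"]

logger = logging.getLogger(__name__)

FILTER_FLAGS = ("cv_fail", "replicate_fail", "presence_fail", "blank_fail")


class QcError(ValueError):
    """The table lacks what a filter needs (pooled samples, blanks, ...)."""


@dataclass
class QcReport:
    """Per-feature pass/fail flags and the statistics behind them."""

    flags: pd.DataFrame          # boolean, columns FILTER_FLAGS
    stats: pd.DataFrame          # pooled_cv, replicate_cv, overall_cv, presence_fraction, blank_fold
    order: list[str] = field(default_factory=list)

    @classmethod
    def empty(cls, feature_ids: pd.Index) -> "QcReport":
        flags = pd.DataFrame(False, index=feature_ids, columns=list(FILTER_FLAGS))
        stats = pd.DataFrame(np.nan, index=feature_ids,
                             columns=["pooled_cv", "replicate_cv", "overall_cv",
                                      "presence_fraction", "blank_fold"])
        return cls(flags, stats)

    @property
    def survivors(self) -> pd.Index:
        return self.flags.index[~self.flags.any(axis=1)]

    @property
    def failed(self) -> pd.Index:
        return self.flags.index[self.flags.any(axis=1)]


def compute_cv(values) -> float:
    """Coefficient of variation: sample standard deviation (ddof=1) / mean.

    Missing values are ignored; at least two finite values and a positive
    mean are required.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 2:
        raise QcError(f"CV needs >= 2 non-missing values, got {v.size}")
    m = v.mean()
    if m <= 0:
        raise QcError(f"CV undefined for non-positive mean {m}")
    return float(v.std(ddof=1) / m)


def _row_cv(df: pd.DataFrame) -> pd.Series:
    """Vectorized per-feature CV over the given columns (NaN-aware).

    Features with <2 observations or non-positive mean get NaN.
    """
    n = df.notna().sum(axis=1)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    cv = sd / mean
    cv[(n < 2) | (mean <= 0)] = np.nan
    return cv


def pooled_cv_filter(table: PeakTable, report: QcReport,
                     threshold: float = 0.30) -> QcReport:
    """Flag features whose pooled-sample CV is strictly above ``threshold``."""
    pooled = table.sample_ids("pooled")
    if len(pooled) < 2:
        raise QcError(
            "pooled-CV filter needs >= 2 pooled samples; none/one present — "
            "skip this stage explicitly if the design has no pooled QC")
    cv = _row_cv(table.areas[pooled])
    report.stats["pooled_cv"] = cv
    report.flags["cv_fail"] = cv > threshold   # NaN compares False -> pass
    report.order.append("cv")
    return report


def replicate_variability_filter(table: PeakTable, report: QcReport) -> QcReport:
    """Flag features more variable within replicates than across all samples.

    The per-feature statistic is the mean, over replicate groups with >= 2
    members, of the within-group CV; it is compared (strict >) with the CV
    over every ``role=sample`` column.
    """
    sample_ids = table.sample_ids("sample")
    groups = table.samples.loc[sample_ids, "replicate_group"].dropna()
    sized = groups.groupby(groups).filter(lambda g: len(g) >= 2)
    if sized.empty:
        warnings.warn("no replicate groups with >= 2 members; "
                      "replicate-variability filter skipped")
        logger.warning("replicate filter skipped: no usable replicate groups")
        report.order.append("replicate(skipped)")
        return report
    within = []
    for _, members in sized.groupby(sized):
        within.append(_row_cv(table.areas[members.index.tolist()]))
    replicate_cv = pd.concat(within, axis=1).mean(axis=1)
    overall_cv = _row_cv(table.areas[sample_ids])
    report.stats["replicate_cv"] = replicate_cv
    report.stats["overall_cv"] = overall_cv
    report.flags["replicate_fail"] = replicate_cv > overall_cv
    report.order.append("replicate")
    return report


def presence_filter(table: PeakTable, report: QcReport,
                    min_fraction: float = 0.5) -> QcReport:
    """Flag features detected (non-missing, nonzero) in fewer than
    ``min_fraction`` of the biological samples; the bound is inclusive."""
    sample_ids = table.sample_ids("sample")
    if not sample_ids:
        raise QcError("presence filter needs role=sample columns")
    present = table.areas[sample_ids].gt(0).sum(axis=1) / len(sample_ids)
    report.stats["presence_fraction"] = present
    report.flags["presence_fail"] = present < min_fraction
    report.order.append("presence")
    return report


def blank_filter(table: PeakTable, report: QcReport, fold: float = 3.0) -> QcReport:
    """Flag features whose mean sample area is below ``fold`` × mean blank
    area.  Missing areas count as 0 in both means; a zero blank passes any
    positive sample mean."""
    blanks = table.blank_ids()
    if not blanks:
        raise QcError("blank filter needs >= 1 blank / medium_blank sample")
    sample_ids = table.sample_ids("sample")
    sample_mean = table.areas[sample_ids].fillna(0.0).mean(axis=1)
    blank_mean = table.areas[blanks].fillna(0.0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        report.stats["blank_fold"] = sample_mean / blank_mean
    report.flags["blank_fail"] = sample_mean < fold * blank_mean
    report.order.append("blank")
    return report


def apply_qc(table: PeakTable,
             cv_threshold: float = 0.30,
             presence_min_fraction: float = 0.5,
             blank_fold: float = 3.0,
             stages: tuple[str, ...] = ("cv", "replicate", "presence", "blank"),
             ) -> tuple[PeakTable, QcReport]:
    """Run the configured filter stages in order and drop failing features.

    Returns the filtered table and the full :class:`QcReport` (flags are
    evaluated on the input table; a feature survives iff all flags are
    false).  Internal-standard rows (``meta['internal_standards']``) are
    exempt from removal: they are spiked at constant concentration, so the
    blank comparison does not apply to them and B-MIS still needs them.
    """
    report = QcReport.empty(table.features.index)
    runners = {
        "cv": lambda: pooled_cv_filter(table, report, cv_threshold),
        "replicate": lambda: replicate_variability_filter(table, report),
        "presence": lambda: presence_filter(table, report, presence_min_fraction),
        "blank": lambda: blank_filter(table, report, blank_fold),
    }
    for stage in stages:
        if stage not in runners:
            raise ValueError(f"unknown QC stage {stage!r}")
        runners[stage]()
    keep = report.survivors.tolist()
    for is_id in table.meta.get("internal_standards", []):
        if is_id in table.features.index and is_id not in keep:
            keep.append(is_id)
    keep = [f for f in table.features.index if f in set(keep)]
    return table.subset_features(keep), report
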