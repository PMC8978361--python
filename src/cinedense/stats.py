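"""Paired-comparison reproducibility statistics.

Agreement between two observations of the same quantity is summarized by
Bland-Altman bias and limits of agreement, the squared Pearson correlation,
the duplicate-measurement coefficient of variation (per myocardial point:
``CV_p = (|x1-x2|/sqrt(2)) / |(x1+x2)/2| * 100``; per segment: the mean CV_p
over the segment's points), and the one-way random, single-measure
intraclass correlation coefficient.  CV and ICC values are classified into
the conventional excellent / good / fair / poor bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InputError


class DegenerateStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


def _pairs(o1, o2):
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    if o1.shape != o2.shape or o1.ndim != 1:
        raise InputError("observations must be equal-length 1-D arrays")
    if not (np.isfinite(o1).all() and np.isfinite(o2).all()):
        raise InputError("observations must be finite")
    return o1, o2


def bland_altman(o1, o2) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired observations.

    bias = mean(o1 - o2); LOA = bias +/- 1.96 * SD(o1 - o2) with the sample
    (n-1) standard deviation.
    """
    o1, o2 = _pairs(o1, o2)
    if o1.size < 2:
        raise InputError("Bland-Altman needs at least 2 pairs")
    d = o1 - o2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r2(o1, o2) -> float:
    """Square of the sample Pearson correlation coefficient."""
    o1, o2 = _pairs(o1, o2)
    if o1.size < 3:
        raise InputError("r^2 needs at least 3 pairs")
    if o1.std() == 0 or o2.std() == 0:
        raise DegenerateStatisticError("zero variance in one observation set")
    return float(np.corrcoef(o1, o2)[0, 1] ** 2)


#: minimum |mean strain| for a point to enter the segmental CV average
CV_MEAN_FLOOR = 0.02


def point_cv(x1, x2) -> np.ndarray:
    """Per-point duplicate CV in percent: (|x1-x2|/sqrt(2)) / |mean| * 100."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    mean = 0.5 * (x1 + x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.abs(x1 - x2) / np.sqrt(2.0) / np.abs(mean) * 100.0


@dataclass
class SegmentCV:
    cv_by_segment: dict            # AHA id -> mean point CV (%)
    n_excluded: int                # points dropped by the near-zero-mean floor
    n_points: int


def duplicate_cv(
    x1,
    x2,
    segment_ids,
    mean_floor: float = CV_MEAN_FLOOR,
) -> SegmentCV:
    """Segmental duplicate CV from pointwise paired observations.

    The per-point mean is the average of the two observations; the segment
    CV is the mean point CV over the segment's points whose |mean| exceeds
    ``mean_floor`` (points with near-zero mean strain make the ratio blow
    up; excluded points are counted, not silently dropped).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    segment_ids = np.asarray(segment_ids)
    cv = point_cv(x1, x2)
    mean = 0.5 * (x1 + x2)
    include = np.abs(mean) > mean_floor
    out = {}
    for seg in np.unique(segment_ids):
        sel = (segment_ids == seg) & include
        out[int(seg)] = float(cv[sel].mean()) if sel.any() else np.nan
    return SegmentCV(
        cv_by_segment=out,
        n_excluded=int((~include).sum()),
        n_points=int(x1.size),
    )


@dataclass
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    degenerate: bool = False       # zero between-unit variance


def icc(o1, o2, confidence: float = 0.95) -> IccResult:
    """One-way random, single-measure intraclass correlation (k = 2).

    ICC = (MSB - MSW) / (MSB + MSW) from the one-way ANOVA mean squares;
    the confidence interval is the standard F-distribution interval for the
    one-way model.  A non-positive between-unit variance is reported as
    computed (no clamping) with a degeneracy flag.
    """
    o1, o2 = _pairs(o1, o2)
    n = o1.size
    if n < 3:
        raise InputError("ICC needs at least 3 units")
    k = 2
    data = np.stack([o1, o2], axis=1)
    unit_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * ((unit_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - unit_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb + msw == 0:
        return IccResult(icc=0.0, ci_lower=np.nan, ci_upper=np.nan, degenerate=True)
    value = (msb - msw) / (msb + (k - 1) * msw)
    alpha = 1.0 - confidence
    if msw == 0:
        return IccResult(icc=1.0, ci_lower=1.0, ci_upper=1.0, degenerate=False)
    f0 = msb / msw
    f_l = f0 / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    f_u = f0 * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    return IccResult(
        icc=float(value),
        ci_lower=float((f_l - 1) / (f_l + k - 1)),
        ci_upper=float((f_u - 1) / (f_u + k - 1)),
        degenerate=bool(value <= 0),
    )


def classify_cv(cv: float) -> str:
    """CV bands: <=10 excellent, <=20 good, <=40 fair, >40 poor."""
    if cv < 0:
        raise InputError("CV must be non-negative")
    if cv <= 10.0:
        return "excellent"
    if cv <= 20.0:
        return "good"
    if cv <= 40.0:
        return "fair"
    return "poor"


def classify_icc(value: float) -> str:
    """ICC bands: >0.74 excellent, (0.6, 0.74] good, [0.4, 0.6] fair, <0.4 poor.

    The published band edges leave (0.59, 0.6] and exactly 0.4 textually
    unassigned; both resolve to "fair" here so the bands partition the line
    (the "poor" rule ICC < 0.4 is strict).
    """
    if not np.isfinite(value):
        raise InputError("ICC must be finite")
    if value > 0.74:
        return "excellent"
    if value > 0.6:
        return "good"
    if value >= 0.4:
        return "fair"
    return "poor"


# ---------------------------------------------------------------------------
# comparison suite

COMPARISON_TYPES = (
    "intra-user",
    "inter-user-same-site",
    "inter-user-different-site",
    "inter-user-human-DL",
    "inter-scan",
)


@dataclass
class ComparisonReport:
    """Agreement statistics for one (comparison type, endpoint) cell."""

    comparison: str
    endpoint: str
    n_units: int
    r2: float | None = None
    bias: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    cv_mean: float | None = None        # mean of per-unit (or per-segment) CVs, %
    cv_sd: float | None = None          # SD across subjects
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    icc_degenerate: bool = False
    cv_band: str | None = None
    icc_band: str | None = None
    segment_cv: dict = field(default_factory=dict)   # AHA id -> CV (bullseye)
    segment_icc: dict = field(default_factory=dict)  # AHA id -> ICC (bullseye)
    n_cv_excluded: int = 0

    def to_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "endpoint": self.endpoint,
            "n": self.n_units,
            "r2": self.r2,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "icc": self.icc,
            "icc_ci_lower": None if self.icc_ci is None else self.icc_ci[0],
            "icc_ci_upper": None if self.icc_ci is None else self.icc_ci[1],
            "cv_band": self.cv_band,
            "icc_band": self.icc_band,
        }


def compare_units(
    comparison: str, endpoint: str, units: pd.DataFrame
) -> ComparisonReport:
    """Unit-level agreement report from a table with columns value_1/value_2.

    The CV is the per-unit duplicate CV (mean +/- SD across units, excluding
    near-zero means by the same floor used segmentally).
    """
    o1 = units["value_1"].to_numpy(dtype=float)
    o2 = units["value_2"].to_numpy(dtype=float)
    report = ComparisonReport(comparison=comparison, endpoint=endpoint, n_units=len(o1))
    bias, lo, hi = bland_altman(o1, o2)
    report.bias, report.loa_lower, report.loa_upper = bias, lo, hi
    try:
        report.r2 = pearson_r2(o1, o2)
    except (DegenerateStatisticError, InputError):
        report.r2 = None
    cv = point_cv(o1, o2)
    include = np.abs(0.5 * (o1 + o2)) > CV_MEAN_FLOOR
    report.n_cv_excluded = int((~include).sum())
    if include.any():
        report.cv_mean = float(cv[include].mean())
        report.cv_sd = float(cv[include].std(ddof=1)) if include.sum() > 1 else 0.0
        report.cv_band = classify_cv(report.cv_mean)
    if len(o1) >= 3:
        res = icc(o1, o2)
        report.icc = res.icc
        report.icc_ci = (res.ci_lower, res.ci_upper)
        report.icc_degenerate = res.degenerate
        report.icc_band = classify_icc(res.icc) if np.isfinite(res.icc) else None
    return report


def compare_segmental(
    comparison: str,
    points: pd.DataFrame,
    mean_floor: float = CV_MEAN_FLOOR,
) -> ComparisonReport:
    """Segmental-strain agreement report from pointwise paired observations.

    ``points`` columns: subject, segment, value_1, value_2 (one row per
    matched myocardial point).  Per subject and segment the pointwise
    duplicate CV is averaged (the segmental CV definition); the pooled CV
    is the mean +/- SD across subjects of their segment-mean CVs.  The ICC
    (and r^2 / Bland-Altman) use per-(subject, segment) mean strains as
    units, so that between-unit spread is available.  Bullseye tables hold
    per-AHA-segment CV (averaged over subjects) and ICC (across subjects
    within the segment).
    """
    seg_means = (
        points.groupby(["subject", "segment"])[["value_1", "value_2"]]
        .mean()
        .reset_index()
    )
    report = compare_units(comparison, "segmental-Ecc", seg_means)
    per_subject_cv = []
    seg_cv_rows = []
    n_excl = 0
    for subject, grp in points.groupby("subject"):
        res = duplicate_cv(
            grp["value_1"], grp["value_2"], grp["segment"], mean_floor=mean_floor
        )
        n_excl += res.n_excluded
        vals = [v for v in res.cv_by_segment.values() if np.isfinite(v)]
        if vals:
            per_subject_cv.append(np.mean(vals))
        for seg, v in res.cv_by_segment.items():
            seg_cv_rows.append({"segment": seg, "cv": v})
    report.n_cv_excluded = n_excl
    if per_subject_cv:
        report.cv_mean = float(np.mean(per_subject_cv))
        report.cv_sd = (
            float(np.std(per_subject_cv, ddof=1)) if len(per_subject_cv) > 1 else 0.0
        )
        report.cv_band = classify_cv(report.cv_mean)
    seg_cv = pd.DataFrame(seg_cv_rows)
    if not seg_cv.empty:
        report.segment_cv = seg_cv.groupby("segment")["cv"].mean().to_dict()
    for seg, grp in seg_means.groupby("segment"):
        if len(grp) >= 3:
            try:
                report.segment_icc[int(seg)] = icc(
                    grp["value_1"], grp["value_2"]
                ).icc
            except InputError:
                pass
    return report


def comparison_suite(
    unit_tables: pd.DataFrame,
    point_tables: pd.DataFrame | None = None,
    mean_floor: float = CV_MEAN_FLOOR,
) -> list[ComparisonReport]:
    """One report per (comparison type x endpoint).

    ``unit_tables`` columns: comparison, endpoint, unit, value_1, value_2 —
    one row per unit (subject / subject-slice).  ``point_tables`` columns:
    comparison, subject, segment, point, value_1, value_2 — pointwise
    end-systolic Ecc pairs for the segmental endpoint.
    """
    reports = []
    for (comparison, endpoint), grp in unit_tables.groupby(
        ["comparison", "endpoint"], sort=True
    ):
        reports.append(compare_units(comparison, endpoint, grp))
    if point_tables is not None and not point_tables.empty:
        for comparison, grp in point_tables.groupby("comparison", sort=True):
            reports.append(compare_segmental(comparison, grp, mean_floor=mean_floor))
    return reports
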