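"""Tumour-growth volumetrics and spinal-cord toxicity statistics.

Caliper measurements (length ``a``, width ``b``) are converted to ellipsoid
volumes with the depth taken as the mean of the two measured axes,

.. math::  V = \\tfrac{4}{3} \\pi \\, a\\, b\\, c, \\qquad c = (a + b)/2,

applied to the axis lengths exactly as measured (no semi-axis halving).
Longitudinal cohort tables are summarised per group and day (mean +- SEM,
with burden-limit censoring handled by animals simply dropping out of later
timepoints).  Forelimb grip strength — a behavioural readout of cervical
spinal-cord injury — is reduced per animal to a median strength and the
fraction of timepoints below a threshold, and related to the fraction of PET
counts in the spinal cord via nonparametric two-sample tests (Mood's median
test, Mann-Whitney) and Pearson correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CaliperMeasurement",
    "GripRecord",
    "SpineActivityRecord",
    "CorrelationResult",
    "ellipsoid_volume",
    "growth_summary",
    "se_median",
    "SE_MEDIAN_FACTOR",
    "grip_metrics",
    "mood_median_test",
    "mann_whitney",
    "pearson_corr",
    "spine_fraction",
]

#: Asymptotic SE-of-the-median factor sqrt(pi/2) relative to sigma/sqrt(n);
#: 1.2533 to five significant figures.
SE_MEDIAN_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class CaliperMeasurement:
    """One caliper reading: tumour length ``a`` and width ``b`` in mm."""

    a: float
    b: float
    day: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("caliper axes must be >= 0")


@dataclass(frozen=True)
class GripRecord:
    """One grip-test timepoint: peak force in as-recorded force units."""

    animal_id: str
    week: int
    peak_force: float
    group: str

    def __post_init__(self) -> None:
        if self.peak_force < 0:
            raise ValueError("peak_force must be >= 0")


@dataclass(frozen=True)
class SpineActivityRecord:
    """PET counts inside the spinal-cord contour and in the whole image."""

    animal_id: str
    spine_counts: float
    total_counts: float

    def __post_init__(self) -> None:
        if not 0 <= self.spine_counts <= self.total_counts:
            raise ValueError("need 0 <= spine_counts <= total_counts")


def ellipsoid_volume(m: CaliperMeasurement) -> float:
    """Tumour volume (mm^3) from a caliper reading.

    ``V = (4/3) pi a b c`` with the unmeasured depth ``c = (a + b)/2``; the
    measured lengths enter as-is.  Symmetric in (a, b) and scaling as s^3
    under (a, b) -> (s a, s b).
    """
    c = (m.a + m.b) / 2.0
    return 4.0 / 3.0 * math.pi * m.a * m.b * c


def growth_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day tumour volume mean +- SEM.

    ``cohort`` needs columns ``animal_id``, ``group``, ``day`` and either
    ``volume_mm3`` or caliper columns ``a_mm``/``b_mm`` (converted via
    :func:`ellipsoid_volume`).  Animals censored at the burden limit simply
    stop contributing rows, so later timepoints average the survivors.
    Single-animal timepoints carry ``sem = NaN`` with ``n = 1``.
    """
    required = {"animal_id", "group", "day"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = cohort.copy()
    if "volume_mm3" not in df.columns:
        if not {"a_mm", "b_mm"} <= set(df.columns):
            raise ValueError("need either volume_mm3 or a_mm/b_mm columns")
        df["volume_mm3"] = [
            ellipsoid_volume(CaliperMeasurement(a, b))
            for a, b in zip(df["a_mm"], df["b_mm"])
        ]
    if df.empty:
        raise ValueError("cohort table is empty")
    out = (
        df.groupby(["group", "day"])["volume_mm3"]
        .agg(mean="mean", sem=lambda v: v.sem(ddof=1), n="count")
        .reset_index()
    )
    return out


def se_median(values: Sequence[float]) -> float:
    """Standard error of the median: ``1.2533 * s / sqrt(n)``.

    The asymptotic factor sqrt(pi/2) relates the sampling error of the
    median of a normal sample to that of the mean; ``s`` is the sample
    standard deviation (ddof=1).  Requires n >= 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return SE_MEDIAN_FACTOR * float(np.std(v, ddof=1)) / math.sqrt(v.size)


def grip_metrics(
    records: pd.DataFrame,
    from_week: int = 6,
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Per-animal grip summaries from week ``from_week`` onwards.

    Early post-irradiation weeks are excluded (no radiation effect is
    expected in the first month).  Returns one row per animal with the
    median peak force over the retained weeks and the fraction of timepoints
    below ``threshold`` (in the as-recorded force units of the input).
    """
    required = {"animal_id", "week", "peak_force"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"grip table missing columns: {sorted(missing)}")
    kept = records[records["week"] >= from_week]
    if kept.empty:
        raise ValueError(f"no grip records at week >= {from_week}")
    rows = []
    for animal, sub in kept.groupby("animal_id", sort=True):
        force = sub["peak_force"].to_numpy(dtype=float)
        row = {
            "animal_id": animal,
            "median_strength": float(np.median(force)),
            "frac_below": float(np.mean(force < threshold)),
            "n_timepoints": int(force.size),
        }
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def mood_median_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mood's median test: chi-square on the 2x2 above/below-pooled-median table."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    stat, p, _, _ = stats.median_test(a, b)
    return float(stat), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact null distribution for small n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    p_value: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two samples with a 95% CI.

    A constant input leaves the correlation undefined; that case is flagged
    (``degenerate=True`` with NaN fields) rather than raised, since it can
    arise in small noisy cohorts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return CorrelationResult(math.nan, math.nan, math.nan, math.nan, True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return CorrelationResult(
        float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)
    )


def spine_fraction(rec: SpineActivityRecord) -> float:
    """Fraction of image counts inside the spinal cord, in [0, 1]."""
    if rec.total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    return rec.spine_counts / rec.total_counts
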