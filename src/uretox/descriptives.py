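"""Creatinine normalization and per-stratum descriptive statistics.

Urinary analyte concentrations depend strongly on urine dilution, so
each toxin (µmol/L) is divided by urinary creatinine (mmol/L) to give a
dilution-corrected value in µmol/mmol creatinine. Group-level summaries
follow the clinical reporting convention: n, mean (SD), median (Q1, Q3),
min–max, plus ASD/control ratio columns of group medians and means.

All statistics are computed at full floating-point precision; rounding
(2 decimals for concentrations and ratios) happens only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import StratifiedCohort
from .toxins import TOXIN_ORDER, Toxin

__all__ = [
    "normalize",
    "SummaryStats",
    "summarize",
    "RatioSummary",
    "group_ratio",
    "descriptive_table",
    "render_descriptive_table",
    "DEFAULT_COMPARISONS",
]


def normalize(raw, creatinine):
    """Creatinine-normalize a concentration: raw (µmol/L) divided by
    urinary creatinine (mmol/L), giving µmol/mmol creatinine.

    Accepts scalars or arrays. Raises on non-positive creatinine or
    negative raw values.
    """
    raw_arr = np.asarray(raw, dtype=float)
    creat_arr = np.asarray(creatinine, dtype=float)
    if np.any(creat_arr <= 0):
        raise ValueError("creatinine must be > 0 mmol/L")
    if np.any(raw_arr < 0):
        raise ValueError("raw concentration must be ≥ 0 µmol/L")
    out = raw_arr / creat_arr
    return float(out) if np.isscalar(raw) and np.isscalar(creatinine) else out


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive block for one group of values (µmol/mmol)."""

    n: int
    mean: float
    sd: float | None  # undefined (None) for n = 1
    median: float
    q1: float
    q3: float
    min: float
    max: float


def summarize(
    values: Sequence[float] | np.ndarray, quantile_method: str = "linear"
) -> SummaryStats:
    """Summarize one group of concentrations.

    SD is the n−1 sample standard deviation (missing for a singleton).
    Quartiles use ``numpy.quantile`` with the given method; the default
    "linear" interpolates between order statistics, the common default
    in scientific software. Missing values must be removed by the
    caller; an empty input is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    if np.isnan(x).any():
        raise ValueError("missing values must be removed before summarizing")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=quantile_method)
    return SummaryStats(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


@dataclass(frozen=True)
class RatioSummary:
    """Case/reference ratios of group medians and means (dimensionless).
    Missing (None) when a reference statistic is not strictly positive."""

    median_ratio: float | None
    mean_ratio: float | None


def group_ratio(case: SummaryStats, reference: SummaryStats) -> RatioSummary:
    """Ratio column of the descriptive table: case median over reference
    median, and likewise for means (ASD/control in the default layout)."""
    return RatioSummary(
        median_ratio=case.median / reference.median if reference.median > 0 else None,
        mean_ratio=case.mean / reference.mean if reference.mean > 0 else None,
    )


#: Default comparison blocks (reference stratum, case stratum): the whole
#: cohort, then the sex- and age-restricted case-control contrasts.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("control", "asd"),
    ("control_boys", "asd_boys"),
    ("control_girls", "asd_girls"),
    ("control_2-5.9y", "asd_2-5.9y"),
    ("control_6-17y", "asd_6-17y"),
)


def descriptive_table(
    strata: StratifiedCohort,
    comparisons: Sequence[tuple[str, str]] | None = None,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Build the descriptive table: one row per (comparison, toxin).

    Each row carries the reference- and case-group summary statistics
    (prefixed ``ref_`` / ``case_``) and the case/reference median and
    mean ratios, at full precision. Comparisons whose strata are empty
    are omitted (a note is recorded in ``frame.attrs['omitted']``).
    Ordering is deterministic: comparisons as given, toxins in panel
    order.
    """
    comparisons = list(comparisons if comparisons is not None else DEFAULT_COMPARISONS)
    rows = []
    omitted = []
    for ref_label, case_label in comparisons:
        if strata.n(ref_label) == 0 or strata.n(case_label) == 0:
            omitted.append((ref_label, case_label))
            continue
        for toxin in TOXIN_ORDER:
            ref = summarize(strata.values(ref_label, toxin), quantile_method)
            case = summarize(strata.values(case_label, toxin), quantile_method)
            ratio = group_ratio(case, ref)
            row = {"comparison": f"{case_label} vs {ref_label}", "toxin": toxin.value}
            for prefix, s in (("ref", ref), ("case", case)):
                row[f"{prefix}_label"] = ref_label if prefix == "ref" else case_label
                for f in ("n", "mean", "sd", "median", "q1", "q3", "min", "max"):
                    row[f"{prefix}_{f}"] = getattr(s, f)
            row["median_ratio"] = ratio.median_ratio
            row["mean_ratio"] = ratio.mean_ratio
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["omitted"] = omitted
    return frame


def _f2(x) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"


def render_descriptive_table(table: pd.DataFrame) -> str:
    """Render the descriptive table as aligned plain text in the
    published layout: per toxin, rows for mean (SD), median (Q1, Q3),
    and min–max, with the case/reference ratio column. Values are
    rounded to 2 decimals here and nowhere else."""
    blocks = []
    for comparison, sub in table.groupby("comparison", sort=False):
        ref_label = sub["ref_label"].iloc[0]
        case_label = sub["case_label"].iloc[0]
        ref_n = int(sub["ref_n"].iloc[0])
        case_n = int(sub["case_n"].iloc[0])
        lines = [
            f"# {comparison}",
            f"{'':<18}{ref_label + f' (N = {ref_n})':<28}"
            f"{case_label + f' (N = {case_n})':<28}{'Ratio':<8}",
        ]
        for _, row in sub.iterrows():
            lines.append(row["toxin"])
            lines.append(
                f"{'  Mean (SD)':<18}"
                f"{_f2(row['ref_mean']) + ' (' + _f2(row['ref_sd']) + ')':<28}"
                f"{_f2(row['case_mean']) + ' (' + _f2(row['case_sd']) + ')':<28}"
                f"{_f2(row['mean_ratio']):<8}"
            )
            lines.append(
                f"{'  Median (Q1, Q3)':<18}"
                f"{_f2(row['ref_median']) + ' (' + _f2(row['ref_q1']) + ', ' + _f2(row['ref_q3']) + ')':<28}"
                f"{_f2(row['case_median']) + ' (' + _f2(row['case_q1']) + ', ' + _f2(row['case_q3']) + ')':<28}"
                f"{_f2(row['median_ratio']):<8}"
            )
            lines.append(
                f"{'  Min–Max':<18}"
                f"{_f2(row['ref_min']) + '–' + _f2(row['ref_max']):<28}"
                f"{_f2(row['case_min']) + '–' + _f2(row['case_max']):<28}"
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
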