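"""Normality screening, rank-based two-group comparison, FDR control.

The analysis is non-parametric throughout: a Shapiro–Wilk screen
documents that the toxin distributions are non-normal (it never switches
the method), each toxin is compared between independent groups with the
two-sided Wilcoxon rank-sum (Mann–Whitney U) test, and the five p-values
of one stratified comparison form a Benjamini–Hochberg family at
alpha = 0.05.

The rank-sum test uses exact enumeration of the U null distribution when
the smaller group has at most 8 subjects and the pooled sample is
tie-free; otherwise the normal approximation with midranks, tie-corrected
variance, and continuity correction. The method actually used is
recorded in every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import StratifiedCohort
from .toxins import TOXIN_ORDER, Toxin

__all__ = [
    "normality_test",
    "rank_sum_test",
    "RankSumResult",
    "bh_adjust",
    "TestResult",
    "compare_groups",
    "results_table",
    "EXACT_MAX_N",
]

logger = logging.getLogger(__name__)

#: Largest "smaller group" size for which the exact U distribution is used.
EXACT_MAX_N = 8


def normality_test(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test: returns (W, p).

    Requires 3 ≤ n ≤ 5000 and a non-constant sample (W is undefined for
    a constant vector). The pipeline uses this only to document the
    non-normality gate; group comparisons are always rank-based.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 ≤ n ≤ 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk W is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


class RankSumResult(NamedTuple):
    statistic: float  # Mann–Whitney U of the first group
    pvalue: float  # two-sided
    method: str  # "exact" | "asymptotic"


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    group_a: Sequence[float] | np.ndarray, group_b: Sequence[float] | np.ndarray
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test for two
    independent groups.

    Exact enumeration of the U null distribution when
    ``min(n_a, n_b) ≤ 8`` and the pooled sample has no ties; the exact
    path refuses ties and falls back to the normal approximation with
    midranks, tie-corrected variance, and continuity correction. The
    returned ``method`` records the path taken.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = min(a.size, b.size) <= EXACT_MAX_N and not _has_ties(
        np.concatenate([a, b])
    )
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Sorts the m p-values ascending, takes ``adj_(i) = min_{j≥i} m p_(j)/j``
    capped at 1, and returns the adjusted values in the original input
    order. Output never decreases any p and is order-preserving in the
    input ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TestResult:
    """One toxin's two-group comparison within a stratified family."""

    toxin: Toxin
    stratum: str  # family label, e.g. "asd vs control"
    test: str  # "rank-sum (exact)" or "rank-sum (asymptotic)"
    statistic: float
    p_raw: float
    p_adj: float
    n_case: int
    n_ref: int

    def __post_init__(self):
        assert 0.0 <= self.p_raw <= 1.0
        assert self.p_raw <= self.p_adj <= 1.0 + 1e-12


def compare_groups(
    strata: StratifiedCohort,
    ref_label: str = "control",
    case_label: str = "asd",
) -> list[TestResult]:
    """Compare the case and reference strata toxin by toxin.

    One rank-sum test per toxin (case vs reference, two-sided), with the
    Benjamini–Hochberg adjustment applied within this five-test family —
    families are per stratified comparison, matching the per-table
    presentation, not pooled across strata. Toxins with an empty group
    are skipped with a logged note; results keep panel order.
    """
    family = f"{case_label} vs {ref_label}"
    raws: list[tuple[Toxin, RankSumResult, int, int]] = []
    for toxin in TOXIN_ORDER:
        case = strata.values(case_label, toxin)
        ref = strata.values(ref_label, toxin)
        if case.size == 0 or ref.size == 0:
            logger.warning(
                "skipping %s in %s: empty group (case n=%d, ref n=%d)",
                toxin.value, family, case.size, ref.size,
            )
            continue
        raws.append((toxin, rank_sum_test(case, ref), case.size, ref.size))
    if not raws:
        return []
    adj = bh_adjust([r.pvalue for _, r, _, _ in raws])
    return [
        TestResult(
            toxin=toxin,
            stratum=family,
            test=f"rank-sum ({res.method})",
            statistic=res.statistic,
            p_raw=res.pvalue,
            p_adj=float(min(a, 1.0)),
            n_case=n_case,
            n_ref=n_ref,
        )
        for (toxin, res, n_case, n_ref), a in zip(raws, adj)
    ]


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten test results for TSV/JSON export."""
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "toxin": r.toxin.value,
                "n_case": r.n_case,
                "n_ref": r.n_ref,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "method": r.test,
            }
            for r in results
        ]
    )
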