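"""Composite uremic-toxin metrics: total burden, contributions, ratios.

Individual toxin concentrations often differ only modestly between
groups; the composite view asks instead how the whole panel is
structured. Three statistics are computed per stratum, each a function
of the five group medians only:

* **total burden** — the sum of the five toxin medians (µmol/mmol
  creatinine), a summary of overall systemic load;
* **percent contributions** — each median as a percentage of the total,
  a compositional profile (sums to 100 before rounding);
* **functional ratios** — IS/PCS (indolic vs phenolic microbial
  metabolism), PCS/TMAO (proteolytic fermentation vs methylamine
  pathway), IS/ADMA (gut-derived vs endogenous vascular toxin), and
  SDMA/ADMA (arginine-metabolism balance).

All metrics are computed from full-precision medians; rounding (2
decimals for burden and most ratios, 1 for contributions and PCS/TMAO)
applies only at rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import StratifiedCohort
from .toxins import RATIO_PAIRS, TOXIN_ORDER, Toxin

__all__ = [
    "total_burden",
    "percent_contributions",
    "functional_ratios",
    "BurdenProfile",
    "burden_profile",
    "per_subject_ratios",
    "composition_figure_data",
    "burden_frames",
    "DEFAULT_BURDEN_STRATA",
]

logger = logging.getLogger(__name__)


def _require_panel(medians: Mapping[Toxin, float]) -> None:
    for toxin in TOXIN_ORDER:
        if toxin not in medians:
            raise ValueError(f"median missing for toxin {toxin.value}")
        if medians[toxin] < 0:
            raise ValueError(f"negative median for toxin {toxin.value}")


def total_burden(medians: Mapping[Toxin, float]) -> float:
    """Sum of the five toxin medians (µmol/mmol creatinine), exact and
    at full precision. All five panel members must be present."""
    _require_panel(medians)
    return float(sum(medians[t] for t in TOXIN_ORDER))


def percent_contributions(
    medians: Mapping[Toxin, float], total: float | None = None
) -> dict[Toxin, float]:
    """Percent contribution of each toxin median to the total burden.

    With the default denominator (the sum of the medians themselves) the
    contributions sum to exactly 100 before rounding. An explicit
    ``total`` supports recomputing published tables whose denominator
    was printed separately.
    """
    _require_panel(medians)
    if total is None:
        total = total_burden(medians)
    if total <= 0:
        raise ValueError("total burden must be > 0")
    return {t: 100.0 * medians[t] / total for t in TOXIN_ORDER}


def functional_ratios(
    medians: Mapping[Toxin, float],
    pairs: Mapping[str, tuple[Toxin, Toxin]] | None = None,
) -> dict[str, float | None]:
    """Ratios of toxin medians for the named pairs (default: IS/PCS,
    PCS/TMAO, IS/ADMA, SDMA/ADMA). A zero denominator yields a missing
    value (None) with a warning, never an exception. Arbitrary
    (numerator, denominator) pairs may be supplied."""
    _require_panel(medians)
    pairs = dict(pairs if pairs is not None else RATIO_PAIRS)
    out: dict[str, float | None] = {}
    for name, (num, den) in pairs.items():
        if medians[den] <= 0:
            logger.warning("ratio %s undefined: %s median is 0", name, den.value)
            out[name] = None
        else:
            out[name] = medians[num] / medians[den]
    return out


@dataclass(frozen=True)
class BurdenProfile:
    """Composite metrics for one stratum."""

    stratum: str
    n: int
    medians: Mapping[Toxin, float]
    total_burden: float
    contributions: Mapping[Toxin, float]
    ratios: Mapping[str, float | None]


#: Strata profiled by default: whole groups, severity classes, sex
#: within ASD, and age band × group.
DEFAULT_BURDEN_STRATA: tuple[str, ...] = (
    "control",
    "asd",
    "cars_mild_moderate",
    "cars_severe",
    "asd_boys",
    "asd_girls",
    "control_2-5.9y",
    "asd_2-5.9y",
    "control_6-17y",
    "asd_6-17y",
)


def burden_profile(
    strata: StratifiedCohort,
    labels: Sequence[str] | None = None,
    quantile_method: str = "linear",
) -> list[BurdenProfile]:
    """Compute one `BurdenProfile` per requested stratum from that
    stratum's per-toxin medians. Empty strata are omitted with a logged
    note; output order follows the requested labels."""
    labels = list(labels if labels is not None else DEFAULT_BURDEN_STRATA)
    profiles = []
    for label in labels:
        if strata.n(label) == 0:
            logger.warning("burden profile omitted for empty stratum %r", label)
            continue
        medians = {
            t: float(np.quantile(strata.values(label, t), 0.5, method=quantile_method))
            for t in TOXIN_ORDER
        }
        total = total_burden(medians)
        profiles.append(
            BurdenProfile(
                stratum=label,
                n=strata.n(label),
                medians=medians,
                total_burden=total,
                contributions=percent_contributions(medians, total),
                ratios=functional_ratios(medians),
            )
        )
    return profiles


def per_subject_ratios(
    strata: StratifiedCohort, label: str, pair: tuple[Toxin, Toxin]
) -> np.ndarray:
    """Per-subject ratio distribution (numerator/denominator of the
    normalized values, complete cases with a positive denominator).

    This is *not* the default composite statistic — the profiled ratios
    are ratios of stratum medians — but is available for exploratory
    use."""
    num_tox, den_tox = pair
    num = strata.cohort.normalized_values(num_tox)[strata.mask(label)]
    den = strata.cohort.normalized_values(den_tox)[strata.mask(label)]
    frame = pd.DataFrame({"num": num, "den": den}).dropna()
    frame = frame[frame["den"] > 0]
    return (frame["num"] / frame["den"]).to_numpy(dtype=float)


def composition_figure_data(profiles: Sequence[BurdenProfile]) -> pd.DataFrame:
    """Long-format stacked-bar data: one row per (stratum, toxin) with
    the percent contribution. Toxin order is the fixed panel order and
    stratum order follows the input, so output is stable across runs."""
    if not profiles:
        raise ValueError("no profiles to export")
    rows = [
        {"stratum": p.stratum, "toxin": t.value, "percent": p.contributions[t]}
        for p in profiles
        for t in TOXIN_ORDER
    ]
    return pd.DataFrame(rows)


def burden_frames(
    profiles: Sequence[BurdenProfile],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten profiles into the three published-table layouts:
    totals (stratum, n, total burden), contributions (stratum × toxin
    percent), and ratios (stratum × ratio name). Full precision;
    rendering decides decimals."""
    totals = pd.DataFrame(
        [{"stratum": p.stratum, "n": p.n, "total_burden": p.total_burden} for p in profiles]
    )
    contrib = pd.DataFrame(
        [
            {"stratum": p.stratum, **{t.value: p.contributions[t] for t in TOXIN_ORDER}}
            for p in profiles
        ]
    )
    ratios = pd.DataFrame(
        [{"stratum": p.stratum, **dict(p.ratios)} for p in profiles]
    )
    return totals, contrib, ratios


#: Rendering precision per ratio name (PCS/TMAO is printed at 1 decimal
#: in the published tables, the others at 2).
RATIO_DECIMALS: dict[str, int] = {
    "IS/PCS": 2,
    "PCS/TMAO": 1,
    "IS/ADMA": 2,
    "SDMA/ADMA": 2,
}


def render_ratio(name: str, value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:.{RATIO_DECIMALS.get(name, 2)}f}"


def render_contribution(value: float) -> str:
    return f"{value:.1f}"


def render_burden(value: float) -> str:
    return f"{value:.2f}"
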