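"""Synthetic cohort generation calibrated to printed summary statistics.

Raw per-subject data for the study cohort are not publicly deposited, so
this module generates cohorts with the same statistical structure: the
published group sizes and sex/age/severity composition, and per-group
toxin marginals whose theoretical median and quartiles match the
published creatinine-normalized values exactly.

Marginals are log-normal per (group, toxin) — all published toxin
distributions are right-skewed and screened non-normal — fitted in
closed form from the printed median and quartiles:

    mu    = ln(median)
    sigma = ln(Q3/Q1) / (2 z_0.75),   z_0.75 = Phi^-1(0.75) ≈ 0.67449

so that exp(mu) is the median and [exp(mu - z sigma), exp(mu + z sigma)]
the interquartile range. Toxins are sampled independently per subject;
an optional Gaussian-copula correlation hook exists but defaults to the
identity (no inter-toxin correlations are published). The fit matches
median and IQR only, not means/SDs — a documented limitation of the
stand-in family.

Urinary creatinine has no published distribution; a configurable
log-normal stand-in (default median 1.0 mmol/L, log-sd 0.4) supplies it,
and raw concentrations are emitted as normalized × creatinine so the
normalization step is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort import Cohort, Group, Sex, _NORM_COL, _RAW_COL
from .toxins import TOXIN_ORDER, Toxin

__all__ = [
    "LogNormalParams",
    "CalibrationCell",
    "CalibrationTable",
    "SimulationConfig",
    "fit_lognormal_from_quartiles",
    "default_calibration",
    "generate_cohort",
    "inject_effect",
]

#: Standard-normal upper quartile Phi^-1(0.75).
Z75: float = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale location and spread of a log-normal marginal."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def quartiles(self) -> tuple[float, float]:
        return (
            math.exp(self.mu - Z75 * self.sigma),
            math.exp(self.mu + Z75 * self.sigma),
        )


def fit_lognormal_from_quartiles(
    median: float, q1: float, q3: float
) -> LogNormalParams:
    """Fit a log-normal whose theoretical median and IQR equal the inputs.

    Requires 0 < q1 ≤ median ≤ q3 and q1 < q3. The fit is exact and in
    closed form; ``exp(mu)`` reproduces the input median to the last bit.
    """
    if not (q1 > 0 and q1 <= median <= q3 and q1 < q3):
        raise ValueError(
            f"need 0 < q1 <= median <= q3 with q1 < q3, got "
            f"(median={median}, q1={q1}, q3={q3})"
        )
    return LogNormalParams(mu=math.log(median), sigma=math.log(q3 / q1) / (2 * Z75))


@dataclass(frozen=True)
class CalibrationCell:
    """Published summary of one (group, toxin) marginal, µmol/mmol."""

    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("calibration cell must satisfy min ≤ q1 ≤ median ≤ q3 ≤ max")

    def params(self) -> LogNormalParams:
        return fit_lognormal_from_quartiles(self.median, self.q1, self.q3)


# Composition counts: within each group, subjects per (sex, age band);
# within the ASD group, CARS severity class per sex. "Unclassified" are
# ASD subjects without a usable severity score, as in the study (161
# ASD vs 58 mild/moderate + 34 severe with scores).
@dataclass(frozen=True)
class GroupComposition:
    n: int
    sex_ageband: Mapping[tuple[Sex, str], int]
    cars_by_sex: Mapping[tuple[Sex, str], int] | None = None  # (sex, class) -> count

    def __post_init__(self):
        if sum(self.sex_ageband.values()) != self.n:
            raise ValueError("sex × age-band counts must sum to the group size")


@dataclass(frozen=True)
class CalibrationTable:
    """Per-(group, toxin) marginal summaries plus cohort composition."""

    cells: Mapping[tuple[Group, Toxin], CalibrationCell]
    composition: Mapping[Group, GroupComposition]
    shifts: Mapping[tuple[Group, Toxin], float] = field(default_factory=dict)

    def cell(self, group: Group, toxin: Toxin) -> CalibrationCell:
        return self.cells[(group, toxin)]

    def params(self, group: Group, toxin: Toxin) -> LogNormalParams:
        p = self.cell(group, toxin).params()
        shift = self.shifts.get((group, toxin), 0.0)
        return LogNormalParams(mu=p.mu + shift, sigma=p.sigma) if shift else p

    def implied_median(self, group: Group, toxin: Toxin) -> float:
        return self.params(group, toxin).median


def default_calibration() -> CalibrationTable:
    """The published study calibration.

    Medians, quartiles, and ranges of the five creatinine-normalized
    toxins per group; group sizes 71 controls vs 161 ASD; sex × age-band
    composition (14/57 vs 35/126 younger/older); CARS classes 58
    mild/moderate + 34 severe among the ASD children. All values are
    transcribed constants, not computed.
    """
    t2 = {
        (Group.CONTROL, Toxin.ADMA): CalibrationCell(12.70, 9.73, 18.74, 1.67, 33.16),
        (Group.ASD, Toxin.ADMA): CalibrationCell(14.72, 11.19, 19.24, 2.50, 34.36),
        (Group.CONTROL, Toxin.SDMA): CalibrationCell(32.06, 23.46, 39.28, 7.07, 80.21),
        (Group.ASD, Toxin.SDMA): CalibrationCell(30.16, 23.66, 44.29, 4.09, 79.83),
        (Group.CONTROL, Toxin.TMAO): CalibrationCell(3.09, 1.48, 5.19, 0.00, 10.38),
        (Group.ASD, Toxin.TMAO): CalibrationCell(2.65, 1.06, 4.37, 0.01, 10.52),
        (Group.CONTROL, Toxin.IS): CalibrationCell(63.80, 39.77, 103.18, 3.57, 168.60),
        (Group.ASD, Toxin.IS): CalibrationCell(57.60, 30.19, 87.37, 3.16, 193.60),
        (Group.CONTROL, Toxin.PCS): CalibrationCell(37.74, 20.02, 80.02, 1.27, 195.67),
        (Group.ASD, Toxin.PCS): CalibrationCell(44.11, 15.73, 84.23, 0.13, 188.20),
    }
    composition = {
        Group.CONTROL: GroupComposition(
            n=71,
            sex_ageband={
                (Sex.BOY, "2-5.9y"): 10,
                (Sex.GIRL, "2-5.9y"): 4,
                (Sex.BOY, "6-17y"): 27,
                (Sex.GIRL, "6-17y"): 30,
            },
        ),
        Group.ASD: GroupComposition(
            n=161,
            sex_ageband={
                (Sex.BOY, "2-5.9y"): 23,
                (Sex.GIRL, "2-5.9y"): 12,
                (Sex.BOY, "6-17y"): 101,
                (Sex.GIRL, "6-17y"): 25,
            },
            cars_by_sex={
                (Sex.BOY, "mild_moderate"): 45,
                (Sex.GIRL, "mild_moderate"): 13,
                (Sex.BOY, "severe"): 27,
                (Sex.GIRL, "severe"): 7,
                (Sex.BOY, "unclassified"): 52,
                (Sex.GIRL, "unclassified"): 17,
            },
        ),
    }
    return CalibrationTable(cells=t2, composition=composition)


def inject_effect(
    calibration: CalibrationTable, toxin: Toxin, group: Group, log_shift: float
) -> CalibrationTable:
    """Return a copy with the (group, toxin) log-location shifted.

    ``log_shift = ln(2)`` doubles the implied median of that marginal;
    0 is the identity. Used for power and type-I studies of the
    rank-based comparison.
    """
    if log_shift == 0:
        return calibration
    shifts = dict(calibration.shifts)
    shifts[(group, toxin)] = shifts.get((group, toxin), 0.0) + log_shift
    return replace(calibration, shifts=shifts)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation settings.

    Group sizes default to the study's (161 ASD, 71 controls). A fixed
    seed reproduces the cohort exactly. Creatinine is log-normal with
    the given median (mmol/L) and log-sd. With ``truncate`` the toxin
    draws are clipped to the calibrated [min, max] of each cell,
    approximating the zero-valued observations in the published ranges;
    off by default because group-level statistics never divide by a
    per-subject toxin value.
    """

    n_asd: int = 161
    n_control: int = 71
    seed: int = 0
    creatinine_median: float = 1.0
    creatinine_sigma: float = 0.4
    truncate: bool = False
    correlation: np.ndarray | None = None  # 5×5 Gaussian-copula matrix

    def __post_init__(self):
        if self.n_asd < 0 or self.n_control < 0:
            raise ValueError("group sizes must be ≥ 0")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (len(TOXIN_ORDER), len(TOXIN_ORDER)):
                raise ValueError("correlation must be 5×5")


#: CARS score ranges sampled per severity class (convention, not a
#: published distribution): mild/moderate uniform on [30, 36], severe
#: uniform on [36.5, 60].
_CARS_RANGE = {"mild_moderate": (30.0, 36.0), "severe": (36.5, 60.0)}


def _largest_remainder(total: int, weights: list[int]) -> list[int]:
    """Integer allocation of `total` proportional to `weights` (Hamilton
    method). Reproduces the reference counts exactly when `total` equals
    their sum."""
    wsum = sum(weights)
    if total == 0 or wsum == 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    counts = [int(math.floor(q)) for q in quotas]
    short = total - sum(counts)
    order = sorted(
        range(len(weights)), key=lambda i: (quotas[i] - counts[i], weights[i]), reverse=True
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def generate_cohort(
    calibration: CalibrationTable | None = None,
    config: SimulationConfig | None = None,
) -> Cohort:
    """Draw a synthetic cohort from the calibration.

    Sex, age band, and CARS class are allocated deterministically by
    largest-remainder scaling of the calibration composition, so the
    default sizes reproduce the published counts exactly. Ages are
    uniform within their band and CARS scores uniform within their class
    range. Each toxin is drawn from its fitted log-normal; raw values are
    normalized × creatinine, so re-normalizing recovers the draws.
    """
    calibration = calibration or default_calibration()
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    frames: list[dict] = []
    sizes = {Group.ASD: config.n_asd, Group.CONTROL: config.n_control}
    band_edges = {"2-5.9y": (2.0, 6.0), "6-17y": (6.0, 17.0)}

    for group in (Group.ASD, Group.CONTROL):
        n = sizes[group]
        comp = calibration.composition[group]
        cells = list(comp.sex_ageband.items())
        counts = _largest_remainder(n, [c for _, c in cells])

        sexes: list[Sex] = []
        bands: list[str] = []
        for ((sex, band), _), k in zip(cells, counts):
            sexes.extend([sex] * k)
            bands.extend([band] * k)

        cars_class: list[str | None] = [None] * n
        if group is Group.ASD and comp.cars_by_sex:
            for sex in (Sex.BOY, Sex.GIRL):
                idx = [i for i, s in enumerate(sexes) if s is sex]
                classes = ["mild_moderate", "severe", "unclassified"]
                ref = [comp.cars_by_sex.get((sex, c), 0) for c in classes]
                alloc = _largest_remainder(len(idx), ref)
                pos = 0
                for cls, k in zip(classes, alloc):
                    for i in idx[pos : pos + k]:
                        cars_class[i] = cls
                    pos += k

        ages = np.empty(n)
        for i, band in enumerate(bands):
            lo, hi = band_edges.get(band, (2.0, 17.0))
            ages[i] = rng.uniform(lo, hi)

        cars = np.full(n, np.nan)
        for i, cls in enumerate(cars_class):
            if cls in _CARS_RANGE:
                lo, hi = _CARS_RANGE[cls]
                cars[i] = rng.uniform(lo, hi)

        # toxin draws: independent log-normals, or a Gaussian copula when
        # a correlation matrix is supplied
        if config.correlation is not None:
            z = rng.multivariate_normal(
                np.zeros(len(TOXIN_ORDER)), np.asarray(config.correlation), size=n
            )
        else:
            z = rng.standard_normal((n, len(TOXIN_ORDER)))
        norm_vals = {}
        for j, toxin in enumerate(TOXIN_ORDER):
            p = calibration.params(group, toxin)
            draws = np.exp(p.mu + p.sigma * z[:, j])
            if config.truncate:
                cell = calibration.cell(group, toxin)
                draws = np.clip(draws, cell.min, cell.max)
            norm_vals[toxin] = draws

        creat = np.exp(
            math.log(config.creatinine_median)
            + config.creatinine_sigma * rng.standard_normal(n)
        )

        prefix = "ASD" if group is Group.ASD else "CTRL"
        for i in range(n):
            row = {
                "subject_id": f"{prefix}-{i + 1:04d}",
                "group": group.value,
                "sex": sexes[i].value,
                "age_years": float(ages[i]),
                "cars_score": round(float(cars[i]), 1) if not np.isnan(cars[i]) else np.nan,
                "creatinine_mmol_l": float(creat[i]),
                "bristol_stool": np.nan,
            }
            for toxin in TOXIN_ORDER:
                v = float(norm_vals[toxin][i])
                row[_NORM_COL[toxin]] = v
                row[_RAW_COL[toxin]] = v * float(creat[i])
            frames.append(row)

    import pandas as pd

    frame = pd.DataFrame(frames)
    meta = {"seed": config.seed, "n_asd": config.n_asd, "n_control": config.n_control}
    return Cohort(frame, meta=meta)
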