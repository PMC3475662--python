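"""Fluctuation-assay mutation-rate estimation.

Parallel cultures grown without selection accumulate loss-of-function
mutants according to the Luria-Delbrueck process: mutations arising early
found large "jackpot" clones, so mutant counts are heavily skewed and the
median is a robust summary.  The method of the median (Lea & Coulson)
converts the median mutant count r~ into m, the expected number of
mutation events per culture, by solving

    r~/m - ln(m) = 1.24

and divides by the mean final viable count to obtain a rate in events
per cell per division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "Condition",
    "Culture",
    "CultureSet",
    "RateEstimate",
    "RateSummary",
    "FluctuationInputError",
    "LEA_COULSON_CONSTANT",
    "MIN_CULTURES",
    "solve_lea_coulson",
    "estimate_rate_median",
    "revertant_frequency",
    "aggregate_rates",
    "rank_sum_test",
]

LEA_COULSON_CONSTANT = 1.24
#: Minimum number of independent cultures accepted for a rate estimate.
MIN_CULTURES = 11
#: Largest number of group assignments enumerated by the exact rank-sum test.
_EXACT_ENUM_LIMIT = 500_000


class FluctuationInputError(ValueError):
    """Raised for counts or culture sets violating the assay contract."""


class Condition(str, Enum):
    """Replication-fork-barrier state of a culture set."""

    RFB_ON = "ON"
    RFB_OFF = "OFF"


@dataclass(frozen=True)
class Culture:
    """One culture: viable-cell count and selected-colony count as plated."""

    n_viable: float
    n_selected: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.n_viable) and math.isfinite(self.n_selected)):
            raise FluctuationInputError("non-finite culture counts")
        if self.n_viable < 1:
            raise FluctuationInputError(f"n_viable must be >= 1, got {self.n_viable}")
        if self.n_selected < 0 or self.n_selected > self.n_viable:
            raise FluctuationInputError(
                f"n_selected must satisfy 0 <= n_selected <= n_viable, "
                f"got {self.n_selected} vs {self.n_viable}"
            )


@dataclass
class CultureSet:
    """One fluctuation experiment for a strain under one barrier condition."""

    strain_id: str
    condition: Condition
    cultures: list[Culture]
    plating_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.cultures = [
            c if isinstance(c, Culture) else Culture(*c) for c in self.cultures
        ]
        if not 0 < self.plating_fraction <= 1:
            raise FluctuationInputError(
                f"plating_fraction must be in (0, 1], got {self.plating_fraction}"
            )


@dataclass(frozen=True)
class RateEstimate:
    """Mutation rate from one fluctuation experiment.

    ``m_hat`` is the expected number of mutation events per culture;
    ``rate`` is ``m_hat`` divided by the mean (plating-corrected) final
    viable count, in events/cell/division.  When the median selected
    count is zero the experiment is uninformative and ``rate`` is an
    upper bound (``censored=True``), obtained by solving with a median
    of one -- the analogue of a "<" entry in a rate table.
    """

    m_hat: float
    rate: float
    n_cultures: int
    ci95: tuple[float, float]
    censored: bool


@dataclass(frozen=True)
class RateSummary:
    """Mean and standard error over replicate median-rate estimates."""

    mean_rate: float
    se: float
    n_replicates: int


def solve_lea_coulson(r_median: float) -> float:
    """Solve r~/m - ln(m) = 1.24 for m by bracketed root finding.

    The left-hand side is strictly decreasing in m, so the root is
    unique; it is bracketed in [1e-6, 1e6] and found to a relative
    tolerance of 1e-9.
    """
    if r_median <= 0:
        raise FluctuationInputError("median selected count must be positive")

    def f(m: float) -> float:
        return r_median / m - math.log(m) - LEA_COULSON_CONSTANT

    return brentq(f, 1e-6, 1e6, rtol=1e-9)


def _point_estimate(selected: np.ndarray, viable: np.ndarray) -> tuple[float, float, bool]:
    r_median = float(np.median(selected))
    censored = r_median == 0
    m_hat = solve_lea_coulson(1.0 if censored else r_median)
    return m_hat, m_hat / float(viable.mean()), censored


def estimate_rate_median(
    cultures: CultureSet, n_boot: int = 1000, seed: int = 0
) -> RateEstimate:
    """Estimate the mutation rate of one experiment by the method of the
    median.

    Counts are divided by the plating fraction before estimation.  The
    95% confidence interval is a seeded nonparametric bootstrap over
    cultures (percentile interval, ``n_boot`` resamples).
    """
    if len(cultures.cultures) < MIN_CULTURES:
        raise FluctuationInputError(
            f"rate estimation requires at least {MIN_CULTURES} independent "
            f"cultures, got {len(cultures.cultures)}"
        )
    pf = cultures.plating_fraction
    selected = np.array([c.n_selected for c in cultures.cultures], dtype=float) / pf
    viable = np.array([c.n_viable for c in cultures.cultures], dtype=float) / pf

    m_hat, rate, censored = _point_estimate(selected, viable)

    rng = np.random.default_rng(seed)
    n = len(selected)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = _point_estimate(selected[idx], viable[idx])[1]
    low, high = np.percentile(boot, [2.5, 97.5])

    return RateEstimate(
        m_hat=m_hat,
        rate=rate,
        n_cultures=n,
        ci95=(float(low), float(high)),
        censored=censored,
    )


def revertant_frequency(
    n_selected_total: float,
    n_viable_total: float,
    plating_fraction_selected: float = 1.0,
    plating_fraction_viable: float = 1.0,
) -> float:
    """Frequency of selected (e.g. Ura+) colonies among viable cells,
    corrected for the fraction of each culture plated."""
    if n_viable_total < 1:
        raise FluctuationInputError("n_viable_total must be >= 1")
    if n_selected_total < 0:
        raise FluctuationInputError("n_selected_total must be >= 0")
    return (n_selected_total / plating_fraction_selected) / (
        n_viable_total / plating_fraction_viable
    )


def aggregate_rates(replicate_rates: Sequence[float]) -> RateSummary:
    """Mean and standard error (sd/sqrt(n)) of replicate median rates.

    Reported summaries require at least three independent experiments.
    """
    rates = np.asarray(replicate_rates, dtype=float)
    if rates.size < 3:
        raise FluctuationInputError(
            f"rate summaries require >= 3 replicate experiments, got {rates.size}"
        )
    if not np.all(np.isfinite(rates)):
        raise FluctuationInputError("non-finite replicate rates")
    se = float(rates.std(ddof=1) / math.sqrt(rates.size))
    return RateSummary(mean_rate=float(rates.mean()), se=se, n_replicates=int(rates.size))


def _rank_sum_u(ranks_a: Iterable[float], n_a: int) -> float:
    return sum(ranks_a) - n_a * (n_a + 1) / 2


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent rate samples.

    For the small samples typical of fluctuation assays the p-value is
    computed by exact enumeration of all group assignments of the pooled
    mid-ranks (which handles ties exactly); beyond the enumeration limit
    a normal approximation with tie and continuity corrections is used.
    Returns (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise FluctuationInputError("rank-sum test requires two non-empty groups")

    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _rank_sum_u(ranks[:n_a], n_a)
    mean_u = n_a * n_b / 2

    if comb(n_a + n_b, n_a) <= _EXACT_ENUM_LIMIT:
        dev = abs(u_obs - mean_u)
        hits = 0
        total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _rank_sum_u((ranks[i] for i in idx), n_a)
            if abs(u - mean_u) >= dev - 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total

    _, p = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_obs, float(p)
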