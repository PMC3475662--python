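"""Replication-slippage rate per generation from revertant-frequency
time series.

For slow-growing strains the reversion frequency is followed as a
function of the number of generations after barrier induction.  Under
constant per-generation slippage with negligible selection, the
frequency grows linearly and the slope of frequency versus generations
is the slippage rate per generation.  Each independent experiment is fit
by ordinary least squares with a free intercept (cultures do not start
at zero frequency); the reported rate is the mean of per-experiment
slopes with its standard error across experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["KineticsSeries", "SlippageRate", "KineticsInputError",
           "slippage_rate_per_generation"]

MIN_POINTS = 3


class KineticsInputError(ValueError):
    pass


@dataclass
class KineticsSeries:
    """Revertant-frequency time series for one strain.

    ``experiments`` holds one (k, 2) array per independent experiment
    with columns (generations, frequency).
    """

    strain_id: str
    experiments: list[np.ndarray]

    def __post_init__(self) -> None:
        checked = []
        for i, exp in enumerate(self.experiments):
            arr = np.asarray(exp, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise KineticsInputError(
                    f"experiment {i}: expected (k, 2) array of "
                    "(generations, frequency)"
                )
            if arr.shape[0] < MIN_POINTS:
                raise KineticsInputError(
                    f"experiment {i}: slope fitting requires >= {MIN_POINTS} points"
                )
            g = arr[:, 0]
            if np.any(np.diff(g) <= 0):
                raise KineticsInputError(
                    f"experiment {i}: generations must be strictly increasing"
                )
            if np.any(g < 0) or np.any(arr[:, 1] < 0):
                raise KineticsInputError(f"experiment {i}: negative values")
            checked.append(arr)
        self.experiments = checked

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


@dataclass(frozen=True)
class SlippageRate:
    """Mean per-generation slippage rate, SE across experiments, and the
    individual per-experiment slopes."""

    rate: float
    se: float
    slopes: tuple[float, ...]


def slippage_rate_per_generation(series: KineticsSeries) -> SlippageRate:
    """Per-generation slippage rate as the mean of per-experiment OLS
    slopes of frequency versus generations."""
    slopes = []
    for i, exp in enumerate(series.experiments):
        g, f = exp[:, 0], exp[:, 1]
        if np.ptp(g) == 0:
            raise KineticsInputError(f"experiment {i}: zero variance in generations")
        fit = stats.linregress(g, f)
        slopes.append(float(fit.slope))
    slopes_arr = np.asarray(slopes)
    n = slopes_arr.size
    se = float(slopes_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return SlippageRate(rate=float(slopes_arr.mean()), se=se, slopes=tuple(slopes))
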