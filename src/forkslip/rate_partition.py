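"""Partitioning of locus-loss rates into per-class rates and induced rates.

A fluctuation assay yields one total rate of marker loss per strain and
barrier condition.  The observed fractions of event classes (genomic
deletion, translocation, point mutation; or mutation-spectrum
categories) "balance" that total into per-class rates.  The
barrier-induced rate of a class is the ON rate minus the OFF rate,
which cancels both spontaneous instability and barrier leakiness; fold
inductions compare ON with OFF, or barrier strains with a barrier-free
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .seq_classify import SpectrumTable

__all__ = [
    "PartitionedRates",
    "RatePartitionError",
    "balance_rates",
    "induced_rate",
    "fold_induction",
    "fold_vs_control",
    "spectrum_rates",
    "rate_share_percent",
    "partition_strain",
]

_FRACTION_TOL = 1e-9


class RatePartitionError(ValueError):
    """Raised for invalid fractions or undefined ratios."""


def balance_rates(
    total_rate: float, class_fractions: Mapping[str, float]
) -> dict[str, float]:
    """Split a total rate into per-class rates by observed fractions.

    class_rate[c] = total_rate * fraction[c]; the outputs sum exactly to
    the total by construction.
    """
    if total_rate < 0:
        raise RatePartitionError("total_rate must be >= 0")
    fracs = dict(class_fractions)
    if any(f < 0 for f in fracs.values()):
        raise RatePartitionError("class fractions must be >= 0")
    s = sum(fracs.values())
    if abs(s - 1.0) > _FRACTION_TOL:
        raise RatePartitionError(f"class fractions must sum to 1, got {s!r}")
    return {c: total_rate * f for c, f in fracs.items()}


def induced_rate(rate_on: float, rate_off: float) -> float:
    """Barrier-induced rate: ON minus OFF, floored at zero.

    Induction is defined as the excess over spontaneous events; a
    negative difference is subtraction noise, not a negative rate.
    """
    if rate_on < 0 or rate_off < 0:
        raise RatePartitionError("rates must be >= 0")
    return max(rate_on - rate_off, 0.0)


def fold_induction(rate_on: float, rate_off: float, ndigits: Optional[int] = None) -> float:
    """Fold induction of a rate by barrier activation (ON / OFF).

    Returned unrounded by default so that reciprocal folds multiply to
    one; pass ``ndigits=1`` for report-style one-decimal values.
    """
    if rate_off <= 0:
        raise RatePartitionError("fold induction undefined for rate_off <= 0")
    fold = rate_on / rate_off
    return round(fold, ndigits) if ndigits is not None else fold


def fold_vs_control(
    rate_on: float, control_rate_on: float, ndigits: Optional[int] = None
) -> float:
    """Fold induction relative to a barrier-free control construct.

    Both sides are rates measured with the barrier protein expressed.
    """
    if control_rate_on <= 0:
        raise RatePartitionError("fold vs control undefined for zero control rate")
    fold = rate_on / control_rate_on
    return round(fold, ndigits) if ndigits is not None else fold


def rate_share_percent(part_rate: float, total_rate: float) -> int:
    """Share of a class rate within a total, as a whole-number percent."""
    if total_rate <= 0:
        raise RatePartitionError("total rate must be > 0")
    return round(100 * part_rate / total_rate)


def spectrum_rates(
    total_mutation_rate: float, spectrum: SpectrumTable
) -> dict[str, dict[str, float]]:
    """Balance a total mutation rate over spectrum categories.

    Returns per category a dict with ``rate`` (events/cell/division) and
    ``percent`` (share of events, rounded to the nearest integer).
    """
    total = spectrum.total
    if total < 1:
        raise RatePartitionError("empty spectrum cannot balance a rate")
    out: dict[str, dict[str, float]] = {}
    for cat, count in spectrum.counts.items():
        out[cat] = {
            "rate": total_mutation_rate * count / total,
            "percent": round(100 * count / total),
        }
    return out


@dataclass
class PartitionedRates:
    """Total, per-class and barrier-induced rates for one strain."""

    strain_id: str
    rate_on: float
    rate_off: float
    class_fractions_on: dict[str, float]
    class_fractions_off: dict[str, float]
    class_rates_on: dict[str, float] = field(default_factory=dict)
    class_rates_off: dict[str, float] = field(default_factory=dict)
    induced_rates: dict[str, float] = field(default_factory=dict)
    fold_rtf1: float = float("nan")
    fold_vs_control: float = float("nan")


def partition_strain(
    strain_id: str,
    rate_on: float,
    rate_off: float,
    class_fractions_on: Mapping[str, float],
    class_fractions_off: Mapping[str, float],
    control_rate_on: Optional[float] = None,
) -> PartitionedRates:
    """Assemble the full rate partition for one strain.

    Per-class rates are balanced within each condition, induced rates
    are computed class-wise as ON minus OFF (floored at zero), and fold
    inductions are reported where defined.
    """
    rates_on = balance_rates(rate_on, class_fractions_on)
    rates_off = balance_rates(rate_off, class_fractions_off)
    classes = set(rates_on) | set(rates_off)
    induced = {
        c: induced_rate(rates_on.get(c, 0.0), rates_off.get(c, 0.0)) for c in classes
    }
    return PartitionedRates(
        strain_id=strain_id,
        rate_on=rate_on,
        rate_off=rate_off,
        class_fractions_on=dict(class_fractions_on),
        class_fractions_off=dict(class_fractions_off),
        class_rates_on=rates_on,
        class_rates_off=rates_off,
        induced_rates=induced,
        fold_rtf1=fold_induction(rate_on, rate_off) if rate_off > 0 else float("nan"),
        fold_vs_control=(
            fold_vs_control(rate_on, control_rate_on)
            if control_rate_on
            else float("nan")
        ),
    )
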