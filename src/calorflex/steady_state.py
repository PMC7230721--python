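"""Steady-state window selection over an epoched basal recording.

The scan discards an initial transient, enumerates epoch-aligned 5-min
windows, screens each on the coefficient of variation of VO2, VCO2,
minute ventilation and the respiratory exchange ratio, and keeps the
most stable qualifying window — defined as the minimum mean of the four
CVs, ties broken by earliest start. A window's mean RER is the ratio of
its mean VCO2 to mean VO2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from calorflex.errors import DomainError, InsufficientDataError, TooShortError
from calorflex.gas_exchange_io import EpochSeries

#: Inclusive physiological bounds on mean RER for substrate-oxidation outputs.
RER_LO = 0.7
RER_HI = 1.0


@dataclass(frozen=True)
class SteadyStateCriteria:
    """Scan parameters: initial discard, window length, CV ceiling."""

    discard_initial_s: float = 300.0
    window_s: float = 300.0
    cv_max_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.discard_initial_s < 0:
            raise ValueError("discard_initial_s must be >= 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.cv_max_pct <= 0:
            raise ValueError("cv_max_pct must be > 0")


@dataclass(frozen=True)
class SteadyStateWindow:
    """One candidate window with its CV profile and mean gas values."""

    start_s: float
    end_s: float
    cv_vo2: float
    cv_vco2: float
    cv_ve: float
    cv_rer: float
    mean_vo2: float  # mL/min
    mean_vco2: float  # mL/min
    mean_rer: float
    meets_criteria: bool

    @property
    def stability(self) -> float:
        """Composite stability score: mean of the four CVs, percent."""
        return (self.cv_vo2 + self.cv_vco2 + self.cv_ve + self.cv_rer) / 4.0


def cv_percent(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation: 100 x sample SD (n-1) / mean.

    Requires at least two values and a strictly positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("cv_percent needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"cv_percent needs mean > 0, got {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def enumerate_windows(
    series: EpochSeries,
    criteria: SteadyStateCriteria = SteadyStateCriteria(),
) -> list[SteadyStateWindow]:
    """All epoch-aligned candidate windows after the initial discard.

    Starts run from ``discard_initial_s`` to ``span - window_s`` in steps
    of one epoch; windows overlapping a missing epoch are omitted.
    Raises :class:`TooShortError` if the series cannot hold one window.
    """
    epoch_s = series.epoch_s
    span = series.span_s
    if span < criteria.discard_initial_s + criteria.window_s:
        raise TooShortError(
            f"series spans {span}s < discard {criteria.discard_initial_s}s "
            f"+ window {criteria.window_s}s"
        )
    w = int(round(criteria.window_s / epoch_s))
    if w < 2:
        raise ValueError("window must cover at least 2 epochs for a CV")
    first = int(np.ceil(criteria.discard_initial_s / epoch_s))
    last = series.n_epochs - w  # inclusive last start index

    windows: list[SteadyStateWindow] = []
    for i in range(first, last + 1):
        sl = slice(i, i + w)
        if series.missing[sl].any():
            continue
        vo2, vco2, ve, rer = series.vo2[sl], series.vco2[sl], series.ve[sl], series.rer[sl]
        cvs = (cv_percent(vo2), cv_percent(vco2), cv_percent(ve), cv_percent(rer))
        mean_vo2 = float(vo2.mean())
        mean_vco2 = float(vco2.mean())
        windows.append(
            SteadyStateWindow(
                start_s=i * epoch_s,
                end_s=(i + w) * epoch_s,
                cv_vo2=cvs[0],
                cv_vco2=cvs[1],
                cv_ve=cvs[2],
                cv_rer=cvs[3],
                mean_vo2=mean_vo2,
                mean_vco2=mean_vco2,
                mean_rer=mean_vco2 / mean_vo2,
                meets_criteria=all(c < criteria.cv_max_pct for c in cvs),
            )
        )
    return windows


def select_most_stable(
    windows: Sequence[SteadyStateWindow],
) -> SteadyStateWindow | None:
    """Minimum-stability window among those meeting criteria.

    Ties break to the earliest start. Returns ``None`` when no window
    qualifies (the participant is then excluded from calorimetry
    outputs). Raises ``ValueError`` on an empty sequence.
    """
    if not windows:
        raise ValueError("select_most_stable requires a non-empty window sequence")
    qualifying = [w for w in windows if w.meets_criteria]
    if not qualifying:
        return None
    return min(qualifying, key=lambda w: (w.stability, w.start_s))


def rer_validity(
    window: SteadyStateWindow, lo: float = RER_LO, hi: float = RER_HI
) -> bool:
    """True iff the window's mean RER lies in [lo, hi], bounds inclusive."""
    return lo <= window.mean_rer <= hi
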