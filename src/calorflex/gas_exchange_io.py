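"""Read, validate, epoch, and write gas-exchange recordings and participant tables.

The native trace dialect is a headered CSV with columns ``t_s``,
``vo2_ml_min``, ``vco2_ml_min``, ``ve_l_min``; a :class:`TraceDialect`
maps other metabolic-cart exports onto it. Times are seconds from
recording start and epochs tile ``[0, duration_s)`` half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from calorflex.errors import (
    EmptyEpochError,
    EmptyTraceError,
    FormatError,
    OrderingError,
)

logger = logging.getLogger(__name__)

SEX_CODES = {"male", "female"}

#: Columns a participant table must carry; everything else passes through.
MANDATORY_PARTICIPANT_COLUMNS = ("id", "sex", "age")


@dataclass(frozen=True)
class TraceDialect:
    """Column mapping from a cart export onto the native trace schema."""

    time: str = "t_s"
    vo2: str = "vo2_ml_min"
    vco2: str = "vco2_ml_min"
    ve: str = "ve_l_min"
    delimiter: str = ","

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.time, self.vo2, self.vco2, self.ve)


DEFAULT_DIALECT = TraceDialect()


@dataclass(frozen=True)
class GasSample:
    """One breath (or cart-averaged) gas-exchange observation.

    ``t`` seconds from recording start, ``vo2``/``vco2`` in mL/min,
    ``ve`` minute ventilation in L/min. All gas values strictly positive.
    """

    t: float
    vo2: float
    vco2: float
    ve: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if self.vo2 <= 0 or self.vco2 <= 0 or self.ve <= 0:
            raise ValueError("gas values must be strictly positive")


@dataclass(frozen=True)
class GasExchangeTrace:
    """A full basal recording for one participant."""

    participant_id: str
    samples: tuple[GasSample, ...]
    duration_s: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ts = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise OrderingError(
                f"trace {self.participant_id}: sample times not strictly increasing"
            )
        if self.samples and self.duration_s < ts[-1]:
            raise ValueError("duration_s shorter than last sample time")

    def __len__(self) -> int:
        return len(self.samples)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (t, vo2, vco2, ve) as float arrays."""
        if not self.samples:
            empty = np.empty(0)
            return empty, empty.copy(), empty.copy(), empty.copy()
        arr = np.array([(s.t, s.vo2, s.vco2, s.ve) for s in self.samples])
        return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


@dataclass(frozen=True)
class EpochSeries:
    """Per-epoch means over a trace; the unit the steady-state scan works on.

    ``rer`` is epoch-mean vco2 / epoch-mean vo2. Epochs with no samples
    are flagged in ``missing`` and carry NaN means.
    """

    epoch_s: float
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    rer: np.ndarray
    missing: np.ndarray
    n_samples: np.ndarray
    participant_id: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.vo2)

    @property
    def span_s(self) -> float:
        return self.n_epochs * self.epoch_s


def read_trace(
    path: str | Path,
    dialect: TraceDialect = DEFAULT_DIALECT,
    participant_id: str | None = None,
    duration_s: float | None = None,
) -> GasExchangeTrace:
    """Read one trace CSV, dropping (and counting) non-positive gas rows.

    Raises :class:`FormatError` on missing columns, :class:`EmptyTraceError`
    if fewer than two valid samples remain, :class:`OrderingError` on a
    non-monotone time column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    missing_cols = [c for c in dialect.columns if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing column(s) {missing_cols}")

    df = df[list(dialect.columns)].apply(pd.to_numeric, errors="coerce")
    n_raw = len(df)
    valid = (
        df[dialect.vo2].gt(0)
        & df[dialect.vco2].gt(0)
        & df[dialect.ve].gt(0)
        & df[dialect.time].ge(0)
        & df.notna().all(axis=1)
    )
    n_dropped = int(n_raw - valid.sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path.name, n_dropped)
    df = df[valid]
    if len(df) < 2:
        raise EmptyTraceError(f"{path}: fewer than 2 valid samples")

    t = df[dialect.time].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise OrderingError(f"{path}: time column not strictly increasing")

    samples = tuple(
        GasSample(t=row[0], vo2=row[1], vco2=row[2], ve=row[3])
        for row in df.to_numpy(float)
    )
    pid = participant_id if participant_id is not None else path.stem
    return GasExchangeTrace(
        participant_id=pid,
        samples=samples,
        duration_s=duration_s if duration_s is not None else float(t[-1]),
        n_dropped=n_dropped,
    )


def write_trace(
    trace: GasExchangeTrace,
    path: str | Path,
    dialect: TraceDialect = DEFAULT_DIALECT,
) -> None:
    """Write a trace back to CSV in the given dialect (round-trip safe)."""
    t, vo2, vco2, ve = trace.as_arrays()
    pd.DataFrame(
        {dialect.time: t, dialect.vo2: vo2, dialect.vco2: vco2, dialect.ve: ve}
    ).to_csv(path, sep=dialect.delimiter, index=False)


def epoch_trace(trace: GasExchangeTrace, epoch_s: float = 30.0) -> EpochSeries:
    """Average a trace into fixed epochs tiling ``[0, duration_s)``.

    Each epoch mean is the arithmetic mean of samples with
    ``epoch_start <= t < epoch_end``; epochs without samples are marked
    missing. Raises :class:`EmptyEpochError` if every epoch is missing.
    """
    if epoch_s <= 0:
        raise ValueError(f"epoch_s must be positive, got {epoch_s}")
    if len(trace) == 0:
        raise EmptyTraceError(f"trace {trace.participant_id} has no samples")

    n_epochs = int(np.floor(trace.duration_s / epoch_s))
    if n_epochs == 0:
        raise EmptyEpochError(
            f"trace {trace.participant_id}: duration {trace.duration_s}s shorter "
            f"than one {epoch_s}s epoch"
        )
    t, vo2, vco2, ve = trace.as_arrays()
    idx = np.floor(t / epoch_s).astype(int)
    in_range = idx < n_epochs
    idx, vo2, vco2, ve = idx[in_range], vo2[in_range], vco2[in_range], ve[in_range]

    counts = np.bincount(idx, minlength=n_epochs).astype(int)
    with np.errstate(invalid="ignore"):
        mean_vo2 = np.bincount(idx, weights=vo2, minlength=n_epochs) / counts
        mean_vco2 = np.bincount(idx, weights=vco2, minlength=n_epochs) / counts
        mean_ve = np.bincount(idx, weights=ve, minlength=n_epochs) / counts
        rer = mean_vco2 / mean_vo2
    missing = counts == 0
    if missing.all():
        raise EmptyEpochError(f"trace {trace.participant_id}: all epochs empty")
    return EpochSeries(
        epoch_s=float(epoch_s),
        vo2=mean_vo2,
        vco2=mean_vco2,
        ve=mean_ve,
        rer=rer,
        missing=missing,
        n_samples=counts,
        participant_id=trace.participant_id,
    )


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read a participant table, validating mandatory columns and sex coding.

    Unknown columns are preserved pass-through; blank biomarker cells stay
    NaN so downstream analyses can use pairwise-complete rows. Units are
    assumed as reported clinically: mg/dL, UI/mL, mm Hg, kg, cm, m, years.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df["id"] = df["id"].astype(str)
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    bad_sex = set(df["sex"].unique()) - SEX_CODES
    if bad_sex:
        raise FormatError(
            f"{path}: sex coding must be one of {sorted(SEX_CODES)}, got {sorted(bad_sex)}"
        )
    numeric_cols = [c for c in df.columns if c not in ("id", "sex")]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
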