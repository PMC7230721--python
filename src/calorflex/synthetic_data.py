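"""Seeded synthetic cohorts and breath-by-breath gas traces.

The cohort generator draws sex-stratified anthropometry, blood pressure
and blood panel from independent truncated normals (default parameters
taken from the study population's published per-sex means/SDs), plants a
lean-mass-driven basal metabolic rate and a basal respiratory exchange
ratio, and links ln-insulin to the planted RER through a configurable
standardized slope. The planted gas-exchange truth (vo2*, vco2*) is
obtained by inverting the energy-expenditure equation at the planted
BMR and RER, so end-to-end recovery checks are self-consistent.

The trace generator emulates a 30-min basal recording: a renewal process
of breath times, an initial elevated transient decaying exponentially to
the basal level, and multiplicative breath-level noise.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from calorflex.errors import ConfigError
from calorflex.gas_exchange_io import GasExchangeTrace, GasSample, write_trace

#: Per-sex (mean, sd) generating parameters for the observable cohort columns.
DEFAULT_TABLE1_PARAMS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "male": {
        "age": (54.2, 5.2),
        "height": (1.73, 0.06),
        "bmi": (28.50, 3.51),
        "waist": (103.13, 8.45),
        "lean_mass_index": (17.49, 2.06),
        "fat_mass_index": (10.15, 3.20),
        "vat_mass": (986.4, 388.8),
        "dbp": (85.16, 10.87),
        "pulse_pressure": (49.10, 8.0),
        "tc": (200.67, 32.29),
        "hdl": (55.33, 12.86),
        "ldl": (138.79, 78.00),
        "tg": (125.06, 27.93),
    },
    "female": {
        "age": (52.7, 4.6),
        "height": (1.61, 0.06),
        "bmi": (25.29, 3.40),
        "waist": (88.09, 9.91),
        "lean_mass_index": (13.26, 1.78),
        "fat_mass_index": (11.28, 2.95),
        "vat_mass": (607.4, 298.7),
        "dbp": (77.64, 11.44),
        "pulse_pressure": (43.28, 8.0),
        "tc": (211.03, 31.70),
        "hdl": (61.73, 11.06),
        "ldl": (124.78, 49.88),
        "tg": (127.27, 26.63),
    },
}

GLUCOSE_MEAN_SD = (93.6, 11.4)
LN_INSULIN_MEAN_SD = (1.95, 0.55)
RER_MEAN_SD = (0.85, 0.05)
RER_BOUNDS = (0.72, 0.98)


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level simulation parameters."""

    n: int = 71
    sex_ratio: float = 0.48  # probability of male
    seed: int = 0
    effect_rer_insulin: float = 0.33  # standardized slope RER -> ln-insulin
    effect_lean_bmr: float = 20.0  # kcal/day of BMR per kg lean mass
    bmr_intercept: float = 370.0  # kcal/day at zero lean mass
    bmr_noise_sd: float = 120.0  # kcal/day residual around the planted line
    table1_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_TABLE1_PARAMS
    )

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigError(f"n must be >= 4, got {self.n}")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ConfigError("sex_ratio must be in (0, 1)")
        for sex, params in self.table1_params.items():
            for name, (_, sd) in params.items():
                if sd <= 0:
                    raise ConfigError(f"sd for {sex}/{name} must be > 0")


@dataclass(frozen=True)
class TraceSimConfig:
    """Single-recording simulation parameters."""

    duration_s: float = 1800.0
    breath_interval_mean_s: float = 4.0
    breath_interval_sd_s: float = 0.8
    transient_amplitude: float = 0.25  # fractional elevation at t = 0
    # settling constant of the initial non-steady segment; subjects rest
    # 20 min before the register starts, so the residual transient is short
    transient_tau_s: float = 120.0
    noise_cv_pct: float = 4.0
    drift_pct: float = 0.0
    ve_per_vo2: float = 27.0  # L ventilation per L O2 uptake
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.duration_s,
            self.breath_interval_mean_s,
            self.breath_interval_sd_s,
            self.transient_tau_s,
        ) <= 0:
            raise ConfigError("durations and intervals must be positive")
        if self.noise_cv_pct < 0 or self.transient_amplitude < 0:
            raise ConfigError("noise and transient amplitude must be >= 0")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = 1e-6,
    high: float = np.inf,
) -> np.ndarray:
    """Rejection-sample a normal truncated to (low, high)."""
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def _invert_weir(bmr_kcal_d: np.ndarray, rer: np.ndarray) -> np.ndarray:
    """VO2 (L/min) whose daily Weir energy at the given RER equals bmr."""
    return bmr_kcal_d / (1440.0 * (3.941 + 1.106 * rer))


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (observable table, hidden truth table).

    The truth table carries the planted BMR, RER and basal gas rates so
    recovery through the calorimetry pipeline can be scored.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    sexes = np.where(rng.random(n) < cfg.sex_ratio, "male", "female")

    cols: dict[str, np.ndarray] = {}
    for name in next(iter(cfg.table1_params.values())):
        vals = np.empty(n)
        for sex in ("male", "female"):
            mask = sexes == sex
            mean, sd = cfg.table1_params[sex][name]
            vals[mask] = _truncated_normal(rng, mean, sd, int(mask.sum()))
        cols[name] = vals

    height = cols["height"]
    weight = cols["bmi"] * height**2
    lean_mass = cols["lean_mass_index"] * height**2
    fat_mass = cols["fat_mass_index"] * height**2
    sbp = cols["dbp"] + np.maximum(cols["pulse_pressure"], 5.0)

    # planted calorimetry truth
    bmr_true = (
        cfg.bmr_intercept
        + cfg.effect_lean_bmr * lean_mass
        + rng.normal(0.0, cfg.bmr_noise_sd, n)
    )
    bmr_true = np.maximum(bmr_true, 500.0)
    rer_true = _truncated_normal(
        rng, RER_MEAN_SD[0], RER_MEAN_SD[1], n, low=RER_BOUNDS[0], high=RER_BOUNDS[1]
    )
    vo2_true = _invert_weir(bmr_true, rer_true)
    vco2_true = rer_true * vo2_true

    # planted insulin link: ln-insulin responds to standardized planted RER
    beta = cfg.effect_rer_insulin
    if not -1.0 < beta < 1.0:
        raise ConfigError("effect_rer_insulin must lie in (-1, 1)")
    z_rer = (rer_true - RER_MEAN_SD[0]) / RER_MEAN_SD[1]
    mu, sigma = LN_INSULIN_MEAN_SD
    eps = rng.normal(0.0, 1.0, n)
    ln_insulin = mu + sigma * (beta * z_rer + np.sqrt(1.0 - beta**2) * eps)
    insulin = np.exp(ln_insulin)
    glucose = _truncated_normal(rng, *GLUCOSE_MEAN_SD, n, low=40.0)

    ids = np.array([f"P{i:04d}" for i in range(n)])
    observable = pd.DataFrame(
        {
            "id": ids,
            "sex": sexes,
            "age": cols["age"],
            "height": height,
            "weight": weight,
            "waist": cols["waist"],
            "lean_mass": lean_mass,
            "fat_mass": fat_mass,
            "vat_mass": cols["vat_mass"],
            "sbp": sbp,
            "dbp": cols["dbp"],
            "glucose": glucose,
            "insulin": insulin,
            "tc": cols["tc"],
            "hdl": cols["hdl"],
            "ldl": cols["ldl"],
            "tg": cols["tg"],
        }
    )
    truth = pd.DataFrame(
        {
            "id": ids,
            "bmr_true_kcal_d": bmr_true,
            "rer_true": rer_true,
            "vo2_true_l_min": vo2_true,
            "vco2_true_l_min": vco2_true,
        }
    )
    return observable, truth


def simulate_trace(
    vo2_l_min: float,
    vco2_l_min: float,
    cfg: TraceSimConfig,
    participant_id: str = "SIM",
) -> GasExchangeTrace:
    """One breath-by-breath recording around planted basal gas rates.

    Instantaneous uptake is the basal level times an initial transient
    ``1 + A*exp(-t/tau)``, an optional linear drift, and multiplicative
    noise of the configured CV; VO2 and VCO2 noise are independent so the
    planted RER holds in expectation.
    """
    if vo2_l_min <= 0 or vco2_l_min <= 0:
        raise ConfigError("planted gas rates must be positive")
    rng = np.random.default_rng(cfg.seed)

    n_max = int(cfg.duration_s / cfg.breath_interval_mean_s * 2) + 20
    intervals = _truncated_normal(
        rng, cfg.breath_interval_mean_s, cfg.breath_interval_sd_s, n_max, low=0.5
    )
    t = np.cumsum(intervals)
    t = t[t < cfg.duration_s]

    shape = 1.0 + cfg.transient_amplitude * np.exp(-t / cfg.transient_tau_s)
    if cfg.drift_pct:
        shape = shape * (1.0 + cfg.drift_pct / 100.0 * t / cfg.duration_s)
    noise_sd = cfg.noise_cv_pct / 100.0
    f_vo2 = np.maximum(1.0 + rng.normal(0.0, noise_sd, len(t)), 0.05)
    f_vco2 = np.maximum(1.0 + rng.normal(0.0, noise_sd, len(t)), 0.05)
    f_ve = np.maximum(1.0 + rng.normal(0.0, noise_sd, len(t)), 0.05)

    vo2 = 1000.0 * vo2_l_min * shape * f_vo2  # mL/min
    vco2 = 1000.0 * vco2_l_min * shape * f_vco2
    ve = cfg.ve_per_vo2 * vo2_l_min * shape * f_ve  # L/min

    samples = tuple(
        GasSample(t=float(ti), vo2=float(a), vco2=float(b), ve=float(c))
        for ti, a, b, c in zip(t, vo2, vco2, ve)
    )
    return GasExchangeTrace(
        participant_id=participant_id,
        samples=samples,
        duration_s=cfg.duration_s,
    )


def make_fixture_suite(
    out_dir: str | Path, n: int = 12, seed: int = 0
) -> dict[str, object]:
    """Write a small seeded cohort + traces + truth JSON for testing.

    Returns a manifest dict with the file paths written.
    """
    if n <= 0:
        raise ConfigError(f"n must be positive, got {n}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)

    cohort_cfg = CohortSimConfig(n=max(n, 4), seed=seed)
    observable, truth = simulate_cohort(cohort_cfg)
    observable, truth = observable.iloc[:n], truth.iloc[:n]

    participants_path = out / "participants.csv"
    observable.to_csv(participants_path, index=False)

    trace_paths = []
    for i, row in truth.reset_index(drop=True).iterrows():
        tcfg = TraceSimConfig(seed=seed * 100_003 + i)
        trace = simulate_trace(
            row["vo2_true_l_min"],
            row["vco2_true_l_min"],
            tcfg,
            participant_id=row["id"],
        )
        path = traces_dir / f"{row['id']}.csv"
        write_trace(trace, path)
        trace_paths.append(str(path))

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict("records"), indent=1))
    return {
        "participants": str(participants_path),
        "traces": trace_paths,
        "truth": str(truth_path),
        "seed": seed,
        "n": n,
    }
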