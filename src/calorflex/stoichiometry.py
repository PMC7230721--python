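"""Stoichiometric conversion of mean gas exchange to energy and substrate rates.

Energy expenditure uses the abbreviated Weir form
``kcal/min = 3.941*VO2 + 1.106*VCO2 - 2.17*N_min`` scaled by 1440 to
kcal/day; substrate rates use the Frayn forms
``fat g/min = 1.67*VO2 - 1.67*VCO2 - 1.92*n`` and
``cho g/min = 4.55*VCO2 - 3.21*VO2 - 2.87*n``, gases in L/min and n the
urinary-nitrogen excretion in g/min. Negative rates are flagged, never
clamped: the upstream RER validity rule is the single exclusion
gatekeeper.
"""

from __future__ import annotations

from dataclasses import dataclass

from calorflex.errors import DomainError
from calorflex.steady_state import SteadyStateWindow, rer_validity

#: RER at which the carbohydrate-oxidation linear form crosses zero.
CHO_ZERO_RER = 3.21 / 4.55

#: Energy equivalents consistent with the gas-exchange coefficients above,
#: so that fat%% + cho%% of energy expenditure ~= 100 over the basal RER
#: range when protein oxidation is zero.
KCAL_PER_G_FAT = 9.60
KCAL_PER_G_CHO = 3.77

MIN_PER_DAY = 1440.0


@dataclass(frozen=True)
class StoichiometryConfig:
    """Urinary nitrogen (g/day; default 0, never measured basally here)
    and the energy equivalents used for the %-of-BMR conversion."""

    n_urinary_g_day: float = 0.0
    kcal_per_g_fat: float = KCAL_PER_G_FAT
    kcal_per_g_cho: float = KCAL_PER_G_CHO

    def __post_init__(self) -> None:
        if self.n_urinary_g_day < 0:
            raise ValueError("n_urinary_g_day must be >= 0")
        if self.kcal_per_g_fat <= 0 or self.kcal_per_g_cho <= 0:
            raise ValueError("energy equivalents must be > 0")

    @property
    def n_urinary_g_min(self) -> float:
        return self.n_urinary_g_day / MIN_PER_DAY


DEFAULT_CONFIG = StoichiometryConfig()


@dataclass(frozen=True)
class MetabolicResult:
    """Per-participant calorimetry outputs with validity flag."""

    participant_id: str
    bmr_kcal_d: float
    bfox_g_min: float
    bchox_g_min: float
    bfox_pct_bmr: float
    bchox_pct_bmr: float
    mean_rer: float
    oxidation_valid: bool


def _check_gases(vo2_l_min: float, vco2_l_min: float) -> None:
    if vo2_l_min <= 0 or vco2_l_min <= 0:
        raise DomainError(
            f"gas values must be > 0 L/min, got vo2={vo2_l_min}, vco2={vco2_l_min}"
        )


def weir_bmr(
    vo2_l_min: float, vco2_l_min: float, cfg: StoichiometryConfig = DEFAULT_CONFIG
) -> float:
    """Basal metabolic rate in kcal/day from mean VO2/VCO2 in L/min."""
    _check_gases(vo2_l_min, vco2_l_min)
    kcal_min = 3.941 * vo2_l_min + 1.106 * vco2_l_min
    return MIN_PER_DAY * kcal_min - 2.17 * cfg.n_urinary_g_day


def frayn_fat_ox(
    vo2_l_min: float, vco2_l_min: float, cfg: StoichiometryConfig = DEFAULT_CONFIG
) -> float:
    """Fat oxidation in g/min; negative above RER 1 (flagged upstream)."""
    _check_gases(vo2_l_min, vco2_l_min)
    return 1.67 * vo2_l_min - 1.67 * vco2_l_min - 1.92 * cfg.n_urinary_g_min


def frayn_cho_ox(
    vo2_l_min: float, vco2_l_min: float, cfg: StoichiometryConfig = DEFAULT_CONFIG
) -> float:
    """Carbohydrate oxidation in g/min; zero at RER = 3.21/4.55 with n = 0."""
    _check_gases(vo2_l_min, vco2_l_min)
    return 4.55 * vco2_l_min - 3.21 * vo2_l_min - 2.87 * cfg.n_urinary_g_min


def pct_of_bmr(rate_g_min: float, kcal_per_g: float, bmr_kcal_d: float) -> float:
    """Express a substrate rate as percent of daily energy expenditure."""
    if bmr_kcal_d <= 0:
        raise DomainError(f"bmr must be > 0, got {bmr_kcal_d}")
    return 100.0 * (rate_g_min * kcal_per_g * MIN_PER_DAY) / bmr_kcal_d


def compute_metabolic_result(
    participant_id: str,
    window: SteadyStateWindow,
    cfg: StoichiometryConfig = DEFAULT_CONFIG,
) -> MetabolicResult:
    """Full calorimetry output from a selected steady-state window.

    The window carries gas means in mL/min; equations run in L/min.
    """
    vo2 = window.mean_vo2 / 1000.0
    vco2 = window.mean_vco2 / 1000.0
    bmr = weir_bmr(vo2, vco2, cfg)
    bfox = frayn_fat_ox(vo2, vco2, cfg)
    bchox = frayn_cho_ox(vo2, vco2, cfg)
    return MetabolicResult(
        participant_id=participant_id,
        bmr_kcal_d=bmr,
        bfox_g_min=bfox,
        bchox_g_min=bchox,
        bfox_pct_bmr=pct_of_bmr(bfox, cfg.kcal_per_g_fat, bmr),
        bchox_pct_bmr=pct_of_bmr(bchox, cfg.kcal_per_g_cho, bmr),
        mean_rer=window.mean_rer,
        oxidation_valid=rer_validity(window),
    )
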