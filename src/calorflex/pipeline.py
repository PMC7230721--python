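"""End-to-end orchestration: ingest -> steady state -> stoichiometry ->
clinical indices -> association -> report bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from calorflex import __version__
from calorflex.association import (
    association_grid,
    descriptives_by_sex,
    phenotype_comparison_table,
)
from calorflex.clinical_indices import derive_indices
from calorflex.errors import CalorflexError, EmptyEpochError, EmptyTraceError, TooShortError
from calorflex.gas_exchange_io import (
    DEFAULT_DIALECT,
    TraceDialect,
    epoch_trace,
    read_participants,
    read_trace,
)
from calorflex.steady_state import (
    SteadyStateCriteria,
    enumerate_windows,
    rer_validity,
    select_most_stable,
)
from calorflex.stoichiometry import StoichiometryConfig, compute_metabolic_result

logger = logging.getLogger(__name__)

#: Exposures reported by the calorimetry stage.
EXPOSURES = (
    "bmr_kcal_d",
    "bfox_g_min",
    "bfox_pct_bmr",
    "bchox_g_min",
    "bchox_pct_bmr",
)

#: Cardiometabolic outcomes screened against each exposure.
OUTCOMES = (
    "sbp",
    "dbp",
    "mean_bp",
    "glucose",
    "insulin",
    "quicki",
    "homa",
    "tc",
    "hdl",
    "ldl",
    "tg",
    "ldl_hdl_ratio",
    "tg_hdl_ratio",
)

DESCRIPTIVE_VARIABLES = (
    "age",
    "bmi",
    "waist",
    "lean_mass_index",
    "fat_mass_index",
    "vat_mass",
    "bmr_kcal_d",
    "bfox_g_min",
    "bfox_pct_bmr",
    "bchox_g_min",
    "bchox_pct_bmr",
    "sbp",
    "dbp",
    "mean_bp",
    "glucose",
    "insulin",
    "quicki",
    "homa",
    "tc",
    "hdl",
    "ldl",
    "tg",
    "ldl_hdl_ratio",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on."""

    traces_dir: str | None = None
    participants_file: str | None = None
    out_dir: str = "calorflex_out"
    epoch_s: float = 30.0
    criteria: SteadyStateCriteria = field(default_factory=SteadyStateCriteria)
    stoichiometry: StoichiometryConfig = field(default_factory=StoichiometryConfig)
    dialect: TraceDialect = field(default_factory=TraceDialect)
    transform_policy: str = "auto"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        criteria = SteadyStateCriteria(**raw.pop("criteria", {}))
        stoich = StoichiometryConfig(**raw.pop("stoichiometry", {}))
        dialect = TraceDialect(**raw.pop("dialect", {}))
        return cls(criteria=criteria, stoichiometry=stoich, dialect=dialect, **raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


def process_traces(cfg: RunConfig, participant_ids: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run calorimetry over every participant trace found on disk.

    Returns (metabolic results, exclusion log). A participant lands in
    exactly one of: results, exclusions (no_valid_window / unreadable),
    or neither (no trace file).
    """
    results: list[dict] = []
    exclusions: list[dict] = []
    traces_dir = Path(cfg.traces_dir) if cfg.traces_dir else None
    for pid in participant_ids:
        path = traces_dir / f"{pid}.csv" if traces_dir else None
        if path is None or not path.exists():
            logger.info("participant=%s stage=ingest outcome=no_trace", pid)
            continue
        try:
            trace = read_trace(path, cfg.dialect, participant_id=pid)
            series = epoch_trace(trace, cfg.epoch_s)
            windows = enumerate_windows(series, cfg.criteria)
            selected = select_most_stable(windows)
        except (CalorflexError, ValueError) as exc:
            logger.warning("participant=%s stage=steadystate outcome=error: %s", pid, exc)
            exclusions.append(
                {"participant_id": pid, "reason": "unreadable_or_too_short", "mean_rer": np.nan}
            )
            continue
        if selected is None:
            logger.info("participant=%s stage=steadystate outcome=no_valid_window", pid)
            exclusions.append(
                {"participant_id": pid, "reason": "no_valid_window", "mean_rer": np.nan}
            )
            continue
        result = compute_metabolic_result(pid, selected, cfg.stoichiometry)
        if not rer_validity(selected):
            logger.info(
                "participant=%s stage=rer_check outcome=rer_out_of_range rer=%.3f",
                pid,
                selected.mean_rer,
            )
            exclusions.append(
                {
                    "participant_id": pid,
                    "reason": "rer_out_of_range",
                    "mean_rer": selected.mean_rer,
                }
            )
        results.append(dataclasses.asdict(result))
        logger.info("participant=%s stage=stoichiometry outcome=ok", pid)

    res_df = pd.DataFrame(
        results,
        columns=[
            "participant_id",
            "bmr_kcal_d",
            "bfox_g_min",
            "bchox_g_min",
            "bfox_pct_bmr",
            "bchox_pct_bmr",
            "mean_rer",
            "oxidation_valid",
        ],
    )
    exc_df = pd.DataFrame(
        exclusions, columns=["participant_id", "reason", "mean_rer"]
    )
    return res_df, exc_df


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the whole chain and write the artifact bundle.

    Returns a mapping of artifact name -> written path. With an empty or
    absent traces directory the calorimetry stages are skipped (with a
    warning) and the association stage runs on the participant table
    alone.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.participants_file is None:
        raise CalorflexError("run_pipeline requires a participants file")
    participants = read_participants(cfg.participants_file)

    metabolic, exclusions = process_traces(cfg, participants["id"].tolist())
    if metabolic.empty:
        logger.warning("no traces processed; calorimetry outputs will be empty")

    indices = derive_indices(participants)
    merged = indices.merge(
        metabolic.rename(columns={"participant_id": "id"}), on="id", how="left"
    )
    # substrate-oxidation outputs only where the RER rule passed
    invalid = merged["oxidation_valid"] == False  # noqa: E712 (NaN-safe)
    for c in ("bfox_g_min", "bchox_g_min", "bfox_pct_bmr", "bchox_pct_bmr"):
        merged.loc[invalid, c] = np.nan

    artifacts: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = path

    write("metabolic_results", metabolic)
    write("exclusions", exclusions)
    write("participant_indices", indices)
    write("analysis_table", merged)
    write(
        "table1_descriptives",
        descriptives_by_sex(merged, DESCRIPTIVE_VARIABLES),
    )
    exposures = [e for e in EXPOSURES if merged[e].notna().sum() >= 8]
    outcomes = [o for o in OUTCOMES if o in merged.columns]
    if exposures:
        write(
            "association_grid",
            association_grid(merged, exposures, outcomes, cfg.transform_policy),
        )
        bundle_targets = [e for e in ("bmr_kcal_d", "bfox_g_min", "bfox_pct_bmr", "bchox_g_min", "bchox_pct_bmr") if e in exposures]
        if merged["phenotype"].notna().sum() >= 8 and merged["phenotype"].nunique() >= 2:
            write(
                "phenotype_comparison",
                phenotype_comparison_table(merged, bundle_targets),
            )
    else:
        logger.warning("calorimetry exposures unavailable; association grid skipped")

    n_total = len(participants)
    n_results = len(metabolic)
    n_excluded_hard = int((exclusions["reason"] != "rer_out_of_range").sum())
    n_missing_trace = n_total - n_results - n_excluded_hard
    manifest = {
        "config": cfg.to_manifest(),
        "counts": {
            "participants": n_total,
            "calorimetry_results": n_results,
            "excluded": n_excluded_hard,
            "missing_trace": n_missing_trace,
            "rer_out_of_range": int(
                (exclusions["reason"] == "rer_out_of_range").sum()
            ),
        },
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    artifacts["manifest"] = manifest_path
    return artifacts
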