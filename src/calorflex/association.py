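"""Association analysis: normality screen, log transform, sex comparisons,
covariate-adjusted regressions and phenotype (AN)COVA.

Regression models come in four flavours: Model 0 (simple regression) and
Models 1-3 adding sex, age, or lean mass as a single covariate. Outcome
and exposure are z-scored on the analyzed subsample, so the exposure
coefficient is the standardized beta; covariates enter untransformed.
The exposure's partial F is the square of its t statistic (df1 = 1,
df2 = n - k - 1), and the model fit is summarized by adjusted R^2.
Rows are pairwise-complete per model cell. Significance level 0.05 per
test; no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from calorflex.errors import DomainError, InsufficientDataError, SingularFitError

MODEL_COVARIATES: dict[int, str | None] = {0: None, 1: "sex", 2: "age", 3: "lean_mass"}

Covariate = Literal["none", "sex", "age", "lean_mass"]

DEFAULT_SEED = 20200423
ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    """One exposure x outcome x covariate regression cell."""

    outcome: str
    exposure: str
    covariate: Covariate = "none"
    transform_policy: Literal["auto", "none", "force"] = "auto"

    def __post_init__(self) -> None:
        if self.covariate not in ("none", "sex", "age", "lean_mass"):
            raise ValueError(f"unknown covariate {self.covariate!r}")


@dataclass(frozen=True)
class AssociationResult:
    """Partial-F summary of the exposure in one fitted model."""

    outcome: str
    exposure: str
    covariate: str
    f_stat: float
    df1: int
    df2: int
    p_value: float
    adj_r2: float
    beta_std: float
    n_used: int
    outcome_log_transformed: bool = False


def normality_screen(values: Sequence[float] | np.ndarray) -> bool:
    """True when a Shapiro-Wilk test does not reject normality at alpha 0.05.

    Degenerate (constant) input counts as non-normal. Requires >= 8
    complete values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 8:
        raise InsufficientDataError(
            f"normality screen needs >= 8 complete values, got {arr.size}"
        )
    if np.ptp(arr) == 0:
        return False
    _, p = stats.shapiro(arr)
    return bool(p >= ALPHA)


def napierian_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Natural logarithm, elementwise; rejects non-positive values."""
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if np.any(finite <= 0):
        raise DomainError("napierian transform requires strictly positive values")
    return np.log(arr)


def sex_ttest(
    values_by_sex: Mapping[str, Sequence[float]],
) -> tuple[float, int, float]:
    """Equal-variance two-sided Student t between two groups: (t, df, p)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_sex.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) != 2:
        raise ValueError("sex_ttest needs exactly two groups")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("each group needs >= 2 values")
    if all(np.ptp(g) == 0 for g in groups) and groups[0].mean() == groups[1].mean():
        # identical constants: define t = 0, p = 1 rather than 0/0
        return 0.0, len(groups[0]) + len(groups[1]) - 2, 1.0
    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    if np.isnan(t):
        raise DomainError("degenerate variance in both groups")
    df = len(groups[0]) + len(groups[1]) - 2
    return float(t), df, float(p)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise SingularFitError("zero variance in a standardized variable")
    return (x - x.mean()) / sd


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares via normal equations; returns (coef, cov_unscaled)."""
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < X.shape[1]:
        raise SingularFitError("exactly collinear design matrix")
    xtx_inv = np.linalg.inv(xtx)
    return xtx_inv @ X.T @ y, xtx_inv


def _prepare_cell(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], bool]:
    """Complete-case outcome/exposure/covariate arrays for one model cell."""
    cols = [spec.outcome, spec.exposure]
    if spec.covariate != "none":
        cols.append(spec.covariate)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not in data")
    sub = data[cols].copy()
    if spec.covariate == "sex":
        sub["sex"] = sub["sex"].map({"male": 1.0, "female": 0.0})
    sub = sub.apply(pd.to_numeric, errors="coerce").dropna()

    y = sub[spec.outcome].to_numpy(float)
    transformed = False
    if spec.transform_policy == "force" or (
        spec.transform_policy == "auto"
        and len(y) >= 8
        and np.all(y > 0)
        and not normality_screen(y)
    ):
        y = np.log(y)
        transformed = True
    x = sub[spec.exposure].to_numpy(float)
    covs = (
        [sub[spec.covariate].to_numpy(float)] if spec.covariate != "none" else []
    )
    return y, x, covs, transformed


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one regression cell and summarize the exposure's partial F.

    Under ``transform_policy='auto'`` the outcome is log-transformed when
    the normality screen rejects and all its values are positive.
    """
    y, x, covs, transformed = _prepare_cell(data, spec)
    n = len(y)
    k = 1 + len(covs)
    if n < k + 2:  # need at least 1 residual df
        raise InsufficientDataError(f"n={n} too small for {k} predictor(s)")

    yz, xz = _zscore(y), _zscore(x)
    X = np.column_stack([np.ones(n), xz, *covs])
    coef, cov_unscaled = _ols(X, yz)
    resid = yz - X @ coef
    rss = float(resid @ resid)
    tss = float(((yz - yz.mean()) ** 2).sum())
    df2 = n - k - 1
    sigma2 = rss / df2
    se_beta = np.sqrt(sigma2 * cov_unscaled[1, 1])
    if se_beta == 0:  # perfect fit
        t_stat = np.inf * np.sign(coef[1]) if coef[1] != 0 else 0.0
    else:
        t_stat = coef[1] / se_beta
    f_stat = float(t_stat**2)
    p = float(2.0 * stats.t.sf(abs(t_stat), df2))
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df2
    return AssociationResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        covariate=spec.covariate,
        f_stat=f_stat,
        df1=1,
        df2=df2,
        p_value=p,
        adj_r2=float(adj_r2),
        beta_std=float(coef[1]),
        n_used=n,
        outcome_log_transformed=transformed,
    )


def phenotype_anova(
    data: pd.DataFrame,
    outcome: str,
    covariate: Covariate = "none",
    group_col: str = "phenotype",
) -> tuple[float, int, int, float]:
    """Group-factor (partial) F comparing an outcome across phenotypes.

    With no covariate this is one-way ANOVA; with one it is the ANCOVA
    group F from the extra-sum-of-squares test. Returns (F, df1, df2, p).
    """
    cols = [outcome, group_col] + ([covariate] if covariate != "none" else [])
    sub = data[cols].dropna()
    if covariate == "sex":
        sub = sub.assign(sex=sub["sex"].map({"male": 1.0, "female": 0.0}))
    groups = sub[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise InsufficientDataError("phenotype comparison needs >= 2 groups")

    y = sub[outcome].to_numpy(float)
    n = len(y)
    dummies = np.column_stack(
        [(groups == lv).to_numpy(float) for lv in levels[1:]]
    )
    cov_cols = (
        [sub[covariate].to_numpy(float)] if covariate != "none" else []
    )
    X_full = np.column_stack([np.ones(n), dummies, *cov_cols])
    X_null = np.column_stack([np.ones(n), *cov_cols])

    def rss(X: np.ndarray) -> float:
        coef, _ = _ols(X, y)
        r = y - X @ coef
        return float(r @ r)

    rss_full, rss_null = rss(X_full), rss(X_null)
    df1 = len(levels) - 1
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise InsufficientDataError("not enough residual degrees of freedom")
    tol = 1e-12 * max(1.0, float(y @ y))  # absorb fp noise around exact fits
    if rss_full <= tol:
        if rss_null <= tol:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = ((rss_null - rss_full) / df1) / (rss_full / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


# ---------------------------------------------------------------------------
# report tables


def descriptives_by_sex(
    data: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Per-sex mean (SD) rows with sex-difference t-test stars."""
    rows = []
    for var in variables:
        if var not in data.columns:
            continue
        vals = pd.to_numeric(data[var], errors="coerce")
        row: dict[str, object] = {"variable": var, "n": int(vals.notna().sum())}
        by_sex = {}
        for sex in ("male", "female"):
            g = vals[data["sex"] == sex].dropna()
            by_sex[sex] = g.to_numpy()
            row[f"mean_{sex}"] = g.mean() if len(g) else np.nan
            row[f"sd_{sex}"] = g.std(ddof=1) if len(g) > 1 else np.nan
        row["mean_all"] = vals.mean()
        row["sd_all"] = vals.std(ddof=1)
        try:
            t, df, p = sex_ttest(by_sex)
            row["t"], row["p"] = t, p
            row["sig"] = "*" if p <= ALPHA else ""
        except (InsufficientDataError, DomainError, ValueError):
            row["t"], row["p"], row["sig"] = np.nan, np.nan, ""
        rows.append(row)
    return pd.DataFrame(rows)


def association_grid(
    data: pd.DataFrame,
    exposures: Sequence[str],
    outcomes: Sequence[str],
    transform_policy: Literal["auto", "none"] = "auto",
) -> pd.DataFrame:
    """Exposure x outcome x model grid of regression cells (long format)."""
    rows = []
    for exposure in exposures:
        for outcome in outcomes:
            for model_id, cov in MODEL_COVARIATES.items():
                spec = ModelSpec(
                    outcome=outcome,
                    exposure=exposure,
                    covariate=cov if cov is not None else "none",
                    transform_policy=transform_policy,
                )
                try:
                    res = fit_model(data, spec)
                    rows.append(
                        {
                            "exposure": exposure,
                            "outcome": outcome,
                            "model": model_id,
                            "F": res.f_stat,
                            "df1": res.df1,
                            "df2": res.df2,
                            "p": res.p_value,
                            "adj_r2": res.adj_r2,
                            "beta_std": res.beta_std,
                            "n": res.n_used,
                            "significant": res.p_value <= ALPHA,
                            "log_outcome": res.outcome_log_transformed,
                        }
                    )
                except (InsufficientDataError, SingularFitError, KeyError):
                    rows.append(
                        {
                            "exposure": exposure,
                            "outcome": outcome,
                            "model": model_id,
                            "F": np.nan,
                            "df1": 1,
                            "df2": 0,
                            "p": np.nan,
                            "adj_r2": np.nan,
                            "beta_std": np.nan,
                            "n": 0,
                            "significant": False,
                            "log_outcome": False,
                        }
                    )
    return pd.DataFrame(rows)


def phenotype_comparison_table(
    data: pd.DataFrame, outcomes: Sequence[str]
) -> pd.DataFrame:
    """Group-comparison table: each outcome under models 0-3."""
    rows = []
    for outcome in outcomes:
        for model_id, cov in MODEL_COVARIATES.items():
            cov_name = cov if cov is not None else "none"
            try:
                f, df1, df2, p = phenotype_anova(data, outcome, cov_name)
            except (InsufficientDataError, SingularFitError, KeyError):
                f, df1, df2, p = np.nan, 0, 0, np.nan
            rows.append(
                {
                    "outcome": outcome,
                    "model": model_id,
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
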