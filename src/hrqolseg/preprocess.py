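"""Inclusion rules and data preparation for raw participant tables.

Mirrors a registry-analysis workflow: keep participants with at least
one complete HRQoL self-assessment (both EQ-5D and VAS at the same
visit) and complete age and diagnosis-date information; per
participant, select the most recent complete measurement; turn missing
values of five categorical covariates into explicit "unknown" levels;
and impute missing BMI deterministically from a least-squares model on
age, sex, gait impairment (SRDSS class) and diabetes/cardiovascular
comorbidity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "apply_inclusion",
    "select_last_complete",
    "encode_missing_categories",
    "impute_bmi",
    "prepare_cohort",
]

UNKNOWN_LEVELS = {
    "phenotype": "unclear",
    "living_situation": "other",
    "marital_status": "unknown",
    "education": "other",
    "smoking": "unknown",
}


def _is_complete_hrqol(table: pd.DataFrame) -> pd.Series:
    has_eq = table["eq5d_index"].notna() if "eq5d_index" in table.columns else pd.Series(False, index=table.index)
    if "eq5d_profile" in table.columns:
        has_eq = has_eq | table["eq5d_profile"].notna()
    return has_eq & table["vas"].notna()


def apply_inclusion(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Retain rows with a complete HRQoL assessment and complete age and
    diagnosis information; return a flowchart-style exclusion accounting."""
    counts = {"assessed": int(len(table))}
    complete_hrqol = _is_complete_hrqol(table)
    has_agediag = table["age_years"].notna() & table["years_since_diagnosis"].notna()
    counts["excluded_incomplete_hrqol"] = int((~complete_hrqol).sum())
    counts["excluded_incomplete_age_or_diagnosis"] = int((complete_hrqol & ~has_agediag).sum())
    kept = table[complete_hrqol & has_agediag].copy()
    counts["included"] = int(len(kept))
    if len(kept) == 0:
        raise ValueError("inclusion criteria exclude every row")
    return kept, counts


def select_last_complete(table: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: the complete measurement with the latest
    measurement date (date ties broken by the last row in file order)."""
    complete = table[_is_complete_hrqol(table)]
    if complete["participant_id"].nunique() < table["participant_id"].nunique():
        raise ValueError("some participants have no complete HRQoL measurement")
    # ties on the date are broken by file order: the last row wins
    out = (
        complete.assign(_pos=np.arange(len(complete)))
        .sort_values(["participant_id", "measurement_date", "_pos"], kind="stable")
        .groupby("participant_id", sort=False)
        .tail(1)
        .drop(columns="_pos")
        .sort_values("participant_id", kind="stable")
        .reset_index(drop=True)
    )
    return out


def encode_missing_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values of the five categoricals with explicit
    unknown levels; no rows are dropped."""
    out = table.copy()
    for col, level in UNKNOWN_LEVELS.items():
        if col in out.columns:
            out[col] = out[col].astype(object)
            out.loc[out[col].isna(), col] = level
    return out


@dataclass
class BmiImputation:
    coef: pd.Series
    n_complete: int
    n_imputed: int


def impute_bmi(table: pd.DataFrame) -> tuple[pd.DataFrame, BmiImputation]:
    """Deterministic least-squares imputation of missing BMI.

    BMI is regressed on age, sex, SRDSS class and diabetes (either type)
    or cardiovascular comorbidity on complete cases; missing BMI values
    are replaced by fitted values and flagged in ``bmi_imputed``.
    Observed BMI is untouched; re-running is a no-op.
    """
    out = table.copy()
    if "bmi_imputed" not in out.columns:
        out["bmi_imputed"] = 0
    missing = out["bmi"].isna()
    if missing.sum() == 0:
        return out, BmiImputation(coef=pd.Series(dtype=float), n_complete=int((~missing).sum()), n_imputed=0)

    def design(df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intercept": 1.0,
                "age_years": df["age_years"].astype(float),
                "male": (df["sex"] == "male").astype(float),
                "srdss_mid": (df["srdss_class"] == "4-6.5").astype(float),
                "srdss_high": (df["srdss_class"] == ">=7").astype(float),
                "diabetes": ((df["comorbidity_diabetes1"] == 1) | (df["comorbidity_diabetes2"] == 1)).astype(float),
                "cardiovascular": (df["comorbidity_cardiovascular"] == 1).astype(float),
            },
            index=df.index,
        )

    complete = out[~missing]
    X = design(complete)
    if len(complete) < X.shape[1]:
        raise ValueError(
            f"only {len(complete)} complete BMI cases for {X.shape[1]} parameters"
        )
    beta, *_ = np.linalg.lstsq(X.to_numpy(), complete["bmi"].to_numpy(dtype=float), rcond=None)
    fitted = design(out[missing]).to_numpy() @ beta
    out.loc[missing, "bmi"] = fitted
    out.loc[missing, "bmi_imputed"] = 1
    return out, BmiImputation(coef=pd.Series(beta, index=X.columns), n_complete=len(complete), n_imputed=int(missing.sum()))


def prepare_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Inclusion, last-complete selection, unknown-category encoding and
    BMI imputation in the order the analysis applies them."""
    included, counts = apply_inclusion(table)
    last = select_last_complete(included)
    counts["unique_participants"] = int(len(last))
    encoded = encode_missing_categories(last)
    if encoded["bmi"].isna().any():
        prepared, imp = impute_bmi(encoded)
        counts["bmi_imputed"] = imp.n_imputed
    else:
        prepared = encoded
        counts["bmi_imputed"] = 0
    return prepared, counts
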