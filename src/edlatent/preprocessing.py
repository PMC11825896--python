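"""Cohort definition, outcome construction, imputation and standardisation.

Implements the study's inclusion/exclusion rules for gray-area ED visits:
triage acuity (ESI) restricted to levels 2-3; visits ending in elopement,
leaving against medical advice or transfer excluded (admission and discharge
to residence / skilled nursing / inpatient rehab retained, the latter two
counted as discharges); visits in the last 45 days of the sample period
dropped for outcome follow-up; and exclusions for objective markers of a
clear admission indication — troponin > 0.10 ng/mL, systolic blood pressure
< 80 mmHg, respiration rate > 30 breaths/min, pulse oximetry < 88%, heart
rate > 120 beats/min, a stroke / myocardial infarction / femur-fracture
diagnosis, or cellulitis with temperature > 100.3 °F.  All cutoffs are
strict as written, so boundary values are retained; missing screening
fields never trigger an exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import OUTCOME_FAMILIES, WINDOWS, INSURANCE_LEVELS

__all__ = [
    "FilterThresholds", "CohortFilterReport", "apply_cohort_filters",
    "derive_outcome_matrix", "impute_missing", "standardize_continuous",
    "encode_design", "CONTINUOUS_COLUMNS", "CATEGORICAL_COLUMNS",
    "OUTCOME_COLUMNS",
]

CONTINUOUS_COLUMNS = ["age", "hcc", "temperature", "blood_pressure",
                      "respiration_rate", "heart_rate"]
CATEGORICAL_COLUMNS = ["female", "insurance", "diabetes", "chf",
                       "hypertension", "acuity"]
OUTCOME_COLUMNS = [f"{fam}_{w}d" for fam in OUTCOME_FAMILIES for w in WINDOWS]

_EVENT_FIELDS = {"revisit": "revisit_days", "readmission": "readmission_days",
                 "mortality": "death_days"}

# attribution order: each excluded visit is counted under its first failing
# rule in this fixed order
RULE_ORDER = ["disposition", "acuity", "tail_45d", "troponin", "vitals",
              "diagnosis_flags", "cellulitis_fever"]


@dataclass
class FilterThresholds:
    """Exclusion cutoffs; defaults are the study values, strict as printed."""
    troponin_max: float = 0.10        # exclude if > (ng/mL)
    systolic_bp_min: float = 80.0     # exclude if < (mmHg)
    respiration_rate_max: float = 30.0  # exclude if > (breaths/min)
    pulse_oximetry_min: float = 88.0  # exclude if < (%)
    heart_rate_max: float = 120.0     # exclude if > (beats/min)
    cellulitis_temp_max: float = 100.3  # exclude if > (deg F) with cellulitis
    acuity_levels: tuple = (2, 3)
    tail_days: int = 45


@dataclass
class CohortFilterReport:
    n_input: int
    n_retained: int
    exclusions: dict = field(default_factory=dict)   # rule -> count
    retained_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "exclusions": dict(self.exclusions),
                "retained_ids": list(self.retained_ids)}


def apply_cohort_filters(table: pd.DataFrame, sample_end_date,
                         thresholds: FilterThresholds | None = None
                         ) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply the inclusion/exclusion rules; returns (filtered table, report).

    Each excluded visit is counted once, under its first failing rule in
    :data:`RULE_ORDER`.  SNF/IRF destinations are mapped to
    ``decision = "discharge"`` in the returned table.
    """
    th = thresholds or FilterThresholds()
    if "visit_date" not in table.columns or table["visit_date"].isna().any():
        raise ValueError("every visit needs a visit_date")
    if isinstance(sample_end_date, str):
        sample_end_date = date.fromisoformat(sample_end_date)
    cutoff = sample_end_date - timedelta(days=th.tail_days)

    t = table
    dates = pd.to_datetime(t["visit_date"]).dt.date

    def _lt(col, bound):   # strict, missing never triggers
        v = t[col]
        return v.notna() & (v < bound)

    def _gt(col, bound):
        v = t[col]
        return v.notna() & (v > bound)

    fails = {}
    fails["disposition"] = (t["decision"].isna()
                            | ~t["decision"].isin(["admit", "discharge"])
                            | ~t["disposition_destination"].isin(
                                ["hospital", "home", "snf", "irf"]))
    fails["acuity"] = ~t["acuity"].isin(th.acuity_levels)
    fails["tail_45d"] = pd.Series([d > cutoff for d in dates], index=t.index)
    fails["troponin"] = _gt("troponin", th.troponin_max)
    fails["vitals"] = (_lt("systolic_bp", th.systolic_bp_min)
                       | _gt("respiration_rate", th.respiration_rate_max)
                       | _lt("pulse_oximetry", th.pulse_oximetry_min)
                       | _gt("heart_rate", th.heart_rate_max))
    fails["diagnosis_flags"] = ((t.get("stroke_flag", 0) == 1)
                                | (t.get("mi_flag", 0) == 1)
                                | (t.get("femur_fracture_flag", 0) == 1))
    fails["cellulitis_fever"] = ((t["presentation"] == "cellulitis")
                                 & _gt("temperature", th.cellulitis_temp_max))

    excluded = pd.Series(False, index=t.index)
    counts = {}
    for rule in RULE_ORDER:
        first_fail = fails[rule].fillna(False) & ~excluded
        counts[rule] = int(first_fail.sum())
        excluded = excluded | first_fail

    kept = t.loc[~excluded].copy()
    # SNF/IRF are discharges for all modelling purposes
    kept.loc[kept["disposition_destination"].isin(["snf", "irf"]),
             "decision"] = "discharge"
    report = CohortFilterReport(
        n_input=len(t), n_retained=len(kept), exclusions=counts,
        retained_ids=list(kept["visit_id"]))
    assert report.n_retained + sum(counts.values()) == report.n_input
    return kept, report


def derive_outcome_matrix(table: pd.DataFrame,
                          windows=tuple(WINDOWS)) -> pd.DataFrame:
    """Nine binary indicators: {revisit, readmission, mortality} x windows.

    An indicator is 1 iff the event offset (days from final discharge) is
    present and <= the window (inclusive); an absent event is 0 everywhere.
    """
    out = pd.DataFrame(index=table.index)
    for fam, col in _EVENT_FIELDS.items():
        offs = table[col]
        if (offs.dropna() < 0).any():
            raise ValueError(f"negative event offset in '{col}'")
        for w in windows:
            out[f"{fam}_{w}d"] = (offs.notna() & (offs <= w)).astype(int)
    return out


def impute_missing(table: pd.DataFrame,
                   continuous=tuple(CONTINUOUS_COLUMNS),
                   categorical=tuple(CATEGORICAL_COLUMNS)
                   ) -> tuple[pd.DataFrame, dict]:
    """Median/mode imputation; returns (table, log of fills per column).

    Continuous columns take the median of observed values; categorical and
    binary columns the most frequent observed category, ties broken by the
    lexicographically smallest category.  Observed values are never changed.
    """
    out = table.copy()
    log = {}
    for col in continuous:
        if col not in out.columns:
            continue
        obs = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if len(obs) == 0:
            raise ValueError(f"column '{col}' is fully missing")
        fill = float(obs.median())
        if n_missing:
            out[col] = out[col].fillna(fill)
        log[col] = {"fill": fill, "n_filled": n_missing}
    for col in categorical:
        if col not in out.columns:
            continue
        obs = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if len(obs) == 0:
            raise ValueError(f"column '{col}' is fully missing")
        counts = obs.value_counts()
        tied = list(counts[counts == counts.max()].index)
        # ties: smallest category (numeric order for numeric columns,
        # lexicographic otherwise)
        fill = min(tied) if obs.dtype.kind in "ifu" else sorted(map(str, tied))[0]
        if n_missing:
            out[col] = out[col].fillna(fill)
        log[col] = {"fill": fill, "n_filled": n_missing}
    return out, log


@dataclass
class ScalingParameters:
    """Per-column (mean, sd) used for standardisation; invertible."""
    stats: dict   # column -> (mean, sd)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, (m, s) in self.stats.items():
            out[col] = (out[col] - m) / s
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, (m, s) in self.stats.items():
            out[col] = out[col] * s + m
        return out


def standardize_continuous(table: pd.DataFrame,
                           columns=tuple(CONTINUOUS_COLUMNS)
                           ) -> tuple[pd.DataFrame, ScalingParameters]:
    """Z-score the named columns using sample mean and SD (ddof=1)."""
    stats = {}
    for col in columns:
        m = float(table[col].mean())
        s = float(table[col].std(ddof=1))
        if not np.isfinite(s) or s == 0.0:
            raise ValueError(f"column '{col}' has zero variance")
        stats[col] = (m, s)
    scaler = ScalingParameters(stats)
    return scaler.transform(table), scaler


def encode_design(table: pd.DataFrame) -> pd.DataFrame:
    """Model-ready numeric design.

    Insurance is dummy-coded with medicare as the reference; acuity becomes
    an ESI=2 indicator; sex is the female indicator.  Continuous columns are
    expected to be already standardised and are suffixed ``_z``.  The output
    column order is fixed: baseline design then proxy design.
    """
    unknown = set(table["insurance"].dropna().unique()) - set(INSURANCE_LEVELS)
    if unknown:
        raise ValueError(f"unknown insurance categories: {sorted(unknown)}")
    bad_acuity = set(table["acuity"].dropna().unique()) - {1, 2, 3, 4, 5}
    if bad_acuity:
        raise ValueError(f"unknown acuity levels: {sorted(bad_acuity)}")
    out = pd.DataFrame(index=table.index)
    out["age_z"] = table["age"].astype(float)
    out["female"] = table["female"].astype(float)
    for lvl in ("medicaid", "commercial", "self_pay"):
        out[f"ins_{lvl}"] = (table["insurance"] == lvl).astype(float)
    for c in ("diabetes", "chf", "hypertension"):
        out[c] = table[c].astype(float)
    out["hcc_z"] = table["hcc"].astype(float)
    out["acuity2"] = (table["acuity"] == 2).astype(float)
    for c in ("temperature", "blood_pressure", "respiration_rate",
              "heart_rate"):
        out[f"{c}_z"] = table[c].astype(float)
    return out
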