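"""New-user, active-comparator cohort construction from claims tables.

The design: patients initiating the treatment or comparator drug class inside
a calendar enrollment window, with no study-drug dispensing in a preceding
washout period, are candidates; candidates with a qualifying cardiovascular
diagnosis in a recent lookback, a controlled-drug dispensing in a longer
lookback, an index age at or above the cap, or no enrollment coverage at
index are excluded.  Follow-up runs from the index date to the first
qualifying admission-primary diagnosis, censored at disenrollment, the 75th
birthday, or the administrative study end, whichever comes first.

All lookback windows are half-open ``(index - k months, index)``: the index
date itself is excluded from lookbacks, and a qualifying diagnosis on the
index date counts as an event at half a day rather than excluding the
subject.  Months are 30.4375 days throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import (
    COMPARATOR_CLASS,
    DAYS_PER_MONTH,
    TREATMENT_CLASS,
    ClaimsDataset,
)

GROUP_TREATMENT = "treatment"
GROUP_COMPARATOR = "comparator"


@dataclass(frozen=True)
class OutcomeDefinition:
    """An outcome as a set of ICD-10 code prefixes plus the primary-diagnosis
    requirement ('I21' matches 'I219' etc.)."""

    name: str
    icd10_prefixes: tuple
    require_primary: bool = True


def default_outcomes() -> dict:
    """Editable default code lists for the cardiovascular endpoints."""
    mi = ("I21", "I22")
    stroke = ("I60", "I61", "I62", "I63")
    hf = ("I50",)
    return {
        "myocardial_infarction": OutcomeDefinition("myocardial_infarction", mi),
        "stroke": OutcomeDefinition("stroke", stroke),
        "heart_failure": OutcomeDefinition("heart_failure", hf),
        "mace": OutcomeDefinition("mace", mi + stroke),
        "all_cardiovascular": OutcomeDefinition("all_cardiovascular", mi + stroke + hf),
    }


@dataclass(frozen=True)
class CohortSpec:
    treatment_class: str = TREATMENT_CLASS
    comparator_class: str = COMPARATOR_CLASS
    enrollment_window: tuple = ("2017-04-01", "2017-06-30")
    washout_months: int = 3
    prior_event_exclusion_months: int = 3
    prior_drug_exclusion_months: int = 12
    max_age_years: int = 75
    study_end: str = "2020-06-30"
    outcome_definitions: dict = field(default_factory=default_outcomes)
    prior_event_outcomes: tuple = ("mace",)
    controlled_drug_classes: tuple = ("controlled_drug",)
    strict_all_drug_washout: bool = False

    def __post_init__(self) -> None:
        start, end = map(pd.Timestamp, self.enrollment_window)
        if not (start <= end <= pd.Timestamp(self.study_end)):
            raise ValueError("need window start <= window end <= study_end")
        for f in ("washout_months", "prior_event_exclusion_months",
                  "prior_drug_exclusion_months", "max_age_years"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH


def identify_new_users(dataset: ClaimsDataset, spec: CohortSpec) -> pd.DataFrame:
    """Candidates with index dates and group labels.

    The index date is a patient's first study-class dispensing inside the
    enrollment window that has no study-class dispensing (any dispensing at
    all under ``strict_all_drug_washout``) in the preceding washout; patients
    dispensing both classes on the index date are dropped.
    """
    start, end = map(pd.Timestamp, spec.enrollment_window)
    study = {spec.treatment_class, spec.comparator_class}
    disp = dataset.dispensings.drop_duplicates()
    washout = disp if spec.strict_all_drug_washout else disp[
        disp["drug_class"].isin(study)
    ]
    study_disp = disp[disp["drug_class"].isin(study)]
    in_window = study_disp[(study_disp["date"] >= start) & (study_disp["date"] <= end)]
    if in_window.empty:
        return pd.DataFrame(columns=["patient_id", "group", "index_date"])

    wdays = _months_to_days(spec.washout_months)
    fills = in_window[["patient_id", "date"]].drop_duplicates()
    merged = fills.merge(
        washout[["patient_id", "date"]].rename(columns={"date": "wdate"}),
        on="patient_id",
    )
    violated = merged[
        (merged["wdate"] > merged["date"] - pd.Timedelta(days=wdays))
        & (merged["wdate"] < merged["date"])
    ][["patient_id", "date"]].drop_duplicates()
    clean = fills.merge(violated, how="left", indicator=True)
    clean = clean[clean["_merge"] == "left_only"]
    index = clean.groupby("patient_id")["date"].min().rename("index_date")

    at_index = in_window.merge(index.reset_index(), on="patient_id")
    at_index = at_index[at_index["date"] == at_index["index_date"]]
    classes = at_index.groupby("patient_id")["drug_class"].agg(set)
    single = classes[classes.map(len) == 1].map(lambda s: next(iter(s)))
    out = pd.DataFrame({
        "patient_id": single.index,
        "group": np.where(
            single.to_numpy() == spec.treatment_class,
            GROUP_TREATMENT,
            GROUP_COMPARATOR,
        ),
        "index_date": index.loc[single.index].to_numpy(),
    }).sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    return out


def _qualifying_diag(dataset: ClaimsDataset, outcome: OutcomeDefinition) -> pd.DataFrame:
    dx = dataset.diagnoses
    mask = dx["icd10"].astype(str).str.startswith(outcome.icd10_prefixes)
    if outcome.require_primary:
        mask &= dx["primary_at_admission"].astype(bool)
    return dx[mask]


def apply_exclusions(candidates: pd.DataFrame, dataset: ClaimsDataset,
                     spec: CohortSpec):
    """Sequential exclusion rules; returns (cohort, attrition counts).

    The cohort frame carries the patients' covariates for downstream
    propensity modelling.  Attrition is attributed stage by stage in the
    order prior event, controlled drug, age, enrollment coverage.
    """
    attrition = {"candidates": len(candidates)}
    cur = candidates.copy()

    prefixes = tuple(
        p
        for name in spec.prior_event_outcomes
        for p in spec.outcome_definitions[name].icd10_prefixes
    )
    dx = dataset.diagnoses
    qual = dx[
        dx["icd10"].astype(str).str.startswith(prefixes)
        & dx["primary_at_admission"].astype(bool)
    ]
    edays = _months_to_days(spec.prior_event_exclusion_months)
    merged = cur.merge(qual, on="patient_id")
    bad = merged[
        (merged["date"] > merged["index_date"] - pd.Timedelta(days=edays))
        & (merged["date"] < merged["index_date"])
    ]["patient_id"].unique()
    cur = cur[~cur["patient_id"].isin(bad)]
    attrition["prior_event"] = int(len(bad))

    ddays = _months_to_days(spec.prior_drug_exclusion_months)
    ctrl = dataset.dispensings[
        dataset.dispensings["drug_class"].isin(spec.controlled_drug_classes)
    ]
    merged = cur.merge(ctrl, on="patient_id")
    bad = merged[
        (merged["date"] > merged["index_date"] - pd.Timedelta(days=ddays))
        & (merged["date"] < merged["index_date"])
    ]["patient_id"].unique()
    cur = cur[~cur["patient_id"].isin(bad)]
    attrition["controlled_drug"] = int(len(bad))

    cur = cur.merge(dataset.patients, on="patient_id")
    age_at_index = (
        (cur["index_date"] - cur["birth_date"]).dt.days / 365.25
    )
    keep = age_at_index < spec.max_age_years
    attrition["age"] = int((~keep).sum())
    cur = cur[keep]

    enr = dataset.enrollment
    merged = cur[["patient_id", "index_date"]].merge(enr, on="patient_id")
    covered = merged[
        (merged["start"] <= merged["index_date"])
        & (merged["index_date"] < merged["end"])
    ]["patient_id"].unique()
    keep = cur["patient_id"].isin(covered)
    attrition["enrollment"] = int((~keep).sum())
    cur = cur[keep].reset_index(drop=True)

    attrition["cohort"] = len(cur)
    return cur, attrition


def build_followup(cohort: pd.DataFrame, dataset: ClaimsDataset,
                   outcome_name: str, spec: CohortSpec) -> pd.DataFrame:
    """One follow-up record per cohort subject for the named outcome.

    Event time is the first qualifying diagnosis on or after the index date;
    censoring at the earliest of enrollment end, 75th birthday, and study
    end.  Same-day (index-date) events count at half a day.
    """
    if outcome_name not in spec.outcome_definitions:
        raise ValueError(f"unknown outcome {outcome_name!r}")
    outcome = spec.outcome_definitions[outcome_name]
    qual = _qualifying_diag(dataset, outcome)
    first_dx = (
        cohort[["patient_id", "index_date"]]
        .merge(qual, on="patient_id")
        .query("date >= index_date")
        .groupby("patient_id")["date"]
        .min()
    )

    sub = cohort.merge(
        dataset.enrollment.groupby("patient_id")["end"].max().rename("enroll_end"),
        on="patient_id",
    )
    birthday75 = sub["birth_date"] + pd.DateOffset(years=spec.max_age_years)
    study_end = pd.Timestamp(spec.study_end)
    censor_date = pd.concat(
        [sub["enroll_end"], birthday75, pd.Series(study_end, index=sub.index)], axis=1
    ).min(axis=1)
    reason = np.select(
        [
            censor_date == sub["enroll_end"],
            censor_date == birthday75,
        ],
        ["disenrollment", "age75"],
        default="study_end",
    )
    # study_end wins naming ties in its favour only when it is the minimum
    reason = np.where(censor_date == study_end, "study_end", reason)

    event_date = pd.to_datetime(sub["patient_id"].map(first_dx))
    has_event = event_date.notna() & (event_date <= censor_date)
    end_date = pd.Series(np.where(has_event, event_date, censor_date), index=sub.index)
    days = (pd.to_datetime(end_date) - sub["index_date"]).dt.days.astype(float)
    days = np.where(has_event & (days == 0.0), 0.5, days)
    return pd.DataFrame({
        "patient_id": sub["patient_id"],
        "group": sub["group"],
        "index_date": sub["index_date"],
        "time_months": days / DAYS_PER_MONTH,
        "event": has_event.to_numpy(),
        "censor_reason": np.where(has_event, "outcome", reason),
    })
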