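"""Naive reference implementations used only to validate the fast paths.

Everything here is written as directly as possible — explicit Python loops,
no shared code with the modules under test — so that agreement between an
oracle and the corresponding implementation is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spontaneous import ContingencyTable


def brute_contingency(reports, drug, event, suspect_only=True) -> ContingencyTable:
    """Double-loop case counting for the 2x2 table."""
    terms = set(event.all_terms())
    n11 = n1 = n2 = 0
    for r in reports:
        has_drug = False
        for name, role in r.drugs:
            if suspect_only and role != "suspect":
                continue
            if drug.matches(name):
                has_drug = True
        has_event = False
        for t in r.events:
            if t in terms:
                has_event = True
        if has_drug:
            n1 += 1
        if has_event:
            n2 += 1
        if has_drug and has_event:
            n11 += 1
    return ContingencyTable(n11, n1, n2, len(reports))


def brute_new_users(dataset, spec) -> list:
    """Per-patient linear scan for the new-user definition.

    Returns (patient_id, group, index_date) tuples, sorted by patient id.
    """
    from .cohort import GROUP_COMPARATOR, GROUP_TREATMENT

    study = {spec.treatment_class, spec.comparator_class}
    start, end = map(pd.Timestamp, spec.enrollment_window)
    wdays = spec.washout_months * 30.4375
    out = []
    for pid, grp in dataset.dispensings.groupby("patient_id"):
        rows = sorted(set(zip(grp["date"], grp["drug_class"])))
        washout_dates = [
            d
            for d, c in rows
            if spec.strict_all_drug_washout or c in study
        ]
        index_date = None
        for d, c in rows:
            if c not in study or not (start <= d <= end):
                continue
            dirty = False
            for wd in washout_dates:
                if d - pd.Timedelta(days=wdays) < wd < d:
                    dirty = True
            if not dirty:
                index_date = d
                break
        if index_date is None:
            continue
        classes = {c for d, c in rows if d == index_date and c in study}
        if len(classes) != 1:
            continue
        group = GROUP_TREATMENT if spec.treatment_class in classes else GROUP_COMPARATOR
        out.append((pid, group, index_date))
    return sorted(out)


def brute_followup(cohort, dataset, outcome, spec) -> dict:
    """Per-subject timeline scan; returns patient_id -> (time_months, event)."""
    study_end = pd.Timestamp(spec.study_end)
    enroll_end = dataset.enrollment.groupby("patient_id")["end"].max()
    out = {}
    for _, row in cohort.iterrows():
        pid, index = row["patient_id"], row["index_date"]
        bday75 = row["birth_date"] + pd.DateOffset(years=spec.max_age_years)
        censor = min(enroll_end[pid], bday75, study_end)
        event_date = None
        dx = dataset.diagnoses[dataset.diagnoses["patient_id"] == pid]
        for _, d in dx.iterrows():
            code = str(d["icd10"])
            if not any(code.startswith(p) for p in outcome.icd10_prefixes):
                continue
            if outcome.require_primary and not d["primary_at_admission"]:
                continue
            if d["date"] >= index and (event_date is None or d["date"] < event_date):
                event_date = d["date"]
        if event_date is not None and event_date <= censor:
            days = (event_date - index).days or 0.5
            out[pid] = (days / 30.4375, True)
        else:
            out[pid] = ((censor - index).days / 30.4375, False)
    return out


def brute_kaplan_meier(times, events):
    """Product-limit survival computed subject-by-subject.

    Returns (event_times, survival_values) at the distinct event times.
    """
    times = list(times)
    events = list(events)
    et = sorted({t for t, e in zip(times, events) if e})
    surv = []
    s = 1.0
    for t in et:
        at_risk = sum(1 for tt in times if tt >= t)
        d = sum(1 for tt, e in zip(times, events) if e and tt == t)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return et, surv


def naive_cox_loglik(times, events, x, b, ties="efron"):
    """Efron/Breslow log partial likelihood by direct summation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in sorted(set(times[events])):
        tied = np.flatnonzero(events & (times == t))
        risk = np.flatnonzero(times >= t)
        d = len(tied)
        sum_risk = float(np.exp(b * x[risk]).sum())
        sum_tied = float(np.exp(b * x[tied]).sum())
        ll += b * float(x[tied].sum())
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            ll -= np.log(sum_risk - f * sum_tied)
    return ll
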