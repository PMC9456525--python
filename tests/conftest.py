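import pandas as pd
import pytest

from dpp4_safety import simulate
from dpp4_safety.spontaneous import Report


def make_report(case_id, drugs, events):
    """drugs: iterable of (name, role) or bare names (treated as suspect)."""
    norm = frozenset(
        d if isinstance(d, tuple) else (d, "suspect") for d in drugs
    )
    return Report(case_id=case_id, drugs=norm, events=frozenset(events))


@pytest.fixture
def ten_cases():
    """10 cases: 3 mention drug A (suspect), 4 mention event E, 2 both."""
    reports = [
        make_report("c1", ["A"], ["E"]),
        make_report("c2", ["A"], ["E"]),
        make_report("c3", ["A"], ["X1"]),
        make_report("c4", ["B"], ["E"]),
        make_report("c5", ["B"], ["E"]),
        make_report("c6", ["B"], ["X2"]),
        make_report("c7", ["C"], ["X3"]),
        make_report("c8", ["C"], ["X4"]),
        make_report("c9", ["C"], ["X5"]),
        make_report("c10", ["C"], ["X6"]),
    ]
    return reports


@pytest.fixture(scope="session")
def planted_claims():
    """Small claims population with planted protocol violations."""
    config = simulate.ClaimsSimConfig(
        n_patients=1000,
        frac_washout_violation=0.08,
        frac_prior_event=0.05,
        frac_controlled_drug=0.05,
        seed=42,
    )
    return config, simulate.generate_claims_population(config)


def tiny_claims(rows_disp, rows_diag=None, rows_enroll=None, patients=None):
    """Assemble a hand-written ClaimsDataset from row tuples."""
    disp = pd.DataFrame(rows_disp, columns=["patient_id", "date", "drug_class"])
    disp["date"] = pd.to_datetime(disp["date"])
    diag = pd.DataFrame(
        rows_diag or [],
        columns=["patient_id", "date", "icd10", "primary_at_admission"],
    )
    if len(diag):
        diag["date"] = pd.to_datetime(diag["date"])
    pids = sorted(disp["patient_id"].unique())
    if rows_enroll is None:
        rows_enroll = [(p, "2015-01-01", "2022-01-01", "active") for p in pids]
    enroll = pd.DataFrame(
        rows_enroll, columns=["patient_id", "start", "end", "end_reason"]
    )
    enroll["start"] = pd.to_datetime(enroll["start"])
    enroll["end"] = pd.to_datetime(enroll["end"])
    if patients is None:
        patients = pd.DataFrame({
            "patient_id": pids,
            "birth_date": pd.Timestamp("1970-01-01"),
            "sex": "M",
            "x1": 0.0,
        })
    return simulate.ClaimsDataset(
        patients=patients,
        dispensings=disp,
        diagnoses=diag,
        enrollment=enroll,
        covariate_names=["x1"],
    )
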