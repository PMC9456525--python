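"""Synthetic spontaneous reports and claims populations with known ground truth.

The two proprietary data sources this pipeline is designed for — a national
spontaneous-report database and an employer-based claims database — cannot be
redistributed, so every downstream stage is exercised on synthetic data whose
generating truth (reporting ratios, hazard ratios, confounding structure) is
known and recoverable.

Report streams
    Each case falls into one cell of the 2x2 cross of {mentions the target
    drug class as suspect} x {mentions the target event group}, with joint
    probability ``reporting_ratio * target_drug_share * target_event_share``;
    a ratio of 1 is independence.  Nuisance drugs and events attach
    independently with small probabilities so the target 2x2 table is the
    only signal carrier.

Claims populations
    Each patient gets demographics and standardized covariates, a treatment
    assignment from a logistic model on those covariates (the confounding
    channel), one initiation dispensing inside a calendar enrollment window,
    latent exponential (optionally Weibull) event times per outcome with
    hazard ``baseline * exp(x . beta_outcome) * true_hr^treated``, and a
    single censoring process standing in for death plus disenrollment.
    Defaults are calibrated to a matched type-2-diabetes new-user cohort:
    age 52.2 +/- 9.74 (truncated below 75), ~70% male, initiation April-June
    2017, administrative study end 2020-06-30 (mean follow-up ~33 months),
    and per-outcome baseline hazards giving cumulative risks of roughly 4%
    (myocardial infarction), 6.5% (stroke) and 11% (heart failure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spontaneous import ROLE_CONCOMITANT, ROLE_SUSPECT, Report

DAYS_PER_MONTH = 30.4375

TREATMENT_CLASS = "dpp4_inhibitor"
COMPARATOR_CLASS = "metformin"

OUTCOME_ICD_PREFIX = {
    "myocardial_infarction": "I21",
    "stroke": "I63",
    "heart_failure": "I50",
}

DEFAULT_BASELINE_HAZARD = {
    "myocardial_infarction": 0.00125,
    "stroke": 0.0020,
    "heart_failure": 0.0036,
}


# ---------------------------------------------------------------------------
# Spontaneous reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportSimConfig:
    """Configuration of the spontaneous-report stream generator."""

    n_cases: int = 100_000
    target_drug_share: float = 0.01
    target_event_share: float = 0.01
    reporting_ratio: float = 1.0
    n_background_drugs: int = 25
    n_background_events: int = 25
    background_attach_prob: float = 0.03
    target_drug_members: tuple = ("target_drug",)
    target_event_terms: tuple = ("target_event",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("target_drug_share", "target_event_share"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.reporting_ratio <= 0:
            raise ValueError("reporting_ratio must be positive")
        p11 = self.reporting_ratio * self.target_drug_share * self.target_event_share
        if p11 > min(self.target_drug_share, self.target_event_share):
            raise ValueError(
                "reporting_ratio: implied joint probability "
                f"{p11:.4g} exceeds a marginal share"
            )
        if self.target_drug_share + self.target_event_share - p11 > 1.0:
            raise ValueError("cell probabilities exceed 1; reduce the shares")
        if not 0.0 <= self.background_attach_prob < 1.0:
            raise ValueError("background_attach_prob must lie in [0, 1)")

    @property
    def cell_probabilities(self) -> np.ndarray:
        """(p11, p10, p01, p00) of the target drug x event cross."""
        p11 = self.reporting_ratio * self.target_drug_share * self.target_event_share
        p10 = self.target_drug_share - p11
        p01 = self.target_event_share - p11
        return np.array([p11, p10, p01, 1.0 - p11 - p10 - p01])


def generate_spontaneous_reports(config: ReportSimConfig) -> list:
    """Draw a case series; returns one :class:`Report` per case.

    Target-class mentions are always suspect-role; background drugs split
    50/50 between suspect and concomitant roles.  Cases that would otherwise
    carry no drug (or no event) receive one forced background label so every
    case is well-formed, without touching the target margins.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    cells = rng.choice(4, size=n, p=config.cell_probabilities)
    has_drug = (cells == 0) | (cells == 1)
    has_event = (cells == 0) | (cells == 2)

    members = list(config.target_drug_members)
    terms = list(config.target_event_terms)
    member_pick = rng.integers(0, len(members), size=n)
    term_pick = rng.integers(0, len(terms), size=n)

    bg_drugs = [f"background_drug_{i:02d}" for i in range(config.n_background_drugs)]
    bg_events = [f"background_event_{i:02d}" for i in range(config.n_background_events)]
    attach_d = rng.random((n, len(bg_drugs))) < config.background_attach_prob
    attach_e = rng.random((n, len(bg_events))) < config.background_attach_prob
    bg_role = rng.random((n, len(bg_drugs))) < 0.5
    forced_d = rng.integers(0, max(len(bg_drugs), 1), size=n)
    forced_e = rng.integers(0, max(len(bg_events), 1), size=n)

    # pre-resolve sparse background attachments once (cheaper than a
    # flatnonzero per case)
    bg_drug_labels = [
        (name, ROLE_SUSPECT) for name in bg_drugs
    ] + [(name, ROLE_CONCOMITANT) for name in bg_drugs]
    drug_lists = [[] for _ in range(n)]
    rows, cols = np.nonzero(attach_d)
    suspect = bg_role[rows, cols]
    for r, c, s in zip(rows.tolist(), cols.tolist(), suspect.tolist()):
        drug_lists[r].append(bg_drug_labels[c if s else c + len(bg_drugs)])
    event_lists = [[] for _ in range(n)]
    rows, cols = np.nonzero(attach_e)
    for r, c in zip(rows.tolist(), cols.tolist()):
        event_lists[r].append(bg_events[c])

    width = len(str(n))
    reports = []
    for i in range(n):
        drugs = drug_lists[i]
        if has_drug[i]:
            drugs.append((members[member_pick[i]], ROLE_SUSPECT))
        if not drugs:
            name = bg_drugs[forced_d[i]] if bg_drugs else "background_drug_00"
            drugs.append((name, ROLE_CONCOMITANT))
        events = event_lists[i]
        if has_event[i]:
            events.append(terms[term_pick[i]])
        if not events:
            events.append(bg_events[forced_e[i]] if bg_events else "background_event_00")
        reports.append(
            Report(
                case_id=f"C{i:0{width}d}",
                drugs=frozenset(drugs),
                events=frozenset(events),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Claims populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClaimsSimConfig:
    """Configuration of the claims-population generator.

    ``covariate_treatment_coefs`` and ``covariate_outcome_coefs`` act on the
    covariate vector (standardized age, male indicator, then ``n_covariates``
    standard-normal covariates) in the treatment logit and in the log hazard
    respectively; any covariate with nonzero coefficients in *both* is a
    confounder.  Hazards are per person-month.  ``weibull_shape`` = 1 gives
    constant hazards; other values stress the proportional-hazards assumption.
    The ``frac_*`` fields plant protocol violations (recorded in the truth
    table) so cohort-exclusion bookkeeping can be tested against known counts.
    """

    n_patients: int = 10_000
    age_mean: float = 52.2
    age_sd: float = 9.74
    age_min: float = 20.0
    age_max: float = 74.9
    male_share: float = 0.70
    n_covariates: int = 4
    treatment_intercept: float = 0.66  # logit of ~66% treated, the observed mix
    covariate_treatment_coefs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    covariate_outcome_coefs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    baseline_hazard: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HAZARD)
    )
    true_hr: dict = field(default_factory=dict)  # outcome -> HR, default 1.0
    censoring_hazard: float = 0.004
    weibull_shape: float = 1.0
    max_followup_months: float = 60.0
    enrollment_start: str = "2017-04-01"
    enrollment_end: str = "2017-06-30"
    study_end: str = "2020-06-30"
    frac_washout_violation: float = 0.0
    frac_prior_event: float = 0.0
    frac_controlled_drug: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name, h in self.baseline_hazard.items():
            if h <= 0:
                raise ValueError(f"baseline_hazard[{name!r}] must be positive")
        for name, hr in self.true_hr.items():
            if hr <= 0:
                raise ValueError(f"true_hr[{name!r}] must be positive")
        if self.censoring_hazard < 0:
            raise ValueError("censoring_hazard must be non-negative")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        k = 2 + self.n_covariates
        for name in ("covariate_treatment_coefs", "covariate_outcome_coefs"):
            if len(getattr(self, name)) != k:
                raise ValueError(
                    f"{name} must have length {k} "
                    "(age_std, male, then the generic covariates)"
                )

    @property
    def covariate_names(self) -> list:
        return ["age_std", "male"] + [f"x{i + 1}" for i in range(self.n_covariates)]

    @staticmethod
    def confounded(seed: int = 0, n_patients: int = 10_000, **kw) -> "ClaimsSimConfig":
        """Default confounded scenario: older, sicker patients preferentially
        receive the treatment drug and carry higher event hazards."""
        return ClaimsSimConfig(
            n_patients=n_patients,
            covariate_treatment_coefs=(0.5, 0.4, 0.6, 0.5, 0.4, 0.3),
            covariate_outcome_coefs=(0.5, 0.3, 0.5, 0.4, 0.3, 0.2),
            seed=seed,
            **kw,
        )


@dataclass
class ClaimsDataset:
    """Claims tables: patients, dispensings, diagnoses, enrollment intervals.

    ``truth`` carries the generator's ground truth (treatment assignment,
    latent times, planted violations); it is None for data read from files.
    """

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    diagnoses: pd.DataFrame
    enrollment: pd.DataFrame
    covariate_names: list
    truth: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "dispensings", "diagnoses", "enrollment"):
            df = getattr(self, name).copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir) -> "ClaimsDataset":
        indir = Path(indir)
        frames = {}
        date_cols = {
            "patients": ["birth_date"],
            "dispensings": ["date"],
            "diagnoses": ["date"],
            "enrollment": ["start", "end"],
        }
        for name, cols in date_cols.items():
            df = pd.read_csv(indir / f"{name}.tsv", sep="\t")
            for c in cols:
                df[c] = pd.to_datetime(df[c])
            frames[name] = df
        cov = [
            c
            for c in frames["patients"].columns
            if c not in ("patient_id", "birth_date", "sex")
        ]
        return cls(covariate_names=cov, truth=None, **frames)


def generate_claims_population(config: ClaimsSimConfig) -> ClaimsDataset:
    """Simulate a new-user claims population; deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = np.array([f"P{i:06d}" for i in range(n)])

    a, b = (
        (config.age_min - config.age_mean) / config.age_sd,
        (config.age_max - config.age_mean) / config.age_sd,
    )
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    male = (rng.random(n) < config.male_share).astype(int)
    x = rng.standard_normal((n, config.n_covariates))
    covs = np.column_stack([(age - config.age_mean) / config.age_sd, male, x])

    # treatment assignment: the confounding channel
    beta_t = np.asarray(config.covariate_treatment_coefs)
    p_treat = 1.0 / (1.0 + np.exp(-(config.treatment_intercept + covs @ beta_t)))
    treated = rng.random(n) < p_treat

    window_start = pd.Timestamp(config.enrollment_start)
    window_end = pd.Timestamp(config.enrollment_end)
    index_offset = rng.integers(0, (window_end - window_start).days + 1, size=n)
    index_date = window_start + pd.to_timedelta(index_offset, unit="D")
    birth_date = window_start - pd.to_timedelta(
        np.round(age * 365.25).astype(int), unit="D"
    )

    # latent event months per outcome under proportional hazards
    beta_o = np.asarray(config.covariate_outcome_coefs)
    lin_out = covs @ beta_o
    event_months = {}
    for outcome, h0 in config.baseline_hazard.items():
        hr = config.true_hr.get(outcome, 1.0)
        rate = h0 * np.exp(lin_out) * np.where(treated, hr, 1.0)
        u = rng.exponential(1.0, size=n)
        event_months[outcome] = (u / rate) ** (1.0 / config.weibull_shape)

    censor_months = (
        rng.exponential(1.0 / config.censoring_hazard, size=n)
        if config.censoring_hazard > 0
        else np.full(n, np.inf)
    )
    censor_months = np.minimum(censor_months, config.max_followup_months)

    patients = pd.DataFrame({"patient_id": ids, "birth_date": birth_date,
                             "sex": np.where(male == 1, "M", "F")})
    for j, name in enumerate(config.covariate_names):
        patients[name] = covs[:, j]

    drug_class = np.where(treated, TREATMENT_CLASS, COMPARATOR_CLASS)
    disp_rows = [pd.DataFrame(
        {"patient_id": ids, "date": index_date, "drug_class": drug_class}
    )]

    # planted protocol violations, recorded in the truth table
    washout_flag = rng.random(n) < config.frac_washout_violation
    prior_event_flag = rng.random(n) < config.frac_prior_event
    controlled_flag = rng.random(n) < config.frac_controlled_drug
    if washout_flag.any():
        m = washout_flag
        disp_rows.append(pd.DataFrame({
            "patient_id": ids[m],
            "date": index_date[m] - pd.Timedelta(days=45),
            "drug_class": np.where(treated[m], COMPARATOR_CLASS, TREATMENT_CLASS),
        }))
    if controlled_flag.any():
        m = controlled_flag
        disp_rows.append(pd.DataFrame({
            "patient_id": ids[m],
            "date": index_date[m] - pd.Timedelta(days=180),
            "drug_class": "controlled_drug",
        }))
    dispensings = pd.concat(disp_rows, ignore_index=True)

    # enrollment: starts well before the window; ends at disenrollment
    enroll_start = window_start - pd.to_timedelta(
        730 + rng.integers(0, 365, size=n), unit="D"
    )
    hard_end = pd.Timestamp(config.study_end) + pd.Timedelta(days=550)
    disenroll = index_date + pd.to_timedelta(
        np.round(censor_months * DAYS_PER_MONTH).astype(int), unit="D"
    )
    active = np.asarray(disenroll >= hard_end)
    enroll_end = pd.Series(disenroll).where(~active, hard_end)
    enrollment = pd.DataFrame({
        "patient_id": ids,
        "start": enroll_start,
        "end": enroll_end,
        "end_reason": np.where(active, "active", "disenrollment"),
    })

    diag_rows = []
    code_digit = rng.integers(0, 10, size=(n, len(config.baseline_hazard)))
    for k, (outcome, months) in enumerate(event_months.items()):
        prefix = OUTCOME_ICD_PREFIX.get(outcome, "R99")
        # times far beyond the data horizon never yield a record; cap them
        # before date arithmetic to stay within timestamp bounds
        date = index_date + pd.to_timedelta(
            np.round(np.minimum(months, 1200.0) * DAYS_PER_MONTH).astype(int),
            unit="D",
        )
        keep = date < enroll_end.to_numpy()
        codes = np.char.add(prefix, code_digit[:, k].astype(str))
        diag_rows.append(pd.DataFrame({
            "patient_id": ids[keep],
            "date": date[keep],
            "icd10": codes[keep],
            "primary_at_admission": True,
        }))
    if prior_event_flag.any():
        m = prior_event_flag
        diag_rows.append(pd.DataFrame({
            "patient_id": ids[m],
            "date": index_date[m] - pd.Timedelta(days=30),
            "icd10": "I219",
            "primary_at_admission": True,
        }))
    # ambient non-primary diagnoses: the admission-primary filter must drop these
    diag_rows.append(pd.DataFrame({
        "patient_id": ids,
        "date": index_date,
        "icd10": "E119",
        "primary_at_admission": False,
    }))
    noise = rng.random(n) < 0.05
    if noise.any():
        diag_rows.append(pd.DataFrame({
            "patient_id": ids[noise],
            "date": index_date[noise] + pd.Timedelta(days=90),
            "icd10": "I219",
            "primary_at_admission": False,
        }))
    diagnoses = (
        pd.concat(diag_rows, ignore_index=True)
        .sort_values(["patient_id", "date", "icd10"], kind="mergesort")
        .reset_index(drop=True)
    )
    dispensings = (
        dispensings.sort_values(["patient_id", "date", "drug_class"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth = pd.DataFrame({
        "patient_id": ids,
        "treated": treated,
        "index_date": index_date,
        "censor_months": censor_months,
        "planted_washout_violation": washout_flag,
        "planted_prior_event": prior_event_flag,
        "planted_controlled_drug": controlled_flag,
    })
    for outcome, months in event_months.items():
        truth[f"months_to_{outcome}"] = months

    return ClaimsDataset(
        patients=patients,
        dispensings=dispensings,
        diagnoses=diagnoses,
        enrollment=enrollment,
        covariate_names=config.covariate_names,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Direct follow-up arms (trial-scale operating characteristics)
# ---------------------------------------------------------------------------

def simulate_followup_arms(
    n_per_arm: int,
    true_hr: float = 1.0,
    event_hazard: float = 0.0035,
    censoring_hazard: float = 0.004,
    max_months: float = 37.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two exchangeable arms of exponential event/censoring times.

    A lightweight stand-in for the full claims pipeline when only the
    time-to-event layer matters (coverage and non-inferiority operating
    characteristics).  Defaults give a cumulative event risk of ~10% per arm
    over a ~3-year administrative horizon, the scale of the matched cohort.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    treated = np.repeat([1, 0], n_per_arm)
    rate = event_hazard * np.where(treated == 1, true_hr, 1.0)
    t_event = rng.exponential(1.0, size=n) / rate
    t_cens = (
        rng.exponential(1.0 / censoring_hazard, size=n)
        if censoring_hazard > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_cens, max_months)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame({
        "patient_id": [f"S{i:06d}" for i in range(n)],
        "group": np.where(treated == 1, "treatment", "comparator"),
        "time_months": time,
        "event": event,
        "censor_reason": np.where(event, "outcome", "disenrollment"),
    })
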