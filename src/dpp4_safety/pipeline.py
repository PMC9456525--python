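"""End-to-end orchestration of the two analysis tracks.

``run_disproportionality`` takes a spontaneous-report stream (file or
simulation config) and a set of drug classes and event groups, and renders a
signal table: one row per drug x event pair with the 2x2 counts, the
information component with its credible interval, and the SDR flag.

``run_rwe`` takes claims tables (files or simulation config), builds the
new-user cohort, matches on the propensity score, and renders per outcome the
event counts and percentages per group, the hazard ratio with its confidence
interval, and the non-inferiority decision, alongside the attrition report,
balance diagnostics and cumulative-incidence step data.

The composite "all cardiovascular" outcome is the first occurrence of any
configured cardiovascular diagnosis (the union of the component code lists at
the subject-first-event level).  Rendered tables round percentages to one
decimal and effect estimates to two; the machine-readable outputs keep full
precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bcpnn, cohort as cohort_mod, psm, simulate, spontaneous, survival

log = logging.getLogger(__name__)

DEFAULT_OUTCOME_ORDER = [
    "mace",
    "myocardial_infarction",
    "heart_failure",
    "stroke",
    "all_cardiovascular",
]


@dataclass
class RunConfig:
    """Inputs for one pipeline run; exactly one source per track.

    Either ``reports_path`` or ``report_sim`` feeds the disproportionality
    track, and either ``claims_dir`` or ``claims_sim`` feeds the claims track.
    """

    reports_path: str | None = None
    report_sim: simulate.ReportSimConfig | None = None
    claims_dir: str | None = None
    claims_sim: simulate.ClaimsSimConfig | None = None
    drug_classes: list = field(default_factory=list)
    event_definitions: list = field(default_factory=list)
    prior: bcpnn.BcpnnPrior = field(default_factory=bcpnn.BcpnnPrior)
    cohort_spec: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    caliper_multiplier: float = 0.2
    noninferiority_margin: float = 1.3
    outcomes: list = field(default_factory=lambda: list(DEFAULT_OUTCOME_ORDER))
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.reports_path is None) == (self.report_sim is None) and (
            self.reports_path is not None or self.report_sim is not None
        ):
            raise ValueError("give exactly one of reports_path / report_sim")
        if (self.claims_dir is None) == (self.claims_sim is None) and (
            self.claims_dir is not None or self.claims_sim is not None
        ):
            raise ValueError("give exactly one of claims_dir / claims_sim")


def _outdir(config: RunConfig) -> Path | None:
    if config.outdir is None:
        return None
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def run_disproportionality(config: RunConfig) -> pd.DataFrame:
    """Signal table for every configured drug class x event group pair."""
    if config.reports_path is not None:
        log.info("reading reports from %s", config.reports_path)
        reports = spontaneous.read_reports(config.reports_path)
    elif config.report_sim is not None:
        log.info("simulating %d cases", config.report_sim.n_cases)
        reports = simulate.generate_spontaneous_reports(config.report_sim)
    else:
        raise ValueError("no spontaneous-track input configured")
    log.info("report stream: %d cases", len(reports))

    rows = []
    for drug, event, table in spontaneous.enumerate_pairs(
        reports, config.drug_classes, config.event_definitions
    ):
        sig = bcpnn.detect_signal(table, config.prior)
        rows.append({
            "drug_class": drug.name,
            "event": event.name,
            "n11": table.n11,
            "n1dot": table.n1dot,
            "ndot1": table.ndot1,
            "ndotdot": table.ndotdot,
            "ic": sig.expected_ic,
            "ic_lower": sig.ic_lower,
            "ic_upper": sig.ic_upper,
            "is_sdr": sig.is_sdr,
        })
    out = pd.DataFrame(rows)
    outdir = _outdir(config)
    if outdir is not None:
        out.to_csv(outdir / "signal_table.tsv", sep="\t", index=False)
        rendered = out.copy()
        for c in ("ic", "ic_lower", "ic_upper"):
            rendered[c] = rendered[c].round(2)
        rendered.to_csv(outdir / "signal_table_rendered.tsv", sep="\t", index=False)
    return out


def run_rwe(config: RunConfig) -> dict:
    """Cohort, matching, and per-outcome hazard/incidence artifacts."""
    if config.claims_dir is not None:
        log.info("reading claims tables from %s", config.claims_dir)
        dataset = simulate.ClaimsDataset.read(config.claims_dir)
    elif config.claims_sim is not None:
        log.info("simulating %d patients", config.claims_sim.n_patients)
        dataset = simulate.generate_claims_population(config.claims_sim)
    else:
        raise ValueError("no claims-track input configured")

    spec = config.cohort_spec
    candidates = identify = cohort_mod.identify_new_users(dataset, spec)
    log.info("new-user candidates: %d", len(candidates))
    cohort, attrition = cohort_mod.apply_exclusions(candidates, dataset, spec)
    log.info("cohort after exclusions: %d (attrition %s)", len(cohort), attrition)

    model = psm.estimate_propensity(cohort, dataset.covariate_names)
    matched = psm.match_nearest_neighbor(
        model, caliper_multiplier=config.caliper_multiplier, seed=config.seed
    )
    if matched.pairs.empty:
        raise ValueError("empty matched cohort: no pairs within the caliper")
    attrition["matched_pairs"] = len(matched.pairs)
    balance = psm.balance_diagnostics(matched, cohort, dataset.covariate_names)
    matched_cohort = cohort[cohort["patient_id"].isin(matched.matched_ids)]
    n_per_group = matched_cohort.groupby("group")["patient_id"].size().to_dict()
    log.info("matched pairs: %d", len(matched.pairs))

    hazard_rows, incidence_rows, curves, decisions = [], [], {}, {}
    for outcome in config.outcomes:
        fu = cohort_mod.build_followup(matched_cohort, dataset, outcome, spec)
        est = survival.fit_cox(fu, outcome_name=outcome)
        ni = survival.assess_noninferiority(est, config.noninferiority_margin)
        decisions[outcome] = ni
        curves[outcome] = survival.cumulative_incidence(fu)
        hazard_rows.append({
            "outcome": outcome,
            "hr": est.hr,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "log_hr_se": est.log_hr_se,
            "non_inferior": ni.non_inferior,
            "margin": ni.margin,
        })
        for group in (cohort_mod.GROUP_TREATMENT, cohort_mod.GROUP_COMPARATOR):
            n = est.n_subjects[group]
            ev = est.n_events[group]
            incidence_rows.append({
                "outcome": outcome,
                "group": group,
                "n": n,
                "events": ev,
                "pct": round(100.0 * ev / n, 1),
            })

    hazard = pd.DataFrame(hazard_rows)
    incidence = pd.DataFrame(incidence_rows)
    result = {
        "attrition": attrition,
        "balance": balance,
        "matched": matched,
        "hazard_table": hazard,
        "incidence_table": incidence,
        "curves": curves,
        "decisions": decisions,
        "n_candidates": len(identify),
    }
    outdir = _outdir(config)
    if outdir is not None:
        hazard.to_csv(outdir / "hazard_table.tsv", sep="\t", index=False)
        rendered = hazard.copy()
        for c in ("hr", "ci_lower", "ci_upper"):
            rendered[c] = rendered[c].round(2)
        rendered.to_csv(outdir / "hazard_table_rendered.tsv", sep="\t", index=False)
        incidence.to_csv(outdir / "incidence_table.tsv", sep="\t", index=False)
        balance.to_csv(outdir / "balance.tsv", sep="\t", index=False)
        curve_rows = [
            {"outcome": oc, "group": g, "time_months": float(t), "incidence": float(v)}
            for oc, by_group in curves.items()
            for g, curve in by_group.items()
            for t, v in zip(curve.times, curve.incidence)
        ]
        pd.DataFrame(curve_rows).to_csv(
            outdir / "cumulative_incidence.tsv", sep="\t", index=False
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(
                {
                    "attrition": attrition,
                    "n_matched_per_group": {k: int(v) for k, v in n_per_group.items()},
                    "non_inferior": {
                        k: bool(v.non_inferior) for k, v in decisions.items()
                    },
                },
                fh,
                indent=2,
            )
    return result
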