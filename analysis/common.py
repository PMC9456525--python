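"""Shared study configuration for the analysis scripts.

The synthetic study mirrors the two-source design: a spontaneous-report
stream in which the DPP-4 inhibitor class over-reports the myocardial
infarction event group (reporting ratio 4) against an independent background,
and a confounded claims population in which treatment assignment and event
hazards share covariates while every true hazard ratio is 1.
"""

from pathlib import Path

from dpp4_safety import simulate
from dpp4_safety.spontaneous import DrugClass, EventDefinition

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

STUDY_SEED = 20170401  # start of the enrollment window

GLIPTINS = (
    "alogliptin", "anagliptin", "linagliptin", "omarigliptin", "saxagliptin",
    "sitagliptin", "teneligliptin", "trelagliptin", "vildagliptin",
)

REPORT_SIM = simulate.ReportSimConfig(
    n_cases=200_000,
    target_drug_share=0.01,
    target_event_share=0.01,
    reporting_ratio=4.0,
    target_drug_members=GLIPTINS,
    target_event_terms=("myocardial infarction", "acute myocardial infarction"),
    seed=STUDY_SEED,
)

CLAIMS_SIM = simulate.ClaimsSimConfig.confounded(
    seed=STUDY_SEED,
    n_patients=12_000,
    frac_washout_violation=0.04,
    frac_prior_event=0.02,
    frac_controlled_drug=0.03,
)

DRUG_CLASSES = [
    DrugClass("dpp4_inhibitors", frozenset(GLIPTINS)),
    DrugClass("background_00", frozenset(["background_drug_00"])),
    DrugClass("background_01", frozenset(["background_drug_01"])),
]

EVENT_DEFINITIONS = [
    EventDefinition(
        "myocardial_infarction",
        frozenset(["myocardial infarction", "acute myocardial infarction"]),
    ),
    EventDefinition("background_00", frozenset(["background_event_00"])),
    EventDefinition("background_01", frozenset(["background_event_01"])),
    EventDefinition("background_02", frozenset(["background_event_02"])),
]
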