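#!/usr/bin/env python
"""Generate the two synthetic data sources for the study.

Writes the spontaneous-report stream and the claims tables (with their
ground-truth bookkeeping) under scratch/data/; prints the realized margins
so the later stages can be read against the generating truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common

from dpp4_safety import simulate
from dpp4_safety.spontaneous import write_reports


def main():
    common.SCRATCH.mkdir(parents=True, exist_ok=True)

    print(f"simulating {common.REPORT_SIM.n_cases:,} spontaneous reports "
          f"(target reporting ratio {common.REPORT_SIM.reporting_ratio}) ...")
    reports = simulate.generate_spontaneous_reports(common.REPORT_SIM)
    write_reports(reports, common.SCRATCH / "reports.tsv")
    n_drug = sum(
        1 for r in reports if r.drug_names(True) & set(common.GLIPTINS)
    )
    n_event = sum(
        1
        for r in reports
        if r.events & set(common.REPORT_SIM.target_event_terms)
    )
    print(f"  cases mentioning the drug class (suspect): {n_drug:,} "
          f"({100 * n_drug / len(reports):.2f}%; configured 1%)")
    print(f"  cases mentioning the event group:          {n_event:,} "
          f"({100 * n_event / len(reports):.2f}%; configured 1%)")

    print(f"simulating {common.CLAIMS_SIM.n_patients:,} claims patients "
          "(confounded treatment assignment, all true HRs = 1) ...")
    ds = simulate.generate_claims_population(common.CLAIMS_SIM)
    ds.write(common.SCRATCH / "claims")
    ds.truth.to_csv(common.SCRATCH / "claims" / "truth.tsv", sep="\t", index=False)
    share = ds.truth["treated"].mean()
    print(f"  treated share: {100 * share:.1f}%")
    for col in ("planted_washout_violation", "planted_prior_event",
                "planted_controlled_drug"):
        print(f"  {col}: {ds.truth[col].sum()}")
    print(f"wrote {common.SCRATCH}")


if __name__ == "__main__":
    main()
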