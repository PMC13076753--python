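"""Apply eligibility rules and build the one-row-per-patient analysis table.

Rules: treatment started no earlier than 4 weeks before baseline; outcome
recorded at baseline and Visit 3 (Visit 4 fallback); dose unchanged through
the endpoint visit.  Features with >= 50% missing values are dropped;
retained feature gaps are median/mode imputed with missing indicators.
"""

import argparse
from pathlib import Path

import pandas as pd

from psadose.cohort import VariableRoles, filter_variables, impute_baseline, select_patients
from psadose.io import load_visits, write_json


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--visits", type=Path, default=Path("results/cohort/visits.csv"))
    ap.add_argument("--truth", type=Path, default=Path("results/cohort/truth.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    visits = load_visits(args.visits)
    if args.truth.exists():
        truth = pd.read_csv(args.truth)
        visits = visits.merge(truth, on=["patient_id", "visit_index"], how="left")

    analysis, log = select_patients(visits)
    roles = VariableRoles()
    analysis, dropped = filter_variables(analysis, roles)
    feature_cols = [c for c in roles.features if c in analysis.columns]
    analysis = impute_baseline(analysis, feature_cols)

    args.out.mkdir(parents=True, exist_ok=True)
    analysis.to_csv(args.out / "analysis.csv", index=False)
    write_json(log, args.out / "exclusion_log.json")

    print(f"eligible: {log['included']} / {log['total']} patients")
    for rule in ("started_too_early", "no_baseline_outcome", "no_followup_outcome",
                 "dose_changed_or_missing"):
        print(f"  excluded ({rule}): {log[rule]}")
    print(f"dropped high-missingness features: {dropped or 'none'}")
    print(f"wrote {args.out}/analysis.csv")


if __name__ == "__main__":
    main()
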