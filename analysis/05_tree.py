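"""Build the heterogeneity tree over per-patient effect estimates.

Partitions patients by baseline covariates so that subgroup mean CATEs differ
maximally; the condition-true branch prints first (left).
"""

import argparse
from pathlib import Path

import pandas as pd

from psadose.cohort import VariableRoles
from psadose.io import write_json
from psadose.tree import build_tree, flatten_tree, render_tree


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/analysis.csv"))
    ap.add_argument("--theta", type=Path, default=Path("results/dml/theta_hat.csv"))
    ap.add_argument("--min-leaf", type=int, default=50)
    ap.add_argument("--max-depth", type=int, default=3)
    ap.add_argument("--out", type=Path, default=Path("results/tree"))
    args = ap.parse_args()

    analysis = pd.read_csv(args.cohort)
    theta = pd.read_csv(args.theta)["theta_hat"].to_numpy()
    roles = VariableRoles()
    covs = analysis[
        [c for c in roles.features
         if c in analysis.columns and pd.api.types.is_numeric_dtype(analysis[c])]
    ]
    root = build_tree(covs, theta, min_leaf=args.min_leaf, max_depth=args.max_depth)

    args.out.mkdir(parents=True, exist_ok=True)
    write_json(root.to_dict(), args.out / "tree.json")
    flatten_tree(root).to_csv(args.out / "leaves.csv", index=False)

    print(render_tree(root))
    print(f"wrote {args.out}/tree.json and leaves.csv")


if __name__ == "__main__":
    main()
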