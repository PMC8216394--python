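#!/usr/bin/env python
"""Pre/post-treatment repertoire dynamics.

Per paired patient: Jaccard clonotype overlap, Pearson similarity of
shared-clone log frequencies, top-10 clone persistence, and per-clone
expansion calls (two-sided Fisher's exact test, Benjamini–Hochberg FDR).
Tests similarity against elapsed time and therapy arm, compares expansion
counts between benefit groups, and lists clones expanded in >= 2 patients.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from repdx.dynamics import (
    detect_expanded_clones,
    jaccard_similarity,
    pearson_similarity,
    shared_expanded_clones,
    similarity_vs_covariate,
    top_clone_persistence,
)
from repdx.outcomes import add_dcb_labels, compare_groups
from repdx.pipeline import load_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    warnings.simplefilter("ignore")

    cohort = load_cohort(args.cohort)
    clin = add_dcb_labels(cohort.clinical).set_index("patient_id")

    rows, calls_by_patient = [], {}
    for pid, pair in cohort.pairs.items():
        calls = detect_expanded_clones(pair, alpha=args.alpha)
        calls_by_patient[pid] = calls
        rows.append(
            {
                "patient_id": pid,
                "elapsed_weeks": pair.elapsed_weeks,
                "jaccard": jaccard_similarity(pair.pre, pair.post),
                "pearson": pearson_similarity(pair.pre, pair.post),
                "n_expanded": int(
                    (calls["significant"] & (calls["direction"] == "expanded")).sum()
                ),
                **top_clone_persistence(pair, k=10),
            }
        )
    dyn = pd.DataFrame(rows).set_index("patient_id")
    args.out.mkdir(parents=True, exist_ok=True)
    dyn.to_csv(args.out / "dynamics.csv")
    print(f"wrote {args.out / 'dynamics.csv'} ({len(dyn)} pairs)")

    rho, p = similarity_vs_covariate(dyn["jaccard"], dyn["elapsed_weeks"])
    print(f"Jaccard similarity vs elapsed weeks: Spearman rho {rho:.2f} (p = {p:.4f})")
    stat, p = similarity_vs_covariate(dyn["jaccard"], clin["therapy"])
    print(f"Jaccard similarity by therapy arm: rank-sum p = {p:.4f}")

    for col, label in (
        ("jaccard", "Jaccard overlap"),
        ("delta", "top-10 clone abundance change"),
        ("n_expanded", "significantly expanded clones"),
    ):
        res = compare_groups(dyn[col].astype(float), clin["dcb"], positive="DCB")
        print(
            f"{label}: DCB median {res['median_DCB']:.3f} vs NDB "
            f"{res['median_NDB']:.3f} (p = {res['p_value']:.4f})"
        )

    shared = shared_expanded_clones(
        calls_by_patient, key="cdr3_aa", min_patients=2, dcb_labels=clin["dcb"].to_dict()
    )
    shared.to_csv(args.out / "shared_expanded_clones.csv", index=False)
    print(f"clones expanded in >= 2 patients: {len(shared)}")
    for _, row in shared.iterrows():
        print(f"  {row['key']}  patients={row['patients']}  dcb={row['dcb_labels']}")


if __name__ == "__main__":
    main()
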