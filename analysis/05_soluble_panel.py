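#!/usr/bin/env python
"""Soluble receptor/ligand panel: baseline differences, fold-change
signatures, signature scoring, and the diversity link.

Applies the %CV <= 10 QC rule, compares baseline analyte levels between
benefit groups, computes per-patient log2 fold changes, discovers
correlated fold-change signatures by hierarchical clustering, scores the
packaged 17-member checkpoint signature (mean of z-scored members and its
co-stimulatory / co-inhibitory halves), groups patients by signature
direction, and tests the D50–sCD30 association."""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from repdx.diversity import dxx_index
from repdx.outcomes import add_dcb_labels, compare_groups
from repdx.panel import (
    SignatureDefinition,
    baseline_comparison,
    correlation_clusters,
    default_signature1,
    fold_change,
    metric_analyte_association,
    qc_filter,
    signature_direction_groups,
    signature_score,
)
from repdx.pipeline import load_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")

    cohort = load_cohort(args.cohort)
    clin = add_dcb_labels(cohort.clinical).set_index("patient_id")
    dcb = clin["dcb"]
    args.out.mkdir(parents=True, exist_ok=True)

    pre = qc_filter(cohort.panel_baseline, cohort.panel_cv)
    post = qc_filter(cohort.panel_on_treatment, cohort.panel_cv)

    base_cmp = baseline_comparison(pre, dcb)
    base_cmp.to_csv(args.out / "panel_baseline_comparison.csv", index=False)
    hits = base_cmp[base_cmp["p_value"] < 0.05]
    print(f"baseline analytes at p < 0.05: {list(hits['analyte'])}")
    for a in ("sIL-2Ra", "sCD27"):
        row = base_cmp[base_cmp["analyte"] == a].iloc[0]
        print(f"  {a}: {row['pct_diff']:+.2f}% (DCB vs NDB), p = {row['p_value']:.4f}")

    shared = pre.index.intersection(post.index)
    fc = fold_change(pre.loc[shared], post.loc[shared])
    fc.to_csv(args.out / "panel_fold_changes.csv")
    sigs = correlation_clusters(fc, min_r=0.6)
    print(f"fold-change signatures discovered: {len(sigs)}")
    for s in sigs:
        print(f"  {s.name}: {len(s.members)} analytes")

    sig1 = default_signature1()
    score = signature_score(fc, sig1)
    res = compare_groups(score, dcb, positive="NDB")
    print(
        f"Signature-1 fold-change score: NDB median {res['median_NDB']:+.2f} vs "
        f"DCB {res['median_DCB']:+.2f} (p = {res['p_value']:.4f})"
    )
    for label in ("co_stimulatory", "co_inhibitory"):
        sub = SignatureDefinition(name=label, members=sig1.subset(label))
        res = compare_groups(signature_score(fc, sub), dcb, positive="NDB")
        print(f"  {label}: p = {res['p_value']:.4f}")

    direction = signature_direction_groups(
        signature_score(pre.loc[shared], sig1), signature_score(post.loc[shared], sig1)
    )
    print(f"signature direction groups: {direction.value_counts().to_dict()}")

    d50_post = pd.Series({p: dxx_index(pair.post, 50) for p, pair in cohort.pairs.items()})
    r, p = metric_analyte_association(d50_post, pre["sCD30"])
    print(f"D50 (on-treatment) vs baseline sCD30: Pearson r = {r:.2f} (p = {p:.2g})")


if __name__ == "__main__":
    main()
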