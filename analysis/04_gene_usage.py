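#!/usr/bin/env python
"""V/J gene-segment usage at baseline, compared between benefit groups.

Computes read-weighted usage profiles per baseline repertoire at the V, J
and paired V–J level and tests each segment between DCB and NDB patients
with a two-sided rank-sum test (nominal p-values, as segment counts are
modest)."""

import argparse
import warnings
from pathlib import Path

from repdx.outcomes import add_dcb_labels
from repdx.pipeline import load_cohort
from repdx.usage import differential_usage, segment_usage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.simplefilter("ignore")

    cohort = load_cohort(args.cohort)
    clin = add_dcb_labels(cohort.clinical).set_index("patient_id")
    baseline = [r for r in cohort.repertoires.values() if r.timepoint_weeks == 0]
    args.out.mkdir(parents=True, exist_ok=True)

    for level in ("V", "J", "VJ"):
        profiles = {r.patient_id: segment_usage(r, level=level) for r in baseline}
        a = [profiles[p] for p in profiles if clin.loc[p, "dcb"] == "DCB"]
        b = [profiles[p] for p in profiles if clin.loc[p, "dcb"] == "NDB"]
        tab = differential_usage(a, b)
        tab.to_csv(args.out / f"usage_{level}.csv", index=False)
        hits = tab[tab["p_value"] < 0.05]
        print(f"{level} level: {len(tab)} segments tested, "
              f"{len(hits)} at nominal p < 0.05")
        for _, row in hits.head(5).iterrows():
            print(
                f"  {row['segment']}: DCB median {row['median_a']:.4f} vs "
                f"NDB {row['median_b']:.4f} (p = {row['p_value']:.4f})"
            )


if __name__ == "__main__":
    main()
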