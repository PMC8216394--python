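"""V/J gene-segment usage profiles and between-group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EmptyRepertoireError, Repertoire

__all__ = ["UsageProfile", "segment_usage", "differential_usage"]

VJ_SEP = "|"


@dataclass
class UsageProfile:
    sample_id: str
    level: str  # "V" | "J" | "VJ"
    usage: pd.Series  # segment -> fraction, sums to 1


def segment_usage(rep: Repertoire, level: str = "V", weight: str = "reads") -> UsageProfile:
    """Usage fraction per V, J, or V–J-paired segment.

    ``weight='reads'`` weights by read frequency; ``weight='clones'`` by the
    proportion of unique clonotypes using the segment.
    """
    if rep.n_clonotypes == 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: empty repertoire")
    df = rep.clonotypes
    if level == "V":
        key = df["v_gene"]
    elif level == "J":
        key = df["j_gene"]
    elif level == "VJ":
        key = df["v_gene"] + VJ_SEP + df["j_gene"]
    else:
        raise ValueError(f"unknown level {level!r}")
    if weight == "reads":
        usage = df.groupby(key.rename("segment"))["frequency"].sum()
    elif weight == "clones":
        usage = key.value_counts() / len(df)
        usage.index.name = "segment"
    else:
        raise ValueError(f"unknown weight {weight!r}")
    usage = usage / usage.sum()
    return UsageProfile(sample_id=rep.sample_id, level=level, usage=usage.sort_index())


def differential_usage(
    group_a: list[UsageProfile],
    group_b: list[UsageProfile],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-segment two-sided rank-sum comparison of usage between two groups.

    Segments absent from a sample contribute usage 0. Nominal p-values by
    default (``adjust='bh'`` adds a q column).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 usage profiles per group")
    levels = {p.level for p in group_a + group_b}
    if len(levels) != 1:
        raise ValueError(f"mismatched usage levels: {sorted(levels)}")

    mat_a = pd.DataFrame({i: p.usage for i, p in enumerate(group_a)}).fillna(0.0)
    mat_b = pd.DataFrame({i: p.usage for i, p in enumerate(group_b)}).fillna(0.0)
    segments = mat_a.index.union(mat_b.index)
    mat_a = mat_a.reindex(segments, fill_value=0.0)
    mat_b = mat_b.reindex(segments, fill_value=0.0)

    rows = []
    for seg in segments:
        xa, xb = mat_a.loc[seg].to_numpy(), mat_b.loc[seg].to_numpy()
        if (xa == xa[0]).all() and (xb == xa[0]).all():
            p = 1.0  # identical constant usage in both groups
        else:
            # exact rank-sum null for small groups, asymptotic otherwise
            method = "exact" if len(xa) + len(xb) <= 20 else "asymptotic"
            p = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)[1]
            )
        rows.append(
            {
                "segment": seg,
                "median_a": float(pd.Series(xa).median()),
                "median_b": float(pd.Series(xb).median()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjust {adjust!r}")
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
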