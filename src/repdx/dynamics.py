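"""Pre/post-treatment repertoire dynamics.

Covers the paired-sample comparisons: Jaccard overlap of clonotype sets,
Pearson correlation of clone frequencies, persistence of the dominant
(top-k) clones, per-clone expansion testing with Fisher's exact test and
FDR control, and clones expanded in multiple patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IDENTITY_COLUMNS, EmptyRepertoireError, Repertoire

__all__ = [
    "PairedRepertoire",
    "jaccard_similarity",
    "pearson_similarity",
    "top_clone_persistence",
    "detect_expanded_clones",
    "storey_qvalues",
    "shared_expanded_clones",
    "similarity_vs_covariate",
]


@dataclass
class PairedRepertoire:
    """Baseline and on-treatment repertoires of one patient."""

    patient_id: str
    pre: Repertoire
    post: Repertoire
    elapsed_weeks: float

    def __post_init__(self) -> None:
        if self.pre.timepoint_weeks != 0:
            raise ValueError("pre-treatment repertoire must be at week 0")
        if self.elapsed_weeks <= 0:
            raise ValueError("elapsed_weeks must be > 0")


def jaccard_similarity(a: Repertoire, b: Repertoire, min_freq: float = 0.0) -> float:
    """|A ∩ B| / |A ∪ B| over clonotype identities.

    ``min_freq`` optionally restricts both sets to dominant clones before
    comparing (default: all clones).
    """

    def ids(rep: Repertoire) -> set:
        df = rep.clonotypes
        if min_freq > 0:
            df = df[df["frequency"] > min_freq]
        return set(map(tuple, df[IDENTITY_COLUMNS].itertuples(index=False)))

    sa, sb = ids(a), ids(b)
    union = sa | sb
    if not union:
        raise EmptyRepertoireError("both repertoires empty")
    return len(sa & sb) / len(union)


def pearson_similarity(
    a: Repertoire,
    b: Repertoire,
    transform: str = "log",
    scope: str = "shared",
    pseudo: float | None = None,
) -> float:
    """Pearson correlation of clone frequencies aligned on identity.

    ``scope='shared'`` correlates over the identity intersection;
    ``scope='union'`` aligns over the union, filling absentees with a
    pseudo-frequency (default ``1/(2*total_reads)`` of the sample the clone
    is missing from) so the log transform stays defined.
    """
    fa, fb = a.frequencies(), b.frequencies()
    if scope == "shared":
        idx = fa.index.intersection(fb.index)
        xa, xb = fa.loc[idx].to_numpy(), fb.loc[idx].to_numpy()
    elif scope == "union":
        idx = fa.index.union(fb.index)
        pa = pseudo if pseudo is not None else 1.0 / (2 * a.total_reads)
        pb = pseudo if pseudo is not None else 1.0 / (2 * b.total_reads)
        xa = fa.reindex(idx, fill_value=pa).to_numpy()
        xb = fb.reindex(idx, fill_value=pb).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(idx) < 3:
        raise ValueError(
            f"pearson_similarity undefined: only {len(idx)} aligned clonotypes"
        )
    if transform == "log":
        xa, xb = np.log(xa), np.log(xb)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    r, _ = stats.pearsonr(xa, xb)
    return float(r)


def top_clone_persistence(pair: PairedRepertoire, k: int = 10) -> dict[str, float]:
    """Track the pre-treatment top-k clones into the post sample.

    Returns their cumulative frequency pre, the cumulative frequency of the
    same identities post (0 for vanished clones), and the difference.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pre = pair.pre.clonotypes.sort_values(
        ["frequency", "count", "cdr3_nt"], ascending=[False, False, True], kind="mergesort"
    ).head(k)
    top_ids = pd.MultiIndex.from_frame(pre[IDENTITY_COLUMNS])
    post_f = pair.post.frequencies()
    pre_ab = float(pre["frequency"].sum())
    post_ab = float(post_f.reindex(top_ids, fill_value=0.0).sum())
    return {
        "pre_topk_abundance": pre_ab,
        "post_abundance_of_same_clones": post_ab,
        "delta": post_ab - pre_ab,
    }


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey-style positive-FDR q-values.

    pi0 is estimated as ``#{p > lam} / ((1-lam) m)`` clipped to (0, 1];
    q-values are the pi0-scaled step-up values (BH * pi0)."""
    p = np.asarray(pvalues, float)
    m = p.size
    pi0 = min(1.0, max((p > lam).sum() / ((1 - lam) * m), 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1) * pi0
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def detect_expanded_clones(
    pair: PairedRepertoire,
    alpha: float = 0.05,
    min_count: int = 10,
    fdr: str = "bh",
) -> pd.DataFrame:
    """Per-clone expansion/contraction calls between baseline and on-treatment.

    For every clonotype present in either sample with combined count >=
    ``min_count``, a 2x2 table ``[[pre_count, pre_total - pre_count],
    [post_count, post_total - post_count]]`` is tested with a two-sided
    Fisher's exact test; p-values are adjusted across clones (``fdr='bh'``
    Benjamini–Hochberg, ``fdr='storey'`` positive-FDR estimate).  Direction
    compares frequencies; frequency ties get direction ``none`` and are
    never significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pre_total, post_total = pair.pre.total_reads, pair.post.total_reads
    if pre_total <= 0 or post_total <= 0:
        raise EmptyRepertoireError("degenerate totals in paired repertoires")

    pre_c, post_c = pair.pre.counts(), pair.post.counts()
    idx = pre_c.index.union(post_c.index)
    aa = (
        pd.concat([pair.pre.clonotypes, pair.post.clonotypes])
        .drop_duplicates(IDENTITY_COLUMNS)
        .set_index(IDENTITY_COLUMNS)["cdr3_aa"]
    )
    a = pre_c.reindex(idx, fill_value=0).to_numpy(int)
    b = post_c.reindex(idx, fill_value=0).to_numpy(int)
    keep = (a + b) >= min_count
    idx, a, b = idx[keep], a[keep], b[keep]

    pvals = np.ones(len(idx))
    for i in range(len(idx)):
        table = [[a[i], pre_total - a[i]], [b[i], post_total - b[i]]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    if len(pvals) == 0:
        q = np.array([])
    elif fdr == "bh":
        q = multipletests(pvals, method="fdr_bh")[1]
    elif fdr == "storey":
        q = storey_qvalues(pvals)
    else:
        raise ValueError(f"unknown fdr method {fdr!r}")

    pre_f = a / pre_total
    post_f = b / post_total
    direction = np.where(post_f > pre_f, "expanded", np.where(post_f < pre_f, "contracted", "none"))
    calls = pd.DataFrame(
        {
            "cdr3_nt": idx.get_level_values(0),
            "v_gene": idx.get_level_values(1),
            "j_gene": idx.get_level_values(2),
            "cdr3_aa": aa.reindex(idx).to_numpy(),
            "pre_count": a,
            "post_count": b,
            "pre_total": pre_total,
            "post_total": post_total,
            "p_value": pvals,
            "q_value": q,
            "direction": direction,
        }
    )
    calls["significant"] = (calls["q_value"] < alpha) & (calls["direction"] != "none")
    return calls.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def shared_expanded_clones(
    calls_by_patient: dict[str, pd.DataFrame],
    key: str = "cdr3_aa",
    min_patients: int = 2,
    dcb_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Clones significantly expanded in at least ``min_patients`` patients.

    ``key='cdr3_aa'`` groups by amino-acid sequence (public clones);
    ``key='cdr3_nt_vj'`` groups by the full nucleotide identity.
    """
    if min_patients < 2:
        raise ValueError("min_patients must be >= 2")
    rows = []
    for patient, calls in calls_by_patient.items():
        hits = calls[(calls["significant"]) & (calls["direction"] == "expanded")]
        for _, row in hits.iterrows():
            k = row["cdr3_aa"] if key == "cdr3_aa" else (row["cdr3_nt"], row["v_gene"], row["j_gene"])
            rows.append({"key": k, "patient_id": patient})
    if not rows:
        return pd.DataFrame(columns=["key", "n_patients", "patients", "dcb_labels"])
    df = pd.DataFrame(rows).drop_duplicates()
    grouped = df.groupby("key")["patient_id"].agg(sorted)
    grouped = grouped[grouped.map(len) >= min_patients]
    out = pd.DataFrame(
        {
            "key": grouped.index,
            "n_patients": grouped.map(len).to_numpy(),
            "patients": grouped.map(lambda ps: ",".join(ps)).to_numpy(),
        }
    )
    if dcb_labels is not None:
        out["dcb_labels"] = [
            ",".join(dcb_labels.get(p, "?") for p in ps.split(",")) for ps in out["patients"]
        ]
    return out.sort_values(["n_patients", "key"], ascending=[False, True]).reset_index(drop=True)


def similarity_vs_covariate(
    similarity: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """Association between per-patient similarity and a covariate.

    Numeric covariate -> Spearman rank correlation; two-level covariate ->
    two-sided Mann–Whitney rank-sum comparison. Returns (statistic, p).
    """
    sim, cov = similarity.align(covariate, join="inner")
    if len(sim) < 3:
        raise ValueError("need at least 3 paired observations")
    if cov.nunique() < 2:
        raise ValueError("constant covariate")
    if pd.api.types.is_numeric_dtype(cov) and cov.nunique() > 2:
        rho, p = stats.spearmanr(sim, cov)
        return float(rho), float(p)
    levels = sorted(cov.unique())
    x = sim[cov == levels[0]]
    y = sim[cov == levels[1]]
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(stat), float(p)
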