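"""Soluble receptor/ligand (sRL) panel analytics.

The panel covers 14 soluble cytokine receptors (sCKRs) and 16 soluble
immune-checkpoint proteins (sICPs) measured in plasma (pg/mL).  This module
provides the bead-panel QC rule (%CV <= 10), baseline group comparison,
pre/post log2 fold changes, correlation-based discovery of co-varying
fold-change signatures, two signature scoring schemes (mean of z-scored
members, and a rank-based single-sample enrichment score in the ssGSEA
convention), and patient grouping by signature direction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SCKR_ANALYTES",
    "SICP_ANALYTES",
    "ANALYTES",
    "SIGNATURE_1_MEMBERS",
    "CO_STIMULATORY",
    "CO_INHIBITORY",
    "SignatureDefinition",
    "default_signature1",
    "canonical_analyte",
    "qc_filter",
    "baseline_comparison",
    "fold_change",
    "correlation_clusters",
    "signature_score",
    "ssgsea_score",
    "ssgsea_scores",
    "signature_direction_groups",
    "metric_analyte_association",
]

SCKR_ANALYTES = [
    "sCD30", "sEGFR", "sgp130", "sIL-1RI", "sIL-1RII", "sIL-2Ra", "sIL-4R",
    "sIL-6R", "sRAGE", "sTNFRI", "sTNFRII", "sVEGFR1", "sVEGFR2", "sVEGFR3",
]
SICP_ANALYTES = [
    "sBTLA", "sCD27", "sCD28", "sTIM-3", "sHVEM", "sCD40", "sGITR", "sLAG-3",
    "sTLR-2", "sGITRL", "sPD-1", "sCTLA-4", "sCD80", "sCD86", "sPD-L1", "sICOS",
]
ANALYTES = SCKR_ANALYTES + SICP_ANALYTES

#: the correlated checkpoint-dominated fold-change block used as the
#: negative predictive signature
SIGNATURE_1_MEMBERS = [
    "sCD27", "sBTLA", "sCD28", "sCD40", "sGITR", "sLAG-3", "sTLR-2", "sGITRL",
    "sPD-1", "sCTLA-4", "sCD80", "sCD86", "sPD-L1", "sICOS", "sTNFRI",
    "sIL-1RI", "sHVEM",
]
CO_STIMULATORY = {
    "sCD27", "sCD28", "sCD40", "sGITR", "sGITRL", "sICOS", "sCD80", "sCD86",
    "sHVEM", "sTLR-2", "sTNFRI", "sIL-1RI",
}
CO_INHIBITORY = {"sBTLA", "sLAG-3", "sPD-1", "sCTLA-4", "sPD-L1"}


def _normkey(name: str) -> str:
    s = str(name).replace("α", "a").replace("Α", "a")
    return re.sub(r"[^0-9a-z]", "", s.lower())


_CANONICAL = {_normkey(a): a for a in ANALYTES}
# common spelling variants seen in panel exports
_CANONICAL[_normkey("sCTLA4")] = "sCTLA-4"
_CANONICAL[_normkey("sIL-2Rα")] = "sIL-2Ra"


def canonical_analyte(name: str) -> str:
    """Map a/α and hyphen spelling variants onto the canonical analyte name."""
    key = _normkey(name)
    if key not in _CANONICAL:
        raise KeyError(f"unknown analyte {name!r}")
    return _CANONICAL[key]


@dataclass
class SignatureDefinition:
    """A named analyte set with optional co-stimulatory/co-inhibitory labels."""

    name: str
    members: tuple[str, ...]
    sub_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("signature must have at least one member")
        extra = set(self.sub_labels) - set(self.members)
        if extra:
            raise ValueError(f"sub_labels for non-members: {sorted(extra)}")

    def subset(self, label: str) -> tuple[str, ...]:
        return tuple(m for m in self.members if self.sub_labels.get(m) == label)


def default_signature1() -> SignatureDefinition:
    labels = {m: "co_stimulatory" for m in CO_STIMULATORY}
    labels.update({m: "co_inhibitory" for m in CO_INHIBITORY})
    return SignatureDefinition(
        name="Signature-1",
        members=tuple(SIGNATURE_1_MEMBERS),
        sub_labels={m: labels.get(m, "other") for m in SIGNATURE_1_MEMBERS},
    )


def qc_filter(panel: pd.DataFrame, cv: pd.DataFrame | pd.Series, max_cv: float = 10.0) -> pd.DataFrame:
    """Drop analyte columns whose %CV exceeds ``max_cv`` (<= is retained).

    ``cv`` gives per-analyte %CV (a Series, or a frame aligned with the panel
    whose per-analyte maximum is used)."""
    cv_per_analyte = cv.max(axis=0) if isinstance(cv, pd.DataFrame) else cv
    bad = [a for a in panel.columns if a in cv_per_analyte.index and cv_per_analyte[a] > max_cv]
    if bad:
        warnings.warn(f"QC removed analytes with %CV > {max_cv}: {bad}", stacklevel=2)
    return panel.drop(columns=bad)


def baseline_comparison(
    panel: pd.DataFrame, labels: pd.Series, positive: str = "DCB", max_missing: float = 0.5
) -> pd.DataFrame:
    """Per-analyte DCB-vs-NDB comparison at baseline.

    ``panel`` is patients x analytes (pg/mL), ``labels`` maps patients to
    DCB/NDB.  Returns medians, ``pct_diff = 100*(median_DCB - median_NDB) /
    median_NDB`` and a two-sided rank-sum p per analyte; analytes missing in
    more than half the patients are excluded with a warning.
    """
    labels = labels.reindex(panel.index)
    groups = labels.value_counts()
    if len(groups) != 2 or (groups < 2).any():
        raise ValueError("need two groups with at least 2 patients each")
    other = [g for g in groups.index if g != positive][0]
    rows = []
    for analyte in panel.columns:
        col = panel[analyte]
        if col.isna().mean() > max_missing:
            warnings.warn(f"{analyte}: missing in >{max_missing:.0%} of patients; excluded",
                          stacklevel=2)
            continue
        x = col[labels == positive].dropna()
        y = col[labels == other].dropna()
        med_x, med_y = float(x.median()), float(y.median())
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided")[1])
        rows.append(
            {
                "analyte": analyte,
                f"median_{positive.lower()}": med_x,
                f"median_{other.lower()}": med_y,
                "pct_diff": 100.0 * (med_x - med_y) / med_y if med_y else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="mergesort").reset_index(drop=True)


def fold_change(pre: pd.Series | pd.DataFrame, post: pd.Series | pd.DataFrame):
    """log2(post/pre) per analyte; nonpositive concentrations are skipped
    with a warning (NaN in the output)."""
    pre_a, post_a = pre.align(post, join="inner")
    valid = (pre_a > 0) & (post_a > 0)
    n_bad = int((~valid).to_numpy().sum())
    if n_bad:
        warnings.warn(f"fold_change: {n_bad} nonpositive value(s) skipped", stacklevel=2)
    out = np.log2(post_a.where(valid) / pre_a.where(valid))
    return out


def correlation_clusters(
    fold_changes: pd.DataFrame, min_r: float = 0.6, min_size: int = 2
) -> list[SignatureDefinition]:
    """Discover co-varying fold-change signatures.

    Pairwise Pearson correlation across patients -> average-linkage
    hierarchical clustering on distance 1 - r -> tree cut at cophenetic
    distance ``1 - min_r``.  Clusters are returned largest-first as
    Signature-1, Signature-2, ...; singletons are dropped unless
    ``min_size=1``.  Constant analyte columns are excluded with a warning.
    """
    if len(fold_changes) < 3:
        raise ValueError("need at least 3 patients")
    fc = fold_changes.dropna(axis=1, how="any")
    constant = [c for c in fc.columns if fc[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant analyte columns excluded: {constant}", stacklevel=2)
        fc = fc.drop(columns=constant)
    if fc.shape[1] < 2:
        raise ValueError("need at least 2 non-constant analytes")
    corr = fc.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assignments = fcluster(z, t=1.0 - min_r, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for analyte, cl in zip(fc.columns, assignments):
        clusters.setdefault(cl, []).append(analyte)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))
    sigs = []
    for i, members in enumerate(ordered, start=1):
        if len(members) < min_size:
            continue
        sigs.append(SignatureDefinition(name=f"Signature-{i}", members=tuple(members)))
    return sigs


def signature_score(
    values: pd.DataFrame, sig: SignatureDefinition, normalization: str = "zscore"
) -> pd.Series:
    """Mean-over-members signature score per patient.

    ``values`` is patients x analytes (fold changes or expression).  With
    ``normalization='zscore'`` each member analyte is standardized across
    patients first, so the cohort-mean score is 0.  Missing member values are
    imputed with the member's cohort median (logged).
    """
    present = [m for m in sig.members if m in values.columns]
    if not present:
        raise ValueError(f"no members of {sig.name} present in the value table")
    sub = values[present].copy()
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"{sig.name}: {n_missing} missing value(s) imputed with member medians",
            stacklevel=2,
        )
        sub = sub.fillna(sub.median())
    if normalization == "zscore":
        std = sub.std(ddof=1).replace(0.0, np.nan)
        sub = (sub - sub.mean()) / std
        sub = sub.dropna(axis=1, how="all")
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return sub.mean(axis=1).rename(sig.name)


def ssgsea_score(expression: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample rank-based enrichment score (ssGSEA convention).

    Genes are ranked by expression descending; at each rank position the
    running difference between the weighted in-set empirical CDF (weight =
    rank statistic ``(N - position + 1)**alpha``) and the uniform out-of-set
    CDF is accumulated.  The score is the sum of that running difference,
    which depends only on the members' rank positions (monotone-transform
    invariant).
    """
    genes_in = [g for g in gene_set if g in expression.index]
    if not genes_in:
        raise ValueError("gene_set does not intersect the expressed genes")
    expr = expression.dropna()
    n = len(expr)
    # descending order, deterministic tie-break on gene name
    order = expr.sort_values(ascending=False, kind="mergesort")
    order = order.loc[sorted(order.index, key=lambda g: (-order[g], str(g)))]
    in_set = np.array([g in set(genes_in) for g in order.index])
    rank_stat = (n - np.arange(n)).astype(float)  # N .. 1 along the ordering
    w = rank_stat**alpha
    w_in = np.where(in_set, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    n_out = n - in_set.sum()
    if n_out == 0:
        return 0.0
    cdf_out = np.cumsum(~in_set) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    expression: pd.DataFrame, gene_set, alpha: float = 0.25, normalize: bool = True
) -> pd.Series:
    """ssGSEA scores for every sample (rows) of an expression matrix.

    With ``normalize=True`` scores are divided by the range of the raw
    scores across the cohort, the usual cohort normalization of the method.
    """
    scores = expression.apply(lambda row: ssgsea_score(row, gene_set, alpha), axis=1)
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


def signature_direction_groups(
    scores_pre: pd.Series, scores_post: pd.Series, scale: str = "z"
) -> pd.Series:
    """Label patients by the sign of the signature-score change.

    On the z scale the difference post - pre is used (ratios are undefined
    for negative scores); on the raw scale the log2 ratio.  Patients with
    exactly zero change are excluded with a warning.
    """
    pre, post = scores_pre.align(scores_post, join="inner")
    if scale == "z":
        change = post - pre
    elif scale == "raw":
        change = np.log2(post / pre)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    zero = change == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} patient(s) with zero signature change excluded",
            stacklevel=2,
        )
    out = pd.Series(
        np.where(change > 0, "upregulated", "downregulated"), index=change.index
    )
    return out[~zero]


def metric_analyte_association(
    metric: pd.Series, analyte_values: pd.Series, log_transform: bool = True
) -> tuple[float, float]:
    """Pearson association between a repertoire metric and an analyte.

    Analyte concentrations are log-transformed by default. Returns (r, p)."""
    m, a = metric.align(analyte_values, join="inner")
    mask = m.notna() & a.notna() & (a > 0 if log_transform else True)
    m, a = m[mask], a[mask]
    if len(m) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.log(a.to_numpy(float)) if log_transform else a.to_numpy(float)
    y = m.to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    r, p = stats.pearsonr(y, x)
    return float(r), float(p)
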