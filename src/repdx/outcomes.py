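"""Clinical endpoint utilities.

Durable-clinical-benefit (DCB) classification, two-group comparisons,
ROC/AUC with the Youden-index cutoff, Kaplan–Meier + log-rank survival
stratification, and the combined dominant-clone-diversity + soluble-
checkpoint-signature classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "classify_dcb",
    "add_dcb_labels",
    "compare_groups",
    "RocResult",
    "roc_youden",
    "survival_compare",
    "combined_classifier",
]

VALID_RESPONSES = {"PR", "SD", "PD"}


def classify_dcb(response: str, survival_months: float) -> str:
    """Durable clinical benefit: PR or SD surviving strictly more than six
    months; everything else (all PD, and PR/SD with survival <= 6) is NDB."""
    if response not in VALID_RESPONSES:
        raise ValueError(f"invalid RECIST response {response!r}")
    return "DCB" if response in ("PR", "SD") and survival_months > 6.0 else "NDB"


def add_dcb_labels(clinical: pd.DataFrame, survival_col: str = "os_months") -> pd.DataFrame:
    """Return a copy of the clinical table with a ``dcb`` column derived from
    RECIST response and the chosen survival column (default overall survival)."""
    out = clinical.copy()
    out["dcb"] = [
        classify_dcb(r, s) for r, s in zip(out["response"], out[survival_col])
    ]
    return out


def compare_groups(values: pd.Series, labels: pd.Series, positive: str | None = None) -> dict:
    """Two-sided rank-sum comparison of a numeric marker between two groups.

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.  Reports per-group medians
    and the positive/other median ratio (NaN when the reference median is 0).
    """
    v, g = values.align(labels, join="inner")
    mask = v.notna()
    v, g = v[mask], g[mask]
    groups = g.value_counts()
    if len(groups) != 2 or (groups < 2).any():
        raise ValueError("need exactly two groups with >= 2 observations each")
    pos = positive if positive is not None else sorted(groups.index)[0]
    other = [x for x in groups.index if x != pos][0]
    x, y = v[g == pos], v[g == other]
    n = len(x) + len(y)
    has_ties = pd.concat([x, y]).duplicated().any()
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    med_x, med_y = float(x.median()), float(y.median())
    return {
        "statistic": float(stat),
        "p_value": float(p),
        f"median_{pos}": med_x,
        f"median_{other}": med_y,
        "median_ratio": med_x / med_y if med_y != 0 else float("nan"),
        "n": {pos: int(len(x)), other: int(len(y))},
    }


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_cutoff: float
    youden_sens: float
    youden_spec: float


def roc_youden(scores: pd.Series, positives: pd.Series) -> RocResult:
    """ROC analysis of a positively-oriented score with the Youden cutoff.

    AUC comes from the rank-sum (Mann–Whitney) identity with midrank tie
    handling.  Candidate thresholds are the midpoints between adjacent
    distinct observed scores (plus sentinels below/above the range); a
    sample is called positive when ``score >= threshold``.  The Youden
    cutoff maximizes sensitivity + specificity - 1, ties broken toward
    higher specificity.
    """
    s, y = scores.align(positives, join="inner")
    mask = s.notna()
    s = s[mask].to_numpy(float)
    y = y[mask].astype(bool).to_numpy()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")

    ranks = stats.rankdata(s)  # midranks handle ties
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    j = sens + spec - 1
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(spec[candidates])]
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        youden_cutoff=float(thresholds[best]),
        youden_sens=float(sens[best]),
        youden_spec=float(spec[best]),
    )


def survival_compare(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> dict:
    """Two-group Kaplan–Meier comparison with the log-rank test.

    Returns the 1-df chi-square statistic, its p-value and the per-group KM
    median survival times."""
    t, e = times.align(events, join="inner")
    t, g = t.align(groups, join="inner")
    e = e.loc[t.index]
    levels = sorted(pd.Series(g).unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    if not e.astype(bool).any():
        raise ValueError("no events observed")
    masks = {lev: (g == lev) for lev in levels}
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("empty group")
    res = logrank_test(
        t[masks[levels[0]]], t[masks[levels[1]]],
        event_observed_A=e[masks[levels[0]]].astype(bool),
        event_observed_B=e[masks[levels[1]]].astype(bool),
    )
    medians = {}
    for lev in levels:
        km = KaplanMeierFitter().fit(t[masks[lev]], e[masks[lev]].astype(bool))
        medians[str(lev)] = float(km.median_survival_time_)
    return {
        "logrank_chi2": float(res.test_statistic),
        "p_value": float(res.p_value),
        "median_survival": medians,
        "n": {str(lev): int(masks[lev].sum()) for lev in levels},
    }


def combined_classifier(
    d50: pd.Series,
    sig_score_change: pd.Series,
    d50_cutoff: float,
    dcb: pd.Series,
) -> tuple[pd.Series, float, pd.DataFrame]:
    """Joint dominant-clone-diversity / signature-direction classifier.

    ``favorable`` = D50 >= cutoff and signature change <= 0 (diverse dominant
    clones, checkpoint signature not rising); ``unfavorable`` = D50 < cutoff
    and change > 0; everything else ``mixed``.  Returns the per-patient
    labels, the two-sided Fisher p comparing DCB rates between favorable and
    all other patients, and the underlying 2x2 table.
    """
    d, c = d50.align(sig_score_change, join="inner")
    missing = d.isna() | c.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} patient(s) with missing values excluded",
            stacklevel=2,
        )
        d, c = d[~missing], c[~missing]
    labels = pd.Series("mixed", index=d.index)
    labels[(d >= d50_cutoff) & (c <= 0)] = "favorable"
    labels[(d < d50_cutoff) & (c > 0)] = "unfavorable"

    dcb_aligned = dcb.reindex(labels.index)
    fav = labels == "favorable"
    is_dcb = dcb_aligned == "DCB"
    table = pd.DataFrame(
        {
            "DCB": [int((fav & is_dcb).sum()), int((~fav & is_dcb).sum())],
            "NDB": [int((fav & ~is_dcb).sum()), int((~fav & ~is_dcb).sum())],
        },
        index=["favorable", "other"],
    )
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return labels, float(p), table
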