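"""End-to-end cohort analysis: diversity -> dynamics -> usage -> panel -> outcomes.

`run_pipeline` executes every stage on a cohort (in memory or loaded from a
cohort directory), writes per-stage tables, and returns a summary dict with
the headline statistics: dominant-clone diversity ratios, the D50 ROC/AUC
and Youden cutoff, log-rank survival p-values, expansion-call counts, and
the soluble-checkpoint signature comparisons.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table, dxx_index
from .dynamics import (
    PairedRepertoire,
    detect_expanded_clones,
    jaccard_similarity,
    pearson_similarity,
    shared_expanded_clones,
    similarity_vs_covariate,
    top_clone_persistence,
)
from .io import read_clinical_table, read_clonotype_table
from .outcomes import (
    add_dcb_labels,
    combined_classifier,
    compare_groups,
    roc_youden,
    survival_compare,
)
from .panel import (
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
from .simulate import Cohort, SimulationConfig
from .usage import differential_usage, segment_usage

__all__ = ["RunConfig", "load_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """Knobs for one pipeline run."""

    min_freqs: tuple[float, ...] = (0.001, 0.01)
    diversity_variant: str = "effective"  # "shannon" or "effective"
    window_weeks: float = 9.0  # on-treatment samples within this window feed efficacy analyses
    alpha: float = 0.05
    fdr: str = "bh"
    min_count: int = 10
    responders: tuple[str, ...] = ("PR",)
    dcb_survival_col: str = "os_months"
    max_cv: float = 10.0
    cluster_min_r: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= f < 1 for f in self.min_freqs):
            raise ValueError("min_freqs must be in [0, 1)")
        if self.window_weeks <= 0:
            raise ValueError("window_weeks must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "min_freqs" in raw:
            raw["min_freqs"] = tuple(raw["min_freqs"])
        if "responders" in raw:
            raw["responders"] = tuple(raw["responders"])
        return cls(**raw)


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`repdx.simulate.simulate_cohort`."""
    d = Path(cohort_dir)
    clinical = read_clinical_table(d / "clinical.csv")
    manifest = pd.read_csv(d / "samples.csv")
    repertoires = {}
    for _, row in manifest.iterrows():
        repertoires[row["sample_id"]] = read_clonotype_table(
            d / row["path"],
            dialect="airr",
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            timepoint_weeks=float(row["timepoint_weeks"]),
        )
    pairs = {}
    for pid, group in manifest.groupby("patient_id"):
        pre = group[group["timepoint_weeks"] == 0]
        post = group[group["timepoint_weeks"] > 0]
        if len(pre) == 1 and len(post) == 1:
            post_rep = repertoires[post.iloc[0]["sample_id"]]
            pairs[pid] = PairedRepertoire(
                patient_id=pid,
                pre=repertoires[pre.iloc[0]["sample_id"]],
                post=post_rep,
                elapsed_weeks=post_rep.timepoint_weeks,
            )
    panel_pre = pd.read_csv(d / "panel_baseline.csv", index_col="patient_id")
    panel_post = pd.read_csv(d / "panel_on_treatment.csv", index_col="patient_id")
    cv_path = d / "panel_cv.csv"
    panel_cv = (
        pd.read_csv(cv_path, index_col="patient_id") if cv_path.exists() else pd.DataFrame()
    )
    truth_path = d / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return Cohort(
        config=SimulationConfig(),
        clinical=clinical,
        repertoires=repertoires,
        pairs=pairs,
        panel_baseline=panel_pre,
        panel_on_treatment=panel_post,
        panel_cv=panel_cv,
        truth=truth,
    )


def _safe(fn, *args, **kwargs):
    """Run an optional statistic; degenerate inputs yield None rather than
    aborting the whole report."""
    try:
        return fn(*args, **kwargs)
    except (ValueError, KeyError) as err:
        warnings.warn(f"{fn.__name__} skipped: {err}", stacklevel=2)
        return None


def run_pipeline(
    cohort: Cohort, config: RunConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    clinical = add_dcb_labels(cohort.clinical, survival_col=config.dcb_survival_col)
    clinical = clinical.set_index("patient_id")
    dcb = clinical["dcb"]
    therapy = clinical["therapy"]

    summary: dict = {
        "provenance": {
            "repdx_version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:12],
            "n_patients": int(len(clinical)),
            "n_paired": int(len(cohort.pairs)),
        }
    }

    # --- stage 1: baseline diversity -------------------------------------
    baseline_reps = [
        r for r in cohort.repertoires.values() if r.timepoint_weeks == 0
    ]
    div = diversity_table(baseline_reps, min_freqs=(0.0, *config.min_freqs))
    div = div.set_index("patient_id")
    if out is not None:
        div.to_csv(out / "diversity_baseline.csv")

    variant = "shannon_eff" if config.diversity_variant == "effective" else "shannon"
    dom_col = f"{variant}_minfreq_{config.min_freqs[0]:g}"
    summary["baseline_diversity"] = {}
    for arm in ("single_agent", "combination", "all"):
        idx = div.index if arm == "all" else therapy.index[therapy == arm]
        sub = div.loc[div.index.intersection(idx)]
        res = _safe(compare_groups, sub[dom_col], dcb, positive="DCB")
        d50_res = _safe(compare_groups, sub["d50"], dcb, positive="DCB")
        summary["baseline_diversity"][arm] = {
            "dominant_clone_metric": dom_col,
            "shannon": res,
            "d50": d50_res,
        }

    # --- stage 2: V/J usage ----------------------------------------------
    summary["gene_usage"] = {}
    for level in ("V", "J"):
        profiles = {r.patient_id: segment_usage(r, level=level) for r in baseline_reps}
        a = [profiles[p] for p in profiles if dcb.get(p) == "DCB"]
        b = [profiles[p] for p in profiles if dcb.get(p) == "NDB"]
        tab = _safe(differential_usage, a, b)
        if tab is not None:
            if out is not None:
                tab.to_csv(out / f"usage_{level}_dcb_vs_ndb.csv", index=False)
            summary["gene_usage"][level] = {
                "n_nominal_significant": int((tab["p_value"] < 0.05).sum()),
                "top_segment": tab.iloc[0]["segment"],
                "top_p": float(tab.iloc[0]["p_value"]),
            }

    # --- stage 3: pre/post dynamics ---------------------------------------
    dyn_rows = []
    calls_by_patient: dict[str, pd.DataFrame] = {}
    for pid, pair in cohort.pairs.items():
        calls = detect_expanded_clones(
            pair, alpha=config.alpha, min_count=config.min_count, fdr=config.fdr
        )
        calls_by_patient[pid] = calls
        persistence = top_clone_persistence(pair, k=10)
        dyn_rows.append(
            {
                "patient_id": pid,
                "elapsed_weeks": pair.elapsed_weeks,
                "jaccard": jaccard_similarity(pair.pre, pair.post),
                "pearson_shared_log": _safe(pearson_similarity, pair.pre, pair.post),
                "n_expanded": int(
                    ((calls["significant"]) & (calls["direction"] == "expanded")).sum()
                ),
                "n_significant": int(calls["significant"].sum()),
                **persistence,
            }
        )
    dyn = pd.DataFrame(dyn_rows).set_index("patient_id") if dyn_rows else pd.DataFrame()
    if out is not None and not dyn.empty:
        dyn.to_csv(out / "dynamics.csv")

    summary["dynamics"] = {}
    if not dyn.empty:
        in_window = dyn[dyn["elapsed_weeks"] <= config.window_weeks]
        summary["dynamics"] = {
            "pearson_vs_weeks_spearman": _safe(
                similarity_vs_covariate, dyn["pearson_shared_log"].dropna(),
                dyn["elapsed_weeks"],
            ),
            "jaccard_vs_weeks_spearman": _safe(
                similarity_vs_covariate, dyn["jaccard"], dyn["elapsed_weeks"]
            ),
            "pearson_vs_therapy": _safe(
                similarity_vs_covariate, dyn["pearson_shared_log"].dropna(), therapy
            ),
            "jaccard_vs_therapy": _safe(
                similarity_vs_covariate, dyn["jaccard"], therapy
            ),
            "jaccard_dcb_vs_ndb": _safe(
                compare_groups, in_window["jaccard"], dcb, positive="DCB"
            ),
            "top10_delta_dcb_vs_ndb": _safe(
                compare_groups, dyn["delta"], dcb, positive="DCB"
            ),
            "n_expanded_dcb_vs_ndb": _safe(
                compare_groups, dyn["n_expanded"].astype(float), dcb, positive="DCB"
            ),
        }
        shared = shared_expanded_clones(
            calls_by_patient, key="cdr3_aa", min_patients=2, dcb_labels=dcb.to_dict()
        )
        if out is not None:
            shared.to_csv(out / "shared_expanded_clones.csv", index=False)
        summary["dynamics"]["n_shared_expanded_clones"] = int(len(shared))

    # --- stage 4: post-treatment D50 / outcomes ---------------------------
    summary["outcomes"] = {}
    if cohort.pairs:
        d50_post = pd.Series(
            {pid: dxx_index(p.post, 50) for pid, p in cohort.pairs.items()}
        )
        responder = clinical["response"].isin(config.responders)
        summary["outcomes"]["d50_post_vs_dcb"] = {
            arm: _safe(
                compare_groups,
                d50_post[therapy.reindex(d50_post.index) == arm]
                if arm != "all"
                else d50_post,
                dcb,
                positive="DCB",
            )
            for arm in ("single_agent", "combination", "all")
        }
        summary["outcomes"]["d50_post_vs_response"] = _safe(
            compare_groups, d50_post, responder.map({True: "R", False: "NR"}),
            positive="R",
        )
        roc = _safe(roc_youden, d50_post, responder)
        if roc is not None:
            summary["outcomes"]["roc"] = {
                "auc": roc.auc,
                "youden_cutoff": roc.youden_cutoff,
                "sensitivity": roc.youden_sens,
                "specificity": roc.youden_spec,
            }
            d50_group = pd.Series(
                np.where(d50_post >= roc.youden_cutoff, "D50_high", "D50_low"),
                index=d50_post.index,
            )
            for label, (tcol, ecol) in {
                "pfs": ("pfs_months", "pfs_event"),
                "os": ("os_months", "os_event"),
            }.items():
                surv = _safe(
                    survival_compare,
                    clinical[tcol].reindex(d50_group.index),
                    clinical[ecol].reindex(d50_group.index),
                    d50_group,
                )
                summary["outcomes"][f"survival_{label}_by_d50"] = surv

    # --- stage 5: soluble-analyte panel ------------------------------------
    summary["panel"] = {}
    panel_pre = cohort.panel_baseline
    panel_post = cohort.panel_on_treatment
    if len(panel_pre):
        if len(cohort.panel_cv):
            panel_pre = qc_filter(panel_pre, cohort.panel_cv, max_cv=config.max_cv)
            panel_post = qc_filter(panel_post, cohort.panel_cv, max_cv=config.max_cv)
        base_cmp = _safe(baseline_comparison, panel_pre, dcb)
        if base_cmp is not None and out is not None:
            base_cmp.to_csv(out / "panel_baseline_comparison.csv", index=False)
        if base_cmp is not None:
            summary["panel"]["baseline_significant"] = base_cmp[
                base_cmp["p_value"] < 0.05
            ]["analyte"].tolist()
            for a in ("sIL-2Ra", "sCD27"):
                row = base_cmp[base_cmp["analyte"] == a]
                if len(row):
                    summary["panel"][f"baseline_pct_diff_{a}"] = float(
                        row["pct_diff"].iloc[0]
                    )
        if len(panel_post):
            shared_pat = panel_pre.index.intersection(panel_post.index)
            fc = fold_change(panel_pre.loc[shared_pat], panel_post.loc[shared_pat])
            if out is not None:
                fc.to_csv(out / "panel_fold_changes.csv")
            sigs = _safe(correlation_clusters, fc, min_r=config.cluster_min_r)
            summary["panel"]["n_discovered_signatures"] = len(sigs) if sigs else 0
            sig1 = default_signature1()
            score = signature_score(fc, sig1, normalization="zscore")
            summary["panel"]["signature1_ndb_vs_dcb"] = _safe(
                compare_groups, score, dcb, positive="NDB"
            )
            for label in ("co_stimulatory", "co_inhibitory"):
                sub = SignatureDefinition(
                    name=f"{sig1.name}:{label}", members=sig1.subset(label)
                )
                sub_score = signature_score(fc, sub, normalization="zscore")
                summary["panel"][f"{label}_ndb_vs_dcb"] = _safe(
                    compare_groups, sub_score, dcb, positive="NDB"
                )
            pre_scores = signature_score(panel_pre.loc[shared_pat], sig1)
            post_scores = signature_score(panel_post.loc[shared_pat], sig1)
            direction = signature_direction_groups(pre_scores, post_scores, scale="z")
            summary["panel"]["signature1_direction_counts"] = (
                direction.value_counts().to_dict()
            )
            if cohort.pairs:
                d50_post = pd.Series(
                    {pid: dxx_index(p.post, 50) for pid, p in cohort.pairs.items()}
                )
                assoc = _safe(
                    metric_analyte_association, d50_post, panel_pre["sCD30"]
                ) if "sCD30" in panel_pre.columns else None
                if assoc is not None:
                    summary["panel"]["d50_vs_sCD30"] = {"r": assoc[0], "p": assoc[1]}
                # combined D50 + signature classifier
                roc_info = summary.get("outcomes", {}).get("roc")
                if roc_info is not None:
                    sig_change = (post_scores - pre_scores).reindex(d50_post.index)
                    labels, p_comb, table = combined_classifier(
                        d50_post, sig_change, roc_info["youden_cutoff"], dcb
                    )
                    summary["outcomes"]["combined_classifier"] = {
                        "fisher_p": p_comb,
                        "table": table.to_dict(),
                        "counts": labels.value_counts().to_dict(),
                    }

    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
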