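"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes so that every
pipeline stage is testable without patient data: heavy-tailed clone
frequency distributions, paired pre/post repertoires with controllable
clone persistence and expansion, a group effect on dominant-clone
diversity (DCB repertoires are more even among clones above the dominance
threshold), a correlated soluble-analyte block mirroring the checkpoint
signature, and censored survival outcomes linked to dominant-clone
diversity through a proportional-hazards model.

Everything is driven by one :class:`SimulationConfig`; the seed fully
determines the output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import panel as panel_mod
from .diversity import dxx_index
from .dynamics import PairedRepertoire
from .io import (
    IDENTITY_COLUMNS,
    Repertoire,
    write_clinical_table,
    write_clonotype_table,
)

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_repertoire",
    "simulate_paired",
    "simulate_panel",
    "simulate_patient_panel",
    "simulate_cohort",
]

# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the cohort this pipeline is built around: 31 patients
    (11 DCB / 20 NDB, i.e. 35% DCB), 24 with a paired on-treatment sample,
    14 on single-agent therapy, a DCB/NDB dominant-clone effective-diversity
    ratio of 2.78, group-specific truly-expanded-clone counts of 27 (DCB)
    vs 18 (NDB), and baseline shifts of +5.04% (sIL-2Ra) and +11.52%
    (sCD27) in the DCB group.
    """

    n_patients: int = 31
    frac_dcb: float = 11 / 31
    paired_fraction: float = 24 / 31
    single_agent_fraction: float = 14 / 31

    # repertoire
    n_clones: int = 1000
    clone_dist: str = "zipf"  # or "lognormal"
    shape: float = 1.1  # zipf exponent / lognormal sigma (1.5 typical)
    depth: int = 100_000
    patient_jitter_sd: float = 0.25  # lognormal jitter on per-patient clone freqs
    dominant_min_freq: float = 0.001  # dominance threshold for the diversity effect
    dcb_diversity_ratio: float = 2.78

    # pre/post dynamics
    persistence: float = 0.85
    persistence_by_group: dict[str, float] = field(
        default_factory=lambda: {"DCB": 0.8, "NDB": 0.9}
    )
    n_expanded: int = 20
    n_expanded_by_group: dict[str, int] = field(
        default_factory=lambda: {"DCB": 27, "NDB": 18}
    )
    expansion_factor: float = 10.0
    top_k: int = 10
    top_clone_decay: dict[str, float] = field(
        default_factory=lambda: {"DCB": 1.0, "NDB": 0.85}
    )
    dynamics_jitter_sd: float = 0.1  # per-clone lognormal drift at nine weeks
    reference_weeks: float = 9.0  # timescale for persistence decay and drift
    therapy_turnover_factor: float = 1.5  # extra turnover under combination therapy
    # probability that a public clone expands under treatment, per group
    public_expansion_prob: dict[str, float] = field(
        default_factory=lambda: {"DCB": 0.6, "NDB": 0.25}
    )

    # soluble-analyte panel
    panel_block_r: float = 0.6
    panel_effect: float = 1.2  # latent-factor on-treatment shift in the NDB group
    panel_fc_sd: float = 0.5  # per-analyte log2 fold-change scale
    panel_baseline_sd: float = 0.3  # between-patient log2 spread at baseline
    baseline_log2_shift_dcb: dict[str, float] = field(
        default_factory=lambda: {
            "sIL-2Ra": float(np.log2(1.0504)),
            "sCD27": float(np.log2(1.1152)),
        }
    )
    global_fc_shift: dict[str, float] = field(
        default_factory=lambda: {"sRAGE": 0.5, "sCD27": 0.5}
    )
    d50_cd30_coupling: float = 0.4  # log2 pg/mL per SD of D50

    # survival
    pfs_base_median: float = 6.0
    pfs_loghr_per_sd: float = -0.8  # log hazard ratio per SD of D50
    censor_low: float = 6.0
    censor_high: float = 36.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dcb", "paired_fraction", "single_agent_fraction", "persistence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clone_dist not in ("zipf", "lognormal"):
            raise ValueError(f"unknown clone_dist {self.clone_dist!r}")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.n_expanded > self.n_clones:
            raise ValueError("n_expanded cannot exceed n_clones")


# ---------------------------------------------------------------------------
# clone-frequency machinery

def _base_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.clone_dist == "zipf":
        p = np.arange(1, cfg.n_clones + 1, dtype=float) ** (-cfg.shape)
    else:  # lognormal
        p = np.sort(rng.lognormal(0.0, cfg.shape, cfg.n_clones))[::-1]
    return p / p.sum()


def _dominant_effective_diversity(p: np.ndarray, min_freq: float) -> float:
    q = p[p > min_freq]
    q = q / q.sum()
    return float(np.exp(-(q * np.log(q)).sum()))


def _evenness_exponent(p: np.ndarray, min_freq: float, target_ratio: float) -> float:
    """Exponent gamma < 1 such that flattening the clone distribution to
    ``p**gamma`` multiplies dominant-clone effective diversity by
    ``target_ratio``.  When the repertoire is too small/even to reach the
    target, the flattest admissible exponent is returned."""
    if target_ratio <= 1:
        return 1.0
    base = _dominant_effective_diversity(p, min_freq)

    def gap(g: float) -> float:
        q = p**g
        return _dominant_effective_diversity(q / q.sum(), min_freq) / base - target_ratio

    lo = 0.02
    if gap(lo) <= 0:  # target unreachable: flatten as far as allowed
        return lo
    return float(brentq(gap, lo, 1.0, xtol=1e-6))


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_SENSE_CODONS = sorted(_CODON_TABLE)

#: public clonotypes present in every simulated patient (antigen-shared
#: rearrangements; the expansion machinery can select them across patients)
PUBLIC_CLONES = [
    {
        "cdr3_nt": "TGCGCATCATCCCTGGGACAAGGCAATACAGAAGCCTTTTTC",
        "cdr3_aa": "CASSLGQGNTEAFF",
        "v_gene": "TRBV15",
        "j_gene": "TRBJ1-3",
    },
    {
        "cdr3_nt": "TGCGCTAGTAGCCCAGATCGTGGTGAGCAGTTTTTC",
        "cdr3_aa": "CASSPDRGEQFF",
        "v_gene": "TRBV2",
        "j_gene": "TRBJ2-1",
    },
    {
        "cdr3_nt": "TGTTCTGCGAGAGACGGGACTGGAAACGGCTATACCTTT",
        "cdr3_aa": "CSARDGTGNGYTF",
        "v_gene": "TRBV19",
        "j_gene": "TRBJ2-7",
    },
]

#: TRB gene segments used for simulated V/J calls
TRBV_SEGMENTS = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV7-2", "TRBV9",
    "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27",
    "TRBV28", "TRBV29-1", "TRBV30",
]
TRBJ_SEGMENTS = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]


def _random_clonotypes(rng: np.random.Generator, n: int, existing: set | None = None):
    """Random in-frame CDR3 nucleotide sequences (stop-free, so the amino
    acid translation is valid) with TRB V/J calls; identities are unique."""
    seen = set(existing or ())
    rows = []
    while len(rows) < n:
        n_codons = int(rng.integers(9, 19))
        codon_idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
        # canonical CDR3 boundaries: cysteine start, phenylalanine end
        codons = ["TGC"] + [_SENSE_CODONS[i] for i in codon_idx[1:-1]] + ["TTC"]
        nt = "".join(codons)
        v = TRBV_SEGMENTS[int(rng.integers(0, len(TRBV_SEGMENTS)))]
        j = TRBJ_SEGMENTS[int(rng.integers(0, len(TRBJ_SEGMENTS)))]
        ident = (nt, v, j)
        if ident in seen:
            continue
        seen.add(ident)
        aa = "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))
        rows.append({"cdr3_nt": nt, "cdr3_aa": aa, "v_gene": v, "j_gene": j})
    return rows


def _sample_repertoire(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    base_freqs: np.ndarray,
    clonotypes: list[dict],
    sample_id: str,
    patient_id: str,
    timepoint_weeks: float,
) -> Repertoire:
    counts = rng.multinomial(cfg.depth, base_freqs / base_freqs.sum())
    keep = counts > 0
    df = pd.DataFrame([clonotypes[i] for i in np.flatnonzero(keep)])
    df["count"] = counts[keep]
    df["frequency"] = df["count"] / counts.sum()
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id,
        timepoint_weeks=timepoint_weeks,
        clonotypes=df.reset_index(drop=True),
    )


def simulate_repertoire(
    cfg: SimulationConfig,
    group: str = "NDB",
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
    patient_id: str | None = None,
    timepoint_weeks: float = 0.0,
) -> Repertoire:
    """One sample: heavy-tailed base clone frequencies (flattened for the
    DCB group to hit ``dcb_diversity_ratio`` among dominant clones in
    expectation), per-patient lognormal jitter, then a multinomial read
    draw at the configured depth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = _base_frequencies(cfg, rng)
    if group == "DCB" and cfg.dcb_diversity_ratio > 1:
        gamma = _evenness_exponent(p, cfg.dominant_min_freq, cfg.dcb_diversity_ratio)
        p = p**gamma
        p /= p.sum()
    if cfg.patient_jitter_sd > 0:
        p = p * rng.lognormal(0.0, cfg.patient_jitter_sd, p.size)
        p /= p.sum()
    public = [dict(c) for c in PUBLIC_CLONES[: max(cfg.n_clones - 1, 0)]]
    existing = {(c["cdr3_nt"], c["v_gene"], c["j_gene"]) for c in public}
    clonotypes = _random_clonotypes(rng, cfg.n_clones - len(public), existing)
    # public clones occupy mid-tail frequency slots in every patient
    for k, clone in enumerate(public):
        clonotypes.insert(min(cfg.n_clones // 3 + k, len(clonotypes)), clone)
    return _sample_repertoire(
        cfg, rng, p, clonotypes, sample_id, patient_id or sample_id, timepoint_weeks
    )


def simulate_paired(
    cfg: SimulationConfig,
    baseline: Repertoire,
    rng: np.random.Generator | None = None,
    group: str = "NDB",
    elapsed_weeks: float = 9.0,
    n_expanded: int | None = None,
    turnover_scale: float = 1.0,
) -> tuple[PairedRepertoire, list[tuple[str, str, str]]]:
    """Build the on-treatment repertoire from a baseline sample.

    Clone turnover is confined to the sub-dominant tail: clones below the
    dominance threshold survive with probability ``persistence``
    (time-scaled, ``persistence ** (weeks / reference_weeks)``), dominant
    clones and the top-k always persist but the top-k decay by the group's
    factor (NDB dominant clones lose abundance, DCB maintain it).  Dropped
    clones are replaced by novel clones entering near the sampling detection
    floor; ``n_expanded`` surviving sub-dominant clones get their base
    frequency multiplied by ``expansion_factor``; every clone drifts by a
    small time-scaled lognormal factor.  Returns the pair plus the
    ground-truth expanded identities.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_exp = cfg.n_expanded if n_expanded is None else n_expanded
    base = baseline.clonotypes.sort_values(
        ["frequency", "count", "cdr3_nt"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(base)
    if n_exp > n:
        raise ValueError("n_expanded exceeds the number of baseline clonotypes")

    w_scale = elapsed_weeks / cfg.reference_weeks
    persistence = cfg.persistence_by_group.get(group, cfg.persistence)
    eff_persistence = persistence ** (w_scale * turnover_scale)

    freqs = base["frequency"].to_numpy(float).copy()
    subdominant = freqs < cfg.dominant_min_freq
    subdominant[: min(cfg.top_k, n)] = False
    keep = ~subdominant | (rng.random(n) < eff_persistence)
    top = np.arange(min(cfg.top_k, n))
    freqs[top] *= cfg.top_clone_decay.get(group, 1.0)

    kept_idx = np.flatnonzero(keep)
    candidates = np.flatnonzero(keep & (base["frequency"].to_numpy() < cfg.dominant_min_freq))
    if candidates.size < n_exp:
        candidates = kept_idx
    expanded_idx = set(
        rng.choice(candidates, size=min(n_exp, candidates.size), replace=False).tolist()
    )
    # public clones expand with a group-dependent probability (shared
    # antigen-driven responses, more often in benefiting patients)
    pub_ids = {(c["cdr3_nt"], c["v_gene"], c["j_gene"]) for c in PUBLIC_CLONES}
    pub_prob = cfg.public_expansion_prob.get(group, 0.0)
    for i in kept_idx:
        ident = (base.at[i, "cdr3_nt"], base.at[i, "v_gene"], base.at[i, "j_gene"])
        if ident in pub_ids and rng.random() < pub_prob:
            expanded_idx.add(int(i))
    expanded_idx = np.array(sorted(expanded_idx), dtype=int)
    freqs[expanded_idx] *= cfg.expansion_factor

    if cfg.dynamics_jitter_sd > 0:
        freqs *= rng.lognormal(0.0, cfg.dynamics_jitter_sd * np.sqrt(w_scale), n)

    # novel clones enter near the detection floor of the configured depth
    n_novel = int((~keep).sum())
    novel_freqs = rng.uniform(0.8, 4.0, n_novel) / cfg.depth
    existing = set(map(tuple, base[IDENTITY_COLUMNS].itertuples(index=False)))
    novel_rows = _random_clonotypes(rng, n_novel, existing)

    post_meta = [base.iloc[i][["cdr3_nt", "cdr3_aa", "v_gene", "j_gene"]].to_dict()
                 for i in kept_idx] + novel_rows
    post_freqs = np.concatenate([freqs[kept_idx], novel_freqs])

    post = _sample_repertoire(
        cfg,
        rng,
        post_freqs,
        post_meta,
        sample_id=f"{baseline.sample_id}_post",
        patient_id=baseline.patient_id,
        timepoint_weeks=elapsed_weeks,
    )
    truth = [
        (base.at[i, "cdr3_nt"], base.at[i, "v_gene"], base.at[i, "j_gene"])
        for i in sorted(expanded_idx)
    ]
    pair = PairedRepertoire(
        patient_id=baseline.patient_id, pre=baseline, post=post, elapsed_weeks=elapsed_weeks
    )
    return pair, truth


# ---------------------------------------------------------------------------
# soluble-analyte panel

_ANALYTE_LOG2_MEAN = pd.Series(
    np.random.default_rng(20210607).uniform(6.0, 14.0, len(panel_mod.ANALYTES)),
    index=panel_mod.ANALYTES,
)


def simulate_patient_panel(
    cfg: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    d50_z: float = 0.0,
) -> tuple[pd.Series, pd.Series]:
    """Baseline and on-treatment concentrations (pg/mL) for one patient.

    Signature-block members share a latent factor on the log2 fold change
    (pairwise correlation ~ ``panel_block_r``); the NDB group's latent
    factor is shifted upward by ``panel_effect`` (checkpoint signature rises
    under treatment in non-benefiting patients).  Baseline sCD30 is coupled
    to the patient's standardized dominant-clone diversity.
    """
    analytes = panel_mod.ANALYTES
    members = set(panel_mod.SIGNATURE_1_MEMBERS)
    log2_pre = _ANALYTE_LOG2_MEAN + rng.normal(0.0, cfg.panel_baseline_sd, len(analytes))
    if group == "DCB":
        for a, shift in cfg.baseline_log2_shift_dcb.items():
            log2_pre[a] += shift
    log2_pre["sCD30"] += cfg.d50_cd30_coupling * d50_z

    shift = cfg.panel_effect if group == "NDB" else 0.0
    latent = rng.normal(shift, 1.0)
    eps = rng.normal(0.0, 1.0, len(analytes))
    r = cfg.panel_block_r
    fc = np.empty(len(analytes))
    for i, a in enumerate(analytes):
        if a in members:
            fc[i] = cfg.panel_fc_sd * (np.sqrt(r) * latent + np.sqrt(1 - r) * eps[i])
        else:
            fc[i] = cfg.panel_fc_sd * eps[i]
    fc = pd.Series(fc, index=analytes)
    for a, s in cfg.global_fc_shift.items():
        fc[a] += s

    pre = (2.0**log2_pre).rename_axis("analyte")
    post = pre * 2.0**fc
    return pre, post


def simulate_panel(
    cfg: SimulationConfig,
    group: str = "NDB",
    timepoint: str = "baseline",
    rng: np.random.Generator | None = None,
    d50_z: float = 0.0,
) -> pd.Series:
    """One patient's panel at one timepoint (see :func:`simulate_patient_panel`)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pre, post = simulate_patient_panel(cfg, group, rng, d50_z)
    if timepoint == "baseline":
        return pre
    if timepoint == "on_treatment":
        return post
    raise ValueError(f"unknown timepoint {timepoint!r}")


# ---------------------------------------------------------------------------
# full cohort

@dataclass
class Cohort:
    """In-memory synthetic cohort: clinical table, repertoires, paired
    samples, analyte panels and the generating ground truth."""

    config: SimulationConfig
    clinical: pd.DataFrame
    repertoires: dict[str, Repertoire]
    pairs: dict[str, PairedRepertoire]
    panel_baseline: pd.DataFrame
    panel_on_treatment: pd.DataFrame
    panel_cv: pd.DataFrame
    truth: dict


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full cohort; optionally write it to ``out_dir`` in the
    pipeline's input formats (AIRR TSVs + samples manifest, clinical CSV,
    panel CSVs, truth JSON)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]

    n_dcb = int(round(cfg.frac_dcb * n))
    groups = np.array(["DCB"] * n_dcb + ["NDB"] * (n - n_dcb))
    rng.shuffle(groups)
    n_single = int(round(cfg.single_agent_fraction * n))
    therapy = np.array(["single_agent"] * n_single + ["combination"] * (n - n_single))
    rng.shuffle(therapy)
    n_paired = int(round(cfg.paired_fraction * n))
    paired_flags = np.array([True] * n_paired + [False] * (n - n_paired))
    rng.shuffle(paired_flags)

    repertoires: dict[str, Repertoire] = {}
    pairs: dict[str, PairedRepertoire] = {}
    truth_expanded: dict[str, list] = {}
    elapsed_by_patient: dict[str, float] = {}
    d50: dict[str, float] = {}

    for pid, group, arm, is_paired in zip(patients, groups, therapy, paired_flags):
        pre = simulate_repertoire(
            cfg, group=group, rng=rng, sample_id=f"{pid}_pre", patient_id=pid,
            timepoint_weeks=0.0,
        )
        repertoires[pre.sample_id] = pre
        if is_paired:
            weeks = float(np.clip(round(rng.lognormal(np.log(9.0), 0.45)), 3, 36))
            pair, truth = simulate_paired(
                cfg, pre, rng=rng, group=group, elapsed_weeks=weeks,
                n_expanded=cfg.n_expanded_by_group.get(group, cfg.n_expanded),
                turnover_scale=cfg.therapy_turnover_factor
                if arm == "combination"
                else 1.0,
            )
            pairs[pid] = pair
            repertoires[pair.post.sample_id] = pair.post
            truth_expanded[pid] = ["|".join(t) for t in truth]
            elapsed_by_patient[pid] = weeks
            d50[pid] = dxx_index(pair.post, 50)
        else:
            d50[pid] = dxx_index(pre, 50)

    d50_s = pd.Series(d50)
    d50_z = (d50_s - d50_s.mean()) / d50_s.std(ddof=1)

    pre_rows, post_rows, cv_rows = {}, {}, {}
    for pid, group, is_paired in zip(patients, groups, paired_flags):
        pre_p, post_p = simulate_patient_panel(cfg, group, rng, d50_z[pid])
        pre_rows[pid] = pre_p
        if is_paired:
            post_rows[pid] = post_p
        cv_rows[pid] = pd.Series(
            rng.uniform(2.0, 9.5, len(panel_mod.ANALYTES)), index=panel_mod.ANALYTES
        )
    panel_pre = pd.DataFrame(pre_rows).T.rename_axis("patient_id")
    panel_post = pd.DataFrame(post_rows).T.rename_axis("patient_id")
    panel_cv = pd.DataFrame(cv_rows).T.rename_axis("patient_id")

    clin_rows = []
    for pid, group, arm, is_paired in zip(patients, groups, therapy, paired_flags):
        # RECIST response and overall survival consistent with the DCB rule;
        # objective response (PR) is more likely at high dominant-clone
        # diversity, within either benefit group
        z = float(d50_z[pid])
        if group == "DCB":
            p_pr = float(np.clip(0.45 + 0.35 * z, 0.05, 0.95))
            response = "PR" if rng.random() < p_pr else "SD"
            os_months = 6.0 + rng.exponential(12.0)
            os_event = bool(rng.random() < 0.5)
        else:
            p_pr = float(np.clip(0.12 + 0.08 * z, 0.02, 0.5))
            u = rng.random()
            if u < p_pr:
                response = "PR"
                os_months = float(rng.uniform(1.0, 6.0))
            elif u < p_pr + 0.45:
                response = "PD"
                os_months = float(rng.exponential(8.0))
            else:
                response = "SD"
                os_months = float(rng.uniform(1.0, 6.0))
            os_event = bool(rng.random() < 0.8)
        # PFS hazard tied to dominant-clone diversity
        rate = np.log(2) / cfg.pfs_base_median * np.exp(cfg.pfs_loghr_per_sd * d50_z[pid])
        pfs_time = rng.exponential(1.0 / rate)
        censor = rng.uniform(cfg.censor_low, cfg.censor_high)
        clin_rows.append(
            {
                "patient_id": pid,
                "therapy": arm,
                "response": response,
                "pfs_months": float(min(pfs_time, censor)),
                "pfs_event": bool(pfs_time <= censor),
                "os_months": round(os_months, 3),
                "os_event": os_event,
                "timepoint_weeks": elapsed_by_patient.get(pid, 0.0),
            }
        )
    clinical = pd.DataFrame(clin_rows)
    clinical["pfs_months"] = clinical["pfs_months"].round(3)
    from .outcomes import add_dcb_labels  # local import avoids a cycle

    clinical = add_dcb_labels(clinical, survival_col="os_months")
    assert (clinical["dcb"].to_numpy() == groups).all()

    truth = {
        "seed": cfg.seed,
        "groups": dict(zip(patients, groups.tolist())),
        "expanded_clones": truth_expanded,
        "signature_members": list(panel_mod.SIGNATURE_1_MEMBERS),
        "dcb_diversity_ratio": cfg.dcb_diversity_ratio,
    }
    cohort = Cohort(
        config=cfg,
        clinical=clinical,
        repertoires=repertoires,
        pairs=pairs,
        panel_baseline=panel_pre,
        panel_on_treatment=panel_post,
        panel_cv=panel_cv,
        truth=truth,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    rep_dir = out / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sample_id in sorted(cohort.repertoires):
        rep = cohort.repertoires[sample_id]
        path = rep_dir / f"{sample_id}.tsv"
        write_clonotype_table(rep, path, dialect="airr")
        manifest.append(
            {
                "sample_id": sample_id,
                "patient_id": rep.patient_id,
                "timepoint_weeks": rep.timepoint_weeks,
                "path": f"repertoires/{sample_id}.tsv",
            }
        )
    pd.DataFrame(manifest).to_csv(out / "samples.csv", index=False)
    write_clinical_table(cohort.clinical, out / "clinical.csv")
    cohort.panel_baseline.to_csv(out / "panel_baseline.csv")
    cohort.panel_on_treatment.to_csv(out / "panel_on_treatment.csv")
    cohort.panel_cv.to_csv(out / "panel_cv.csv")
    cfg = asdict(cohort.config)
    with open(out / "truth.json", "w") as fh:
        json.dump({"config": cfg, **cohort.truth}, fh, indent=2, sort_keys=True)
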