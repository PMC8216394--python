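"""Repertoire diversity statistics.

Shannon–Wiener entropy ``H = -sum p_i ln p_i`` of the clone-frequency
distribution, optionally restricted to dominant clones (frequency above a
threshold) and optionally transformed to the order-1 Hill number ``exp(H)``
("effective number of clones").  The D10/D20/D50 indexes measure how many
distinct clonotypes, as a percentage of the repertoire, are needed to
account for 10/20/50% of the reads — small values mean an oligoclonal
repertoire dominated by a few clones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EmptyRepertoireError, Repertoire, filter_by_frequency

__all__ = ["shannon_index", "dxx_index", "topk_abundance", "diversity_table"]

# tolerance on the cumulative-frequency comparison at the Dxx boundary
_CUM_TOL = 1e-12


def _sorted_frequencies(rep: Repertoire) -> np.ndarray:
    """Frequencies sorted descending with a deterministic tie-break
    (count desc, then cdr3_nt lexicographic)."""
    df = rep.clonotypes.sort_values(
        ["frequency", "count", "cdr3_nt"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return df["frequency"].to_numpy(float)


def shannon_index(rep: Repertoire, min_freq: float = 0.0, effective: bool = False) -> float:
    """Shannon–Wiener index of the (optionally frequency-thresholded) repertoire.

    Thresholding keeps clones with frequency strictly above ``min_freq``
    (relative to the full repertoire) and renormalizes before computing
    entropy.  With ``effective=True`` returns ``exp(H)``, the order-1 Hill
    number, which equals the clone count for a perfectly even repertoire.
    """
    sub = filter_by_frequency(rep, min_freq) if min_freq > 0 else rep
    p = sub.clonotypes["frequency"].to_numpy(float)
    p = p[p > 0]
    if p.size == 0:
        raise EmptyRepertoireError(
            f"{rep.sample_id}: no clonotypes above frequency {min_freq}"
        )
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    return float(np.exp(h)) if effective else h


def dxx_index(rep: Repertoire, level: int = 50) -> float:
    """D10/D20/D50: minimum percentage of distinct clonotypes whose cumulative
    frequency reaches ``level`` percent of the reads.

    Clones are ranked by frequency descending (deterministic tie-break); the
    returned value is ``100 * k / richness`` where ``k`` is the smallest
    prefix reaching the level.
    """
    if level not in (10, 20, 50):
        raise ValueError("level must be one of 10, 20, 50")
    freqs = _sorted_frequencies(rep)
    if freqs.size == 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: empty repertoire")
    freqs = freqs / freqs.sum()
    cum = np.cumsum(freqs)
    k = int(np.argmax(cum >= level / 100 - _CUM_TOL)) + 1
    return 100.0 * k / freqs.size


def topk_abundance(rep: Repertoire, k: int = 10) -> float:
    """Cumulative frequency of the ``k`` most frequent clonotypes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = _sorted_frequencies(rep)
    return float(freqs[:k].sum())


def diversity_table(
    reps: list[Repertoire],
    min_freqs: tuple[float, ...] = (0.0, 0.001, 0.01),
    topk: int = 10,
) -> pd.DataFrame:
    """One row per sample with Shannon (raw and effective) at each threshold,
    D10/D20/D50 and top-k abundance. Convenience for the pipeline and CLI."""
    rows = []
    for rep in reps:
        row: dict[str, object] = {
            "sample_id": rep.sample_id,
            "patient_id": rep.patient_id,
            "timepoint_weeks": rep.timepoint_weeks,
            "richness": rep.n_clonotypes,
        }
        for mf in min_freqs:
            tag = f"{mf:g}"
            try:
                row[f"shannon_minfreq_{tag}"] = shannon_index(rep, mf)
                row[f"shannon_eff_minfreq_{tag}"] = shannon_index(rep, mf, effective=True)
            except EmptyRepertoireError:
                row[f"shannon_minfreq_{tag}"] = np.nan
                row[f"shannon_eff_minfreq_{tag}"] = np.nan
        for level in (10, 20, 50):
            row[f"d{level}"] = dxx_index(rep, level)
        row[f"top{topk}_abundance"] = topk_abundance(rep, topk)
        rows.append(row)
    return pd.DataFrame(rows)
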