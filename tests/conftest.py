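import numpy as np
import pandas as pd
import pytest

from repdx.io import Repertoire
from repdx.simulate import _CODON_TABLE, _SENSE_CODONS


def _cdr3(i: int, n_codons: int = 5) -> tuple[str, str]:
    """Deterministic distinct in-frame CDR3 for clone index ``i``."""
    codons = [_SENSE_CODONS[(i * 7 + k * 13) % len(_SENSE_CODONS)] for k in range(n_codons - 1)]
    nt = "TGC" + "".join(codons)
    aa = "".join(_CODON_TABLE[nt[j : j + 3]] for j in range(0, len(nt), 3))
    return nt, aa


def make_repertoire(
    counts,
    v_genes=None,
    j_genes=None,
    sample_id="S1",
    patient_id=None,
    timepoint_weeks=0.0,
    cdr3s=None,
):
    """Build a repertoire from raw counts (frequencies derived)."""
    counts = list(counts)
    n = len(counts)
    v_genes = v_genes or ["TRBV15"] * n
    j_genes = j_genes or ["TRBJ1-3"] * n
    rows = []
    for i, c in enumerate(counts):
        nt, aa = _cdr3(i) if cdr3s is None else cdr3s[i]
        rows.append(
            {
                "cdr3_nt": nt,
                "cdr3_aa": aa,
                "v_gene": v_genes[i],
                "j_gene": j_genes[i],
                "count": int(c),
            }
        )
    df = pd.DataFrame(rows)
    df["frequency"] = df["count"] / df["count"].sum()
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id or sample_id,
        timepoint_weeks=timepoint_weeks,
        clonotypes=df,
    )


def freqs_to_counts(freqs, total=10_000):
    """Integer counts approximating the requested frequencies."""
    freqs = np.asarray(freqs, float)
    return np.round(freqs / freqs.sum() * total).astype(int)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured synthetic cohort shared across tests."""
    from repdx.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_patients=10,
        n_clones=200,
        depth=20_000,
        paired_fraction=0.8,
        seed=42,
    )
    return simulate_cohort(cfg)
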