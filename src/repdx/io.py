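"""Reading, validating and writing clonotype abundance tables.

A *clonotype* is a unique TCR-beta rearrangement identified by its CDR3
nucleotide sequence together with the V and J gene-segment calls; its read
count proxies the abundance of the corresponding T-cell clone.  Two table
dialects are supported:

``airr``
    The subset of the AIRR Rearrangement TSV schema this pipeline needs:
    ``junction``, ``junction_aa``, ``v_call``, ``j_call``,
    ``duplicate_count``.
``simple_tsv``
    A minimal five-column TSV: ``cdr3_nt``, ``cdr3_aa``, ``v_gene``,
    ``j_gene``, ``count``.

Gene calls are compared allele-free: anything after ``*`` is stripped, so
``TRBV15*01`` and ``TRBV15*02`` collapse into one identity.  Rows sharing an
identity are merged by summing counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClonotypeTableError",
    "EmptyRepertoireError",
    "Repertoire",
    "PatientRecord",
    "IDENTITY_COLUMNS",
    "strip_allele",
    "read_clonotype_table",
    "write_clonotype_table",
    "normalize_frequencies",
    "filter_by_frequency",
    "read_clinical_table",
    "write_clinical_table",
]

#: columns that together define clonotype identity
IDENTITY_COLUMNS = ["cdr3_nt", "v_gene", "j_gene"]

CLONOTYPE_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count"]

_AIRR_TO_SIMPLE = {
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_gene",
    "j_call": "j_gene",
    "duplicate_count": "count",
}
_SIMPLE_TO_AIRR = {v: k for k, v in _AIRR_TO_SIMPLE.items()}

FREQ_TOL = 1e-9


class ClonotypeTableError(ValueError):
    """A clonotype table violates the format contract (e.g. missing column)."""


class EmptyRepertoireError(ValueError):
    """An operation received a repertoire with no reads/clonotypes."""


def strip_allele(call: str) -> str:
    """Drop the IMGT allele suffix: ``TRBV15*01`` -> ``TRBV15``."""
    return str(call).split("*", 1)[0]


@dataclass
class Repertoire:
    """One sample's clonotype abundance table.

    ``clonotypes`` holds one row per unique identity with columns
    ``cdr3_nt, cdr3_aa, v_gene, j_gene, count, frequency`` and, after
    :func:`filter_by_frequency`, also ``frequency_full`` (the clone's
    frequency relative to the unfiltered repertoire).
    """

    sample_id: str
    patient_id: str
    timepoint_weeks: float
    clonotypes: pd.DataFrame = field(repr=False)

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def identities(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.clonotypes[IDENTITY_COLUMNS].itertuples(index=False)))

    def frequencies(self) -> pd.Series:
        """Frequencies indexed by identity tuple."""
        idx = pd.MultiIndex.from_frame(self.clonotypes[IDENTITY_COLUMNS])
        return pd.Series(self.clonotypes["frequency"].to_numpy(), index=idx)

    def counts(self) -> pd.Series:
        idx = pd.MultiIndex.from_frame(self.clonotypes[IDENTITY_COLUMNS])
        return pd.Series(self.clonotypes["count"].to_numpy(), index=idx)


@dataclass
class PatientRecord:
    """Clinical record for one patient (therapy arm, RECIST response, survival)."""

    patient_id: str
    therapy: str  # "single_agent" | "combination"
    response: str  # "PR" | "SD" | "PD"
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    timepoint_weeks: float = 0.0
    dcb: str | None = None  # derived, see outcomes.classify_dcb


def _merge_and_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Strip alleles, merge duplicate identities (summing counts), recompute
    frequencies. Raises on zero total reads."""
    df = df.copy()
    df["v_gene"] = df["v_gene"].map(strip_allele)
    df["j_gene"] = df["j_gene"].map(strip_allele)
    df["count"] = pd.to_numeric(df["count"])
    if (df["count"] < 0).any():
        raise ClonotypeTableError("negative read counts are not allowed")
    merged = (
        df.groupby(IDENTITY_COLUMNS, as_index=False, sort=False)
        .agg(cdr3_aa=("cdr3_aa", "first"), count=("count", "sum"))
    )
    merged = merged[CLONOTYPE_COLUMNS]
    total = merged["count"].sum()
    if total <= 0:
        raise EmptyRepertoireError("repertoire has zero total reads")
    merged["frequency"] = merged["count"] / total

    bad = merged["cdr3_aa"].notna() & (
        merged["cdr3_nt"].str.len() != merged["cdr3_aa"].str.len() * 3
    )
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} clonotype(s) have cdr3_nt length inconsistent "
            "with 3x the amino-acid length",
            stacklevel=3,
        )
    return merged.reset_index(drop=True)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    sample_id: str | None = None,
    patient_id: str | None = None,
    timepoint_weeks: float = 0.0,
) -> Repertoire:
    """Read one sample's clonotype table.

    Duplicate identities are merged by summing counts and frequencies are
    recomputed from counts regardless of any frequency column in the file.
    """
    path = Path(path)
    if dialect == "airr":
        required = list(_AIRR_TO_SIMPLE)
    elif dialect == "simple_tsv":
        required = CLONOTYPE_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    raw = pd.read_csv(path, sep="\t", dtype={c: str for c in required[:4]})
    for col in required:
        if col not in raw.columns:
            raise ClonotypeTableError(
                f"{path.name}: required column {col!r} missing for dialect {dialect!r}"
            )
    if dialect == "airr":
        raw = raw.rename(columns=_AIRR_TO_SIMPLE)
    df = _merge_and_normalize(raw[CLONOTYPE_COLUMNS])
    return Repertoire(
        sample_id=sample_id or path.stem,
        patient_id=patient_id or path.stem,
        timepoint_weeks=timepoint_weeks,
        clonotypes=df,
    )


def write_clonotype_table(rep: Repertoire, path: str | Path, dialect: str = "simple_tsv") -> None:
    df = rep.clonotypes[CLONOTYPE_COLUMNS + ["frequency"]].copy()
    if dialect == "airr":
        df = df.rename(columns=_SIMPLE_TO_AIRR)
    elif dialect != "simple_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep="\t", index=False)


def repertoire_from_frame(
    df: pd.DataFrame,
    sample_id: str,
    patient_id: str | None = None,
    timepoint_weeks: float = 0.0,
) -> Repertoire:
    """Build a repertoire from an in-memory frame with the simple_tsv columns."""
    return Repertoire(
        sample_id=sample_id,
        patient_id=patient_id or sample_id,
        timepoint_weeks=timepoint_weeks,
        clonotypes=_merge_and_normalize(df[CLONOTYPE_COLUMNS]),
    )


def normalize_frequencies(rep: Repertoire) -> Repertoire:
    """Recompute ``frequency = count / total`` (errors on all-zero counts)."""
    total = rep.clonotypes["count"].sum()
    if total <= 0:
        raise EmptyRepertoireError(f"{rep.sample_id}: all-zero counts")
    df = rep.clonotypes.copy()
    df["frequency"] = df["count"] / total
    assert abs(df["frequency"].sum() - 1.0) < FREQ_TOL
    return replace(rep, clonotypes=df)


def filter_by_frequency(rep: Repertoire, min_freq: float) -> Repertoire:
    """Keep clonotypes with frequency strictly above ``min_freq``.

    The threshold is applied to the *input* repertoire's frequencies.  The
    returned table keeps those input-relative frequencies in
    ``frequency_full`` and renormalizes ``frequency`` over the retained
    clones, so either convention is available downstream.  May return an
    empty repertoire.
    """
    if not 0 <= min_freq < 1:
        raise ValueError("min_freq must be in [0, 1)")
    df = rep.clonotypes
    base = df["frequency_full"] if "frequency_full" in df.columns else df["frequency"]
    kept = df[base > min_freq].copy()
    if "frequency_full" not in kept.columns:
        kept["frequency_full"] = kept["frequency"]
    retained = kept["frequency"].sum()
    if retained > 0:
        kept["frequency"] = kept["frequency"] / retained
    return replace(rep, clonotypes=kept.reset_index(drop=True))


CLINICAL_COLUMNS = [
    "patient_id",
    "therapy",
    "response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "timepoint_weeks",
]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ClonotypeTableError(f"clinical table missing columns: {missing}")
    clin["pfs_event"] = clin["pfs_event"].astype(bool)
    clin["os_event"] = clin["os_event"].astype(bool)
    bad_resp = set(clin["response"]) - {"PR", "SD", "PD"}
    if bad_resp:
        raise ClonotypeTableError(f"invalid RECIST responses: {sorted(bad_resp)}")
    return clin


def write_clinical_table(clin: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in clin.columns]
    cols += [c for c in clin.columns if c not in cols]
    clin[cols].to_csv(path, index=False)
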