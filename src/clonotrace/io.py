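"""Readers and writers for clone tables, reference pairs and sample manifests.

Two clone-table dialects are supported: the AIRR Rearrangement TSV standard
(columns ``junction``, ``junction_aa``, ``v_call``, ``j_call``,
``duplicate_count``, ``productive``) and the MiXCR clone-table export
(``cloneCount``, ``cloneFraction``, ``nSeqCDR3``, ``aaSeqCDR3``,
``allVHitsWithScore``/``bestVHit``, ...). Both canonicalize to the same
:class:`~clonotrace.repertoire.Repertoire`: clones are keyed by CDR3β
nucleotide sequence, rows sharing a key are merged by summing read counts,
and frequencies are recomputed from the merged counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

from .repertoire import (
    CloneRecord,
    EmptyRepertoireError,
    ReferencePair,
    Repertoire,
    RepertoireError,
    is_productive,
)

AIRR_COLUMNS = ["junction", "junction_aa", "v_call", "j_call",
                "duplicate_count", "productive"]

_MIXCR_V_COLUMNS = ("bestVHit", "allVHitsWithScore", "vHit")
_MIXCR_J_COLUMNS = ("bestJHit", "allJHitsWithScore", "jHit")


class FormatError(RepertoireError):
    """A required column is missing or a file is structurally unusable."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    return df


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _majority(values) -> str:
    """Most common non-empty value; ties broken lexicographically."""
    counts = Counter(v for v in values if v)
    if not counts:
        return ""
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def _build_repertoire(rows: pd.DataFrame, sample_id: str, patient_id: str,
                      compartment: str, timepoint: str) -> Repertoire:
    """Merge rows by nucleotide key, sum counts, recompute frequencies."""
    if rows.empty:
        raise EmptyRepertoireError(f"{sample_id}: no clones in table")
    grouped = rows.groupby("cdr3_nt", sort=True)
    total = int(rows["read_count"].sum())
    if total <= 0:
        raise EmptyRepertoireError(f"{sample_id}: zero total reads")
    clones: dict[str, CloneRecord] = {}
    for nt, grp in grouped:
        count = int(grp["read_count"].sum())
        clones[nt] = CloneRecord(
            cdr3_nt=nt,
            cdr3_aa=_majority(grp["cdr3_aa"]),
            v_call=_majority(grp["v_call"]),
            j_call=_majority(grp["j_call"]),
            read_count=count,
            frequency=count / total,
            productive=bool(grp["productive"].any()),
        )
    return Repertoire(sample_id, patient_id, compartment, timepoint, clones)


def read_airr(path, sample_id: str | None = None, patient_id: str = "",
              compartment: str = "blood", timepoint: str = "baseline") -> Repertoire:
    """Read an AIRR Rearrangement TSV into a canonical repertoire.

    Rows with identical ``junction`` are merged by summing
    ``duplicate_count``; frequencies are recomputed from merged counts.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, AIRR_COLUMNS, path)
    if df.empty:
        raise EmptyRepertoireError(f"{path}: no rearrangement rows")
    rows = pd.DataFrame(
        {
            "cdr3_nt": df["junction"].str.upper(),
            "cdr3_aa": df["junction_aa"],
            "v_call": df["v_call"],
            "j_call": df["j_call"],
            "read_count": pd.to_numeric(df["duplicate_count"]).astype(int),
            "productive": df["productive"].str.upper().isin(["T", "TRUE", "1"]),
        }
    )
    return _build_repertoire(rows, sample_id or path.stem, patient_id,
                             compartment, timepoint)


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (one row per clone)."""
    df = rep.to_frame()
    out = pd.DataFrame(
        {
            "junction": df["cdr3_nt"],
            "junction_aa": df["cdr3_aa"],
            "v_call": df["v_call"],
            "j_call": df["j_call"],
            "duplicate_count": df["read_count"],
            "productive": df["productive"].map({True: "T", False: "F"}),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_mixcr(path, sample_id: str | None = None, patient_id: str = "",
               compartment: str = "blood", timepoint: str = "baseline") -> Repertoire:
    """Read a MiXCR clone-table TSV export.

    Productivity is inferred from the amino-acid sequence: a stop codon
    ('*'), a frameshift marker ('_') or a nucleotide length that is not
    three times the protein length marks the clone non-productive.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, ["cloneCount", "nSeqCDR3", "aaSeqCDR3"], path)
    if df.empty:
        raise EmptyRepertoireError(f"{path}: no clone rows")
    v_col = next((c for c in _MIXCR_V_COLUMNS if c in df.columns), None)
    j_col = next((c for c in _MIXCR_J_COLUMNS if c in df.columns), None)
    nt = df["nSeqCDR3"].str.upper()
    aa = df["aaSeqCDR3"]
    rows = pd.DataFrame(
        {
            "cdr3_nt": nt,
            "cdr3_aa": aa,
            # strip "(score)" suffixes and "*00" allele designations
            "v_call": df[v_col].str.split("(").str[0].str.split("*").str[0] if v_col else "",
            "j_call": df[j_col].str.split("(").str[0].str.split("*").str[0] if j_col else "",
            "read_count": pd.to_numeric(df["cloneCount"]).round().astype(int),
            "productive": [is_productive(n, a) for n, a in zip(nt, aa)],
        }
    )
    return _build_repertoire(rows, sample_id or path.stem, patient_id,
                             compartment, timepoint)


def apply_clone_filters(rep: Repertoire, min_reads: int = 50,
                        productive_only: bool = True,
                        renormalize: bool = True) -> Repertoire:
    """Apply the standard clone-table quality filters.

    Clones with fewer than ``min_reads`` reads are removed (strictly less
    than: a clone at exactly ``min_reads`` is kept) — these low-count clones
    are dominated by sequencing artifacts. Non-productive clones are removed
    when ``productive_only``. Frequencies are recomputed from the surviving
    read counts unless ``renormalize`` is disabled.
    """
    kept = {
        k: c
        for k, c in rep.clones.items()
        if c.read_count >= min_reads and (c.productive or not productive_only)
    }
    if not kept:
        raise EmptyRepertoireError(
            f"{rep.sample_id}: no clones survive filtering "
            f"(min_reads={min_reads}, productive_only={productive_only})"
        )
    out = Repertoire(rep.sample_id, rep.patient_id, rep.compartment,
                     rep.timepoint, kept)
    return out.renormalized() if renormalize else out


def read_reference_pairs(path, min_score: int = 1) -> list[ReferencePair]:
    """Read a VDJdb-style export of CDR3β–antigen pairs.

    Only pairs with confidence score >= ``min_score`` (default: above zero)
    are retained; duplicate (cdr3, epitope) rows collapse to one pair.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require(df, ["cdr3", "antigen.epitope", "antigen.species", "vdjdb.score"], path)
    if df.empty:
        warnings.warn(f"{path}: reference file contains no pairs", stacklevel=2)
        return []
    df = df.assign(score=pd.to_numeric(df["vdjdb.score"]).astype(int))
    df = df[df["score"] >= min_score]
    df = df.drop_duplicates(subset=["cdr3", "antigen.epitope"])
    pairs = [
        ReferencePair(cdr3_aa=r["cdr3"], antigen_epitope=r["antigen.epitope"],
                      antigen_species=r["antigen.species"], score=r["score"])
        for _, r in df.iterrows()
    ]
    if not pairs:
        warnings.warn(f"{path}: no reference pairs pass min_score={min_score}",
                      stacklevel=2)
    return pairs


def write_reference_pairs(pairs, path) -> None:
    pd.DataFrame(
        {
            "cdr3": [p.cdr3_aa for p in pairs],
            "antigen.epitope": [p.antigen_epitope for p in pairs],
            "antigen.species": [p.antigen_species for p in pairs],
            "vdjdb.score": [p.score for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)


MANIFEST_COLUMNS = ["sample_id", "patient_id", "compartment", "timepoint", "path"]


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest CSV mapping samples to clone-table files."""
    df = pd.read_csv(path, dtype=str)
    _require(df, MANIFEST_COLUMNS, path)
    dup = df.duplicated(subset=["patient_id", "compartment", "timepoint"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (patient, compartment, timepoint) rows: "
            f"{df.loc[dup, 'sample_id'].tolist()}"
        )
    return df


def load_manifest_repertoires(manifest: pd.DataFrame, base_dir=None,
                              dialect: str = "airr", min_reads: int = 50,
                              productive_only: bool = True) -> dict[str, Repertoire]:
    """Load, filter and canonicalize every sample listed in a manifest."""
    reader = read_airr if dialect == "airr" else read_mixcr
    out: dict[str, Repertoire] = {}
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        rep = reader(p, sample_id=row["sample_id"], patient_id=row["patient_id"],
                     compartment=row["compartment"], timepoint=row["timepoint"])
        out[row["sample_id"]] = apply_clone_filters(
            rep, min_reads=min_reads, productive_only=productive_only)
    return out
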