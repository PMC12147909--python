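"""Core repertoire containers.

A *clone* (clonotype) is the set of T cells carrying an identical TCR,
identified here by the CDR3β nucleotide junction sequence. A
:class:`Repertoire` is the filtered, frequency-normalized collection of
clones observed in one sample (one patient / compartment / timepoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

_NT_ALPHABET = frozenset("ACGT")


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide sequence; '*' marks stop codons."""
    if len(nt) % 3 != 0:
        raise ValueError("sequence length not a multiple of 3")
    return str(Seq(nt).translate())


class RepertoireError(ValueError):
    """Raised on malformed or unusable repertoire input."""


class EmptyRepertoireError(RepertoireError):
    """Raised when filtering leaves no clones (sample unusable)."""


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype in one sample, keyed by CDR3β nucleotide sequence."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    read_count: int
    frequency: float
    productive: bool

    def __post_init__(self) -> None:
        if not self.cdr3_nt or not set(self.cdr3_nt) <= _NT_ALPHABET:
            raise RepertoireError(f"invalid CDR3 nucleotide sequence: {self.cdr3_nt!r}")
        if self.read_count < 0:
            raise RepertoireError("read_count must be non-negative")
        if not 0.0 <= self.frequency <= 1.0 + 1e-12:
            raise RepertoireError(f"frequency outside [0, 1]: {self.frequency}")


@dataclass
class Repertoire:
    """A set of clones for one sample, with per-clone frequencies summing to 1.

    ``n_clones`` is the N and ``frequencies`` the p_i of the normalized
    Shannon diversity index.
    """

    sample_id: str
    patient_id: str
    compartment: str = "blood"
    timepoint: str = "baseline"
    clones: dict[str, CloneRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, rec in self.clones.items():
            if key != rec.cdr3_nt:
                raise RepertoireError("clone key must equal cdr3_nt")

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def keys(self) -> list[str]:
        return list(self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        """Clone frequencies p_i, in clone-key insertion order."""
        return np.array([c.frequency for c in self.clones.values()], dtype=float)

    @property
    def read_counts(self) -> np.ndarray:
        return np.array([c.read_count for c in self.clones.values()], dtype=np.int64)

    def frequency_of(self, key: str) -> float:
        return self.clones[key].frequency if key in self.clones else 0.0

    def check_normalized(self, tol: float = 1e-9) -> None:
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > tol:
            raise RepertoireError(
                f"clone frequencies sum to {total:.12f}, expected 1 within {tol}"
            )

    def renormalized(self) -> "Repertoire":
        """Recompute frequencies from read counts so that they sum to 1."""
        total = int(self.read_counts.sum())
        if total <= 0:
            raise EmptyRepertoireError("repertoire has zero total reads")
        clones = {
            k: replace(c, frequency=c.read_count / total) for k, c in self.clones.items()
        }
        return Repertoire(self.sample_id, self.patient_id, self.compartment,
                          self.timepoint, clones)

    def subset(self, keys) -> "Repertoire":
        """Sub-repertoire restricted to ``keys``; frequencies are NOT renormalized."""
        clones = {k: self.clones[k] for k in keys if k in self.clones}
        return Repertoire(self.sample_id, self.patient_id, self.compartment,
                          self.timepoint, clones)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3_nt": [c.cdr3_nt for c in self.clones.values()],
                "cdr3_aa": [c.cdr3_aa for c in self.clones.values()],
                "v_call": [c.v_call for c in self.clones.values()],
                "j_call": [c.j_call for c in self.clones.values()],
                "read_count": [c.read_count for c in self.clones.values()],
                "frequency": [c.frequency for c in self.clones.values()],
                "productive": [c.productive for c in self.clones.values()],
            }
        )


@dataclass(frozen=True)
class ReferencePair:
    """A CDR3β amino-acid sequence paired with a named antigen and epitope."""

    cdr3_aa: str
    antigen_epitope: str
    antigen_species: str
    score: int

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")


def is_productive(cdr3_nt: str, cdr3_aa: str) -> bool:
    """In-frame, stop-free, frameshift-free junction.

    A junction is productive when the nucleotide length is a multiple of 3,
    the amino-acid sequence matches that length, and it contains neither a
    stop ('*') nor a frameshift marker ('_').
    """
    if len(cdr3_nt) % 3 != 0:
        return False
    if "*" in cdr3_aa or "_" in cdr3_aa:
        return False
    return len(cdr3_aa) * 3 == len(cdr3_nt)
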