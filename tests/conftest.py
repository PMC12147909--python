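import numpy as np
import pytest

from clonotrace.repertoire import CloneRecord, Repertoire

#: distinct in-frame nucleotide keys for hand-built fixtures
NT_KEYS = [
    "TGTGCTAGCTTC", "TGTGGTAGCTTC", "TGTCATAGCTTC", "TGTACTAGCTTC",
    "TGTGATAGCTTC", "TGTAATAGCTTC", "TGTCCTAGCTTC", "TGTCAGAGCTTC",
]


def make_repertoire(freqs, keys=None, sample_id="S1", patient_id="P1",
                    compartment="blood", timepoint="baseline",
                    total_reads=1_000_000):
    """Repertoire with the given frequencies (counts derived to match)."""
    freqs = np.asarray(freqs, dtype=float)
    if keys is None:
        keys = [f"TGT{index_to_codons(i)}TTC" for i in range(len(freqs))]
    clones = {
        k: CloneRecord(k, "", "TRBV1", "TRBJ1",
                       int(round(f * total_reads)), float(f), True)
        for k, f in zip(keys, freqs)
    }
    return Repertoire(sample_id, patient_id, compartment, timepoint, clones)


def index_to_codons(i: int, n_codons: int = 8) -> str:
    """Unique stop-free codon string per index (base-4 over a safe codon set)."""
    safe = ["GCT", "TGC", "GAT", "GAA"]
    out = []
    for _ in range(n_codons):
        out.append(safe[i % 4])
        i //= 4
    return "".join(out)


@pytest.fixture
def uniform_rep():
    return make_repertoire([0.25] * 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
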