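"""Synthetic repertoire, cohort and outcome generators.

Emulates the statistical structure the analysis modules assume, so every
stage of the pipeline is testable without controlled-access patient data:

* a right-skewed clone-size distribution — a log-normal bulk of
  non-expanded clones plus an injected hyper-expanded tail whose target
  frequencies are drawn uniformly from [0.002, 0.15], spanning repertoires
  from almost no clonal expansion to heavy domination;
* longitudinal series in which redetection is driven by clone size through
  finite multinomial read sampling (detection probability rises with true
  frequency), with optional post-treatment depletion of non-expanded
  clones;
* paired tumor samples in which a blood clone seeds the tumor with a
  logistic probability in its log10 blood frequency and the tumor adds a
  majority of private clones;
* planted CDR3β specificity groups sharing interior motifs, with matching
  reference pairs plus decoys;
* proportional-hazards outcomes linked to a low-diversity group label.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import CloneRecord, Repertoire, translate
from .dynamics import PatientSeries
from .survival import SurvivalRecord, median_split

_AA_CODON = {  # one representative codon per residue (stop-free)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AAS = sorted(_AA_CODON)
_SAFE_CODONS = sorted(_AA_CODON.values())


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    n_background_clones: int = 5000
    background_law: str = "lognormal"   # or "pareto"
    lognormal_sigma: float = 1.0
    pareto_alpha: float = 1.5
    n_hyperexpanded: int = 5
    hyper_freq_low: float = 0.002
    hyper_freq_high: float = 0.15
    total_reads: int = 1_000_000
    n_timepoints: int = 4
    drift_sd: float = 0.2               # log-frequency drift per step
    nonexpanded_depletion: float = 1.0  # post-treatment multiplier
    sharing_logit_intercept: float = 8.0   # logistic sharing in log10 freq
    sharing_logit_slope: float = 2.5
    tumor_private_clones: int = 1500
    tumor_total_reads: int = 300_000
    n_planted_groups: int = 10
    planted_group_size: int = 8
    planted_motif_length: int = 4
    baseline_hazard: float = 0.02       # events per month
    hr_low_diversity: float = 2.0
    censoring_window: float = 120.0     # months

    def validate(self) -> None:
        for name in ("hyper_freq_low", "hyper_freq_high"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.background_law not in ("lognormal", "pareto"):
            raise ValueError(f"unknown background_law {self.background_law!r}")


def _stable_id(name: str) -> int:
    """Process-independent integer stream id for a sample/patient name."""
    return zlib.crc32(name.encode()) % (2 ** 31)


def _rng(config: SimConfig, *streams) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2 ** 31), *streams])


def _random_cdr3_nt(rng: np.random.Generator, n: int,
                    min_len: int = 9, max_len: int = 17) -> list[str]:
    """Distinct in-frame CDR3β nucleotide sequences.

    Sequences look like C...F junctions ('TGT' start, 'TTC' end) with
    stop-free interior codons; the shape is cosmetic realism only.
    """
    out: set[str] = set()
    lengths = rng.integers(min_len, max_len + 1, size=2 * n + 16)
    i = 0
    while len(out) < n:
        if i >= len(lengths):
            lengths = rng.integers(min_len, max_len + 1, size=2 * n)
            i = 0
        n_aa = int(lengths[i]); i += 1
        inner = rng.integers(0, len(_SAFE_CODONS), size=n_aa - 2)
        out.add("TGT" + "".join(_SAFE_CODONS[c] for c in inner) + "TTC")
    return sorted(out)


def _latent_frequencies(config: SimConfig, rng: np.random.Generator):
    """True clone frequencies: background bulk plus hyper-expanded tail."""
    n_bg = config.n_background_clones
    if config.background_law == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_bg)
    else:
        w = rng.pareto(config.pareto_alpha, size=n_bg) + 1.0
    hyper = rng.uniform(config.hyper_freq_low, config.hyper_freq_high,
                        size=config.n_hyperexpanded)
    hyper_mass = float(hyper.sum())
    if hyper_mass >= 1.0:
        raise ValueError(
            f"hyper-expanded target mass {hyper_mass:.3f} >= 1; "
            "reduce n_hyperexpanded or the target frequency range"
        )
    bg = w / w.sum() * (1.0 - hyper_mass)
    freqs = np.concatenate([bg, hyper])
    classes = np.array(["background"] * n_bg + ["hyperexpanded"] * len(hyper))
    return freqs, classes


def _sample_repertoire(keys, freqs, total_reads, rng, sample_id, patient_id,
                       compartment, timepoint) -> Repertoire:
    counts = rng.multinomial(total_reads, freqs / freqs.sum())
    keep = counts > 0
    kept_counts = counts[keep]
    total = int(kept_counts.sum())
    clones = {}
    for key, count in zip(np.asarray(keys)[keep], kept_counts):
        nt = str(key)
        clones[nt] = CloneRecord(
            cdr3_nt=nt, cdr3_aa=translate(nt), v_call="TRBV" + nt[3:5],
            j_call="TRBJ" + nt[-5:-3], read_count=int(count),
            frequency=int(count) / total, productive=True,
        )
    return Repertoire(sample_id, patient_id, compartment, timepoint, clones)


def simulate_repertoire(config: SimConfig, patient_id: str = "P1",
                        sample_id: str | None = None,
                        timepoint: str = "baseline"):
    """One blood repertoire plus its truth table.

    Returns ``(Repertoire, truth)`` where the truth table records each
    clone's latent frequency and class (background vs hyper-expanded).
    Read counts are multinomial over the latent frequencies; the standard
    50-read filter is applied downstream exactly as for real data.
    """
    config.validate()
    rng = _rng(config, _stable_id(patient_id), 0)
    freqs, classes = _latent_frequencies(config, rng)
    keys = _random_cdr3_nt(rng, len(freqs))
    rep = _sample_repertoire(keys, freqs, config.total_reads, rng,
                             sample_id or f"{patient_id}_{timepoint}",
                             patient_id, "blood", timepoint)
    truth = pd.DataFrame({"cdr3_nt": keys, "true_freq": freqs, "class": classes})
    return rep, truth


DEFAULT_TIMEPOINTS = ("baseline", "post_chemo", "post_cystectomy", "followup")


def simulate_series(config: SimConfig, patient_id: str = "P1",
                    timepoints=None):
    """Longitudinal blood series with size-dependent redetection.

    Latent frequencies drift log-normally between samples; when
    ``nonexpanded_depletion`` < 1 the non-expanded latent frequencies are
    multiplied by it from the second timepoint on (then renormalized),
    emulating a post-treatment diversity drop. Redetection is purely a
    consequence of finite read sampling, so larger clones persist more.
    """
    config.validate()
    if config.n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    tps = list(timepoints or DEFAULT_TIMEPOINTS[: config.n_timepoints])
    rng = _rng(config, _stable_id(patient_id), 1)
    freqs, classes = _latent_frequencies(config, rng)
    keys = _random_cdr3_nt(rng, len(freqs))
    latent = freqs.copy()
    reps, truth_rows = [], []
    for step, tp in enumerate(tps):
        if step > 0:
            latent = latent * np.exp(rng.normal(0.0, config.drift_sd, len(latent)))
            if config.nonexpanded_depletion != 1.0 and step == 1:
                latent[classes == "background"] *= config.nonexpanded_depletion
            latent = latent / latent.sum()
        reps.append(
            _sample_repertoire(keys, latent, config.total_reads, rng,
                               f"{patient_id}_{tp}", patient_id, "blood", tp)
        )
        for key, f, cl in zip(keys, latent, classes):
            truth_rows.append((patient_id, tp, key, float(f), cl))
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "timepoint", "cdr3_nt",
                             "true_freq", "class"]
    )
    return PatientSeries(patient_id, reps), truth


def simulate_paired_tumor(blood: Repertoire, config: SimConfig):
    """A tumor repertoire paired with a blood sample.

    Each blood clone seeds the tumor with probability
    sigmoid(intercept + slope * log10 blood frequency); shared clones keep a
    jittered copy of their blood frequency. The tumor then adds private
    clones forming the majority of its (smaller) repertoire — most
    tumor-infiltrating T cells show limited recirculation.
    """
    config.validate()
    rng = _rng(config, _stable_id(blood.sample_id), 2)
    keys = list(blood.clones)
    bf = blood.frequencies
    logit = config.sharing_logit_intercept + \
        config.sharing_logit_slope * np.log10(bf)
    p_share = 1.0 / (1.0 + np.exp(-logit))
    shared = rng.random(len(keys)) < p_share
    shared_keys = [k for k, s in zip(keys, shared) if s]
    shared_w = bf[shared] * np.exp(rng.normal(0, 0.5, int(shared.sum())))
    private_keys = _random_cdr3_nt(rng, config.tumor_private_clones,
                                   min_len=9, max_len=17)
    private_keys = [k for k in private_keys if k not in blood.clones]
    if config.background_law == "lognormal":
        private_w = rng.lognormal(0.0, config.lognormal_sigma, len(private_keys))
    else:
        private_w = rng.pareto(config.pareto_alpha, len(private_keys)) + 1.0
    # private clones carry most of the tumor mass
    shared_mass = 0.4 if len(shared_w) else 0.0
    parts = []
    if len(shared_w):
        parts.append(shared_w / shared_w.sum() * shared_mass)
    parts.append(private_w / private_w.sum() * (1.0 - shared_mass))
    w = np.concatenate(parts)
    all_keys = shared_keys + private_keys
    return _sample_repertoire(all_keys, w, config.tumor_total_reads, rng,
                              blood.sample_id + "_tumor", blood.patient_id,
                              "tumor", blood.timepoint)


def _random_cdr3_aa(rng: np.random.Generator, n: int,
                    min_len: int = 11, max_len: int = 17) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        n_aa = int(rng.integers(min_len, max_len + 1))
        inner = rng.integers(0, 20, size=n_aa - 2)
        out.add("C" + "".join(_AAS[i] for i in inner) + "F")
    return sorted(out)


def _implant(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Place a motif in the interior (outside the 3-residue flanks)."""
    lo, hi = 3, len(seq) - 3 - len(motif)
    pos = int(rng.integers(lo, hi + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


ANTIGEN_NAMES = ("CMV", "EBV", "InfluenzaA", "HCV", "HIV-1", "SARS-CoV-2",
                 "HSV-2", "YFV", "HTLV-1", "DENV1", "RSV", "MCPyV")


def simulate_reference_and_motifs(config: SimConfig):
    """Clones with planted specificity groups plus a matching reference set.

    Returns ``(clones, reference, naive_pool, truth)``: a clone table
    (cdr3_aa, patient_id, v_call) of background clones spread over patients
    with ``n_planted_groups`` planted groups of ``planted_group_size``
    members sharing an interior motif; reference pairs carrying the same
    motifs labelled with named antigens, plus an equal number of decoy
    pairs; a naive pool for the motif background table; and a truth table
    mapping each planted clone to its group and antigen.
    """
    config.validate()
    rng = _rng(config, 3)
    n_bg = 5000
    n_patients = 20
    bg = _random_cdr3_aa(rng, n_bg + config.n_planted_groups
                         * config.planted_group_size + 64)
    naive_pool = _random_cdr3_aa(_rng(config, 4), 20000)
    motifs = []
    seen = set()
    while len(motifs) < config.n_planted_groups:
        m = "".join(_AAS[i] for i in rng.integers(0, 20, config.planted_motif_length))
        if m not in seen:
            seen.add(m)
            motifs.append(m)
    antigens = [ANTIGEN_NAMES[i % len(ANTIGEN_NAMES)]
                for i in range(config.n_planted_groups)]

    rows, truth_rows = [], []
    it = iter(bg)
    for gi, (motif, antigen) in enumerate(zip(motifs, antigens)):
        # planted members spread over >= 3 patients, shared V gene
        v = f"TRBV{gi + 1}"
        for j in range(config.planted_group_size):
            seq = _implant(next(it), motif, rng)
            pid = f"P{(j % max(3, min(n_patients, config.planted_group_size))) + 1}"
            rows.append((seq, pid, v))
            truth_rows.append((seq, gi, motif, antigen))
    for i in range(n_bg):
        seq = next(it)
        pid = f"P{int(rng.integers(1, n_patients + 1))}"
        rows.append((seq, pid, f"TRBV{int(rng.integers(1, 31))}"))
    clones = pd.DataFrame(rows, columns=["cdr3_aa", "patient_id", "v_call"])

    from .repertoire import ReferencePair
    reference = []
    ref_seqs = _random_cdr3_aa(_rng(config, 5), 4 * config.n_planted_groups + 40)
    it_ref = iter(ref_seqs)
    for motif, antigen in zip(motifs, antigens):
        for _ in range(2):  # two reference TCRs per planted antigen motif
            seq = _implant(next(it_ref), motif, rng)
            reference.append(ReferencePair(seq, f"EPI_{motif}", antigen,
                                           int(rng.integers(1, 4))))
    for i in range(2 * config.n_planted_groups):  # decoys, no planted motif
        reference.append(
            ReferencePair(next(it_ref), f"DECOY_{i}",
                          ANTIGEN_NAMES[int(rng.integers(0, len(ANTIGEN_NAMES)))],
                          int(rng.integers(1, 4)))
        )
    truth = pd.DataFrame(truth_rows,
                         columns=["cdr3_aa", "group", "motif", "antigen"])
    return clones, reference, naive_pool, truth


def simulate_cohort_outcomes(diversity: dict[str, float], config: SimConfig):
    """Clinical table with proportional-hazards outcome linkage.

    Event times are exponential with hazard h0 * HR^{I(low diversity)}
    where groups come from the cohort median split of the supplied
    diversity values; censoring is independent Uniform(0, window).
    """
    config.validate()
    rng = _rng(config, 6)
    groups = median_split(diversity)
    records = []
    for pid in sorted(diversity):
        hazard = config.baseline_hazard * (
            config.hr_low_diversity if groups[pid] == "low" else 1.0
        )
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0.0, config.censoring_window)
        records.append(
            SurvivalRecord(
                patient_id=pid,
                time=float(min(t_event, t_cens)),
                event=bool(t_event <= t_cens),
                covariates={"diversity_group_low": 1.0 if groups[pid] == "low" else 0.0},
            )
        )
    return records, groups
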