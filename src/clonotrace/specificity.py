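"""Specificity grouping of CDR3β sequences and two-step antigen annotation.

T cells recognizing the same peptide-MHC tend to carry CDR3β sequences
sharing short interior motifs (local similarity) or differing at a single
position (global similarity). This module groups clones by a deliberately
simple similarity engine — interior k-mer motifs gated on fold-enrichment
over a naive background, plus Hamming-distance-1 components of equal-length
sequences — and then annotates groups with antigens by a two-step
procedure: clusters are built once from patient clones alone and once from
patient clones pooled with reference CDR3β–antigen pairs; a cluster
re-emerging in the pooled run and co-grouping at least one reference
sequence inherits that reference's antigen (the most common named antigen
when several occur). Clustering is independent of clone frequency
throughout, so annotation cannot be biased by clone size.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repertoire import ReferencePair

#: CDR3 sequences at or above this many residues are considered abnormal
MAX_CDR3_LENGTH = 25
#: residues trimmed from each end before motif extraction (germline-encoded
#: flanks carry little specificity information)
_TRIM = 3

DEFAULT_KS = (3, 4)
DEFAULT_ENRICHMENT_FOLD = 10.0
DEFAULT_MIN_COUNT = 3


@dataclass
class SpecificityCluster:
    cluster_id: str            # "L:<motif>" or "G:<seed sequence>"
    members: list[tuple[str, str]]  # (cdr3_aa, patient_id)
    inferred_antigen: str | None = None
    inferred_epitopes: list[str] = field(default_factory=list)
    antigen_tie: bool = False

    @property
    def n_unique_seqs(self) -> int:
        return len({m[0] for m in self.members})

    @property
    def n_patients(self) -> int:
        return len({m[1] for m in self.members})


@dataclass
class AnnotationResult:
    clusters: list[SpecificityCluster]
    clone_antigen: dict[str, str]  # cdr3_aa -> named antigen


def extract_motifs(cdr3_aa: str, k: int) -> set[str]:
    """Interior k-mers of a CDR3β amino-acid sequence.

    The first and last three residues are trimmed before enumerating
    contiguous k-mers. Sequences of abnormal length (>= 25 residues) must
    be excluded upstream; sequences too short to yield an interior k-mer
    return an empty set (unclusterable by local similarity).
    """
    if len(cdr3_aa) >= MAX_CDR3_LENGTH:
        raise ValueError(
            f"sequence of length {len(cdr3_aa)} >= {MAX_CDR3_LENGTH}: "
            "apply the length filter before motif extraction"
        )
    interior = cdr3_aa[_TRIM:len(cdr3_aa) - _TRIM]
    if len(interior) < k:
        return set()
    return {interior[i:i + k] for i in range(len(interior) - k + 1)}


def motif_background_table(sequences, ks=DEFAULT_KS) -> dict[str, float]:
    """Per-motif background frequency from a naive sequence pool.

    Frequency = fraction of (length-admissible) sequences containing the
    motif. Consumers should use a pseudocount of 1/(n+1) for unseen motifs.
    """
    seqs = [s for s in set(sequences) if len(s) < MAX_CDR3_LENGTH]
    counts: Counter = Counter()
    for s in seqs:
        for k in ks:
            counts.update(extract_motifs(s, k))
    n = max(len(seqs), 1)
    table = {m: c / n for m, c in counts.items()}
    table["__n_background__"] = float(n)
    return table


def _hamming1_components(seqs: list[str]):
    """Connected components of equal-length sequences at Hamming distance <= 1."""
    by_len: dict[int, list[str]] = defaultdict(list)
    for s in seqs:
        by_len[len(s)].append(s)
    for bucket in by_len.values():
        if len(bucket) < 2:
            continue
        arr = np.frombuffer("".join(bucket).encode(), dtype=np.uint8)
        arr = arr.reshape(len(bucket), len(bucket[0]))
        parent = list(range(len(bucket)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # chunked pairwise Hamming distance
        step = 512
        for lo in range(0, len(bucket), step):
            block = arr[lo:lo + step]
            dist = (block[:, None, :] != arr[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(dist <= 1)
            for i, j in zip(ii + lo, jj):
                if i < j:
                    ri, rj = find(int(i)), find(int(j))
                    if ri != rj:
                        parent[ri] = rj
        comp: dict[int, list[str]] = defaultdict(list)
        for i, s in enumerate(bucket):
            comp[find(i)].append(s)
        for members in comp.values():
            if len(members) >= 2:
                yield sorted(members)


def build_clusters(clones: pd.DataFrame, background: dict[str, float],
                   ks=DEFAULT_KS, enrichment_fold: float = DEFAULT_ENRICHMENT_FOLD,
                   min_count: int = DEFAULT_MIN_COUNT) -> list[SpecificityCluster]:
    """Cluster clones by local (motif) and global (Hamming-1) similarity.

    ``clones`` needs columns ``cdr3_aa`` and ``patient_id`` (``v_call``
    optional, used later for the Vβ bias filter). Local clusters form
    around each interior k-mer whose frequency among the input sequences
    is at least ``enrichment_fold`` times its background frequency and
    which occurs in at least ``min_count`` unique sequences. Global
    clusters are Hamming-distance-1 components of equal-length sequences.
    Clone frequency plays no role; a clone may belong to several clusters.
    """
    if clones.empty:
        return []
    df = clones[[c for c in ("cdr3_aa", "patient_id", "v_call")
                 if c in clones.columns]].drop_duplicates()
    df = df[df["cdr3_aa"].str.len() < MAX_CDR3_LENGTH]
    if df.empty:
        return []
    seq_patients: dict[str, set[str]] = defaultdict(set)
    for _, row in df.iterrows():
        seq_patients[row["cdr3_aa"]].add(row["patient_id"])
    unique_seqs = sorted(seq_patients)
    n_sample = len(unique_seqs)
    n_bg = background.get("__n_background__", 0.0)
    pseudo = 1.0 / (n_bg + 1.0) if n_bg else 1.0 / (n_sample + 1.0)

    motif_seqs: dict[str, set[str]] = defaultdict(set)
    for s in unique_seqs:
        for k in ks:
            for m in extract_motifs(s, k):
                motif_seqs[m].add(s)

    clusters: list[SpecificityCluster] = []
    for motif in sorted(motif_seqs):
        members = motif_seqs[motif]
        if len(members) < min_count:
            continue
        sample_freq = len(members) / n_sample
        bg_freq = background.get(motif, 0.0) or pseudo
        if sample_freq < enrichment_fold * bg_freq:
            continue
        clusters.append(_make_cluster(f"L:{motif}", members, seq_patients))
    for members in _hamming1_components(unique_seqs):
        if len(members) < min_count:
            continue
        clusters.append(_make_cluster(f"G:{members[0]}", members, seq_patients))
    return clusters


def _make_cluster(cid: str, seqs, seq_patients) -> SpecificityCluster:
    members = [(s, p) for s in sorted(seqs) for p in sorted(seq_patients[s])]
    return SpecificityCluster(cluster_id=cid, members=members)


def filter_high_confidence(clusters, clone_v_calls: dict[str, str] | None = None,
                           min_seqs: int = 3, min_patients: int = 3,
                           vbias_alpha: float = 0.05) -> list[SpecificityCluster]:
    """High-confidence clusters: size, patient spread, and Vβ usage bias.

    A cluster is retained when it holds at least ``min_seqs`` unique
    sequences from at least ``min_patients`` patients, and its modal Vβ
    gene is used more often than expected from the cohort-wide Vβ
    distribution (one-sided exact binomial, p < ``vbias_alpha``). Without V
    calls the bias test is skipped with a warning.
    """
    kept = [c for c in clusters
            if c.n_unique_seqs >= min_seqs and c.n_patients >= min_patients]
    if clone_v_calls is None:
        warnings.warn("no V calls supplied; Vβ bias filter skipped", stacklevel=2)
        return kept
    cohort = Counter(v for v in clone_v_calls.values() if v)
    total = sum(cohort.values())
    if total == 0:
        warnings.warn("V calls all empty; Vβ bias filter skipped", stacklevel=2)
        return kept
    out = []
    for c in kept:
        vs = [clone_v_calls.get(s, "") for s in {m[0] for m in c.members}]
        vs = [v for v in vs if v]
        if not vs:
            continue
        modal_v, modal_n = Counter(vs).most_common(1)[0]
        p0 = cohort[modal_v] / total
        pval = stats.binomtest(modal_n, len(vs), p0, alternative="greater").pvalue
        if pval < vbias_alpha:
            out.append(c)
    return out


def annotate_two_step(run1_clusters: list[SpecificityCluster],
                      patient_clones: pd.DataFrame,
                      reference: list[ReferencePair],
                      background: dict[str, float],
                      ks=DEFAULT_KS,
                      enrichment_fold: float = DEFAULT_ENRICHMENT_FOLD,
                      min_count: int = DEFAULT_MIN_COUNT) -> AnnotationResult:
    """Infer cluster antigens by re-clustering with reference pairs.

    The pooled second run adds each reference CDR3β as a pseudo-clone; the
    two-step design keeps reference sequences from shaping the original
    clusters. A run-1 cluster whose id re-emerges in the pooled run and
    co-groups at least one reference sequence is annotated with the most
    common named antigen among those references (ties broken
    lexicographically and flagged). Member clones inherit their cluster's
    antigen; a clone in several annotated clusters takes the antigen of the
    largest one.
    """
    clusters = [
        SpecificityCluster(c.cluster_id, list(c.members)) for c in run1_clusters
    ]
    if not reference:
        return AnnotationResult(clusters, {})
    ref_df = pd.DataFrame(
        {
            "cdr3_aa": [r.cdr3_aa for r in reference],
            "patient_id": "__reference__",
        }
    )
    ref_antigens: dict[str, list[ReferencePair]] = defaultdict(list)
    for r in reference:
        ref_antigens[r.cdr3_aa].append(r)
    pooled = pd.concat(
        [patient_clones[["cdr3_aa", "patient_id"]], ref_df], ignore_index=True
    )
    run2 = {
        c.cluster_id: c
        for c in build_clusters(pooled, background, ks=ks,
                                enrichment_fold=enrichment_fold,
                                min_count=min_count)
    }
    for cluster in clusters:
        match = run2.get(cluster.cluster_id)
        if match is None:
            continue  # cluster did not re-emerge in the pooled run
        ref_members = [m[0] for m in match.members if m[0] in ref_antigens]
        if not ref_members:
            continue
        pairs = list(itertools.chain.from_iterable(
            ref_antigens[s] for s in set(ref_members)))
        counts = Counter(p.antigen_species for p in pairs)
        best = max(counts.values())
        winners = sorted(a for a, c in counts.items() if c == best)
        cluster.inferred_antigen = winners[0]
        cluster.antigen_tie = len(winners) > 1
        cluster.inferred_epitopes = sorted(
            {p.antigen_epitope for p in pairs
             if p.antigen_species == cluster.inferred_antigen}
        )
    clone_antigen: dict[str, str] = {}
    best_size: dict[str, int] = {}
    for cluster in clusters:
        if cluster.inferred_antigen is None:
            continue
        size = len(cluster.members)
        for seq, _pid in cluster.members:
            if size > best_size.get(seq, -1):
                clone_antigen[seq] = cluster.inferred_antigen
                best_size[seq] = size
    return AnnotationResult(clusters, clone_antigen)


def expansion_target_association(annotation: AnnotationResult,
                                 expansion_labels: dict[str, str]) -> dict:
    """Association between having an inferred target and being hyper-expanded.

    Builds the 2x2 table {has inferred target} x {hyper-expanded} over all
    labelled clones and reports the odds ratio with a two-sided Fisher
    exact p-value, then tests each named antigen for one-sided enrichment
    among hyper-expanded clones with Benjamini-Hochberg adjustment.
    """
    seqs = list(expansion_labels)
    hyper = np.array([expansion_labels[s] == "hyper_expanded" for s in seqs])
    has_target = np.array([s in annotation.clone_antigen for s in seqs])
    a = int((has_target & hyper).sum())      # target & hyper
    b = int((has_target & ~hyper).sum())     # target & non
    c = int((~has_target & hyper).sum())     # no target & hyper
    d = int((~has_target & ~hyper).sum())    # no target & non
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        overall = {"odds_ratio": None, "p_value": None,
                   "note": "degenerate margin; odds ratio undefined",
                   "table": table}
    elif b * c == 0 or a * d == 0:
        # unbounded odds ratio: report direction, not a number
        direction = ("toward_hyperexpanded" if b * c == 0
                     else "away_from_hyperexpanded")
        pval = float(stats.fisher_exact(table).pvalue)
        overall = {"odds_ratio": None, "p_value": pval,
                   "note": f"degenerate cell; odds ratio unbounded "
                           f"{direction}", "table": table}
    else:
        res = stats.fisher_exact(table, alternative="two-sided")
        overall = {"odds_ratio": (a * d) / (b * c),
                   "p_value": float(res.pvalue), "note": "", "table": table}

    per_antigen = []
    antigens = sorted(set(annotation.clone_antigen.values()))
    for antigen in antigens:
        tgt = np.array([annotation.clone_antigen.get(s) == antigen for s in seqs])
        t = [[int((tgt & hyper).sum()), int((tgt & ~hyper).sum())],
             [int((~tgt & hyper).sum()), int((~tgt & ~hyper).sum())]]
        pval = stats.fisher_exact(t, alternative="greater").pvalue
        per_antigen.append({"antigen": antigen, "n_hyper": t[0][0],
                            "n_non": t[0][1], "p_value": float(pval)})
    if per_antigen:
        adj = multipletests([r["p_value"] for r in per_antigen], method="fdr_bh")[1]
        for r, q in zip(per_antigen, adj):
            r["p_adjusted"] = float(q)
    return {"overall": overall, "per_antigen": pd.DataFrame(per_antigen)}
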