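import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonotrace.repertoire import ReferencePair
from clonotrace.simulate import SimConfig, simulate_reference_and_motifs
from clonotrace.specificity import (annotate_two_step, build_clusters,
                                    expansion_target_association,
                                    extract_motifs, filter_high_confidence,
                                    motif_background_table)


class TestExtractMotifs:
    def test_interior_kmers_after_trimming_flanks(self):
        motifs = extract_motifs("CASSLGQAYEQYF", k=3)
        assert motifs == {"SLG", "LGQ", "GQA", "QAY", "AYE"}

    def test_abnormal_length_must_be_filtered_upstream(self):
        with pytest.raises(ValueError, match="length"):
            extract_motifs("C" + "A" * 23 + "F", k=3)  # 25 residues

    def test_minimal_length_single_motif(self):
        assert extract_motifs("CASGLYF", k=1) == {"G"}
        assert extract_motifs("CASGLTYQF", k=3) == {"GLT"}

    def test_too_short_sequence_yields_empty_set(self):
        assert extract_motifs("CASSF", k=3) == set()


def clone_table(seqs_patients):
    return pd.DataFrame(seqs_patients, columns=["cdr3_aa", "patient_id"])


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=42)
    clones, reference, naive_pool, truth = simulate_reference_and_motifs(cfg)
    background = motif_background_table(naive_pool)
    return cfg, clones, reference, background, truth


class TestBuildClusters:
    def test_planted_motif_forms_local_cluster(self, planted):
        _, clones, _, background, truth = planted
        clusters = {c.cluster_id: c for c in build_clusters(clones, background)}
        for motif in truth["motif"].unique():
            assert f"L:{motif}" in clusters
            members = {m[0] for m in clusters[f"L:{motif}"].members}
            group = set(truth[truth["motif"] == motif]["cdr3_aa"])
            assert group <= members

    def test_background_rate_motif_not_clustered(self):
        # motif present in sample at the same rate as the background
        seqs = [f"CASW{chr(65 + i)}QRSTP{chr(65 + i)}LYF" for i in range(5)]
        bg = {"QRS": 5 / 10, "RST": 5 / 10, "__n_background__": 10.0}
        clusters = build_clusters(clone_table([(s, "P1") for s in seqs]), bg,
                                  ks=(3,))
        assert not any(c.cluster_id.startswith("L:QRS") for c in clusters)

    def test_identical_sequences_share_global_cluster(self):
        seqs = [("CASSLGQAYEQYF", "P1"), ("CASSLGQAYEQYF", "P2"),
                ("CASSLGQAYEQYW", "P3")]
        bg = {"__n_background__": 1e9}  # huge background kills local clusters
        clusters = build_clusters(clone_table(seqs), bg, min_count=2)
        globals_ = [c for c in clusters if c.cluster_id.startswith("G:")]
        assert len(globals_) == 1
        assert {m[0] for m in globals_[0].members} == {
            "CASSLGQAYEQYF", "CASSLGQAYEQYW"}

    def test_empty_input_empty_output(self):
        assert build_clusters(clone_table([]), {}) == []


class TestHighConfidenceFilter:
    def _cluster(self, seqs, patients):
        from clonotrace.specificity import SpecificityCluster
        return SpecificityCluster("L:XYZ", list(zip(seqs, patients)))

    def test_v_bias_enriched_cluster_retained(self):
        c = self._cluster(["A1", "A2", "A3"], ["P1", "P2", "P3"])
        v_calls = {"A1": "TRBV9", "A2": "TRBV9", "A3": "TRBV9"}
        # cohort background: TRBV9 rare (5%)
        cohort = {f"B{i}": "TRBV1" for i in range(57)}
        cohort.update(v_calls)
        out = filter_high_confidence([c], clone_v_calls=cohort)
        assert out == [c]
        # oracle: P(X >= 3 | n=3, p=3/60) = (0.05)^3
        p0 = 3 / 60
        assert stats.binom.sf(2, 3, p0) == pytest.approx(p0 ** 3)

    def test_too_few_patients_removed(self):
        c = self._cluster([f"A{i}" for i in range(5)],
                          ["P1", "P2", "P1", "P2", "P1"])
        assert filter_high_confidence([c], clone_v_calls=None) == []

    def test_too_few_sequences_removed(self):
        c = self._cluster(["A1", "A2"], ["P1", "P2"])
        assert filter_high_confidence([c], clone_v_calls=None) == []

    def test_missing_v_calls_skips_bias_test_with_warning(self):
        c = self._cluster(["A1", "A2", "A3"], ["P1", "P2", "P3"])
        with pytest.warns(UserWarning, match="V"):
            assert filter_high_confidence([c]) == [c]


class TestTwoStepAnnotation:
    def test_planted_groups_recovered(self, planted):
        _, clones, reference, background, truth = planted
        run1 = build_clusters(clones, background)
        ann = annotate_two_step(run1, clones, reference, background)
        truth_map = dict(zip(truth["cdr3_aa"], truth["antigen"]))
        recovered = 0
        for _, grp in truth.groupby("group"):
            hits = sum(ann.clone_antigen.get(s) == grp["antigen"].iloc[0]
                       for s in grp["cdr3_aa"])
            recovered += hits >= len(grp) / 2
        assert recovered >= 9  # >= 90% of the 10 planted groups
        correct = sum(truth_map.get(s) == a
                      for s, a in ann.clone_antigen.items())
        assert correct >= 0.9 * len(ann.clone_antigen)

    def test_no_reference_means_no_annotation_same_clusters(self, planted):
        _, clones, _, background, _ = planted
        run1 = build_clusters(clones, background)
        ann = annotate_two_step(run1, clones, [], background)
        assert ann.clone_antigen == {}
        assert [c.cluster_id for c in ann.clusters] == \
            [c.cluster_id for c in run1]
        assert all(c.inferred_antigen is None for c in ann.clusters)

    def test_most_common_named_antigen_wins(self):
        seqs = [(f"CASW{c}QRSTPLYF", "P%d" % i)
                for i, c in enumerate("ADEGH")]
        bg = {"__n_background__": 1e6}
        reference = [
            ReferencePair("CAAAQRSTPAAAF", "e1", "CMV", 1),
            ReferencePair("CAGGQRSTPGGGF", "e2", "CMV", 1),
            ReferencePair("CATTQRSTPTTTF", "e3", "EBV", 1),
        ]
        run1 = build_clusters(clone_table(seqs), bg, ks=(4,))
        ann = annotate_two_step(run1, clone_table(seqs), reference, bg,
                                ks=(4,))
        cluster = next(c for c in ann.clusters if "QRST" in c.cluster_id)
        assert cluster.inferred_antigen == "CMV"
        assert not cluster.antigen_tie

    def test_antigen_tie_flagged_lexicographic(self):
        seqs = [(f"CASW{c}QRSTPLYF", "P%d" % i) for i, c in enumerate("ADE")]
        bg = {"__n_background__": 1e6}
        reference = [ReferencePair("CAAAQRSTPAAAF", "e1", "EBV", 1),
                     ReferencePair("CAGGQRSTPGGGF", "e2", "CMV", 1)]
        run1 = build_clusters(clone_table(seqs), bg, ks=(4,))
        ann = annotate_two_step(run1, clone_table(seqs), reference, bg,
                                ks=(4,))
        cluster = next(c for c in ann.clusters if "QRST" in c.cluster_id)
        assert cluster.inferred_antigen == "CMV"  # lexicographic tie-break
        assert cluster.antigen_tie

    def test_annotation_independent_of_clone_frequency(self, planted):
        """Clustering consumes only sequences and patients, never clone
        frequency, so shuffling frequencies cannot change the result."""
        _, clones, reference, background, _ = planted
        run1 = build_clusters(clones, background)
        ann1 = annotate_two_step(run1, clones, reference, background)
        shuffled = clones.sample(frac=1.0, random_state=1).reset_index(
            drop=True)
        run2 = build_clusters(shuffled, background)
        ann2 = annotate_two_step(run2, shuffled, reference, background)
        assert ann1.clone_antigen == ann2.clone_antigen


def fisher_enumeration_oracle(a, b, c, d, alternative="two-sided"):
    """Hypergeometric enumeration over all tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1)
             for x in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-7)))


class TestExpansionTargetAssociation:
    def _annotation(self, mapping):
        from clonotrace.specificity import AnnotationResult
        return AnnotationResult([], mapping)

    def test_odds_ratio_cross_product(self):
        # table (10, 90; 5, 195) -> OR = (10*195)/(90*5)
        labels = {}
        mapping = {}
        i = 0
        for n, (target, hyper) in [(10, (True, True)), (90, (True, False)),
                                   (5, (False, True)), (195, (False, False))]:
            for _ in range(n):
                s = f"S{i}"; i += 1
                labels[s] = "hyper_expanded" if hyper else "non_expanded"
                if target:
                    mapping[s] = "CMV"
        res = expansion_target_association(self._annotation(mapping), labels)
        assert res["overall"]["odds_ratio"] == pytest.approx(13 / 3)
        oracle = fisher_enumeration_oracle(10, 90, 5, 195)
        assert res["overall"]["p_value"] == pytest.approx(oracle, rel=1e-10)

    def test_fisher_pvalues_match_enumeration(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 300, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p_scipy = stats.fisher_exact([[a, b], [c, d]]).pvalue
            p_oracle = fisher_enumeration_oracle(a, b, c, d)
            assert p_scipy == pytest.approx(p_oracle, rel=1e-10)

    def test_degenerate_margin_reported_not_crashed(self):
        labels = {"A": "hyper_expanded", "B": "hyper_expanded",
                  "C": "non_expanded"}
        mapping = {"A": "CMV", "B": "CMV"}  # all hyper annotated, none else
        res = expansion_target_association(self._annotation(mapping), labels)
        assert res["overall"]["odds_ratio"] is None
        assert "degenerate" in res["overall"]["note"]

    def test_per_antigen_fdr_null_calibrated(self, rng):
        """Independent random annotation: ~5% of antigens significant."""
        n_sig, n_total = 0, 0
        for rep in range(40):
            labels = {f"S{i}": ("hyper_expanded" if rng.random() < 0.3
                                else "non_expanded") for i in range(400)}
            mapping = {f"S{i}": f"AG{rng.integers(0, 8)}"
                       for i in range(400) if rng.random() < 0.5}
            res = expansion_target_association(self._annotation(mapping),
                                               labels)
            pa = res["per_antigen"]
            n_sig += int((pa["p_adjusted"] < 0.05).sum())
            n_total += len(pa)
        assert n_sig / n_total < 0.08
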