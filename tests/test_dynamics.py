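import dataclasses

import numpy as np
import pytest
from scipy import stats

from clonotrace.dynamics import (PatientSeries, binom_minlike_pvalue,
                                 binomial_sharing_test, classify_persistence,
                                 diversity_trajectory,
                                 persistence_by_size_curve,
                                 persistent_recurrent_baseline_mass)
from clonotrace.simulate import SimConfig, simulate_series
from tests.conftest import make_repertoire


def series_from_freqsets(freqsets, keysets, patient="P1"):
    tps = [f"t{i}" for i in range(len(freqsets))]
    reps = [
        make_repertoire(f, keys=k, sample_id=f"{patient}_{tp}",
                        patient_id=patient, timepoint=tp)
        for f, k, tp in zip(freqsets, keysets, tps)
    ]
    return PatientSeries(patient, reps)


K = ["TGTGCTTTC", "TGTGGTTTC", "TGTCATTTC", "TGTACTTTC"]


class TestPersistence:
    def _series(self):
        # clone K0 in all 4, K1 in 2, K2 in 1, K3 in baseline only
        return series_from_freqsets(
            [[0.4, 0.3, 0.2, 0.1], [0.5, 0.5], [0.6, 0.4], [1.0]],
            [K, [K[0], K[1]], [K[0], K[1]], [K[0]]],
        )

    def test_labels_follow_detection_counts(self):
        labels = classify_persistence(self._series())
        assert labels[K[0]].label == "persistent"   # 4/4
        assert labels[K[1]].label == "recurrent"    # 3/4
        assert labels[K[2]].label == "transient"    # 1/4
        assert labels[K[3]].label == "transient"

    def test_labels_partition_observed_clones(self):
        labels = classify_persistence(self._series())
        assert set(labels) == set(K)
        counts = {lab: sum(1 for v in labels.values() if v.label == lab)
                  for lab in ("persistent", "recurrent", "transient")}
        assert sum(counts.values()) == len(labels)

    def test_single_sample_series_rejected(self):
        series = series_from_freqsets([[1.0]], [[K[0]]])
        with pytest.raises(ValueError, match="2 samples|single"):
            classify_persistence(series)

    def test_baseline_mass_of_persistent_and_recurrent(self):
        series = self._series()
        # persistent K0 at 0.4 + recurrent K1 at 0.3 = 0.7
        assert persistent_recurrent_baseline_mass(series) == pytest.approx(0.7)

    def test_all_transient_means_zero_mass(self):
        series = series_from_freqsets(
            [[0.5, 0.5], [1.0]], [[K[0], K[1]], [K[2]]])
        assert persistent_recurrent_baseline_mass(series) == 0.0

    def test_all_persistent_means_full_mass(self):
        series = series_from_freqsets(
            [[0.5, 0.5], [0.3, 0.7]], [K[:2], K[:2]])
        assert persistent_recurrent_baseline_mass(series) == pytest.approx(1.0)

    def test_labels_match_set_membership_recount(self):
        """Independent oracle: recount detection by raw set membership."""
        cfg = SimConfig(seed=5, n_background_clones=400, total_reads=30_000,
                        n_hyperexpanded=3)
        for i in range(5):
            series, _ = simulate_series(cfg, f"P{i}")
            labels = classify_persistence(series)
            key_sets = [set(r.clones) for r in series.repertoires]
            for key, lab in labels.items():
                n = sum(key in s for s in key_sets)
                expected = ("persistent" if n == len(key_sets)
                            else "recurrent" if n > 1 else "transient")
                assert lab.label == expected
                assert lab.n_samples_detected == n

    def test_size_curve_all_persistent_is_one(self):
        series = series_from_freqsets(
            [[0.5, 0.3, 0.1, 0.1], [0.25] * 4], [K, K])
        curve = persistence_by_size_curve([series], n_bins=3)
        assert (curve["frac_persistent"] == 1.0).all()
        assert (curve["n_clones"] > 0).all()  # empty bins omitted, not zero

    def test_size_dependent_detection_gives_monotone_trend(self):
        """Finite-read sampling redetects large clones more often, so the
        persistent fraction should rise with baseline clone size."""
        cfg = SimConfig(seed=9, n_background_clones=1500, total_reads=40_000,
                        n_hyperexpanded=5)
        series_list = [simulate_series(cfg, f"P{i}")[0] for i in range(8)]
        curve = persistence_by_size_curve(series_list, n_bins=6)
        frac = curve["frac_persistent"].to_numpy()
        rho = stats.spearmanr(np.arange(len(frac)), frac).statistic
        assert rho > 0.7
        assert frac[-1] > frac[0]


def minlike_enumeration_oracle(x, n, p):
    """Brute-force two-sided minimum-likelihood binomial p-value."""
    pmf = np.array([stats.binom.pmf(k, n, p) for k in range(n + 1)])
    return min(1.0, pmf[pmf <= pmf[x] * (1 + 1e-12)].sum())


class TestBinomialSharingTest:
    def test_pvalues_match_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 2000))
            p = float(rng.uniform(1e-4, 0.5))
            x = int(rng.integers(0, n + 1))
            mine = binom_minlike_pvalue(x, n, p)
            oracle = minlike_enumeration_oracle(x, n, p)
            assert mine == pytest.approx(oracle, rel=1e-10)

    def test_scipy_binomtest_cross_check(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 1500))
            p = float(rng.uniform(1e-3, 0.4))
            x = int(rng.integers(0, n + 1))
            assert binom_minlike_pvalue(x, n, p) == pytest.approx(
                stats.binomtest(x, n, p).pvalue, rel=1e-7)

    def test_observation_at_expectation_is_neutral(self):
        base = make_repertoire([0.01] + [0.99 / 999] * 999,
                               total_reads=10 ** 6)
        paired = make_repertoire([0.01] + [0.99 / 999] * 999,
                                 total_reads=10 ** 6)
        res = binomial_sharing_test(base, paired)
        r0 = res[0]
        assert r0.trials == 1000 and r0.observed == 10
        assert r0.p_value > 0.9
        assert r0.call == "neutral"

    def test_absent_clone_closed_form_tail(self):
        # x = 0, p = 0.001, n = 1000: lower tail is (1-p)^n ~ 0.3677
        pv = binom_minlike_pvalue(0, 1000, 0.001)
        assert pv >= (1 - 0.001) ** 1000 - 1e-12
        assert pv == pytest.approx(minlike_enumeration_oracle(0, 1000, 0.001),
                                   rel=1e-10)

    def test_strong_excess_called_enriched(self):
        freqs_base = [0.01] + [0.99 / 999] * 999
        freqs_paired = [0.05] + [0.95 / 999] * 999
        base = make_repertoire(freqs_base, total_reads=10 ** 6)
        paired = make_repertoire(freqs_paired, total_reads=10 ** 6,
                                 sample_id="S2")
        res = binomial_sharing_test(base, paired)
        r0 = res[0]
        assert r0.observed == 50
        oracle = minlike_enumeration_oracle(50, 1000, 0.01)
        assert r0.p_value == pytest.approx(oracle, rel=1e-10)
        assert (r0.call == "enriched") == (len(res) * oracle < 0.05)

    def test_bonferroni_set_matches_brute_force(self, rng):
        w = rng.lognormal(0, 1, 200)
        base = make_repertoire(w / w.sum(), total_reads=10 ** 7)
        w2 = w * np.exp(rng.normal(0, 1.5, 200))
        paired = make_repertoire(w2 / w2.sum(), total_reads=10 ** 7,
                                 sample_id="S2")
        res = binomial_sharing_test(base, paired, alpha=0.05)
        m = len(res)
        for r in res:
            brute = min(1.0, m * minlike_enumeration_oracle(
                r.observed, r.trials, r.baseline_freq))
            assert (r.call != "neutral") == (brute < 0.05)
            if r.call == "enriched":
                assert r.observed > r.trials * r.baseline_freq
            if r.call == "depleted":
                assert r.observed < r.trials * r.baseline_freq

    def test_invalid_alpha_rejected(self):
        base = make_repertoire([1.0])
        with pytest.raises(ValueError):
            binomial_sharing_test(base, base, alpha=1.5)


class TestDiversityTrajectory:
    def _series(self, patient, values):
        freqs = {
            v: np.array([v, (1 - v) / 2, (1 - v) / 2]) for v in values
        }
        reps = [
            make_repertoire(freqs[v], sample_id=f"{patient}_t{i}",
                            patient_id=patient, timepoint=f"t{i}")
            for i, v in enumerate(values)
        ]
        return PatientSeries(patient, reps)

    def test_group_median_and_identical_values_give_p_one(self):
        series = [self._series(f"P{i}", [v, v])
                  for i, v in enumerate([0.2, 0.4, 0.6])]
        table = diversity_trajectory(series)
        t0 = table[table["timepoint"] == "t0"].iloc[0]
        t1 = table[table["timepoint"] == "t1"].iloc[0]
        assert t0["median"] == pytest.approx(np.median(
            table[table["timepoint"] == "t0"]["median"]))
        assert t1["p_signed_rank_vs_baseline"] == 1.0

    def test_monotone_decrease_reflected_in_medians(self):
        series = [self._series(f"P{i}", [0.2, 0.5, 0.8]) for i in range(4)]
        table = diversity_trajectory(series)
        meds = table.sort_values("timepoint")["median"].to_numpy()
        assert meds[0] > meds[1] > meds[2]  # dominance rises, evenness falls

    def test_too_few_pairs_warns_and_omits(self):
        series = [self._series("P1", [0.2, 0.5])]
        with pytest.warns(UserWarning, match="paired"):
            table = diversity_trajectory(series)
        assert np.isnan(
            table[table["timepoint"] == "t1"]
            ["p_signed_rank_vs_baseline"].iloc[0])
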