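"""Longitudinal clone tracking and the random-sharing binomial test.

Clones observed in several samples of one patient are classified as
*persistent* (found in all available samples), *recurrent* (found in more
than one but not all), or *transient* (found in exactly one).

Per-clone enrichment or depletion relative to baseline is tested under a
random-sharing null: a paired sample is treated as a draw from the baseline
clone frequencies. For a baseline clone with frequency p the number of
trials n is the unique-clone count of the paired sample (a lower-bound
estimate of the number of T cells surveyed), the observation x is the
clone's paired-sample frequency times n rounded to the nearest integer, and
the p-value is the exact two-sided binomial probability (minimum-likelihood
tail definition). Significance is called at alpha = 0.05 after Bonferroni
correction over the baseline clones tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import normalized_shannon
from .repertoire import Repertoire


@dataclass
class PatientSeries:
    """Ordered repertoires for one patient (one compartment, increasing time)."""

    patient_id: str
    repertoires: list[Repertoire] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.repertoires:
            raise ValueError("PatientSeries requires at least one repertoire")
        for rep in self.repertoires:
            if rep.patient_id != self.patient_id:
                raise ValueError("all repertoires must share the patient_id")
        tps = [r.timepoint for r in self.repertoires]
        if len(set(tps)) != len(tps):
            raise ValueError(f"duplicate timepoints in series: {tps}")

    @property
    def n_samples(self) -> int:
        return len(self.repertoires)

    @property
    def baseline(self) -> Repertoire:
        return self.repertoires[0]


@dataclass(frozen=True)
class PersistenceLabel:
    clone_key: str
    label: str  # persistent | recurrent | transient
    n_samples_detected: int
    n_samples_total: int


@dataclass(frozen=True)
class SharingTestResult:
    clone_key: str
    baseline_freq: float
    trials: int
    observed: int
    p_value: float
    p_bonferroni: float
    call: str  # enriched | depleted | neutral


def classify_persistence(series: PatientSeries) -> dict[str, PersistenceLabel]:
    """Label every clone observed anywhere in the series.

    Detection is post-filter presence of the clone key in a sample. The
    three labels partition the observed clones. A single-sample series is
    rejected (every clone would be both persistent and transient).
    """
    total = series.n_samples
    if total < 2:
        raise ValueError(
            "persistence classification needs >= 2 samples; "
            "skip single-sample patients"
        )
    detected: dict[str, int] = {}
    for rep in series.repertoires:
        for key in rep.clones:
            detected[key] = detected.get(key, 0) + 1
    out: dict[str, PersistenceLabel] = {}
    for key, n_det in detected.items():
        if n_det == total:
            label = "persistent"
        elif n_det > 1:
            label = "recurrent"
        else:
            label = "transient"
        out[key] = PersistenceLabel(key, label, n_det, total)
    return out


def persistent_recurrent_baseline_mass(series: PatientSeries) -> float:
    """Total baseline frequency of persistent plus recurrent clones."""
    labels = classify_persistence(series)
    return float(
        sum(
            c.frequency
            for k, c in series.baseline.clones.items()
            if labels[k].label in ("persistent", "recurrent")
        )
    )


def persistence_by_size_curve(series_list, n_bins: int = 10) -> pd.DataFrame:
    """Fraction of clones in each persistence class across baseline-size bins.

    Baseline clones from all series are pooled and binned uniformly in
    log10 baseline frequency; empty bins are omitted. Captures the sharp
    rise of persistence with clone size.
    """
    rows = []
    for series in series_list:
        labels = classify_persistence(series)
        for key, clone in series.baseline.clones.items():
            rows.append((math.log10(clone.frequency), labels[key].label))
    if not rows:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "n_clones",
                                     "frac_persistent", "frac_recurrent",
                                     "frac_transient"])
    logf = np.array([r[0] for r in rows])
    lab = np.array([r[1] for r in rows])
    lo, hi = logf.min(), logf.max()
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo - .5, lo + .5])
    idx = np.clip(np.searchsorted(edges, logf, side="right") - 1, 0, len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue  # empty bins reported missing, not zero
        out.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n_clones": n,
                "frac_persistent": float((lab[mask] == "persistent").mean()),
                "frac_recurrent": float((lab[mask] == "recurrent").mean()),
                "frac_transient": float((lab[mask] == "transient").mean()),
            }
        )
    return pd.DataFrame(out)


def binom_minlike_pvalue(x: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value, minimum-likelihood tail.

    Sums Pr(X = k) over every k whose probability mass does not exceed
    Pr(X = x) (within a 1e-12 relative guard against float noise).
    """
    return float(_minlike_pvalues(np.array([x]), n, np.array([p]))[0])


def _minlike_pvalues(x: np.ndarray, n: int, p: np.ndarray,
                     chunk: int = 256) -> np.ndarray:
    """Vectorized minlike p-values for many clones sharing the trial count n."""
    k = np.arange(n + 1)
    out = np.empty(len(x), dtype=float)
    for start in range(0, len(x), chunk):
        sl = slice(start, start + chunk)
        pm = stats.binom.pmf(k[None, :], n, p[sl, None])
        d = pm[np.arange(pm.shape[0]), x[sl]]
        out[sl] = np.where(pm <= d[:, None] * (1 + 1e-12), pm, 0.0).sum(axis=1)
    return np.minimum(out, 1.0)


def binomial_sharing_test(baseline: Repertoire, paired: Repertoire,
                          alpha: float = 0.05) -> list[SharingTestResult]:
    """Test every baseline clone for enrichment/depletion in a paired sample.

    Clones private to the paired sample have no baseline frequency to serve
    as the null probability and are not tested. The Bonferroni factor m is
    the number of baseline clones tested in this comparison.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    baseline.check_normalized()
    paired.check_normalized()
    keys = list(baseline.clones)
    if not keys:
        raise ValueError("baseline repertoire is empty")
    n = paired.n_clones  # unique TCRs: lower bound on T cells surveyed
    p = np.array([baseline.clones[k].frequency for k in keys])
    paired_freq = np.array([paired.frequency_of(k) for k in keys])
    # round half away from zero
    x = np.floor(paired_freq * n + 0.5).astype(int)
    pvals = _minlike_pvalues(x, n, p)
    m = len(keys)
    p_bonf = np.minimum(1.0, m * pvals)
    results = []
    for i, key in enumerate(keys):
        if p_bonf[i] < alpha:
            call = "enriched" if x[i] > n * p[i] else "depleted"
        else:
            call = "neutral"
        results.append(
            SharingTestResult(key, float(p[i]), n, int(x[i]), float(pvals[i]),
                              float(p_bonf[i]), call)
        )
    return results


def diversity_trajectory(series_list, groups: dict[str, str] | None = None,
                         paired_with_baseline: bool = True) -> pd.DataFrame:
    """Group-wise diversity medians per timepoint with paired signed-rank tests.

    Each patient contributes one normalized Shannon diversity value per
    timepoint. For every group and non-baseline timepoint, a paired
    Wilcoxon signed-rank test compares patients observed at both the
    baseline and that timepoint; with fewer than two informative pairs the
    test is omitted with a warning.
    """
    rows = []
    for series in series_list:
        grp = (groups or {}).get(series.patient_id, "all")
        for rep in series.repertoires:
            rows.append((grp, series.patient_id, rep.timepoint,
                         normalized_shannon(rep)))
    df = pd.DataFrame(rows, columns=["group", "patient_id", "timepoint", "diversity"])
    out = []
    for (grp, tp), sub in df.groupby(["group", "timepoint"], sort=False):
        vals = sub["diversity"].to_numpy()
        rec = {
            "group": grp, "timepoint": tp, "n": len(vals),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "p_signed_rank_vs_baseline": np.nan,
        }
        base_tp = df[df["group"] == grp]["timepoint"].iloc[0]
        if paired_with_baseline and tp != base_tp:
            base = df[(df["group"] == grp) & (df["timepoint"] == base_tp)]
            merged = sub.merge(base, on="patient_id", suffixes=("", "_base"))
            diffs = merged["diversity"] - merged["diversity_base"]
            if len(merged) < 2:
                warnings.warn(
                    f"group {grp!r} timepoint {tp!r}: <2 paired patients, "
                    "signed-rank test omitted", stacklevel=2)
            elif np.allclose(diffs, 0):
                rec["p_signed_rank_vs_baseline"] = 1.0
            else:
                rec["p_signed_rank_vs_baseline"] = float(
                    stats.wilcoxon(merged["diversity"], merged["diversity_base"]).pvalue
                )
        out.append(rec)
    return pd.DataFrame(out)
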