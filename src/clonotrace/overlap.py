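"""Blood–tumor (and blood–blood) repertoire overlap analysis.

Overlapping clones are determined by exact CDR3β nucleotide identity. The
overlap of a pair of repertoires is summarized by the number of common
clones and the total frequency (mass) those clones carry on each side.
Sharing as a function of clone size is profiled by binning the reference
repertoire's clones uniformly in log10 frequency and reporting the percent
shared per bin; the sizes of shared clones in the two compartments are
compared by rank correlation and a log-log linear fit, with per-clone
enrichment calls from the random-sharing binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import binomial_sharing_test
from .repertoire import Repertoire


@dataclass(frozen=True)
class OverlapSummary:
    sample_a: str
    sample_b: str
    n_common: int
    mass_common_in_a: float
    mass_common_in_b: float


@dataclass(frozen=True)
class SharedCloneComparison:
    clone_key: str
    freq_a: float
    freq_b: float
    enrichment_call: str = "neutral"


def common_clones(a: Repertoire, b: Repertoire) -> list[SharedCloneComparison]:
    """Clones present in both repertoires, with their two frequencies."""
    shared = sorted(set(a.clones) & set(b.clones))
    return [
        SharedCloneComparison(k, a.clones[k].frequency, b.clones[k].frequency)
        for k in shared
    ]


def overlap_summary(a: Repertoire, b: Repertoire) -> OverlapSummary:
    shared = common_clones(a, b)
    return OverlapSummary(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_common=len(shared),
        mass_common_in_a=float(sum(c.freq_a for c in shared)),
        mass_common_in_b=float(sum(c.freq_b for c in shared)),
    )


def sharing_by_size_bin(a: Repertoire, b: Repertoire, n_bins: int = 10,
                        reference: str = "a") -> pd.DataFrame:
    """Percent of reference-repertoire clones shared, per log10-size bin.

    Bins span [min, max] of the reference repertoire's log10 frequencies;
    the top edge is right-closed so the largest clone falls in the last
    bin. Empty bins are omitted. ``bin_hi`` is the plotting x-coordinate
    (the end of the bin).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ref, other = (a, b) if reference == "a" else (b, a)
    keys = list(ref.clones)
    logf = np.log10(ref.frequencies)
    shared = np.array([k in other.clones for k in keys])
    lo, hi = logf.min(), logf.max()
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo - .5, lo + .5])
    idx = np.clip(np.searchsorted(edges, logf, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for bin_ in range(len(edges) - 1):
        mask = idx == bin_
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            {
                "bin_lo": edges[bin_],
                "bin_hi": edges[bin_ + 1],
                "n_clones": n,
                "pct_common": 100.0 * float(shared[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def shared_size_correlation(a: Repertoire, b: Repertoire,
                            restrict_keys=None, alpha: float = 0.05):
    """Rank correlation and log-log linear fit of shared-clone sizes.

    Returns ``(rho, slope, intercept, comparisons)`` where ``rho`` is the
    Spearman correlation of log10 frequencies, the slope/intercept are an
    ordinary least-squares fit of log10 freq_b on log10 freq_a, and
    ``comparisons`` carries per-clone enrichment calls from the binomial
    sharing test with ``a`` as baseline. With fewer than three shared
    clones after restriction the correlation is omitted (NaNs) with a
    warning.
    """
    shared = common_clones(a, b)
    if restrict_keys is not None:
        restrict = set(restrict_keys)
        shared = [c for c in shared if c.clone_key in restrict]
    calls = {
        r.clone_key: r.call
        for r in binomial_sharing_test(a, b, alpha=alpha)
    }
    shared = [
        SharedCloneComparison(c.clone_key, c.freq_a, c.freq_b,
                              calls.get(c.clone_key, "neutral"))
        for c in shared
    ]
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared clones; correlation omitted",
                      stacklevel=2)
        return np.nan, np.nan, np.nan, shared
    la = np.log10([c.freq_a for c in shared])
    lb = np.log10([c.freq_b for c in shared])
    rho = float(stats.spearmanr(la, lb).statistic)
    slope, intercept = np.polyfit(la, lb, 1)
    return rho, float(slope), float(intercept), shared
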