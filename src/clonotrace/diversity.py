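"""Repertoire-level diversity and clonal-expansion statistics.

The central statistic is the normalized Shannon diversity index (Pielou
evenness):

    D = -(1 / log N) * sum_i p_i * log p_i

where N is the number of unique clones and p_i the frequency of clone i.
D = 1 for a perfectly even repertoire and decreases as the repertoire is
dominated by expanded clones. Clones above a fixed frequency threshold
(default 0.2% of the repertoire) are classed *hyper-expanded*; the total
frequency carried by those clones is the hyper-expanded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import Repertoire

#: clone frequency above which a clone is called hyper-expanded
HYPEREXPANDED_THRESHOLD = 0.002


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    n_clones: int
    normalized_shannon: float
    hyperexpanded_fraction: float
    n_hyperexpanded: int
    pct_unique_hyperexpanded: float


def normalized_shannon(rep: Repertoire) -> float:
    """Normalized Shannon diversity index of a repertoire.

    Returns a value in [0, 1]; the logarithm base cancels. A single-clone
    repertoire (N = 1, where the normalization log N vanishes) returns 0,
    the limit of a maximally uneven repertoire.
    """
    rep.check_normalized()
    p = rep.frequencies
    n = rep.n_clones
    if n == 1:
        return 0.0
    p = p[p > 0]
    entropy = -float(np.sum(p * np.log(p)))
    value = entropy / np.log(n)
    # clip float noise at the uniform boundary
    return float(min(max(value, 0.0), 1.0))


def classify_expansion(rep: Repertoire,
                       threshold: float = HYPEREXPANDED_THRESHOLD) -> dict[str, str]:
    """Label each clone ``hyper_expanded`` (frequency strictly above the
    threshold) or ``non_expanded``; a clone exactly at the threshold is
    non-expanded."""
    return {
        k: "hyper_expanded" if c.frequency > threshold else "non_expanded"
        for k, c in rep.clones.items()
    }


def hyperexpanded_fraction(rep: Repertoire,
                           threshold: float = HYPEREXPANDED_THRESHOLD) -> float:
    """Total frequency carried by clones above the expansion threshold.

    Summed in clone order so the result is bit-identical to adding up the
    frequencies of the clones labelled hyper-expanded by
    :func:`classify_expansion`.
    """
    return float(sum(c.frequency for c in rep.clones.values()
                     if c.frequency > threshold))


def diversity_summary(rep: Repertoire,
                      threshold: float = HYPEREXPANDED_THRESHOLD) -> DiversitySummary:
    labels = classify_expansion(rep, threshold)
    n_hyper = sum(1 for v in labels.values() if v == "hyper_expanded")
    return DiversitySummary(
        sample_id=rep.sample_id,
        n_clones=rep.n_clones,
        normalized_shannon=normalized_shannon(rep),
        hyperexpanded_fraction=hyperexpanded_fraction(rep, threshold),
        n_hyperexpanded=n_hyper,
        pct_unique_hyperexpanded=100.0 * n_hyper / rep.n_clones,
    )


def weighted_size_distribution(rep: Repertoire, n_bins: int = 30) -> pd.DataFrame:
    """Clone-size histogram over log10 frequency, weighted by frequency.

    Weighting each clone by its own frequency turns the clone-level
    histogram into a distribution of *cells* over clone sizes; bin masses
    sum to 1. Bins are uniform in log10 frequency between the observed
    minimum and maximum (a single distinct size collapses to one bin).
    """
    p = rep.frequencies
    logp = np.log10(p)
    lo, hi = float(logp.min()), float(logp.max())
    if hi - lo < 1e-12:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    mass, edges = np.histogram(logp, bins=edges, weights=p)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "mass": mass / p.sum()}
    )


def top_clones_by_cumulative_mass(rep: Repertoire, mass: float = 0.75) -> Repertoire:
    """Smallest set of top clones whose cumulative frequency reaches ``mass``.

    Clones are taken in descending frequency order (ties broken by clone
    key) until the cumulative frequency is >= ``mass``. Used for bubble-plot
    style displays showing the top clones carrying e.g. 75% of the
    repertoire.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    order = sorted(rep.clones.values(), key=lambda c: (-c.frequency, c.cdr3_nt))
    keys, cum = [], 0.0
    for clone in order:
        keys.append(clone.cdr3_nt)
        cum += clone.frequency
        if cum >= mass - 1e-12:
            break
    return rep.subset(keys)
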