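# Methods

This note records the statistical model behind each module, the default
parameters and why they were chosen, the scope of the synthetic-data
generators, and the numerical conventions that matter for reproducing
results exactly.

## Clone tables and filtering

A clone is keyed by its CDR3β **nucleotide** sequence; amino-acid identity
is used only for specificity inference. Rows of an input table sharing a
key are merged: read counts are summed and the majority V/J call is kept.
Productivity requires an in-frame junction whose translation contains no
stop codon and matches the reported amino-acid sequence when present.

The standard filter (`apply_clone_filters`) removes non-productive clones
and clones with **fewer than 50 reads** (a clone with exactly 50 reads is
kept), then renormalizes frequencies over the retained clones. The 50-read
floor suppresses sequencing artifacts and makes frequencies comparable
across samples of different depth; all downstream statistics are computed
on filtered, renormalized tables unless stated otherwise.

Supported dialects: AIRR Rearrangement TSV (`junction`, `junction_aa`,
`v_call`, `j_call`, `duplicate_count`, `productive`) and MiXCR export
(`cloneCount`, `nSeqCDR3`, `aaSeqCDR3`, `bestVHit`/`allVHitsWithScore`,
with productivity inferred from the junction when absent). Gene names are
stripped of allele suffixes and score annotations.

## Diversity and expansion

Normalized Shannon diversity (Pielou evenness) of frequencies *p₁…p_N*:

    H_norm = −(1/log N) Σ pᵢ log pᵢ

Conventions: a single-clone repertoire has `H_norm = 0` (the `log N = 0`
limit); terms with `pᵢ = 0` contribute 0. A clone is **hyper-expanded**
when its frequency is **strictly greater than 0.002**; exact equality is
non-expanded. `hyperexpanded_fraction` sums clone frequencies in clone
order with plain sequential addition so that it is bit-identical to
summing the frequencies of the clones labelled hyper-expanded by
`classify_expansion`.

## Longitudinal dynamics

Persistence labels partition the clones observed anywhere in a patient's
series: **persistent** = detected in all samples, **recurrent** = in more
than one but not all, **transient** = in exactly one. Detection is
post-filter presence of the clone key. Single-sample series are rejected
rather than labelled.

**Random-sharing binomial test.** Null: the paired sample is a multinomial
draw from baseline clone frequencies. For each baseline clone with
frequency *p*, the trial count is *n* = the paired sample's **unique clone
count** (a deliberate lower bound on the number of cells surveyed, making
the test conservative), and the observed success count is
*x* = round(paired frequency × *n*), rounding half away from zero. The
two-sided p-value uses the **minimum-likelihood (minlike)** definition:
the sum of Pr(X = k) over all k with Pr(X = k) ≤ Pr(X = x), evaluated by
full enumeration of the pmf with a relative tie guard of 1e-12 (a k whose
pmf exceeds the observed pmf by less than one part in 10¹² is counted in
the tail; this makes the inclusion decision stable against floating-point
noise). The p-value enumeration is implemented in-repo because library
implementations use a looser tie guard (~1e-7) that can change tail
membership at the tolerances we verify against. Bonferroni correction uses
m = the number of baseline clones tested in that comparison. Calls:
`enriched` if significant and x > np, `depleted` if significant and
x < np, else `neutral`. Clones private to the paired sample have no
baseline frequency to serve as a null and are not tested.

## Compartment overlap

Clones are shared when their nucleotide sequences are identical. Sharing
vs clone size bins the **reference** repertoire's clones uniformly in
log10 frequency: the top edge is right-closed so the largest clone falls
in the last bin, empty bins are omitted from the output (not reported as
zero), and `bin_hi` is the plotting coordinate. Shared-clone sizes are
compared by Spearman correlation of log10 frequencies and an ordinary
least-squares fit of log10 freq_b on log10 freq_a; fewer than three shared
clones yields NaNs with a warning. Per-clone enrichment calls reuse the
binomial sharing test with the reference side as baseline.

## Specificity inference

A simplified GLIPH-style procedure on CDR3β amino-acid sequences:

- Sequences of length ≥ 25 residues are excluded as junction artifacts.
- **Local clusters**: interior k-mers (first and last 3 residues trimmed,
  k ∈ {3, 4}) whose frequency among input sequences is ≥ 10× their
  frequency in a naive background pool, occurring in ≥ 3 unique
  sequences. Unseen background motifs get a pseudocount of 1/(n_bg + 1).
- **Global clusters**: connected components of equal-length sequences at
  Hamming distance ≤ 1 with ≥ 3 members.
- Clustering is frequency-independent; a clone may join several clusters.
- **High-confidence filter**: ≥ 3 unique sequences, ≥ 3 patients, and a
  biased Vβ usage (one-sided binomial test of the cluster's modal V
  proportion against the cohort's modal-V proportion).
- **Annotation** is two-step: the clustering is re-run with reference
  sequences of known specificity added as pseudo-clones; clusters are
  matched by id between the runs, and a cluster inherits the most common
  named antigen among captured reference sequences. Lexicographic
  tie-breaks are flagged (`antigen_tie`). A clone annotated by several
  clusters takes the largest cluster's antigen.
- **Expansion-target association**: 2×2 Fisher exact test of
  {has inferred target} × {hyper-expanded}, plus per-antigen one-sided
  tests with Benjamini–Hochberg adjustment. Degenerate tables report
  `odds_ratio = None` with a note (direction of unboundedness when only
  one cell is empty); the p-value is still computed when defined.

## Survival

`median_split` assigns "low" to values **strictly below** the cohort
median; an all-equal cohort is rejected as degenerate. Kaplan–Meier
estimation and the log-rank test use lifelines. The Cox
proportional-hazards fit is implemented in-repo (it is exercised directly
by the acceptance properties): Newton–Raphson on the Breslow partial
likelihood with covariates centered for numerical stability, step-halving
with an acceptance tolerance scaled to the log-likelihood magnitude
(1e-9·(|ℓ|+1)), convergence when the largest score component falls below
1e-8 or the Newton step falls below 1e-10, at most 50 iterations. Monotone
likelihood (complete separation) is reported via an `unbounded` flag
(triggered by |β| > 20 or a singular information matrix) rather than
raised. The result exposes Wald confidence intervals and p-values, the
likelihood-ratio p-value, and the score statistic at β = 0 — which equals
the log-rank statistic for a binary covariate in the absence of ties
(verified to 1e-6 relative error). The in-repo fit is cross-checked
against lifelines' `CoxPHFitter` in the test suite.

## Synthetic-data generators

All generators are deterministic given a seed: random streams are
`numpy.random.default_rng([seed, stream...])` where per-sample stream ids
come from CRC-32 of the sample name (process-independent, unlike Python's
salted `hash`). Seeds are reduced modulo 2³¹.

- **Repertoire**: latent background frequencies are lognormal
  (σ = 1.0 by default) over `n_background_clones = 5000`, plus
  `n_hyperexpanded` injected clones with target frequencies
  Uniform(0.002, 0.15). σ = 1.0 with N = 5000 keeps the background bulk
  below the 0.002 threshold so that injected clones — not the background
  tail — carry the hyper-expanded mass; a heavier tail (e.g. σ = 1.5)
  blurs the two-class structure. If the drawn hyper-expanded mass reaches
  1 the configuration is rejected with an error rather than silently
  renormalized. Reads are a multinomial draw (10⁶ by default), so small
  clones drop out purely through finite sampling — this is the only
  detection mechanism, and it produces the size-dependent persistence
  structure.
- **Series**: per-timepoint lognormal drift (sd 0.2 in log frequency) and
  an optional post-treatment multiplier on non-expanded clones
  (`nonexpanded_depletion`).
- **Paired tumor**: each blood clone is shared with probability
  logistic(8.0 + 2.5·log10 f); shared clones carry 40% of tumor mass,
  the rest goes to private tumor clones.
- **Motifs/reference**: planted groups of clones carrying a common
  interior 4-mer, spread over ≥ 3 patients with a shared V gene; reference
  pairs carry the same motifs plus decoys; a 20,000-sequence naive pool
  provides the motif background.
- **Outcomes**: exponential event times with hazard
  h₀ · HR^{I(low diversity)} (defaults h₀ = 0.02/month, HR = 2.0) and
  independent Uniform(0, 120) censoring.

**Scope and limitations.** The generators are designed to exercise the
analysis code under known truth, not to be biologically calibrated: clone
sequences are cosmetic (stop-free random codons framed C…F), V/J calls
are arbitrary labels, drift is stationary lognormal rather than
antigen-driven, tumor sharing depends only on blood clone size, and
outcomes depend on diversity only through the median-split group. Problem
sizes in the tests and acceptance script (clone counts, read depths,
replicate counts) are chosen for statistical power within desk-scale
runtimes, not to mirror any particular study.

## Pipeline

`run_pipeline` drives simulate → filter → diversity → dynamics → overlap →
annotate → survival from a single YAML config (unknown keys are rejected;
invalid parameters fail before any compute). Outputs are TSV/JSON with
floats formatted `%.10g`, a parameter header line per table, and a run
manifest recording the package version, full parameter set and SHA-256
checksums of all simulated inputs — no timestamps, so identical configs
rerun byte-identically. Input validation produces machine-readable
diagnostics; duplicate (patient, compartment, timepoint) axes are errors,
while a patient missing from the clinical table is a warning (excluded
from survival analysis only).
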