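# clonotrace

Analysis of T-cell receptor (TCR) CDR3β clone tables: repertoire
diversity, longitudinal clone tracking, blood–tumor overlap, sequence-based
antigen-specificity inference, and survival association — with a matching
synthetic-data generator and an end-to-end pipeline.

The package targets the analysis style used in tumor-immunology repertoire
studies (e.g. bladder-cancer cohorts followed through chemotherapy and
cystectomy): clones are keyed by their CDR3β nucleotide sequence, small and
non-productive clones are filtered, and per-sample statistics are linked to
clinical outcome.

## Scientific model

**Clone table.** A sample is a set of clones, each with a CDR3β nucleotide
sequence (the clone key), its amino-acid translation, V/J gene calls, a
read count and a frequency. Readers are provided for AIRR Rearrangement TSV
and MiXCR export dialects; rows sharing a nucleotide sequence are merged.
The standard filter removes non-productive clones and clones with fewer
than 50 reads, then renormalizes frequencies.

**Diversity.** Repertoire evenness is the normalized Shannon entropy
(Pielou evenness) of clone frequencies *p₁…p_N*:

    H_norm = −(1/log N) · Σᵢ pᵢ log pᵢ

A clone is *hyper-expanded* when its frequency strictly exceeds 0.002
(0.2%). Evenness and the total frequency mass carried by hyper-expanded
clones are two views of the same clonality axis and are strongly
anti-correlated across patients.

**Clone tracking.** Across a patient's longitudinal samples a clone is
*persistent* (detected in all samples), *recurrent* (more than one, not
all) or *transient* (exactly one). Whether a clone's frequency in a paired
sample departs from random resampling of the baseline is tested with an
exact two-sided binomial test (minimum-likelihood tail): under the null the
paired sample is a multinomial draw from baseline frequencies, the trial
count is the paired sample's unique clone count, and Bonferroni correction
is applied over the baseline clones tested. Calls are
enriched / depleted / neutral.

**Compartment overlap.** Blood and tumor repertoires are intersected by
nucleotide identity; sharing is profiled across log10 clone-size bins
(larger blood clones are more likely to appear in the tumor), and the
sizes of shared clones are compared by Spearman correlation and a log-log
linear fit.

**Specificity inference.** A simplified GLIPH-style clustering groups
CDR3β amino-acid sequences by *local* similarity (shared interior 3-/4-mers
enriched ≥10-fold over a naive background) and *global* similarity
(Hamming distance 1 at equal length). Clusters are annotated by re-running
the clustering with VDJdb-style reference sequences of known specificity
mixed in; a cluster inherits the most common named antigen among the
reference sequences it captures. Enrichment of inferred targets among
hyper-expanded clones is tested with Fisher's exact test
(Benjamini–Hochberg across antigens).

**Survival.** Patients are split at the cohort median of a repertoire
statistic (strictly-below-median = "low"); groups are compared with
Kaplan–Meier curves and the log-rank test, and effect sizes come from a
Cox proportional-hazards fit (Breslow tie handling, Newton–Raphson).

**Synthetic data.** Generators simulate every data type above under known
truth: lognormal background clone sizes plus injected hyper-expanded
clones, multinomial read sampling, longitudinal drift and treatment
depletion, logistic size-dependent blood→tumor sharing, planted CDR3 motif
groups with matching reference pairs, and exponential survival outcomes
with a configurable hazard ratio. Everything is deterministic given a
seed.

## Quick start (CLI)

```bash
# full synthetic-cohort pipeline from the bundled config
clonotrace run --config configs/demo.yaml

# per-sample diversity from a manifest of AIRR TSV files
clonotrace diversity --manifest manifest.csv --out diversity.tsv

# clone tracking across a patient's timepoints
clonotrace dynamics --manifest manifest.csv \
    --out-labels persistence.tsv --out-tests sharing_tests.tsv

# blood-tumor overlap for one pair of clone tables
clonotrace overlap --pair blood.tsv tumor.tsv --out overlap.tsv
```

The manifest is a CSV with columns `sample_id, patient_id, compartment,
timepoint, path`.

## Worked example (library)

Simulate one patient followed over three timepoints, apply the standard
filters, and run the core analyses:

```python
from collections import Counter
from clonotrace.diversity import diversity_summary
from clonotrace.dynamics import binomial_sharing_test, classify_persistence
from clonotrace.io import apply_clone_filters
from clonotrace.overlap import overlap_summary
from clonotrace.simulate import (SimConfig, simulate_paired_tumor,
                                 simulate_series)

cfg = SimConfig(seed=7, n_background_clones=2000, total_reads=500_000,
                n_hyperexpanded=4, n_timepoints=3,
                nonexpanded_depletion=0.6)
series, truth = simulate_series(cfg, patient_id="P001")
series.repertoires = [apply_clone_filters(r) for r in series.repertoires]

for rep in series.repertoires:
    s = diversity_summary(rep)
    print(rep.sample_id, s.n_clones, round(s.normalized_shannon, 3),
          round(s.hyperexpanded_fraction, 3))

print(Counter(l.label for l in classify_persistence(series).values()))
tests = binomial_sharing_test(series.baseline, series.repertoires[1])
print(Counter(t.call for t in tests))

tumor = apply_clone_filters(simulate_paired_tumor(series.baseline, cfg))
ov = overlap_summary(series.baseline, tumor)
print(ov.n_common, round(ov.mass_common_in_a, 3),
      round(ov.mass_common_in_b, 3))
```

Output:

```
P001_baseline 1588 0.797 0.368
P001_post_chemo 1380 0.692 0.497
P001_post_cystectomy 1381 0.699 0.485
Counter({'persistent': 1293, 'transient': 166, 'recurrent': 152})
Counter({'neutral': 1586, 'enriched': 2})
355 0.593 0.41
```

Treatment depletes mostly small, non-expanded clones, so evenness drops
while hyper-expanded mass rises; most observed clones persist across all
three samples; the binomial sharing test is conservative and flags only
clones with strong frequency shifts; roughly a third of baseline blood
clones are found in the paired tumor, and they carry a disproportionate
share of mass on both sides.

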