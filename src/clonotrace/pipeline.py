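"""End-to-end pipeline orchestration.

Runs simulate → filter → diversity → dynamics → overlap → annotate →
survival from a single config, writing one tabular report per stage plus a
run manifest (parameters, package version, input checksums) sufficient to
reproduce every output. All stages are deterministic given the config seed
and single-threaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_summary
from .dynamics import (PatientSeries, binomial_sharing_test,
                       classify_persistence, persistent_recurrent_baseline_mass)
from .io import (load_manifest_repertoires, read_manifest, write_airr,
                 write_reference_pairs, read_reference_pairs)
from .overlap import overlap_summary, sharing_by_size_bin
from .simulate import SimConfig, simulate_paired_tumor, simulate_series, \
    simulate_cohort_outcomes, simulate_reference_and_motifs
from .specificity import (annotate_two_step, build_clusters,
                          expansion_target_association, motif_background_table)
from .diversity import classify_expansion, normalized_shannon
from .survival import SurvivalRecord, cox_fit, group_test, median_split

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    out_dir: str = "clonotrace_out"
    seed: int = 0
    n_patients: int = 6
    n_timepoints: int = 3
    # repertoire scale (kept modest; scale up for production runs)
    n_background_clones: int = 800
    n_hyperexpanded: int = 4
    total_reads: int = 200_000
    nonexpanded_depletion: float = 0.6
    # analysis parameters (defaults follow the published analysis)
    min_reads: int = 50
    expansion_threshold: float = 0.002
    alpha: float = 0.05
    n_bins: int = 10
    ks: tuple = (3, 4)
    enrichment_fold: float = 10.0
    min_count: int = 3
    min_seqs: int = 3
    min_patients: int = 3
    split: str = "median"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ks" in data:
            data["ks"] = tuple(data["ks"])
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.expansion_threshold < 1:
            raise ValueError("expansion_threshold must be in (0, 1)")
        if self.min_reads < 0 or self.n_patients < 2:
            raise ValueError("min_reads >= 0 and n_patients >= 2 required")


def validate_inputs(manifest: pd.DataFrame,
                    clinical: pd.DataFrame | None = None) -> list[dict]:
    """Machine-readable diagnostics for manifest/clinical consistency."""
    diags: list[dict] = []
    dup = manifest.duplicated(subset=["patient_id", "compartment", "timepoint"])
    for _, row in manifest[dup].iterrows():
        diags.append({"level": "error", "code": "duplicate_sample",
                      "sample_id": row["sample_id"]})
    for _, row in manifest.iterrows():
        if not Path(row["path"]).exists():
            diags.append({"level": "error", "code": "missing_file",
                          "sample_id": row["sample_id"], "path": row["path"]})
    if clinical is not None:
        clin_ids = set(clinical["patient_id"])
        for pid in sorted(set(manifest["patient_id"]) - clin_ids):
            diags.append({"level": "warning", "code": "no_clinical_record",
                          "patient_id": pid,
                          "note": "patient excluded from survival analysis only"})
    return diags


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    header = "# " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns paths of the outputs."""
    config.validate()
    out = Path(config.out_dir)
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(seed=config.seed,
                    n_background_clones=config.n_background_clones,
                    n_hyperexpanded=config.n_hyperexpanded,
                    total_reads=config.total_reads,
                    n_timepoints=config.n_timepoints,
                    nonexpanded_depletion=config.nonexpanded_depletion,
                    tumor_private_clones=max(200, config.n_background_clones // 2),
                    tumor_total_reads=config.total_reads // 2,
                    n_planted_groups=4, planted_group_size=6)

    # ---- simulate cohort and write inputs as AIRR TSV ------------------
    manifest_rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        # vary expansion burden across patients; cap at 6 injected clones so
        # the drawn target mass stays safely below 1 for any seed
        series, _truth = simulate_series(
            dataclasses.replace(sim, n_hyperexpanded=(i % 4) * 2), pid)
        for rep in series.repertoires:
            path = sim_dir / f"{rep.sample_id}.tsv"
            write_airr(rep, path)
            manifest_rows.append((rep.sample_id, pid, rep.compartment,
                                  rep.timepoint, str(path)))
        tumor = simulate_paired_tumor(series.baseline, sim)
        tpath = sim_dir / f"{tumor.sample_id}.tsv"
        write_airr(tumor, tpath)
        manifest_rows.append((tumor.sample_id, pid, "tumor",
                              tumor.timepoint, str(tpath)))
    manifest = pd.DataFrame(manifest_rows, columns=["sample_id", "patient_id",
                                                    "compartment", "timepoint",
                                                    "path"])
    manifest.to_csv(sim_dir / "manifest.csv", index=False)

    diags = validate_inputs(manifest)
    if any(d["level"] == "error" for d in diags):
        raise RuntimeError(f"input validation failed: {diags}")

    reps = load_manifest_repertoires(manifest, min_reads=config.min_reads)

    # ---- diversity ------------------------------------------------------
    tp_order = {tp: i for i, tp in
                enumerate(dict.fromkeys(manifest["timepoint"]))}
    div_rows = [dataclasses.asdict(
        diversity_summary(rep, config.expansion_threshold))
        for rep in reps.values()]
    diversity_df = pd.DataFrame(div_rows)
    _write_tsv(diversity_df, out / "diversity.tsv",
               {"threshold": config.expansion_threshold,
                "min_reads": config.min_reads})

    # ---- longitudinal dynamics -----------------------------------------
    series_by_patient: dict[str, PatientSeries] = {}
    for pid, sub in manifest[manifest["compartment"] == "blood"].groupby(
            "patient_id"):
        ordered = sub.sort_values("timepoint",
                                  key=lambda s: s.map(tp_order))
        series_by_patient[pid] = PatientSeries(
            pid, [reps[s] for s in ordered["sample_id"]])
    persist_rows, test_rows = [], []
    for pid, series in series_by_patient.items():
        labels = classify_persistence(series)
        mass = persistent_recurrent_baseline_mass(series)
        for lab in labels.values():
            persist_rows.append((pid, lab.clone_key, lab.label,
                                 lab.n_samples_detected, lab.n_samples_total,
                                 mass))
        for rep in series.repertoires[1:]:
            for r in binomial_sharing_test(series.baseline, rep,
                                           alpha=config.alpha):
                test_rows.append((pid, rep.sample_id, r.clone_key,
                                  r.baseline_freq, r.trials, r.observed,
                                  r.p_value, r.p_bonferroni, r.call))
    _write_tsv(pd.DataFrame(
        persist_rows, columns=["patient_id", "cdr3_nt", "label",
                               "n_detected", "n_total",
                               "persistent_recurrent_baseline_mass"]),
        out / "persistence.tsv", {"min_reads": config.min_reads})
    _write_tsv(pd.DataFrame(
        test_rows, columns=["patient_id", "sample_id", "cdr3_nt",
                            "baseline_freq", "trials", "observed", "p_value",
                            "p_bonferroni", "call"]),
        out / "sharing_tests.tsv", {"alpha": config.alpha})

    # ---- blood-tumor overlap -------------------------------------------
    overlap_rows = []
    for pid, series in series_by_patient.items():
        tumor_id = series.baseline.sample_id + "_tumor"
        if tumor_id not in reps:
            continue
        s = overlap_summary(series.baseline, reps[tumor_id])
        overlap_rows.append(dataclasses.asdict(s))
    _write_tsv(pd.DataFrame(overlap_rows), out / "overlap.tsv",
               {"n_bins": config.n_bins})

    # ---- specificity annotation ----------------------------------------
    clones, reference, naive_pool, _truth = simulate_reference_and_motifs(sim)
    background = motif_background_table(naive_pool, ks=config.ks)
    run1 = build_clusters(clones, background, ks=config.ks,
                          enrichment_fold=config.enrichment_fold,
                          min_count=config.min_count)
    annotation = annotate_two_step(run1, clones, reference, background,
                                   ks=config.ks,
                                   enrichment_fold=config.enrichment_fold,
                                   min_count=config.min_count)
    ann_df = pd.DataFrame(
        sorted(annotation.clone_antigen.items()),
        columns=["cdr3_aa", "inferred_antigen"],
    )
    _write_tsv(ann_df, out / "annotations.tsv",
               {"ks": config.ks, "enrichment_fold": config.enrichment_fold,
                "min_count": config.min_count})

    # ---- survival -------------------------------------------------------
    baseline_div = {
        pid: normalized_shannon(series.baseline)
        for pid, series in series_by_patient.items()
    }
    records, groups = simulate_cohort_outcomes(baseline_div, sim)
    clinical = pd.DataFrame(
        {"patient_id": [r.patient_id for r in records],
         "time_months": [r.time for r in records],
         "event": [int(r.event) for r in records]})
    clinical.to_csv(sim_dir / "clinical.csv", index=False,
                    float_format=_FLOAT_FMT)
    chi2, lr_p, cox_lrt_p = group_test(records, groups)
    cox = cox_fit(records, ["diversity_group_low"])
    survival = {
        "split": config.split,
        "groups": {k: groups[k] for k in sorted(groups)},
        "logrank_chi2": chi2,
        "logrank_p": lr_p,
        "cox_lrt_p": cox_lrt_p,
        "hr": float(cox.hr[0]),
        "hr_ci": [float(cox.ci_low[0]), float(cox.ci_high[0])],
        "wald_p": float(cox.wald_p[0]),
        "unbounded": bool(cox.unbounded),
    }
    (out / "survival.json").write_text(json.dumps(survival, indent=2,
                                                  sort_keys=True) + "\n")

    # ---- run manifest ---------------------------------------------------
    outputs = ["diversity.tsv", "persistence.tsv", "sharing_tests.tsv",
               "overlap.tsv", "annotations.tsv", "survival.json"]
    run_manifest = {
        "version": __version__,
        "parameters": {f.name: _jsonable(getattr(config, f.name))
                       for f in dataclasses.fields(config)},
        "input_checksums": {
            row["sample_id"]: _checksum(Path(row["path"]))
            for _, row in manifest.iterrows()
        },
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    return {name: str(out / name) for name in outputs + ["run_manifest.json"]}


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v
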