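"""End-to-end orchestration: config-driven runs with a reproducibility manifest.

Stages hand off through plain files (TSV/JSON) so any stage can be
audited or rerun in isolation; one top-level seed expands
deterministically into per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import io as bio
from .batch import batch_variance_reduction, corrected_dataset, eb_batch_correct
from .classify import ModelSpec, loco_cv, tune_final
from .core_taxa import consensus, feature_directions, healthy_prevalence, index_discriminative_set
from .classify import feature_importance
from .datamodel import AnalysisConfig
from .diffmeta import classify_directions, cohort_association, pool_associations
from .ecology import distance_matrix, permanova, shannon
from .health_index import HealthIndex, evaluate_index
from .qc import filter_samples, filter_species
from .simulate import SimulationParams, simulate_dataset

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    sim_params: Optional[SimulationParams] = None,
    profiles_path: Optional[str] = None,
    metadata_path: Optional[str] = None,
    cfg: Optional[AnalysisConfig] = None,
    spec: Optional[ModelSpec] = None,
    seed: int = 0,
    batch_correct: bool = True,
    n_permutations: int = 199,
) -> dict[str, Any]:
    """Run simulate/ingest -> QC -> correction -> ecology -> differential
    meta-analysis -> LOCO classification -> health index -> core taxa.

    Returns the run manifest (also written to ``manifest.json``).
    Intended for modest problem sizes; every threshold and seed used is
    recorded in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or AnalysisConfig()
    spec = spec or ModelSpec(search_budget=8, seed=stage_seed(seed, "model"))
    manifest: dict[str, Any] = {
        "seed": seed,
        "config": cfg.to_dict(),
        "model_spec": {
            "family": spec.family,
            "search_budget": spec.search_budget,
            "k_grid": list(spec.k_grid),
        },
        "stages": [],
        "outputs": {},
    }

    # --- data preparation
    if sim_params is not None:
        sim_params = dataclasses.replace(sim_params, seed=stage_seed(seed, "simulate"))
        ds = simulate_dataset(sim_params)
        manifest["stages"].append("simulate")
        manifest["simulation"] = dataclasses.asdict(sim_params) | {
            "zero_inflation_range": list(sim_params.zero_inflation_range),
            "unclassified_beta": list(sim_params.unclassified_beta),
        }
    else:
        if not (profiles_path and metadata_path):
            raise ValueError("either sim_params or profiles+metadata paths required")
        table = bio.read_profile_table(profiles_path)
        records = bio.read_metadata(metadata_path)
        ds = bio.align_dataset(table, records)
        manifest["stages"].append("ingest")
        manifest["inputs"] = {
            "profiles": file_checksum(profiles_path),
            "metadata": file_checksum(metadata_path),
        }

    # --- QC
    ds_qc, sample_audit = filter_samples(ds, cfg)
    ds_qc, taxon_audit = filter_species(ds_qc, cfg)
    sample_audit.to_frame().to_csv(out / "qc_sample_audit.tsv", sep="\t", index=False)
    taxon_audit.to_frame().to_csv(out / "qc_taxon_audit.tsv", sep="\t", index=False)
    manifest["stages"].append("qc")
    manifest["qc"] = {
        "samples_before": sample_audit.n_samples_before,
        "samples_after": sample_audit.n_samples_after,
        "taxa_before": taxon_audit.n_taxa_before,
        "taxa_after": taxon_audit.n_taxa_after,
    }

    # --- batch correction
    if batch_correct and len(ds_qc.study_ids) >= 2:
        result = eb_batch_correct(ds_qc)
        ds_model = corrected_dataset(ds_qc, result)
        red = batch_variance_reduction(
            ds_qc, ds_model, n_permutations=n_permutations, seed=stage_seed(seed, "permanova")
        )
        manifest["stages"].append("batch_correction")
        manifest["batch_correction"] = {
            "r2_before": red["before"].r_squared,
            "r2_after": red["after"].r_squared,
            "percent_reduction": red["percent_reduction"],
        }
        bio.write_profile_table(ds_model.profiles, out / "corrected_profiles.tsv")
    else:
        ds_model = ds_qc

    # --- ecology
    X = ds_model.profiles.values
    sh = [shannon(row) for row in X]
    d = distance_matrix(X, ds_model.sample_ids, "bray_curtis")
    perm = permanova(
        d, ["case" if c else "control" for c in ds_model.labels()],
        n_permutations=n_permutations, seed=stage_seed(seed, "ecology"),
    )
    manifest["stages"].append("ecology")
    manifest["ecology"] = {
        "shannon_median": float(np.median(sh)),
        "disease_permanova_r2": perm.r_squared,
        "disease_permanova_p": perm.p_value,
    }

    # --- differential + meta-analysis
    per_cohort = []
    for study in ds_model.study_ids:
        sub = ds_model.subset_studies([study])
        per_cohort.extend(cohort_association(sub, mode="abundance"))
    disease = next(s.disease for s in ds_model.samples if s.is_case)
    pooled = pool_associations(per_cohort, disease=disease, mode="abundance")
    classifications = classify_directions(pooled, q_threshold=cfg.fdr_threshold)
    n_sig = sum(1 for p in pooled if p.q < cfg.fdr_threshold)
    manifest["stages"].append("differential_meta")
    manifest["differential"] = {"n_taxa_tested": len(pooled), "n_significant": n_sig}

    # --- LOCO classification (log-abundance feature representation)
    from .classify import log_abundance

    y = ds_model.labels()
    X_model = log_abundance(X)
    loco = loco_cv(X_model, y, ds_model.studies(), spec=spec, seed=stage_seed(seed, "loco"))
    manifest["stages"].append("loco_cv")
    manifest["loco"] = {"per_cohort_auroc": loco.cohort_aurocs, "mean_auroc": loco.mean_auroc}

    feats = loco.consensus_features()
    if feats.size == 0:
        feats = next(iter(loco.selected_features.values()))
    model, tuning_auc, fit_auc = tune_final(
        X_model, y, feats, spec=spec, seed=stage_seed(seed, "final")
    )
    manifest["final_model"] = {
        "n_features": int(feats.size),
        "tuning_auroc": tuning_auc,
        "final_fit_auroc": fit_auc,
    }

    # --- health index
    hi = HealthIndex().fit(loco.oof_probabilities, y)
    index = hi.transform(loco.oof_probabilities)
    ev = evaluate_index(index, y, n_boot=200, seed=stage_seed(seed, "index"))
    manifest["stages"].append("health_index")
    manifest["health_index"] = {
        "threshold": hi.threshold_,
        "wilcoxon_p": ev.wilcoxon_p,
        "cliffs_delta": ev.cliffs_delta,
    }

    # --- core taxa
    taxa = ds_model.taxon_ids
    prev = healthy_prevalence(ds_model, cfg.abundance_cutoff)
    imp = feature_importance(model, [taxa[j] for j in model.feature_indices])
    dirs = feature_directions(model, X_model, taxa)
    idx_set = index_discriminative_set(imp, dirs)
    report = consensus(classifications, idx_set, prev, importance=imp,
                       prevalence_cutoff=cfg.prevalence_cutoff)
    (out / "core_taxa.json").write_text(report.to_json())
    manifest["stages"].append("core_taxa")
    manifest["core_taxa"] = {"n_consensus": len(report.consensus), "consensus": report.consensus}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
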