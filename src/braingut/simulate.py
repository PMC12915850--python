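"""Synthetic multi-study case-control microbiome cohorts with planted truth.

Generative family: zero-inflated log-normal latent abundances closed to
relative abundances.  Per sample, each taxon's latent log-abundance is

    base_log_mean + study_log_bias + is_case * disease_lfc + noise,

a structural-zero mask is applied, values are exponentiated and divided
by their total, then scaled by ``1 - unclassified_fraction``.  Batch
effects act multiplicatively per study-taxon (additively on logs), the
bias model the correction stage targets.  A chosen subset of taxa
carries a signed disease log2 fold change; "protective" taxa are planted
health-enriched (negative fold change), structurally present and
abundant, so the core-taxa consensus has a recoverable target.

One global seed expands into per-study substreams, so adding a study
never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import HEALTHY_LABEL, MultiStudyDataset, SampleRecord, TaxonProfileTable

_LN2 = float(np.log(2.0))


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a simulated dataset.

    disease_taxa maps taxon -> signed log2 fold change in cases;
    protective_taxa is the subset planted health-enriched, prevalent and
    discriminative; batch_bias maps study -> per-taxon multiplicative
    factors.
    """

    taxon_ids: list[str]
    disease_taxa: dict[str, float]
    protective_taxa: set[str]
    batch_bias: dict[str, np.ndarray]
    base_log_mean: np.ndarray
    base_log_sd: float
    zero_inflation: np.ndarray

    def __post_init__(self) -> None:
        for t in self.protective_taxa:
            if self.disease_taxa.get(t, 0.0) >= 0:
                raise ValueError(f"protective taxon {t!r} lacks a negative fold change")
        for study, f in self.batch_bias.items():
            if np.any(np.asarray(f) <= 0):
                raise ValueError(f"non-positive batch factor in study {study!r}")
        zi = np.asarray(self.zero_inflation)
        if np.any((zi < 0) | (zi > 1)):
            raise ValueError("zero_inflation outside [0, 1]")


@dataclass
class SimulationParams:
    """Knobs of the generative model.

    Defaults describe a moderate three-cohort case-control design: 50
    cases + 50 controls per study, 200 species, 10 disease-associated
    species at 1 log2 unit, per-study log-bias sd 0.5 — a regime where a
    sound pipeline should both detect the signal and see a real batch
    effect.  ``effect_size`` is in log2 units.
    """

    n_studies: int = 3
    cases_per_study: int = 50
    controls_per_study: int = 50
    n_taxa: int = 200
    n_disease_taxa: int = 10
    n_protective_taxa: int = 0
    effect_size: float = 1.0
    batch_sd: float = 0.5
    base_log_mean_loc: float = -7.0
    base_log_mean_scale: float = 1.5
    sample_log_sd: float = 0.7
    zero_inflation_range: tuple[float, float] = (0.0, 0.5)
    disease_taxon_max_zero_inflation: float = 0.05
    read_count_log10_mean: float = 7.5
    read_count_log10_sd: float = 0.15
    unclassified_beta: tuple[float, float] = (2.0, 18.0)
    frac_low_reads: float = 0.0
    frac_high_unclassified: float = 0.0
    frac_high_bmi: float = 0.0
    phenotype_effect: float = 0.0
    disease: str = "PD"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_studies, self.cases_per_study, self.controls_per_study, self.n_taxa) < 1:
            raise ValueError("all counts must be >= 1 (matched case-control design)")
        if not (0 <= self.n_disease_taxa <= self.n_taxa):
            raise ValueError("n_disease_taxa outside [0, n_taxa]")
        if self.n_protective_taxa > self.n_disease_taxa:
            raise ValueError("n_protective_taxa exceeds n_disease_taxa")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        lo, hi = self.zero_inflation_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("zero_inflation_range outside [0, 1]")


def _draw_truth(params: SimulationParams, rng: np.random.Generator) -> PlantedTruth:
    taxa = [f"s__Taxon_{i:04d}" for i in range(params.n_taxa)]
    base = rng.normal(params.base_log_mean_loc, params.base_log_mean_scale, params.n_taxa)
    lo, hi = params.zero_inflation_range
    zi = rng.uniform(lo, hi, params.n_taxa)

    idx = rng.choice(params.n_taxa, size=params.n_disease_taxa, replace=False)
    signs = rng.choice([-1.0, 1.0], size=params.n_disease_taxa)
    # abundance-mode disease signals live on mostly-present taxa; heavily
    # zero-inflated taxa would carry prevalence signals instead
    zi[idx] = np.minimum(zi[idx], params.disease_taxon_max_zero_inflation)
    # protective subset: health-enriched, never structurally absent, and
    # lifted toward the abundant end so healthy prevalence clears 50%;
    # with a protective arm planted, the remaining disease taxa form the
    # disease-enriched arm so the two planted groups are disjoint in sign
    for j in range(params.n_protective_taxa):
        signs[j] = -1.0
        zi[idx[j]] = 0.0
        base[idx[j]] = max(base[idx[j]], params.base_log_mean_loc + params.base_log_mean_scale)
    if params.n_protective_taxa:
        signs[params.n_protective_taxa :] = 1.0
    disease_taxa = {
        taxa[i]: float(s * params.effect_size) for i, s in zip(idx, signs)
    }
    protective = {taxa[idx[j]] for j in range(params.n_protective_taxa)}
    if params.effect_size == 0:
        protective = set()
        disease_taxa = {t: 0.0 for t in disease_taxa}
    return PlantedTruth(
        taxon_ids=taxa,
        disease_taxa=disease_taxa if params.effect_size != 0 else {},
        protective_taxa=protective,
        batch_bias={},
        base_log_mean=base,
        base_log_sd=params.sample_log_sd,
        zero_inflation=zi,
    )


def _simulate_study(
    study_id: str,
    params: SimulationParams,
    truth: PlantedTruth,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[SampleRecord], np.ndarray]:
    n_taxa = len(truth.taxon_ids)
    n = params.cases_per_study + params.controls_per_study
    log_bias = rng.normal(0.0, params.batch_sd, n_taxa)

    lfc_ln = np.zeros(n_taxa)
    for t, lfc2 in truth.disease_taxa.items():
        lfc_ln[truth.taxon_ids.index(t)] = lfc2 * _LN2

    is_case = np.array([True] * params.cases_per_study + [False] * params.controls_per_study)
    latent = (
        truth.base_log_mean[None, :]
        + log_bias[None, :]
        + is_case[:, None] * lfc_ln[None, :]
        + rng.normal(0.0, truth.base_log_sd, (n, n_taxa))
    )
    present = rng.random((n, n_taxa)) >= truth.zero_inflation[None, :]
    # keep each sample's strongest taxon so no sample is entirely empty
    top = np.argmax(latent, axis=1)
    present[np.arange(n), top] = True
    abund = np.where(present, np.exp(latent), 0.0)

    a, b = params.unclassified_beta
    unclassified = rng.beta(a, b, n)
    high_uncl = rng.random(n) < params.frac_high_unclassified
    unclassified = np.where(high_uncl, rng.uniform(0.31, 0.5, n), unclassified)

    fractions = abund / abund.sum(axis=1, keepdims=True) * (1.0 - unclassified[:, None])

    read_count = np.round(
        10 ** rng.normal(params.read_count_log10_mean, params.read_count_log10_sd, n)
    ).astype(np.int64)
    low = rng.random(n) < params.frac_low_reads
    read_count = np.where(low, rng.integers(1_000_000, 9_999_999, n), read_count)

    bmi = np.clip(rng.normal(24.0, 3.0, n), 16.0, 29.9)
    high_bmi = rng.random(n) < params.frac_high_bmi
    bmi = np.where(high_bmi, rng.uniform(30.5, 40.0, n), bmi)
    age = np.clip(rng.normal(45.0, 12.0, n), 18.0, 90.0)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    score = params.phenotype_effect * is_case + rng.normal(0.0, 1.0, n)

    records = [
        SampleRecord(
            sample_id=f"{study_id}_S{i:04d}",
            study_id=study_id,
            disease=params.disease if is_case[i] else HEALTHY_LABEL,
            is_case=bool(is_case[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            read_count=int(read_count[i]),
            unclassified_fraction=float(unclassified[i]),
            phenotypes={"symptom_score": float(score[i])},
        )
        for i in range(n)
    ]
    return fractions, records, np.exp(log_bias)


def simulate_dataset(params: SimulationParams) -> MultiStudyDataset:
    """Simulate a multi-study case-control dataset with recorded truth."""
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(params.n_studies + 1)
    truth = _draw_truth(params, np.random.default_rng(streams[0]))

    blocks, records = [], []
    for k in range(params.n_studies):
        study_id = f"study_{k + 1}"
        frac, recs, bias = _simulate_study(
            study_id, params, truth, np.random.default_rng(streams[k + 1])
        )
        truth.batch_bias[study_id] = bias
        blocks.append(frac)
        records.extend(recs)

    values = np.vstack(blocks)
    profiles = TaxonProfileTable(
        values, sample_ids=[r.sample_id for r in records], taxon_ids=truth.taxon_ids
    )
    return MultiStudyDataset(profiles, records, ground_truth=truth)


def inject_external_cohort(
    params: SimulationParams,
    truth: PlantedTruth,
    n_studies: Optional[int] = None,
    study_prefix: str = "external",
) -> MultiStudyDataset:
    """Draw unseen studies from an existing truth with fresh batch biases.

    The disease effects, baseline abundances and zero-inflation profile
    are those of ``truth``; only the per-study multiplicative biases and
    sampling noise are new, emulating an external validation cohort from
    a different platform or population.
    """
    ext_truth = PlantedTruth(
        taxon_ids=list(truth.taxon_ids),
        disease_taxa=dict(truth.disease_taxa),
        protective_taxa=set(truth.protective_taxa),
        batch_bias={},
        base_log_mean=truth.base_log_mean.copy(),
        base_log_sd=truth.base_log_sd,
        zero_inflation=truth.zero_inflation.copy(),
    )
    if n_studies is None:
        n_studies = params.n_studies
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(n_studies)
    blocks, records = [], []
    for k in range(n_studies):
        study_id = f"{study_prefix}_{k + 1}"
        frac, recs, bias = _simulate_study(
            study_id, params, ext_truth, np.random.default_rng(streams[k])
        )
        ext_truth.batch_bias[study_id] = bias
        blocks.append(frac)
        records.extend(recs)
    profiles = TaxonProfileTable(
        np.vstack(blocks),
        sample_ids=[r.sample_id for r in records],
        taxon_ids=ext_truth.taxon_ids,
    )
    return MultiStudyDataset(profiles, records, ground_truth=ext_truth)
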