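"""Tri-criteria consensus for core protective taxa.

A taxon qualifies as core-protective when three independent lines of
evidence agree: (1) consistently health-enriched in the pooled
differential analysis, (2) discriminative for health in the index's
underlying classifier (nonzero importance with a health-pointing
direction), and (3) prevalent in >= half of healthy individuals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import FeatureImportance, FinalModel
from .datamodel import MultiStudyDataset
from .diffmeta import CrossDiseaseClassification

logger = logging.getLogger(__name__)


def healthy_prevalence(
    ds: MultiStudyDataset, abundance_cutoff: float = 1e-4
) -> dict[str, float]:
    """Per-taxon prevalence among healthy samples (pooled across studies).

    Prevalence = fraction of healthy samples whose abundance is at or
    above ``abundance_cutoff`` (default the 1e-4 detection cutoff).
    """
    healthy = [s.sample_id for s in ds.samples if not s.is_case]
    if not healthy:
        raise ValueError("no healthy samples")
    X = ds.profiles.select_samples(healthy).values
    prev = (X >= abundance_cutoff).mean(axis=0)
    return {t: float(p) for t, p in zip(ds.taxon_ids, prev)}


def healthy_prevalence_per_cohort(
    ds: MultiStudyDataset, abundance_cutoff: float = 1e-4
) -> dict[str, float]:
    """Variant: minimum over cohorts of within-cohort healthy prevalence."""
    out: Optional[dict[str, float]] = None
    for study in ds.study_ids:
        sub = ds.subset_studies([study])
        if not any(not s.is_case for s in sub.samples):
            continue
        prev = healthy_prevalence(sub, abundance_cutoff)
        out = prev if out is None else {t: min(out[t], prev[t]) for t in out}
    if out is None:
        raise ValueError("no healthy samples in any cohort")
    return out


def feature_directions(
    model: FinalModel,
    X_reference: np.ndarray,
    feature_names: Sequence[str],
    delta: float = 1.0,
) -> dict[str, int]:
    """Per-feature direction by single-feature perturbation.

    ``X_reference`` must be in the model's own input space (e.g. log10
    abundances).  A feature is health-pointing (-1) when adding
    ``delta`` to it (one decade, for log10 inputs) lowers the model's
    mean predicted disease probability on the reference data,
    disease-pointing (+1) when it raises it, 0 when the prediction does
    not move.
    """
    X = np.asarray(X_reference, dtype=float)
    base = model.predict_proba_matrix(X).mean()
    directions: dict[str, int] = {}
    for j in model.feature_indices:
        Xp = X.copy()
        Xp[:, j] = Xp[:, j] + delta
        shifted = model.predict_proba_matrix(Xp).mean()
        diff = shifted - base
        name = feature_names[j]
        directions[name] = 0 if diff == 0 else (-1 if diff < 0 else 1)
    return directions


def index_discriminative_set(
    importance: FeatureImportance,
    directionality: dict[str, int],
    top_fraction: float = 1.0,
) -> set[str]:
    """Features with nonzero importance and a health-pointing direction.

    ``top_fraction`` < 1 keeps only that upper quantile of nonzero
    importances.  Features without an estimable direction are excluded
    (and logged).
    """
    nonzero = {k: v for k, v in importance.scores.items() if v > 0}
    if top_fraction < 1.0 and nonzero:
        cut = np.quantile(list(nonzero.values()), 1.0 - top_fraction)
        nonzero = {k: v for k, v in nonzero.items() if v >= cut}
    out = set()
    missing = []
    for k in nonzero:
        d = directionality.get(k)
        if d is None:
            missing.append(k)
        elif d == -1:
            out.add(k)
    if missing:
        logger.info("direction not estimable for %d features; excluded", len(missing))
    return out


@dataclass
class CoreTaxaReport:
    health_enriched: set[str]
    index_discriminative: set[str]
    prevalent_in_health: set[str]
    consensus: list[str]  # ordered by importance, descending
    prevalence: dict[str, float] = field(default_factory=dict)
    importance: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "health_enriched": sorted(self.health_enriched),
                "index_discriminative": sorted(self.index_discriminative),
                "prevalent_in_health": sorted(self.prevalent_in_health),
                "consensus": self.consensus,
                "prevalence": {k: self.prevalence[k] for k in sorted(self.prevalence)},
                "importance": {k: self.importance[k] for k in sorted(self.importance)},
            },
            indent=2,
            sort_keys=True,
        )


def consensus(
    classifications: Sequence[CrossDiseaseClassification],
    index_set: set[str],
    prevalence: dict[str, float],
    importance: Optional[FeatureImportance] = None,
    prevalence_cutoff: float = 0.5,
) -> CoreTaxaReport:
    """Intersect the three evidence sets into the core-protective report.

    ``classifications`` supplies the consistently health-enriched taxa;
    ``index_set`` the health-discriminative taxa; ``prevalence`` the
    healthy-population prevalences thresholded at ``prevalence_cutoff``
    (default 50%).  The consensus is ordered by importance (descending,
    taxon id as tie-break) for deterministic output.
    """
    if not prevalence:
        raise ValueError("empty taxon universe")
    health_enriched = {
        c.taxon for c in classifications if c.category == "consistent-health"
    }
    prevalent = {t for t, p in prevalence.items() if p >= prevalence_cutoff}
    inter = health_enriched & index_set & prevalent
    imp = dict(importance.scores) if importance is not None else {}
    ordered = sorted(inter, key=lambda t: (-imp.get(t, 0.0), t))
    return CoreTaxaReport(
        health_enriched=health_enriched,
        index_discriminative=set(index_set),
        prevalent_in_health=prevalent,
        consensus=ordered,
        prevalence={t: prevalence[t] for t in inter},
        importance={t: imp.get(t, 0.0) for t in inter},
    )
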