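"""Sample, study and species inclusion rules with a full audit trail.

Filter order: per-sample filters (read depth, unclassified fraction,
BMI) first, then removal of whole studies left with fewer than the
minimum sample count, then species refinement by the paired
abundance/occurrence rule.  A sample's audit records the FIRST rule it
failed.  Missing BMI (or any other metadata field) never excludes a
sample here — analyses that need a field drop records themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, MultiStudyDataset


@dataclass
class FilterAudit:
    """Per-item exclusion reasons plus before/after counts."""

    sample_reasons: dict[str, str] = field(default_factory=dict)
    taxon_reasons: dict[str, str] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_taxa_before: int = 0
    n_taxa_after: int = 0

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in list(self.sample_reasons.values()) + list(self.taxon_reasons.values()):
            counts[r] = counts.get(r, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": k, "kind": "sample", "reason": v}
            for k, v in self.sample_reasons.items()
        ] + [
            {"item": k, "kind": "taxon", "reason": v}
            for k, v in self.taxon_reasons.items()
        ]
        return pd.DataFrame(rows, columns=["item", "kind", "reason"])


def filter_samples(
    ds: MultiStudyDataset, cfg: AnalysisConfig | None = None
) -> tuple[MultiStudyDataset, FilterAudit]:
    """Apply the sample-level and study-level inclusion rules.

    Rules (checked in order; the first failure is recorded):

    - ``low_reads``: read_count below ``cfg.min_read_count`` (default 10M);
    - ``high_unclassified``: unclassified fraction above
      ``cfg.max_unclassified`` (default 30%);
    - ``high_bmi``: BMI above ``cfg.max_bmi`` (default 30 kg/m^2) —
      missing BMI passes;
    - ``small_study``: after the above, studies with fewer than
      ``cfg.min_study_n`` samples (default 10) are removed entirely.
    """
    cfg = cfg or AnalysisConfig()
    audit = FilterAudit(
        n_samples_before=len(ds.samples),
        n_taxa_before=ds.profiles.n_taxa,
        n_taxa_after=ds.profiles.n_taxa,
    )
    surviving: list[str] = []
    for s in ds.samples:
        if s.read_count is not None and s.read_count < cfg.min_read_count:
            audit.sample_reasons[s.sample_id] = "low_reads"
        elif (
            s.unclassified_fraction is not None
            and s.unclassified_fraction > cfg.max_unclassified
        ):
            audit.sample_reasons[s.sample_id] = "high_unclassified"
        elif s.bmi is not None and s.bmi > cfg.max_bmi:
            audit.sample_reasons[s.sample_id] = "high_bmi"
        else:
            audit.sample_reasons[s.sample_id] = "none"
            surviving.append(s.sample_id)

    study_n: dict[str, int] = {}
    for s in ds.samples:
        if audit.sample_reasons[s.sample_id] == "none":
            study_n[s.study_id] = study_n.get(s.study_id, 0) + 1
    small = {st for st, n in study_n.items() if n < cfg.min_study_n}
    if small:
        for s in ds.samples:
            if s.study_id in small and audit.sample_reasons[s.sample_id] == "none":
                audit.sample_reasons[s.sample_id] = "small_study"
        surviving = [
            sid for sid in surviving if audit.sample_reasons[sid] == "none"
        ]

    if not surviving:
        raise ValueError("sample filtering removed every sample")
    audit.n_samples_after = len(surviving)
    return ds.subset_samples(surviving), audit


def filter_species(
    ds: MultiStudyDataset, cfg: AnalysisConfig | None = None
) -> tuple[MultiStudyDataset, FilterAudit]:
    """Apply the paired abundance/occurrence species rule.

    A taxon is retained iff the fraction of samples where its abundance
    is >= ``cfg.abundance_cutoff`` (default 1e-4) reaches
    ``cfg.occurrence_cutoff`` (default 1%).  In retained taxa, values
    below the abundance cutoff are zeroed (sub-threshold observations
    are treated as noise).  No renormalization unless
    ``cfg.renormalize_after_species_filter`` is set.

    With ``cfg.occurrence_on_nonzero``, occurrence counts any nonzero
    value instead of values above the abundance cutoff.
    """
    cfg = cfg or AnalysisConfig()
    X = ds.profiles.values
    present = (X > 0) if cfg.occurrence_on_nonzero else (X >= cfg.abundance_cutoff)
    occurrence = present.mean(axis=0)
    keep = occurrence >= cfg.occurrence_cutoff

    audit = FilterAudit(
        n_samples_before=len(ds.samples),
        n_samples_after=len(ds.samples),
        n_taxa_before=ds.profiles.n_taxa,
        n_taxa_after=int(keep.sum()),
    )
    for j, t in enumerate(ds.taxon_ids):
        audit.taxon_reasons[t] = "none" if keep[j] else "low_abundance_and_occurrence"
    for s in ds.samples:
        audit.sample_reasons[s.sample_id] = "none"
    if not keep.any():
        raise ValueError("species filtering removed every taxon")

    kept_ids = [t for t, k in zip(ds.taxon_ids, keep) if k]
    out = ds.subset_taxa(kept_ids)
    vals = out.profiles.data.to_numpy()
    vals[vals < cfg.abundance_cutoff] = 0.0
    if cfg.renormalize_after_species_filter:
        sums = vals.sum(axis=1, keepdims=True)
        np.divide(vals, sums, out=vals, where=sums > 0)
    df = pd.DataFrame(vals, index=out.profiles.data.index, columns=out.profiles.data.columns)
    out.profiles.data = df
    return out, audit
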