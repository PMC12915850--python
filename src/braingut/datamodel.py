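"""Shared containers for multi-study microbiome case-control data.

The central unit is :class:`MultiStudyDataset`: a samples x taxa
relative-abundance table plus aligned per-sample metadata records and,
for simulated data, the planted ground truth.  Abundances are stored as
fractions; a per-sample sum below 1 is interpreted as an unclassified
remainder, which shotgun taxonomic profilers routinely leave.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

HEALTHY_LABEL = "healthy"

#: metadata columns every analysis can rely on
REQUIRED_METADATA_COLUMNS = ("sample_id", "study_id", "disease", "is_case")
OPTIONAL_METADATA_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "read_count",
    "unclassified_fraction",
)

_SUM_TOL = 1e-6


class TaxonProfileTable:
    """Samples x taxa relative-abundance matrix (fractions in [0, 1]).

    Parameters
    ----------
    data
        DataFrame with sample ids as index and taxon ids as columns, or
        anything :func:`pandas.DataFrame` accepts together with
        ``sample_ids`` / ``taxon_ids``.

    Invariants enforced at construction: nonnegative values, unique
    sample and taxon ids, per-sample sum <= 1 + 1e-6 (the remainder is
    the unclassified fraction).
    """

    def __init__(
        self,
        data: pd.DataFrame | np.ndarray,
        sample_ids: Optional[Sequence[str]] = None,
        taxon_ids: Optional[Sequence[str]] = None,
    ):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(np.asarray(data, dtype=float), index=list(sample_ids), columns=list(taxon_ids))
        else:
            data = data.astype(float)
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = data.to_numpy()
        if np.isnan(values).any():
            raise ValueError("abundance table contains NaN")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {data.index[i]!r}, taxon {data.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        bad = np.where(sums > 1.0 + _SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"sample {data.index[bad[0]]!r} abundances sum to {sums[bad[0]]:.6g} > 1"
            )
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "TaxonProfileTable":
        return TaxonProfileTable(self.data.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "TaxonProfileTable":
        return TaxonProfileTable(self.data.loc[:, list(taxon_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonProfileTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"TaxonProfileTable({self.n_samples} samples x {self.n_taxa} taxa)"


@dataclass
class SampleRecord:
    """Harmonized per-sample metadata.

    ``is_case`` must be False exactly when ``disease`` equals the
    healthy label.  Missing numeric fields are ``None``; missingness is
    preserved at read time and handled per-analysis downstream.
    """

    sample_id: str
    study_id: str
    disease: str
    is_case: bool
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    read_count: Optional[int] = None
    unclassified_fraction: Optional[float] = None
    phenotypes: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_case == (self.disease == HEALTHY_LABEL):
            raise ValueError(
                f"sample {self.sample_id!r}: is_case={self.is_case} inconsistent "
                f"with disease={self.disease!r}"
            )
        if self.read_count is not None and self.read_count < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative read_count")
        if self.unclassified_fraction is not None and not (
            0.0 <= self.unclassified_fraction <= 1.0
        ):
            raise ValueError(
                f"sample {self.sample_id!r}: unclassified_fraction outside [0, 1]"
            )


@dataclass
class MultiStudyDataset:
    """Profile table + aligned metadata records (+ optional planted truth)."""

    profiles: TaxonProfileTable
    samples: list[SampleRecord]
    ground_truth: Optional[Any] = None  # PlantedTruth for simulated data

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if ids != self.profiles.sample_ids:
            raise ValueError("sample ids of profiles and metadata disagree in content or order")

    @property
    def sample_ids(self) -> list[str]:
        return self.profiles.sample_ids

    @property
    def taxon_ids(self) -> list[str]:
        return self.profiles.taxon_ids

    @property
    def study_ids(self) -> list[str]:
        """Distinct study ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.study_id, None)
        return list(seen)

    def metadata_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sample id (phenotypes expanded)."""
        rows = []
        for s in self.samples:
            row: dict[str, Any] = {
                "sample_id": s.sample_id,
                "study_id": s.study_id,
                "disease": s.disease,
                "is_case": s.is_case,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "read_count": s.read_count,
                "unclassified_fraction": s.unclassified_fraction,
            }
            row.update(s.phenotypes)
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id", drop=False)

    def labels(self) -> np.ndarray:
        return np.array([s.is_case for s in self.samples], dtype=int)

    def studies(self) -> np.ndarray:
        return np.array([s.study_id for s in self.samples])

    def subset_samples(self, sample_ids: Sequence[str]) -> "MultiStudyDataset":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        order = [s.sample_id for s in samples]
        return MultiStudyDataset(
            self.profiles.select_samples(order), samples, self.ground_truth
        )

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "MultiStudyDataset":
        return MultiStudyDataset(
            self.profiles.select_taxa(taxon_ids), list(self.samples), self.ground_truth
        )

    def subset_studies(self, study_ids: Sequence[str]) -> "MultiStudyDataset":
        keep = set(study_ids)
        ids = [s.sample_id for s in self.samples if s.study_id in keep]
        return self.subset_samples(ids)


@dataclass
class AnalysisConfig:
    """Thresholds and cross-validation settings with published defaults.

    QC defaults: minimum 10 million reads, at most 30% unclassified,
    BMI <= 30 kg/m^2, >= 10 samples per study after sample filters,
    species retained when present at >= 1e-4 relative abundance in
    >= 1% of samples.
    """

    min_read_count: int = 10_000_000
    max_unclassified: float = 0.30
    max_bmi: float = 30.0
    min_study_n: int = 10
    abundance_cutoff: float = 1e-4
    occurrence_cutoff: float = 0.01
    fdr_threshold: float = 0.1
    prevalence_cutoff: float = 0.5
    occurrence_on_nonzero: bool = False  # alt: "present" = any nonzero value
    renormalize_after_species_filter: bool = False
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 10
    search_budget: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_read_count < 0:
            raise ValueError("min_read_count must be >= 0")
        if not 0.0 <= self.max_unclassified <= 1.0:
            raise ValueError("max_unclassified must be in [0, 1]")
        if self.max_bmi <= 0:
            raise ValueError("max_bmi must be positive")
        if self.min_study_n < 1:
            raise ValueError("min_study_n must be >= 1")
        if self.abundance_cutoff < 0 or self.occurrence_cutoff < 0 or self.occurrence_cutoff > 1:
            raise ValueError("abundance/occurrence cutoffs outside their domains")
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in [0, 1]")
        if min(self.outer_folds, self.inner_folds, self.repeats, self.search_budget) < 1:
            raise ValueError("CV settings must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
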