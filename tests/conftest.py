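import numpy as np
import pytest

from braingut.datamodel import MultiStudyDataset, SampleRecord, TaxonProfileTable
from braingut.simulate import SimulationParams, simulate_dataset


def make_dataset(values, studies, is_case, taxa=None, **record_kwargs):
    """Small hand-built MultiStudyDataset from a samples x taxa array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    taxa = taxa or [f"s__T{j}" for j in range(p)]
    sample_ids = [f"S{i}" for i in range(n)]
    records = []
    for i in range(n):
        kw = {k: (v[i] if isinstance(v, (list, np.ndarray)) else v) for k, v in record_kwargs.items()}
        records.append(
            SampleRecord(
                sample_id=sample_ids[i],
                study_id=studies[i],
                disease="PD" if is_case[i] else "healthy",
                is_case=bool(is_case[i]),
                **kw,
            )
        )
    table = TaxonProfileTable(values, sample_ids=sample_ids, taxon_ids=taxa)
    return MultiStudyDataset(table, records)


@pytest.fixture(scope="session")
def small_sim():
    """Three tiny cohorts with a moderate planted effect (shared across tests)."""
    return simulate_dataset(
        SimulationParams(
            n_studies=3, cases_per_study=15, controls_per_study=15,
            n_taxa=60, n_disease_taxa=6, seed=123,
        )
    )


@pytest.fixture(scope="session")
def null_sim():
    """Three tiny cohorts with no planted effect and no batch bias."""
    return simulate_dataset(
        SimulationParams(
            n_studies=3, cases_per_study=15, controls_per_study=15,
            n_taxa=60, n_disease_taxa=0, effect_size=0.0, batch_sd=0.0, seed=321,
        )
    )
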