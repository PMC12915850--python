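"""Reading and writing the tabular formats the analyses consume.

Profile tables follow the MetaPhlAn merged-abundance dialect: a leading
clade-name column, optional ``#`` comment lines, tab separation, one
column per sample, values in percent.  Clade names carry the full
lineage (``k__...|p__...|...|s__Species_name``); only species-level rows
(deepest rank prefix ``s__``, or SGB-style unclassified species names)
are retained on ingest.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from .datamodel import (
    OPTIONAL_METADATA_COLUMNS,
    REQUIRED_METADATA_COLUMNS,
    MultiStudyDataset,
    SampleRecord,
    TaxonProfileTable,
)

logger = logging.getLogger(__name__)

_CLADE_RANKS = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")
# MetaPhlAn SGB placeholders such as "GGB3746_SGB5089" denote species-level
# entries even without an s__ prefix in the deepest field.
_SGB_RE = re.compile(r"^GGB\d+.*SGB\d+", re.IGNORECASE)


def _is_clade_string(name: str) -> bool:
    return "|" in name or name.startswith(_CLADE_RANKS)


def _is_species_level(name: str) -> bool:
    deepest = name.rsplit("|", 1)[-1]
    if deepest.startswith("s__"):
        return True
    if deepest.startswith(_CLADE_RANKS):
        return False
    return bool(_SGB_RE.match(deepest))


def read_profile_table(
    path: str | Path,
    orientation: Literal["taxa-in-rows", "samples-in-rows"] = "taxa-in-rows",
    unit: Literal["percent", "fraction"] = "percent",
) -> TaxonProfileTable:
    """Read a tab-separated relative-abundance table.

    Parameters
    ----------
    path
        TSV file with a header row; lines starting with ``#`` are skipped.
    orientation
        ``taxa-in-rows`` is the MetaPhlAn merged-table layout (first
        column = clade name, remaining columns = samples).
    unit
        ``percent`` values are divided by 100 on ingest; internal unit
        is always fraction.

    When clade-style taxon names are detected, only species-level rows
    are retained.
    """
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"no header row in {path}")
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column names in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate row names in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "taxa-in-rows":
        df = df.T  # now samples x taxa
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if unit == "percent":
        df = df / 100.0
    elif unit != "fraction":
        raise ValueError(f"unknown unit {unit!r}")

    neg = df.lt(0)
    if neg.to_numpy().any():
        col = neg.any(axis=0).idxmax()
        row = neg[col].idxmax()
        raise ValueError(f"negative abundance at sample {row!r}, taxon {col!r}")

    if any(_is_clade_string(t) for t in df.columns):
        species = [t for t in df.columns if _is_species_level(t)]
        dropped = df.shape[1] - len(species)
        if dropped:
            logger.info("dropped %d non-species clade rows", dropped)
        df = df.loc[:, species]
    return TaxonProfileTable(df)


def write_profile_table(
    table: TaxonProfileTable,
    path: str | Path,
    orientation: Literal["taxa-in-rows", "samples-in-rows"] = "taxa-in-rows",
    unit: Literal["percent", "fraction"] = "percent",
) -> None:
    """Write a profile table in the same dialect ``read_profile_table`` reads."""
    df = table.data
    if unit == "percent":
        df = df * 100.0
    if orientation == "taxa-in-rows":
        df = df.T
        df.index.name = "clade_name"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def _parse_optional_float(v: object) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_metadata(path: str | Path, na_token: str = "NA") -> list[SampleRecord]:
    """Read per-sample metadata from TSV.

    Required columns: sample_id, study_id, disease, is_case.  Cells
    equal to ``na_token`` become missing values; no record is dropped at
    read time — each downstream analysis removes records missing its own
    required fields.  Any column beyond the standard set is treated as a
    numeric phenotype score.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[na_token]
    )
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    phen_cols = [
        c
        for c in df.columns
        if c not in REQUIRED_METADATA_COLUMNS and c not in OPTIONAL_METADATA_COLUMNS
    ]
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        is_case = str(row["is_case"]).strip().lower() in ("1", "true", "yes")
        rc = _parse_optional_float(row.get("read_count"))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                study_id=str(row["study_id"]),
                disease=str(row["disease"]),
                is_case=is_case,
                age=_parse_optional_float(row.get("age")),
                sex=None if pd.isna(row.get("sex")) else str(row.get("sex")),
                bmi=_parse_optional_float(row.get("bmi")),
                read_count=None if rc is None else int(rc),
                unclassified_fraction=_parse_optional_float(
                    row.get("unclassified_fraction")
                ),
                phenotypes={
                    c: _parse_optional_float(row.get(c)) for c in phen_cols
                },
            )
        )
    return records


def write_metadata(
    records: Sequence[SampleRecord], path: str | Path, na_token: str = "NA"
) -> None:
    """Write metadata TSV round-trippable through :func:`read_metadata`."""
    phen_cols: list[str] = []
    for r in records:
        for k in r.phenotypes:
            if k not in phen_cols:
                phen_cols.append(k)

    def fmt(v: object) -> str:
        if v is None:
            return na_token
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float):
            return f"{v:.17g}"
        return str(v)

    cols = list(REQUIRED_METADATA_COLUMNS) + list(OPTIONAL_METADATA_COLUMNS) + phen_cols
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            vals = [
                r.sample_id,
                r.study_id,
                r.disease,
                fmt(r.is_case),
                fmt(r.age),
                fmt(r.sex),
                fmt(r.bmi),
                fmt(r.read_count),
                fmt(r.unclassified_fraction),
            ] + [fmt(r.phenotypes.get(c)) for c in phen_cols]
            fh.write("\t".join(vals) + "\n")


def align_dataset(
    profiles: TaxonProfileTable, samples: Sequence[SampleRecord]
) -> MultiStudyDataset:
    """Join profiles and metadata on sample id (intersection, profile order)."""
    by_id = {s.sample_id: s for s in samples}
    common = [sid for sid in profiles.sample_ids if sid in by_id]
    if not common:
        raise ValueError("no overlap between profile and metadata sample ids")
    n_prof_dropped = profiles.n_samples - len(common)
    n_meta_dropped = len(by_id) - len(common)
    if n_prof_dropped or n_meta_dropped:
        logger.info(
            "align_dataset: dropped %d profile-only and %d metadata-only samples",
            n_prof_dropped,
            n_meta_dropped,
        )
    return MultiStudyDataset(
        profiles.select_samples(common), [by_id[sid] for sid in common]
    )
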