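"""Cohort bookkeeping: sample metadata, pairing, timing, mutation tables.

A liver metastasis resected at least 12 months after the primary tumor is
metachronous; anything earlier is synchronous. Paired analyses enumerate
(patient, locus) measurement pairs where both the primary and the metastasis
density are observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ThresholdConfig
from .matrix import MethylationMatrix

__all__ = [
    "ROLES", "TIMINGS", "MUTATION_GENES",
    "classify_timing", "read_sample_metadata", "validate_metadata",
    "pair_samples", "PairEnumeration", "enumerate_measurement_pairs",
    "read_mutation_table", "validate_mutation_table",
]

ROLES = ("primary", "metastasis", "normal", "cell_line")
TIMINGS = ("synchronous", "metachronous", "not_applicable")
MUTATION_GENES = ("KRAS", "BRAF", "p53")

META_COLUMNS = ("sample_id", "patient_id", "role", "stage", "location",
                "liver_metastasis", "timing", "interval_months")


def classify_timing(interval_months: float | None,
                    cfg: ThresholdConfig = DEFAULT_CONFIG) -> str | None:
    """Classify a metastasis as synchronous or metachronous from the interval
    (in months) between resection of the primary and of the metastasis.

    The metachronous bound is closed: an interval of exactly
    ``cfg.metachronous_min_months`` (default 12) is metachronous. A missing
    interval yields ``None``.
    """
    if interval_months is None or (isinstance(interval_months, float)
                                   and np.isnan(interval_months)):
        return None
    if interval_months < 0:
        raise ValueError(f"interval_months must be >= 0, got {interval_months}")
    return ("metachronous" if interval_months >= cfg.metachronous_min_months
            else "synchronous")


def read_sample_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata TSV (columns: sample_id, patient_id, role, stage,
    location, liver_metastasis, timing, interval_months)."""
    meta = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       comment="#")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta.replace({"NA": np.nan, "": np.nan})
    meta["interval_months"] = pd.to_numeric(meta["interval_months"])
    meta["stage"] = pd.to_numeric(meta["stage"]).astype("Int64")
    return meta


def validate_metadata(meta: pd.DataFrame,
                      cfg: ThresholdConfig = DEFAULT_CONFIG) -> None:
    """Check role/timing enums, pairing uniqueness and timing consistency."""
    bad_roles = set(meta["role"].dropna()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    bad_timing = set(meta["timing"].dropna()) - set(TIMINGS)
    if bad_timing:
        raise ValueError(f"unknown timing values: {sorted(bad_timing)}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    primaries = meta[meta["role"] == "primary"]
    counts = primaries["patient_id"].value_counts()
    for _, row in meta[meta["role"] == "metastasis"].iterrows():
        n = counts.get(row["patient_id"], 0)
        if n != 1:
            raise ValueError(
                f"metastasis sample {row['sample_id']!r} must match exactly one "
                f"primary for patient {row['patient_id']!r} (found {n})"
            )
        interval = row["interval_months"]
        expected = classify_timing(
            float(interval) if pd.notna(interval) else None, cfg)
        stated = row["timing"] if pd.notna(row["timing"]) else None
        if expected is not None and stated not in (None, expected):
            raise ValueError(
                f"sample {row['sample_id']!r}: timing {stated!r} inconsistent "
                f"with interval {interval} months (expected {expected!r})"
            )


def pair_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """Match each metastasis sample to its patient's primary sample.

    Returns a frame with columns patient_id, primary_sample,
    metastasis_sample, interval_months, timing.
    """
    primaries = meta[meta["role"] == "primary"].set_index("patient_id")
    records = []
    for _, row in meta[meta["role"] == "metastasis"].iterrows():
        pid = row["patient_id"]
        if pid not in primaries.index:
            raise ValueError(f"no primary sample for patient {pid!r}")
        prim = primaries.loc[pid]
        if isinstance(prim, pd.DataFrame):
            raise ValueError(f"multiple primary samples for patient {pid!r}")
        records.append({
            "patient_id": pid,
            "primary_sample": prim["sample_id"],
            "metastasis_sample": row["sample_id"],
            "interval_months": row["interval_months"],
            "timing": row["timing"],
        })
    return pd.DataFrame(records, columns=["patient_id", "primary_sample",
                                          "metastasis_sample",
                                          "interval_months", "timing"])


@dataclass
class PairEnumeration:
    """Measurement pairs with both members observed, plus the count of
    (pair, locus) cells excluded because either member was missing."""
    records: pd.DataFrame  # patient_id, locus_id, primary_value, metastasis_value
    n_excluded_missing: int

    @property
    def n_pairs(self) -> int:
        return len(self.records)


def enumerate_measurement_pairs(matrix: MethylationMatrix,
                                meta: pd.DataFrame) -> PairEnumeration:
    """Enumerate (patient, locus) measurement pairs across matched
    primary/metastasis samples.

    A record is produced only when both densities are non-missing; cells with
    at least one missing member are counted in ``n_excluded_missing``.
    """
    pairs = pair_samples(meta)
    data = matrix.data
    for col in ("primary_sample", "metastasis_sample"):
        absent = [s for s in pairs[col] if s not in data.index]
        if absent:
            raise ValueError(f"samples missing from methylation matrix: {absent}")
    records = []
    n_excluded = 0
    for _, pair in pairs.iterrows():
        prim = data.loc[pair["primary_sample"]]
        met = data.loc[pair["metastasis_sample"]]
        for locus in matrix.locus_ids:
            p, m = prim[locus], met[locus]
            if pd.isna(p) or pd.isna(m):
                n_excluded += 1
            else:
                records.append({"patient_id": pair["patient_id"],
                                "locus_id": locus,
                                "primary_value": float(p),
                                "metastasis_value": float(m)})
    frame = pd.DataFrame(records, columns=["patient_id", "locus_id",
                                           "primary_value", "metastasis_value"])
    return PairEnumeration(records=frame, n_excluded_missing=n_excluded)


def read_mutation_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format mutation table (sample_id, gene, status)."""
    mut = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      comment="#")
    for col in ("sample_id", "gene", "status"):
        if col not in mut.columns:
            raise ValueError(f"mutation table missing column {col!r}")
    mut = mut.replace({"NA": np.nan, "": np.nan})
    validate_mutation_table(mut)
    return mut


def validate_mutation_table(mut: pd.DataFrame) -> None:
    bad = set(mut["status"].dropna()) - {"mutant", "wildtype"}
    if bad:
        raise ValueError(f"unknown mutation status values: {sorted(bad)}")
    bad_gene = set(mut["gene"].dropna()) - set(MUTATION_GENES)
    if bad_gene:
        raise ValueError(f"unknown genes in mutation table: {sorted(bad_gene)}")
    # KRAS and BRAF activating mutations are expected to be mutually exclusive
    wide = (mut.pivot_table(index="sample_id", columns="gene", values="status",
                            aggfunc="first")
            if len(mut) else pd.DataFrame())
    if {"KRAS", "BRAF"} <= set(wide.columns):
        both = wide[(wide["KRAS"] == "mutant") & (wide["BRAF"] == "mutant")]
        if len(both):
            warnings.warn(
                f"samples with both KRAS and BRAF mutant (expected mutually "
                f"exclusive): {list(both.index)}", UserWarning, stacklevel=2)
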