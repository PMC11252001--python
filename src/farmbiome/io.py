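"""Readers and writers for the pipeline's TSV formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

VALID_STATUSES = {"HHS", "LHS"}
VALID_SAMPLE_TYPES = {"wall", "slat", "slurry"}


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a samples x genera count TSV (first column ``sample_id``).

    Validates uniqueness of sample ids, integrality and non-negativity of
    every entry, and positive row sums.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    for col in df.columns:
        values = df[col]
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"{path}: non-numeric counts in genus {col!r}")
        frac, _ = np.modf(values.to_numpy(dtype=float))
        if frac.any():
            bad = df.index[frac != 0][0]
            raise ValueError(
                f"{path}: non-integer count at sample {bad!r}, genus {col!r}"
            )
        if (values < 0).any():
            bad = values.index[values < 0][0]
            raise ValueError(
                f"{path}: negative count at sample {bad!r}, genus {col!r}"
            )
    if (df.sum(axis=1) == 0).any():
        empty = list(df.index[df.sum(axis=1) == 0])
        raise ValueError(f"{path}: samples with zero total counts: {empty}")
    return df.astype(np.int64)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its enums."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "status", "sample_type", "farm_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    bad_status = sorted(set(df["status"]) - VALID_STATUSES)
    if bad_status:
        raise ValueError(
            f"{path}: unknown status values {bad_status} (expected HHS/LHS)"
        )
    bad_type = sorted(set(df["sample_type"]) - VALID_SAMPLE_TYPES)
    if bad_type:
        raise ValueError(f"{path}: unknown sample types {bad_type}")
    return df


def cross_check(counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Every counted sample must have exactly one metadata row."""
    meta_ids = set(metadata["sample_id"])
    missing = [s for s in counts.index if s not in meta_ids]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a DataFrame as TSV with a stable float format (reproducible)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path
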