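"""Compositional preprocessing of genus count tables.

The fixed stage order is: sparse-genus exclusion (within-status zero
fraction), zero replacement, additive log-ratio (ALR) transformation with
a lowest-coefficient-of-variation reference genus, a Procrustes check of
how far the ALR representation departs from an isometric (CLR) one, and
column autoscaling to mean 0 / SD 1.

ALR for genus j with reference genus r in sample s is

    alr_sj = ln(x_sj) - ln(x_sr),

which is invariant to per-sample closure (rescaling a sample's row by any
positive constant). ALR is not an isometry of the simplex; the Procrustes
correlation against centred log-ratio (CLR) coordinates quantifies how
much the sample geometry is distorted by the particular reference choice.
All logs are natural; any base change is a column-wise constant absorbed
by autoscaling. Standard deviations use the n-1 (sample) denominator
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

__all__ = [
    "AlrMatrix",
    "ScalingRecord",
    "filter_sparse_genera",
    "replace_zeros",
    "select_alr_reference",
    "alr_transform",
    "clr_transform",
    "procrustes_correlation",
    "procrustes_isometry_check",
    "autoscale",
]


@dataclass(frozen=True)
class AlrMatrix:
    """ALR-transformed abundances (samples x (G-1)) and their reference."""

    values: pd.DataFrame
    reference: str

    @property
    def source_genus_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ScalingRecord:
    """Per-column means and SDs used for autoscaling (for back-transform)."""

    means: pd.Series
    sds: pd.Series

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise ValueError(f"non-positive SDs for columns {bad}")


def filter_sparse_genera(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    max_zero_fraction: float = 0.25,
) -> pd.DataFrame:
    """Drop genera whose zero fraction reaches the threshold in any status.

    A genus is retained iff its within-status zero fraction is strictly
    below ``max_zero_fraction`` in *both* status groups. Sample set and
    genus order are preserved. Raises if every genus would be excluded.
    """
    if not 0.0 < max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must lie in (0, 1]")
    status = metadata.set_index("sample_id")["status"]
    missing = counts.index.difference(status.index)
    if len(missing):
        raise ValueError(f"samples without status labels: {list(missing)}")
    status = status.loc[counts.index]

    zero_frac = (counts == 0).groupby(status.values).mean()
    keep = (zero_frac < max_zero_fraction).all(axis=0)
    if not keep.any():
        diag = zero_frac.T.to_string()
        raise ValueError(
            "all genera excluded by the sparsity filter; "
            f"per-genus zero fractions by status:\n{diag}"
        )
    return counts.loc[:, keep]


def replace_zeros(
    counts: pd.DataFrame, mode: str = "pseudocount_one"
) -> pd.DataFrame:
    """Replace zeros so logs are defined.

    ``pseudocount_one`` sets every zero to 1 (the microbiome-count
    convention); ``half_minimum`` sets zeros in genus g to half the
    smallest nonzero value observed for g. Non-zero entries are never
    touched.
    """
    if mode not in ("pseudocount_one", "half_minimum"):
        raise ValueError(f"unknown zero-replacement mode {mode!r}")
    values = counts.astype(float)
    if (values < 0).any().any():
        raise ValueError("negative abundances")
    all_zero = (values == 0).all(axis=0)
    if all_zero.any():
        raise ValueError(
            f"all-zero genera cannot be zero-replaced: {list(values.columns[all_zero])}"
        )
    if mode == "pseudocount_one":
        return values.mask(values == 0, 1.0)
    half_min = values.where(values > 0).min(axis=0) / 2.0
    return values.mask(values == 0, half_min, axis=1)


def select_alr_reference(values: pd.DataFrame) -> str:
    """Reference genus: lowest coefficient of variation of relative abundance.

    CV = SD / mean of the genus's relative abundance across all samples
    (both statuses pooled). Exact ties break to the lexicographically
    smaller genus id.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two genera to pick an ALR reference")
    if (values <= 0).any().any():
        raise ValueError("reference selection requires strictly positive values")
    rel = values.div(values.sum(axis=1), axis=0)
    cv = rel.std(axis=0, ddof=1) / rel.mean(axis=0)
    candidates = sorted(cv.index[cv == cv.min()])
    return candidates[0]


def alr_transform(values: pd.DataFrame, reference: str) -> AlrMatrix:
    """Additive log-ratio transform against ``reference`` (column dropped)."""
    if reference not in values.columns:
        raise ValueError(f"reference genus {reference!r} not in table")
    if (values <= 0).any().any():
        raise ValueError("ALR requires strictly positive values")
    logs = np.log(values)
    alr = logs.drop(columns=reference).sub(logs[reference], axis=0)
    return AlrMatrix(values=alr, reference=reference)


def clr_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio: log values minus their per-sample mean log."""
    if (values <= 0).any().any():
        raise ValueError("CLR requires strictly positive values")
    logs = np.log(values)
    return logs.sub(logs.mean(axis=1), axis=0)


def procrustes_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes correlation between two sample configurations.

    Configurations are compared after optimal translation, uniform
    scaling and rotation; 1 means identical geometry. Configurations
    with different column counts are zero-padded to a common width,
    which leaves their geometry unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples for a Procrustes comparison")
    width = max(a.shape[1], b.shape[1])
    a = np.pad(a, ((0, 0), (0, width - a.shape[1])))
    b = np.pad(b, ((0, 0), (0, width - b.shape[1])))
    _, _, disparity = _scipy_procrustes(a, b)
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def procrustes_isometry_check(alr: AlrMatrix, values: pd.DataFrame) -> float:
    """Procrustes correlation of the ALR configuration against CLR.

    CLR is an isometric representation of the same strictly positive
    matrix, so this measures how much the chosen ALR reference distorts
    between-sample geometry (the motivating analyses report 0.82-0.92).
    """
    if not alr.values.index.equals(values.index):
        raise ValueError("ALR matrix and abundance table have different samples")
    clr = clr_transform(values)
    return procrustes_correlation(alr.values.to_numpy(), clr.to_numpy())


def autoscale(alr: AlrMatrix) -> tuple[pd.DataFrame, ScalingRecord]:
    """Column-wise scale to mean 0 / SD 1 (sample SD, n-1 denominator)."""
    values = alr.values if isinstance(alr, AlrMatrix) else alr
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    zero_var = sds.index[sds == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance columns cannot be autoscaled: {list(zero_var)}")
    scaled = (values - means) / sds
    return scaled, ScalingRecord(means=means, sds=sds)
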