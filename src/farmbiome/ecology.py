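"""Alpha and beta diversity with two-group testing.

Alpha diversity (Shannon entropy in nats, inverse Simpson) and the
Bray-Curtis dissimilarity are computed on relative abundances of the
retained, zero-replaced genera — log-ratio coordinates are signed and
therefore unsuitable for these indices. Group differences in alpha
diversity use a two-sided Mann-Whitney U test (exact enumeration for
small samples, tie-corrected normal approximation otherwise), which for
two groups coincides with Kruskal-Wallis. Beta diversity: Bray-Curtis ->
nonmetric multidimensional scaling (Kruskal stress-1, SMACOF majorisation
with isotonic regression, best of several restarts) -> one-way PERMANOVA
on the Euclidean geometry of the first two ordination axes with a label
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "shannon",
    "inverse_simpson",
    "diversity_report",
    "rank_test_two_groups",
    "bray_curtis",
    "NmdsResult",
    "nmds",
    "permanova_on_axes",
]


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
    return p


def shannon(proportions: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (nats); zero proportions are skipped."""
    p = _check_proportions(proportions)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(proportions: np.ndarray) -> float:
    """Inverse Simpson index D2 = 1 / sum p^2 (effective genus number)."""
    p = _check_proportions(proportions)
    return float(1.0 / (p**2).sum())


def rank_test_two_groups(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for group A, p-value).

    Uses exact enumeration when the combined sample is small (<= 12) and
    tie-free, otherwise the tie-corrected normal approximation. For two
    groups the p-value equals the Kruskal-Wallis p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    if a.size + b.size <= 12 and no_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        # No continuity correction: makes the two-group p identical to
        # Kruskal-Wallis, the formulation quoted alongside it in practice.
        res = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
    return float(res.statistic), float(res.pvalue)


def diversity_report(
    rel_abundance: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample alpha diversity plus per-index HHS vs LHS rank tests.

    Returns (per-sample table with columns ``shannon``/``inverse_simpson``
    and the status label, per-index test table with U and p).
    """
    status = metadata.set_index("sample_id")["status"].loc[rel_abundance.index]
    per_sample = pd.DataFrame(
        {
            "status": status,
            "shannon": [shannon(row) for row in rel_abundance.to_numpy()],
            "inverse_simpson": [
                inverse_simpson(row) for row in rel_abundance.to_numpy()
            ],
        },
        index=rel_abundance.index,
    )
    tests = []
    for index_name in ("shannon", "inverse_simpson"):
        u, p = rank_test_two_groups(
            per_sample.loc[status == "HHS", index_name],
            per_sample.loc[status == "LHS", index_name],
        )
        tests.append({"index": index_name, "U": u, "p_value": p})
    return per_sample, pd.DataFrame(tests)


def bray_curtis(abundance: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix: sum|x-y| / sum(x+y), in [0, 1]."""
    arr = np.asarray(abundance, dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    d = squareform(pdist(arr, metric="braycurtis"))
    if isinstance(abundance, pd.DataFrame):
        return pd.DataFrame(d, index=abundance.index, columns=abundance.index)
    return pd.DataFrame(d)


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame  # samples x dims
    stress: float  # Kruskal stress-1 of the best restart
    stress_sequence: tuple[float, ...]  # accepted iterations, best restart
    converged: bool


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _smacof_run(
    diss: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """One nonmetric SMACOF run; returns (coords, stress-1, stress trace).

    Each iteration fits disparities by isotonic regression of the current
    configuration distances on the dissimilarity order, then applies the
    Guttman transform. An iteration is accepted only if stress-1 does not
    increase, so the returned trace is non-increasing by construction.
    """
    n = diss.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(diss[iu], kind="stable")
    iso = IsotonicRegression(increasing=True)
    X = init.copy()
    trace: list[float] = []
    for _ in range(max_iter):
        d_flat = pdist(X)
        disp_flat = np.empty_like(d_flat)
        disp_flat[order] = iso.fit_transform(
            np.arange(len(order)), d_flat[order]
        )
        stress = _stress1(d_flat, disp_flat)
        if trace and stress > trace[-1] + 1e-15:
            break  # majorisation stalled on the normalised scale
        improved = not trace or trace[-1] - stress > tol
        trace.append(stress)
        if not improved:
            break
        # Guttman transform with ratio disp/dist (0 where dist is 0).
        dist = squareform(d_flat)
        disp = squareform(disp_flat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / np.where(dist > 0, dist, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X, trace[-1], trace


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    dims: int = 2,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Nonmetric MDS minimising Kruskal stress-1; best of ``restarts``.

    The first start is a classical (principal-coordinate) configuration,
    the rest are random; the restart with the lowest final stress wins.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    n = D.shape[0]
    rng = np.random.default_rng(seed)

    # Classical-scaling start: eigendecomposition of the Gower-centred -D^2/2.
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(G)
    idx = np.argsort(evals)[::-1][:dims]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))

    inits = [pcoa] + [rng.normal(size=(n, dims)) for _ in range(max(restarts - 1, 0))]
    best = None
    for init in inits:
        X, stress, trace = _smacof_run(D, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best
    converged = len(trace) < max_iter
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    coords = pd.DataFrame(
        X, index=index, columns=[f"NMDS{k + 1}" for k in range(dims)]
    )
    return NmdsResult(
        coordinates=coords,
        stress=stress,
        stress_sequence=tuple(trace),
        converged=converged,
    )


def _permanova_f_batch(
    d2: np.ndarray, groups: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Pseudo-F for a batch of label assignments (rows of ``labels``).

    ``d2`` is the squared Euclidean distance matrix. SS_total =
    sum_{i<j} d2_ij / n; SS_within sums the analogous per-group terms.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(labels.shape[0])
    n_groups = len(groups)
    for g in groups:
        mask = (labels == g).astype(float)  # batch x n
        n_g = mask[0].sum()
        ss_within += np.einsum("bi,ij,bj->b", mask, d2, mask) / (2.0 * n_g)
    df_b = n_groups - 1
    df_w = n - n_groups
    ss_between = ss_total - ss_within
    return (ss_between / df_b) / (ss_within / df_w)


def permanova_on_axes(
    coordinates: pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    n_permutations: int = 9_999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA on the Euclidean geometry of ordination axes.

    Pseudo-F comes from the distance-based decomposition of the total sum
    of squares (equivalently the classical one-way ANOVA decomposition,
    since distances are Euclidean); the p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_permutations) over label
    permutations from a seeded generator.
    """
    coords = np.asarray(coordinates, dtype=float)
    lab = np.asarray(labels).astype(str)
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    for g in groups:
        if (lab == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    d2 = squareform(pdist(coords)) ** 2
    f_obs = _permanova_f_batch(d2, groups, lab[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(lab) for _ in range(n_permutations)])
    f_perm = _permanova_f_batch(d2, groups, perms)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_permutations)
    return float(f_obs), float(p)
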