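"""PLS-DA with Mahalanobis classification, VIP pruning and permutation checks.

The discriminant stage regresses the autoscaled ALR matrix X against a
single-column class encoding (+1 for the lexicographically smaller class
label, -1 for the other) using deflation-based (NIPALS) partial least
squares. Samples are classified in latent-score space by Mahalanobis
distance to the class centroids under the pooled within-class score
covariance. Model size (number of components A) is picked by the balanced
error rate (BER) under repeated stratified 4-fold cross-validation; the
variable-selection loop drops all genera with a variable importance in
projection (VIP) score below 1, refits, and keeps the iteration with the
lowest cross-validated BER. Final models are validated with an observed
and a label-permuted confusion matrix.

Cross-validation here re-splits the *already autoscaled* matrix; the
scaling is not refit per fold, mirroring the analysis sequence the
pipeline reproduces. The optimism this induces is quantified by the
permuted confusion matrix rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlsdaModel",
    "SelectionTrace",
    "ConfusionSummary",
    "encode_labels",
    "fit_plsda",
    "project_scores",
    "classify_mahalanobis",
    "cv_ber",
    "vip_scores",
    "iterative_vip_selection",
    "confusion_matrices",
]


@dataclass(frozen=True)
class PlsdaModel:
    """A fitted two-class PLS-DA model.

    ``x_weights`` (p x A), ``x_loadings`` (p x A) and ``y_loadings`` (A,)
    come from the NIPALS deflation; ``scores`` (n x A) are the training
    latent variables. ``class_labels`` is sorted; ``centroids`` holds the
    per-class mean score vectors in that order and ``score_cov`` the
    pooled within-class covariance of the training scores, both used by
    the Mahalanobis classifier. ``y_ss`` are the per-component explained
    sums of squares of the class encoding, consumed by the VIP formula.
    """

    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    class_labels: tuple[str, str]
    centroids: np.ndarray
    score_cov: np.ndarray
    y_ss: np.ndarray
    variable_ids: tuple[str, ...] | None = None


@dataclass
class SelectionTrace:
    """Record of the iterative VIP-pruning loop.

    ``iterations`` holds one dict per iteration with keys ``retained``
    (genus ids entering the fit), ``n_components`` and ``ber`` (mean CV
    BER at the chosen A). ``final_selected``/``final_model`` correspond to
    the iteration with the lowest BER; ``stop_reason`` documents why the
    loop ended.
    """

    iterations: list[dict] = field(default_factory=list)
    final_selected: list[str] = field(default_factory=list)
    final_model: PlsdaModel | None = None
    final_ber: float = float("nan")
    stop_reason: str = ""

    def to_jsonable(self) -> dict:
        return {
            "iterations": [
                {
                    "retained": list(it["retained"]),
                    "n_components": int(it["n_components"]),
                    "ber": float(it["ber"]),
                }
                for it in self.iterations
            ],
            "final_selected": list(self.final_selected),
            "final_ber": float(self.final_ber),
            "stop_reason": self.stop_reason,
        }


@dataclass(frozen=True)
class ConfusionSummary:
    """Mean cross-validated confusion matrix, rows normalised to 100%."""

    matrix: pd.DataFrame  # true class x predicted class, percentages
    variant: str  # "observed" or "permuted"
    folds: int
    repetitions: int

    @property
    def true_positive_pct(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix), index=self.matrix.index)


def encode_labels(y: np.ndarray | pd.Series) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode two class labels as +1 (lexicographically first) / -1."""
    y = np.asarray(y)
    labels = sorted(set(map(str, y)))
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    encoded = np.where(y.astype(str) == labels[0], 1.0, -1.0)
    return encoded, (labels[0], labels[1])


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int):
    """Single-response NIPALS PLS; returns W, P, q, T on centred data."""
    n, p = X.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    Xd, yd = X.copy(), y.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            if a > 0:  # residual y exhausted: return the components found
                return W[:, :a], P[:, :a], q[:a], T[:, :a]
            raise ValueError("X carries no covariance with y")
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            if a > 0:
                return W[:, :a], P[:, :a], q[:a], T[:, :a]
            raise ValueError("degenerate score at the first component")
        pa = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    return W, P, q, T


def _pooled_score_stats(T: np.ndarray, encoded: np.ndarray):
    """Class centroids and pooled within-class covariance of scores."""
    A = T.shape[1]
    centroids = np.vstack(
        [T[encoded > 0].mean(axis=0), T[encoded < 0].mean(axis=0)]
    )
    cov = np.zeros((A, A))
    dof = 0
    for sign, mu in zip((1, -1), centroids):
        grp = T[encoded * sign > 0] - mu
        cov += grp.T @ grp
        dof += grp.shape[0] - 1
    cov /= max(dof, 1)
    return centroids, cov


def fit_plsda(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    n_components: int,
) -> PlsdaModel:
    """Fit a two-class PLS-DA model with ``n_components`` latent variables."""
    variable_ids = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    encoded, labels = encode_labels(y)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rank = np.linalg.matrix_rank(Xa - Xa.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components ({n_components}) exceeds rank(X) ({rank})")

    x_mean = Xa.mean(axis=0)
    y_mean = float(encoded.mean())
    W, P, q, T = _nipals(Xa - x_mean, encoded - y_mean, n_components)
    centroids, cov = _pooled_score_stats(T, encoded)
    y_ss = q**2 * np.einsum("ia,ia->a", T, T)
    return PlsdaModel(
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        class_labels=labels,
        centroids=centroids,
        score_cov=cov,
        y_ss=y_ss,
        variable_ids=variable_ids,
    )


def project_scores(model: PlsdaModel, X_new: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Latent scores of new samples: (X - x_mean) W (P'W)^-1."""
    Xa = np.asarray(X_new, dtype=float)
    R = model.x_weights @ np.linalg.inv(model.x_loadings.T @ model.x_weights)
    return (Xa - model.x_mean) @ R


def _mahalanobis_predict(
    scores: np.ndarray,
    centroids: np.ndarray,
    cov: np.ndarray,
    labels: tuple[str, str],
) -> np.ndarray:
    A = cov.shape[0]
    cov = cov.copy()
    # Ridge fallback for singular pooled covariance (tiny training folds).
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.inv(cov + 1e-8 * np.trace(cov) / A * np.eye(A))
    d = np.empty((scores.shape[0], 2))
    for k, mu in enumerate(centroids):
        delta = scores - mu
        d[:, k] = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    # Ties break to the lexicographically smaller label (index 0).
    return np.where(d[:, 0] <= d[:, 1], labels[0], labels[1])


def classify_mahalanobis(
    model: PlsdaModel, X_new: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Assign samples to the nearest class centroid in Mahalanobis distance."""
    scores = project_scores(model, X_new)
    return _mahalanobis_predict(
        scores, model.centroids, model.score_cov, model.class_labels
    )


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment, each class dealt round-robin after a shuffle."""
    assignment = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if len(idx) < folds:
            raise ValueError(
                f"class {label!r} has {len(idx)} samples, fewer than {folds} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def _cv_errors_per_a(
    Xa: np.ndarray,
    y: np.ndarray,
    encoded: np.ndarray,
    labels: tuple[str, str],
    folds: int,
    a_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One CV repetition; returns per-A BER (shape (a_max,)).

    A model with ``a_max`` components is fitted once per fold; nested
    sub-models reuse its leading score columns, so evaluating every A
    costs a single deflation.
    """
    assignment = _stratified_folds(y, folds, rng)
    errors = np.zeros((a_max, 2))
    counts = np.zeros(2)
    for f in range(folds):
        test = assignment == f
        train = ~test
        x_mean = Xa[train].mean(axis=0)
        y_mean = encoded[train].mean()
        W, P, q, T = _nipals(Xa[train] - x_mean, encoded[train] - y_mean, a_max)
        a_eff = W.shape[1]  # deflation can exhaust y below a_max
        for a in range(1, a_max + 1):
            a_use = min(a, a_eff)
            R = W[:, :a_use] @ np.linalg.inv(P[:, :a_use].T @ W[:, :a_use])
            test_scores = (Xa[test] - x_mean) @ R
            centroids, cov = _pooled_score_stats(T[:, :a_use], encoded[train])
            pred = _mahalanobis_predict(test_scores, centroids, cov, labels)
            truth = y[test].astype(str)
            for k, lbl in enumerate(labels):
                in_class = truth == lbl
                errors[a - 1, k] += np.sum(pred[in_class] != lbl)
                if a == 1:
                    counts[k] += in_class.sum()
    return (errors / counts).mean(axis=1)


def cv_ber(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    folds: int = 4,
    repetitions: int = 100,
    a_max: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, int]:
    """Mean balanced error rate per component count; choose A by its minimum.

    BER is the mean over classes of the per-class error rate, pooled over
    folds within a repetition and averaged over ``repetitions`` re-randomised
    stratified fold assignments. Ties in the minimum go to the smallest A.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    encoded, labels = encode_labels(y)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_train_min = len(y) - int(np.ceil(len(y) / folds))
    hard_cap = max(1, min(Xa.shape[1], n_train_min - 1))
    # Default search depth of 10 keeps repeated CV desk-scale; with ~12-24
    # samples the optimum is invariably far below this.
    a_max = min(10 if a_max is None else a_max, hard_cap)
    total = np.zeros(a_max)
    for _ in range(repetitions):
        total += _cv_errors_per_a(Xa, y, encoded, labels, folds, a_max, rng)
    mean_ber = total / repetitions
    chosen = int(np.argmin(mean_ber)) + 1
    return mean_ber, chosen


def vip_scores(model: PlsdaModel) -> pd.Series | np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), with
    SS_a the class-encoding variance explained by component a. Satisfies
    sum_j VIP_j^2 = p.
    """
    W = model.x_weights
    p = W.shape[0]
    w_norm2 = (W**2).sum(axis=0)
    contrib = (W**2 / w_norm2) @ model.y_ss
    vip = np.sqrt(p * contrib / model.y_ss.sum())
    if model.variable_ids is not None:
        return pd.Series(vip, index=list(model.variable_ids))
    return vip


def iterative_vip_selection(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    folds: int = 4,
    repetitions: int = 100,
    vip_threshold: float = 1.0,
    a_max: int | None = None,
    seed: int = 0,
) -> SelectionTrace:
    """Iteratively drop VIP < threshold genera until BER stops improving.

    Each iteration: pick A by :func:`cv_ber`, fit on all samples, compute
    VIPs, drop variables below the threshold, refit. The loop stops when
    (a) no variable falls below the threshold, (b) the cross-validated
    BER fails to improve, or (c) fewer than two variables would remain;
    the iteration with the minimum BER is returned as final.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    trace = SelectionTrace()
    retained = list(X.columns)
    best_ber = np.inf
    while True:
        mean_ber, chosen_a = cv_ber(
            X[retained], y, folds=folds, repetitions=repetitions,
            a_max=a_max, seed=rng,
        )
        model = fit_plsda(X[retained], y, chosen_a)
        ber = float(mean_ber[chosen_a - 1])
        trace.iterations.append(
            {
                "retained": list(retained),
                "n_components": chosen_a,
                "ber": ber,
                "model": model,
            }
        )
        if len(trace.iterations) > 1 and ber >= best_ber:
            trace.stop_reason = "ber_not_improved"
            break
        best_ber = min(best_ber, ber)
        vip = vip_scores(model)
        survivors = [g for g in retained if vip[g] >= vip_threshold]
        if len(survivors) == len(retained):
            trace.stop_reason = "no_variable_below_threshold"
            break
        if len(survivors) < 2:
            trace.stop_reason = "fewer_than_two_variables_would_remain"
            break
        retained = survivors

    best = min(trace.iterations, key=lambda it: it["ber"])
    trace.final_selected = list(best["retained"])
    trace.final_model = best["model"]
    trace.final_ber = float(best["ber"])
    return trace


def confusion_matrices(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    n_components: int,
    folds: int = 4,
    repetitions: int = 500,
    seed: int = 0,
) -> tuple[ConfusionSummary, ConfusionSummary]:
    """Observed and label-permuted cross-validated confusion matrices.

    Each repetition re-randomises the stratified folds; the permuted
    variant additionally shuffles the labels before splitting, so its
    per-class true-positive rate estimates the chance level (50% for two
    balanced classes). Matrices are averaged over repetitions and
    row-normalised to percentages.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    _, labels = encode_labels(y)
    rng = np.random.default_rng(seed)
    n_train_min = len(y) - int(np.ceil(len(y) / folds))
    a = max(1, min(n_components, Xa.shape[1], n_train_min - 1))

    def _one_variant(permute: bool) -> ConfusionSummary:
        total = np.zeros((2, 2))
        for _ in range(repetitions):
            y_rep = rng.permutation(y) if permute else y
            encoded, _ = encode_labels(y_rep)
            assignment = _stratified_folds(y_rep, folds, rng)
            counts = np.zeros((2, 2))
            for f in range(folds):
                test = assignment == f
                train = ~test
                x_mean = Xa[train].mean(axis=0)
                y_mean = encoded[train].mean()
                W, P, q, T = _nipals(
                    Xa[train] - x_mean, encoded[train] - y_mean, a
                )
                R = W @ np.linalg.inv(P.T @ W)
                scores = (Xa[test] - x_mean) @ R
                centroids, cov = _pooled_score_stats(T, encoded[train])
                pred = _mahalanobis_predict(scores, centroids, cov, labels)
                for i, true_lbl in enumerate(labels):
                    in_class = y_rep[test] == true_lbl
                    for j, pred_lbl in enumerate(labels):
                        counts[i, j] += np.sum(pred[in_class] == pred_lbl)
            total += counts / counts.sum(axis=1, keepdims=True)
        matrix = pd.DataFrame(
            100.0 * total / repetitions, index=labels, columns=labels
        )
        return ConfusionSummary(
            matrix=matrix,
            variant="permuted" if permute else "observed",
            folds=folds,
            repetitions=repetitions,
        )

    return _one_variant(False), _one_variant(True)
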