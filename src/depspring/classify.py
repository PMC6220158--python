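"""0-1-loss linear discrimination of cells from multi-frequency Re[CM] features.

With at most three features per cell (Re[CM] at each measured frequency) the
0-1 loss can be minimized essentially exactly by exhaustive search: unit
directions are enumerated on a 1-degree grid (a circle for k = 2, a sphere
for k = 3), and for each direction the optimal threshold is found among the
midpoints of consecutive sorted projections.  The resulting rule is
deterministic and reproducible — ties are broken by larger margin, then by
lexicographically smallest direction.

Multi-class discrimination uses all pairwise rules with majority voting;
statistical significance is assessed by a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearRule",
    "FitResult",
    "fit_01_linear",
    "classify_multiclass",
    "discrimination_accuracy",
    "accuracy_significance",
]


@dataclass(frozen=True)
class LinearRule:
    """Unit-norm weight vector and threshold: predict the positive class
    where ``weights @ x > threshold``."""

    weights: np.ndarray
    threshold: float
    positive_class: object
    negative_class: object

    def decision(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights - self.threshold

    def predict(self, features: np.ndarray) -> np.ndarray:
        d = self.decision(features)
        return np.where(d > 0, self.positive_class, self.negative_class)


@dataclass(frozen=True)
class FitResult:
    """A fitted rule plus its training 0-1 performance."""

    rule: LinearRule
    n_errors: int
    n_samples: int

    @property
    def accuracy(self) -> float:
        return discrimination_accuracy(self.n_samples, self.n_errors)


def _direction_grid(k: int, resolution_deg: float = 1.0) -> np.ndarray:
    """Unit directions covering the sphere in k <= 3 dimensions."""
    if k == 1:
        return np.array([[1.0], [-1.0]])
    step = np.deg2rad(resolution_deg)
    if k == 2:
        ang = np.arange(0.0, 2 * np.pi, step)
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if k == 3:
        rows = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
        polar = np.arange(step, np.pi, step)
        azim = np.arange(0.0, 2 * np.pi, step)
        ca, sa = np.cos(azim), np.sin(azim)
        for th in polar:
            st, ct = np.sin(th), np.cos(th)
            rows.append(np.column_stack([st * ca, st * sa, np.full_like(azim, ct)]))
        return np.vstack([np.vstack(rows[:2]), np.vstack(rows[2:])])
    raise ValueError("exhaustive 0-1 search supports at most 3 features")


def fit_01_linear(
    features: np.ndarray, labels: np.ndarray, resolution_deg: float = 1.0
) -> FitResult:
    """Exact-search linear rule minimizing training 0-1 loss (k <= 3).

    Ties between (direction, threshold) candidates break toward the larger
    margin, then the lexicographically smallest direction vector.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("fit_01_linear needs exactly two classes present")
    neg, pos = classes[0], classes[1]
    positive = y == pos
    k = X.shape[1]
    directions = _direction_grid(k, resolution_deg)

    n = len(y)
    n_pos = int(positive.sum())
    best = None  # ((errors, -margin, direction tuple), weights, threshold)
    # the direction grid is large for k = 3 (~65k); evaluate in vectorized chunks
    for start in range(0, len(directions), 4096):
        D = directions[start : start + 4096]
        P = X @ D.T  # (n, m)
        order = np.argsort(P, axis=0, kind="stable")
        p_sorted = np.take_along_axis(P, order, axis=0)
        pos_sorted = positive[order]
        cum_pos = np.vstack([np.zeros(D.shape[0], dtype=int), np.cumsum(pos_sorted, axis=0)])
        above = (n - np.arange(n + 1))[:, None]
        errors = cum_pos + above - (n_pos - cum_pos)  # (n+1, m)
        gaps = np.full((n + 1, D.shape[0]), np.inf)
        mids = np.empty((n + 1, D.shape[0]))
        spread = np.maximum(p_sorted[-1] - p_sorted[0], 1.0)
        mids[0] = p_sorted[0] - spread
        mids[-1] = p_sorted[-1] + spread
        if n > 1:
            d = np.diff(p_sorted, axis=0)
            mids[1:-1] = p_sorted[:-1] + d / 2
            gaps[1:-1] = d / 2
        col_err = errors.min(axis=0)
        # per column: the largest-margin cut among its minimal-error cuts
        cut = np.argmax(np.where(errors == col_err[None, :], gaps, -np.inf), axis=0)
        cols = np.arange(D.shape[0])
        margin = gaps[cut, cols]
        margin = np.where(np.isfinite(margin), margin, spread)
        chunk_best_err = int(col_err.min())
        if best is not None and chunk_best_err > best[0][0]:
            continue
        cand = np.flatnonzero(col_err == chunk_best_err)
        cand = cand[margin[cand] == margin[cand].max()]
        j = min(cand, key=lambda c: tuple(D[c]))  # lexicographic direction tie-break
        key = (chunk_best_err, -float(margin[j]), tuple(D[j]))
        if best is None or key < best[0]:
            best = (key, D[j], float(mids[cut[j], j]))
    (err, _, _), w, t = best
    rule = LinearRule(weights=w.copy(), threshold=t, positive_class=pos, negative_class=neg)
    return FitResult(rule=rule, n_errors=err, n_samples=len(y))


@dataclass(frozen=True)
class MulticlassResult:
    """Pairwise rules + majority vote over >= 2 classes."""

    rules: dict[tuple[object, object], LinearRule]
    predictions: np.ndarray
    n_errors: int
    n_samples: int

    @property
    def accuracy(self) -> float:
        return discrimination_accuracy(self.n_samples, self.n_errors)


def classify_multiclass(
    features: np.ndarray, labels: np.ndarray, resolution_deg: float = 1.0
) -> MulticlassResult:
    """One-vs-one 0-1-loss rules with majority vote.

    Vote ties are broken toward the tied class whose feature-space centroid is
    nearest to the sample.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes = list(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes present")
    rules = {}
    votes = {c: np.zeros(len(y), dtype=int) for c in classes}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            sel = (y == a) | (y == b)
            fit = fit_01_linear(X[sel], y[sel], resolution_deg=resolution_deg)
            rules[(a, b)] = fit.rule
            pred = fit.rule.predict(X)
            for c in (a, b):
                votes[c] += pred == c
    vote_matrix = np.column_stack([votes[c] for c in classes])
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    dists = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
    top = vote_matrix.max(axis=1)
    # mask non-top classes with infinite distance, then take the nearest centroid
    masked = np.where(vote_matrix == top[:, None], dists, np.inf)
    predictions = np.asarray(classes, dtype=object)[np.argmin(masked, axis=1)]
    n_errors = int(np.sum(predictions != y))
    return MulticlassResult(
        rules=rules, predictions=predictions, n_errors=n_errors, n_samples=len(y)
    )


def discrimination_accuracy(n_tested: int, n_errors: int) -> float:
    """(cells tested - errors made) / cells tested."""
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not 0 <= n_errors <= n_tested:
        raise ValueError("need 0 <= n_errors <= n_tested")
    return (n_tested - n_errors) / n_tested


def accuracy_significance(
    features: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    fitter=None,
) -> float:
    """Label-permutation p-value for the training discrimination accuracy.

    ``fitter(features, labels)`` must return an object with an ``accuracy``
    attribute; defaults to :func:`fit_01_linear` for two classes and
    :func:`classify_multiclass` otherwise.  p = (1 + #{permuted >= observed})
    / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if fitter is None:
        fitter = fit_01_linear if len(np.unique(y)) == 2 else classify_multiclass
    observed = fitter(X, y).accuracy
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        hits += fitter(X, perm).accuracy >= observed
    return (1 + hits) / (1 + n_permutations)
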