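"""Weighted k-means++ classification of implant sizes.

The feature vector of an implant is (D, L): its radiographic diameter and
length in millimetres.  Because the nine catalogue sizes span only 1.5 mm
in diameter but 4 mm in length, the raw Euclidean metric under-weights the
diameter; an anisotropic stretch

    f(D, L) = (w*D, L),  w > 0

of the feature plane compensates.  Clustering with k-means++ (distance-
squared-proportional seeding followed by Lloyd iterations) in the stretched
plane with k = 9 yields one cluster per size; the cluster -> size-code
bijection is fixed on training data by optimal assignment, after which
prediction is nearest-centroid.  The stretch factor w is tuned on a grid
(default integers 1..10) by classification accuracy on a selection set.

Everything here is implemented directly — seeding, Lloyd iterations, the
bijective cluster-label assignment — so that each step is reproducible and
auditable; no clustering library is wrapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import CardinalityError, InsufficientDataError, ModelStateError


def transform(features, w: float) -> np.ndarray:
    """Anisotropic stretch f(D, L) = (w*D, L) of feature vectors.

    ``features`` is (n, 2) or a single (D, L) pair; w must be positive.
    At w = 1 this is the identity.
    """
    if not w > 0:
        raise ValueError(f"weight w must be positive, got {w}")
    pts = np.array(features, dtype=float, copy=True)
    pts[..., 0] *= w
    return pts


def kmeanspp_seed(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Choose k initial centroids by distance-squared-proportional sampling.

    The first centroid is uniform over the points; each subsequent one is
    drawn with probability proportional to its squared Euclidean distance
    to the nearest centroid already chosen (the classic "++" seeding,
    without greedy local trials).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if len(np.unique(points, axis=0)) < k:
        raise InsufficientDataError(
            f"need at least {k} distinct points to seed {k} clusters"
        )
    chosen = np.empty((k, points.shape[1]))
    idx = int(rng.integers(n))
    chosen[0] = points[idx]
    d2 = ((points - chosen[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        probs = d2 / total
        idx = int(rng.choice(n, p=probs))
        chosen[j] = points[idx]
        d2 = np.minimum(d2, ((points - chosen[j]) ** 2).sum(axis=1))
    return chosen


def lloyd_fit(
    points: np.ndarray,
    initial_centroids: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iterations from given centroids.

    Alternates nearest-centroid assignment and mean update until the
    relative inertia change drops below ``tol`` or ``max_iter`` is reached.
    A cluster left empty by an assignment step is re-seeded with the point
    farthest from its currently assigned centroid.  Returns
    ``(centroids, assignment, inertia, inertia_history)``; the history is
    monotonically non-increasing.
    """
    points = np.asarray(points, dtype=float)
    centroids = np.array(initial_centroids, dtype=float, copy=True)
    k = len(centroids)
    n = len(points)
    history: list[float] = []
    prev = np.inf
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(points, centroids, "sqeuclidean")
        assign = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(assign == c):
                # farthest point from its own centroid becomes the seed
                far = int(d2[np.arange(n), assign].argmax())
                assign[far] = c
                d2[far] = 0.0  # keep it from being stolen by another empty cluster
        for c in range(k):
            centroids[c] = points[assign == c].mean(axis=0)
        inertia = float(
            ((points - centroids[assign]) ** 2).sum()
        )
        history.append(inertia)
        if prev < np.inf and (prev - inertia) <= tol * max(prev, 1e-300):
            break
        prev = inertia
    # final assignment consistent with returned centroids
    d2 = cdist(points, centroids, "sqeuclidean")
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), assign].sum())
    return centroids, assign, inertia, history


@dataclass(frozen=True)
class ClusterModel:
    """A fitted weighted k-means model in the stretched (w*D, L) plane.

    ``label_map`` (cluster index -> size code) is None until fixed by
    :func:`map_clusters_to_labels`; with k = 9 it is a bijection onto the
    nine catalogue codes.
    """

    k: int
    w: float
    centroids: np.ndarray
    inertia: float
    label_map: dict[int, str] | None = None
    seed: int | None = None

    def centroids_feature_plane(self) -> np.ndarray:
        """Centroids mapped back to the raw (D, L) plane (mm units)."""
        out = self.centroids.copy()
        out[:, 0] /= self.w
        return out


def fit(
    features,
    k: int = 9,
    w: float = 1.0,
    n_init: int = 10,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Fit k-means++ in the stretched plane; keep the best of ``n_init`` runs.

    Each restart gets an independent child seed spawned from ``seed``, so
    the whole fit is bit-reproducible.
    """
    pts = transform(features, w)
    ss = np.random.SeedSequence(seed)
    best: tuple[float, np.ndarray] | None = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        init = kmeanspp_seed(pts, k, rng)
        centroids, _, inertia, _ = lloyd_fit(pts, init, max_iter=max_iter, tol=tol)
        if best is None or inertia < best[0]:
            best = (inertia, centroids)
    assert best is not None
    return ClusterModel(k=k, w=w, centroids=best[1], inertia=best[0], seed=seed)


def assign_clusters(model: ClusterModel, features) -> np.ndarray:
    """Index of the nearest centroid for each feature vector (ties -> lowest)."""
    pts = transform(np.atleast_2d(np.asarray(features, dtype=float)), model.w)
    d2 = cdist(pts, model.centroids, "sqeuclidean")
    return d2.argmin(axis=1)


def _lexicographic_optimal_assignment(contingency: np.ndarray) -> list[int]:
    """Agreement-maximising bijection rows->columns, lexicographically smallest.

    Among all bijections maximising sum_i C[i, sigma(i)], returns the one
    whose column sequence (sigma(0), sigma(1), ...) is lexicographically
    smallest.  Columns are assumed pre-sorted (ascending size code), so
    "smallest column index" means "smallest code".
    """
    cont = np.asarray(contingency, dtype=float)
    k = cont.shape[0]
    if cont.shape[1] != k:
        raise CardinalityError(f"contingency must be square, got {cont.shape}")

    def best_value(matrix: np.ndarray) -> float:
        if matrix.size == 0:
            return 0.0
        r, c = linear_sum_assignment(-matrix)
        return float(matrix[r, c].sum())

    target = best_value(cont)
    chosen: list[int] = []
    used: set[int] = set()
    fixed = 0.0
    for i in range(k):
        remaining_rows = np.arange(i + 1, k)
        for j in range(k):
            if j in used:
                continue
            cols = np.array([c for c in range(k) if c not in used and c != j], dtype=int)
            sub = cont[np.ix_(remaining_rows, cols)]
            if fixed + cont[i, j] + best_value(sub) >= target - 1e-9:
                chosen.append(j)
                used.add(j)
                fixed += cont[i, j]
                break
        else:  # pragma: no cover - cannot happen for a square matrix
            raise RuntimeError("assignment search failed")
    return chosen


def map_clusters_to_labels(
    model: ClusterModel, features, true_codes: Sequence[str]
) -> ClusterModel:
    """Fix the cluster -> size-code bijection on labelled training data.

    Builds the k x k contingency of cluster index vs true code and chooses
    the bijection maximising total agreement (optimal assignment); among
    ties, the lexicographically smallest code sequence.  A cluster with no
    training points still receives a code (its contingency row is zero).
    """
    true_codes = list(true_codes)
    codes = sorted(set(true_codes))
    if len(codes) > model.k:
        raise CardinalityError(
            f"{len(codes)} distinct labels but only {model.k} clusters"
        )
    if len(codes) < model.k:
        raise CardinalityError(
            f"{len(codes)} distinct labels for {model.k} clusters; "
            "a bijection requires equal counts"
        )
    assign = assign_clusters(model, features)
    if len(assign) != len(true_codes):
        raise CardinalityError("features and true_codes length mismatch")
    code_index = {c: j for j, c in enumerate(codes)}
    cont = np.zeros((model.k, model.k), dtype=np.int64)
    for a, code in zip(assign, true_codes):
        cont[a, code_index[code]] += 1
    perm = _lexicographic_optimal_assignment(cont)
    label_map = {i: codes[perm[i]] for i in range(model.k)}
    return replace(model, label_map=label_map)


def predict(model: ClusterModel, features) -> list[str]:
    """Size code of the nearest centroid for each (D, L) feature vector."""
    if model.label_map is None:
        raise ModelStateError("model has no cluster->label map; fit and map first")
    assign = assign_clusters(model, features)
    return [model.label_map[int(a)] for a in assign]


def accuracy(true_codes: Sequence[str], pred_codes: Sequence[str]) -> float:
    """Fraction of exact size-code agreements."""
    true_codes, pred_codes = list(true_codes), list(pred_codes)
    if len(true_codes) != len(pred_codes):
        raise CardinalityError("sequences differ in length")
    if not true_codes:
        raise ValueError("empty sequences")
    hits = sum(t == p for t, p in zip(true_codes, pred_codes))
    return hits / len(true_codes)


def tune_weight(
    train_features,
    train_codes: Sequence[str],
    selection_features,
    selection_codes: Sequence[str],
    w_grid: Sequence[float] = tuple(range(1, 11)),
    k: int | None = None,
    n_init: int = 10,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[float, list[tuple[float, float]], ClusterModel]:
    """Grid-search the diameter weight w by selection-set accuracy.

    For every w in the grid a fresh model is fitted and label-mapped on the
    training data, then scored on the selection set.  Returns
    ``(best_w, curve, best_model)`` where ``curve`` is the list of
    (w, accuracy) pairs in grid order; accuracy ties resolve to the
    smallest w.
    """
    w_grid = list(w_grid)
    if not w_grid:
        raise ValueError("w_grid must be non-empty")
    if any(not w > 0 for w in w_grid):
        raise ValueError("all weights must be positive")
    if k is None:
        k = len(set(train_codes))
    curve: list[tuple[float, float]] = []
    best: tuple[float, float, ClusterModel] | None = None  # (acc, w, model)
    for w in sorted(w_grid):
        model = fit(train_features, k=k, w=w, n_init=n_init, seed=seed,
                    max_iter=max_iter, tol=tol)
        model = map_clusters_to_labels(model, train_features, train_codes)
        acc = accuracy(selection_codes, predict(model, selection_features))
        curve.append((w, acc))
        if best is None or acc > best[0]:
            best = (acc, w, model)
    assert best is not None
    return best[1], curve, best[2]


def save_model(model: ClusterModel, path) -> None:
    """Serialise a model (with or without label map) to JSON."""
    doc = {
        "k": model.k,
        "w": model.w,
        "centroids": model.centroids.tolist(),
        "inertia": model.inertia,
        "label_map": (
            {str(i): c for i, c in model.label_map.items()}
            if model.label_map is not None
            else None
        ),
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_model(path) -> ClusterModel:
    """Load a model serialised by :func:`save_model`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    label_map = doc["label_map"]
    return ClusterModel(
        k=int(doc["k"]),
        w=float(doc["w"]),
        centroids=np.asarray(doc["centroids"], dtype=float),
        inertia=float(doc["inertia"]),
        label_map=(
            {int(i): str(c) for i, c in label_map.items()} if label_map else None
        ),
        seed=doc.get("seed"),
    )
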