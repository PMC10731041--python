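"""K-means connectivity states and elbow-based model selection.

All subjects' windowed FNC matrices are pooled, vectorized to their
upper triangles, and clustered with k-means (Euclidean distance,
k-means++ starts, best of ``n_replicates`` initializations).  The number
of states is chosen by an elbow criterion on the within-/between-cluster
dispersion ratio curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .windows import WindowedFNCSeries

__all__ = [
    "ConnectivityStateKMeans",
    "StateModel",
    "ElbowCurve",
    "matrices_to_features",
    "features_to_matrix",
    "cluster_states",
    "elbow_select",
    "top_edges",
    "match_states",
]


def matrices_to_features(matrices: np.ndarray) -> np.ndarray:
    """Vectorize N×C×C symmetric matrices to their C(C−1)/2 upper triangles."""
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim == 2:
        matrices = matrices[None]
    c = matrices.shape[-1]
    iu = np.triu_indices(c, k=1)
    return matrices[:, iu[0], iu[1]]


def features_to_matrix(features: np.ndarray, n_components: int) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from an upper-triangle vector."""
    m = np.zeros((n_components, n_components))
    iu = np.triu_indices(n_components, k=1)
    m[iu] = features
    return m + m.T


class ConnectivityStateKMeans(BaseEstimator, ClusterMixin):
    """Best-of-replicates k-means over vectorized connectivity windows.

    Accepts an (N, E) feature matrix or an (N, C, C) stack of symmetric
    matrices.  States are numbered 1..k in fit order; ties in nearest-
    centroid assignment resolve to the lowest state id (sklearn argmin
    convention), and the whole fit is deterministic given ``random_state``.

    Attributes
    ----------
    centroids_ : (k, C, C) symmetric state centroids (or (k, E) when the
        input was already vectorized).
    labels_ : 1-based state label per window.
    inertia_ : within-cluster sum of squared Euclidean distances.
    occurrence_percent_ : per state, percentage of all windows assigned.
    """

    def __init__(self, k: int = 4, n_replicates: int = 100, random_state: int | None = None):
        self.k = k
        self.n_replicates = n_replicates
        self.random_state = random_state

    def _features(self, X) -> tuple[np.ndarray, int | None]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return matrices_to_features(X), X.shape[-1]
        return X, None

    def fit(self, X, y=None):
        feats, c = self._features(X)
        if feats.shape[0] < self.k:
            raise ValueError(f"need at least k={self.k} windows, got {feats.shape[0]}")
        km = KMeans(
            n_clusters=self.k,
            n_init=self.n_replicates,
            init="k-means++",
            random_state=self.random_state,
        ).fit(feats)
        self.n_components_ = c
        self.kmeans_ = km
        self.centroid_features_ = km.cluster_centers_
        if c is not None:
            self.centroids_ = np.stack(
                [features_to_matrix(f, c) for f in km.cluster_centers_]
            )
        else:
            self.centroids_ = km.cluster_centers_
        self.labels_ = km.labels_ + 1
        self.inertia_ = float(km.inertia_)
        counts = np.bincount(km.labels_, minlength=self.k)
        self.occurrence_percent_ = 100.0 * counts / counts.sum()
        return self

    def predict(self, X) -> np.ndarray:
        feats, _ = self._features(X)
        return self.kmeans_.predict(feats) + 1


@dataclass
class StateModel:
    """Fitted connectivity states plus per-subject window labels."""

    k: int
    centroids: np.ndarray  # k x C x C
    labels_by_subject: dict[str, np.ndarray]  # 1-based labels per window
    inertia: float
    occurrence_percent: np.ndarray
    random_state: int | None = None

    @property
    def n_components(self) -> int:
        return self.centroids.shape[-1]

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "inertia": self.inertia,
            "random_state": self.random_state,
            "occurrence_percent": self.occurrence_percent.tolist(),
            "centroids": self.centroids.tolist(),
            "labels_by_subject": {s: l.tolist() for s, l in self.labels_by_subject.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _exemplar_windows(stack: np.ndarray) -> np.ndarray:
    """Local maxima of per-window connectivity variance (one subject)."""
    feats = matrices_to_features(stack)
    v = feats.var(axis=1)
    peaks = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    idx = np.flatnonzero(peaks) + 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(v))])
    return stack[idx]


def cluster_states(
    windows_by_subject: dict[str, WindowedFNCSeries] | list[WindowedFNCSeries],
    k: int = 4,
    n_replicates: int = 100,
    random_state: int | None = None,
    exemplar_init: bool = False,
) -> StateModel:
    """Pool all subjects' windows, cluster into k states, split labels back.

    With ``exemplar_init`` the replicated k-means runs on each subject's
    high-variance exemplar windows first and the full dataset is then
    fit once from those centroids (the two-stage toolbox strategy);
    otherwise all windows are clustered directly.
    """
    if not isinstance(windows_by_subject, dict):
        windows_by_subject = {w.subject_id: w for w in windows_by_subject}
    subjects = list(windows_by_subject)
    stacks = [windows_by_subject[s].matrices for s in subjects]
    pooled = np.concatenate(stacks)
    if exemplar_init:
        exemplars = np.concatenate([_exemplar_windows(s) for s in stacks])
        first = ConnectivityStateKMeans(k, n_replicates, random_state).fit(exemplars)
        km = KMeans(n_clusters=k, n_init=1, init=first.centroid_features_).fit(
            matrices_to_features(pooled)
        )
        est = ConnectivityStateKMeans(k, 1, random_state)
        est.n_components_ = pooled.shape[-1]
        est.kmeans_ = km
        est.centroid_features_ = km.cluster_centers_
        est.centroids_ = np.stack(
            [features_to_matrix(f, pooled.shape[-1]) for f in km.cluster_centers_]
        )
        est.labels_ = km.labels_ + 1
        est.inertia_ = float(km.inertia_)
        counts = np.bincount(km.labels_, minlength=k)
        est.occurrence_percent_ = 100.0 * counts / counts.sum()
    else:
        est = ConnectivityStateKMeans(k, n_replicates, random_state).fit(pooled)
    bounds = np.cumsum([0] + [s.shape[0] for s in stacks])
    labels = {
        subj: est.labels_[bounds[i] : bounds[i + 1]] for i, subj in enumerate(subjects)
    }
    return StateModel(
        k=k,
        centroids=est.centroids_,
        labels_by_subject=labels,
        inertia=est.inertia_,
        occurrence_percent=est.occurrence_percent_,
        random_state=random_state,
    )


@dataclass
class ElbowCurve:
    """Within/between dispersion ratio over candidate k, with the elbow pick."""

    k_values: np.ndarray
    criterion: np.ndarray  # WSS / BSS per k
    selected_k: int
    distances: np.ndarray  # normalized perpendicular distance per k
    weak_elbow: bool


def kneedle(ks: np.ndarray, crit: np.ndarray, weak_tol: float = 1e-3) -> tuple[int, np.ndarray, bool]:
    """Maximum-curvature point of a criterion-vs-k curve.

    Both axes are min-max normalized; the chosen k maximizes the
    perpendicular distance to the chord joining the endpoints.  The
    selection is flagged weak when no point departs from the chord by
    more than ``weak_tol`` of the normalized range (a near-linear curve
    carries no elbow information).
    """
    ks = np.asarray(ks, dtype=float)
    crit = np.asarray(crit, dtype=float)
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    rng_c = crit.max() - crit.min()
    y = (crit - crit.min()) / rng_c if rng_c > 0 else np.zeros_like(crit)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = float(np.hypot(dx, dy))
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    selected = int(ks[int(np.argmax(dist))])
    weak = bool(dist.max() < weak_tol)
    return selected, dist, weak


def elbow_select(
    windows,
    k_min: int = 2,
    k_max: int = 10,
    n_replicates: int = 20,
    random_state: int | None = None,
    weak_tol: float = 1e-3,
) -> ElbowCurve:
    """Choose the number of states at the maximum-curvature (kneedle) point.

    For each k the criterion is the ratio of within-cluster to
    between-cluster sum of squared distances.  Both axes are min-max
    normalized and the selected k maximizes the perpendicular distance
    to the chord joining the curve's endpoints; if that distance never
    exceeds ``weak_tol`` the curve is near-linear and the selection is
    flagged as a weak elbow.
    """
    if isinstance(windows, dict):
        feats = matrices_to_features(
            np.concatenate([w.matrices for w in windows.values()])
        )
    else:
        feats, _ = ConnectivityStateKMeans()._features(windows)
    if k_max <= k_min:
        raise ValueError("k_max must exceed k_min")
    tss = float(((feats - feats.mean(axis=0)) ** 2).sum())
    ks = np.arange(k_min, k_max + 1)
    crit = np.empty(ks.size)
    for i, k in enumerate(ks):
        wss = float(
            KMeans(n_clusters=int(k), n_init=n_replicates, random_state=random_state)
            .fit(feats)
            .inertia_
        )
        bss = max(tss - wss, 1e-12)
        crit[i] = wss / bss
    # Selection runs on the between/within curve anchored at its exact k=1
    # value (BSS/WSS = 0 since WSS(1) = TSS).  Anchoring makes k_min an
    # interior point, so a true elbow at the smallest searched k is still
    # selectable; the perpendicular-distance rule is unchanged otherwise.
    selected, dist_aug, weak = kneedle(
        np.concatenate([[1], ks]), np.concatenate([[0.0], 1.0 / crit]), weak_tol
    )
    dist = dist_aug[1:]
    if selected == 1:  # anchor itself can never be the answer
        selected = int(ks[int(np.argmax(dist))])
    if weak:
        warnings.warn(
            "weak elbow: criterion curve is near-linear, selected k is unreliable",
            stacklevel=2,
        )
    return ElbowCurve(ks, crit, selected, dist, weak)


def top_edges(
    centroid: np.ndarray,
    fraction: float = 0.05,
    component_ids: list[str] | None = None,
    network_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Strongest connections of one state centroid.

    Returns the ceil(fraction · C(C−1)/2) unordered component pairs with
    the largest |z|, sorted descending, tagged by sign and network pair.
    """
    centroid = np.asarray(centroid, dtype=float)
    c = centroid.shape[0]
    if not np.allclose(centroid, centroid.T, atol=1e-9):
        raise ValueError("centroid must be symmetric")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    iu = np.triu_indices(c, k=1)
    z = centroid[iu]
    n_keep = int(np.ceil(fraction * z.size))
    order = np.argsort(-np.abs(z), kind="stable")[:n_keep]
    ids = component_ids or [f"IC{j + 1}" for j in range(c)]
    rows = []
    for idx in order:
        i, j = int(iu[0][idx]), int(iu[1][idx])
        row = {
            "component_i": ids[i],
            "component_j": ids[j],
            "z": float(z[idx]),
            "sign": "positive" if z[idx] >= 0 else "negative",
        }
        if network_labels is not None:
            pair = sorted([network_labels[i], network_labels[j]])
            row["network_pair"] = f"{pair[0]}-{pair[1]}"
        rows.append(row)
    return pd.DataFrame(rows)


def match_states(
    centroids: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of fitted centroids to reference matrices.

    Maximizes the summed Pearson correlation between upper-triangle
    vectors.  Returns ``(assignment, correlations)`` where
    ``assignment[i]`` is the reference index matched to centroid i.
    Intended for validation against planted templates; downstream
    statistics never depend on state numbering.
    """
    a = matrices_to_features(np.asarray(centroids))
    b = matrices_to_features(np.asarray(reference))
    corr = np.corrcoef(a, b)[: a.shape[0], a.shape[0] :]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]
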