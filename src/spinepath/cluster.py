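"""K-means clustering of normalized spinal curves with silhouette model selection.

Patients at each timepoint are clustered on the 34-dimensional feature
vector of their normalized curve using Lloyd's algorithm with k-means++
seeding, run from many random restarts; the restart with the smallest
within-cluster sum of squared Euclidean distances (SSE) wins.  The number
of clusters k is chosen by maximizing the mean silhouette value over a
candidate range, ties going to the smaller k.

Cluster labels produced by k-means are arbitrary, so results are
canonicalized: clusters are renumbered 1..k by descending size, ties broken
by lexicographic comparison of their centers.  With a fixed seed and
restart count the whole procedure is bit-reproducible.

The model/results split follows the usual statistical-modelling idiom:
:class:`CurveClusterModel` holds the data, ``fit(k)`` / ``select_k()``
return an immutable :class:`CurveClusterResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import Timepoint
from .normalize import NormalizedCurve

__all__ = [
    "CurveClusterModel",
    "CurveClusterResults",
    "kmeans_cluster",
    "mean_silhouette",
    "select_k",
    "canonicalize_labels",
]

DEFAULT_RESTARTS = 100
DEFAULT_SEED = 20181102
SSE_TOL = 1e-10


class DegenerateDataError(ValueError):
    """All points coincide; k >= 2 clustering is undefined."""


def _as_features(features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _kmeanspp_init(X: np.ndarray, k: int, restarts: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for all restarts at once; returns (restarts, k, d)."""
    n = X.shape[0]
    centers = np.empty((restarts, k, X.shape[1]))
    first = rng.integers(n, size=restarts)
    centers[:, 0] = X[first]
    # squared distance of every point to its nearest chosen center, per restart
    d2 = np.sum((X[None, :, :] - centers[:, 0, None, :]) ** 2, axis=2)
    for j in range(1, k):
        total = d2.sum(axis=1)
        # degenerate restart (all remaining distances 0): fall back to uniform
        probs = np.where(total[:, None] > 0, d2 / np.maximum(total, 1e-300)[:, None], 1.0 / n)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(restarts)
        idx = np.minimum((cum < u[:, None]).sum(axis=1), n - 1)
        centers[:, j] = X[idx]
        d2 = np.minimum(d2, np.sum((X[None, :, :] - centers[:, j, None, :]) ** 2, axis=2))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-center assignment for all restarts; returns (labels, point_cost, sse)."""
    x_sq = np.einsum("nd,nd->n", X, X)
    cross = np.einsum("nd,rkd->rnk", X, centers)
    c_sq = np.einsum("rkd,rkd->rk", centers, centers)
    dists = x_sq[None, :, None] - 2.0 * cross + c_sq[:, None, :]
    np.maximum(dists, 0.0, out=dists)
    labels = dists.argmin(axis=2)
    point_cost = np.take_along_axis(dists, labels[:, :, None], axis=2)[:, :, 0]
    return labels, point_cost, point_cost.sum(axis=1)


def _update_centers(
    X: np.ndarray, labels: np.ndarray, point_cost: np.ndarray, k: int
) -> np.ndarray:
    """Means of each cluster; an empty cluster is reseeded at the costliest point."""
    R, n = labels.shape
    centers = np.empty((R, k, X.shape[1]))
    cost = point_cost.copy()
    for r in range(R):
        counts = np.bincount(labels[r], minlength=k)
        for j in range(k):
            if counts[j]:
                centers[r, j] = X[labels[r] == j].mean(axis=0)
            else:
                far = int(np.argmax(cost[r]))
                centers[r, j] = X[far]
                cost[r, far] = 0.0
    return centers


def _lloyd_batch(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run Lloyd iterations for every restart simultaneously.

    Returns (labels (R, n), centers (R, k, d), sse (R,)); at convergence the
    centers are exactly the means of their members.  SSE is asserted
    non-increasing across iterations for every restart.
    """
    k = centers.shape[1]
    prev_sse = np.full(centers.shape[0], np.inf)
    labels = None
    for _ in range(max_iter):
        new_labels, point_cost, sse = _assign(X, centers)
        # Lloyd's algorithm never increases SSE (allow FP slack)
        assert np.all(sse <= prev_sse + 1e-8 * (1.0 + np.where(np.isfinite(prev_sse), prev_sse, 0.0))), "SSE increased"
        if labels is not None and np.array_equal(new_labels, labels):
            # centers are the means of these same labels from the last update
            return labels, centers, sse
        labels = new_labels
        prev_sse = sse
        centers = _update_centers(X, labels, point_cost, k)
    # max_iter exhausted: make centers consistent with the final labels
    _, point_cost, _ = _assign(X, centers)
    centers = _update_centers(X, labels, point_cost, k)
    _, point_cost, sse = _assign(X, centers)
    return labels, centers, sse


@dataclass(frozen=True)
class CurveClusterResults:
    """Fitted clustering at one timepoint.

    ``labels`` are canonical 1-based cluster indices (1 = largest cluster);
    ``centers[i]`` is the mean feature vector of cluster i+1;
    ``silhouette_by_k`` records the mean silhouette of every candidate k
    examined during model selection (just {k: value} after a plain fit).
    """

    timepoint: Timepoint | None
    k: int
    labels: np.ndarray  # (n,), values in 1..k
    centers: np.ndarray  # (k, d)
    sse: float
    mean_silhouette: float
    patient_ids: tuple[str, ...] | None = None
    silhouette_by_k: Mapping[int, float] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def to_frame(self):
        import pandas as pd

        ids = self.patient_ids or [str(i) for i in range(len(self.labels))]
        tp = self.timepoint.value if self.timepoint else ""
        return pd.DataFrame(
            {"patient_id": ids, "timepoint": tp, "cluster": self.labels}
        )

    def summary(self) -> str:
        tp = self.timepoint.value if self.timepoint else "?"
        lines = [
            f"Curve clustering results [{tp}]",
            f"  n = {len(self.labels)}, k = {self.k}, "
            f"mean silhouette = {self.mean_silhouette:.4f}, SSE = {self.sse:.6g}",
            "  cluster sizes: "
            + ", ".join(
                f"{tp}{i + 1} n={s}" for i, s in enumerate(self.cluster_sizes)
            ),
        ]
        if len(self.silhouette_by_k) > 1:
            lines.append(
                "  silhouette by k: "
                + ", ".join(
                    f"k={k}: {v:.4f}" for k, v in sorted(self.silhouette_by_k.items())
                )
            )
        return "\n".join(lines)

    def plot_centers(self, ax=None):
        """Frontal and sagittal projections of the cluster-center curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(7, 5), sharey=True)
        d = self.centers.shape[1] // 2
        z = np.linspace(1.0, 0.0, d)
        for i, center in enumerate(self.centers):
            ax[0].plot(center[:d], z, label=f"cluster {i + 1}")
            ax[1].plot(center[d:], z)
        ax[0].set_xlabel("x (frontal)")
        ax[1].set_xlabel("y (sagittal)")
        ax[0].set_ylabel("z (unit height)")
        ax[0].legend(fontsize=8)
        return ax


class CurveClusterModel:
    """K-means model over normalized-curve feature vectors.

    Parameters
    ----------
    features : (n, d) array
        One row per patient; for spinal curves d = 34 (x1..x17, y1..y17).
    patient_ids : sequence of str, optional
    timepoint : Timepoint, optional
        Carried through to results for reporting only.
    """

    def __init__(
        self,
        features: np.ndarray,
        patient_ids: Sequence[str] | None = None,
        timepoint: Timepoint | None = None,
    ):
        self.features = _as_features(features)
        if patient_ids is not None and len(patient_ids) != len(self.features):
            raise ValueError("patient_ids length does not match features")
        self.patient_ids = tuple(patient_ids) if patient_ids is not None else None
        self.timepoint = timepoint

    @classmethod
    def from_curves(cls, curves: Sequence[NormalizedCurve]) -> "CurveClusterModel":
        if not curves:
            raise ValueError("no curves supplied")
        tps = {c.timepoint for c in curves}
        tp = tps.pop() if len(tps) == 1 else None
        return cls(
            features=np.stack([c.feature for c in curves]),
            patient_ids=[c.patient_id for c in curves],
            timepoint=tp,
        )

    def fit(
        self,
        k: int,
        restarts: int = DEFAULT_RESTARTS,
        seed: int = DEFAULT_SEED,
    ) -> CurveClusterResults:
        """Best-of-``restarts`` k-means fit with canonical labels."""
        X = self.features
        n = X.shape[0]
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds n={n}")
        if np.allclose(X, X[0]):
            raise DegenerateDataError("all feature vectors identical; cannot cluster")
        rng = np.random.default_rng(seed)
        centers0 = _kmeanspp_init(X, k, restarts, rng)
        labels_all, centers_all, sse_all = _lloyd_batch(X, centers0)
        best = int(np.argmin(sse_all))
        res = CurveClusterResults(
            timepoint=self.timepoint,
            k=k,
            labels=labels_all[best] + 1,
            centers=centers_all[best],
            sse=float(sse_all[best]),
            mean_silhouette=mean_silhouette(X, labels_all[best] + 1),
            patient_ids=self.patient_ids,
        )
        res = canonicalize_labels(res)
        return replace(res, silhouette_by_k={k: res.mean_silhouette})

    def select_k(
        self,
        k_range: Iterable[int] = range(2, 7),
        restarts: int = DEFAULT_RESTARTS,
        seed: int = DEFAULT_SEED,
    ) -> CurveClusterResults:
        """Fit every k in ``k_range`` and keep the silhouette-maximizing one.

        Ties are broken toward smaller k.  Candidate k larger than n-1 are
        invalid and rejected; an empty range is an error.
        """
        ks = sorted(set(int(k) for k in k_range))
        n = self.features.shape[0]
        if not ks:
            raise ValueError("empty k range")
        if ks[0] < 2 or ks[-1] > n - 1:
            raise ValueError(f"k range {ks} not within [2, n-1] = [2, {n - 1}]")
        sil_by_k: dict[int, float] = {}
        best_res: CurveClusterResults | None = None
        for k in ks:
            res = self.fit(k, restarts=restarts, seed=seed)
            sil_by_k[k] = res.mean_silhouette
            if best_res is None or res.mean_silhouette > best_res.mean_silhouette:
                best_res = res
        assert best_res is not None
        return replace(best_res, silhouette_by_k=sil_by_k)


def kmeans_cluster(
    features: np.ndarray,
    k: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    timepoint: Timepoint | None = None,
) -> CurveClusterResults:
    """Functional wrapper around :meth:`CurveClusterModel.fit`."""
    return CurveClusterModel(features, timepoint=timepoint).fit(
        k, restarts=restarts, seed=seed
    )


def select_k(
    features: np.ndarray,
    k_range: Iterable[int] = range(2, 7),
    restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    timepoint: Timepoint | None = None,
) -> CurveClusterResults:
    """Functional wrapper around :meth:`CurveClusterModel.select_k`."""
    return CurveClusterModel(features, timepoint=timepoint).select_k(
        k_range, restarts=restarts, seed=seed
    )


def mean_silhouette(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette value over all points, Euclidean distances.

    For point i with cluster C: a = mean distance to other members of C,
    b = min over other clusters of the mean distance to that cluster, and
    s = (b - a) / max(a, b).  Members of singleton clusters score 0.
    """
    X = _as_features(features)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(X, X)
    n = len(X)
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    # mean distance from every point to every cluster
    mean_to = np.empty((n, len(uniq)))
    for j, c in enumerate(uniq):
        mean_to[:, j] = D[:, labels == c].mean(axis=1)
    s = np.zeros(n)
    for j, c in enumerate(uniq):
        mask = labels == c
        nc = sizes[c]
        if nc == 1:
            continue  # singleton: s = 0
        a = mean_to[mask, j] * nc / (nc - 1)  # exclude self-distance
        b = np.min(np.delete(mean_to[mask], j, axis=1), axis=1)
        s[mask] = (b - a) / np.maximum(a, b)
    return float(s.mean())


def canonicalize_labels(res: CurveClusterResults) -> CurveClusterResults:
    """Renumber clusters 1..k by descending size; ties by center lexicographic order.

    Pure relabelling (a permutation); idempotent.
    """
    sizes = np.bincount(res.labels, minlength=res.k + 1)[1:]
    order = sorted(
        range(res.k), key=lambda j: (-sizes[j], tuple(res.centers[j]))
    )
    perm = np.empty(res.k, dtype=np.intp)  # old index -> new 1-based label
    for new, old in enumerate(order):
        perm[old] = new + 1
    return replace(
        res,
        labels=perm[res.labels - 1],
        centers=res.centers[order],
    )
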