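"""Unsupervised segmentation and validation metrics.

Mini-batch k-means (k = 9 for the brain workflows) segments foreground
spectra; clustering quality is summarized by the mean silhouette
coefficient; fusion fidelity by the spectral correlation coefficient (SCC,
mean per-pixel Pearson r between original and fused spectra); cross-modal
consistency by mutual information (MI, joint-histogram estimate in nats);
and agreement with a known ground-truth partition by the adjusted Rand
index (ARI).  Background pixels are excluded from clustering, silhouette
and SCC throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import adjusted_rand_score

from .datacube import DataCube, Modality
from .errors import MetricError, ParameterError, ValidationError

DEFAULT_K = 9
DEFAULT_BATCH_SIZE = 1024
DEFAULT_MAX_BATCHES = 300
DEFAULT_SILHOUETTE_MAX_POINTS = 5000
DEFAULT_MI_BINS = 64


@dataclass
class ClusterResult:
    """Per-pixel label map plus the fitted centers.

    ``labels`` is a (y, x) integer map with values in ``0..k-1`` for
    foreground pixels and ``-1`` for background; ``centers`` is the
    ``k x B`` center matrix; ``inertia`` the sum of squared distances of
    foreground spectra to their assigned centers.
    """

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    k: int
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        fg = self.labels >= 0
        if fg.any() and (self.labels[fg].max() >= self.k):
            raise ValidationError("labels exceed cluster count")
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("cluster centers must be finite")
        if self.inertia < 0:
            raise ValidationError("inertia must be >= 0")


@dataclass
class MetricsReport:
    """Validation metrics of one pipeline run."""

    silhouette_mean: float | None = None
    scc_per_modality: dict[str, float] = field(default_factory=dict)
    mi_pairs: dict[str, float] = field(default_factory=dict)
    ari: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "silhouette_mean": self.silhouette_mean,
            "scc_per_modality": self.scc_per_modality,
            "mi_pairs": self.mi_pairs,
            "ari": self.ari,
        }


def minibatch_kmeans(
    cube: DataCube,
    k: int = DEFAULT_K,
    seed: int = 0,
    batch_size: int = DEFAULT_BATCH_SIZE,
    max_batches: int = DEFAULT_MAX_BATCHES,
    n_init: int = 10,
) -> ClusterResult:
    """Mini-batch k-means over foreground spectra.

    k-means++ seeded initialization followed by uniform random mini-batch
    updates with per-center learning rates; the final label map comes from
    a full nearest-center assignment pass, with background pixels labeled
    -1.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ParameterError("k must be >= 2 (silhouette is undefined below)")
    fg = cube.foreground()
    X = cube.data[fg].astype(np.float64)
    if X.shape[0] < k:
        raise ParameterError(
            f"foreground pixel count {X.shape[0]} is below k={k}")
    # max_batches bounds the total number of mini-batch updates; sklearn
    # counts epochs, so translate.
    epochs = max(1, int(np.ceil(max_batches * batch_size / X.shape[0])))
    km = MiniBatchKMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        batch_size=batch_size,
        max_iter=epochs,
        max_no_improvement=10,
        tol=1e-4,
        random_state=int(seed),
    )
    km.fit(X)
    centers = km.cluster_centers_.astype(np.float64)
    # full assignment pass
    d2 = _sq_dists(X, centers)
    assign = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(assign)), assign].sum())
    labels = np.full(cube.data.shape[:2], -1, dtype=np.int32)
    labels[fg] = assign
    return ClusterResult(labels=labels, centers=centers, inertia=inertia,
                         k=k, seed=int(seed),
                         meta={"batch_size": batch_size,
                               "max_batches": max_batches, "n_init": n_init})


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2) if X.shape[0] * C.shape[0] * X.shape[1] < 5e7 else None
    if d2 is None:
        d2 = (X**2).sum(1)[:, None] - 2 * X @ C.T + (C**2).sum(1)[None, :]
        np.maximum(d2, 0, out=d2)
    return d2


def silhouette_mean(
    features: np.ndarray,
    labels: np.ndarray,
    max_points: int = DEFAULT_SILHOUETTE_MAX_POINTS,
    seed: int = 0,
) -> float:
    """Mean silhouette coefficient s(i) = (b_i - a_i) / max(a_i, b_i).

    ``a_i`` is the mean distance to the other members of i's cluster,
    ``b_i`` the smallest mean distance to any other cluster; singleton
    clusters score 0.  When more than ``max_points`` points are given, a
    seeded uniform subsample is scored instead (silhouette is quadratic).
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) != len(labels):
        raise ParameterError("features must be (n, B) with matching labels")
    if max_points is not None and len(features) > max_points:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(features), size=max_points, replace=False)
        features, labels = features[pick], labels[pick]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise MetricError("silhouette undefined for a single cluster")

    from scipy.spatial.distance import cdist

    n = len(features)
    s = np.zeros(n)
    dists_to = {c: cdist(features, features[labels == c]) for c in uniq}
    counts = {c: int((labels == c).sum()) for c in uniq}
    for c in uniq:
        members = labels == c
        if counts[c] == 1:
            s[members] = 0.0
            continue
        a = dists_to[c][members].sum(axis=1) / (counts[c] - 1)
        b = np.full(counts[c], np.inf)
        for other in uniq:
            if other == c:
                continue
            b = np.minimum(b, dists_to[other][members].mean(axis=1))
        denom = np.maximum(a, b)
        s[members] = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def spectral_correlation(original: DataCube, fused: DataCube,
                         modality: Modality | str) -> float:
    """Mean per-pixel Pearson correlation between original spectra and the
    fused cube's band block of the given modality (the SCC fidelity metric).

    Foreground pixels only; pixels whose spectrum is constant in either
    cube are skipped (their count is recorded in the fused provenance).
    """
    block = fused.wavelengths.band_block(modality)
    if original.data.shape[:2] != fused.data.shape[:2]:
        raise ParameterError("original and fused cubes must share spatial dims")
    if block.stop - block.start != original.n_bands:
        raise ParameterError(
            f"fused block of {Modality(modality).value} has "
            f"{block.stop - block.start} bands, original has {original.n_bands}")
    fg = original.foreground() & fused.foreground()
    A = original.data[fg].astype(np.float64)
    B = fused.data[fg][:, block].astype(np.float64)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        raise MetricError("all spectra constant; SCC undefined")
    r = (A[ok] * B[ok]).sum(axis=1) / (na[ok] * nb[ok])
    fused.meta.setdefault("scc_skipped_pixels", {})[Modality(modality).value] = int((~ok).sum())
    return float(r.mean())


def mutual_information(a: np.ndarray, b: np.ndarray,
                       bins: int = DEFAULT_MI_BINS) -> float:
    """Joint-histogram mutual information in nats.

    Both images are min-max scaled to [0, 1] and binned into a
    ``bins x bins`` equal-width joint histogram;
    ``MI = sum p_xy ln(p_xy / (p_x p_y)) >= 0`` and is symmetric.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ParameterError("images must share shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("mutual information undefined for constant images")
    a = (a - a.min()) / np.ptp(a)
    b = (b - b.min()) / np.ptp(b)
    if a.tobytes() > b.tobytes():
        a, b = b, a  # canonical order makes symmetry exact, not just analytic
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected partition agreement; background (-1) positions are
    excluded pairwise (a position is dropped when either labeling marks it
    background)."""
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise ParameterError("labelings must have equal length")
    keep = (labels_a >= 0) & (labels_b >= 0)
    if not keep.any():
        raise ValidationError("no overlapping foreground positions")
    return float(adjusted_rand_score(labels_a[keep], labels_b[keep]))
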