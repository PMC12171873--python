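"""tICA projection and k-means microstate discretisation.

tICA solves the symmetrised time-lagged generalised eigenproblem
C(tau) v = lambda C(0) v with a small ridge on C(0); the leading
eigenvectors are the slowest linear coordinates of the feature space.
Covariances are accumulated per trajectory so that trajectory boundaries
never contribute spurious transitions.  Circular features (chi1 angles)
must be encoded as (cos, sin) pairs before entering tICA; see
:func:`encode_circular`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .trajectory_io import FeatureDescriptor, FeatureTable

__all__ = ["TICAModel", "MicrostateModel", "encode_circular", "fit_tica", "fit_kmeans"]


@dataclass
class TICAModel:
    lag: int
    means: np.ndarray
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # features x n_components, C0-orthonormal
    n_components: int

    def transform(self, X) -> np.ndarray:
        if isinstance(X, FeatureTable):
            X = X.values
        return (np.asarray(X, float) - self.means) @ self.components


@dataclass
class MicrostateModel:
    k: int
    centers: np.ndarray
    labels: list  # per-trajectory microstate index arrays
    seed: int
    inertia: float

    def assign(self, projected: np.ndarray) -> np.ndarray:
        d = ((projected[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return np.argmin(d, axis=1)


def _as_arrays(features) -> list[np.ndarray]:
    if isinstance(features, FeatureTable):
        return [features.values]
    if isinstance(features, np.ndarray):
        return [features] if features.ndim == 2 else [np.atleast_2d(features)]
    return [f.values if isinstance(f, FeatureTable) else np.asarray(f, float) for f in features]


def encode_circular(table: FeatureTable) -> FeatureTable:
    """Replace each chi1 column (degrees) by (cos, sin) columns so the
    ±180° wrap does not create artificial jumps; other columns pass through."""
    cols, descs = [], []
    for j, desc in enumerate(table.descriptors):
        col = table.values[:, j]
        if desc.kind == "chi1":
            rad = np.radians(col)
            cols.append(np.cos(rad))
            descs.append(FeatureDescriptor("chi1_cos", desc.selection, "1"))
            cols.append(np.sin(rad))
            descs.append(FeatureDescriptor("chi1_sin", desc.selection, "1"))
        else:
            cols.append(col)
            descs.append(desc)
    return FeatureTable(np.column_stack(cols), descs)


def fit_tica(features, lag: int, n_components: int, reg: float | None = None) -> TICAModel:
    """Symmetrised tICA on one or more feature trajectories.

    The instantaneous covariance uses both window ends and C(tau) is
    symmetrised, which guarantees a real spectrum with |lambda| <= 1 up to
    the ridge perturbation.
    """
    trajs = _as_arrays(features)
    if any(t.shape[0] <= lag for t in trajs):
        raise ValueError(f"every trajectory must be longer than the lag ({lag})")
    d = trajs[0].shape[1]
    # pass 1: mean over both window ends
    total = np.zeros(d)
    count = 0
    for X in trajs:
        total += X[:-lag].sum(axis=0) + X[lag:].sum(axis=0)
        count += 2 * (X.shape[0] - lag)
    mean = total / count
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for X in trajs:
        a = X[:-lag] - mean
        b = X[lag:] - mean
        c0 += 0.5 * (a.T @ a + b.T @ b)
        ct += 0.5 * (a.T @ b + b.T @ a)
    c0 /= count / 2
    ct /= count / 2
    if reg is None:
        reg = 1e-6 * np.trace(c0) / d
    c0 += reg * np.eye(d)
    w, v = scipy.linalg.eigh(ct, c0)
    order = np.argsort(w)[::-1][:n_components]
    return TICAModel(
        lag=lag,
        means=mean,
        eigenvalues=w[order],
        components=v[:, order],
        n_components=n_components,
    )


def fit_kmeans(projected, k: int, seed: int) -> MicrostateModel:
    """Seeded k-means++ microstate clustering of projected coordinates.

    ``projected`` may be a single (n, d) array or a list of per-trajectory
    arrays; per-trajectory label arrays are returned either way.
    """
    trajs = _as_arrays(projected)
    X = np.vstack(trajs)
    if X.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {X.shape[0]} points")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=500,
        tol=1e-6,
        random_state=int(seed),
    ).fit(X)
    labels = []
    start = 0
    for t in trajs:
        labels.append(km.labels_[start : start + t.shape[0]].astype(int))
        start += t.shape[0]
    return MicrostateModel(
        k=k, centers=km.cluster_centers_, labels=labels, seed=int(seed), inertia=float(km.inertia_)
    )
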