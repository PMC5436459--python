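"""Population stratification: classical MDS of IBS distances + k-means.

The IBS kinship is turned into the distance D = 1 - IBS, embedded by
classical (metric) multidimensional scaling — double-centring of squared
distances and eigendecomposition — and the leading three axes are clustered
with k-means into subpopulations. When the number of subpopulations is not
imposed, it is chosen by mean silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .kinship import IBSMatrix


@dataclass
class MdsCoordinates:
    individual_ids: list[str]
    coordinates: np.ndarray  # n x k, columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray  # all n eigenvalues, decreasing
    zeroed_axes: list[int]  # requested axes with non-positive eigenvalue


@dataclass
class SubpopulationAssignment:
    individual_ids: list[str]
    labels: np.ndarray  # in 1..k
    k: int

    @property
    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.individual_ids, self.labels) if l == label]


def classical_mds(ibs: IBSMatrix, n_dims: int = 3) -> MdsCoordinates:
    """Gower's classical scaling of D = 1 - IBS.

    B = -1/2 J D^2 J with J the centring projector; coordinates are the top
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    A requested axis whose eigenvalue is not positive is zeroed and flagged.
    """
    n = ibs.values.shape[0]
    if n_dims >= n:
        raise ValueError("n_dims must be smaller than the number of individuals")
    D = 1.0 - ibs.values
    np.fill_diagonal(D, 0.0)
    D2 = D * D
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, n_dims))
    zeroed = []
    for k in range(n_dims):
        if eigvals[k] > 0:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
        else:
            zeroed.append(k)
    return MdsCoordinates(
        individual_ids=list(ibs.individual_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        zeroed_axes=zeroed,
    )


def kmeans_clusters(
    coords: MdsCoordinates,
    k: int,
    n_starts: int = 50,
    seed: int = 0,
) -> SubpopulationAssignment:
    """Lloyd's algorithm with k-means++ starts; best of ``n_starts`` by WCSS."""
    n = len(coords.individual_ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(coords.coordinates) + 1  # labels 1..k
    return SubpopulationAssignment(
        individual_ids=list(coords.individual_ids), labels=labels, k=k
    )


def choose_k(
    coords: MdsCoordinates,
    k_range=range(2, 11),
    n_starts: int = 50,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick the k maximizing mean silhouette over the candidate range."""
    k_range = list(k_range)
    n = len(coords.individual_ids)
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if np.allclose(coords.coordinates, coords.coordinates[0]):
        raise ValueError("degenerate coordinates: all individuals identical")
    rows = []
    for k in k_range:
        assignment = kmeans_clusters(coords, k, n_starts=n_starts, seed=seed)
        sil = float(silhouette_score(coords.coordinates, assignment.labels))
        rows.append({"k": k, "mean_silhouette": sil})
    diagnostics = pd.DataFrame(rows)
    best = int(diagnostics.loc[diagnostics["mean_silhouette"].idxmax(), "k"])
    return best, diagnostics
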