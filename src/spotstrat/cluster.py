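"""Stage 2: UPGMA (average-linkage) clustering of patient %Vol profiles.

Distances are Euclidean over a chosen spot list. Main clusters are obtained
by cutting the dendrogram at successively finer levels until the requested
number of non-outlier clusters remains; small branches become outliers.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

OUTLIER_LABEL = "OUT"


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree in scipy linkage encoding.

    ``linkage`` has one row per merge: (node_a, node_b, height, size); leaf
    ids are 0..n-1 in the order of ``leaves``.
    """

    leaves: tuple[str, ...]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows of 4")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("UPGMA merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclasses.dataclass(frozen=True)
class ClusterAssignment:
    """Patient -> cluster label map; main clusters ordered by size."""

    labels: dict[str, str]
    main_clusters: tuple[str, ...]

    def members(self, label: str) -> list[str]:
        return sorted(p for p, l in self.labels.items() if l == label)

    @property
    def outliers(self) -> list[str]:
        return self.members(OUTLIER_LABEL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": sorted(self.labels), "cluster": [self.labels[p] for p in sorted(self.labels)]}
        )


def euclidean_distance_matrix(
    matrix: pd.DataFrame,
    spots: Sequence[str] | None = None,
    missing: str = "zero",
) -> pd.DataFrame:
    """Pairwise Euclidean distances between patient profiles.

    ``missing="zero"`` treats an undetected spot as true zero abundance;
    ``missing="pairwise"`` restricts each pair to spots measured in both
    (scaled back to the full spot count).
    """
    if spots is not None:
        if len(spots) == 0:
            raise ValueError("spot list is empty")
        missing_cols = [s for s in spots if s not in matrix.columns]
        if missing_cols:
            raise ValueError(f"spots not in profile matrix: {missing_cols}")
        matrix = matrix[list(spots)]
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if matrix.shape[1] == 0:
        raise ValueError("spot list is empty")
    values = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(values), axis=1).any():
        bad = matrix.index[np.all(np.isnan(values), axis=1)][0]
        raise ValueError(f"profile {bad!r} has no measured spots")
    if missing == "zero":
        dist = squareform(pdist(np.nan_to_num(values, nan=0.0), metric="euclidean"))
    elif missing == "pairwise":
        n, p = values.shape
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = ~np.isnan(values[i]) & ~np.isnan(values[j])
                if not both.any():
                    raise ValueError(
                        f"profiles {matrix.index[i]!r} and {matrix.index[j]!r} share no spots"
                    )
                d2 = np.sum((values[i, both] - values[j, both]) ** 2) * (p / both.sum())
                dist[i, j] = dist[j, i] = np.sqrt(d2)
    else:
        raise ValueError(f"unknown missing-value policy {missing!r}")
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def upgma(dist_matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix."""
    values = dist_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("distance matrix contains non-finite values")
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(leaves=tuple(str(i) for i in dist_matrix.index), linkage=linkage)


def _canonical_labels(groups: list[list[str]]) -> dict[str, str]:
    """Name main clusters C1, C2, ... by decreasing size, ties by smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    labels: dict[str, str] = {}
    for rank, group in enumerate(ordered, start=1):
        for member in group:
            labels[member] = f"C{rank}"
    return labels


def extract_clusters(
    dendrogram: Dendrogram, k_main: int = 2, outlier_max_size: int = 1
) -> ClusterAssignment:
    """Cut the tree into ``k_main`` main clusters plus outliers.

    The tree is cut at 2, 3, ... clusters; at each cut, branches with at most
    ``outlier_max_size`` leaves count as outliers. The first cut yielding
    exactly ``k_main`` non-outlier branches is used. If no cut does, the cut
    with the largest feasible number of main clusters is kept with a warning.
    """
    if k_main < 1:
        raise ValueError("k_main must be >= 1")
    n = len(dendrogram.leaves)
    best: tuple[int, list[list[str]]] | None = None
    for m in range(k_main, n + 1):
        flat = hierarchy.fcluster(dendrogram.linkage, t=m, criterion="maxclust")
        groups: dict[int, list[str]] = {}
        for leaf, cl in zip(dendrogram.leaves, flat):
            groups.setdefault(int(cl), []).append(leaf)
        mains = [g for g in groups.values() if len(g) > outlier_max_size]
        if len(mains) == k_main:
            best = (m, mains)
            break
        if mains and (best is None or len(mains) > len(best[1])):
            best = (m, mains)
    if best is None:  # every branch is outlier-sized; treat all leaves as one cluster
        warnings.warn("tree exhausted before any main cluster emerged; returning one cluster")
        mains = [list(dendrogram.leaves)]
    else:
        mains = best[1]
        if len(mains) != k_main:
            warnings.warn(
                f"requested {k_main} main clusters but only {len(mains)} separable; "
                "returning fewer"
            )
    labels = _canonical_labels(mains)
    assigned = set(labels)
    for leaf in dendrogram.leaves:
        if leaf not in assigned:
            labels[leaf] = OUTLIER_LABEL
    main_order = tuple(
        sorted({l for l in labels.values() if l != OUTLIER_LABEL}, key=lambda s: int(s[1:]))
    )
    return ClusterAssignment(labels=labels, main_clusters=main_order)


def cluster_profiles(
    matrix: pd.DataFrame,
    spots: Sequence[str] | None = None,
    k_main: int = 2,
    outlier_max_size: int = 1,
    missing: str = "zero",
) -> tuple[Dendrogram, ClusterAssignment]:
    """Distance matrix -> UPGMA -> cluster extraction, in one call."""
    dist = euclidean_distance_matrix(matrix, spots=spots, missing=missing)
    dendro = upgma(dist)
    return dendro, extract_clusters(dendro, k_main=k_main, outlier_max_size=outlier_max_size)


def assignment_from_mapping(mapping: Mapping[str, str]) -> ClusterAssignment:
    """Build a ClusterAssignment from an explicit patient -> label map."""
    labels = {str(k): str(v) for k, v in mapping.items()}
    mains = sorted({v for v in labels.values() if v != OUTLIER_LABEL})
    return ClusterAssignment(labels=labels, main_clusters=tuple(mains))
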