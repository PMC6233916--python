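"""Component clustering from distance-correlation structure.

Pairwise dependence between allergen-component IgE levels is measured with
Székely's distance correlation (dCor), which detects nonlinear as well as
linear association and is zero (in the population) only under independence.
Components are clustered on the dissimilarity ``1 - dCor`` with average
linkage and a fixed dendrogram cut; a divisive (DIANA) and a k-medoids (PAM)
partition act as robustness comparators via the Rand index; a weighted
connectivity graph summarises the co-expression structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import CRDMatrix

logger = logging.getLogger(__name__)

#: Default dendrogram cut on the 1 - dCor scale.
DEFAULT_CUT_HEIGHT = 0.40


def _centered_distance(x: np.ndarray) -> np.ndarray:
    """Double-centred Euclidean distance matrix of a 1-D sample."""
    x = np.asarray(x, dtype=float).ravel()
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two equal-length vectors, in [0, 1].

    Computed from double-centred pairwise-distance matrices:
    ``dCov^2 = mean(A * B)``, ``dCor = dCov / sqrt(dVar_x * dVar_y)``.
    Defined as 0 when either vector is constant (the statistic is 0/0).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    a = _centered_distance(x)
    b = _centered_distance(y)
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    dcov2 = (a * b).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


@dataclass
class DissimilarityMatrix:
    """Symmetric p x p matrix of ``1 - dCor`` values with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        d = self.to_numpy().copy()
        np.fill_diagonal(d, 0.0)
        return squareform(np.clip(d, 0.0, None), checks=False)


def dissimilarity_matrix(m: CRDMatrix, log1: bool = True) -> DissimilarityMatrix:
    """``1 - dCor`` between every pair of component columns.

    By default dependence is measured on log(x+1)-transformed ISU values, for
    consistency with the modelling stages (heavy right tails otherwise
    dominate the pairwise distances); ``log1=False`` switches to raw values.
    Constant columns get dCor 0 against everything (logged).
    """
    x = m.to_numpy()
    if log1:
        x = np.log1p(x)
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least 2 components")
    centered = np.empty((p, n, n))
    for j in range(p):
        centered[j] = _centered_distance(x[:, j])
    dvar = np.einsum("jab,jab->j", centered, centered) / (n * n)
    constant = dvar <= 0
    if constant.any():
        logger.warning(
            "constant component columns (dCor set to 0): %s",
            [m.component_ids[j] for j in np.flatnonzero(constant)],
        )
    dcor = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                continue
            dcov2 = float((centered[i] * centered[j]).mean())
            dcor[i, j] = dcor[j, i] = np.sqrt(
                max(dcov2, 0.0) / np.sqrt(dvar[i] * dvar[j])
            )
    diss = np.clip(1.0 - dcor, 0.0, 1.0)
    np.fill_diagonal(diss, 0.0)
    return DissimilarityMatrix(
        pd.DataFrame(diss, index=m.component_ids, columns=m.component_ids)
    )


@dataclass
class ComponentClustering:
    """Average-linkage dendrogram cut into flat component clusters."""

    component_ids: list
    linkage_matrix: np.ndarray
    labels: np.ndarray
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels)))

    @property
    def singleton_flags(self) -> np.ndarray:
        _, counts = np.unique(self.labels, return_counts=True)
        sizes = dict(zip(np.unique(self.labels), counts))
        return np.array([sizes[l] == 1 for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component_id": self.component_ids,
                "cluster_id": self.labels,
                "is_singleton": self.singleton_flags,
            }
        )


def agglomerative_cluster(
    d: DissimilarityMatrix,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    method: str = "average",
) -> ComponentClustering:
    """UPGMA clustering of the dissimilarity matrix, cut at ``cut_height``.

    Average-linkage merge heights are monotone, which is asserted on every
    fit.  SciPy breaks exact-tie merges by original observation index, so
    dendrograms are reproducible.
    """
    z = linkage(d.condensed(), method=method)
    heights = z[:, 2]
    if (np.diff(heights) < -1e-10).any():
        raise AssertionError("linkage produced a height inversion")
    labels = fcluster(z, t=cut_height, criterion="distance")
    return ComponentClustering(
        component_ids=d.component_ids,
        linkage_matrix=z,
        labels=labels,
        cut_height=cut_height,
    )


# ---------------------------------------------------------------------------
# Comparator partitions: DIANA and PAM
# ---------------------------------------------------------------------------

def _diameter(d: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = d[np.ix_(members, members)]
    return float(sub.max())


def _diana_split(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: peel a splinter group off ``members``."""
    rest = list(members)
    sub = d[np.ix_(rest, rest)]
    avg = sub.sum(axis=1) / (len(rest) - 1)
    splinter = [rest.pop(int(avg.argmax()))]
    while len(rest) > 1:
        to_rest = d[np.ix_(rest, rest)].sum(axis=1) / (len(rest) - 1)
        to_spl = d[np.ix_(rest, splinter)].mean(axis=1)
        gain = to_rest - to_spl
        best = int(gain.argmax())
        if gain[best] <= 0:
            break
        splinter.append(rest.pop(best))
    return splinter, rest


def divisive_cluster(d: DissimilarityMatrix, k: int) -> np.ndarray:
    """DIANA divisive clustering into ``k`` flat clusters.

    Kaufman-Rousseeuw scheme: repeatedly split the cluster with the largest
    diameter by moving objects towards a splinter group seeded with the
    object of maximal average dissimilarity.
    """
    mat = d.to_numpy()
    p = mat.shape[0]
    if not 2 <= k <= p:
        raise ValueError(f"k={k} out of range [2, {p}]")
    clusters: list[list[int]] = [list(range(p))]
    while len(clusters) < k:
        diams = [_diameter(mat, c) for c in clusters]
        target = int(np.argmax(diams))
        if diams[target] == 0:  # all remaining clusters are point masses
            for c in clusters:
                if len(c) > 1:
                    target = clusters.index(c)
                    break
            else:
                break
        members = clusters.pop(target)
        a, b = _diana_split(mat, members)
        clusters.extend([a, b])
    labels = np.empty(p, dtype=int)
    for cid, members in enumerate(sorted(clusters, key=min), start=1):
        labels[members] = cid
    return labels


def pam_cluster(d: DissimilarityMatrix, k: int, max_swaps: int = 200) -> np.ndarray:
    """PAM (partition around medoids) on the precomputed dissimilarity.

    Classic BUILD then SWAP; the total within-cluster dissimilarity to the
    medoids never increases during SWAP (asserted).
    """
    mat = d.to_numpy()
    p = mat.shape[0]
    if not 2 <= k <= p:
        raise ValueError(f"k={k} out of range [2, {p}]")

    # BUILD: greedy medoid selection minimising total cost.
    medoids = [int(mat.sum(axis=1).argmin())]
    while len(medoids) < k:
        nearest = mat[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(nearest - mat[:, c], 0.0).sum() if c not in medoids else -1.0
                for c in range(p)
            ]
        )
        medoids.append(int(gains.argmax()))

    def cost(meds: list[int]) -> float:
        return float(mat[:, meds].min(axis=1).sum())

    build_cost = cost(medoids)
    current = build_cost
    for _ in range(max_swaps):
        best_delta, best_pair = 0.0, None
        for mi, med in enumerate(medoids):
            for cand in range(p):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                delta = cost(trial) - current
                if delta < best_delta - 1e-12:
                    best_delta, best_pair = delta, (mi, cand)
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
        current += best_delta
    assert current <= build_cost + 1e-9, "SWAP worsened the PAM objective"
    labels = mat[:, medoids].argmin(axis=1)
    # medoids are their own cluster centres regardless of tie direction
    for mi, med in enumerate(medoids):
        labels[med] = mi
    return labels + 1


def rand_index(labels_a, labels_b) -> float:
    """Plain (unadjusted) Rand index: fraction of agreeing pairs."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree) / (n * (n - 1) // 2)


def build_connectivity_graph(
    d: DissimilarityMatrix,
    clustering: ComponentClustering | None = None,
    edge_min_dcor: float = 0.3,
) -> nx.Graph:
    """Weighted component co-expression graph.

    Node connectivity ``k_i`` is the sum of dCor to all other components
    (all pairs, not only displayed edges); node attribute
    ``scaled_connectivity`` is ``k_i / max_j k_j``.  Edges with
    ``dCor >= edge_min_dcor`` are retained with the dCor as weight.
    """
    dcor = 1.0 - d.to_numpy()
    np.fill_diagonal(dcor, 0.0)
    ids = d.component_ids
    connectivity = dcor.sum(axis=1)
    scale = connectivity.max()
    scaled = connectivity / scale if scale > 0 else np.ones_like(connectivity)
    g = nx.Graph()
    labels = dict(zip(ids, clustering.labels)) if clustering is not None else {}
    for i, cid in enumerate(ids):
        g.add_node(
            cid,
            connectivity=float(connectivity[i]),
            scaled_connectivity=float(scaled[i]),
            cluster=int(labels.get(cid, 0)),
        )
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if dcor[i, j] >= edge_min_dcor:
                g.add_edge(ids[i], ids[j], dcor=float(dcor[i, j]))
    return g
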