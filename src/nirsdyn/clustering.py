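"""k-means clustering of edge-wise dRSFC time courses and group unification.

Each subject's 630 edge time courses (windowed correlations) are clustered
with Euclidean k-means under many random restarts; the centroid time
courses represent the typical connectivity fluctuations of each network.
The number of clusters is selected at the group level: for each k a
between/within distance ratio A is computed per subject, and the validity
index sd(A)/mean(A) across subjects is scanned over k, choosing the elbow
(maximum discrete curvature).

Because resting fluctuations are not time-locked across subjects, clusters
are matched between subjects on their *spatial* signature — the binary
edge-membership map — by a two-loop relabeling: loop 1 matches every
subject to one subject's maps (optimal one-to-one assignment on spatial
correlation), loop 2 iterates matching against the group-mean maps until
labels stabilize.  The group atlas reports each edge's probability of
occurrence in each cluster across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .connectivity import DRSFCSeries
from .core import ChannelLayout

logger = logging.getLogger(__name__)


@dataclass
class ClusterSolution:
    """One subject's edge clustering at a fixed k."""

    labels: np.ndarray  # [edges], values 0..k-1
    centroids: np.ndarray  # [k x windows]
    inertia: float
    ratio_a: float  # between-cluster / within-cluster distance; NaN at k=1
    k: int
    seed: int | None
    restarts: int

    def membership_maps(self) -> np.ndarray:
        """Binary [k x edges] spatial maps (the cluster 'spatial
        distribution' used for cross-subject matching)."""
        return np.stack([(self.labels == c).astype(float) for c in range(self.k)])


@dataclass
class ValidityScan:
    k_values: np.ndarray
    mean_a: np.ndarray
    sd_a: np.ndarray
    validity: np.ndarray  # sd_a / mean_a
    chosen_k: int
    a_values: np.ndarray  # [k_values x subjects]


@dataclass
class GroupClusterAtlas:
    """Relabeled memberships and group occurrence probabilities."""

    labels: np.ndarray  # [subjects x edges]
    occurrence_prob: np.ndarray  # [clusters x edges]
    k: int
    roi_consistency: dict | None = None  # cluster -> {roi-pair: mean occurrence}
    dominant_edges: list | None = None  # per cluster, edges with occurrence > 0.5


def _feature_matrix(d: DRSFCSeries) -> np.ndarray:
    """Edge x window features; windows with any undefined entry dropped."""
    X = d.r
    good = np.all(np.isfinite(X), axis=0)
    if not good.all():
        logger.warning("dropping %d windows with undefined correlations", (~good).sum())
    X = X[:, good]
    if X.shape[1] == 0:
        raise ValueError("no fully-defined windows available for clustering")
    return X


def ratio_a(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Between/within distance ratio A of a clustering.

    between = mean pairwise Euclidean distance among centroids;
    within = mean Euclidean distance of members to their own centroid.
    """
    k = centroids.shape[0]
    if k < 2:
        return float("nan")
    iu = np.triu_indices(k, 1)
    diff = centroids[:, None, :] - centroids[None, :, :]
    between = np.sqrt((diff**2).sum(-1))[iu].mean()
    within = np.linalg.norm(X - centroids[labels], axis=1).mean()
    if within == 0:
        return float("inf")
    return float(between / within)


def kmeans_edges(
    d: DRSFCSeries | np.ndarray,
    k: int,
    restarts: int = 100,
    seed: int | None = None,
) -> ClusterSolution:
    """Best-of-``restarts`` Euclidean k-means over edge time courses.

    Random centroid initialization per restart; the lowest-inertia run
    wins.  At k=1 the ratio A is undefined (NaN).
    """
    X = _feature_matrix(d) if isinstance(d, DRSFCSeries) else np.asarray(d, float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of edges {X.shape[0]}")
    if k == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        centroids = X.mean(axis=0, keepdims=True)
        inertia = float(((X - centroids) ** 2).sum())
        return ClusterSolution(labels, centroids, inertia, float("nan"), 1, seed, restarts)
    km = KMeans(n_clusters=k, init="random", n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    # recompute centroids as exact member means (k-means invariant)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterSolution(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        ratio_a=ratio_a(X, labels, centroids),
        k=k,
        seed=seed,
        restarts=restarts,
    )


def elbow_k(k_values: np.ndarray, validity: np.ndarray) -> int:
    """Elbow of the validity curve: maximum discrete curvature
    (second difference); ties resolved toward the smaller k."""
    k_values = np.asarray(k_values)
    v = np.asarray(validity, float)
    if len(v) < 3:
        return int(k_values[np.nanargmin(v)])
    curv = v[2:] - 2 * v[1:-1] + v[:-2]
    best = int(np.nanargmax(np.round(curv, 12)))  # first (smallest k) on ties
    return int(k_values[1 + best])


def validity_scan(
    series: list[DRSFCSeries | np.ndarray],
    k_range: range = range(2, 11),
    restarts: int = 100,
    seed: int | None = None,
) -> ValidityScan:
    """Scan k over subjects: validity(k) = sd(A)/mean(A) across subjects."""
    if len(series) < 2:
        raise ValueError("validity scan requires >= 2 subjects")
    ks = []
    for k in k_range:
        feasible = all(
            k <= (_feature_matrix(d).shape[0] if isinstance(d, DRSFCSeries) else d.shape[0])
            for d in series
        )
        if feasible:
            ks.append(k)
        else:
            logger.warning("k=%d infeasible for some subject; dropped", k)
    ks = np.array(ks)
    A = np.empty((len(ks), len(series)))
    for i, k in enumerate(ks):
        # independent restart streams per subject: cross-subject variance
        # of A then reflects both data differences and solution
        # instability, which is what inflates the index beyond the true k
        for s, d in enumerate(series):
            sub_seed = None if seed is None else seed + 1000 * int(k) + s
            A[i, s] = kmeans_edges(d, int(k), restarts=restarts, seed=sub_seed).ratio_a
    mean_a = A.mean(axis=1)
    sd_a = A.std(axis=1, ddof=1)
    validity = np.where(mean_a > 0, sd_a / mean_a, np.nan)
    return ValidityScan(
        k_values=ks,
        mean_a=mean_a,
        sd_a=sd_a,
        validity=validity,
        chosen_k=elbow_k(ks, validity),
        a_values=A,
    )


def _spatial_corr(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between rows of two map stacks."""
    a = maps_a - maps_a.mean(axis=1, keepdims=True)
    b = maps_b - maps_b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na[:, None]) @ (b / nb[:, None]).T


def _match(maps: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Optimal one-to-one label assignment maximizing total spatial
    correlation; returns perm with perm[old_label] = new_label."""
    C = _spatial_corr(maps, template)
    row, col = linear_sum_assignment(-C)
    perm = np.empty(maps.shape[0], dtype=int)
    perm[row] = col
    return perm


def relabel_group(
    solutions: list[ClusterSolution],
    layout: ChannelLayout | None = None,
    edges: np.ndarray | None = None,
    channel_idx: np.ndarray | None = None,
    template_subject: int = 0,
    max_iter: int = 100,
) -> GroupClusterAtlas:
    """Two-loop relabeling unifying cluster labels across subjects.

    Loop 1 uses one subject's binary membership maps as the template and
    matches every subject to it by optimal assignment on spatial
    correlation.  Loop 2 replaces the template with the group-mean map per
    label and re-matches until no label changes (or ``max_iter``).
    Relabeling is a bijection per subject — partitions are untouched.
    """
    ks = {s.k for s in solutions}
    if len(ks) != 1:
        raise ValueError("all subjects must be clustered with the same k")
    k = ks.pop()
    maps = [s.membership_maps() for s in solutions]

    template = maps[template_subject]
    perms = [_match(m, template) for m in maps]
    for it in range(max_iter):
        relabeled = np.stack(
            [m[np.argsort(p)] for m, p in zip(maps, perms)]
        )  # [S x k x E]; row c = members of new label c
        template = relabeled.mean(axis=0)
        new_perms = [_match(m, template) for m in maps]
        if all(np.array_equal(a, b) for a, b in zip(perms, new_perms)):
            break
        perms = new_perms
    else:
        logger.warning("relabeling did not converge in %d iterations", max_iter)

    labels = np.stack([p[s.labels] for p, s in zip(perms, solutions)])
    occurrence = np.stack([(labels == c).mean(axis=0) for c in range(k)])

    atlas = GroupClusterAtlas(labels=labels, occurrence_prob=occurrence, k=k)
    atlas.dominant_edges = [list(np.flatnonzero(occurrence[c] > 0.5)) for c in range(k)]
    if layout is not None and edges is not None and channel_idx is not None:
        rois = [layout.roi[c] for c in channel_idx]
        cats = [
            "-".join(sorted((rois[i], rois[j]))) for i, j in edges
        ]
        uniq = sorted(set(cats))
        atlas.roi_consistency = {
            c: {
                u: float(
                    occurrence[c, [i for i, lab in enumerate(cats) if lab == u]].mean()
                )
                for u in uniq
            }
            for c in range(k)
        }
    return atlas


def match_atlases(a: GroupClusterAtlas, b: GroupClusterAtlas) -> np.ndarray:
    """Per-cluster spatial correlations between two atlases' occurrence
    maps after optimal matching."""
    perm = _match(b.occurrence_prob, a.occurrence_prob)
    C = _spatial_corr(a.occurrence_prob, b.occurrence_prob)
    return np.array([C[perm[c], c] for c in range(a.k)])


def reproducibility_split(
    series: list[DRSFCSeries | np.ndarray],
    k: int,
    restarts: int = 100,
    seed: int | None = None,
) -> tuple[GroupClusterAtlas, GroupClusterAtlas, np.ndarray]:
    """Random half-split of the cohort; full clustering per half.

    Returns both half-atlases and the matched-cluster correlation of their
    occurrence maps.  With an odd cohort the first half gets the extra
    subject.
    """
    if len(series) < 4:
        raise ValueError("reproducibility split requires >= 4 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(series))
    n_first = (len(series) + 1) // 2
    halves = [order[:n_first], order[n_first:]]
    atlases = []
    for h, idx in enumerate(halves):
        sols = [
            kmeans_edges(series[i], k, restarts=restarts,
                         seed=None if seed is None else seed + 7919 * h + j)
            for j, i in enumerate(idx)
        ]
        atlases.append(relabel_group(sols))
    corr = match_atlases(atlases[0], atlases[1])
    return atlases[0], atlases[1], corr
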