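"""Probabilistic mode-seeking clustering of conformer maps (PAMM-style).

The procedure: (1) select a landmark grid from the projected frames by
farthest point sampling and attach to each landmark the fraction of frames
in its Voronoi cell; (2) estimate a kernel density on the landmarks with a
localised Silverman bandwidth (Silverman's rule applied to the covariance
of the nearest fraction ``f_points`` of the samples around each landmark);
(3) find density modes by quick-shift: every landmark links to its nearest
landmark of strictly higher density within ``alpha`` times its local
bandwidth, and the trees rooted at unlinked landmarks are the clusters;
(4) assign every frame the cluster of its nearest landmark, define the
canonical cluster weight w_c as the fraction of frames in the cluster, and
pick the lowest-energy frame of each cluster as its representative
conformer; (5) optionally merge clusters agglomeratively under Ward's
criterion restricted to clusters adjacent on the density grid, producing a
dendrogram of progressively coarser conformer families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .descriptors import farthest_point_sampling

__all__ = ["PammClustering", "ClusterSet", "MergeTree", "merge_hierarchy"]

_BANDWIDTH_FLOOR = 1e-8


@dataclass
class ClusterSet:
    """Frame labels, canonical weights and representative frames."""

    labels: np.ndarray  # cluster id per frame, 0..n_clusters-1
    weights: np.ndarray  # fraction of frames per cluster, sums to 1
    representative: np.ndarray  # frame index per cluster
    n_clusters: int

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("cluster weights must sum to 1")


class PammClustering(ClusterMixin, BaseEstimator):
    """Density-based conformer clustering on a landmark grid.

    Parameters
    ----------
    n_grid:
        Number of FPS landmarks (default ``min(1000, n_frames)``).
    f_points:
        Fraction of samples defining the local neighbourhood for the
        localised Silverman bandwidth (floored at d+1 samples).
    alpha:
        Quick-shift cutoff scaling: links are only allowed within
        ``alpha * bandwidth`` of a landmark.
    start_index:
        FPS starting frame (determinism knob).

    Attributes (after ``fit``)
    --------------------------
    grid_indices_, grid_points_, voronoi_weights_, bandwidths_,
    grid_density_ (continuous KDE value per landmark),
    grid_prob_ (Voronoi-weighted probability mass per landmark, sums to 1),
    parent_ (quick-shift link per landmark, -1 for modes),
    cluster_of_grid_, labels_, n_clusters_; with energies also
    weights_ and representatives_.
    """

    def __init__(self, n_grid=None, f_points=0.008, alpha=0.9, start_index=0,
                 dip_threshold=0.5, min_cluster_weight=0.0):
        self.n_grid = n_grid
        self.f_points = f_points
        self.alpha = alpha
        self.start_index = start_index
        self.dip_threshold = dip_threshold
        self.min_cluster_weight = min_cluster_weight

    # -- stages -----------------------------------------------------------
    def _build_grid(self, X):
        n = X.shape[0]
        n_grid = self.n_grid if self.n_grid is not None else min(1000, n)
        if n_grid > n:
            raise ValueError(f"n_grid={n_grid} exceeds n_frames={n}")
        self.grid_indices_ = np.array(
            farthest_point_sampling(X, n_grid, start_index=self.start_index)
        )
        self.grid_points_ = X[self.grid_indices_]
        d = cdist(X, self.grid_points_)
        self.nearest_grid_ = np.argmin(d, axis=1)
        # second-nearest landmark per frame, for grid adjacency
        if n_grid >= 2:
            order = np.argsort(d, axis=1, kind="stable")
            self.second_grid_ = order[:, 1]
        else:
            self.second_grid_ = np.zeros(n, dtype=int)
        counts = np.bincount(self.nearest_grid_, minlength=n_grid)
        self.voronoi_weights_ = counts / n

    def _estimate_density(self, X):
        n, d = X.shape
        G = self.grid_points_.shape[0]
        k = max(d + 1, int(np.ceil(self.f_points * n)))
        if int(np.ceil(self.f_points * n)) < d + 1:
            warnings.warn(
                f"f_points={self.f_points} gives fewer than d+1 local samples; "
                f"flooring at {d + 1}"
            )
        dist_gx = cdist(self.grid_points_, X)
        bw = np.empty(G)
        silverman = (4.0 / ((d + 2) * k)) ** (1.0 / (d + 4))
        for i in range(G):
            nbr = np.argpartition(dist_gx[i], min(k, n) - 1)[:k]
            local = X[nbr]
            cov = np.cov(local.T) if k > 1 else np.zeros((d, d))
            cov = np.atleast_2d(cov)
            scale = np.sqrt(max(np.trace(cov) / d, 0.0))
            bw[i] = max(silverman * scale, _BANDWIDTH_FLOOR)
        self.bandwidths_ = bw
        # balloon KDE over all frames, evaluated at each landmark with its
        # local bandwidth
        norm = (2.0 * np.pi * bw**2) ** (d / 2.0)
        self.grid_density_ = (
            np.exp(-0.5 * (dist_gx / bw[:, None]) ** 2).sum(axis=1)
            / (n * norm)
        )
        mass = self.voronoi_weights_ * self.grid_density_
        self.grid_prob_ = mass / mass.sum()

    def _quickshift(self):
        G = self.grid_points_.shape[0]
        rho = self.grid_density_
        d_gg = cdist(self.grid_points_, self.grid_points_)
        parent = np.full(G, -1, dtype=int)
        for i in range(G):
            ok = (rho > rho[i]) & (d_gg[i] <= self.alpha * self.bandwidths_[i])
            cand = np.where(ok)[0]
            if cand.size:
                parent[i] = cand[np.argmin(d_gg[i, cand])]  # ties: lowest index
        self.parent_ = parent
        root = np.arange(G)
        for i in range(G):
            r = i
            while parent[r] != -1:
                r = parent[r]
            root[i] = r
        modes = np.unique(root)
        relabel = {m: c for c, m in enumerate(modes)}
        self.cluster_of_grid_ = np.array([relabel[r] for r in root])
        self.n_clusters_ = len(modes)

    def _merge_shallow_modes(self):
        """Merge adjacent clusters separated by an insignificant density dip.

        Kernel-density mode-seeking always produces spurious shallow modes
        on finite samples; a pair of adjacent clusters is fused when the
        density at their common boundary (saddle) exceeds ``dip_threshold``
        times the lower of the two mode densities.  Deterministic: the
        shallowest dip is merged first.
        """
        if self.dip_threshold is None:
            return
        rho = self.grid_density_
        adj = self.grid_adjacency()
        labels = self.cluster_of_grid_.copy()
        gi, gj = np.nonzero(adj)
        while True:
            k = labels.max() + 1
            peak = np.array(
                [rho[labels == c].max() for c in range(k)]
            )
            saddle = np.full((k, k), -np.inf)
            ca, cb = labels[gi], labels[gj]
            cross = ca != cb
            for a, b, s in zip(ca[cross], cb[cross],
                               np.minimum(rho[gi[cross]], rho[gj[cross]])):
                if s > saddle[a, b]:
                    saddle[a, b] = saddle[b, a] = s
            best, best_ratio = None, self.dip_threshold
            for a in range(k):
                for b in range(a + 1, k):
                    if not np.isfinite(saddle[a, b]):
                        continue
                    ratio = saddle[a, b] / min(peak[a], peak[b])
                    if ratio > best_ratio + 1e-15:
                        best, best_ratio = (a, b), ratio
            if best is None:
                break
            a, b = best
            labels[labels == b] = a
            labels[labels > b] -= 1
        self.cluster_of_grid_ = labels
        self.n_clusters_ = labels.max() + 1

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None, energies=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.X_ = X
        self._build_grid(X)
        self._estimate_density(X)
        self._quickshift()
        self.quickshift_labels_ = self.cluster_of_grid_.copy()
        self._merge_shallow_modes()
        self.labels_ = self.cluster_of_grid_[self.nearest_grid_]
        if energies is not None:
            cs = self.cluster_set(energies)
            self.weights_ = cs.weights
            self.representatives_ = cs.representative
        return self

    def cluster_set(self, energies) -> ClusterSet:
        """Frame assignment, canonical weights and lowest-energy representatives.

        Clusters holding less than ``min_cluster_weight`` of the frames are
        treated as outlier islands: their frames are reassigned to the
        nearest surviving cluster's landmarks.
        """
        energies = np.asarray(energies, dtype=float)
        labels = self.cluster_of_grid_[self.nearest_grid_].copy()
        n = labels.size
        if energies.shape != (n,):
            raise ValueError("one energy per frame required")
        if self.min_cluster_weight > 0.0:
            w = np.bincount(labels, minlength=self.n_clusters_) / n
            survive = w >= self.min_cluster_weight
            if not np.any(survive):
                survive[np.argmax(w)] = True
            if not np.all(survive):
                good_grid = np.where(survive[self.cluster_of_grid_])[0]
                moved = np.where(~survive[labels])[0]
                d = cdist(self.X_[moved], self.grid_points_[good_grid])
                nearest = good_grid[np.argmin(d, axis=1)]
                labels[moved] = self.cluster_of_grid_[nearest]
        keep = []
        for c in range(self.n_clusters_):
            if np.any(labels == c):
                keep.append(c)
            else:
                warnings.warn(f"cluster {c} received no frames; dropped")
        remap = {c: i for i, c in enumerate(keep)}
        labels = np.array([remap[c] for c in labels])
        k = len(keep)
        weights = np.bincount(labels, minlength=k) / n
        reps = np.empty(k, dtype=int)
        for c in range(k):
            members = np.where(labels == c)[0]
            reps[c] = members[np.argmin(energies[members])]  # ties: lowest index
        return ClusterSet(labels=labels, weights=weights,
                          representative=reps, n_clusters=k)

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, **kw).labels_

    def grid_adjacency(self) -> np.ndarray:
        """Landmark adjacency: i and j are adjacent when some frame has them
        as its two nearest landmarks (shared Voronoi boundary), or when they
        lie within each other's local KDE bandwidth."""
        G = self.grid_points_.shape[0]
        adj = np.zeros((G, G), dtype=bool)
        adj[self.nearest_grid_, self.second_grid_] = True
        d_gg = cdist(self.grid_points_, self.grid_points_)
        bw = np.maximum(self.bandwidths_[:, None], self.bandwidths_[None, :])
        adj |= d_gg <= bw
        adj |= adj.T
        np.fill_diagonal(adj, False)
        return adj


class MergeTree:
    """Binary agglomeration record over the initial clusters.

    Leaves are the clusters 0..n_leaves-1; merge ``i`` creates node
    ``n_leaves + i``.  Heights are Ward linkage distances, clamped to be
    non-decreasing (standard dendrogram convention).
    """

    def __init__(self, n_leaves, merges, leaf_rep_energies):
        self.n_leaves = int(n_leaves)
        self.merges = [(int(a), int(b), float(h)) for a, b, h in merges]
        self.leaf_rep_energies = np.asarray(leaf_rep_energies, dtype=float)
        self._leaves_of = {i: frozenset([i]) for i in range(self.n_leaves)}
        for idx, (a, b, _h) in enumerate(self.merges):
            self._leaves_of[self.n_leaves + idx] = (
                self._leaves_of[a] | self._leaves_of[b]
            )

    def leaves_of(self, node) -> frozenset:
        return self._leaves_of[node]

    def nodes_at_level(self, level: int) -> list:
        """Active nodes when exactly ``level`` clusters remain."""
        if not 1 <= level <= self.n_leaves:
            raise ValueError("level must be in [1, n_leaves]")
        active = set(range(self.n_leaves))
        for idx, (a, b, _h) in enumerate(self.merges):
            if len(active) == level:
                break
            active.discard(a)
            active.discard(b)
            active.add(self.n_leaves + idx)
        return sorted(active)

    def node_weight(self, node, leaf_weights) -> float:
        w = np.asarray(leaf_weights, dtype=float)
        return float(sum(w[leaf] for leaf in self._leaves_of[node]))

    def representative_leaf(self, node) -> int:
        """Leaf whose representative has the lowest energy in the node."""
        leaves = sorted(self._leaves_of[node])
        e = self.leaf_rep_energies[leaves]
        return leaves[int(np.argmin(e))]

    def level_labels(self, level: int, leaf_labels: np.ndarray) -> np.ndarray:
        """Per-frame labels at a merge level (0..level-1 in node order)."""
        nodes = self.nodes_at_level(level)
        leaf_to_lvl = {}
        for i, node in enumerate(nodes):
            for leaf in self._leaves_of[node]:
                leaf_to_lvl[leaf] = i
        return np.array([leaf_to_lvl[c] for c in leaf_labels])

    def to_newick(self, names=None) -> str:
        if names is None:
            names = [f"c{i}" for i in range(self.n_leaves)]
        label = {i: names[i] for i in range(self.n_leaves)}
        height = {i: 0.0 for i in range(self.n_leaves)}
        for idx, (a, b, h) in enumerate(self.merges):
            node = self.n_leaves + idx
            la = h - height[a]
            lb = h - height[b]
            label[node] = f"({label[a]}:{la:.6g},{label[b]}:{lb:.6g})"
            height[node] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return label[root] + ";"


def merge_hierarchy(cluster_set: ClusterSet, model: PammClustering,
                    energies=None) -> MergeTree:
    """Adjacency-restricted Ward agglomeration of the clusters.

    Clusters are merged by Ward's criterion on their centroids in the
    clustering space, considering only pairs adjacent on the density grid
    (their landmark Voronoi cells share a boundary); if no adjacent pair
    exists the restriction is lifted with a warning.  Ward distance follows
    d(A,B) = sqrt(2 n_A n_B / (n_A + n_B)) * ||c_A - c_B||.
    """
    k = cluster_set.n_clusters
    if k < 2:
        raise ValueError("need at least 2 clusters to merge")
    X = model.X_
    labels = cluster_set.labels
    sizes = np.array([np.sum(labels == c) for c in range(k)], dtype=float)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(k)])

    grid_adj = model.grid_adjacency()
    cg = model.cluster_of_grid_
    # map grid-cluster ids onto the (possibly renumbered) cluster-set ids via
    # the frames: each grid cluster maps to the label its frames carry
    grid_to_set = np.full(model.n_clusters_, -1, dtype=int)
    for gc in range(model.n_clusters_):
        members = np.where(model.cluster_of_grid_[model.nearest_grid_] == gc)[0]
        if members.size:
            grid_to_set[gc] = labels[members[0]]
    adj = {i: set() for i in range(k)}
    gi, gj = np.nonzero(grid_adj)
    for a, b in zip(gi, gj):
        ca, cb = grid_to_set[cg[a]], grid_to_set[cg[b]]
        if ca != cb and ca >= 0 and cb >= 0:
            adj[ca].add(cb)
            adj[cb].add(ca)

    if energies is None:
        rep_e = np.arange(k, dtype=float)  # fall back to leaf order
    else:
        energies = np.asarray(energies, dtype=float)
        rep_e = energies[cluster_set.representative]

    active = {i: (centroids[i], sizes[i]) for i in range(k)}
    node_of = {i: i for i in range(k)}
    merges = []
    warned = False
    last_h = 0.0
    next_node = k
    while len(active) > 1:
        keys = sorted(active)
        best = None
        candidates = []
        for ii, a in enumerate(keys):
            for b in keys[ii + 1 :]:
                if b in adj[a]:
                    candidates.append((a, b))
        if not candidates:
            if not warned:
                warnings.warn(
                    "cluster adjacency graph disconnected; "
                    "falling back to unrestricted Ward merging"
                )
                warned = True
            candidates = [
                (a, b) for ii, a in enumerate(keys) for b in keys[ii + 1 :]
            ]
        for a, b in candidates:
            ca, na = active[a]
            cb, nb = active[b]
            dist = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or dist < best[0] - 1e-15:
                best = (dist, a, b)
        dist, a, b = best
        h = max(dist, last_h)  # monotone dendrogram heights
        last_h = h
        ca, na = active.pop(a)
        cb, nb = active.pop(b)
        merged = ((na * ca + nb * cb) / (na + nb), na + nb)
        merges.append((node_of[a], node_of[b], h))
        new_key = min(a, b)
        active[new_key] = merged
        node_of[new_key] = next_node
        next_node += 1
        neigh = (adj[a] | adj[b]) - {a, b}
        adj[new_key] = neigh
        for c in list(adj):
            if a in adj[c]:
                adj[c].discard(a)
                adj[c].add(new_key)
            if b in adj[c]:
                adj[c].discard(b)
                adj[c].add(new_key)
        adj[new_key].discard(new_key)
    return MergeTree(k, merges, rep_e)
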