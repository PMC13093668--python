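"""Free-energy curves, barrier cutting, PCA reduction and density clustering.

The 1D free energy is the histogram estimate dG(x) = -kBT ln P(x)
(shifted so its minimum is zero).  States along a 1D coordinate are
defined by cutting the curve at its barriers; in reduced spaces of
several dimensions, microstates come from robust density-based
clustering: every frame gets a local free energy from the number of
neighbours in a hypersphere of fixed radius, and minima of the landscape
are grown by processing frames in order of increasing free energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

__all__ = [
    "FreeEnergyCurve",
    "free_energy_1d",
    "MinimaBarriers",
    "find_minima_and_barriers",
    "assign_by_thresholds",
    "count_states_1d",
    "PCAResult",
    "pca_reduce",
    "DensityClustering",
    "density_cluster",
]


@dataclass
class FreeEnergyCurve:
    """Binned 1D free energy in kBT units.

    ``dG`` is NaN for undefined bins (fewer counts than ``min_count``);
    defined values are shifted so the global minimum is zero.
    """

    bin_centers: np.ndarray
    dG: np.ndarray
    counts: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.dG)


def free_energy_1d(series: np.ndarray,
                   n_bins: int | str | None = None,
                   min_count: int = 1,
                   range: tuple | None = None) -> FreeEnergyCurve:
    """Histogram-based free energy dG(x) = -ln(P/P_max) of a 1D series.

    ``n_bins`` defaults to Scott's rule.  Bins with fewer than
    ``min_count`` frames are undefined (NaN), not zero: an empty bin has
    infinite free energy, and near-empty bins carry too much shot noise
    to define states from.
    """
    x = np.asarray(series, dtype=np.float64).squeeze()
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size == 0:
        raise ValueError("empty series")
    if n_bins is None:
        n_bins = "scott"
    counts, edges = np.histogram(x, bins=n_bins, range=range)
    if x.size < len(counts):
        raise ValueError("fewer frames than bins")
    centers = 0.5 * (edges[1:] + edges[:-1])
    dG = np.full(len(counts), np.nan)
    ok = counts >= max(min_count, 1)
    if not ok.any():
        raise ValueError("no bin reaches min_count")
    dG[ok] = -np.log(counts[ok] / counts.max())
    return FreeEnergyCurve(centers, dG, counts)


@dataclass
class MinimaBarriers:
    """Locations of free-energy minima and of the barriers between them."""

    minima: np.ndarray            # coordinate of each minimum
    minima_values: np.ndarray     # dG at each minimum
    barriers: np.ndarray          # coordinate of each barrier (len = n_min - 1)
    barrier_heights: np.ndarray   # saddle dG minus higher adjacent minimum dG

    @property
    def n_states(self) -> int:
        return len(self.minima)


def _alternating_extrema(d: np.ndarray):
    """Indices of alternating minima and maxima of a sequence.

    Plateaus are collapsed to their first index.  Returns (mins, maxs)
    with len(maxs) == len(mins) - 1 and barriers interleaving minima.
    """
    n = len(d)
    mins, maxs = [], []
    # walk and classify turning points, treating equal runs as one point
    idx = [0]
    for i in range(1, n):
        if d[i] != d[idx[-1]]:
            idx.append(i)
    if len(idx) == 1:
        return [0], []
    cur_min = idx[0] if d[idx[0]] < d[idx[1]] else None
    if cur_min is not None:
        mins.append(cur_min)
    for j in range(1, len(idx) - 1):
        prev, here, nxt = d[idx[j - 1]], d[idx[j]], d[idx[j + 1]]
        if here < prev and here < nxt:
            mins.append(idx[j])
        elif here > prev and here > nxt:
            maxs.append(idx[j])
    if d[idx[-1]] < d[idx[-2]]:
        mins.append(idx[-1])
    # an endpoint that starts a descent is not a minimum; ensure alternation
    # by construction: every interior max separates two mins
    return mins, maxs


def find_minima_and_barriers(curve: FreeEnergyCurve,
                             min_depth: float = 0.0,
                             max_energy: float | None = None) -> MinimaBarriers:
    """Locate free-energy minima and the barriers separating them.

    Shallow features are merged: while any barrier height (saddle dG
    minus the higher adjacent minimum dG) is below ``min_depth``, that
    barrier and its shallower minimum are removed.  Bins with
    dG > ``max_energy`` are excluded from the search (high-energy tail
    bins carry little data and do not define states).
    """
    mask = curve.defined
    if max_energy is not None:
        mask = mask & (curve.dG <= max_energy)
    if mask.sum() < 1:
        raise ValueError("curve has no defined bins")
    d = curve.dG[mask]
    c = curve.bin_centers[mask]
    mins, maxs = _alternating_extrema(d)
    mins, maxs = list(mins), list(maxs)
    # merge features below the prominence floor
    while maxs:
        heights = [d[b] - max(d[mins[k]], d[mins[k + 1]])
                   for k, b in enumerate(maxs)]
        k = int(np.argmin(heights))
        if heights[k] >= min_depth:
            break
        # drop the barrier and the higher (shallower) adjacent minimum
        hi = k if d[mins[k]] > d[mins[k + 1]] else k + 1
        if d[mins[k]] == d[mins[k + 1]]:
            hi = k + 1
        del maxs[k]
        del mins[hi]
    heights = np.array([d[b] - max(d[mins[k]], d[mins[k + 1]])
                        for k, b in enumerate(maxs)])
    return MinimaBarriers(c[np.array(mins, dtype=int)],
                          d[np.array(mins, dtype=int)],
                          c[np.array(maxs, dtype=int)] if maxs else np.array([]),
                          heights)


def assign_by_thresholds(series: np.ndarray, cut_points) -> np.ndarray:
    """Assign 1D frames to states by cut points: state = #cuts below value."""
    cuts = np.asarray(cut_points, dtype=np.float64)
    if cuts.size and np.any(np.diff(cuts) <= 0):
        raise ValueError("cut points must be strictly ascending")
    x = np.asarray(series, dtype=np.float64).squeeze()
    return np.searchsorted(cuts, x).astype(np.int64)


def count_states_1d(series: np.ndarray,
                    n_bins: int = 100,
                    min_depth: float = 0.5,
                    max_energy: float = 6.0,
                    min_count: int | None = None,
                    return_assignment: bool = False):
    """Count metastable states of a 1D coordinate by barrier cutting.

    Convenience wrapper: free-energy curve -> prominence-filtered minima
    -> (optionally) per-frame state labels.  ``min_count`` defaults to
    ``max(10, 2e-5 T)``; together with ``max_energy`` this guards the
    minima search against shot noise in barely populated tail bins.
    """
    x = np.asarray(series, dtype=np.float64).squeeze()
    if min_count is None:
        min_count = max(10, int(2e-5 * x.size))
    curve = free_energy_1d(x, n_bins, min_count=min_count)
    mb = find_minima_and_barriers(curve, min_depth=min_depth,
                                  max_energy=max_energy)
    if not return_assignment:
        return mb.n_states
    return mb.n_states, assign_by_thresholds(x, mb.barriers), mb


@dataclass
class PCAResult:
    """Principal component scores with deterministic component signs."""

    scores: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_reduce(traj: np.ndarray, n_components: int) -> PCAResult:
    """Project features onto their top-variance principal components.

    Thin wrapper around scikit-learn's PCA with a deterministic sign
    convention: each component's largest-magnitude loading is positive.
    """
    X = np.asarray(traj, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("trajectory must be 2D (frames x features)")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of features")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    return PCAResult(scores, comps, pca.explained_variance_ratio_.copy(),
                     pca.mean_.copy())


class DensityClustering(ClusterMixin, BaseEstimator):
    """Robust density-based microstate clustering.

    Every frame receives a local free energy F_i = -ln(n_i / max_j n_j)
    from its neighbour count n_i within a hypersphere of radius
    ``radius``.  Frames are then processed in order of increasing F:
    connected components of the radius-neighbourhood graph restricted to
    already-processed frames seed new clusters (accepted as microstates
    once their population reaches ``p_min * T``), grow existing ones, or
    — when a frame first bridges two clusters — mark boundary frames
    that are assigned to the cluster of their nearest higher-density
    neighbour.  Frames never absorbed are finally attached to the
    cluster of their nearest assigned neighbour.

    Parameters
    ----------
    radius : hypersphere radius in reduced-space units.  ``None`` picks
        the radius such that a typical frame has ~``auto_density`` of
        all frames as neighbours (median over a subsample).
    p_min : minimal population of a microstate, as a fraction of frames.
    n_levels : number of screening levels (batches of frames between
        component inspections).
    auto_density : target neighbour fraction for the automatic radius.
    """

    def __init__(self, radius: float | None = None, p_min: float = 1e-4,
                 n_levels: int = 50, auto_density: float = 0.005):
        self.radius = radius
        self.p_min = p_min
        self.n_levels = n_levels
        self.auto_density = auto_density

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        T = X.shape[0]
        if not 0 < self.p_min < 1:
            raise ValueError("p_min must be in (0, 1)")
        if T < 1.0 / self.p_min:
            warnings.warn("fewer than 1/p_min frames; microstate "
                          "populations are poorly resolved", stacklevel=2)
        tree = cKDTree(X)
        radius = self.radius if self.radius is not None else \
            self._auto_radius(X, tree)
        counts = tree.query_ball_point(X, radius, return_length=True)
        if counts.max() <= 1:
            raise ValueError("all points isolated at this radius; "
                             "increase the clustering radius")
        free_energy = -np.log(counts / counts.max())
        # ties in F broken by frame index (stable argsort)
        order = np.argsort(free_energy, kind="stable")
        labels = self._screen(X, tree, radius, free_energy, order, T)
        self.radius_ = float(radius)
        self.neighbor_counts_ = counts
        self.frame_free_energy_ = free_energy
        self.labels_ = labels
        self.n_clusters_ = int(labels.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    # -- internals ---------------------------------------------------------
    def _auto_radius(self, X, tree):
        T = len(X)
        k = max(2, int(round(self.auto_density * T)))
        sample = X[np.linspace(0, T - 1, min(T, 512)).astype(int)]
        dist, _ = tree.query(sample, k=k)
        return float(np.median(dist[:, -1]))

    def _screen(self, X, tree, radius, F, order, T):
        import scipy.sparse as sp

        pairs = tree.query_pairs(radius, output_type="ndarray")
        rank = np.empty(T, dtype=np.int64)
        rank[order] = np.arange(T)
        labels = np.full(T, -1, dtype=np.int64)
        # union-find over frames added in order of increasing F
        parent = np.arange(T)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        # neighbours sorted so we can add edges as frames activate
        if len(pairs):
            pr = np.maximum(rank[pairs[:, 0]], rank[pairs[:, 1]])
            edge_order = np.argsort(pr, kind="stable")
            pairs = pairs[edge_order]
            pair_rank = pr[edge_order]
        else:
            pair_rank = np.array([], dtype=np.int64)
        min_pop = self.p_min * T
        boundary: list[int] = []
        next_label = 0
        e = 0
        level_ends = np.unique(np.linspace(T / self.n_levels, T,
                                           self.n_levels).astype(int))
        for end in level_ends:
            # activate frames and their edges up to this level
            while e < len(pairs) and pair_rank[e] < end:
                i, j = pairs[e]
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
                e += 1
            active = order[:end]
            roots = np.fromiter((find(i) for i in active), dtype=np.int64,
                                count=len(active))
            for root in np.unique(roots):
                members = active[roots == root]
                labs = np.unique(labels[members])
                labs = labs[labs >= 0]
                if len(labs) == 0:
                    if len(members) >= min_pop:
                        labels[members] = next_label
                        next_label += 1
                elif len(labs) == 1:
                    labels[members] = labs[0]
                else:
                    newly = members[labels[members] < 0]
                    boundary.extend(newly.tolist())
            # boundary frames: nearest higher-density neighbour's cluster
            bnd = [i for i in sorted(set(boundary), key=lambda i: rank[i])
                   if labels[i] < 0]
            if bnd:
                _, nbrs = tree.query(X[bnd], k=min(32, T))
                nbrs = np.atleast_2d(nbrs)
                for i, row in zip(bnd, nbrs):
                    lab = -1
                    for j in row:
                        if j != i and labels[j] >= 0 and F[j] < F[i]:
                            lab = labels[j]
                            break
                    labels[i] = lab if lab >= 0 else \
                        self._nearest_label(X, i, labels, F)
            boundary = []
        # leftover noise frames -> nearest assigned neighbour
        unassigned = np.where(labels < 0)[0]
        if len(unassigned) and next_label > 0:
            assigned = np.where(labels >= 0)[0]
            atree = cKDTree(X[assigned])
            _, nn = atree.query(X[unassigned])
            labels[unassigned] = labels[assigned[nn]]
        elif next_label == 0:
            raise ValueError("no cluster reached the minimal population; "
                             "decrease p_min or increase the radius")
        return labels

    @staticmethod
    def _nearest_label(X, i, labels, F):
        mask = (labels >= 0) & (F < F[i])
        if not mask.any():
            mask = labels >= 0
        cand = np.where(mask)[0]
        d = np.linalg.norm(X[cand] - X[i], axis=1)
        return labels[cand[int(np.argmin(d))]]


def density_cluster(traj: np.ndarray,
                    radius: float | None = None,
                    p_min: float = 1e-4,
                    n_levels: int = 50) -> np.ndarray:
    """Microstate labels from robust density-based clustering (functional API)."""
    return DensityClustering(radius=radius, p_min=p_min,
                             n_levels=n_levels).fit_predict(traj)
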