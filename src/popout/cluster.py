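"""Nonparametric cluster-based permutation tests (paired designs).

Paired t-values are computed per (channel, bin); samples exceeding the
two-tailed alpha threshold are clustered over spatial (electrode-neighbor)
and bin (frequency or time) adjacency, positive and negative clusters
separately.  A channel enters a cluster only if at least ``min_neighbors``
of its spatial neighbors are supra-threshold in the same bin.  Each
cluster's summed-t mass is compared against the permutation null of the
maximum absolute mass over random within-participant condition swaps (sign
flips of the paired differences); p uses the add-one Monte Carlo estimator,
so the smallest attainable p is 1/(n_perm+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import StructuralError
from .layout import ChannelLayout
from .utils import rng_for


@dataclass
class NeighborGraph:
    """Channel adjacency: edge iff 3-D distance < radius (symmetric, irreflexive)."""
    adjacency: np.ndarray       # (C, C) bool
    radius: float
    names: tuple[str, ...] = ()

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors(self, i: int) -> np.ndarray:
        return np.where(self.adjacency[i])[0]


def build_neighbors(layout: ChannelLayout, radius: float = 0.040) -> NeighborGraph:
    d = layout.distance_matrix()
    adj = (d < radius) & ~np.eye(layout.n_channels, dtype=bool)
    return NeighborGraph(adjacency=adj, radius=radius, names=layout.names)


@dataclass
class Cluster:
    members: list                  # (channel, bin) index pairs
    mass: float
    sign: int
    p: float = float("nan")


@dataclass
class ClusterResult:
    clusters: list
    n_perm: int
    null_max_mass: np.ndarray
    seed: int | None = None

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _prune_min_neighbors(supra: np.ndarray, adj: np.ndarray,
                         min_neighbors: int) -> np.ndarray:
    """Drop supra-threshold samples with < min_neighbors supra spatial neighbors."""
    if min_neighbors <= 0:
        return supra
    nbr_count = adj.astype(int) @ supra.astype(int)   # (C, B)
    return supra & (nbr_count >= min_neighbors)


def _find_clusters(tmap: np.ndarray, supra: np.ndarray,
                   adj: np.ndarray | None):
    """Connected components over (channel, bin) with bin +/-1 and graph adjacency."""
    C, B = supra.shape
    labels = -np.ones((C, B), int)
    clusters = []
    cid = 0
    where = np.argwhere(supra)
    supra_set = supra
    for c0, b0 in where:
        if labels[c0, b0] >= 0:
            continue
        stack = [(c0, b0)]
        labels[c0, b0] = cid
        members = []
        mass = 0.0
        while stack:
            c, b = stack.pop()
            members.append((c, b))
            mass += tmap[c, b]
            if b > 0 and supra_set[c, b - 1] and labels[c, b - 1] < 0:
                labels[c, b - 1] = cid
                stack.append((c, b - 1))
            if b < B - 1 and supra_set[c, b + 1] and labels[c, b + 1] < 0:
                labels[c, b + 1] = cid
                stack.append((c, b + 1))
            if adj is not None:
                for cn in np.where(adj[c] & supra_set[:, b])[0]:
                    if labels[cn, b] < 0:
                        labels[cn, b] = cid
                        stack.append((cn, b))
        clusters.append((members, mass))
        cid += 1
    return clusters


_T_DEGENERATE = 1e12  # stand-in for t = +/-inf when differences are constant


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Dependent-samples t over axis 0 of participant x ... differences."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    t = mean / np.where(sd == 0, np.inf, sd) * np.sqrt(n)
    return np.where((sd == 0) & (mean != 0), np.sign(mean) * _T_DEGENERATE, t)


def _clusters_of(tmap: np.ndarray, tcrit: float, adj: np.ndarray | None,
                 min_neighbors: int):
    out = []
    for sign in (1, -1):
        supra = (sign * tmap) > tcrit
        if adj is not None:
            supra = _prune_min_neighbors(supra, adj, min_neighbors)
        for members, mass in _find_clusters(tmap, supra, adj):
            out.append(Cluster(members=members, mass=mass, sign=sign))
    return out


def _max_abs_mass(tmap: np.ndarray, tcrit: float, adj: np.ndarray | None,
                  min_neighbors: int) -> float:
    best = 0.0
    for cl in _clusters_of(tmap, tcrit, adj, min_neighbors):
        best = max(best, abs(cl.mass))
    return best


def cluster_permutation(data_a: np.ndarray, data_b: np.ndarray,
                        graph: NeighborGraph | None,
                        alpha_cluster: float = 0.025, min_neighbors: int = 2,
                        n_perm: int = 1000, seed: int = 0) -> ClusterResult:
    """Paired cluster permutation test on participant x channel x bin arrays."""
    data_a = np.asarray(data_a, float)
    data_b = np.asarray(data_b, float)
    if data_a.shape != data_b.shape:
        raise StructuralError("paired condition arrays must share a shape")
    if data_a.ndim != 3:
        raise StructuralError("expected participant x channel x bin arrays")
    P = data_a.shape[0]
    if P < 2:
        raise StructuralError("need >= 2 participants for a paired test")
    if graph is not None and graph.adjacency.shape[0] != data_a.shape[1]:
        raise StructuralError("neighbor graph does not match the channel count")
    adj = graph.adjacency if graph is not None else None

    diff = data_a - data_b
    tcrit = float(stats.t.ppf(1 - alpha_cluster, df=P - 1))
    tmap = _paired_t(diff)
    clusters = _clusters_of(tmap, tcrit, adj, min_neighbors)

    # permutation null: random sign flips of the participant-wise differences.
    # E[x^2] is flip-invariant, so all permutation t-maps come from one GEMM.
    rng = rng_for(seed, "cluster-perm")
    flat = diff.reshape(P, -1)
    sumsq = (flat ** 2).sum(axis=0)
    signs = rng.integers(0, 2, size=(n_perm, P)) * 2 - 1
    sums = signs @ flat                                  # (n_perm, C*B)
    means = sums / P
    var = (sumsq[None, :] - P * means ** 2) / (P - 1)
    degenerate = var <= 1e-30
    var[degenerate] = np.inf
    t_all = means / np.sqrt(var / P)
    t_all = np.where(degenerate & (means != 0),
                     np.sign(means) * _T_DEGENERATE, t_all)
    shape = diff.shape[1:]
    null = np.array([_max_abs_mass(t_all[i].reshape(shape), tcrit, adj,
                                   min_neighbors) for i in range(n_perm)])

    for cl in clusters:
        cl.p = (1 + int(np.sum(null >= abs(cl.mass)))) / (1 + n_perm)
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, n_perm=n_perm, null_max_mass=null,
                         seed=seed)


def cluster_permutation_1d(data_a: np.ndarray, data_b: np.ndarray,
                           alpha_cluster: float = 0.025, n_perm: int = 1000,
                           seed: int = 0) -> ClusterResult:
    """Temporal-only variant: participant x time arrays, consecutive-bin adjacency."""
    data_a = np.asarray(data_a, float)[:, None, :]
    data_b = np.asarray(data_b, float)[:, None, :]
    return cluster_permutation(data_a, data_b, graph=None,
                               alpha_cluster=alpha_cluster, min_neighbors=0,
                               n_perm=n_perm, seed=seed)
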