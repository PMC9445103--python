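"""Nonparametric cluster-based permutation inference.

Implements the max-cluster-mass sign-flip permutation scheme for paired /
one-sample designs: per-pixel paired t statistics are thresholded two-sided
at the cluster-forming alpha, suprathreshold pixels of the same sign are
clustered under the adjacency structure (montage neighbors in space,
nearest neighbors along time and frequency), each cluster's mass is the sum
of its t values, and the Monte-Carlo null is the distribution of the
maximal absolute cluster mass over random sign flips of the subject-wise
difference maps.  ``n_permutations="all"`` enumerates every sign pattern
(exact test, n <= 20 subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .inference import adjusted_partial_eta_sq

#: distance threshold on the unit-sphere montage giving a median of ~6
#: neighbors per channel
DEFAULT_ADJACENCY_THRESHOLD = 0.55


@dataclass
class AdjacencyGraph:
    """Symmetric channel neighborhood derived from montage positions."""

    channel_names: list[str]
    matrix: np.ndarray  # boolean (n_ch, n_ch), no self-edges

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.channel_names):
            raise ValueError("adjacency matrix shape mismatch")
        if m.diagonal().any():
            raise ValueError("adjacency must have no self-edges")
        if not (m == m.T).all():
            raise ValueError("adjacency must be symmetric")
        self.matrix = m

    def neighbors(self, name: str) -> list[str]:
        i = self.channel_names.index(name)
        return [self.channel_names[j] for j in np.flatnonzero(self.matrix[i])]


def build_adjacency(
    montage: pd.DataFrame,
    distance_threshold: float = DEFAULT_ADJACENCY_THRESHOLD,
) -> AdjacencyGraph:
    """Neighbor channels are those within ``distance_threshold`` (Euclidean,
    montage units).  Isolated channels trigger a warning."""
    pos = montage[["x", "y", "z"]].to_numpy()
    dist = squareform(pdist(pos))
    mat = (dist > 1e-12) & (dist < distance_threshold)
    isolated = [montage.index[i] for i in np.flatnonzero(mat.sum(1) == 0)]
    if isolated:
        warnings.warn(f"isolated channels (no neighbors): {isolated}", stacklevel=2)
    return AdjacencyGraph(channel_names=list(montage.index), matrix=mat)


@dataclass
class Cluster:
    """One connected suprathreshold cluster."""

    pixels: tuple[np.ndarray, ...]  # index arrays, one per data axis
    mass: float
    p: float
    sign: int

    @property
    def n_pixels(self) -> int:
        return len(self.pixels[0])

    def centroid(self) -> tuple[float, ...]:
        return tuple(float(np.mean(ax)) for ax in self.pixels)


@dataclass
class ClusterTestResult:
    """Observed t map, clusters with Monte-Carlo p values, and the
    family-wise significance mask at ``alpha``."""

    t_map: np.ndarray
    clusters: list[Cluster]
    mask: np.ndarray
    alpha: float
    cluster_alpha: float
    n_permutations: int | str
    df: int
    seed: int | None
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < self.alpha]

    def eta_map(self) -> np.ndarray:
        """Adjusted partial eta squared per pixel, from F = t**2."""
        return adjusted_partial_eta_sq(self.t_map, self.df)

    def summary(self) -> str:
        lines = [
            f"Cluster-based permutation test (df={self.df}, "
            f"{self.n_permutations} permutations, cluster-forming "
            f"alpha={self.cluster_alpha}, alpha={self.alpha})",
            f"{len(self.clusters)} cluster(s), {len(self.significant)} significant",
        ]
        for i, c in enumerate(sorted(self.clusters, key=lambda c: c.p)):
            star = "*" if c.p < self.alpha else " "
            lines.append(
                f"  {star} cluster {i}: sign={c.sign:+d} mass={c.mass:.2f} "
                f"pixels={c.n_pixels} p={c.p:.4f}")
        return "\n".join(lines)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """t statistics per column of (n_subjects, n_pixels) differences;
    zero-variance pixels get t = 0 with a warning."""
    n = diffs.shape[0]
    mean = diffs.mean(0)
    sd = diffs.std(0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance pixels; t set to 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t


def _clusters_from_t(t: np.ndarray, thr: float, adj: sparse.csr_matrix):
    """Connected same-sign suprathreshold clusters: (list of node-index
    arrays, list of masses)."""
    out_nodes, out_mass = [], []
    for sign in (1, -1):
        nodes = np.flatnonzero(sign * t > thr)
        if nodes.size == 0:
            continue
        if nodes.size == 1:
            out_nodes.append(nodes)
            out_mass.append(float(t[nodes[0]]))
            continue
        sub = adj[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            members = nodes[labels == k]
            out_nodes.append(members)
            out_mass.append(float(t[members].sum()))
    return out_nodes, out_mass


def _max_mass(t: np.ndarray, thr: float, adj: sparse.csr_matrix) -> float:
    _, masses = _clusters_from_t(t, thr, adj)
    return max((abs(m) for m in masses), default=0.0)


def _sign_patterns(n_sub, n_permutations, rng):
    if n_permutations == "all":
        if n_sub > 20:
            raise ValueError("exact enumeration limited to <= 20 subjects")
        bits = np.arange(2**n_sub)[:, None] >> np.arange(n_sub)[None, :]
        return np.where(bits & 1, 1.0, -1.0), True
    signs = rng.choice([-1.0, 1.0], size=(int(n_permutations), n_sub))
    return signs, False


def _cluster_engine(diffs, adj, shape, n_permutations, cluster_alpha, alpha, seed):
    n_sub = diffs.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    df = n_sub - 1
    thr = t_dist.ppf(1.0 - cluster_alpha / 2.0, df)
    t_obs = _paired_t(diffs)
    obs_nodes, obs_mass = _clusters_from_t(t_obs, thr, adj)

    rng = np.random.default_rng(seed)
    signs, exact = _sign_patterns(n_sub, n_permutations, rng)
    ss = (diffs**2).sum(0)  # invariant under sign flips
    null = np.empty(len(signs))
    chunk = max(1, int(2e7 // max(diffs.shape[1], 1)))
    row = 0
    for lo in range(0, len(signs), chunk):
        s = signs[lo:lo + chunk]
        mean = s @ diffs / n_sub
        var = (ss[None, :] - n_sub * mean**2) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var <= 0, 0.0, mean / np.sqrt(var / n_sub))
        for r in range(t_perm.shape[0]):
            null[row] = _max_mass(t_perm[r], thr, adj)
            row += 1

    clusters = []
    for nodes, mass in zip(obs_nodes, obs_mass):
        if exact:
            p = float(np.mean(null >= abs(mass) - 1e-12))
        else:
            p = (1.0 + float(np.sum(null >= abs(mass) - 1e-12))) / (1.0 + len(null))
        clusters.append(Cluster(
            pixels=np.unravel_index(nodes, shape),
            mass=mass,
            p=p,
            sign=1 if mass > 0 else -1,
        ))
    mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        if c.p < alpha:
            mask[c.pixels] = True
    return ClusterTestResult(
        t_map=t_obs.reshape(shape),
        clusters=clusters,
        mask=mask,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        n_permutations=n_permutations if exact else int(len(signs)),
        df=df,
        seed=seed,
        null_max_mass=null,
    )


def _grid_adjacency(graph: AdjacencyGraph | None, n_ch, n_f, n_t) -> sparse.csr_matrix:
    """Pixel adjacency over a (channel, freq, time) grid: montage neighbors
    in space, +-1 along frequency and time."""
    if graph is None:
        a_ch = sparse.csr_matrix((n_ch, n_ch))
    else:
        a_ch = sparse.csr_matrix(graph.matrix.astype(np.int8))
    def path(n):
        return sparse.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1], format="csr") \
            if n > 1 else sparse.csr_matrix((n, n))
    i_ch, i_f, i_t = (sparse.identity(n, format="csr") for n in (n_ch, n_f, n_t))
    adj = (
        sparse.kron(a_ch, sparse.kron(i_f, i_t))
        + sparse.kron(i_ch, sparse.kron(path(n_f), i_t))
        + sparse.kron(i_ch, sparse.kron(i_f, path(n_t)))
    )
    return adj.tocsr()


def paired_cluster_test_3d(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    graph: AdjacencyGraph,
    n_permutations: int | str = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """Paired cluster test over (subjects, channels, freqs, times) dB maps."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError(f"condition shapes differ: {cond_a.shape} vs {cond_b.shape}")
    if cond_a.ndim != 4:
        raise ValueError("expected subjects x channels x freqs x times")
    n_sub, n_ch, n_f, n_t = cond_a.shape
    if graph is not None and len(graph.channel_names) != n_ch:
        raise ValueError("adjacency graph channel count mismatch")
    adj = _grid_adjacency(graph, n_ch, n_f, n_t)
    diffs = (cond_a - cond_b).reshape(n_sub, -1)
    return _cluster_engine(diffs, adj, (n_ch, n_f, n_t),
                           n_permutations, cluster_alpha, alpha, seed)


def cluster_test_1d(
    values: np.ndarray,
    reference: float = 0.0,
    paired_partner: np.ndarray | None = None,
    n_permutations: int | str = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster test over time only: one-sample against ``reference`` or
    paired against ``paired_partner`` (subjects x times inputs)."""
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValueError("expected subjects x times")
    if paired_partner is not None:
        partner = np.asarray(paired_partner, float)
        if partner.shape != values.shape:
            raise ValueError("paired partner shape mismatch")
        diffs = values - partner
    else:
        diffs = values - reference
    n_sub, n_t = diffs.shape
    adj = _grid_adjacency(None, 1, 1, n_t)
    return _cluster_engine(diffs, adj, (n_t,),
                           n_permutations, cluster_alpha, alpha, seed)


class ClusterPermutationTest:
    """Model-style front end: construct from condition data, ``fit`` runs the
    permutation scheme and returns a :class:`ClusterTestResult`.

    4-D inputs (subjects x channels x freqs x times) run the 3-D spatial
    test and need ``adjacency``; 2-D inputs (subjects x times) run the
    over-time test against ``reference`` or a paired partner.
    """

    def __init__(self, cond_a, cond_b=None, reference: float = 0.0,
                 adjacency: AdjacencyGraph | None = None):
        self.cond_a = np.asarray(cond_a, float)
        self.cond_b = None if cond_b is None else np.asarray(cond_b, float)
        self.reference = reference
        self.adjacency = adjacency

    def fit(self, n_permutations: int | str = 1000, cluster_alpha: float = 0.05,
            alpha: float = 0.05, seed: int | None = None) -> ClusterTestResult:
        if self.cond_a.ndim == 4:
            if self.cond_b is None:
                raise ValueError("3-D test requires two conditions")
            return paired_cluster_test_3d(
                self.cond_a, self.cond_b, self.adjacency,
                n_permutations, cluster_alpha, alpha, seed)
        return cluster_test_1d(
            self.cond_a, self.reference, self.cond_b,
            n_permutations, cluster_alpha, alpha, seed)
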