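"""SOM-based ligand egress pathway detection.

A sheet-shaped (non-periodic) self-organizing map is trained online on
capped ligand-residue distance vectors; every frame is assigned to its
best-matching unit (BMU).  Neurons are grouped by Ward clustering with the
cluster count chosen by the silhouette profile, consecutive-frame BMU
transitions (within trajectories only) form a directed neuron transition
network, and egress pathways are read from its cluster-level condensation
as maximum-bottleneck simple paths from the bound to the unbound cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .trajectory_io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "SOMModel",
    "NeuronClustering",
    "TransitionNetwork",
    "Pathway",
    "train_som",
    "cluster_neurons",
    "build_transition_network",
    "cluster_heatmap",
    "identify_endpoints",
    "extract_pathways",
    "trajectory_supports_path",
    "assign_trajectories",
    "representative_frames",
]


@dataclass
class SOMModel:
    grid: tuple
    codebook: np.ndarray  # neurons x features
    bmu: list  # per-trajectory BMU index arrays
    cycles: int
    alpha: tuple
    seed: int
    feature_names: list = field(default_factory=list)
    qe_history: np.ndarray | None = None  # (cycle, quantization error)

    @property
    def n_neurons(self) -> int:
        return self.grid[0] * self.grid[1]

    def bmu_concat(self) -> np.ndarray:
        return np.concatenate(self.bmu)

    def neuron_counts(self) -> np.ndarray:
        return np.bincount(self.bmu_concat(), minlength=self.n_neurons)


@dataclass
class NeuronClustering:
    k: int
    cluster_of: np.ndarray  # neuron -> cluster label, -1 for empty neurons
    silhouette_by_k: dict
    representative_neuron: list  # per cluster
    representative_frame: dict  # neuron -> global frame index

    def frame_clusters(self, som: SOMModel) -> np.ndarray:
        return self.cluster_of[som.bmu_concat()]


@dataclass
class TransitionNetwork:
    neuron_graph: nx.DiGraph
    self_transitions: int
    total_transitions: int  # consecutive-frame pairs, excluding self-pairs

    def cluster_graph(self, clustering: NeuronClustering) -> nx.DiGraph:
        """Condense neuron transitions to the cluster level (self edges,
        i.e. intra-cluster moves, are dropped)."""
        G = nx.DiGraph()
        G.add_nodes_from(sorted(set(clustering.cluster_of[clustering.cluster_of >= 0])))
        for u, v, data in self.neuron_graph.edges(data=True):
            cu, cv = clustering.cluster_of[u], clustering.cluster_of[v]
            if cu < 0 or cv < 0 or cu == cv:
                continue
            w = G.edges[cu, cv]["weight"] if G.has_edge(cu, cv) else 0
            G.add_edge(int(cu), int(cv), weight=w + data["weight"])
        return G


@dataclass
class Pathway:
    clusters: list
    bottleneck: int
    support: int = 0  # trajectories containing the path as a subsequence


# ---------------------------------------------------------------------------
# training


@njit(cache=True)
def _train_chunk(codebook, data, grid_pos, alphas, sigmas, seed):  # pragma: no cover
    n, d = data.shape
    m = codebook.shape[0]
    np.random.seed(seed)
    order = np.empty(n, dtype=np.int64)
    for c in range(alphas.shape[0]):
        alpha = alphas[c]
        sigma = sigmas[c]
        cut = 9.0 * sigma * sigma
        inv = 1.0 / (2.0 * sigma * sigma)
        for i in range(n):
            order[i] = i
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for t in range(n):
            x = data[order[t]]
            best = 0
            bestd = 1e300
            for k in range(m):
                s = 0.0
                for f in range(d):
                    diff = codebook[k, f] - x[f]
                    s += diff * diff
                if s < bestd:
                    bestd = s
                    best = k
            bx = grid_pos[best, 0]
            by = grid_pos[best, 1]
            for k in range(m):
                dx = grid_pos[k, 0] - bx
                dy = grid_pos[k, 1] - by
                gd2 = dx * dx + dy * dy
                if gd2 > cut:
                    continue
                h = alpha * np.exp(-gd2 * inv)
                for f in range(d):
                    codebook[k, f] += h * (x[f] - codebook[k, f])


def _quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def _as_tables(features) -> tuple[list[np.ndarray], list[str]]:
    if isinstance(features, (FeatureTable, np.ndarray)):
        features = [features]
    arrays, names = [], []
    for f in features:
        if isinstance(f, FeatureTable):
            arrays.append(f.values)
            names = [d.selection for d in f.descriptors]
        else:
            arrays.append(np.atleast_2d(np.asarray(f, float)))
    return arrays, names


def train_som(
    features,
    grid: tuple = (10, 10),
    cycles: int = 5000,
    seed: int = 0,
    alpha: tuple = (0.05, 0.01),
) -> SOMModel:
    """Train a sheet SOM online; one cycle presents every frame once in a
    seeded random order.

    The learning rate decays linearly over the cycles and the Gaussian
    neighbourhood radius shrinks linearly from half the grid diagonal to
    one lattice spacing.  The codebook is initialised from per-feature
    data quantiles (seeded).  Returns the model with final per-frame BMU
    assignments and a quantisation-error history at 5% checkpoints.
    """
    arrays, names = _as_tables(features)
    data = np.ascontiguousarray(np.vstack(arrays), dtype=np.float64)
    if data.shape[0] < 1:
        raise ValueError("no frames to train on")
    rows, cols = grid
    m = rows * cols
    rng = np.random.default_rng(seed)
    q = rng.random((m, data.shape[1]))
    codebook = np.empty((m, data.shape[1]))
    for j in range(data.shape[1]):
        codebook[:, j] = np.quantile(data[:, j], q[:, j])
    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=np.float64)
    sigma0 = 0.5 * float(np.hypot(rows, cols))
    sigma1 = 1.0
    fracs = np.arange(cycles) / max(1, cycles - 1)
    alphas = alpha[0] + (alpha[1] - alpha[0]) * fracs
    sigmas = sigma0 + (sigma1 - sigma0) * fracs
    n_checkpoints = 20
    bounds = np.unique(np.linspace(0, cycles, n_checkpoints + 1).astype(int))
    qe = [(0, _quantization_error(codebook, data))]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        _train_chunk(
            codebook,
            data,
            grid_pos,
            alphas[lo:hi],
            sigmas[lo:hi],
            int((seed + 17 * lo) % 2**31),
        )
        qe.append((int(hi), _quantization_error(codebook, data)))
    # final BMU assignment
    bmu_all = np.argmin(
        ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1), axis=1
    )
    bmu = []
    start = 0
    for arr in arrays:
        bmu.append(bmu_all[start : start + arr.shape[0]].astype(int))
        start += arr.shape[0]
    return SOMModel(
        grid=tuple(grid),
        codebook=codebook,
        bmu=bmu,
        cycles=cycles,
        alpha=tuple(alpha),
        seed=int(seed),
        feature_names=names,
        qe_history=np.asarray(qe),
    )


# ---------------------------------------------------------------------------
# neuron clustering


def cluster_neurons(som: SOMModel, k_range=range(2, 9)) -> NeuronClustering:
    """Ward clustering of the occupied codebook vectors; the cluster count
    maximising the mean silhouette over ``k_range`` wins (ties toward the
    smaller k)."""
    counts = som.neuron_counts()
    occupied = np.nonzero(counts > 0)[0]
    if occupied.size < 3:
        raise ValueError("fewer than 3 occupied neurons")
    X = som.codebook[occupied]
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("degenerate codebook: all occupied neurons identical")
    ks = [k for k in k_range if 2 <= k <= occupied.size - 1]
    if not ks:
        raise ValueError("k_range has no feasible cluster counts")
    silhouettes: dict[int, float] = {}
    labels_by_k = {}
    for k in ks:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
        labels_by_k[k] = labels
        silhouettes[k] = float(silhouette_score(X, labels))
    best_k = max(ks, key=lambda k: (silhouettes[k], -k))
    labels = labels_by_k[best_k]
    cluster_of = np.full(som.n_neurons, -1, dtype=int)
    cluster_of[occupied] = labels
    representative_neuron = []
    for c in range(best_k):
        members = occupied[labels == c]
        centroid = som.codebook[members].mean(axis=0)
        d = np.linalg.norm(som.codebook[members] - centroid, axis=1)
        representative_neuron.append(int(members[np.argmin(d)]))
    # per-neuron representative frames need the feature data; filled by
    # representative_frames() when the caller wants them
    representative_frame: dict[int, int] = {}
    return NeuronClustering(
        k=best_k,
        cluster_of=cluster_of,
        silhouette_by_k=silhouettes,
        representative_neuron=representative_neuron,
        representative_frame=representative_frame,
    )


def representative_frames(som: SOMModel, features) -> dict:
    """Frame (global index) closest to each occupied neuron's codebook."""
    arrays, _ = _as_tables(features)
    data = np.vstack(arrays)
    bmu_all = som.bmu_concat()
    out: dict[int, int] = {}
    for neuron in np.nonzero(som.neuron_counts() > 0)[0]:
        members = np.nonzero(bmu_all == neuron)[0]
        d = np.linalg.norm(data[members] - som.codebook[neuron], axis=1)
        out[int(neuron)] = int(members[np.argmin(d)])
    return out


# ---------------------------------------------------------------------------
# transition network and pathways


def build_transition_network(som: SOMModel) -> TransitionNetwork:
    """Directed neuron graph weighted by consecutive-frame BMU transitions;
    trajectory boundaries contribute no edges.  Self-loops are recorded on
    the graph but excluded from pathway search downstream."""
    G = nx.DiGraph()
    G.add_nodes_from(range(som.n_neurons))
    self_count = 0
    total = 0
    for seq in som.bmu:
        for u, v in zip(seq[:-1], seq[1:]):
            u, v = int(u), int(v)
            if u == v:
                self_count += 1
            else:
                total += 1
            w = G.edges[u, v]["weight"] if G.has_edge(u, v) else 0
            G.add_edge(u, v, weight=w + 1)
    return TransitionNetwork(neuron_graph=G, self_transitions=self_count, total_transitions=total)


def cluster_heatmap(features, som: SOMModel, clustering: NeuronClustering) -> pd.DataFrame:
    """clusters x residues table of mean capped ligand distances; residues
    with a mean below 4 Å are the cluster's contacts (flagged in the
    companion boolean table ``.attrs['contact']``)."""
    arrays, names = _as_tables(features)
    data = np.vstack(arrays)
    if not names:
        names = [f"f{j}" for j in range(data.shape[1])]
    frame_cluster = clustering.frame_clusters(som)
    rows = []
    for c in range(clustering.k):
        mask = frame_cluster == c
        if mask.any():
            rows.append(data[mask].mean(axis=0))
        else:
            logger.warning("cluster %d has no frames; heatmap row is NaN", c)
            rows.append(np.full(data.shape[1], np.nan))
    df = pd.DataFrame(rows, columns=names)
    df.index.name = "cluster"
    df.attrs["contact"] = df < 4.0
    return df


def identify_endpoints(
    clustering: NeuronClustering,
    heatmap: pd.DataFrame,
    network: TransitionNetwork,
) -> tuple[int, int]:
    """(bound, unbound) cluster labels.

    Unbound is the cluster whose mean capped distance is maximal (ligand
    far from every residue, distances saturated at the cap); bound is the
    minimal-mean cluster that sits at an edge of the cluster-level network
    (undirected degree ≤ 2), falling back to the overall minimum with a
    warning.  Ties resolve to the lowest label.
    """
    means = heatmap.mean(axis=1).to_numpy()
    unbound = int(np.nanargmax(means))
    G = network.cluster_graph(clustering).to_undirected()
    candidates = [
        c for c in range(clustering.k)
        if c != unbound and not np.isnan(means[c]) and G.degree(c) <= 2
    ]
    if not candidates:
        logger.warning("no low-degree candidate for the bound cluster; using global minimum")
        candidates = [c for c in range(clustering.k) if c != unbound and not np.isnan(means[c])]
    bound = int(min(candidates, key=lambda c: (means[c], c)))
    n_min = np.isclose(means[[c for c in range(clustering.k) if c != unbound]],
                       means[bound]).sum()
    if n_min > 1:
        logger.warning("bound-cluster tie broken toward lowest label")
    return bound, unbound


def trajectory_supports_path(cluster_seq: np.ndarray, path: list) -> bool:
    """True when the deduplicated cluster sequence contains ``path`` as an
    ordered subsequence."""
    dedup = [c for i, c in enumerate(cluster_seq) if i == 0 or c != cluster_seq[i - 1]]
    it = iter(dedup)
    return all(any(c == p for c in it) for p in path)


def extract_pathways(
    network: TransitionNetwork,
    clustering: NeuronClustering,
    som: SOMModel,
    bound: int,
    unbound: int,
    n_paths: int | None = None,
) -> list[Pathway]:
    """Simple paths bound → unbound in the cluster condensation, ranked by
    decreasing bottleneck (minimum edge) weight.

    Per-path support counts the trajectories whose cluster sequence
    contains the path as a subsequence.  Requesting more paths than exist
    returns all of them.
    """
    G = network.cluster_graph(clustering)
    if bound not in G or unbound not in G or not nx.has_path(G, bound, unbound):
        raise ValueError("no egress observed: unbound cluster unreachable from bound cluster")
    paths = []
    for nodes in nx.all_simple_paths(G, bound, unbound):
        bottleneck = min(G.edges[u, v]["weight"] for u, v in zip(nodes[:-1], nodes[1:]))
        paths.append(Pathway(clusters=[int(x) for x in nodes], bottleneck=int(bottleneck)))
    paths.sort(key=lambda p: (-p.bottleneck, p.clusters))
    if n_paths is not None:
        paths = paths[:n_paths]
    for p in paths:
        p.support = sum(
            trajectory_supports_path(clustering.cluster_of[seq], p.clusters) for seq in som.bmu
        )
    return paths


def assign_trajectories(som: SOMModel, clustering: NeuronClustering, pathways: list) -> list:
    """Assign each trajectory to the pathway it follows.

    A trajectory supporting exactly one pathway (as a cluster
    subsequence) gets that pathway; ambiguous cases (both or neither,
    e.g. a trajectory brushing the junction between branches) are resolved
    by dwell time in the clusters unique to each candidate pathway.
    Returns one pathway index (or None) per trajectory.
    """
    out = []
    cluster_sets = [set(p.clusters) for p in pathways]
    for seq in som.bmu:
        cs = clustering.cluster_of[seq]
        sup = [trajectory_supports_path(cs, p.clusters) for p in pathways]
        if sum(sup) == 1:
            out.append(sup.index(True))
            continue
        cands = [i for i, s in enumerate(sup) if s] if any(sup) else list(range(len(pathways)))
        shared = set.intersection(*(cluster_sets[i] for i in cands)) if len(cands) > 1 else set()
        dwell = [
            int(np.isin(cs, list(cluster_sets[i] - shared)).sum()) for i in cands
        ]
        if not any(sup) and max(dwell, default=0) == 0:
            out.append(None)
        else:
            out.append(cands[int(np.argmax(dwell))])
    return out
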