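"""Cortical network definition by modularity maximization.

Nodes of the whole-cortex Fisher-z connectivity matrix are grouped into
nonoverlapping communities with the Louvain algorithm; negative edges are
zeroed first (the most common signed-network convention, which keeps the
configuration null model of modularity valid). Detected communities are named
by maximum overlap with reference resting-state-network labels via a Hungarian
assignment, and the visual network is excluded downstream by default because
of its sparse direct striatal projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .connectivity import ConnectivityMatrix
from .io import AtlasLabels

logger = logging.getLogger(__name__)

CANONICAL_NETWORKS = ("DMN", "SMN", "CON", "DAT", "AUD", "VIS")
DEFAULT_EXCLUDED = frozenset({"VIS"})


@dataclass
class NetworkAssignment:
    """Node-to-community map with community names and an exclusion set.

    ``membership[i]`` is the community index of the i-th node (positional,
    aligned with the connectivity-matrix row order); ``names`` maps community
    index to a network name; ``excluded`` names communities dropped from all
    downstream striatal computations.
    """

    membership: np.ndarray
    names: dict[int, str]
    excluded: frozenset[str] = frozenset()
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=int)
        present = set(np.unique(self.membership).tolist())
        if not present <= set(self.names):
            raise ValueError("every community index must be named")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("community names must be unique")
        unknown = set(self.excluded) - set(self.names.values())
        if unknown:
            raise ValueError(f"excluded names not among communities: {sorted(unknown)}")

    @property
    def n_communities(self) -> int:
        return len(set(np.unique(self.membership)))

    @property
    def active_networks(self) -> list[str]:
        """Names of non-excluded communities, sorted for a deterministic order."""
        return sorted(name for name in self.names.values() if name not in self.excluded)

    def node_indices_of(self, name: str) -> np.ndarray:
        idx = [k for k, v in self.names.items() if v == name]
        if not idx:
            raise ValueError(f"unknown network name {name!r}")
        return np.flatnonzero(self.membership == idx[0])

    def sizes(self) -> dict[str, int]:
        return {name: len(self.node_indices_of(name)) for name in self.active_networks}


@dataclass
class ModularityResult:
    Q: float
    gamma: float
    seed: int
    n_runs: int
    all_Q: list = field(default_factory=list)


def _as_weight_matrix(conn) -> np.ndarray:
    W = conn.z if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, dtype=float)
    W = np.clip(W, 0.0, None)  # negative z zeroed before modularity
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if W.sum() == 0:
        raise ValueError("weight matrix is all-zero")
    return W


def modularity(W, partition, gamma: float = 1.0) -> float:
    """Newman-Girvan weighted modularity.

    Q = (1/2m) sum_ij [W_ij - gamma * k_i k_j / (2m)] delta(c_i, c_j),
    evaluated over the full matrix including the diagonal (zero here).
    """
    W = _as_weight_matrix(W)
    c = np.asarray(partition, dtype=int)
    if c.shape[0] != W.shape[0]:
        raise ValueError("partition length must match node count")
    k = W.sum(axis=1)
    two_m = k.sum()
    delta = c[:, None] == c[None, :]
    return float(((W - gamma * np.outer(k, k) / two_m) * delta).sum() / two_m)


def _canonical_membership(comms: list[set], n: int) -> np.ndarray:
    memb = np.empty(n, dtype=int)
    for idx, nodes in enumerate(comms):
        for node in nodes:
            memb[node] = idx
    # relabel by first occurrence so equal partitions compare equal
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, m in enumerate(memb):
        if m not in seen:
            seen[m] = len(seen)
        out[i] = seen[m]
    return out


def louvain(
    conn,
    gamma: float = 1.0,
    seed: int = 0,
    n_runs: int = 100,
) -> tuple[NetworkAssignment, ModularityResult]:
    """Best-of-``n_runs`` Louvain community detection on the clipped z matrix.

    Each run uses a distinct RNG stream derived from ``seed``; the partition
    with the highest modularity Q (own Newman-Girvan evaluation, same gamma)
    is returned. Ties in Q are broken by the lexicographically smallest
    canonical membership vector, so results are fully deterministic given
    (seed, n_runs).
    """
    W = _as_weight_matrix(conn)
    n = W.shape[0]
    node_ids = conn.node_ids if isinstance(conn, ConnectivityMatrix) else np.arange(n)
    G = nx.from_numpy_array(W)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    best: tuple[float, tuple] | None = None
    all_q = []
    for rs in run_seeds:
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=int(rs)
        )
        memb = _canonical_membership([set(c) for c in comms], n)
        q = modularity(W, memb, gamma)
        all_q.append(q)
        key = (-q, tuple(memb))
        if best is None or key < best:
            best = key
    q_best = -best[0]
    memb_best = np.asarray(best[1], dtype=int)
    names = {k: f"community-{k}" for k in np.unique(memb_best)}
    assignment = NetworkAssignment(
        membership=memb_best, names=names, node_ids=np.asarray(node_ids)
    )
    result = ModularityResult(Q=q_best, gamma=gamma, seed=seed, n_runs=n_runs, all_Q=all_q)
    logger.info("louvain: %d communities, Q=%.4f over %d runs", len(names), q_best, n_runs)
    return assignment, result


def match_networks(assignment: NetworkAssignment, atlas: AtlasLabels) -> NetworkAssignment:
    """Name detected communities by maximum overlap with reference networks.

    Builds the community x reference-network node-count matrix and solves the
    one-to-one assignment maximizing total overlap (Hungarian); communities
    left unmatched (more communities than reference names, or zero overlap)
    become ``unmatched-k``. Without reference names, communities keep
    ``community-k`` identity names.
    """
    ref = atlas.reference_networks
    if ref is None:
        logger.warning("atlas has no reference network names; keeping identity names")
        return assignment
    ref_vals = np.asarray(ref)
    if len(ref_vals) != len(assignment.membership):
        raise ValueError("reference names length must match node count")
    comm_ids = np.unique(assignment.membership)
    ref_names = sorted(set(ref_vals.tolist()))
    overlap = np.zeros((len(comm_ids), len(ref_names)), dtype=int)
    for i, c in enumerate(comm_ids):
        in_c = assignment.membership == c
        for j, rname in enumerate(ref_names):
            overlap[i, j] = int(np.sum(in_c & (ref_vals == rname)))
    rows, cols = linear_sum_assignment(-overlap)
    names: dict[int, str] = {}
    for i, j in zip(rows, cols):
        if overlap[i, j] > 0:
            names[int(comm_ids[i])] = ref_names[j]
    for c in comm_ids:
        if int(c) not in names:
            names[int(c)] = f"unmatched-{int(c)}"
    return replace(assignment, names=names, excluded=frozenset())


def exclude_networks(
    assignment: NetworkAssignment, names: set[str] | frozenset[str] = DEFAULT_EXCLUDED
) -> NetworkAssignment:
    """Flag networks (visual, by default) to be ignored downstream."""
    unknown = set(names) - set(assignment.names.values())
    if unknown:
        raise ValueError(f"cannot exclude unknown networks: {sorted(unknown)}")
    return replace(assignment, excluded=frozenset(names))
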