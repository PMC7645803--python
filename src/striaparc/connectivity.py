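"""Node time-series extraction and Fisher-z functional connectivity.

Functional connectivity between two regions is the Fisher z-transform
(arctanh) of the Pearson correlation of their BOLD time series. Correlations
are clipped to |r| <= 1 - 1e-12 before the transform so degenerate duplicates
stay finite; zero-variance series yield correlation 0 with a logged warning
rather than an error, because clipped masks in real cohorts must not abort a
pipeline mid-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AtlasLabels, TimeSeries4D, check_shared_grid

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-12


@dataclass
class NodeTimeSeriesMatrix:
    """Per-node mean BOLD series, rows aligned with the atlas node table."""

    values: np.ndarray  # node x time
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if self.values.ndim != 2:
            raise ValueError("node time series must be a 2-D node x time matrix")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length must match row count")

    @property
    def zero_variance_rows(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(self.values, axis=1)
        return (sd == 0) | ~np.isfinite(sd)


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z matrix with a zero diagonal."""

    z: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix has non-finite entries")
        if np.max(np.abs(self.z - self.z.T)) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric to 1e-12")
        if np.max(np.abs(np.diag(self.z))) != 0:
            raise ValueError("connectivity matrix diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class VoxelNodeConnectivity:
    """Cached striatal-voxel x cortical-node Fisher-z matrix.

    This is the reusable intermediate for the node-permutation null: permuting
    node-to-network labels only re-groups its columns, so no time series are
    touched when building null parcellations. Voxel order is the sorted
    flat-index order of the striatal mask.
    """

    z_vn: np.ndarray  # voxel x node
    node_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_vn = np.asarray(self.z_vn, dtype=float)
        if self.z_vn.ndim != 2:
            raise ValueError("voxel-node connectivity must be 2-D")
        if not np.all(np.isfinite(self.z_vn)):
            raise ValueError("voxel-node connectivity has non-finite entries")


def extract_node_series(ts: TimeSeries4D, atlas: AtlasLabels) -> NodeTimeSeriesMatrix:
    """Average the BOLD series over each atlas node's voxels.

    Nodes with no voxels on the grid yield all-NaN rows with a warning.
    """
    check_shared_grid(ts, atlas)
    node_ids = atlas.node_ids
    n_t = ts.n_timepoints
    flat = ts.data.reshape(-1, n_t)
    labels = atlas.labels.ravel()
    out = np.full((len(node_ids), n_t), np.nan)
    empty = []
    for row, lab in enumerate(node_ids):
        sel = labels == lab
        if not sel.any():
            empty.append(int(lab))
            continue
        out[row] = flat[sel].mean(axis=0)
    if empty:
        logger.warning("atlas nodes with no voxels on grid: %s", empty)
    nts = NodeTimeSeriesMatrix(values=out, node_ids=node_ids)
    if nts.zero_variance_rows.any():
        logger.warning(
            "zero-variance node series at rows %s",
            np.flatnonzero(nts.zero_variance_rows).tolist(),
        )
    return nts


def fisher_z(r):
    """Fisher z-transform arctanh(r), clipping |r| at 1 - 1e-12.

    Odd function; accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    clipped = np.clip(r, -R_CLIP, R_CLIP)
    if np.any(np.abs(r) > R_CLIP):
        logger.info("correlations at |r|>=1 clipped before arctanh")
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def _safe_corr_rows(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Row-wise Pearson correlation with zero-variance rows mapped to r=0."""
    a = np.asarray(a, dtype=float)
    a_sd = a.std(axis=1)
    bad_a = a_sd == 0
    az = (a - a.mean(axis=1, keepdims=True)) / np.where(bad_a, 1.0, a_sd)[:, None]
    az[bad_a] = 0.0
    if b is None:
        bz, bad_b = az, bad_a
    else:
        b = np.asarray(b, dtype=float)
        b_sd = b.std(axis=1)
        bad_b = b_sd == 0
        bz = (b - b.mean(axis=1, keepdims=True)) / np.where(bad_b, 1.0, b_sd)[:, None]
        bz[bad_b] = 0.0
    if bad_a.any() or bad_b.any():
        logger.warning("zero-variance series: correlations set to 0")
    r = az @ bz.T / a.shape[1]
    return np.clip(r, -1.0, 1.0)


def connectivity_matrix(nts: NodeTimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Fisher-z Pearson connectivity over all node pairs.

    The diagonal is set to 0 (self-connectivity carries no information and
    would otherwise sit at the clip ceiling).
    """
    if nts.values.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    vals = np.where(np.isfinite(nts.values), nts.values, 0.0)
    r = _safe_corr_rows(vals)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, node_ids=nts.node_ids)


def voxel_node_connectivity(
    vox_ts: np.ndarray, nts: NodeTimeSeriesMatrix
) -> VoxelNodeConnectivity:
    """Fisher-z correlation of every striatal voxel with every cortical node."""
    vox_ts = np.asarray(vox_ts, dtype=float)
    if vox_ts.shape[1] != nts.values.shape[1]:
        raise ValueError("voxel and node series have different lengths")
    node_vals = np.where(np.isfinite(nts.values), nts.values, 0.0)
    r = _safe_corr_rows(vox_ts, node_vals)
    return VoxelNodeConnectivity(z_vn=fisher_z(r), node_ids=nts.node_ids)


def group_columns(
    vnc: VoxelNodeConnectivity, membership: np.ndarray, n_groups: int
) -> np.ndarray:
    """Mean voxel-node z over each column group (network) — the re-grouping
    primitive shared by the observed pipeline and the node-permutation null."""
    z = vnc.z_vn
    out = np.empty((z.shape[0], n_groups))
    for k in range(n_groups):
        cols = membership == k
        if not cols.any():
            raise ValueError(f"network group {k} has no nodes")
        out[:, k] = z[:, cols].mean(axis=1)
    return out


def voxel_network_connectivity(vnc, assignment, vox_ts=None, nts=None) -> np.ndarray:
    """Mean connectivity of each striatal voxel to each active cortical network.

    Entry (v, k) is the mean over nodes n in network k of the voxel-node
    Fisher z. Works from a cached :class:`VoxelNodeConnectivity` (pass
    ``vnc``) or recomputes it from series (pass ``vox_ts`` and ``nts``).
    Excluded networks (e.g. visual) are dropped; columns follow
    ``assignment.active_networks``.
    """
    if vnc is None:
        if vox_ts is None or nts is None:
            raise ValueError("need either a cached vnc or raw series")
        vnc = voxel_node_connectivity(vox_ts, nts)
    active = assignment.active_networks
    z = vnc.z_vn
    out = np.empty((z.shape[0], len(active)))
    for j, name in enumerate(active):
        cols = assignment.node_indices_of(name)
        if len(cols) == 0:
            raise ValueError(f"network {name!r} has no nodes")
        out[:, j] = z[:, cols].mean(axis=1)
    return out
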