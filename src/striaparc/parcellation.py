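"""Probabilistic striatal weight maps and spatial summaries.

Each striatal voxel receives a weight in [0, 1] per cortical network: negative
voxel-network connectivity is clipped to zero and each voxel's remaining
connectivity is normalized by its total positive connectivity strength. This
soft (probabilistic) assignment deliberately avoids winner-takes-all labelling
because corticostriatal projections, while topographic, overlap heavily.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class StriatalWeightMaps:
    """Per-network voxel weights over the striatal mask.

    ``weights`` is voxel x network in [0, 1]; voxels with any positive
    connectivity have weights summing to 1. ``connectivity`` keeps the clipped
    (pre-normalization) voxel-network z values, used for the mean-weight group
    contrast where normalized weights would be vacuous by construction.
    Voxel order is sorted flat-index order of ``mask``.
    """

    weights: np.ndarray
    network_names: list[str]
    mask: np.ndarray | None = None
    connectivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be voxel x network")
        if self.weights.shape[1] != len(self.network_names):
            raise ValueError("network name count must match weight columns")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != self.weights.shape[0]:
                raise ValueError("mask voxel count must match weight rows")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.network_names.index(name)]

    def to_volume(self, name: str) -> np.ndarray:
        """Embed one network's weights back into the 3-D mask grid."""
        if self.mask is None:
            raise ValueError("no mask attached")
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.column(name)
        return vol


@dataclass
class AnatomicalROIs:
    """Anatomical striatal subdivision labels (limbic / associative / sensorimotor).

    Subdivisions are disjoint; the whole striatum is their union.
    """

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be integer")
        present = set(np.unique(self.labels).tolist()) - {0}
        if not present <= set(self.names):
            raise ValueError("unnamed ROI label ids present")

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.names.items() if v == name]
        if not ids:
            raise ValueError(f"unknown ROI {name!r}")
        return self.labels == ids[0]


def weight_maps(
    vnc_net: np.ndarray,
    network_names: list[str],
    mask: np.ndarray | None = None,
) -> StriatalWeightMaps:
    """Turn voxel-network connectivity into normalized [0, 1] weight maps.

    Negative entries are clipped to 0; each voxel's clipped values are divided
    by their sum (total positive connectivity strength). Voxels with no
    positive connectivity to any network get an all-zero row and are logged.
    """
    vnc_net = np.asarray(vnc_net, dtype=float)
    if not np.all(np.isfinite(vnc_net)):
        raise ValueError("voxel-network connectivity must be finite")
    clipped = np.clip(vnc_net, 0.0, None)
    totals = clipped.sum(axis=1)
    dead = totals <= 0
    if dead.any():
        logger.warning("%d voxels with no positive connectivity; weights zeroed", dead.sum())
    weights = np.where(dead[:, None], 0.0, clipped / np.where(dead, 1.0, totals)[:, None])
    return StriatalWeightMaps(
        weights=weights, network_names=list(network_names), mask=mask, connectivity=clipped
    )


def threshold_map(weights: np.ndarray, keep_fraction: float = 0.35) -> np.ndarray:
    """Retain the top ``keep_fraction`` of voxels by weight (display maps).

    Keeps exactly ceil(keep_fraction * n) voxels; ties at the cut are broken
    by sorted voxel index, so the result is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    w = np.asarray(weights, dtype=float).ravel()
    n = w.size
    if n == 0:
        raise ValueError("empty mask")
    m = math.ceil(keep_fraction * n)
    # stable sort on -w keeps ascending index order among ties
    order = np.argsort(-w, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[:m]] = True
    return keep.reshape(np.shape(weights))


def roi_mean(values: np.ndarray, rois: AnatomicalROIs, include_union: bool = True) -> dict:
    """Unweighted mean of a voxel map over each anatomical subdivision.

    Returns a name -> mean dict; ``whole`` (the union of subdivisions) is the
    whole-striatum mean.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != rois.labels.shape:
        raise ValueError("map and ROI label shapes differ")
    out = {}
    for name in sorted(set(rois.names.values())):
        m = rois.roi_mask(name)
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        out[name] = float(values[m].mean())
    if include_union:
        out["whole"] = float(values[rois.union_mask].mean())
    return out


def _ramp(mask: np.ndarray, axis: int) -> np.ndarray:
    idx = np.nonzero(mask)[axis]
    lo, hi = int(idx.min()), int(idx.max())
    if hi == lo:
        logger.warning("degenerate axis %d (1 voxel thick); ramp constant 0.5", axis)
        return np.full(mask.sum(), 0.5)
    coords = np.argwhere(mask)[:, axis]
    return (coords - lo) / (hi - lo)


def spatial_gradient_score(
    weights: np.ndarray, mask: np.ndarray, axis: int | str
) -> float:
    """Weighted position of a map along one voxel axis of the mask bounding box.

    A ramp running linearly from 0 to 1 across the mask's bounding box along
    the chosen axis (constant along the others) multiplies the weights; the
    score is the sum. Sensitive to lateral/rostrocaudal/dorsoventral shifts of
    a subdivision's weighting between groups. ``weights`` may be the in-mask
    vector (sorted flat-index order) or a full 3-D volume.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    w = np.asarray(weights, dtype=float)
    if w.shape == mask.shape:
        w = w[mask]
    elif w.ndim != 1 or w.size != int(mask.sum()):
        raise ValueError("weights must match the mask grid or its voxel count")
    return float(w @ _ramp(mask, int(axis)))


def mean_weight(connectivity: np.ndarray) -> np.ndarray:
    """Per-network mean of the clipped (pre-normalization) connectivity values.

    Computed on clipped z rather than on normalized weights: per-voxel
    normalization forces every cohort member's weights to sum to the voxel
    count, which would make a between-group comparison of means vacuous.
    """
    connectivity = np.asarray(connectivity, dtype=float)
    if connectivity.ndim != 2:
        raise ValueError("expected voxel x network connectivity")
    return connectivity.mean(axis=0)
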