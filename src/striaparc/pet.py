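"""Network-specific Ki from voxelwise parametric maps, and reference-region
Patlak slope estimation.

Ki (1/min) is the influx rate constant of an irreversible tracer; for
18F-DOPA with a cerebellar reference it indexes dopamine synthesis capacity.
Network-specific Ki is the weight-map-weighted mean of the voxelwise Ki map
over the striatal mask. Values are always stored unscaled (1/min); any
display scaling (e.g. x100) happens at presentation time only.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import AnatomicalROIs, StriatalWeightMaps, roi_mean

logger = logging.getLogger(__name__)

ANATOMICAL_COLUMNS = ["WST", "AST", "LST", "SMST"]
_ROI_TO_COLUMN = {"whole": "WST", "associative": "AST", "limbic": "LST", "sensorimotor": "SMST"}


def network_ki(ki_values: np.ndarray, wmaps: StriatalWeightMaps) -> dict[str, float]:
    """Weighted mean Ki per network: Ki_k = sum_v w_vk Ki_v / sum_v w_vk.

    ``ki_values`` is the in-mask Ki vector (sorted flat-index order) or a 3-D
    volume sharing the weight maps' mask. A convex combination, so every
    network Ki lies within [min, max] of the in-mask Ki.
    """
    ki = np.asarray(ki_values, dtype=float)
    if wmaps.mask is not None and ki.shape == wmaps.mask.shape:
        ki = ki[wmaps.mask]
    if ki.ndim != 1 or ki.size != wmaps.n_voxels:
        raise ValueError("Ki values must match the weight maps' voxel count")
    if not np.all(np.isfinite(ki)):
        raise ValueError("non-finite Ki inside striatal mask")
    sums = wmaps.weights.sum(axis=0)
    if np.any(sums <= 0):
        empty = [n for n, s in zip(wmaps.network_names, sums) if s <= 0]
        raise ValueError(f"zero total weight for networks: {empty}")
    vals = (wmaps.weights.T @ ki) / sums
    if np.any(vals > 0.1) or np.any(vals < 0):
        logger.info("network Ki outside the typical ~1e-2 1/min range")
    return dict(zip(wmaps.network_names, vals.tolist()))


def cumulative_trapezoid_from_zero(curve: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Running integral of a TAC assuming zero activity at t=0.

    Trapezoidal rule over the sampled frames plus the initial triangle from
    (0, 0) to the first frame.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    inner = np.concatenate(
        [[0.0], np.cumsum(np.diff(times) * (curve[1:] + curve[:-1]) / 2.0)]
    )
    return inner + times[0] * curve[0] / 2.0


def patlak_slope(
    target_tac: np.ndarray,
    ref_tac: np.ndarray,
    frame_times: np.ndarray,
    t_star: float = 20.0,
) -> tuple[float, float]:
    """Reference-region Patlak graphical analysis.

    Regresses y(T) = target(T)/ref(T) on x(T) = int_0^T ref / ref(T) by OLS
    over frames with T >= t_star (minutes). For an irreversible tracer the
    plot is linear after t_star and the slope is Ki (1/min); the intercept is
    the effective distribution volume. Default t_star of 20 min follows
    conventional DOPA practice and is configurable.
    """
    target = np.asarray(target_tac, dtype=float)
    ref = np.asarray(ref_tac, dtype=float)
    times = np.asarray(frame_times, dtype=float)
    if not (target.shape == ref.shape == times.shape):
        raise ValueError("TACs and frame times must have equal length")
    late = times >= t_star
    if late.sum() < 3:
        raise ValueError(f"need >= 3 frames at or after t_star={t_star}, got {int(late.sum())}")
    if np.any(ref[late] <= 0):
        raise ValueError("reference TAC must be positive after t_star")
    integ = cumulative_trapezoid_from_zero(ref, times)
    x = integ[late] / ref[late]
    y = target[late] / ref[late]
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


def assemble_ki_table(
    subject_ids: list,
    ki_maps: dict,
    wmaps_by_subject: dict,
    rois: AnatomicalROIs | None = None,
    ki_volumes: dict | None = None,
) -> pd.DataFrame:
    """Build the subject x subdivision Ki table feeding all inference.

    Columns are ordered [WST, AST, LST, SMST] (anatomical, when ROI labels are
    supplied) followed by the active networks alphabetically. ``ki_maps`` maps
    subject id to the in-mask Ki vector; ``ki_volumes`` (optional) maps to the
    full 3-D Ki volume needed for anatomical ROI means. Subjects with missing
    data are skipped with a logged reason. Provenance (weight and mask hashes)
    is stored in ``DataFrame.attrs``.
    """
    records, kept = [], []
    for sid in subject_ids:
        if sid not in ki_maps or sid not in wmaps_by_subject:
            logger.warning("subject %s skipped: missing Ki map or weight maps", sid)
            continue
        wm = wmaps_by_subject[sid]
        row = {}
        if rois is not None:
            vol = None if ki_volumes is None else ki_volumes.get(sid)
            if vol is None and wm.mask is not None:
                vol = np.zeros(wm.mask.shape)
                vol[wm.mask] = np.asarray(ki_maps[sid], dtype=float)
            if vol is None:
                logger.warning("subject %s skipped: no volume for anatomical ROIs", sid)
                continue
            means = roi_mean(vol, rois)
            for roi_name, col in _ROI_TO_COLUMN.items():
                if roi_name in means:
                    row[col] = means[roi_name]
        row.update(network_ki(ki_maps[sid], wm))
        records.append(row)
        kept.append(sid)
    df = pd.DataFrame.from_records(records, index=pd.Index(kept, name="subject"))
    anat = [c for c in ANATOMICAL_COLUMNS if c in df.columns]
    nets = sorted(c for c in df.columns if c not in ANATOMICAL_COLUMNS)
    df = df[anat + nets]
    if kept:
        df.attrs["weights_hash"] = _hash_array(wmaps_by_subject[kept[0]].weights)
        wm0 = wmaps_by_subject[kept[0]]
        if wm0.mask is not None:
            df.attrs["mask_hash"] = _hash_array(wm0.mask)
    return df
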