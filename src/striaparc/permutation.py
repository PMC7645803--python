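"""Permutation inference for dopamine-symptom associations.

Two complementary nulls are provided. Participant-level permutation shuffles
the mapping between subjects' Ki values and symptom scores (jointly across
all subdivisions, preserving the inter-subdivision correlation structure) and
tests whether any association exists. Cortical-node permutation shuffles the
node-to-network assignment (size-preserving, identically across subjects) and
rebuilds the entire parcellation-to-Ki pipeline per iteration by re-grouping
cached voxel-node connectivity columns; because every null parcellation still
tiles the same striatum, this null retains any global whole-striatum
Ki-symptom relationship and therefore tests topographic *specificity*.

All p-values use the add-one rule p = (1 + #{null >= observed}) / (1 + P),
which is a valid p-value under exchangeability and can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import VoxelNodeConnectivity
from .community import NetworkAssignment
from .parcellation import StriatalWeightMaps, mean_weight, spatial_gradient_score, weight_maps
from .stats import bh_fdr, student_t_independent


@dataclass
class PermutationSpec:
    """Permutation-test configuration; the seed is mandatory."""

    seed: int
    n_perm: int = 10_000
    sidedness: str = "two"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.sidedness not in {"two", "greater", "less"}:
            raise ValueError("sidedness must be 'two', 'greater' or 'less'")


@dataclass
class PermutationResults:
    """Tidy per-(subdivision, factor) results plus the full null archive.

    ``table`` has columns subdivision, factor, r, p, p_fdr; ``null_r`` is the
    n_perm x subdivision x factor array of null correlations, reused by the
    pairwise correlation-difference tests so their null preserves the
    dependence between subdivisions.
    """

    table: pd.DataFrame
    null_r: np.ndarray
    observed_r: np.ndarray
    subdivisions: list[str]
    factors: list[str]
    spec: PermutationSpec
    extra: dict = field(default_factory=dict)


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def _perm_pvalues(observed: np.ndarray, null: np.ndarray, sidedness: str) -> np.ndarray:
    """Add-one permutation p-values; ``null`` has iterations on axis 0."""
    if sidedness == "two":
        exceed = np.abs(null) >= np.abs(observed)[None]
    elif sidedness == "greater":
        exceed = null >= observed[None]
    else:
        exceed = null <= observed[None]
    return (1.0 + exceed.sum(axis=0)) / (1.0 + null.shape[0])


def _tidy_table(observed, pvals, subdivisions, factors) -> pd.DataFrame:
    rows = []
    p_flat = pvals.ravel()
    p_fdr = bh_fdr(p_flat).reshape(pvals.shape)
    for i, sub in enumerate(subdivisions):
        for j, fac in enumerate(factors):
            rows.append(
                {
                    "subdivision": sub,
                    "factor": fac,
                    "r": float(observed[i, j]),
                    "p": float(pvals[i, j]),
                    "p_fdr": float(p_fdr[i, j]),
                }
            )
    return pd.DataFrame(rows)


def _aligned_arrays(ki: pd.DataFrame, symptoms: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not ki.index.equals(symptoms.index):
        raise ValueError("Ki table and symptom table must share identical subject rows")
    return np.asarray(ki, dtype=float), np.asarray(symptoms, dtype=float)


def participant_permutation(
    ki: pd.DataFrame, symptoms: pd.DataFrame, spec: PermutationSpec
) -> PermutationResults:
    """Participant-level permutation test of every (subdivision, factor) pair.

    Ki rows are permuted jointly across all subdivisions — one subject
    permutation per iteration, reused for every subdivision and factor — while
    symptom scores stay fixed, so each null iteration preserves the
    subdivision x subdivision Ki correlation matrix exactly. FDR is applied
    across all (subdivision, factor) tests (the 5 x 5 = 25 family in the
    standard configuration).
    """
    X, Y = _aligned_arrays(ki, symptoms)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    Zx, Zy = _standardize_columns(X), _standardize_columns(Y)
    observed = Zx.T @ Zy / n
    rng = np.random.default_rng(spec.seed)
    perms = np.argsort(rng.random((spec.n_perm, n)), axis=1)
    null = np.einsum("pnd,nf->pdf", Zx[perms], Zy) / n
    pvals = _perm_pvalues(observed, null, spec.sidedness)
    table = _tidy_table(observed, pvals, list(ki.columns), list(symptoms.columns))
    table["scheme"] = "participant"
    return PermutationResults(
        table=table,
        null_r=null,
        observed_r=observed,
        subdivisions=list(ki.columns),
        factors=list(symptoms.columns),
        spec=spec,
    )


def correlation_difference_test(
    ki: pd.DataFrame,
    symptoms: pd.DataFrame,
    pair: tuple[str, str],
    factor: str,
    spec: PermutationSpec,
    results: PermutationResults | None = None,
) -> dict:
    """Test whether two subdivisions' correlations with a factor differ.

    The statistic is the absolute difference |r_a - r_b|; the null comes from
    the same joint participant permutations (so the a-b dependence is
    preserved) and the p-value is one-sided: fraction of null differences at
    least as large, with the add-one rule.
    """
    if results is None:
        results = participant_permutation(ki, symptoms, spec)
    a, b = pair
    ia, ib = results.subdivisions.index(a), results.subdivisions.index(b)
    jf = results.factors.index(factor)
    observed = abs(results.observed_r[ia, jf] - results.observed_r[ib, jf])
    null = np.abs(results.null_r[:, ia, jf] - results.null_r[:, ib, jf])
    p = float((1.0 + np.sum(null >= observed)) / (1.0 + null.shape[0]))
    return {
        "subdivision_a": a,
        "subdivision_b": b,
        "factor": factor,
        "observed_diff": float(observed),
        "p": p,
        "n_perm": results.spec.n_perm,
    }


def _active_membership(assignment: NetworkAssignment) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Node -> active-network index (-1 for excluded), names, group sizes."""
    n_nodes = len(assignment.membership)
    active = assignment.active_networks
    memb = np.full(n_nodes, -1, dtype=int)
    for k, name in enumerate(active):
        memb[assignment.node_indices_of(name)] = k
    sizes = np.array([np.sum(memb == k) for k in range(len(active))])
    if np.any(sizes == 0):
        empty = [active[k] for k in np.flatnonzero(sizes == 0)]
        raise ValueError(f"networks with no nodes: {empty}")
    return memb, active, sizes


def _null_network_ki_chunk(
    z_stack: np.ndarray, ki_stack: np.ndarray, perm_nodes: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Network Ki for a chunk of node permutations, all subjects at once.

    ``z_stack`` is subjects x voxels x active-node-pool (columns already
    restricted and ordered by the node pool); ``perm_nodes`` is chunk x pool
    of permuted pool positions. Per permutation the first sizes[0] positions
    form network 0, the next sizes[1] network 1, and so on — a size-preserving
    relabelling. Weight maps are rebuilt per iteration (clip + per-voxel
    normalization) and Ki is the weighted mean. Returns chunk x subjects x K.
    """
    n_sub, n_vox, _ = z_stack.shape
    chunk = perm_nodes.shape[0]
    n_k = len(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    # grouping matrix: pool-position x (chunk * K), entries 1/size_k
    G = np.zeros((z_stack.shape[2], chunk * n_k))
    cols = np.arange(chunk) * n_k
    for k in range(n_k):
        rows = perm_nodes[:, bounds[k]:bounds[k + 1]]  # chunk x size_k
        G[rows.ravel(), np.repeat(cols + k, sizes[k])] = 1.0 / sizes[k]
    out = np.empty((chunk, n_sub, n_k))
    for s in range(n_sub):
        vn = (z_stack[s] @ G).reshape(n_vox, chunk, n_k)
        np.clip(vn, 0.0, None, out=vn)
        totals = vn.sum(axis=2, keepdims=True)
        np.divide(vn, totals, out=vn, where=totals > 0)
        wsum = vn.sum(axis=0)  # chunk x K
        out[:, s, :] = np.einsum("vck,v->ck", vn, ki_stack[s]) / np.where(wsum > 0, wsum, 1.0)
    return out


def node_permutation(
    vnc_by_subject: list[VoxelNodeConnectivity],
    assignment: NetworkAssignment,
    ki_by_subject: list[np.ndarray],
    symptoms: pd.DataFrame,
    spec: PermutationSpec,
    chunk_size: int = 500,
) -> PermutationResults:
    """Cortical-node permutation test of network-Ki-symptom associations.

    Node-to-network labels are permuted uniformly at random (preserving the
    observed network sizes), identically across all subjects within an
    iteration; weight maps and network Ki are recomputed by re-grouping the
    cached voxel-node connectivity columns — no time series are touched. The
    resulting null retains each subject's whole-striatum Ki structure, so
    small p-values indicate symptom associations specific to a network's
    striatal topography rather than a global Ki-symptom relationship.
    """
    if len(vnc_by_subject) != len(symptoms) or len(ki_by_subject) != len(symptoms):
        raise ValueError("need one cached connectivity matrix and Ki map per subject")
    if not vnc_by_subject:
        raise ValueError("cache missing: no subjects supplied")
    memb, active, sizes = _active_membership(assignment)
    pool = np.flatnonzero(memb >= 0)
    order = np.argsort(memb[pool], kind="stable")
    pool = pool[order]  # pool ordered network-block-wise; identity perm = observed grouping
    z_stack = np.stack([v.z_vn[:, pool] for v in vnc_by_subject])
    ki_stack = np.stack([np.asarray(k, dtype=float) for k in ki_by_subject])
    n_sub = z_stack.shape[0]

    identity = np.arange(pool.size)[None]
    obs_ki = _null_network_ki_chunk(z_stack, ki_stack, identity, sizes)[0]  # S x K
    Zy = _standardize_columns(np.asarray(symptoms, dtype=float))
    obs_r = _standardize_columns(obs_ki).T @ Zy / n_sub

    rng = np.random.default_rng(spec.seed)
    null = np.empty((spec.n_perm, len(active), len(symptoms.columns)))
    done = 0
    while done < spec.n_perm:
        m = min(chunk_size, spec.n_perm - done)
        perms = np.argsort(rng.random((m, pool.size)), axis=1)
        nk = _null_network_ki_chunk(z_stack, ki_stack, perms, sizes)  # m x S x K
        sd = nk.std(axis=1, keepdims=True)
        nk = (nk - nk.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        null[done:done + m] = np.einsum("psk,sf->pkf", nk, Zy) / n_sub
        done += m
    pvals = _perm_pvalues(obs_r, null, spec.sidedness)
    table = _tidy_table(obs_r, pvals, active, list(symptoms.columns))
    table["scheme"] = "node"
    return PermutationResults(
        table=table,
        null_r=null,
        observed_r=obs_r,
        subdivisions=active,
        factors=list(symptoms.columns),
        spec=spec,
        extra={"observed_network_ki": obs_ki},
    )


def group_topography_tests(
    wmaps_by_subject: list[StriatalWeightMaps],
    groups,
    axes: tuple[str, ...] = ("x", "y", "z"),
) -> pd.DataFrame:
    """Patient-control contrasts of subdivision weighting and spatial layout.

    Per subject and network: (a) the mean of the clipped connectivity values
    within the subdivision, and (b) the gradient score of the normalized
    weights along each voxel axis. Each quantity is compared between groups
    with a pooled-variance independent-samples t test; one row per test.
    """
    groups = np.asarray(groups)
    if len(groups) != len(wmaps_by_subject):
        raise ValueError("one group label per subject required")
    is_pat = groups == "patient"
    is_con = groups == "control"
    if not (is_pat.any() and is_con.any()):
        raise ValueError("need both patients and controls")
    names = wmaps_by_subject[0].network_names
    rows = []
    mw = np.stack([mean_weight(w.connectivity) for w in wmaps_by_subject])
    for k, name in enumerate(names):
        t, df, p = student_t_independent(mw[is_pat, k], mw[is_con, k])
        rows.append({"test": "mean_weight", "network": name, "axis": "", "t": t, "df": df, "p": p})
    for axis in axes:
        scores = np.array(
            [
                [spatial_gradient_score(w.weights[:, k], w.mask, axis) for k in range(len(names))]
                for w in wmaps_by_subject
            ]
        )
        for k, name in enumerate(names):
            t, df, p = student_t_independent(scores[is_pat, k], scores[is_con, k])
            rows.append(
                {"test": "gradient", "network": name, "axis": axis, "t": t, "df": df, "p": p}
            )
    return pd.DataFrame(rows)


def observed_network_ki_table(
    vnc_by_subject: list[VoxelNodeConnectivity],
    assignment: NetworkAssignment,
    ki_by_subject: list[np.ndarray],
    subject_ids: list,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[StriatalWeightMaps]]:
    """Convenience: weight maps and network-Ki table for the observed assignment."""
    from .connectivity import voxel_network_connectivity
    from .pet import network_ki

    active = assignment.active_networks
    wmaps_list, records = [], []
    for vnc, ki in zip(vnc_by_subject, ki_by_subject):
        vn = voxel_network_connectivity(vnc, assignment)
        wm = weight_maps(vn, active, mask=mask)
        wmaps_list.append(wm)
        records.append(network_ki(np.asarray(ki, dtype=float), wm))
    df = pd.DataFrame.from_records(records, index=pd.Index(subject_ids, name="subject"))
    return df[sorted(df.columns)], wmaps_list
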