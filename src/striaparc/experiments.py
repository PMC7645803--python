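"""Simulation studies validating the pipeline's statistical machinery.

Each function runs a self-contained experiment on synthetic cohorts with
planted ground truth and returns summary numbers: community recovery of the
network definition step, the orthogonality contrast between
connectivity-defined and anatomical parcellations, calibration (type-I error)
of the participant-level permutation test, the specificity property of the
cortical-node permutation null (uniform p-values under a purely global
Ki-symptom association, power under a topographic one), Patlak slope
recovery, and calibration of the dependent-correlation comparison.

Problem sizes default to desk scale: node counts, voxel counts and numbers of
timepoints are chosen so each experiment finishes in seconds to a few minutes
on one core while leaving the planted effects comfortably detectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import normalized_mutual_info_score

from .community import NetworkAssignment, louvain
from .connectivity import (
    NodeTimeSeriesMatrix,
    connectivity_matrix,
    voxel_network_connectivity,
    voxel_node_connectivity,
)
from .parcellation import weight_maps
from .permutation import PermutationSpec, node_permutation, participant_permutation
from .pet import network_ki, patlak_slope
from .stats import compare_dependent_correlations, correlation_matrix
from .synth import (
    MARDER_FACTORS,
    SyntheticConfig,
    generate_cortical_series,
    generate_dynamic_tacs,
    generate_ki_maps,
    generate_striatal_voxels,
    generate_symptoms,
    make_reference_tac,
    striatal_loadings,
)


def _planted_assignment(cfg: SyntheticConfig) -> NetworkAssignment:
    sizes = np.full(cfg.n_networks, cfg.n_nodes // cfg.n_networks)
    sizes[: cfg.n_nodes % cfg.n_networks] += 1
    part = np.repeat(np.arange(cfg.n_networks), sizes)
    return NetworkAssignment(
        membership=part, names={k: cfg.network_names[k] for k in range(cfg.n_networks)}
    )


def community_recovery(
    seeds=range(1, 11),
    n_nodes: int = 333,
    n_networks: int = 5,
    n_timepoints: int = 500,
    within: float = 0.6,
    between: float = 0.0,
    n_runs: int = 3,
) -> list[float]:
    """NMI between Louvain partitions and the planted 5-block truth, per seed."""
    out = []
    for seed in seeds:
        cfg = SyntheticConfig(
            seed=int(seed), n_nodes=n_nodes, n_networks=n_networks,
            n_striatal_voxels=10, n_timepoints=n_timepoints,
            within_network_corr=within, between_network_corr=between,
        )
        series, part, _ = generate_cortical_series(cfg)
        conn = connectivity_matrix(
            NodeTimeSeriesMatrix(values=series, node_ids=np.arange(n_nodes))
        )
        asg, _ = louvain(conn, seed=int(seed), n_runs=n_runs)
        out.append(float(normalized_mutual_info_score(part, asg.membership)))
    return out


def orthogonality_contrast(
    seed: int,
    n_subjects: int = 200,
    n_nodes: int = 60,
    n_voxels: int = 90,
    n_timepoints: int = 255,
) -> dict:
    """Connectivity-defined vs anatomical subdivision Ki collinearity.

    The cohort has disjoint one-hot network topographies and independent
    per-network subject Ki factors (no global factor), while the anatomical
    subdivisions interleave across every network slab — the configuration in
    which the two parcellation philosophies differ most sharply.
    """
    cfg = SyntheticConfig(
        seed=seed, n_nodes=n_nodes, n_networks=5, n_striatal_voxels=n_voxels,
        n_timepoints=n_timepoints, striatal_mixing="one-hot",
        ki_subject_sd=0.002, ki_global_sd=0.0,
    )
    root = np.random.default_rng(seed)
    loadings = striatal_loadings(cfg)
    asg = _planted_assignment(cfg)
    ki_sim = generate_ki_maps(
        cfg, loadings, n_subjects=n_subjects, rng=np.random.default_rng(root.integers(2**31))
    )
    net_rows = []
    for s in range(n_subjects):
        rng_s = np.random.default_rng(root.integers(2**31))
        series, _, factors = generate_cortical_series(cfg, rng_s)
        vox, _ = generate_striatal_voxels(cfg, factors, rng_s)
        nts = NodeTimeSeriesMatrix(values=series, node_ids=np.arange(n_nodes))
        vnc = voxel_node_connectivity(vox, nts)
        wm = weight_maps(voxel_network_connectivity(vnc, asg), asg.active_networks)
        net_rows.append(network_ki(ki_sim.ki[s], wm))
    net_table = pd.DataFrame.from_records(net_rows)
    # anatomical subdivisions interleave across the network slabs (mod 3)
    roi_ids = np.arange(n_voxels) % 3
    anat_table = pd.DataFrame(
        {f"roi{r}": ki_sim.ki[:, roi_ids == r].mean(axis=1) for r in range(3)}
    )
    conn_r = correlation_matrix(net_table).to_numpy()
    anat_r = correlation_matrix(anat_table).to_numpy()
    conn_off = conn_r[np.triu_indices_from(conn_r, 1)]
    anat_off = anat_r[np.triu_indices_from(anat_r, 1)]
    return {
        "conn_max_abs_r": float(np.max(np.abs(conn_off))),
        "conn_mean_abs_r": float(np.mean(np.abs(conn_off))),
        "anat_min_r": float(np.min(anat_off)),
        "anat_mean_r": float(np.mean(anat_off)),
        "n": n_subjects,
    }


def participant_calibration(
    seed: int, n_datasets: int = 1000, n_perm: int = 1000, n: int = 29, alpha: float = 0.05
) -> dict:
    """Type-I error of the participant permutation under the null (rho = 0)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_datasets):
        ki = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        sym = pd.DataFrame(rng.standard_normal((n, 5)), columns=MARDER_FACTORS)
        res = participant_permutation(
            ki, sym, PermutationSpec(seed=int(rng.integers(2**31)), n_perm=n_perm)
        )
        cell = res.table[(res.table.subdivision == "a") & (res.table.factor == "negative")]
        rejections += cell["p"].iloc[0] < alpha
    return {"rejection_rate": rejections / n_datasets, "n_datasets": n_datasets, "n": n}


def _node_perm_cfg(seed: int, **kw) -> SyntheticConfig:
    base = dict(
        seed=seed, n_nodes=50, n_networks=5, n_striatal_voxels=60, n_timepoints=150,
        n_patients=29,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def _one_node_perm_dataset(cfg: SyntheticConfig, spec: PermutationSpec, global_effect: bool):
    """p-values for the (DMN, negative) cell under both permutation schemes."""
    root = np.random.default_rng(cfg.seed)
    loadings = striatal_loadings(cfg)
    asg = _planted_assignment(cfg)
    n = cfg.n_patients
    vncs = []
    for _ in range(n):
        rng_s = np.random.default_rng(root.integers(2**31))
        series, _, factors = generate_cortical_series(cfg, rng_s)
        vox, _ = generate_striatal_voxels(cfg, factors, rng_s)
        nts = NodeTimeSeriesMatrix(values=series, node_ids=np.arange(cfg.n_nodes))
        vncs.append(voxel_node_connectivity(vox, nts))
    ki_sim = generate_ki_maps(
        cfg, loadings, n_subjects=n, rng=np.random.default_rng(root.integers(2**31))
    )
    target = ki_sim.ki.mean(axis=1) if global_effect else None
    sym = generate_symptoms(
        cfg, ki_sim.true_network_ki,
        rng=np.random.default_rng(root.integers(2**31)), target=target,
    )
    node_res = node_permutation(vncs, asg, list(ki_sim.ki), sym, spec)
    net_cols = asg.active_networks
    obs_ki = pd.DataFrame(node_res.extra["observed_network_ki"], columns=net_cols)
    part_res = participant_permutation(obs_ki, sym, spec)

    def cell(table, sub):
        row = table[(table.subdivision == sub) & (table.factor == "negative")]
        return float(row["p"].iloc[0])

    return (
        {s: cell(node_res.table, s) for s in net_cols},
        cell(part_res.table, "DMN"),
    )


def node_permutation_specificity(
    seed: int, n_datasets: int = 200, n_perm: int = 500
) -> dict:
    """Uniformity of node-permutation p under a purely global Ki-symptom link.

    Symptoms are generated from the whole-striatum map mean; any network's
    association with them is fully explained by global dopamine synthesis
    capacity, which the node-permutation null retains — so its p-values should
    be uniform while the participant permutation (which destroys the global
    relationship too) keeps rejecting.

    The scenario removes all corticostriatal structure (uniform voxel
    loadings, unstructured node series, no network-specific Ki), because the
    exchangeability that makes permutation p-values exactly uniform requires
    the observed node grouping to be statistically equivalent to a random
    one; any genuine topography makes the observed grouping special and the
    test deviates from uniformity in the tails — which is precisely the
    alternative the power scenario covers.
    """
    rng = np.random.default_rng(seed)
    node_p, part_p = [], []
    for _ in range(n_datasets):
        cfg = _node_perm_cfg(int(rng.integers(2**31)), ki_subject_sd=0.0,
                             ki_global_sd=0.002, symptom_rho=0.5,
                             striatal_mixing="uniform",
                             within_network_corr=0.0, between_network_corr=0.0)
        spec = PermutationSpec(seed=int(rng.integers(2**31)), n_perm=n_perm)
        per_net, p_part = _one_node_perm_dataset(cfg, spec, global_effect=True)
        node_p.append(per_net["DMN"])
        part_p.append(p_part)
    ks = sps.kstest(node_p, "uniform")
    return {
        "node_p": node_p,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "participant_median_p": float(np.median(part_p)),
        "n_datasets": n_datasets,
    }


def node_permutation_power(
    seed: int, n_datasets: int = 100, n_perm: int = 500, rho: float = 0.5
) -> dict:
    """Median node-permutation p per network under a planted DMN-topographic
    Ki-symptom association (no global component)."""
    rng = np.random.default_rng(seed)
    collected: dict[str, list] = {}
    for _ in range(n_datasets):
        cfg = _node_perm_cfg(int(rng.integers(2**31)), ki_subject_sd=0.002,
                             ki_global_sd=0.0, symptom_rho=rho,
                             symptom_network="DMN", symptom_factor="negative")
        spec = PermutationSpec(seed=int(rng.integers(2**31)), n_perm=n_perm)
        per_net, _ = _one_node_perm_dataset(cfg, spec, global_effect=False)
        for name, p in per_net.items():
            collected.setdefault(name, []).append(p)
    return {f"median_p_{name}": float(np.median(ps)) for name, ps in collected.items()} | {
        "n_datasets": n_datasets
    }


def patlak_recovery(seed: int, n_reps: int = 1000, noise_sd: float = 0.5) -> dict:
    """Noise-free and noisy Patlak slope recovery against OLS theory."""
    t = np.linspace(0.5, 90.0, 26)
    ref = make_reference_tac(t)
    errors = []
    for ki_true in (0.005, 0.012, 0.02):
        target = generate_dynamic_tacs(ki_true, ref, t, v_dist=0.4)
        ki_hat, _ = patlak_slope(target, ref, t, t_star=20.0)
        errors.append(abs(ki_hat - ki_true))
    from .pet import cumulative_trapezoid_from_zero

    late = t >= 20.0
    x = cumulative_trapezoid_from_zero(ref, t)[late] / ref[late]
    sd_i = noise_sd / ref[late]
    sxx = np.sum((x - x.mean()) ** 2)
    analytic_sd = float(np.sqrt(np.sum(((x - x.mean()) / sxx) ** 2 * sd_i**2)))
    rng = np.random.default_rng(seed)
    clean = generate_dynamic_tacs(0.012, ref, t, v_dist=0.4)
    slopes = np.array(
        [
            patlak_slope(clean + noise_sd * rng.standard_normal(clean.shape), ref, t, 20.0)[0]
            for _ in range(n_reps)
        ]
    )
    return {
        "max_noise_free_error": float(max(errors)),
        "noisy_sd": float(slopes.std()),
        "analytic_sd": analytic_sd,
        "noisy_bias": float(slopes.mean() - 0.012),
        "n_reps": n_reps,
    }


def dependent_correlation_calibration(
    seed: int, n_sims: int = 5000, n: int = 50, alpha: float = 0.05
) -> dict:
    """Type-I error of the dependent-correlation z under equal-correlation MVN."""
    rho, cross = 0.5, 0.3
    C = np.array(
        [
            [1, rho, cross, cross],
            [rho, 1, cross, cross],
            [cross, cross, 1, rho],
            [cross, cross, rho, 1.0],
        ]
    )
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        X = rng.standard_normal((n, 4)) @ L.T
        R = np.corrcoef(X, rowvar=False)
        res = compare_dependent_correlations(
            R[0, 1], R[2, 3], R[0, 2], R[0, 3], R[1, 2], R[1, 3], n
        )
        rejections += res.p < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims, "n": n}
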