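"""Shared builders for permutation-test cohorts (arrays only, no volumes)."""

import numpy as np

from striaparc.community import NetworkAssignment
from striaparc.connectivity import NodeTimeSeriesMatrix, voxel_node_connectivity
from striaparc.synth import (
    SyntheticConfig,
    generate_cortical_series,
    generate_ki_maps,
    generate_striatal_voxels,
    generate_symptoms,
    striatal_loadings,
)


def planted_assignment(cfg: SyntheticConfig) -> NetworkAssignment:
    sizes = np.full(cfg.n_networks, cfg.n_nodes // cfg.n_networks)
    sizes[: cfg.n_nodes % cfg.n_networks] += 1
    part = np.repeat(np.arange(cfg.n_networks), sizes)
    names = {k: cfg.network_names[k] for k in range(cfg.n_networks)}
    return NetworkAssignment(membership=part, names=names)


def build_cohort(cfg: SyntheticConfig, n_subjects: int | None = None):
    """Per-subject cached voxel-node connectivity, Ki maps and symptoms.

    All subjects are treated as patients (symptom scores exist for everyone).
    """
    root = np.random.default_rng(cfg.seed)
    n = n_subjects if n_subjects is not None else cfg.n_patients
    loadings = striatal_loadings(cfg)
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
    symptoms = generate_symptoms(
        cfg, ki_sim.true_network_ki, rng=np.random.default_rng(root.integers(2**31))
    )
    return vncs, planted_assignment(cfg), ki_sim, symptoms
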