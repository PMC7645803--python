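"""Coupled synthetic fMRI / PET / symptom cohorts with planted ground truth.

The generator emulates the data model of the corticostriatal integration
pipeline at desk scale:

* cortical BOLD as a block-factor model — node i in network k follows
  sqrt(a) * f_k + sqrt(1-a) * eps, giving within-network correlation ``a``
  and, through a shared global factor inside the network factors,
  between-network correlation ``b`` (requires b <= a; guarantees a positive
  semidefinite covariance without any Cholesky factorization, and scales to
  hundreds of nodes trivially);
* striatal voxels as noisy mixtures of the network factors with a spatial
  topography (network slabs along the x axis of the striatal box), either
  one-hot or softly mixed with overlap kappa;
* voxelwise Ki maps as baseline + loading-weighted network effects, with
  subject-level global and network-specific Ki factors plus voxel noise;
* Marder-style symptom factors, with a planted correlation between one
  factor and one network's true Ki;
* dynamic TACs built to obey the reference-region Patlak relation exactly.

Cortex and striatum share one 4-D grid (a single functional run covers both),
with the striatum marked by a separate mask, mirroring real data layout.
All randomness flows from the mandatory config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AtlasLabels, BrainVolume, SubjectTable, TimeSeries4D
from .parcellation import AnatomicalROIs
from .pet import cumulative_trapezoid_from_zero

MARDER_FACTORS = ["positive", "negative", "disorganization", "excitement", "depression/anxiety"]
NETWORK_NAME_POOL = ("DMN", "SMN", "CON", "DAT", "AUD", "VIS")
ANATOMICAL_NAMES = {1: "limbic", 2: "associative", 3: "sensorimotor"}


@dataclass
class SyntheticConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the target study design: 333 cortical nodes in 5
    networks, an 8.5-minute run at TR 2 s (255 timepoints), 29 patients and
    21 controls, a Ki baseline of 1.28e-2 1/min with between-subject network
    SD ~1.5e-3 and a planted DMN-negative symptom correlation of 0.49.
    """

    seed: int
    n_nodes: int = 333
    n_networks: int = 5
    n_striatal_voxels: int = 300
    n_timepoints: int = 255
    n_patients: int = 29
    n_controls: int = 21
    within_network_corr: float = 0.6
    between_network_corr: float = 0.0
    striatal_mixing: str = "one-hot"  # or "soft"
    kappa: float = 0.3
    noise_sd: float = 0.5  # striatal voxel time-series noise (factor units)
    ki_baseline: float = 0.0128  # 1/min
    ki_network_effect: tuple = ()
    ki_subject_sd: float = 0.0015  # between-subject network-specific Ki SD
    ki_global_sd: float = 0.001  # between-subject whole-striatum Ki SD
    ki_noise_sd: float = 0.002  # voxelwise Ki noise
    ki_session_sd: float = 0.0008  # between-session within-subject Ki variability
    symptom_rho: float = 0.49
    symptom_network: str = "DMN"
    symptom_factor: str = "negative"

    def __post_init__(self) -> None:
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if not 0 <= self.within_network_corr < 1:
            raise ValueError("within_network_corr must be in [0, 1)")
        if self.striatal_mixing not in {"one-hot", "soft", "uniform"}:
            raise ValueError("striatal_mixing must be 'one-hot', 'soft' or 'uniform'")
        a, b = self.within_network_corr, self.between_network_corr
        if b != 0 and (b < 0 or a == 0 or b / a > 1):
            raise ValueError(
                "infeasible correlation pair: need 0 <= between <= within (PSD constraint)"
            )
        if not -1 <= self.symptom_rho <= 1:
            raise ValueError("symptom_rho must be in [-1, 1]")

    @property
    def network_names(self) -> list[str]:
        names = list(NETWORK_NAME_POOL[: self.n_networks])
        names += [f"net-{k}" for k in range(len(names), self.n_networks)]
        return names

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def effects(self) -> np.ndarray:
        eff = np.zeros(self.n_networks)
        eff[: len(self.ki_network_effect)] = self.ki_network_effect
        return eff


@dataclass
class KiSim:
    """Simulated PET session: maps plus the latent per-subject factors."""

    ki: np.ndarray  # subjects x voxels
    true_network_ki: np.ndarray  # subjects x networks
    subject_factors: np.ndarray  # subjects x networks
    global_factors: np.ndarray  # subjects


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth."""

    config: SyntheticConfig
    atlas: AtlasLabels
    striatal_mask: np.ndarray
    rois: AnatomicalROIs
    subjects: SubjectTable
    timeseries: dict
    ki_volumes: dict
    ki_vectors: dict  # subject -> in-mask Ki (sorted flat-index order)
    symptoms: pd.DataFrame  # patients only
    truth: dict


def _partition(n_nodes: int, n_networks: int) -> np.ndarray:
    """Planted node partition: near-equal contiguous blocks."""
    sizes = np.full(n_networks, n_nodes // n_networks)
    sizes[: n_nodes % n_networks] += 1
    return np.repeat(np.arange(n_networks), sizes)


def generate_cortical_series(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-factor cortical BOLD: returns (node x time, partition, factors).

    Network factors f_k = sqrt(b/a) g + sqrt(1 - b/a) h_k share a global
    component so that nodes within a block correlate at ``a`` and across
    blocks at ``b`` in expectation.
    """
    rng = rng or np.random.default_rng(config.seed)
    a, b = config.within_network_corr, config.between_network_corr
    part = _partition(config.n_nodes, config.n_networks)
    T = config.n_timepoints
    share = 0.0 if a == 0 else b / a
    g = rng.standard_normal(T)
    h = rng.standard_normal((config.n_networks, T))
    factors = np.sqrt(share) * g + np.sqrt(1 - share) * h
    eps = rng.standard_normal((config.n_nodes, T))
    series = np.sqrt(a) * factors[part] + np.sqrt(1 - a) * eps
    return series, part, factors


def striatal_loadings(config: SyntheticConfig) -> np.ndarray:
    """Planted voxel -> network loading matrix (rows sum to 1).

    Voxels form contiguous per-network blocks in sorted flat-index order,
    which the box-shaped mask lays out as slabs along x (spatial topography).
    Soft mixing moves ``kappa`` of each voxel's loading to the next network;
    the ``uniform`` scheme loads every voxel equally on every network — a
    striatum with no differential corticostriatal topography at all.
    """
    V, K = config.n_striatal_voxels, config.n_networks
    if config.striatal_mixing == "uniform":
        return np.full((V, K), 1.0 / K)
    primary = _partition(V, K)
    load = np.zeros((V, K))
    load[np.arange(V), primary] = 1.0
    if config.striatal_mixing == "soft":
        partner = (primary + 1) % K
        load[np.arange(V), primary] = 1.0 - config.kappa
        load[np.arange(V), partner] += config.kappa
    return load


def generate_striatal_voxels(
    config: SyntheticConfig,
    network_factors: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Striatal voxel series = loadings @ factors + noise; returns (V x T, loadings)."""
    rng = rng or np.random.default_rng(config.seed)
    load = striatal_loadings(config)
    series = load @ network_factors
    if config.noise_sd > 0:
        series = series + config.noise_sd * rng.standard_normal(series.shape)
    return series, load


def generate_ki_maps(
    config: SyntheticConfig,
    loadings: np.ndarray,
    n_subjects: int | None = None,
    rng: np.random.Generator | None = None,
    subject_factors: np.ndarray | None = None,
    global_factors: np.ndarray | None = None,
) -> "KiSim":
    """Per-subject voxelwise Ki and the true network Ki.

    Ki_{s,v} = baseline + global_s + sum_k loading_{v,k} (effect_k + u_{s,k})
    + noise. The true network Ki is the loading-weighted mean of the map.
    Pass ``subject_factors`` and ``global_factors`` to regenerate a second
    PET session for the same subjects with fresh measurement noise.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_subjects = n_subjects if n_subjects is not None else config.n_subjects
    V, K = loadings.shape
    if subject_factors is not None:
        u = np.asarray(subject_factors, dtype=float)
        n_subjects = u.shape[0]
    else:
        u = config.ki_subject_sd * rng.standard_normal((n_subjects, K))
    if global_factors is not None:
        g = np.asarray(global_factors, dtype=float)
    else:
        g = config.ki_global_sd * rng.standard_normal(n_subjects)
    ki = (
        config.ki_baseline
        + g[:, None]
        + (loadings @ (config.effects()[None] + u).T).T
        + config.ki_noise_sd * rng.standard_normal((n_subjects, V))
    )
    col_sums = loadings.sum(axis=0)
    true_net = ki @ loadings / np.where(col_sums > 0, col_sums, 1.0)
    return KiSim(ki=ki, true_network_ki=true_net, subject_factors=u, global_factors=g)


def generate_symptoms(
    config: SyntheticConfig,
    true_network_ki: np.ndarray,
    rng: np.random.Generator | None = None,
    target: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marder five-factor scores with one planted Ki correlation.

    The designated factor is rho * z(target Ki) + sqrt(1-rho^2) * noise
    (Gaussian copula with Gaussian margins); the other four factors are
    independent standard normals. The target defaults to the configured
    network's true Ki; pass ``target`` explicitly to plant, e.g., a purely
    global whole-striatum association.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = true_network_ki.shape[0]
    out = rng.standard_normal((n, len(MARDER_FACTORS)))
    if target is None:
        k = config.network_names.index(config.symptom_network)
        target = true_network_ki[:, k]
    sd = target.std()
    z = (target - target.mean()) / (sd if sd > 0 else 1.0)
    j = MARDER_FACTORS.index(config.symptom_factor)
    rho = config.symptom_rho
    out[:, j] = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    return pd.DataFrame(out, columns=MARDER_FACTORS)


def make_reference_tac(frame_times: np.ndarray, peak_time: float = 10.0) -> np.ndarray:
    """A smooth, strictly positive cerebellar-like reference curve (gamma shape)."""
    t = np.asarray(frame_times, dtype=float)
    return 100.0 * (t / peak_time) * np.exp(1.0 - t / peak_time) + 5.0


def generate_dynamic_tacs(
    ki_true: float,
    ref_tac: np.ndarray,
    frame_times: np.ndarray,
    v_dist: float = 0.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Target TAC obeying the Patlak relation exactly:
    target(T) = Ki * int_0^T ref + V * ref(T), so the late-time Patlak slope
    equals ``ki_true`` by construction (plus optional Gaussian noise)."""
    ref = np.asarray(ref_tac, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    target = ki_true * cumulative_trapezoid_from_zero(ref, t) + v_dist * ref
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        target = target + noise_sd * rng.standard_normal(target.shape)
    return target


# ---------------------------------------------------------------------------
# Grid assembly: cortex sheet at z=0, striatal box above it on one 4-D grid.
# ---------------------------------------------------------------------------


def _grid_layout(config: SyntheticConfig):
    K = config.n_networks
    V = config.n_striatal_voxels
    per = -(-V // K)  # voxels per x-slab (last slab may be partial)
    m = max(2, int(np.ceil(np.sqrt(per))))
    n = -(-per // m)
    gy = max(m, int(np.ceil(np.sqrt(config.n_nodes))))
    gx = max(K, -(-config.n_nodes // gy))
    gz = 1 + n
    return gx, gy, gz, m, n


def build_grid(config: SyntheticConfig):
    """Atlas labels, striatal mask and anatomical ROI labels on one grid.

    Cortical nodes occupy the z=0 plane one voxel each; the striatum is a box
    in the z>=1 slabs with network topography running along x. Anatomical
    subdivisions interleave across the box (voxel position mod 3), so each
    anatomical ROI samples every network slab — the overlap with functional
    topography that drives their Ki collinearity.
    """
    gx, gy, gz, m, n = _grid_layout(config)
    labels = np.zeros((gx, gy, gz), dtype=np.int64)
    for node in range(config.n_nodes):
        labels[node // gy, node % gy, 0] = node + 1
    mask = np.zeros((gx, gy, gz), dtype=bool)
    voxel_net = _partition(config.n_striatal_voxels, config.n_networks)
    slab_sizes = np.bincount(voxel_net, minlength=config.n_networks)
    # place each network's voxels in its x-slab, filling (y, z>=1) in C order
    coords = []
    for k in range(config.n_networks):
        cells = [(k, j, 1 + kk) for j in range(m) for kk in range(n)]
        coords.extend(cells[: slab_sizes[k]])
    coords = np.array(coords)
    mask[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    # sorted flat-index order of the mask must match loading row order
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    if not np.array_equal(order, np.arange(len(coords))):
        raise AssertionError("mask voxel order out of sync with loadings")
    roi_labels = np.zeros_like(labels)
    roi_labels[mask] = (np.arange(config.n_striatal_voxels) % 3) + 1
    part = _partition(config.n_nodes, config.n_networks)
    names = config.network_names
    table = pd.DataFrame(
        {
            "label": np.arange(1, config.n_nodes + 1),
            "name": [f"node-{i:03d}" for i in range(1, config.n_nodes + 1)],
            "network": [names[k] for k in part],
        }
    ).set_index("label")
    atlas = AtlasLabels(labels=labels, table=table, affine=np.eye(4))
    rois = AnatomicalROIs(labels=roi_labels, names=dict(ANATOMICAL_NAMES))
    return atlas, mask, rois


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full coupled cohort: per-subject 4-D runs, Ki volumes, symptoms, truth."""
    root = np.random.default_rng(config.seed)
    atlas, mask, rois = build_grid(config)
    loadings = striatal_loadings(config)
    ki_sim = generate_ki_maps(config, loadings, rng=np.random.default_rng(root.integers(2**31)))
    ki, true_net = ki_sim.ki, ki_sim.true_network_ki
    part = _partition(config.n_nodes, config.n_networks)
    sids = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    timeseries, ki_volumes, ki_vectors = {}, {}, {}
    gx, gy, gz, _, _ = _grid_layout(config)
    affine = np.eye(4)
    for s, sid in enumerate(sids):
        rng_s = np.random.default_rng(root.integers(2**31))
        cortex, _, factors = generate_cortical_series(config, rng_s)
        vox, _ = generate_striatal_voxels(config, factors, rng_s)
        vol = np.zeros((gx, gy, gz, config.n_timepoints))
        node_idx = np.arange(config.n_nodes)
        vol[node_idx // gy, node_idx % gy, 0, :] = cortex
        vol[mask] = vox
        timeseries[sid] = TimeSeries4D(data=vol, affine=affine, tr_seconds=2.0)
        ki_vol = np.full((gx, gy, gz), np.nan)
        ki_vol[mask] = ki[s]
        ki_volumes[sid] = BrainVolume(data=ki_vol, affine=affine, mask=mask)
        ki_vectors[sid] = ki[s]
    symptoms = generate_symptoms(
        config, true_net[: config.n_patients], rng=np.random.default_rng(root.integers(2**31))
    )
    symptoms.index = pd.Index(sids[: config.n_patients], name="subject")
    subjects = SubjectTable(
        rows=pd.DataFrame({"group": groups}, index=pd.Index(sids, name="subject"))
    )
    truth = {
        "partition": part,
        "loadings": loadings,
        "true_network_ki": true_net,
        "subject_factors": ki_sim.subject_factors,
        "global_factors": ki_sim.global_factors,
        "network_names": config.network_names,
    }
    return SyntheticDataset(
        config=config,
        atlas=atlas,
        striatal_mask=mask,
        rois=rois,
        subjects=subjects,
        timeseries=timeseries,
        ki_volumes=ki_volumes,
        ki_vectors=ki_vectors,
        symptoms=symptoms,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Persist a cohort as a BIDS-flavoured directory of NIfTI + TSV + JSON."""
    from .io import write_timeseries, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import nibabel as nib

    nib.Nifti1Image(ds.atlas.labels.astype(np.int16), ds.atlas.affine).to_filename(
        str(out / "atlas.nii.gz")
    )
    nib.Nifti1Image(ds.striatal_mask.astype(np.uint8), ds.atlas.affine).to_filename(
        str(out / "striatal_mask.nii.gz")
    )
    nib.Nifti1Image(ds.rois.labels.astype(np.int16), ds.atlas.affine).to_filename(
        str(out / "anatomical_rois.nii.gz")
    )
    ds.atlas.table.reset_index().to_csv(out / "nodes.tsv", sep="\t", index=False)
    for sid in ds.subjects.subject_ids:
        write_timeseries(ds.timeseries[sid], out / f"{sid}_bold.nii.gz")
        vol = ds.ki_volumes[sid]
        data = np.where(ds.striatal_mask, vol.data, 0.0)
        write_volume(BrainVolume(data=data, affine=vol.affine), out / f"{sid}_ki.nii.gz")
    ds.symptoms.reset_index().to_csv(out / "symptoms.tsv", sep="\t", index=False)
    ds.subjects.rows.reset_index().to_csv(out / "subjects.tsv", sep="\t", index=False)
    truth = {
        "partition": ds.truth["partition"].tolist(),
        "network_names": ds.truth["network_names"],
        "true_network_ki": ds.truth["true_network_ki"].tolist(),
        "seed": ds.config.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
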