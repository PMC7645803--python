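import numpy as np
import pandas as pd
import pytest

from striaparc.community import NetworkAssignment
from striaparc.connectivity import voxel_network_connectivity
from striaparc.parcellation import StriatalWeightMaps, weight_maps
from striaparc.permutation import (
    PermutationSpec,
    _null_network_ki_chunk,
    correlation_difference_test,
    group_topography_tests,
    node_permutation,
    participant_permutation,
)
from striaparc.pet import network_ki
from striaparc.synth import SyntheticConfig

from _cohorts import build_cohort


def _tables(rng, n=29, rho=0.0, d=5, f=5):
    """Ki and symptom tables with an optional planted correlation in cell (0, 0)."""
    ki = rng.standard_normal((n, d))
    sym = rng.standard_normal((n, f))
    if rho:
        sym[:, 0] = rho * ki[:, 0] + np.sqrt(1 - rho**2) * sym[:, 0]
    ki_df = pd.DataFrame(ki, columns=[f"net{j}" for j in range(d)])
    sym_df = pd.DataFrame(sym, columns=[f"fac{j}" for j in range(f)])
    return ki_df, sym_df


class TestParticipantPermutation:
    def test_strong_effect_reaches_minimum_p(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ki, sym = _tables(rng, rho=0.9)
            res = participant_permutation(ki, sym, PermutationSpec(seed=seed, n_perm=1000))
            cell = res.table.query("subdivision == 'net0' and factor == 'fac0'")
            assert cell["p"].iloc[0] == pytest.approx(1 / 1001)

    def test_add_one_formula_edge(self, rng):
        ki, sym = _tables(rng)
        res = participant_permutation(ki, sym, PermutationSpec(seed=0, n_perm=1))
        assert set(np.round(res.table["p"], 10)) <= {0.5, 1.0}

    def test_p_never_zero(self, rng):
        ki, sym = _tables(rng, rho=0.99)
        res = participant_permutation(ki, sym, PermutationSpec(seed=1, n_perm=200))
        assert (res.table["p"] >= 1 / 201).all()

    def test_joint_permutation_shared_across_columns(self, rng):
        """One subject permutation per iteration is reused for every
        (subdivision, factor) cell, preserving inter-subdivision structure."""
        ki, sym = _tables(rng, n=15)
        spec = PermutationSpec(seed=42, n_perm=3)
        res = participant_permutation(ki, sym, spec)
        n = len(ki)
        perms = np.argsort(np.random.default_rng(42).random((3, n)), axis=1)
        X = (ki - ki.mean()) / ki.std(ddof=0)
        Y = (sym - sym.mean()) / sym.std(ddof=0)
        for p_i in range(3):
            expected = X.to_numpy()[perms[p_i]].T @ Y.to_numpy() / n
            np.testing.assert_allclose(res.null_r[p_i], expected, atol=1e-12)
            # permuting rows jointly leaves the Ki correlation matrix intact
            np.testing.assert_allclose(
                np.corrcoef(ki.to_numpy()[perms[p_i]].T), np.corrcoef(ki.to_numpy().T),
                atol=1e-12,
            )

    def test_too_few_subjects_rejected(self, rng):
        ki, sym = _tables(rng, n=4)
        with pytest.raises(ValueError, match="5 subjects"):
            participant_permutation(ki, sym, PermutationSpec(seed=0, n_perm=10))

    def test_fdr_family_is_all_cells(self, rng):
        ki, sym = _tables(rng)
        res = participant_permutation(ki, sym, PermutationSpec(seed=0, n_perm=100))
        assert len(res.table) == 25
        assert (res.table["p_fdr"] >= res.table["p"] - 1e-12).all()


class TestCorrelationDifference:
    def test_duplicated_subdivision_gives_p_one(self, rng):
        ki, sym = _tables(rng, n=20)
        ki["net1"] = ki["net0"]
        spec = PermutationSpec(seed=0, n_perm=200)
        out = correlation_difference_test(ki, sym, ("net0", "net1"), "fac0", spec)
        assert out["observed_diff"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_pair_order_symmetric(self, rng):
        ki, sym = _tables(rng, n=25, rho=0.5)
        spec = PermutationSpec(seed=3, n_perm=300)
        res = participant_permutation(ki, sym, spec)
        a = correlation_difference_test(ki, sym, ("net0", "net2"), "fac0", spec, results=res)
        b = correlation_difference_test(ki, sym, ("net2", "net0"), "fac0", spec, results=res)
        assert a["p"] == b["p"]

    def test_power_with_orthogonal_subdivisions(self):
        hits = 0
        n_sim = 60
        for seed in range(n_sim):
            rng = np.random.default_rng(1000 + seed)
            n = 100
            ki = rng.standard_normal((n, 2))
            sym = rng.standard_normal((n, 1))
            sym[:, 0] = 0.6 * ki[:, 0] + np.sqrt(1 - 0.36) * sym[:, 0]
            ki_df = pd.DataFrame(ki, columns=["a", "b"])
            sym_df = pd.DataFrame(sym, columns=["f"])
            out = correlation_difference_test(
                ki_df, sym_df, ("a", "b"), "f", PermutationSpec(seed=seed, n_perm=500)
            )
            hits += out["p"] < 0.05
        assert hits / n_sim >= 0.9


def _small_cfg(seed, **kw):
    base = dict(
        seed=seed, n_nodes=30, n_networks=5, n_striatal_voxels=40, n_timepoints=150,
        n_patients=10,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestNodePermutation:
    def test_identity_permutation_reproduces_observed(self):
        cfg = _small_cfg(7)
        vncs, asg, ki_sim, sym = build_cohort(cfg)
        res = node_permutation(
            vncs, asg, list(ki_sim.ki), sym, PermutationSpec(seed=0, n_perm=5)
        )
        # recompute observed network Ki through the public single-subject path
        for s, vnc in enumerate(vncs):
            vn = voxel_network_connectivity(vnc, asg)
            wm = weight_maps(vn, asg.active_networks)
            expected = network_ki(ki_sim.ki[s], wm)
            got = dict(zip(asg.active_networks, res.extra["observed_network_ki"][s]))
            for name in asg.active_networks:
                assert got[name] == pytest.approx(expected[name], abs=1e-12)

    def test_weight_mass_conservation_across_relabellings(self):
        """Per-voxel-normalized weights make the weight-sum-weighted mean over
        all networks equal to the plain striatal mean, for any node grouping."""
        cfg = _small_cfg(8)
        vncs, asg, ki_sim, _ = build_cohort(cfg, n_subjects=3)
        rng = np.random.default_rng(0)
        for s, vnc in enumerate(vncs):
            for _ in range(3):
                perm = rng.permutation(cfg.n_nodes)
                shuffled = NetworkAssignment(
                    membership=asg.membership[perm], names=asg.names
                )
                vn = voxel_network_connectivity(vnc, shuffled)
                wm = weight_maps(vn, shuffled.active_networks)
                alive = wm.weights.sum(axis=1) > 0
                assert alive.all()
                kis = network_ki(ki_sim.ki[s], wm)
                wsums = wm.weights.sum(axis=0)
                pooled = sum(
                    kis[name] * wsums[j] for j, name in enumerate(wm.network_names)
                ) / wsums.sum()
                assert pooled == pytest.approx(ki_sim.ki[s].mean(), abs=1e-10)

    def test_chunk_helper_identity_matches_observed(self):
        cfg = _small_cfg(9)
        vncs, asg, ki_sim, sym = build_cohort(cfg, n_subjects=4)
        res = node_permutation(
            vncs, asg, list(ki_sim.ki[:4]), sym.iloc[:4], PermutationSpec(seed=0, n_perm=2)
        )
        pool = np.concatenate([asg.node_indices_of(n) for n in asg.active_networks])
        pool_sizes = np.array([len(asg.node_indices_of(n)) for n in asg.active_networks])
        z_stack = np.stack([v.z_vn[:, pool] for v in vncs])
        obs = _null_network_ki_chunk(
            z_stack, ki_sim.ki[:4], np.arange(pool.size)[None], pool_sizes
        )[0]
        np.testing.assert_allclose(obs, res.extra["observed_network_ki"], atol=1e-12)

    def test_determinism(self):
        cfg = _small_cfg(10)
        vncs, asg, ki_sim, sym = build_cohort(cfg, n_subjects=6)
        spec = PermutationSpec(seed=5, n_perm=50)
        r1 = node_permutation(vncs, asg, list(ki_sim.ki[:6]), sym.iloc[:6], spec)
        r2 = node_permutation(vncs, asg, list(ki_sim.ki[:6]), sym.iloc[:6], spec)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_missing_cache_rejected(self, rng):
        sym = pd.DataFrame(rng.standard_normal((3, 2)), columns=["a", "b"])
        asg = NetworkAssignment(membership=np.array([0, 1]), names={0: "x", 1: "y"})
        with pytest.raises(ValueError, match="per subject"):
            node_permutation([], asg, [], sym, PermutationSpec(seed=0, n_perm=5))


class TestGroupTopography:
    def _wmaps(self, rng, shift=False, mask_shape=(10, 4, 3), n_nets=5):
        mask = np.ones(mask_shape, dtype=bool)
        V = mask.sum()
        xcoord = np.argwhere(mask)[:, 0]
        raw = rng.random((V, n_nets)) + 0.3
        if shift:
            # rearrange whole voxel rows so DMN connectivity increases along x:
            # a pure spatial shift that leaves every mass total untouched
            new = np.empty_like(raw)
            # jitter randomizes placement within each x-slab so no y/z
            # gradient is created as a side effect
            new[np.argsort(xcoord + rng.random(V))] = raw[np.argsort(raw[:, 3])]
            raw = new
        w = raw / raw.sum(axis=1, keepdims=True)
        return StriatalWeightMaps(
            weights=w, network_names=["AUD", "CON", "DAT", "DMN", "SMN"], mask=mask,
            connectivity=raw,
        )

    def test_bookkeeping_counts(self, rng):
        wmaps = [self._wmaps(rng) for _ in range(8)]
        groups = ["patient"] * 4 + ["control"] * 4
        out = group_topography_tests(wmaps, groups)
        assert (out["test"] == "gradient").sum() == 15
        assert (out["test"] == "mean_weight").sum() == 5

    def test_null_rejection_rate_near_alpha(self):
        n_rej = n_tot = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            wmaps = [self._wmaps(rng) for _ in range(16)]
            out = group_topography_tests(wmaps, ["patient"] * 8 + ["control"] * 8)
            n_rej += (out["p"] < 0.05).sum()
            n_tot += len(out)
        assert 0.01 <= n_rej / n_tot <= 0.09

    def test_planted_lateral_shift_detected_on_x_only(self):
        hits_x, hits_yz = 0, 0
        n_sim = 25
        for seed in range(n_sim):
            rng = np.random.default_rng(500 + seed)
            wmaps = [self._wmaps(rng, shift=True) for _ in range(10)]
            wmaps += [self._wmaps(rng, shift=False) for _ in range(10)]
            out = group_topography_tests(wmaps, ["patient"] * 10 + ["control"] * 10)
            dmn = out[(out["network"] == "DMN") & (out["test"] == "gradient")]
            hits_x += dmn.loc[dmn["axis"] == "x", "p"].iloc[0] < 0.05
            hits_yz += (dmn.loc[dmn["axis"] != "x", "p"] < 0.05).any()
        assert hits_x / n_sim >= 0.9
        assert hits_yz / n_sim <= 0.3

    def test_single_group_rejected(self, rng):
        wmaps = [self._wmaps(rng) for _ in range(4)]
        with pytest.raises(ValueError, match="both"):
            group_topography_tests(wmaps, ["patient"] * 4)
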