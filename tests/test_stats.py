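"""Paired t-tests, the voxel-wise GLM, BH-FDR, and cluster extent filtering."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alffpipe.stats import (
    build_design,
    cluster_extent_filter,
    fdr_threshold,
    fit_voxelwise_glm,
    paired_ttest_maps,
    threshold_stat_map,
)

import _oracles

MASK = np.ones((4, 4, 3), dtype=bool)


def _vols(rows):
    """List of volumes from a (n, V) matrix."""
    return [r.reshape(MASK.shape) for r in rows]


class TestPairedTTest:
    def test_identical_stacks_give_zero(self, rng):
        a = _vols(rng.standard_normal((5, MASK.size)))
        smap = paired_ttest_maps(a, [v.copy() for v in a], MASK)
        assert np.all(smap.stat == 0.0)
        assert np.all(smap.p == 1.0)

    def test_closed_form_example(self):
        # differences {1, 1, 1, 2}: mean 1.25, sd 0.5 -> t = 5, df = 3
        diffs = np.array([1.0, 1.0, 1.0, 2.0])
        a = _vols(np.zeros((4, MASK.size)) + diffs[:, None])
        b = _vols(np.zeros((4, MASK.size)))
        smap = paired_ttest_maps(a, b, MASK)
        assert smap.stat[0, 0, 0] == pytest.approx(5.0)
        assert smap.df == (3,)
        assert smap.p[0, 0, 0] == pytest.approx(2 * sps.t.sf(5.0, 3), rel=1e-9)

    def test_antisymmetry(self, rng):
        a = _vols(rng.standard_normal((6, MASK.size)))
        b = _vols(rng.standard_normal((6, MASK.size)))
        np.testing.assert_allclose(
            paired_ttest_maps(a, b, MASK).stat,
            -paired_ttest_maps(b, a, MASK).stat,
            atol=1e-12,
        )

    def test_too_few_subjects(self, rng):
        a = _vols(rng.standard_normal((2, MASK.size)))
        with pytest.raises(ValueError, match="3 subjects"):
            paired_ttest_maps(a, a, MASK)


def _table(n_per_group=20, sites=("A", "B"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for site in sites:
        for dx in ("HC", "SZ"):
            for i in range(n_per_group):
                rows.append(
                    {
                        "subject_id": f"{site}{dx}{i}",
                        "site_id": site,
                        "diagnosis": dx,
                        "age_years": float(rng.uniform(20, 60)),
                    }
                )
    return pd.DataFrame(rows)


class TestDesign:
    def test_columns_and_baseline(self):
        design = build_design(_table(sites=("A", "B", "C")))
        assert design.columns == [
            "intercept", "site_A", "site_B", "diagnosis", "age", "age_x_diagnosis",
        ]
        assert design.site_columns == ["site_A", "site_B"]  # C is the baseline

    def test_age_mean_centred(self):
        design = build_design(_table())
        j = design.columns.index("age")
        assert abs(design.matrix[:, j].mean()) < 1e-10

    def test_single_site_drops_site_factor(self):
        design = build_design(_table(sites=("A",)))
        assert design.site_columns == []

    def test_needs_two_per_group(self):
        table = _table(n_per_group=3, sites=("A",))
        table = table[table["diagnosis"] == "HC"].reset_index(drop=True)
        with pytest.raises(ValueError, match="2 subjects per diagnosis"):
            build_design(table)


class TestVoxelwiseGLM:
    def test_recovers_diagnosis_effect(self):
        table = _table(n_per_group=20, sites=("A",))
        rng = np.random.default_rng(1)
        dx = (table["diagnosis"] == "SZ").to_numpy(float)
        stack = [
            np.full(MASK.shape, 2.0 * d) + 0.1 * rng.standard_normal(MASK.shape)
            for d in dx
        ]
        design = build_design(table)
        glm = fit_voxelwise_glm(stack, design, MASK)
        t = glm["dx_t_SZgtHC"].stat
        assert np.all(t > 10)
        beta = np.linalg.pinv(design.matrix) @ np.stack([s[MASK] for s in stack])
        j = design.columns.index("diagnosis")
        assert np.all((beta[j] > 1.9) & (beta[j] < 2.1))

    def test_null_t_follows_reference_distribution(self):
        table = _table(n_per_group=15, sites=("A", "B"), seed=2)
        rng = np.random.default_rng(3)
        stack = [rng.standard_normal(MASK.shape) for _ in range(len(table))]
        design = build_design(table)
        smap = fit_voxelwise_glm(stack, design, MASK)["dx_t_SZgtHC"]
        t = smap.stat[MASK]
        ks = sps.kstest(t, "t", args=(smap.df[0],))
        assert ks.pvalue > 0.01

    def test_site_offsets_orthogonal_to_balanced_diagnosis(self):
        table = _table(n_per_group=10, sites=("A", "B"))
        offset = {"A": 1.0, "B": 0.0}
        stack = [
            np.full(MASK.shape, offset[row.site_id]) for row in table.itertuples()
        ]
        design = build_design(table)
        glm = fit_voxelwise_glm(stack, design, MASK)
        assert np.all(np.abs(glm["dx_t_SZgtHC"].stat) < 1e-6)
        assert np.all(glm["site_F"].p[MASK] < 1e-10)

    def test_site_f_invariant_to_baseline_choice(self):
        table = _table(n_per_group=8, sites=("A", "B", "C"), seed=4)
        rng = np.random.default_rng(5)
        stack = [
            rng.standard_normal(MASK.shape)
            + {"A": 0.5, "B": -0.2, "C": 0.0}[row.site_id]
            for row in table.itertuples()
        ]
        f_maps = [
            fit_voxelwise_glm(stack, build_design(table, baseline_site=b), MASK)[
                "site_F"
            ].stat
            for b in ("A", "C")
        ]
        np.testing.assert_allclose(f_maps[0], f_maps[1], rtol=1e-8)

    def test_one_sided_contrasts_are_mirrors(self, rng):
        table = _table(n_per_group=10, sites=("A",))
        stack = [rng.standard_normal(MASK.shape) for _ in range(len(table))]
        glm = fit_voxelwise_glm(stack, build_design(table), MASK)
        np.testing.assert_allclose(
            glm["dx_t_SZgtHC"].stat, -glm["dx_t_HCgtSZ"].stat, atol=1e-12
        )
        np.testing.assert_allclose(
            glm["dx_t_SZgtHC"].p + glm["dx_t_HCgtSZ"].p, 1.0, atol=1e-9
        )


class TestFDR:
    def test_all_ones_empty(self):
        p = np.ones(MASK.shape)
        assert fdr_threshold(p, MASK).sum() == 0

    def test_hand_executed_example(self):
        # p = {0.01, 0.02, 0.2, 0.8}, m=4, q=0.05 -> first two rejected
        mask = np.zeros((4, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        p = np.ones((4, 1, 1))
        p[:, 0, 0] = [0.01, 0.02, 0.2, 0.8]
        got = fdr_threshold(p, mask)
        np.testing.assert_array_equal(got[:, 0, 0], [True, True, False, False])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            m = rng.integers(1, 60)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            mask = np.ones((m, 1, 1), dtype=bool)
            got = fdr_threshold(p.reshape(-1, 1, 1), mask, q=0.05)[:, 0, 0]
            np.testing.assert_array_equal(got, _oracles.benjamini_hochberg(p, 0.05))

    def test_monotone_in_q(self, rng):
        p = rng.random(MASK.shape)
        small = fdr_threshold(p, MASK, q=0.01)
        large = fdr_threshold(p, MASK, q=0.05)
        assert np.all(large[small])


class TestClusterExtent:
    def test_size_threshold(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0, 0, :9] = True  # 9-voxel line
        mask[5, 5:7, 0:6] = True  # 12-voxel slab (kept at k=10... 2x6=12)
        out = cluster_extent_filter(mask, k_min=10)
        assert not out[0, 0, 0]
        assert out[5, 5, 0]
        assert out.sum() == 12

    def test_empty_in_empty_out(self):
        assert cluster_extent_filter(np.zeros((5, 5, 5), dtype=bool)).sum() == 0

    def test_exactly_k_voxels_survive(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, :5] = True
        mask[1, 0, :5] = True  # 10 voxels, 18-connected
        assert cluster_extent_filter(mask, k_min=10).sum() == 10

    def test_diagonal_connectivity_rules(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 1] = True  # edge-diagonal neighbours
        comps18 = _oracles.flood_fill_components(mask, 18)
        comps6 = _oracles.flood_fill_components(mask, 6)
        assert len(comps18) == 1 and len(comps6) == 2
        # the filter agrees: at 18-connectivity the pair forms one 2-voxel cluster
        assert cluster_extent_filter(mask, k_min=2, connectivity=18).sum() == 2
        assert cluster_extent_filter(mask, k_min=2, connectivity=6).sum() == 0

    def test_components_match_flood_fill_oracle(self, rng):
        mask = rng.random((8, 8, 8)) > 0.7
        for conn in (6, 18, 26):
            comps = _oracles.flood_fill_components(mask, conn)
            for k_min in (1, 3, 5):
                expected = np.zeros_like(mask)
                for comp in comps:
                    if len(comp) >= k_min:
                        for v in comp:
                            expected[v] = True
                got = cluster_extent_filter(mask, k_min=k_min, connectivity=conn)
                np.testing.assert_array_equal(got, expected)


def test_threshold_stat_map_combines_fdr_and_extent(rng):
    table = _table(n_per_group=15, sites=("A",))
    dx = (table["diagnosis"] == "SZ").to_numpy(float)
    effect = np.zeros(MASK.shape)
    effect[:3, :4, :1] = 1.5  # 12-voxel slab
    stack = [effect * d + 0.5 * rng.standard_normal(MASK.shape) for d in dx]
    smap = fit_voxelwise_glm(stack, build_design(table), MASK)["dx_t_SZgtHC"]
    out = threshold_stat_map(smap, q=0.05, k_min=10)
    assert out.sig_mask is not None
    assert out.sig_mask.sum() >= 10
    assert out.sig_mask[:3, :4, :1].sum() >= 10
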