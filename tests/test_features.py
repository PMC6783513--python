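"""Connectivity features: FCS, Kendall's W / ReHo, large-scale FC, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rsmvpa as rm
from rsmvpa.volumes import BOLDSeries


def _bold(data):
    return BOLDSeries(np.asarray(data, dtype=float))


def brute_force_fcs(x, thr):
    """O(V^2) double loop over all voxel pairs."""
    v = x.shape[0]
    out = np.zeros(v)
    for i in range(v):
        for j in range(v):
            if i == j:
                continue
            r = np.corrcoef(x[i], x[j])[0, 1]
            if r > thr:
                out[i] += r
    return out


def brute_force_kendalls_w(block):
    """Independent evaluation of the rank-sum formula with hand-built
    midranks (no scipy)."""
    k, n = block.shape
    ranks = np.empty((k, n))
    for i in range(k):
        order = np.argsort(block[i], kind="stable")
        r = np.empty(n)
        pos = 0
        while pos < n:
            tied = [order[pos]]
            while (pos + len(tied) < n
                   and block[i, order[pos + len(tied)]] == block[i, tied[0]]):
                tied.append(order[pos + len(tied)])
            mid = pos + (len(tied) + 1) / 2.0
            for t in tied:
                r[t] = mid
            pos += len(tied)
        ranks[i] = r
    r_t = ranks.sum(axis=0)
    s = ((r_t - r_t.mean()) ** 2).sum()
    return 12.0 * s / (k**2 * (n**3 - n))


class TestGmMask:
    def test_strict_inequality_at_threshold(self):
        prob = np.array([0.19, 0.20, 0.21]).reshape(3, 1, 1)
        np.testing.assert_array_equal(
            rm.make_gm_mask(prob, 0.2).ravel(), [False, False, True]
        )

    def test_random_map_matches_brute_count(self, rng):
        prob = rng.random((6, 6, 6))
        assert rm.make_gm_mask(prob, 0.2).sum() == int((prob > 0.2).sum())

    def test_non_probability_values_rejected(self):
        with pytest.raises(ValueError):
            rm.make_gm_mask(np.full((2, 2, 2), 1.5))


class TestFCS:
    def test_perfect_correlation_block(self, rng):
        """4 identical-series voxels give FCS ~= 3; independent noise ~0."""
        n_t = 200
        shared = rng.standard_normal(n_t)
        data = np.empty((24, n_t))
        data[:4] = shared
        data[4:] = rng.standard_normal((20, n_t))
        vol = data.reshape(24, 1, 1, n_t)
        mask = np.ones((24, 1, 1), dtype=bool)
        fcs = rm.voxelwise_fcs(_bold(vol), mask, 0.25)
        np.testing.assert_allclose(fcs.ravel()[:4], 3.0, atol=0.01)
        assert np.abs(fcs.ravel()[4:]).max() < 1.0

    def test_threshold_near_one_zeroes_everything(self, rng):
        vol = rng.standard_normal((10, 1, 1, 50))
        mask = np.ones((10, 1, 1), dtype=bool)
        fcs = rm.voxelwise_fcs(_bold(vol), mask, 1.0 - 1e-9)
        assert not fcs.any()

    @pytest.mark.parametrize("chunk", [7, 1024])
    def test_matches_brute_force_double_loop(self, rng, chunk):
        v, n_t = 50, 40
        vol = rng.standard_normal((v, 1, 1, n_t))
        mask = np.ones((v, 1, 1), dtype=bool)
        fcs = rm.voxelwise_fcs(_bold(vol), mask, 0.25, chunk_size=chunk)
        np.testing.assert_allclose(
            fcs.ravel(), brute_force_fcs(vol[:, 0, 0], 0.25), atol=1e-10
        )

    def test_zero_variance_voxel_reported(self, rng):
        vol = rng.standard_normal((5, 1, 1, 30))
        vol[2] = 4.2
        mask = np.ones((5, 1, 1), dtype=bool)
        with pytest.raises(ValueError, match=r"\[2\]"):
            rm.voxelwise_fcs(_bold(vol), mask)

    def test_affine_rescaling_invariance(self, rng):
        """Correlation-based: per-voxel a*x+b rescaling leaves FCS unchanged."""
        v = 20
        vol = rng.standard_normal((v, 1, 1, 60))
        mask = np.ones((v, 1, 1), dtype=bool)
        a = rng.uniform(0.5, 3.0, v)[:, None]
        b = rng.uniform(-5, 5, v)[:, None]
        scaled = (a * vol[:, 0, 0] + b).reshape(v, 1, 1, 60)
        np.testing.assert_allclose(
            rm.voxelwise_fcs(_bold(vol), mask), rm.voxelwise_fcs(_bold(scaled), mask),
            atol=1e-10,
        )


class TestZscoreAndFisher:
    def test_hand_computed_three_values(self):
        vol = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        mask = np.ones((3, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            rm.zscore_map(vol, mask).ravel(), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_idempotent_and_affine_invariant(self, rng):
        vol = rng.standard_normal((4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        z = rm.zscore_map(vol, mask)
        np.testing.assert_allclose(rm.zscore_map(z, mask), z, atol=1e-10)
        np.testing.assert_allclose(rm.zscore_map(2.5 * vol - 7, mask), z, atol=1e-10)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            rm.zscore_map(np.ones((2, 2, 2)), np.ones((2, 2, 2), dtype=bool))

    def test_fisher_values_and_oddness(self):
        assert rm.fisher_z(0.0) == 0.0
        assert rm.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        for r in (0.1, 0.33, 0.9):
            assert rm.fisher_z(-r) == pytest.approx(-rm.fisher_z(r))

    def test_fisher_clamps_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = rm.fisher_z(1.0)
        assert np.isfinite(z)


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        vol = rng.standard_normal((5, 5, 5))
        np.testing.assert_array_equal(rm.gaussian_smooth(vol, 0.0, 3.0), vol)

    def test_delta_profile_fwhm(self):
        """The impulse response's measured full width at half maximum matches
        the requested kernel width within half a voxel."""
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        fwhm_mm, vox = 9.0, 3.0
        sm = rm.gaussian_smooth(vol, fwhm_mm, vox)
        profile = sm[:, 20, 20]
        half = profile.max() / 2.0
        above = np.flatnonzero(profile >= half)
        width_vox = above[-1] - above[0] + 1
        assert abs(width_vox * vox - fwhm_mm) <= vox / 2.0 + vox  # discrete sampling
        # sub-voxel check via Gaussian fit of log-profile
        sel = profile > profile.max() * 1e-3
        x = (np.flatnonzero(sel) - 20.0) * vox
        coef = np.polyfit(x, np.log(profile[sel]), 2)
        sigma_mm = np.sqrt(-1.0 / (2.0 * coef[0]))
        assert sigma_mm * np.sqrt(8 * np.log(2)) == pytest.approx(fwhm_mm, rel=0.05)

    def test_constant_image_unchanged_full_mask(self):
        vol = np.full((8, 8, 8), 3.3)
        out = rm.gaussian_smooth(vol, 6.0, 3.0, np.ones_like(vol, dtype=bool))
        np.testing.assert_allclose(out, vol, atol=1e-10)

    def test_mask_renormalization_preserves_constant_at_edges(self):
        vol = np.full((8, 8, 8), 2.0)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        out = rm.gaussian_smooth(vol, 6.0, 3.0, mask, renormalize=True)
        np.testing.assert_allclose(out[mask], 2.0, atol=1e-10)
        assert not out[~mask].any()


class TestKendallsW:
    def test_identical_monotone_series_give_one(self):
        block = np.tile(np.array([1.0, 3.0, 4.0, 7.0, 9.0]), (4, 1))
        assert rm.kendalls_w(block) == pytest.approx(1.0)

    def test_exact_rank_reversal_gives_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert rm.kendalls_w(np.stack([a, a[::-1]])) == pytest.approx(0.0)

    def test_matches_independent_rank_formula(self, rng):
        for _ in range(20):
            block = rng.integers(0, 6, size=(3, 5)).astype(float)
            if np.any(np.ptp(block, axis=1) == 0):
                continue
            assert rm.kendalls_w(block) == pytest.approx(
                brute_force_kendalls_w(block), abs=1e-12
            )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform_of_one_series(self, seed):
        """Rank-based: strictly monotone transforms of any single series
        leave W unchanged."""
        r = np.random.default_rng(seed)
        block = r.standard_normal((4, 8))
        w0 = rm.kendalls_w(block)
        block2 = block.copy()
        block2[seed % 4] = np.exp(2.0 * block2[seed % 4]) + 1.0
        assert rm.kendalls_w(block2) == pytest.approx(w0, abs=1e-12)


class TestReHo:
    def test_identical_monotone_volume_is_one_then_normalized_one(self):
        n_t = 8
        base = np.arange(n_t, dtype=float)
        vol = np.tile(base, (4, 4, 4, 1))
        mask = np.ones((4, 4, 4), dtype=bool)
        raw = rm.reho_map(_bold(vol), mask)
        np.testing.assert_allclose(raw[mask], 1.0, atol=1e-12)
        from rsmvpa.features import normalize_reho
        np.testing.assert_allclose(normalize_reho(raw, mask)[mask], 1.0, atol=1e-12)

    def test_normalized_in_mask_mean_is_one(self, rng):
        vol = rng.standard_normal((5, 5, 5, 12))
        mask = rng.random((5, 5, 5)) > 0.3
        from rsmvpa.features import normalize_reho
        raw = rm.reho_map(_bold(vol), mask)
        assert normalize_reho(raw, mask)[mask].mean() == pytest.approx(1.0)

    def test_interior_voxel_consistent_with_direct_kendalls_w(self, rng):
        vol = rng.standard_normal((5, 5, 5, 10))
        mask = np.ones((5, 5, 5), dtype=bool)
        raw = rm.reho_map(_bold(vol), mask, neighborhood=27)
        block = vol[1:4, 1:4, 1:4].reshape(27, 10)
        assert raw[2, 2, 2] == pytest.approx(rm.kendalls_w(block), abs=1e-12)

    @pytest.mark.parametrize("neighborhood,expected_k", [(7, 7), (19, 19), (27, 27)])
    def test_neighborhood_sizes(self, neighborhood, expected_k):
        from rsmvpa.features import _neighborhood_offsets
        assert _neighborhood_offsets(neighborhood).shape[0] == expected_k

    def test_isolated_voxel_flagged_zero(self, rng):
        vol = rng.standard_normal((5, 5, 5, 8))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = mask[4, 4, 3] = True
        with pytest.warns(UserWarning, match="no in-mask neighbors"):
            raw = rm.reho_map(_bold(vol), mask)
        assert raw[0, 0, 0] == 0.0
        assert raw[4, 4, 4] != 0.0


class TestLargescaleFC:
    def test_single_voxel_nodes_equal_their_series(self, rng):
        vol = rng.standard_normal((3, 1, 1, 10))
        atlas = np.array([2, 1, 3]).reshape(3, 1, 1)
        ts, labels = rm.node_timeseries(_bold(vol), atlas)
        np.testing.assert_array_equal(labels, [1, 2, 3])
        np.testing.assert_allclose(ts[0], vol[1, 0, 0])
        np.testing.assert_allclose(ts[1], vol[0, 0, 0])

    def test_two_voxel_node_average_and_groupby_oracle(self, rng):
        vol = rng.standard_normal((4, 2, 1, 6))
        atlas = rng.integers(1, 4, size=(4, 2, 1))
        ts, labels = rm.node_timeseries(_bold(vol), atlas)
        for i, lab in enumerate(labels):
            np.testing.assert_allclose(ts[i], vol[atlas == lab].mean(axis=0))

    def test_empty_node_policy(self, rng):
        vol = rng.standard_normal((2, 1, 1, 5))
        atlas = np.array([1, 3]).reshape(2, 1, 1)  # node 2 empty
        with pytest.raises(ValueError, match=r"\[2\]"):
            rm.node_timeseries(_bold(vol), atlas)
        with pytest.warns(UserWarning):
            ts, labels = rm.node_timeseries(_bold(vol), atlas, on_empty="drop")
        np.testing.assert_array_equal(labels, [1, 3])

    def test_two_nodes_single_arctanh_value(self, rng):
        ts = rng.standard_normal((2, 30))
        vec = rm.largescale_fc(ts)
        assert vec.shape == (1,)
        assert vec[0] == pytest.approx(np.arctanh(np.corrcoef(ts)[0, 1]))

    def test_five_nodes_match_brute_force_pairwise_loop(self, rng):
        ts = rng.standard_normal((5, 40))
        vec = rm.largescale_fc(ts)
        pairs = rm.pair_index_map(5)
        assert vec.shape == (10,)
        for idx, (i, j) in enumerate(pairs):
            r = np.corrcoef(ts[i], ts[j])[0, 1]
            assert vec[idx] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_label_permutation_consistent_with_index_map(self, rng):
        """Permuting node order permutes the vector per the pair index map."""
        ts = rng.standard_normal((6, 25))
        perm = rng.permutation(6)
        v1 = rm.largescale_fc(ts)
        v2 = rm.largescale_fc(ts[perm])
        pairs = rm.pair_index_map(6)
        lookup = {tuple(sorted((perm[i], perm[j]))): v2[idx]
                  for idx, (i, j) in enumerate(pairs)}
        for idx, (i, j) in enumerate(pairs):
            assert v1[idx] == pytest.approx(lookup[tuple(sorted((i, j)))], abs=1e-12)

    def test_constant_node_rejected(self, rng):
        ts = rng.standard_normal((3, 20))
        ts[1] = 2.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            rm.largescale_fc(ts)


class TestFeatureTable:
    def test_fcs_table_shape_and_roundtrip(self, small_fcs_table, small_masks):
        tab = small_fcs_table
        mask, _ = small_masks
        assert tab.X.shape == (10, int(mask.sum()))
        # index-map bijection: column j -> voxel coordinate -> re-extracted value
        vol = rm.vector_to_map(tab.X[3], tab.index_map, tab.grid_shape)
        for j in (0, 5, tab.n_features - 1):
            assert vol[tuple(tab.index_map[j])] == tab.X[3, j]
        np.testing.assert_array_equal(vol[mask], tab.X[3])

    def test_largescale_table_dimensions(self, small_config, small_cohort, small_masks):
        manifest, series, _ = small_cohort
        _, parc = small_masks
        tab = rm.build_feature_table(series, manifest,
                                     rm.FeatureSpec(kind="largescale_FC"), atlas=parc)
        n = small_config.n_regions
        assert tab.X.shape == (10, n * (n - 1) // 2)
        np.testing.assert_array_equal(tab.index_map, rm.pair_index_map(n))

    def test_grid_mismatch_rejected(self, small_cohort, small_masks):
        manifest, series, _ = small_cohort
        mask, _ = small_masks
        bad = [series[0], _bold(np.zeros((4, 4, 4, 8)))]
        with pytest.raises(ValueError, match="grid"):
            rm.build_feature_table(bad, manifest.iloc[:2],
                                   rm.FeatureSpec(kind="FCS", smooth_fwhm_mm=0.0),
                                   mask=mask)
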