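"""Texture matrices and features against brute-force enumeration oracles."""

import numpy as np
import pytest

import oracles
from csprad.texture import (DIRECTIONS, glcm_features, glcm_matrices,
                            gldm_features, gldm_matrix, glrlm_features,
                            glrlm_matrices, glszm_features, glszm_matrix,
                            ngtdm_features, ngtdm_table)


def _random_case(rng, shape=(4, 4, 3), levels=4):
    labels = rng.integers(1, levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) > 0.25
    if not mask.any():
        mask[0, 0, 0] = True
    return labels, mask, levels


@pytest.fixture(scope="module")
def sweep_cases():
    rng = np.random.default_rng(2024)
    return [_random_case(rng) for _ in range(25)]


class TestMatrixOracles:
    """Every texture matrix equals exhaustive enumeration on random small
    arrays (<= 4 gray levels, 4x4x3)."""

    def test_glcm_matches_pair_enumeration(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            mats = glcm_matrices(q)
            for d, m in zip(DIRECTIONS, mats):
                np.testing.assert_array_equal(
                    m, oracles.oracle_glcm(q.labels, mask, d, ng))

    def test_glrlm_matches_run_enumeration(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            mats = glrlm_matrices(q)
            for d, m in zip(DIRECTIONS, mats):
                o = oracles.oracle_glrlm(q.labels, mask, d, ng, m.shape[1])
                np.testing.assert_array_equal(m, o)

    def test_glszm_matches_flood_fill(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            m = glszm_matrix(q).raw
            np.testing.assert_array_equal(
                m, oracles.oracle_glszm(q.labels, mask, ng))

    def test_gldm_matches_neighbor_counts(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            m = gldm_matrix(q).raw
            np.testing.assert_array_equal(
                m, oracles.oracle_gldm(q.labels, mask, ng))

    def test_ngtdm_matches_neighborhood_averages(self, sweep_cases,
                                                 make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            n, _, s = ngtdm_table(q)
            n_o, s_o = oracles.oracle_ngtdm(q.labels, mask, ng)
            np.testing.assert_allclose(n, n_o)
            np.testing.assert_allclose(s, s_o, atol=1e-10)


class TestFeatureOracles:
    """Headline features recomputed with independent loop-written formulas
    from the oracle matrices."""

    def test_glcm_cluster_shade(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases:
            q = make_quantized(labels, mask, ng)
            expected = np.mean([
                oracles.oracle_cluster_shade(m)
                for m in (oracles.oracle_glcm(q.labels, mask, d, ng)
                          for d in DIRECTIONS)
                if m.sum() > 0])
            got = glcm_features(q)["ClusterShade"]
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_glrlm_emphases(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases[:10]:
            q = make_quantized(labels, mask, ng)
            feats = glrlm_features(q)
            oracle_mats = [oracles.oracle_glrlm(q.labels, mask, d, ng,
                                                max(labels.shape))
                           for d in DIRECTIONS]
            np.testing.assert_allclose(
                feats["LongRunHighGrayLevelEmphasis"],
                np.mean([oracles.oracle_lrhgle(m) for m in oracle_mats]),
                rtol=1e-10)
            np.testing.assert_allclose(
                feats["ShortRunHighGrayLevelEmphasis"],
                np.mean([oracles.oracle_srhgle(m) for m in oracle_mats]),
                rtol=1e-10)

    def test_glszm_variance_and_lglze(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases[:10]:
            q = make_quantized(labels, mask, ng)
            feats = glszm_features(q)
            o = oracles.oracle_glszm(q.labels, mask, ng)
            np.testing.assert_allclose(feats["GrayLevelVariance"],
                                       oracles.oracle_glv(o), rtol=1e-10)
            np.testing.assert_allclose(feats["LowGrayLevelZoneEmphasis"],
                                       oracles.oracle_lglze(o), rtol=1e-10)

    def test_gldm_high_gray_level_emphasis(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases[:10]:
            q = make_quantized(labels, mask, ng)
            got = gldm_features(q)["HighGrayLevelEmphasis"]
            np.testing.assert_allclose(
                got, oracles.oracle_hgle(oracles.oracle_gldm(q.labels, mask, ng)),
                rtol=1e-10)


class TestHandComputedExamples:
    def test_constant_region_cluster_shade_zero(self, make_quantized):
        q = make_quantized(np.ones((3, 3, 2), dtype=int))
        assert glcm_features(q)["ClusterShade"] == pytest.approx(0.0)

    def test_checkerboard_cluster_shade_zero(self, make_quantized):
        idx = np.indices((4, 4, 2)).sum(axis=0)
        q = make_quantized(1 + idx % 2)
        assert glcm_features(q)["ClusterShade"] == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_level2_lrhgle(self, make_quantized):
        labels = np.zeros((3, 3, 1), dtype=int)
        labels[1, 1, 0] = 2
        q = make_quantized(labels, n_levels=2)
        # P(2,1)=1, Nr=1 in every direction: LRHGLE = 2^2 * 1^2 = 4
        assert glrlm_features(q)["LongRunHighGrayLevelEmphasis"] == \
            pytest.approx(4.0)

    def test_constant_line_single_direction_lrhgle(self, make_quantized):
        n = 5
        labels = np.zeros((n, 3, 1), dtype=int)
        labels[:, 1, 0] = 1
        q = make_quantized(labels, n_levels=1)
        mats = glrlm_matrices(q)
        m = mats[DIRECTIONS.index((1, 0, 0))]
        # one run of length n: LRHGLE = 1^2 * n^2 / 1
        lrhgle = oracles.oracle_lrhgle(m)
        assert lrhgle == pytest.approx(n ** 2)

    def test_constant_region_single_zone(self, make_quantized):
        q = make_quantized(np.ones((3, 3, 2), dtype=int))
        feats = glszm_features(q)
        assert feats["GrayLevelVariance"] == pytest.approx(0.0)
        assert glszm_matrix(q).norm == 1

    def test_two_equal_zones_glv(self, make_quantized):
        labels = np.zeros((4, 2, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 3
        q = make_quantized(labels, n_levels=3)
        # two zones at levels 1 and 3, p = 0.5 each: mu = 2, GLV = 1
        assert glszm_features(q)["GrayLevelVariance"] == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [1, 3])
    def test_gldm_constant_region(self, make_quantized, g):
        labels = np.full((3, 3, 2), g, dtype=int)
        q = make_quantized(labels, n_levels=g)
        assert gldm_features(q)["HighGrayLevelEmphasis"] == pytest.approx(g ** 2)


class TestMatrixInvariants:
    def test_glcm_symmetric_and_normalizable(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases[:8]:
            q = make_quantized(labels, mask, ng)
            for m in glcm_matrices(q):
                np.testing.assert_array_equal(m, m.T)
                assert (m >= 0).all()
                if m.sum() > 0:
                    assert (m / m.sum()).sum() == pytest.approx(1.0)

    def test_counts_account_for_all_voxels(self, sweep_cases, make_quantized):
        for labels, mask, ng in sweep_cases[:8]:
            q = make_quantized(labels, mask, ng)
            # GLSZM zone sizes and GLDM entries partition the masked voxels
            m = glszm_matrix(q).raw
            sizes = np.arange(1, m.shape[1] + 1)
            assert (m * sizes).sum() == mask.sum()
            assert gldm_matrix(q).raw.sum() == mask.sum()
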