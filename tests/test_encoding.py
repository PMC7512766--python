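"""Image encoding: contrast/frequency/coupling maps and link topology."""

import numpy as np
import pytest

from oscatt.encoding import (
    DEFAULT_WEIGHTS,
    NEIGHBOR_OFFSETS,
    FeatureStack,
    build_topology,
    central_frequency,
    contrast_map,
    coupling_maps,
    frequency_map,
    preprocess,
)


@pytest.fixture
def two_tone_features():
    """Left half dark, right half bright, all four features."""
    img = np.zeros((6, 8, 3), dtype=np.uint8)
    img[:, 4:] = 200
    return preprocess(img)


class TestPreprocess:
    def test_uniform_midgray(self):
        feats = preprocess(np.full((5, 5, 3), 127.5))
        assert np.allclose(feats.features, 0.5)

    def test_no_blur_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (6, 7, 3), dtype=np.uint8)
        feats = preprocess(img, blur=False)
        assert np.allclose(feats.features[1], img[..., 0] / 255.0)
        assert np.allclose(feats.features[0], img.mean(axis=-1) / 255.0)

    def test_grayscale_replicates_channels(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4) * 20
        feats = preprocess(img)
        for l in range(4):
            assert np.allclose(feats.features[l], img / 255.0)

    def test_resize(self):
        img = np.zeros((30, 42, 3), dtype=np.uint8)
        feats = preprocess(img, resize=(15, 21))
        assert feats.shape == (15, 21)

    def test_weights_default(self):
        assert DEFAULT_WEIGHTS == pytest.approx([0.5, 1 / 6, 1 / 6, 1 / 6])
        assert DEFAULT_WEIGHTS.sum() == pytest.approx(1.0)


class TestContrast:
    def test_uniform_image_zero(self):
        feats = preprocess(np.full((4, 4, 3), 80, dtype=np.uint8))
        assert np.allclose(contrast_map(feats), 0.0)

    def test_single_feature_two_pixels(self):
        feats = FeatureStack(features=np.array([[[0.0, 1.0]]]), weights=np.array([1.0]))
        assert np.allclose(contrast_map(feats), 0.5)

    def test_hand_computed_toy(self):
        """2x2 four-feature stack against an explicit loop."""
        rng = np.random.default_rng(7)
        f = rng.uniform(0, 1, (4, 2, 2))
        feats = FeatureStack(features=f)
        got = contrast_map(feats)
        w = DEFAULT_WEIGHTS
        for j in range(2):
            for k in range(2):
                expect = sum(w[l] * abs(f[l, j, k] - f[l].mean()) for l in range(4)) / w.sum()
                assert got[j, k] == pytest.approx(expect)

    def test_range_invariant(self, two_tone_features):
        c = contrast_map(two_tone_features)
        assert np.all((c >= 0.0) & (c <= 1.0))

    def test_position_permutation_equivariance(self):
        """Contrast depends on values and the global mean only."""
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 1, (4, 3, 4))
        perm = rng.permutation(12)
        f_perm = f.reshape(4, 12)[:, perm].reshape(4, 3, 4)
        c = contrast_map(FeatureStack(features=f)).ravel()[perm]
        c_perm = contrast_map(FeatureStack(features=f_perm)).ravel()
        assert np.allclose(c, c_perm)


class TestFrequency:
    @pytest.mark.parametrize("c,delta_o,expect", [
        (0.0, 0.04, 0.98),
        (1.0, 0.04, 1.02),
        (0.5, 0.1, 1.0),
    ])
    def test_endpoints(self, c, delta_o, expect):
        assert frequency_map(np.array([c]), delta_o)[0] == pytest.approx(expect)

    def test_order_preserving(self):
        c = np.linspace(0, 1, 11)
        assert np.all(np.diff(frequency_map(c, 0.04)) > 0)

    def test_band_invariant(self, two_tone_features):
        o = frequency_map(contrast_map(two_tone_features), 0.04)
        assert np.all((o >= 0.98) & (o <= 1.02))

    def test_central_frequency(self):
        assert central_frequency(np.array([0.98, 1.02])) == pytest.approx(1.0)
        rng = np.random.default_rng(2)
        m = rng.uniform(0.98, 1.02, (5, 6))
        assert central_frequency(m) == pytest.approx(sum(map(float, m.ravel())) / m.size)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            frequency_map(np.array([0.5]), delta_o=0.0)
        with pytest.raises(ValueError):
            central_frequency(np.array([]))


class TestCouplingMaps:
    def test_full_contrast(self):
        lp, ln = coupling_maps(np.array([1.0]), 0.05, 0.02, 0.2)
        assert lp[0] == pytest.approx(0.05)
        assert ln[0] == pytest.approx(0.0)

    def test_zero_contrast_direct_evaluation(self):
        lp, ln = coupling_maps(np.array([0.0]), 0.05, 0.02, 0.2)
        g = np.exp(-1.0 / (2 * 0.2**2))  # exp(-12.5)
        assert lp[0] == pytest.approx(0.05 * g)
        assert ln[0] == pytest.approx(0.02 * (1 - g))

    def test_monotone_in_contrast(self):
        c = np.linspace(0, 1, 21)
        lp, ln = coupling_maps(c)
        assert np.all(np.diff(lp) > 0)
        assert np.all(np.diff(ln) < 0)
        assert np.all((lp >= 0) & (lp <= 0.05))
        assert np.all((ln >= 0) & (ln <= 0.02))

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            coupling_maps(np.array([0.5]), sigma=0.0)


class TestTopology:
    def test_uniform_image_all_positive(self):
        feats = preprocess(np.full((4, 5, 3), 90, dtype=np.uint8))
        topo = build_topology(feats, theta=0.1)
        assert topo.negative.sum() == 0
        assert topo.positive.sum() > 0

    def test_two_region_split(self, two_tone_features):
        topo = build_topology(two_tone_features, theta=0.1)
        # cross-boundary links (between col 3 and 4) are negative
        assert topo.negative[:, :, 3:5].sum() > 0
        # within-region horizontal neighbours are positive
        right = NEIGHBOR_OFFSETS.index((0, 1))
        assert topo.positive[right, :, :3].all()
        assert topo.negative[:, :, :3].sum() == 0

    def test_degrees(self):
        feats = preprocess(np.full((5, 7, 3), 10, dtype=np.uint8))
        deg = build_topology(feats).degree()
        assert deg[0, 0] == 3 and deg[-1, -1] == 3
        assert deg[0, 3] == 5 and deg[2, 0] == 5
        assert deg[2, 3] == 8

    def test_partition_and_symmetry(self, two_tone_features):
        topo = build_topology(two_tone_features, theta=0.1)
        assert not np.any(topo.positive & topo.negative)
        m, n = two_tone_features.shape
        for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            j = NEIGHBOR_OFFSETS.index((-dr, -dc))
            for links in (topo.positive, topo.negative):
                for r in range(m):
                    for c in range(n):
                        if links[i, r, c]:
                            assert links[j, r + dr, c + dc]
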