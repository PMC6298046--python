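import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msifilter import (
    DegenerateImageError,
    DimensionMismatchError,
    IonImage,
    ROIMask,
    UndefinedScoreError,
    gini_index,
    scatter_ratio,
    similarity,
    spatial_chaos,
)
from msifilter.metrics import SIMILARITY_MEASURES


def gini_pairwise_oracle(x):
    x = np.asarray(x, float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())


class TestScatterRatio:
    def test_solid_block_fully_regular(self):
        img = np.zeros((9, 9))
        img[3:6, 3:6] = 10.0
        s = scatter_ratio(IonImage(img))
        assert s.raw == 0.0
        assert s.value == 1.0

    def test_five_isolated_pixels(self):
        img = np.zeros((9, 9))
        for r, c in [(0, 0), (0, 4), (4, 0), (4, 4), (8, 8)]:
            img[r, c] = 5.0
        s = scatter_ratio(IonImage(img))
        assert s.raw == pytest.approx(4 / 5)

    def test_block_plus_isolated_pixel(self):
        img = np.zeros((9, 9))
        img[1:3, 1:3] = 5.0  # 4-pixel block
        img[7, 7] = 5.0  # one isolated pixel
        s = scatter_ratio(IonImage(img))
        assert s.raw == pytest.approx(1 / 5)

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateImageError):
            scatter_ratio(IonImage(np.full((4, 4), 2.0)))

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(0)
        img = rng.gamma(0.5, 1.0, size=(12, 12))
        a = scatter_ratio(IonImage(img)).raw
        b = scatter_ratio(IonImage(img * 7.5)).raw
        assert a == b


class TestSpatialChaos:
    def test_solid_block_zero_chaos(self):
        img = np.zeros((10, 10))
        img[2:7, 2:7] = 3.0
        s = spatial_chaos(IonImage(img))
        assert s.raw == 0.0
        assert s.value == 1.0

    def test_diagonal_contacts_not_isolated(self):
        # checkerboard: 4-neighbour gaps but diagonal contacts -> no isolation
        img = np.indices((8, 8)).sum(axis=0) % 2 * 5.0
        s = spatial_chaos(IonImage(img))
        assert s.raw == 0.0

    def test_salt_and_pepper_is_chaotic(self):
        chaos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = (rng.random((64, 64)) < 0.05) * rng.uniform(0.5, 1, (64, 64))
            chaos.append(spatial_chaos(IonImage(img)).raw)
        assert np.mean(chaos) > 0.5

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateImageError):
            spatial_chaos(IonImage(np.zeros((4, 4))))


class TestGini:
    def test_uniform_image_zero(self):
        assert gini_index(IonImage(np.full((3, 3), 4.0))).value == pytest.approx(0.0)

    def test_single_hot_pixel(self):
        g = gini_index(IonImage(np.array([[1.0, 0.0], [0.0, 0.0]])))
        assert g.value == pytest.approx(0.75)
        assert g.value == pytest.approx(gini_pairwise_oracle([1, 0, 0, 0]))

    def test_half_and_half(self):
        g = gini_index(IonImage(np.array([[0.0, 0.0], [1.0, 1.0]])))
        assert g.value == pytest.approx(0.5)
        assert g.value == pytest.approx(gini_pairwise_oracle([0, 0, 1, 1]))

    def test_matches_pairwise_oracle_random(self, rng):
        x = rng.gamma(0.7, 1.0, size=(6, 7))
        assert gini_index(IonImage(x)).value == pytest.approx(
            gini_pairwise_oracle(x.ravel())
        )

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=4, max_size=16),
        st.floats(0.1, 50.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, c):
        n = len(values) - len(values) % 2
        x = np.asarray(values[:n] or values + values).reshape(2, -1)
        g1 = gini_index(IonImage(x)).value
        g2 = gini_index(IonImage(c * x)).value
        assert g1 == pytest.approx(g2, abs=1e-9)

    def test_all_zero_errors(self):
        with pytest.raises(DegenerateImageError):
            gini_index(IonImage(np.zeros((3, 3))))


class TestSimilarity:
    @pytest.mark.parametrize("measure", SIMILARITY_MEASURES)
    def test_self_similarity_is_one(self, measure, rng):
        x = IonImage(rng.random((16, 16)))
        assert similarity(x, x, measure).value == pytest.approx(1.0, abs=1e-9)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.random((8, 8))
        s = similarity(IonImage(x), IonImage(np.exp(x)), "spearman")
        assert s.value == pytest.approx(1.0)

    def test_anticorrelated_masks_negative_spearman(self):
        a = np.zeros((6, 6))
        a[:, :3] = 1.0
        s = similarity(IonImage(a), IonImage(1.0 - a), "spearman")
        assert s.value == pytest.approx(-1.0)

    def test_nmi_independent_noise_near_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            a = IonImage(rng.random((64, 64)))
            b = IonImage(rng.random((64, 64)))
            vals.append(similarity(a, b, "nmi", n_bins=16).value)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("measure", SIMILARITY_MEASURES)
    def test_symmetry(self, measure, rng):
        a = IonImage(rng.random((12, 12)))
        b = IonImage(rng.gamma(1.0, 1.0, (12, 12)))
        assert similarity(a, b, measure).value == pytest.approx(
            similarity(b, a, measure).value, abs=1e-9
        )

    def test_binary_mask_keeps_two_levels(self):
        rng = np.random.default_rng(5)
        mask = ROIMask(rng.random((10, 10)) < 0.4)
        img = IonImage(mask.mask * 3.0)
        assert similarity(img, mask, "nmi").value == pytest.approx(1.0)

    def test_constant_input_undefined_for_correlation(self):
        a = IonImage(np.ones((4, 4)))
        b = IonImage(np.arange(16.0).reshape(4, 4))
        for measure in ("pearson", "spearman"):
            with pytest.raises(UndefinedScoreError):
                similarity(a, b, measure)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(DimensionMismatchError):
            similarity(IonImage(rng.random((4, 4))), IonImage(rng.random((4, 5))), "pearson")
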