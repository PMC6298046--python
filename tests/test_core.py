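import numpy as np
import pytest

from msifilter import (
    DegenerateImageError,
    MSIDataset,
    ROIMask,
    detect_roi,
    ion_image,
    load_dataset,
    make_reference,
    otsu_mask,
    otsu_threshold,
    save_dataset,
    tic_image,
)
from msifilter.errors import MSIFilterError

from conftest import make_dataset


def brute_force_otsu(x, n_bins=256):
    """Independent exhaustive search over the same interior-bin-edge grid."""
    x = np.asarray(x, float).ravel()
    edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    best_t, best_v = None, -1.0
    for t in edges:
        c0, c1 = x[x <= t], x[x > t]
        if c0.size == 0 or c1.size == 0:
            continue
        v = c0.size * c1.size * (c0.mean() - c1.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestDatasetInvariants:
    def test_rejects_negative_intensities(self):
        with pytest.raises(MSIFilterError):
            make_dataset([[-1.0, 2.0]] * 6)

    def test_rejects_unsorted_mz(self):
        with pytest.raises(MSIFilterError):
            make_dataset(np.ones((6, 2)), mz=[500.0, 499.0])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(MSIFilterError):
            MSIDataset(np.ones((6, 2)), [500.0, 510.0], (2, 2))


class TestIonImage:
    def test_row_major_reshape(self):
        ds = make_dataset(np.array([[1, 2, 3, 4, 5, 6]]).T, shape=(2, 3))
        np.testing.assert_array_equal(
            ion_image(ds, 0).values, [[1, 2, 3], [4, 5, 6]]
        )

    def test_flatten_is_exact_inverse_for_every_column(self, rng):
        ds = make_dataset(rng.random((24, 5)), shape=(4, 6))
        for j in range(ds.n_peaks):
            np.testing.assert_array_equal(
                ion_image(ds, j).flatten(), ds.intensities[:, j]
            )

    def test_all_zero_column_ok(self):
        ds = make_dataset(np.zeros((6, 1)))
        assert not ion_image(ds, 0).values.any()

    def test_out_of_range_index(self):
        ds = make_dataset(np.ones((6, 2)))
        with pytest.raises(IndexError):
            ion_image(ds, 2)


class TestReference:
    def test_sum_single_peak_equals_its_image(self, rng):
        ds = make_dataset(rng.random((12, 1)))
        np.testing.assert_array_equal(
            make_reference(ds, "sum").values, ion_image(ds, 0).values
        )

    def test_mean_of_identical_peaks(self, rng):
        col = rng.random(12)
        ds = make_dataset(np.stack([col, col], axis=1))
        np.testing.assert_allclose(
            make_reference(ds, "mean").values.ravel(), col
        )

    def test_median_matches_per_pixel_sort_oracle(self, rng):
        ds = make_dataset(rng.random((20, 6)), shape=(4, 5))
        expected = np.array(
            [sorted(row)[2:4] for row in ds.intensities]
        ).mean(axis=1)
        np.testing.assert_allclose(
            make_reference(ds, "median").values.ravel(), expected
        )

    def test_sum_reference_equals_tic(self, rng):
        ds = make_dataset(rng.random((24, 5)), shape=(4, 6))
        np.testing.assert_array_equal(
            make_reference(ds, "sum").values, tic_image(ds).values
        )
        np.testing.assert_allclose(
            tic_image(ds).values.ravel(), ds.intensities.sum(axis=1)
        )

    def test_pca1_sign_fixed_against_tic(self, rng):
        ds = make_dataset(rng.random((30, 4)) * [1, 2, 3, 4], shape=(5, 6))
        ref = make_reference(ds, "pca1")
        assert np.corrcoef(ref.values.ravel(), tic_image(ds).values.ravel())[0, 1] >= 0

    def test_pca1_constant_data_errors(self):
        ds = make_dataset(np.ones((6, 3)))
        with pytest.raises(DegenerateImageError):
            make_reference(ds, "pca1")


class TestOtsu:
    def test_perfectly_bimodal_separation(self):
        img = np.concatenate([np.zeros(50), np.full(50, 10.0)]).reshape(10, 10)
        t = otsu_threshold(img)
        assert (img > t).sum() == 50
        assert np.all(img[img > t] == 10.0)

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((4, 4), 3.0))

    def test_matches_exhaustive_oracle_gaussian_mixture(self, rng):
        x = np.concatenate(
            [rng.normal(2, 0.5, 256), rng.normal(8, 0.5, 256)]
        ).reshape(16, 32)
        assert otsu_threshold(x) == pytest.approx(brute_force_otsu(x), abs=0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle_random_images(self, trial):
        rng = np.random.default_rng(100 + trial)
        x = rng.gamma(1.5, 2.0, size=(8, 8))
        assert otsu_threshold(x) == brute_force_otsu(x)


class TestROI:
    def test_kmeans_recovers_separable_halves(self, rng):
        # left half 10x the intensity of the right half in every peak
        base = rng.random((8, 8, 5)) + 1.0
        base[:, 4:, :] /= 10.0
        ds = make_dataset(base.reshape(64, 5), shape=(8, 8))
        roi = detect_roi(ds, "kmeans")
        expected = np.zeros((8, 8), bool)
        expected[:, :4] = True
        np.testing.assert_array_equal(roi.mask, expected)

    def test_otsu_roi_on_bimodal_reference(self):
        vals = np.zeros((6, 6))
        vals[2:4, 2:4] = 10.0
        ds = make_dataset(vals.reshape(36, 1))
        roi = detect_roi(ds, "otsu")
        np.testing.assert_array_equal(roi.mask, vals == 10.0)

    def test_external_mask_passthrough(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        roi = ROIMask(mask, origin="external")
        np.testing.assert_array_equal(roi.mask, mask)

    def test_kmeans_invariant_to_pixel_permutation(self, rng):
        ds, _ = __import__("msifilter").generate(
            shape=(16, 16), n_structured=4, n_off_tissue=2, n_noise=2, seed=9
        )
        roi = detect_roi(ds, "kmeans")
        perm = rng.permutation(ds.n_pixels)
        ds2 = MSIDataset(ds.intensities[perm], ds.mz, ds.shape, list(ds.peak_ids))
        roi2 = detect_roi(ds2, "kmeans")
        np.testing.assert_array_equal(roi2.flatten(), roi.flatten()[perm])


class TestIO:
    def test_imzml_round_trip(self, tmp_path, rng):
        ds = make_dataset(rng.random((12, 5)), shape=(4, 3))
        path = save_dataset(ds, tmp_path / "t.imzML")
        back = load_dataset(path)
        assert back.shape == (4, 3)
        np.testing.assert_allclose(back.intensities, ds.intensities, rtol=1e-6)
        np.testing.assert_allclose(back.mz, ds.mz, rtol=1e-6)

    def test_matrix_round_trip_with_header_shape(self, tmp_path, rng):
        ds = make_dataset(rng.random((12, 3)), shape=(4, 3))
        path = save_dataset(ds, tmp_path / "t.tsv")
        back = load_dataset(path)
        assert back.shape == (4, 3)
        assert back.n_pixels == 12
        np.testing.assert_allclose(back.intensities, ds.intensities, rtol=1e-6)

    def test_imzml_missing_pixel_zero_filled_with_warning(self, tmp_path):
        from pyimzml.ImzMLWriter import ImzMLWriter

        mz = np.array([100.0, 200.0])
        path = tmp_path / "gap.imzML"
        # enumerate coordinates manually: write 11 of 12 cells, skip (row=3, col=2)
        with ImzMLWriter(str(path), mode="continuous") as w:
            for row in range(4):
                for col in range(3):
                    if (row, col) == (3, 2):
                        continue
                    w.addSpectrum(mz, [row + 1.0, col + 1.0], (col + 1, row + 1, 1))
        with pytest.warns(UserWarning, match="zero-filled"):
            ds = load_dataset(path)
        assert ds.n_pixels == 12
        np.testing.assert_array_equal(ds.intensities[3 * 3 + 2], [0.0, 0.0])
        np.testing.assert_array_equal(ds.intensities[0], [1.0, 1.0])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "nope.imzML")
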