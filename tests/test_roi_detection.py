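import math

import numpy as np
import pytest
from scipy.signal import convolve2d

from catk import (
    DoGParams,
    InvalidParameterError,
    ROIMap,
    detect_rois,
    dog_filter,
    gaussian_kernel,
    load_roi_mask,
    save_roi_mask,
    suggest_parameters,
)


def dense_dog_oracle(image, params):
    """Independent dense 2-D DoG: edge-pad, convolve with the full 2-D
    kernel (outer product of the truncated 1-D kernels), per sigma."""

    def blur(img, sigma):
        k = gaussian_kernel(sigma)
        r = (len(k) - 1) // 2
        padded = np.pad(img, r, mode="edge")
        return convolve2d(padded, np.outer(k, k), mode="valid")

    return blur(image, params.sigma_a) - blur(image, params.sigma_b)


def blob_image(shape, centers, sigma, amplitude, background):
    ys = np.arange(shape[0])[:, None]
    xs = np.arange(shape[1])[None, :]
    image = np.full(shape, background, dtype=float)
    for cx, cy in centers:
        image += amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    return image


class TestGaussianKernel:
    def test_sigma_one_shape_and_normalization(self):
        k = gaussian_kernel(1.0)
        assert len(k) == 7
        assert np.argmax(k) == 3
        assert k.sum() == pytest.approx(1.0)

    def test_closed_form_ratio(self):
        k = gaussian_kernel(2.0)
        center = (len(k) - 1) // 2
        assert k[center + 2] / k[center] == pytest.approx(math.exp(-(2**2) / (2 * 2**2)))

    @pytest.mark.parametrize("sigma", [0.7, 1.0, 2.5, 4.8])
    def test_even_symmetry_and_length(self, sigma):
        k = gaussian_kernel(sigma)
        assert len(k) == 2 * math.ceil(3 * sigma) + 1
        np.testing.assert_allclose(k, k[::-1])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            gaussian_kernel(0.0)


class TestDogFilter:
    def test_constant_image_gives_zero_response(self):
        params = DoGParams(2.0, 3.2, 0.003)
        response = dog_filter(np.full((32, 32), 0.6), params)
        np.testing.assert_allclose(response, 0.0, atol=1e-12)

    def test_impulse_response_is_kernel_difference(self):
        params = DoGParams(2.0, 3.2, 0.003)
        image = np.zeros((64, 64))
        image[32, 32] = 1.0
        response = dog_filter(image, params)
        ka, kb = gaussian_kernel(2.0), gaussian_kernel(3.2)
        # embed both 2-D kernels centered on the impulse
        expected = np.zeros((64, 64))
        for k, sign in [(ka, 1.0), (kb, -1.0)]:
            r = (len(k) - 1) // 2
            expected[32 - r : 32 + r + 1, 32 - r : 32 + r + 1] += sign * np.outer(k, k)
        np.testing.assert_allclose(response, expected, atol=1e-12)

    def test_separable_matches_dense_oracle(self, rng):
        params = DoGParams(3.0, 4.8, 0.0032)
        image = rng.uniform(0, 1, size=(64, 64))
        np.testing.assert_allclose(
            dog_filter(image, params), dense_dog_oracle(image, params), atol=1e-10
        )

    def test_kernel_len_rule(self):
        assert DoGParams(3.0, 4.8, 0.0032).kernel_len == 2 * math.ceil(3 * 4.8) + 1


class TestDetectRois:
    def test_five_planted_blobs_detected(self):
        centers = [(20, 20), (60, 25), (100, 20), (40, 70), (90, 80)]
        image = blob_image((110, 120), centers, sigma=4, amplitude=0.8, background=0.05)
        params = DoGParams(4.0, 6.4, 0.0032)
        roi_map = detect_rois(image, params)
        assert roi_map.n_rois == 5
        for cx, cy in centers:
            assert roi_map.labels[cy, cx] > 0  # each blob center inside an ROI
        labels_at_centers = {roi_map.labels[cy, cx] for cx, cy in centers}
        assert len(labels_at_centers) == 5  # all distinct

    def test_all_zero_image_yields_no_rois(self):
        roi_map = detect_rois(np.zeros((40, 40)), DoGParams(3.0, 4.8, 0.0032))
        assert roi_map.n_rois == 0

    def test_ring_interior_is_filled(self):
        # bright annulus: super-threshold DoG boundary around a sub-threshold
        # interior must come back as one solid ROI
        ys, xs = np.mgrid[0:61, 0:61]
        r = np.hypot(xs - 30, ys - 30)
        image = np.where(np.abs(r - 12) <= 2, 1.0, 0.0)
        params = DoGParams(2.0, 3.2, 0.0032)
        response = dog_filter(image, params)
        mask = response > params.th_dog
        assert not mask[30, 30], "interior must be sub-threshold for this test"
        roi_map = detect_rois(image, params)
        assert roi_map.n_rois == 1
        assert roi_map.labels[30, 30] == 1
        # fill oracle: flood the complement from the border; unreachable
        # complement pixels are holes and belong to the ROI
        from scipy import ndimage as ndi

        outside = np.zeros_like(mask)
        outside[0, :] = outside[-1, :] = outside[:, 0] = outside[:, -1] = True
        reach = ndi.binary_propagation(outside & ~mask, mask=~mask)
        expected = mask | ~reach
        np.testing.assert_array_equal(roi_map.labels > 0, expected)

    def test_translation_equivariance(self, rng):
        image = blob_image((96, 96), [(40, 44), (60, 58)], sigma=3, amplitude=0.9, background=0.02)
        params = DoGParams(3.0, 4.8, 0.0032)
        base = detect_rois(image, params)
        dx, dy = 7, 5
        shifted = np.roll(np.roll(image, dy, axis=0), dx, axis=1)
        moved = detect_rois(shifted, params)
        assert moved.n_rois == base.n_rois
        got = sorted((r.centroid_xy for r in moved.rois))
        want = sorted(((x + dx, y + dy) for x, y in (r.centroid_xy for r in base.rois)))
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_roi_count_matches_planted_blobs_across_seeds(self):
        # spacing above four sigma_b guarantees blob masks never merge
        from catk import AnalysisParams, SceneSpec, average_frames, contrast_stretch, generate_movie

        params = AnalysisParams()
        for seed in range(20):
            spec = SceneSpec(width=110, length=110, n_frames=20, n_cells=5,
                             cell_spacing_min=20.0, seed=seed)
            stack, truth = generate_movie(spec)
            image = contrast_stretch(average_frames(stack))
            roi_map = detect_rois(image, DoGParams.from_params(params), min_area=params.min_area)
            assert roi_map.n_rois == 5, f"seed {seed}"

    def test_threshold_monotonicity(self, rng):
        image = rng.uniform(0, 1, size=(64, 64))
        params_lo = DoGParams(3.0, 4.8, 0.002)
        response = dog_filter(image, params_lo)
        counts = [(response > th).sum() for th in (0.001, 0.002, 0.004, 0.008)]
        assert counts == sorted(counts, reverse=True)

    def test_labels_are_raster_ordered(self):
        image = blob_image((60, 60), [(45, 45), (15, 12)], sigma=3, amplitude=0.9, background=0.0)
        roi_map = detect_rois(image, DoGParams(3.0, 4.8, 0.0032))
        assert [r.id for r in roi_map.rois] == [1, 2]
        # ROI 1 is the one encountered first in raster order (smaller y)
        assert roi_map.rois[0].centroid_xy[1] < roi_map.rois[1].centroid_xy[1]


class TestSuggestParameters:
    def test_table_ratio_and_threshold(self):
        for radius in (2.0, 5.0, 8.0, 20.0):
            p = suggest_parameters(1.0, radius)
            assert p.sigma_b / p.sigma_a == pytest.approx(1.6)
            assert p.th_dog == pytest.approx(0.0032)

    def test_radius_clamped_to_recommended_band(self):
        assert suggest_parameters(1.0, 20.0).sigma_a == 10.0
        assert suggest_parameters(1.0, 1.0).sigma_a == 3.0

    def test_windows_contain_one_spike(self):
        p = suggest_parameters(1.0, 5.0, expected_spike_duration_s=20.0)
        assert p.k_window >= 20
        assert p.lf_window >= 20
        p10 = suggest_parameters(10.0, 5.0, expected_spike_duration_s=20.0)
        assert p10.k_window >= 200  # hundreds of frames at ~10 Hz

    def test_midpoint_defaults(self):
        p = suggest_parameters(1.0, 5.0)
        assert p.q_percent == 15.0
        assert p.th_z == 3.0
        assert p.jin == 0.15

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            suggest_parameters(0.0, 5.0)
        with pytest.raises(InvalidParameterError):
            suggest_parameters(1.0, -2.0)


class TestRoiMasks:
    def test_label_values_preserved(self, tmp_path):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[8:11, 8:11] = 2
        labels[14:17, 3:6] = 5
        roi_map = ROIMap.from_labels(labels)
        path = tmp_path / "mask.tif"
        save_roi_mask(roi_map, path)
        loaded = load_roi_mask(path, expected_shape=(20, 20))
        assert sorted(r.id for r in loaded.rois) == [1, 2, 5]
        np.testing.assert_array_equal(loaded.labels, labels)

    def test_all_zero_mask(self, tmp_path):
        path = tmp_path / "zero.tif"
        save_roi_mask(ROIMap.from_labels(np.zeros((8, 8), dtype=np.int32)), path)
        assert load_roi_mask(path).n_rois == 0

    def test_shape_mismatch_rejected(self, tmp_path):
        path = tmp_path / "m.tif"
        save_roi_mask(ROIMap.from_labels(np.ones((8, 8), dtype=np.int32)), path)
        with pytest.raises(InvalidParameterError):
            load_roi_mask(path, expected_shape=(9, 9))

    def test_detected_map_round_trips(self, tmp_path):
        image = blob_image((50, 50), [(25, 25)], sigma=3, amplitude=0.9, background=0.0)
        roi_map = detect_rois(image, DoGParams(3.0, 4.8, 0.0032))
        path = tmp_path / "detected.tif"
        save_roi_mask(roi_map, path)
        np.testing.assert_array_equal(load_roi_mask(path).labels, roi_map.labels)
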