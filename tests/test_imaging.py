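"""Image quantification: LoG filtering, segmentation, partition ratios,
ring SD, condensate ROIs, granule statistics, colocalization."""

import numpy as np
import pytest
from scipy import signal

from granulekit.images import ImageStack
from granulekit.imaging import (
    EmptyResultError,
    SegmentationParams,
    condensate_partition_ratio,
    default_aggregate_exclusion,
    granule_count_volume,
    granule_cytoplasm_ratio,
    log_filter,
    make_cytoplasm_mask,
    pearson_colocalization,
    perinuclear_ring_metric,
    segment_granules,
)
from granulekit.simulate import (
    GranuleImageSpec,
    default_condensate_rois,
    generate_condensate_image,
    generate_granule_image,
)

from _oracles import (
    digital_sphere_voxels,
    partition_ratio_pixel_loop,
)
from conftest import NOISE_OFF


def stack_from(data, channel_names=("marker", "query"), px=0.1, dz=0.1):
    return ImageStack(np.asarray(data, dtype=float), px, dz, list(channel_names))


class TestLogFilter:
    def test_constant_image_gives_zero_response(self):
        st = stack_from(np.full((1, 1, 32, 32), 7.0), ["a"])
        resp = log_filter(st, "a", sigma_um=0.2)
        np.testing.assert_allclose(resp, 0.0, atol=1e-9)

    def test_impulse_response_defines_the_convolution(self):
        """The filter is a convolution: an arbitrary image's response
        equals explicit convolution with the impulse response kernel
        (checked on the interior, away from boundary handling)."""
        big = np.zeros((1, 1, 81, 81))
        big[0, 0, 40, 40] = 1.0
        kernel = log_filter(stack_from(big, ["a"]), "a", 0.2)[0]
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(1, 1, 72, 72))
        resp = log_filter(stack_from(img, ["a"]), "a", 0.2)[0]
        full = signal.convolve2d(img[0, 0], kernel, mode="same")
        # interior only: an 18-px margin clears the kernel support
        # (sigma 2 px, truncation 8) and the reflective boundary
        np.testing.assert_allclose(resp[18:-18, 18:-18], full[18:-18, 18:-18],
                                   rtol=1e-6, atol=1e-8)

    def test_linear_in_input(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 50, size=(1, 2, 16, 16))
        st1 = stack_from(img, ["a"])
        st2 = stack_from(2 * img, ["a"])
        np.testing.assert_allclose(
            log_filter(st2, "a", 0.3), 2 * log_filter(st1, "a", 0.3), rtol=1e-12
        )

    def test_bright_blob_yields_positive_peak(self):
        img = np.zeros((1, 1, 33, 33))
        yy, xx = np.mgrid[:33, :33]
        img[0, 0] = 100 * np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / (2 * 2.0**2))
        resp = log_filter(stack_from(img, ["a"]), "a", 0.2)
        assert resp[0, 16, 16] > 0

    def test_sigma_must_be_positive(self):
        st = stack_from(np.zeros((1, 1, 8, 8)), ["a"])
        with pytest.raises(ValueError):
            log_filter(st, "a", 0.0)


class TestSegmentation:
    def test_blank_channel_gives_empty_segmentation(self):
        st = stack_from(np.zeros((2, 3, 32, 32)))
        seg = segment_granules(st, "marker")
        assert not seg.mask.any() and seg.n_components == 0

    def test_planted_puncta_recovered_with_centroid_accuracy(self):
        spec = GranuleImageSpec(
            n_nuclei=1, granules_per_nucleus=5, n_planes=9,
            query_enrichment_ratio=3.0,
        )
        stack, truth = generate_granule_image(spec, seed=21)
        seg = segment_granules(stack, "marker")
        mid = spec.n_planes // 2
        from scipy import ndimage

        lab = seg.labels[mid]
        n = len(np.unique(lab)) - 1
        assert n == 5
        centroids = ndimage.center_of_mass(lab > 0, lab, np.unique(lab)[1:])
        px = spec.pixel_size_um
        planted = {(round(c[1] / px), round(c[2] / px)) for c in truth.granule_centers}
        for cy, cx in centroids:
            nearest = min(
                np.hypot(cy - py, cx - px_) for py, px_ in planted
            )
            assert nearest <= 1.0

    def test_constant_offset_leaves_mask_unchanged(self):
        spec = GranuleImageSpec(n_nuclei=1, granules_per_nucleus=3, n_planes=9,
                                noise_model=dict(NOISE_OFF))
        stack, _ = generate_granule_image(spec, seed=2)
        seg1 = segment_granules(stack, "marker")
        shifted = ImageStack(
            stack.data + 50.0, stack.pixel_size_um, stack.plane_spacing_um,
            stack.channel_names,
        )
        seg2 = segment_granules(shifted, "marker")
        np.testing.assert_array_equal(seg1.mask, seg2.mask)

    def test_min_area_suppresses_hot_pixels_but_keeps_blobs(self):
        from scipy import ndimage

        img = np.zeros((1, 1, 48, 48))
        yy, xx = np.mgrid[:48, :48]
        img[0, 0] = 300 * np.exp(-((yy - 24) ** 2 + (xx - 24) ** 2) / (2 * 2.0**2))
        img[0, 0, 5, 5] = 400.0  # isolated hot pixels
        img[0, 0, 40, 8] = 400.0
        st = stack_from(img, ["m"])
        params = dict(log_sigma_um=0.15)
        loose = segment_granules(st, "m", SegmentationParams(min_area_px=0, **params))
        tight = segment_granules(st, "m", SegmentationParams(min_area_px=4, **params))

        def areas(seg):
            out = []
            lab = seg.labels[0]
            for l in np.unique(lab):
                if l:
                    out.append(int((lab == l).sum()))
            return out

        assert any(a < 4 for a in areas(loose))  # hot pixels detected loose
        assert all(a >= 4 for a in areas(tight))
        assert not tight.mask[0, 5, 5] and not tight.mask[0, 40, 8]
        assert tight.mask[0, 24, 24]
        # tight mask is exactly the loose mask minus sub-threshold
        # components (independent 4-connected relabeling)
        struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        lab, n = ndimage.label(loose.mask[0], structure=struct)
        expected = loose.mask[0].copy()
        for l in range(1, n + 1):
            comp = lab == l
            if comp.sum() < 4:
                expected &= ~comp
        np.testing.assert_array_equal(tight.mask[0], expected)


class TestPartitionRatio:
    def test_uniform_query_gives_ratio_one_everywhere(self, clean_stack):
        stack, truth = clean_stack
        flat = ImageStack(
            np.stack([stack.channel("marker"), np.full(stack.shape_zyx, 42.0)]),
            stack.pixel_size_um, stack.plane_spacing_um, ["marker", "query"],
        )
        res = granule_cytoplasm_ratio(
            flat, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        np.testing.assert_allclose(res.per_plane_ratio, 1.0, rtol=1e-12)
        assert res.sd_ratio == pytest.approx(0.0, abs=1e-12)

    def test_truth_masks_recover_planted_ratio_noise_off(self, clean_stack):
        stack, truth = clean_stack
        res = granule_cytoplasm_ratio(
            stack, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        assert abs(res.mean_ratio - 3.0) / 3.0 < 0.01

    def test_54_plane_stack_uses_at_most_54_planes(self):
        spec = GranuleImageSpec(n_nuclei=1, granules_per_nucleus=4, n_planes=54)
        stack, truth = generate_granule_image(spec, seed=1)
        res = granule_cytoplasm_ratio(
            stack, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        assert res.n_planes_used + res.n_planes_skipped == 54
        assert res.n_planes_used <= 54

    def test_agrees_with_pixel_loop_oracle_on_small_fixture(self):
        rng = np.random.default_rng(5)
        q = rng.uniform(1, 100, size=(3, 32, 32))
        gm = rng.random((3, 32, 32)) < 0.1
        cm = (rng.random((3, 32, 32)) < 0.5) & ~gm
        st = stack_from(np.stack([np.zeros_like(q), q]))
        res = granule_cytoplasm_ratio(st, "query", gm, cm)
        oracle = partition_ratio_pixel_loop(q, gm, cm & ~gm)
        np.testing.assert_allclose(res.per_plane_ratio, oracle, rtol=1e-12)

    def test_scale_invariance_and_additive_shift(self, clean_stack):
        """Multiplying the query channel leaves ratios unchanged; adding
        a constant moves each plane ratio to (g+c)/(cyt+c)."""
        stack, truth = clean_stack
        res = granule_cytoplasm_ratio(
            stack, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        scaled = ImageStack(stack.data * 3.7, stack.pixel_size_um,
                            stack.plane_spacing_um, stack.channel_names)
        res_s = granule_cytoplasm_ratio(
            scaled, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        np.testing.assert_allclose(res_s.per_plane_ratio, res.per_plane_ratio,
                                   rtol=1e-12)
        shifted = ImageStack(stack.data + 100.0, stack.pixel_size_um,
                             stack.plane_spacing_um, stack.channel_names)
        res_a = granule_cytoplasm_ratio(
            shifted, "query", truth.granule_mask, truth.cytoplasm_mask
        )
        # planted levels: granule 300, cytoplasm 100 -> (300+100)/(100+100)=2
        assert res_a.mean_ratio == pytest.approx(2.0, rel=1e-6)

    def test_disjointness_enforced_and_empty_result_raises(self, clean_stack):
        stack, truth = clean_stack
        with pytest.raises(ValueError):
            granule_cytoplasm_ratio(stack, "query", truth.granule_mask,
                                    truth.granule_mask)
        empty = np.zeros(stack.shape_zyx, dtype=bool)
        with pytest.raises(EmptyResultError):
            granule_cytoplasm_ratio(stack, "query", empty, truth.cytoplasm_mask)


class TestRingMetric:
    def test_uniform_intensity_gives_zero_sd(self):
        nuc = np.zeros((1, 32, 32), dtype=np.int32)
        nuc[0, 10:20, 10:20] = 1
        st = stack_from(np.full((2, 1, 32, 32), 13.0))
        profiles = perinuclear_ring_metric(st, "query", nuc, band_um=0.3)
        assert len(profiles) == 1
        assert profiles[0].sd == pytest.approx(0.0)

    def test_alternating_ring_values_give_population_sd(self):
        """Ring pixels alternating {10, 30} in equal numbers: the
        population SD is exactly 10."""
        nuc = np.zeros((1, 33, 33), dtype=np.int32)
        nuc[0, 12:21, 12:21] = 1
        img = np.zeros((2, 1, 33, 33))
        yy, xx = np.mgrid[:33, :33]
        img[1, 0] = np.where((yy + xx) % 2 == 0, 10.0, 30.0)
        st = stack_from(img)
        prof = perinuclear_ring_metric(st, "query", nuc, band_um=0.2)[0]
        vals, counts = np.unique(prof.intensities, return_counts=True)
        assert set(vals) == {10.0, 30.0}
        if counts[0] == counts[1]:
            assert prof.sd == pytest.approx(10.0)
        else:  # checkerboard parity may unbalance by a pixel; enumerate
            assert prof.sd == pytest.approx(
                float(np.std(prof.intensities, ddof=0))
            )

    def test_sd_increases_with_granule_contrast(self):
        sds = []
        for enrich in (1.0, 2.0, 4.0, 8.0):
            spec = GranuleImageSpec(
                n_nuclei=1, granules_per_nucleus=6, n_planes=9,
                query_enrichment_ratio=enrich, noise_model=dict(NOISE_OFF),
            )
            stack, truth = generate_granule_image(spec, seed=3)
            prof = perinuclear_ring_metric(
                stack, "query", truth.nucleus_masks, band_um=0.5
            )[0]
            sds.append(prof.sd)
        assert all(a < b for a, b in zip(sds, sds[1:]))

    def test_border_nucleus_flagged_as_clipped(self):
        nuc = np.zeros((1, 20, 20), dtype=np.int32)
        nuc[0, 0:8, 0:8] = 1
        st = stack_from(np.ones((2, 1, 20, 20)))
        prof = perinuclear_ring_metric(st, "query", nuc, band_um=0.3)[0]
        assert prof.clipped


class TestCondensatePartition:
    def test_uniform_query_gives_unit_ratios(self):
        stack, truth = generate_condensate_image(100.0, 100.0, seed=2,
                                                 gaussian_sd=0.0)
        inside, outside = default_condensate_rois(truth)
        res = condensate_partition_ratio(stack, "query", inside, outside,
                                         aggregate_exclusion=None)
        np.testing.assert_allclose(res.per_roi_ratio, 1.0, rtol=1e-9)

    def test_two_phase_truth_ratio_recovered(self):
        stack, truth = generate_condensate_image(500.0, 100.0, seed=4)
        inside, outside = default_condensate_rois(truth)
        assert len(inside) == len(outside) == 6
        res = condensate_partition_ratio(stack, "query", inside, outside)
        assert len(res.per_roi_ratio) == 6  # none excluded
        assert abs(res.mean_ratio - 5.0) / 5.0 < 0.10

    def test_aggregate_rois_are_excluded(self):
        stack, truth = generate_condensate_image(200.0, 100.0, seed=5)
        inside, outside = default_condensate_rois(truth)
        # paint a bright aggregate into the first inside ROI
        r0, c0 = (int(round(v / stack.pixel_size_um)) for v in inside[0][:2])
        stack.data[1, 0, r0 + 2 : r0 + 5, c0 + 2 : c0 + 5] = 50_000.0
        res = condensate_partition_ratio(stack, "query", inside, outside)
        assert (0, "aggregate") in res.excluded_rois
        assert len(res.per_roi_ratio) == 5

    def test_zero_dilute_phase_raises(self):
        stack, truth = generate_condensate_image(100.0, 0.0, seed=6,
                                                 gaussian_sd=0.0)
        inside, outside = default_condensate_rois(truth)
        with pytest.raises(ValueError):
            condensate_partition_ratio(stack, "query", inside, outside)


class TestGranuleCountVolume:
    def test_empty_mask_gives_zeros(self):
        nuc = np.zeros((5, 10, 10), dtype=np.int32)
        nuc[2, 4:6, 4:6] = 1
        stats_ = granule_count_volume(np.zeros((5, 10, 10), bool), 0.001, nuc)
        assert stats_.per_nucleus[0]["granule_count"] == 0
        assert stats_.per_nucleus[0]["total_volume_um3"] == 0.0

    def test_two_digital_spheres_counted_with_enumerated_volume(self):
        """Two disjoint lattice spheres (squared radius 7 -> 81 voxels
        each, enumerated) at voxel 0.1^3 um^3: count 2, volume 0.162."""
        shape = (16, 24, 24)
        mask = np.zeros(shape, dtype=bool)
        vox_a = digital_sphere_voxels((7, 6, 6), 7, shape)
        vox_b = digital_sphere_voxels((7, 17, 17), 7, shape)
        assert len(vox_a) == len(vox_b) == 81
        for v in vox_a + vox_b:
            mask[v] = True
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[7, 6, 6] = 1
        nuc[7, 17, 17] = 2
        stats_ = granule_count_volume(mask, 0.001, nuc)
        total = sum(s["total_volume_um3"] for s in stats_.per_nucleus)
        counts = [s["granule_count"] for s in stats_.per_nucleus]
        assert counts == [1, 1]
        assert total == pytest.approx(0.162)

    def test_overlapping_spheres_are_one_component(self):
        shape = (12, 20, 20)
        mask = np.zeros(shape, dtype=bool)
        for v in digital_sphere_voxels((6, 9, 8), 7, shape):
            mask[v] = True
        for v in digital_sphere_voxels((6, 9, 11), 7, shape):
            mask[v] = True
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[6, 9, 9] = 1
        stats_ = granule_count_volume(mask, 0.001, nuc)
        assert stats_.per_nucleus[0]["granule_count"] == 1


class TestColocalization:
    def test_perfect_and_inverted_correlation(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 100, size=(1, 4, 16, 16))
        st = ImageStack(np.concatenate([a, a]), 0.1, 0.1, ["a", "b"])
        mask = np.ones((4, 16, 16), bool)
        assert pearson_colocalization(st, "a", "b", mask) == pytest.approx(1.0)
        st2 = ImageStack(np.concatenate([a, 200 - a]), 0.1, 0.1, ["a", "b"])
        assert pearson_colocalization(st2, "a", "b", mask) == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.uniform(0, 100, size=(2, 1, 100, 100))
            st = ImageStack(data, 0.1, 0.1, ["a", "b"])
            rs.append(pearson_colocalization(st, "a", "b",
                                             np.ones((1, 100, 100), bool)))
        assert max(abs(r) for r in rs) < 0.05

    def test_zero_variance_raises(self):
        st = ImageStack(np.ones((2, 1, 8, 8)), 0.1, 0.1, ["a", "b"])
        with pytest.raises(ValueError):
            pearson_colocalization(st, "a", "b", np.ones((1, 8, 8), bool))


def test_cytoplasm_mask_excludes_nuclei_and_guarded_granules():
    nuc = np.zeros((1, 20, 20), dtype=np.int32)
    nuc[0, 2:8, 2:8] = 1
    gran = np.zeros((1, 20, 20), bool)
    gran[0, 12:14, 12:14] = True
    cyto = make_cytoplasm_mask(np.ones_like(gran), nuc, gran, guard_px=1)
    assert not cyto[0, 3, 3]
    assert not cyto[0, 12, 12]
    assert not cyto[0, 14, 13]  # guard band (1-px 4-connected dilation)
    assert cyto[0, 18, 2]
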