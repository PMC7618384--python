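"""Thresholding, masking, segmentation and counting: each operation against an
independent oracle, plus the counting invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from periquant.quantify import (
    ChannelThreshold,
    DegenerateHistogramError,
    NucleusROI,
    PlanesSpec,
    VesselMask,
    broaden_mask,
    classify_and_count,
    compute_threshold,
    evaluate_against_truth,
    isodata_threshold,
    make_vessel_mask,
    quantify_region,
    aggregate_region_images,
    segment_nuclei,
)
from periquant.simulate import (
    AcquisitionSpec,
    Cell,
    GroundTruth,
    MultiChannelVolume,
    Vessel,
    build_scene,
    render_volume,
)


def volume_from(arrs: dict, acq: AcquisitionSpec) -> MultiChannelVolume:
    shape = acq.shape_zyx
    channels = {
        ch: arrs.get(ch, np.zeros(shape, dtype=float))
        for ch in ("FITC", "tdTomato", "DAPI")
    }
    return MultiChannelVolume(channels=channels, acquisition=acq)


def isodata_oracle(values: np.ndarray) -> float:
    """Direct histogram fixed-point of the intermeans recursion."""
    t = values.mean()
    while True:
        lo, hi = values[values <= t], values[values > t]
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-9:
            return t_new
        t = t_new


class TestThresholds:
    def test_bimodal_image_threshold_separates_modes(self, small_acq):
        arr = np.zeros(small_acq.shape_zyx)
        arr[:, :10] = 100.0
        vol = volume_from({"FITC": arr}, small_acq)
        thr = compute_threshold(vol, "FITC", "auto")
        assert 0.0 < thr.value < 100.0

    def test_auto_matches_intermeans_fixed_point_oracle(self, rng):
        values = np.concatenate(
            [rng.normal(20, 3, 4000), rng.normal(90, 8, 1000)]
        ).clip(min=0)
        assert isodata_threshold(values) == pytest.approx(
            isodata_oracle(values), abs=1e-6
        )

    def test_auto_agrees_with_reference_histogram_isodata(self, rng):
        # independent cross-check against the 256-bin histogram implementation
        from skimage.filters import threshold_isodata

        values = np.concatenate(
            [rng.normal(30, 5, 5000), rng.normal(150, 10, 2000)]
        ).clip(min=0)
        bin_width = np.ptp(values) / 256
        assert isodata_threshold(values) == pytest.approx(
            threshold_isodata(values), abs=2 * bin_width
        )

    def test_constant_image_raises_degenerate_histogram(self, small_acq):
        vol = volume_from({"FITC": np.full(small_acq.shape_zyx, 5.0)}, small_acq)
        with pytest.raises(DegenerateHistogramError):
            compute_threshold(vol, "FITC", "auto")

    def test_cross_channel_copies_fitc_threshold_verbatim(self, small_acq):
        vol = volume_from({}, small_acq)
        fitc = ChannelThreshold(channel="FITC", method="manual", value=40.0)
        td = compute_threshold(
            vol, "tdTomato", "cross-channel", source_threshold=fitc
        )
        assert td.channel == "tdTomato"
        assert td.value == 40.0
        assert td.source_channel == "FITC"

    def test_manual_requires_value_and_cross_requires_source(self, small_acq):
        vol = volume_from({}, small_acq)
        with pytest.raises(ValueError):
            compute_threshold(vol, "FITC", "manual")
        with pytest.raises(ValueError):
            compute_threshold(vol, "tdTomato", "cross-channel")


class TestVesselMask:
    def test_threshold_above_max_gives_empty_mask(self, small_acq):
        vol = volume_from({"FITC": np.ones(small_acq.shape_zyx)}, small_acq)
        thr = ChannelThreshold(channel="FITC", method="manual", value=10.0)
        m = make_vessel_mask(vol, thr)
        assert not m.mask.any()
        assert np.all(m.plane_areas_um2 == 0.0)

    def test_mask_is_exactly_strict_exceedance(self, small_acq, rng):
        arr = rng.uniform(0, 10, small_acq.shape_zyx)
        vol = volume_from({"FITC": arr}, small_acq)
        thr = ChannelThreshold(channel="FITC", method="manual", value=5.0)
        np.testing.assert_array_equal(make_vessel_mask(vol, thr).mask, arr > 5.0)

    def test_cylinder_area_matches_rasterization_oracle(self, small_acq):
        # noise-free rendered cylinder: mid-vessel plane area vs voxel count
        bz, by, bx = (
            n * v for n, v in zip(small_acq.shape_zyx, small_acq.voxel_size_zyx)
        )
        vessel = Vessel(points_um=((bz / 2, 0.0, bx / 2), (bz / 2, by, bx / 2)),
                        radius_um=6.0)
        truth = GroundTruth(cells=(), vessels=(vessel,), bounds_zyx=(bz, by, bx))
        vol = render_volume(truth, small_acq, blur=False, noise=False)
        thr = ChannelThreshold(channel="FITC", method="manual", value=50.0)
        m = make_vessel_mask(vol, thr)
        mid = small_acq.shape_zyx[0] // 2
        # oracle: directly count voxel centres within the tube in that plane
        z = (mid + 0.5) * small_acq.voxel_size_zyx[0]
        ys = (np.arange(small_acq.shape_zyx[1]) + 0.5) * small_acq.voxel_size_zyx[1]
        xs = (np.arange(small_acq.shape_zyx[2]) + 0.5) * small_acq.voxel_size_zyx[2]
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        inside = (z - bz / 2) ** 2 + (xx - bx / 2) ** 2 <= 6.0**2
        oracle = inside.sum() * small_acq.pixel_area_um2
        assert m.plane_areas_um2[mid] == pytest.approx(oracle, rel=0.10)


def disk_cardinality_oracle(radius_px: int) -> int:
    """Exhaustive enumeration of the discrete L2 disk."""
    count = 0
    for dy in range(-radius_px, radius_px + 1):
        for dx in range(-radius_px, radius_px + 1):
            if dy * dy + dx * dx <= radius_px * radius_px:
                count += 1
    return count


class TestBroadenMask:
    def _single_voxel_mask(self, acq):
        m = np.zeros(acq.shape_zyx, dtype=bool)
        m[5, 30, 30] = True
        return VesselMask(mask=m, pixel_area_um2=acq.pixel_area_um2)

    def test_radius_zero_is_identity(self, small_acq):
        vm = self._single_voxel_mask(small_acq)
        out = broaden_mask(vm, 0.0, small_acq.voxel_size_zyx[2])
        np.testing.assert_array_equal(out.mask, vm.mask)
        assert out.broadened

    @pytest.mark.parametrize("radius_px", [1, 2, 3])
    def test_single_voxel_dilation_matches_disk_enumeration(self, small_acq, radius_px):
        vm = self._single_voxel_mask(small_acq)
        radius_um = radius_px * small_acq.voxel_size_zyx[2]
        out = broaden_mask(vm, radius_um, small_acq.voxel_size_zyx[2])
        assert out.mask.sum() == disk_cardinality_oracle(radius_px)
        assert out.mask[5].sum() == out.mask.sum()  # strictly in-plane

    def test_negative_radius_rejected(self, small_acq):
        with pytest.raises(ValueError):
            broaden_mask(self._single_voxel_mask(small_acq), -1.0, 0.62)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), radius_px=st.integers(0, 4))
    def test_dilation_is_extensive(self, seed, radius_px):
        acq = AcquisitionSpec(shape_zyx=(3, 32, 32))
        r = np.random.default_rng(seed)
        mask = r.random((3, 32, 32)) > 0.9
        vm = VesselMask(mask=mask, pixel_area_um2=acq.pixel_area_um2)
        out = broaden_mask(vm, radius_px * 0.62, 0.62)
        assert np.all(out.mask[mask])


def disk_image(acq, centers_px, radius_px=4, amplitude=100.0):
    arr = np.zeros(acq.shape_zyx)
    yy, xx = np.meshgrid(
        np.arange(acq.shape_zyx[1]), np.arange(acq.shape_zyx[2]), indexing="ij"
    )
    for (cy, cx) in centers_px:
        arr[0][(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2] = amplitude
    return arr


class TestSegmentNuclei:
    def test_blank_plane_yields_no_rois(self, small_acq):
        vol = volume_from({}, small_acq)
        assert segment_nuclei(vol, 0) == []

    def test_two_separated_disks_found_with_correct_area(self, small_acq):
        arr = disk_image(small_acq, [(20, 20), (20, 40)])
        vol = volume_from({"DAPI": arr}, small_acq)
        rois = segment_nuclei(vol, 0)
        assert len(rois) == 2
        rendered = disk_cardinality_oracle(4) * small_acq.pixel_area_um2
        for r in rois:
            assert r.area_um2 == pytest.approx(rendered, rel=0.15)

    def test_overlapping_disks_split_by_watershed(self, small_acq):
        # two disks whose rims overlap by ~2 px
        arr = disk_image(small_acq, [(20, 24), (20, 31)])
        vol = volume_from({"DAPI": arr}, small_acq)
        rois = segment_nuclei(vol, 0)
        assert len(rois) == 2

    def test_invalid_plane_index_raises(self, small_acq):
        vol = volume_from({}, small_acq)
        with pytest.raises(IndexError):
            segment_nuclei(vol, 99)


def make_roi(coords, acq, plane=0, roi_id=1):
    coords = np.asarray(coords)
    area = len(coords) * acq.pixel_area_um2
    cy, cx = coords.mean(axis=0)
    return NucleusROI(
        id=roi_id, plane=plane, coords=coords, area_um2=area,
        centroid_um=((cy + 0.5) * acq.voxel_size_zyx[1],
                     (cx + 0.5) * acq.voxel_size_zyx[2]),
    )


def square_roi(acq, y0, x0, side, **kw):
    coords = [(y, x) for y in range(y0, y0 + side) for x in range(x0, x0 + side)]
    return make_roi(coords, acq, **kw)


class TestClassifyAndCount:
    def test_small_roi_excluded_from_all_counts(self, small_acq):
        # 4x4 px at 0.62 um -> 6.1 um^2 < 10 um^2 floor
        shape = small_acq.shape_zyx[1:]
        roi = square_roi(small_acq, 10, 10, 4)
        full = np.ones(shape, dtype=bool)
        counts = classify_and_count([roi], full, full)
        assert (counts.n_nuclei, counts.n_tdtomato, counts.n_mural) == (0, 0, 0)

    def test_coexpression_overlap_counts_in_all_three(self, small_acq):
        shape = small_acq.shape_zyx[1:]
        roi = square_roi(small_acq, 10, 10, 6)  # 13.8 um^2
        td = np.zeros(shape, dtype=bool)
        td[10:20, 10:20] = True
        vessel = np.zeros(shape, dtype=bool)
        vessel[12:30, 12:30] = True
        counts = classify_and_count([roi], td, vessel)
        assert (counts.n_nuclei, counts.n_tdtomato, counts.n_mural) == (1, 1, 1)

    def test_empty_tdtomato_mask_zeroes_classified_counts(self, small_acq):
        shape = small_acq.shape_zyx[1:]
        rois = [square_roi(small_acq, 10, 10, 6, roi_id=1),
                square_roi(small_acq, 30, 30, 6, roi_id=2)]
        empty = np.zeros(shape, dtype=bool)
        full = np.ones(shape, dtype=bool)
        counts = classify_and_count(rois, empty, full)
        assert (counts.n_nuclei, counts.n_tdtomato, counts.n_mural) == (2, 0, 0)

    def test_overlap_fraction_threshold_applies(self, small_acq):
        shape = small_acq.shape_zyx[1:]
        roi = square_roi(small_acq, 10, 10, 6)
        td = np.zeros(shape, dtype=bool)
        td[10:16, 10:13] = True  # covers half the ROI
        vessel = np.ones(shape, dtype=bool)
        half = classify_and_count([roi], td, vessel, overlap_frac=0.5)
        assert half.n_tdtomato == 1
        strict = classify_and_count([roi], td, vessel, overlap_frac=0.6)
        assert strict.n_tdtomato == 0

    def test_shape_mismatch_rejected(self, small_acq):
        roi = square_roi(small_acq, 10, 10, 6)
        with pytest.raises(ValueError):
            classify_and_count(
                [roi], np.zeros((10, 10), bool), np.zeros((20, 20), bool)
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_count_ordering_invariant_on_random_inputs(self, seed):
        """n_mural <= n_tdtomato <= n_nuclei for arbitrary masks and ROIs."""
        acq = AcquisitionSpec(shape_zyx=(1, 48, 48))
        r = np.random.default_rng(seed)
        shape = (48, 48)
        rois = []
        for i in range(r.integers(0, 8)):
            y0, x0 = r.integers(0, 40, size=2)
            side = int(r.integers(2, 8))
            rois.append(square_roi(acq, int(y0), int(x0), side, roi_id=i + 1))
        td = r.random(shape) > r.uniform(0.2, 0.95)
        vessel = r.random(shape) > r.uniform(0.2, 0.95)
        counts = classify_and_count(rois, td, vessel)
        assert counts.n_mural <= counts.n_tdtomato <= counts.n_nuclei

    def test_mural_count_nondecreasing_in_broaden_radius(self, small_acq):
        truth = build_scene(
            dataclasses.replace(
                build_default_scene_for(small_acq), seed=21
            )
        )
        vol = render_volume(truth, small_acq, seed=3)
        prev = -1
        for radius in (0.0, 2.0, 5.0, 8.0):
            q = quantify_region(vol, broaden_radius_um=radius,
                                planes_spec=PlanesSpec(n_planes=3, spacing_um=8.0))
            n_mural = sum(p.n_mural for p in q.per_plane)
            assert n_mural >= prev
            prev = n_mural


def build_default_scene_for(acq):
    from periquant.simulate import SceneSpec

    bz, by, bx = (n * v for n, v in zip(acq.shape_zyx, acq.voxel_size_zyx))
    vessel = Vessel(points_um=((bz / 2, 0.0, bx / 2), (bz / 2, by, bx / 2)))
    return SceneSpec(bounds_zyx=(bz, by, bx), vessels=(vessel,),
                     mural_density=8.0, fibroblast_density=4.0)


class TestQuantifyRegion:
    def test_default_planes_spec_selects_five_planes_8um_apart(self, default_acq):
        planes = PlanesSpec().select(default_acq)
        assert len(planes) == 5
        zs = [default_acq.plane_z_um(p) for p in planes]
        assert np.allclose(np.diff(zs), 8.0)

    def test_unrepresentable_spacing_rejected(self, default_acq):
        with pytest.raises(ValueError):
            PlanesSpec(spacing_um=5.0).select(default_acq)  # z_step = 2 um

    def test_planes_outside_stack_rejected(self):
        acq = AcquisitionSpec(shape_zyx=(4, 32, 32))
        with pytest.raises(ValueError):
            PlanesSpec(n_planes=5, spacing_um=8.0).select(acq)

    def test_identical_planes_average_to_single_plane_counts(self, small_acq):
        # constant-in-z volume: every plane gives the same counts
        arr = np.zeros(small_acq.shape_zyx)
        arr[:] = disk_image(small_acq, [(20, 20), (40, 40)])[0]
        vol = volume_from(
            {"DAPI": arr, "tdTomato": arr, "FITC": arr}, small_acq
        )
        q = quantify_region(
            vol,
            planes_spec=PlanesSpec(n_planes=3, spacing_um=2.0),
            broaden_radius_um=0.0,
        )
        per_plane = [p.n_nuclei for p in q.per_plane]
        assert len(set(per_plane)) == 1
        assert q.mean("n_nuclei") == per_plane[0]

    def test_two_image_region_averages_the_image_averages(self, small_acq):
        arrs = []
        for n_disks in (2, 3):
            centers = [(15 + 15 * i, 15 + 15 * i) for i in range(n_disks)]
            arrs.append(disk_image(small_acq, centers))
        quants = []
        for arr in arrs:
            full = np.tile(arr[0], (small_acq.shape_zyx[0], 1, 1))
            vol = volume_from({"DAPI": full, "tdTomato": full, "FITC": full},
                              small_acq)
            quants.append(
                quantify_region(vol, planes_spec=PlanesSpec(2, 2.0),
                                broaden_radius_um=0.0)
            )
        agg = aggregate_region_images(quants)
        assert agg["n_nuclei"] == pytest.approx(
            (quants[0].mean("n_nuclei") + quants[1].mean("n_nuclei")) / 2
        )

    def test_region_params_logged(self, small_acq):
        truth = build_scene(build_default_scene_for(small_acq))
        vol = render_volume(truth, small_acq, seed=1)
        q = quantify_region(vol, planes_spec=PlanesSpec(3, 8.0))
        for key in ("fitc_threshold", "tdtomato_threshold", "broaden_radius_um",
                    "min_area_um2", "overlap_frac"):
            assert key in q.params
        assert q.params["tdtomato_method"] == "cross-channel"


class TestEvaluateAgainstTruth:
    def test_exact_recovery_on_clean_volume(self, default_acq):
        """Noise- and blur-free rendering with well-separated nuclei is
        recovered exactly, plane by plane."""
        acq = dataclasses.replace(default_acq, background=(0.0, 0.0, 0.0))
        planes = PlanesSpec().select(acq)
        bz, by, bx = (n * v for n, v in zip(acq.shape_zyx, acq.voxel_size_zyx))
        vessel = Vessel(points_um=((bz / 2, 0.0, bx / 2), (bz / 2, by, bx / 2)))
        cells = []
        cid = 0
        # mural cells centred exactly on the central analysed plane
        z_mid = acq.plane_z_um(planes[2])
        for y in (15.0, 45.0, 75.0):
            cells.append(Cell(cid, "mural",
                              (z_mid, y, bx / 2 + vessel.radius_um + 1.0),
                              (2.2, 3.0, 2.6), 1.0))
            cid += 1
        # fibroblasts centred on other analysed planes, far from the vessel
        for p, y in [(planes[1], 20.0), (planes[3], 60.0)]:
            cells.append(Cell(cid, "fibroblast",
                              (acq.plane_z_um(p), y, 12.0), (2.2, 3.0, 2.6), 30.0))
            cid += 1
        truth = GroundTruth(cells=tuple(cells), vessels=(vessel,),
                            bounds_zyx=(bz, by, bx))
        vol = render_volume(truth, acq, blur=False, noise=False)
        q = quantify_region(vol)
        # per-plane counts equal ground-truth cells intersecting each plane
        for pc in q.per_plane:
            z = acq.plane_z_um(pc.plane)
            true_here = [
                c for c in cells
                if abs(z - c.centroid_um[0]) < c.axes_um[0]
            ]
            assert pc.n_nuclei == len(true_here)
            assert pc.n_tdtomato == len(true_here)
            assert pc.n_mural == sum(c.cls == "mural" for c in true_here)
        scores = evaluate_against_truth(q, truth, acq)
        assert scores["mural"].precision == 1.0
        assert scores["mural"].recall == 1.0
        assert scores["tdtomato"].f1 == 1.0

    def test_zero_predictions_give_zero_recall(self, default_acq):
        truth = build_scene(build_default_scene_for(
            dataclasses.replace(default_acq)
        ))
        blank = ChannelThreshold(channel="FITC", method="manual", value=1.0)
        empty = quantify_region(
            volume_from({}, default_acq), fitc_threshold=blank,
            broaden_radius_um=5.0, planes_spec=PlanesSpec(),
        )
        scores = evaluate_against_truth(empty, truth, default_acq)
        assert scores["tdtomato"].recall == 0.0

    def test_constructed_confusion_counts(self, default_acq):
        """3 TP, 1 FP, 1 FN -> precision = recall = 0.75."""
        from periquant.quantify import ClassScores

        s = ClassScores(tp=3, fp=1, fn=1)
        assert s.precision == 0.75
        assert s.recall == 0.75
        assert s.f1 == pytest.approx(0.75)

    def test_greedy_matching_is_one_to_one(self):
        from periquant.quantify import _greedy_match

        # two predictions near one true cell: only one may match
        assert _greedy_match([(0.0, 0.0), (1.0, 0.0)], [(0.5, 0.0)], 5.0) == 1
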