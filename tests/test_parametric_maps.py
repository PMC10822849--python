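"""Window planning, map assembly and 224x224 rendering."""

import numpy as np
import pytest

import qusresponse as q
from qusresponse.parametric_maps import ParametricMap, plan_windows, render_map_image


def rect_roi(height_mm=10.0, width_mm=10.0, spacing=0.1, depth_offset=0.0):
    """Rectangular all-core ROI spanning exactly height x width mm."""
    rows, cols = int(height_mm / spacing) + 1, int(width_mm / spacing) + 1
    core = np.ones((rows, cols), dtype=bool)
    return q.ROIMask(core=core, margin=np.zeros_like(core), axial_spacing_mm=spacing,
                     lateral_spacing_mm=spacing, depth_offset_mm=depth_offset)


class TestPlanWindows:
    def test_94_percent_overlap_of_2p2mm_blocks_steps_0p132mm(self, pulse):
        plan = plan_windows(rect_roi(), pulse, overlap=0.94, block_side_mm=2.2)
        assert plan.step_mm == pytest.approx(0.132)
        assert plan.block_side_mm == 2.2

    def test_ten_wavelength_rule_when_no_explicit_side(self, pulse):
        plan = plan_windows(rect_roi(), pulse, sound_speed=1540.0, overlap=0.5, block_side_mm=None)
        assert plan.block_side_mm == pytest.approx(10 * 1540.0 / 6e6 * 1e3)  # ~2.57 mm

    def test_zero_overlap_tiles_10mm_roi_with_25_blocks(self, pulse):
        plan = plan_windows(rect_roi(10.0, 10.0), pulse, overlap=0.0, block_side_mm=2.0)
        assert plan.n_blocks == 25

    def test_every_block_footprint_intersects_roi(self, tiny_cohort, pulse):
        # brute-force geometric check on a real (elliptical) ROI
        roi = tiny_cohort.patients[0].rois[0]
        plan = plan_windows(roi, pulse, overlap=0.5)
        half = plan.block_side_mm / 2
        combined = roi.combined
        for a, l in plan.centers:
            r0 = max(0, int((a - half - roi.depth_offset_mm) / roi.axial_spacing_mm))
            r1 = int((a + half - roi.depth_offset_mm) / roi.axial_spacing_mm) + 1
            c0 = max(0, int((l - half) / roi.lateral_spacing_mm))
            c1 = int((l + half) / roi.lateral_spacing_mm) + 1
            assert combined[r0:r1, c0:c1].any()

    def test_roi_smaller_than_block_rejected(self, pulse):
        with pytest.raises(q.InsufficientSupportError):
            plan_windows(rect_roi(1.0, 1.0), pulse, overlap=0.0, block_side_mm=2.2)

    def test_bad_overlap_rejected(self, pulse):
        with pytest.raises(q.ValidationError):
            plan_windows(rect_roi(), pulse, overlap=1.0)


class TestBuildMaps:
    def test_frame_equal_to_reference_gives_null_ss_map(self, pulse, reference_frame, phantom):
        core = np.ones((reference_frame.n_samples, reference_frame.n_lines), dtype=bool)
        roi = q.ROIMask(core=core, margin=np.zeros_like(core),
                        axial_spacing_mm=reference_frame.axial_spacing_mm,
                        lateral_spacing_mm=reference_frame.lateral_spacing_mm,
                        depth_offset_mm=reference_frame.depth_offset_mm)
        plan = plan_windows(roi, pulse, overlap=0.5)
        config = q.QUSMapConfig(
            alpha_sample_db_mhz_cm=phantom.attenuation_db_mhz_cm,
            phantom=q.PhantomSpec(
                attenuation_db_mhz_cm=phantom.attenuation_db_mhz_cm,
                sound_speed=pulse.sound_speed,  # same grid: frame is its own reference
                bead_radius_um=phantom.bead_radius_um,
                bead_density_per_mm2=phantom.bead_density_per_mm2,
            ),
            overlap=0.5, max_invalid_fraction=1.0, reference_gating="matched",
        )
        maps = q.build_maps(reference_frame, reference_frame, roi, plan, config)
        ss = maps["SS"]
        assert ss.valid.sum() > 0
        assert np.all(np.abs(ss.values[ss.valid]) < 0.2)

    def test_maps_share_plan_and_validity(self, homogeneous_maps):
        plans = {id(m.plan) for m in homogeneous_maps.values()}
        assert len(plans) == 1
        valid = [m.valid for m in homogeneous_maps.values()]
        for v in valid[1:]:
            np.testing.assert_array_equal(v, valid[0])
        centers = [m.plan.centers for m in homogeneous_maps.values()]
        assert all(c == centers[0] for c in centers)

    def test_homogeneous_tumor_ss_map_has_no_structure_beyond_speckle(
        self, homogeneous_maps, pulse, small_geometry, reference_frame, full_roi
    ):
        # oracle = repeat-simulation spread: the in-map dispersion of SS must
        # be explained by per-block speckle noise measured across two
        # independent realizations of the same homogeneous medium
        ss = homogeneous_maps["SS"]
        vals = ss.values[ss.valid]
        rng = np.random.default_rng(77)
        fieldspec = q.homogeneous_field(small_geometry, 8.0, 28.0, 1.0, rng)
        frame2 = q.simulate_rf_frame(fieldspec, pulse, 1.0, small_geometry, seed=78, snr_db=30)
        config = q.QUSMapConfig(alpha_sample_db_mhz_cm=1.0, overlap=0.5, max_invalid_fraction=0.8)
        maps2 = q.build_maps(frame2, reference_frame, full_roi, ss.plan, config)
        both = ss.valid & maps2["SS"].valid
        sigma_block = np.std(ss.values[both] - maps2["SS"].values[both]) / np.sqrt(2)
        assert np.std(vals) < 1.5 * sigma_block

    def test_two_region_tumor_core_asd_exceeds_margin_asd(self, pulse, reference_frame,
                                                          small_geometry):
        rng = np.random.default_rng(31)
        geom = small_geometry
        bg = q.homogeneous_field(geom, 8.0, 20.0, 1.0, rng)
        center = (14.0, 3.0)
        inside = (((bg.positions[:, 0] - center[0]) / 3.0) ** 2
                  + ((bg.positions[:, 1] - center[1]) / 2.0) ** 2) <= 1.0
        n_core = int(8.0 * np.pi * 3.0 * 2.0)
        theta = rng.uniform(0, 2 * np.pi, n_core)
        r = np.sqrt(rng.uniform(0, 1, n_core))
        core_pos = np.column_stack([center[0] + 3.0 * r * np.cos(theta),
                                    center[1] + 2.0 * r * np.sin(theta)])
        pos = np.vstack([bg.positions[~inside], core_pos])
        radii = np.concatenate([np.full((~inside).sum(), 20.0), np.full(n_core, 32.0)])
        frame = q.simulate_rf_frame(
            q.ScattererField(positions=pos, effective_radius_um=radii), pulse, 1.0, geom,
            seed=5, snr_db=30,
        )
        ax = frame.depth_offset_mm + np.arange(frame.n_samples) * frame.axial_spacing_mm
        lat = np.arange(frame.n_lines) * frame.lateral_spacing_mm
        core_mask = ((ax[:, None] - center[0]) / 3.0) ** 2 + ((lat[None, :] - center[1]) / 2.0) ** 2 <= 1.0
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~core_mask, sampling=(frame.axial_spacing_mm, frame.lateral_spacing_mm))
        margin = (dist <= 3.0) & ~core_mask
        roi = q.ROIMask(core=core_mask, margin=margin, axial_spacing_mm=frame.axial_spacing_mm,
                        lateral_spacing_mm=frame.lateral_spacing_mm, depth_offset_mm=frame.depth_offset_mm)
        plan = plan_windows(roi, pulse, overlap=0.5)
        config = q.QUSMapConfig(alpha_sample_db_mhz_cm=1.0, overlap=0.5, max_invalid_fraction=0.8)
        maps = q.build_maps(frame, reference_frame, roi, plan, config)
        asd = maps["ASD"]
        in_core, in_margin = [], []
        for i, a in enumerate(asd.plan.axial_centers_mm):
            for j, l in enumerate(asd.plan.lateral_centers_mm):
                if not asd.valid[i, j]:
                    continue
                dc = ((a - center[0]) / 3.0) ** 2 + ((l - center[1]) / 2.0) ** 2
                (in_core if dc <= 0.5 else in_margin if dc > 1.2 else []).append(asd.values[i, j])
        assert np.median(in_core) > np.median(in_margin)


class TestRenderMapImage:
    def test_constant_map_renders_constant_image(self, homogeneous_maps, full_roi):
        base = homogeneous_maps["MBF"]
        const = ParametricMap("MBF", np.full_like(base.values, 4.2),
                              np.ones_like(base.valid), base.plan)
        img = render_map_image(const, full_roi)
        assert img.pixels.shape == (224, 224)
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_output_is_exactly_224_by_224_with_3_channel_replication(self, homogeneous_maps, full_roi):
        img = render_map_image(homogeneous_maps["SS"], full_roi)
        assert img.pixels.shape == (224, 224)
        arr = img.to_3channel()
        assert arr.shape == (224, 224, 3)
        for c in range(3):
            np.testing.assert_array_equal(arr[:, :, c], img.pixels)

    def test_nearest_neighbour_upsampled_map_renders_alike(self, homogeneous_maps, full_roi):
        # smooth fully-valid surrogate map: resampling differences are pure
        # interpolation error, bounded by the surface's cell-to-cell change
        ii, jj = np.meshgrid(np.linspace(0, 1, 33), np.linspace(0, 1, 49), indexing="ij")
        smooth = ii + jj + 0.3 * np.sin(2 * np.pi * ii)
        valid = np.ones_like(smooth, dtype=bool)
        plan = q.WindowPlan(2.2, 1.1, np.arange(33, dtype=float), np.arange(49, dtype=float),
                            valid.copy())
        a = render_map_image(ParametricMap("MBF", smooth, valid, plan), full_roi).pixels
        up = ParametricMap(
            "MBF",
            np.repeat(np.repeat(smooth, 2, axis=0), 2, axis=1),
            np.repeat(np.repeat(valid, 2, axis=0), 2, axis=1),
            q.WindowPlan(
                block_side_mm=plan.block_side_mm,
                step_mm=plan.step_mm / 2,
                axial_centers_mm=np.repeat(plan.axial_centers_mm, 2),
                lateral_centers_mm=np.repeat(plan.lateral_centers_mm, 2),
                inclusion=np.repeat(np.repeat(valid, 2, axis=0), 2, axis=1),
            ),
        )
        b = render_map_image(up, full_roi).pixels
        assert np.max(np.abs(a - b)) < 0.05

    def test_rendering_is_idempotent(self, homogeneous_maps, full_roi):
        ss = homogeneous_maps["SS"]
        first = render_map_image(ss, full_roi).pixels
        as_map = ParametricMap(
            "SS", first, np.ones_like(first, dtype=bool),
            q.WindowPlan(1.0, 1.0, np.arange(224, dtype=float), np.arange(224, dtype=float),
                         np.ones((224, 224), dtype=bool)),
        )
        second = render_map_image(as_map, full_roi).pixels
        assert np.max(np.abs(second - first)) < 0.05

    def test_pixels_outside_roi_are_exactly_zero(self, tiny_cohort, reference_frame, pulse):
        patient = tiny_cohort.patients[0]
        frame, roi = patient.frames[0], patient.rois[0]
        plan = plan_windows(roi, pulse, overlap=0.5)
        config = q.QUSMapConfig(alpha_sample_db_mhz_cm=1.0, overlap=0.5, max_invalid_fraction=0.9)
        ref = q.make_reference_frame(config.phantom, pulse, tiny_cohort.config.geometry, seed=71)
        maps = q.build_maps(frame, ref, roi, plan, config)
        img = render_map_image(maps["SS"], roi)
        # unsupported corners of the resized raster must be exactly zero
        mask = maps["SS"].valid & maps["SS"].plan.inclusion
        rows = np.any(mask, axis=1).nonzero()[0]
        cols = np.any(mask, axis=0).nonzero()[0]
        sub = maps["SS"].plan.inclusion[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
        from skimage.transform import resize
        support = resize(sub.astype(float), (224, 224), order=1, mode="edge", anti_aliasing=False)
        assert np.all(img.pixels[support <= 0.0] == 0.0)
        assert (support <= 0.0).sum() > 0  # the ellipse leaves real corners

    def test_all_invalid_map_cannot_render(self, homogeneous_maps, full_roi):
        base = homogeneous_maps["SS"]
        dead = ParametricMap("SS", base.values, np.zeros_like(base.valid), base.plan)
        with pytest.raises(q.ValidationError):
            render_map_image(dead, full_roi)
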