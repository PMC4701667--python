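import math

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from wormbench.patterns import (
    DEFAULT_BLUR_SIGMA_UM,
    CorrugatedChannel,
    Disk,
    Frame,
    GridMismatchError,
    MaskBitmap,
    OutOfFieldError,
    PatternExtentError,
    PillarArray,
    PolygonSpec,
    ProjectionTransform,
    Spiral,
    StrokeStream,
    TMaze,
    apply_optical_blur,
    cured_footprint,
    dmd_to_world,
    fit_corner_radius,
    rasterize,
    stitch,
    stroke_to_mask_updates,
    world_to_dmd,
)


class TestProjectionTransform:
    def test_origin_maps_to_center_pixel(self, t5):
        row, col = world_to_dmd((0.0, 0.0), t5)
        assert (row, col) == t5.center_pixel

    def test_round_trip_identity(self, t5, rng):
        xmin, ymin, xmax, ymax = t5.field_bounds()
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, 1000), rng.uniform(ymin, ymax, 1000)]
        )
        errs = []
        for p in pts:
            rc = world_to_dmd(p, t5)
            back = dmd_to_world(rc, t5)
            errs.append(math.hypot(back[0] - p[0], back[1] - p[1]))
        assert max(errs) < 1e-6

    def test_affine_column_offset(self, t5):
        # oracle: stepping +x by k pixels-worth of μm advances col by exactly k,
        # checked by brute-force accumulation of single-pixel steps
        s = t5.sample_um_per_dmd_px
        _, col0 = world_to_dmd((0.0, 0.0), t5)
        col_expected = col0
        for k in range(1, 101):
            col_expected += 1
            _, col = world_to_dmd((k * s, 0.0), t5)
            assert col == pytest.approx(col_expected, abs=1e-9)

    def test_out_of_field_raises(self, t5):
        w, h = t5.field_extent_um
        with pytest.raises(OutOfFieldError):
            world_to_dmd((w, 0.0), t5)

    def test_invalid_transform_rejected(self):
        with pytest.raises(ValueError):
            ProjectionTransform(5, -1.0)
        with pytest.raises(ValueError):
            ProjectionTransform(5, 1.0, dmd_shape=(0, 10))

    def test_y_down_convention(self, t5):
        row_up, _ = world_to_dmd((0.0, 100.0), t5)
        row_dn, _ = world_to_dmd((0.0, -100.0), t5)
        assert row_up < t5.center_pixel[0] < row_dn


class TestRasterize:
    def test_empty_polygon_is_all_zero(self, t5):
        mask = rasterize(PolygonSpec(), t5)
        assert not mask.pixels.any()

    def test_deterministic_bit_exact(self, t5):
        spec = TMaze(1200, 2000, 300, 150, 350)
        a = rasterize(spec, t5)
        b = rasterize(spec, t5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_mask_is_binary(self, t5):
        mask = rasterize(Disk((0, 0), 500), t5)
        assert mask.pixels.dtype == bool

    def test_disc_diameter(self, fine_grid):
        mask = rasterize(Disk((0, 0), 50), fine_grid)
        rows, cols = np.nonzero(mask.pixels)
        extent_x = (cols.max() - cols.min() + 1) * fine_grid.sample_um_per_dmd_px
        extent_y = (rows.max() - rows.min() + 1) * fine_grid.sample_um_per_dmd_px
        px = fine_grid.sample_um_per_dmd_px
        assert abs(extent_x - 100) <= px
        assert abs(extent_y - 100) <= px

    def test_pillar_array_paper_config_diameter_and_spacing(self):
        # 100 μm discs at 100 μm centre-to-centre (touching); disc centres are
        # recovered independently as distance-transform peaks
        tr = ProjectionTransform(5, 2.0, dmd_shape=(400, 400))
        spec = PillarArray(diameter=100, pitch=100, region=(-300, -300, 300, 300))
        mask = rasterize(spec, tr)
        um = tr.sample_um_per_dmd_px
        edt = distance_transform_edt(mask.pixels) * um
        # disc centres = per-component maxima of the thresholded EDT
        from scipy.ndimage import label as cc_label

        labels, n = cc_label(edt > 45.0)
        centers = []
        for i in range(1, n + 1):
            rows, cols = np.nonzero(labels == i)
            k = np.argmax(edt[rows, cols])
            x, y = dmd_to_world((rows[k], cols[k]), tr)
            centers.append((x, y))
            # measured radius at the disc centre ≈ 50 μm (EDT to the nearest
            # background pixel centre under-reads by up to ~1.5 px)
            assert edt[rows[k], cols[k]] == pytest.approx(50.0, abs=1.5 * um)
        centers = np.array(centers)
        assert len(centers) >= 9
        # nearest-neighbour spacing = 100 μm ± 1 px
        from scipy.spatial.distance import cdist

        d = cdist(centers, centers)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1), 100.0, atol=um)

    def test_pillar_count_matches_enumeration_oracle(self):
        # brute-force oracle: walk the lattice anchored at (xmin+r, ymin+r)
        # and count discs entirely inside the region
        region = (-2350.0, -1350.0, 2350.0, 1350.0)  # 5x3 mm frame interior
        diameter, pitch = 100.0, 100.0

        def oracle_count():
            xmin, ymin, xmax, ymax = region
            r = diameter / 2
            n = 0
            y = ymin + r
            while y + r <= ymax + 1e-9:
                x = xmin + r
                while x + r <= xmax + 1e-9:
                    n += 1
                    x += pitch
                y += pitch
            return n

        spec = PillarArray(diameter=diameter, pitch=pitch, region=region)
        assert len(spec.centers()) == oracle_count()

    def test_pitch_below_diameter_rejected(self):
        with pytest.raises(ValueError):
            PillarArray(diameter=100, pitch=80, region=(0, 0, 1000, 1000))

    def test_extent_error_without_clip(self, t5):
        big = Frame(outer_w=8000, outer_h=8000, wall_thickness=150)
        with pytest.raises(PatternExtentError):
            rasterize(big, t5)
        rasterize(big, t5, allow_clip=True)  # stitching path

    def test_resolution_convergence(self):
        # rasterizing at half the μm/px and 2x2-downsampling differs from the
        # direct raster only on boundary pixels
        spec = Disk((0, 0), 300)
        coarse_tr = ProjectionTransform(5, 10.0, dmd_shape=(100, 100))
        coarse = rasterize(spec, coarse_tr).pixels
        fine_tr = ProjectionTransform(5, 5.0, dmd_shape=(200, 200))
        fine = rasterize(spec, fine_tr).pixels
        down = fine.reshape(100, 2, 100, 2).mean(axis=(1, 3)) >= 0.5
        from scipy.ndimage import binary_dilation, binary_erosion

        boundary = binary_dilation(coarse) & ~binary_erosion(coarse)
        disagree = coarse != down
        assert disagree.sum() <= boundary.sum()
        assert not (disagree & ~boundary).any()

    def test_walls_are_exposed_lumen_is_not(self, t5):
        maze = TMaze(1200, 2000, 300, 150, 350)
        mask = rasterize(maze, t5)
        # lumen centre (junction) is clear, wall midpoint is exposed
        jr, jc = world_to_dmd((0.0, 0.0), t5)
        assert not mask.pixels[round(jr), round(jc)]
        wr, wc = world_to_dmd((0.0, 150.0 + 75.0), t5)
        assert mask.pixels[round(wr), round(wc)]

    @pytest.mark.parametrize(
        "spec",
        [
            Frame(outer_w=3000, outer_h=2000, wall_thickness=150),
            Spiral(turns=2, channel_width=200, wall_thickness=100),
            CorrugatedChannel(length=3000, width=200, ripple_amplitude=30, ripple_period=400),
        ],
    )
    def test_variants_rasterize_nonempty(self, t5, spec):
        assert rasterize(spec, t5).pixels.any()


class TestStitch:
    def test_single_mask_identity(self, t5):
        mask = rasterize(Disk((0, 0), 300), t5)
        occ = stitch([(mask, (0.0, 0.0))])
        assert occ.area_um2() == pytest.approx(
            mask.pixels.sum() * t5.sample_um_per_dmd_px**2
        )

    def test_idempotent_same_mask_twice(self, t5):
        mask = rasterize(Disk((0, 0), 300), t5)
        once = stitch([(mask, (0.0, 0.0))])
        twice = stitch([(mask, (0.0, 0.0)), (mask, (0.0, 0.0))])
        assert np.array_equal(once.grid, twice.grid)

    def test_abutting_frames_no_seam(self):
        # oracle: direct rasterization of the doubled-width pattern; the
        # shared edge sits between pixel centres so the tiles truly abut
        tr = ProjectionTransform(5, 10.0, dmd_shape=(400, 400))
        half = PolygonSpec(vertices=((-995, -200), (5, -200), (5, 200), (-995, 200)))
        m = rasterize(half, tr)
        occ = stitch([(m, (0.0, 0.0)), (m, (1000.0, 0.0))])
        full = PolygonSpec(vertices=((-995, -200), (1005, -200), (1005, 200), (-995, 200)))
        direct = rasterize(full, tr)
        direct_occ = stitch([(direct, (0.0, 0.0))])
        assert occ.area_um2() == pytest.approx(direct_occ.area_um2(), rel=0.01)
        # every column across the stitched wall is occupied: no seam gap
        x = occ.col_x()
        span = (x > -990) & (x < 1000)
        assert occ.grid[:, span].any(axis=0).all()

    def test_union_algebra(self, t5):
        a = rasterize(Disk((-200, 0), 150), t5)
        b = rasterize(Disk((200, 0), 150), t5)
        ab = stitch([(a, (0.0, 0.0)), (b, (0.0, 0.0))])
        ba = stitch([(b, (0.0, 0.0)), (a, (0.0, 0.0))])
        assert ab.area_um2() == ba.area_um2()  # commutative
        aab = stitch([(a, (0.0, 0.0)), (a, (0.0, 0.0)), (b, (0.0, 0.0))])
        assert aab.area_um2() == ab.area_um2()  # idempotent

    def test_grid_mismatch_raises(self):
        a = rasterize(Disk((0, 0), 150), ProjectionTransform.for_objective(5))
        b = rasterize(Disk((0, 0), 150), ProjectionTransform.for_objective(20))
        with pytest.raises(GridMismatchError):
            stitch([(a, (0.0, 0.0)), (b, (0.0, 0.0))])
        stitch([(a, (0.0, 0.0)), (b, (0.0, 0.0))], resample=True)


class TestStrokes:
    def test_empty_stream(self, t5):
        assert stroke_to_mask_updates(StrokeStream(events=()), t5) == []

    def test_times_must_be_ordered(self):
        with pytest.raises(ValueError):
            StrokeStream(events=((0, 0, 1.0), (1, 1, 0.5)))

    def test_latency_delay(self, t5):
        stream = StrokeStream(events=((0.0, 0.0, 2.0),), brush_radius_tablet=2500)
        (t_proj, _), = stroke_to_mask_updates(stream, t5)
        assert t_proj == pytest.approx(2.25)

    def test_fifty_fold_reduction(self):
        # tablet stroke of length L projects to L/50 (within 2%)
        tr = ProjectionTransform(5, 1.0, dmd_shape=(600, 2400))
        tablet_len = 100_000.0
        ev = tuple((x, 0.0, i * 0.05) for i, x in enumerate(np.linspace(-tablet_len / 2, tablet_len / 2, 50)))
        stream = StrokeStream(events=ev, brush_radius_tablet=2500.0)
        updates = stroke_to_mask_updates(stream, tr)
        acc = updates[0][1]
        for _, m in updates[1:]:
            acc = acc.union(m)
        pts = acc.set_pixel_world_coords()
        r_world = 2500.0 / 50.0
        measured = (pts[:, 0].max() - pts[:, 0].min()) - 2 * r_world
        assert measured == pytest.approx(tablet_len / 50.0, rel=0.02)

    def test_dot_sequence_k_stamps(self, t5):
        k = 7
        ev = tuple((i * 20000.0 - 60000.0, 0.0, i * 0.5) for i in range(k))
        stream = StrokeStream(events=ev, brush_radius_tablet=2500.0)
        updates = stroke_to_mask_updates(stream, t5)
        assert len(updates) == k
        for i, (t_proj, _) in enumerate(updates):
            assert t_proj == pytest.approx(i * 0.5 + 0.25)

    def test_out_of_field_event_skipped_with_warning(self, t5):
        ev = ((0.0, 0.0, 0.0), (1e9, 0.0, 1.0))
        with pytest.warns(UserWarning):
            updates = stroke_to_mask_updates(StrokeStream(events=ev, brush_radius_tablet=2500), t5)
        assert len(updates) == 1

    def test_cumulative_or_consistency(self, t5):
        ev = tuple((x, 0.0, i * 0.1) for i, x in enumerate(np.linspace(0, 40000, 10)))
        updates = stroke_to_mask_updates(StrokeStream(events=ev, brush_radius_tablet=2500), t5)
        acc = np.zeros(t5.dmd_shape, dtype=bool)
        counts = []
        for _, m in updates:
            acc |= m.pixels
            counts.append(acc.sum())
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestOpticalBlur:
    def test_zero_width_limit_reproduces_mask(self, fine_grid):
        mask = rasterize(Disk((0, 0), 60), fine_grid)
        dose = apply_optical_blur(mask, sigma_um=1e-9)
        assert np.array_equal(cured_footprint(dose), mask.pixels)

    def test_corner_radius_5x_default(self, fine_grid):
        spec = PolygonSpec(vertices=((-190, -190), (0, -190), (0, 0), (-190, 0)))
        mask = rasterize(spec, fine_grid)
        dose = apply_optical_blur(mask, objective=5)
        r = fit_corner_radius(dose, fine_grid, (0.0, 0.0), sigma_um=DEFAULT_BLUR_SIGMA_UM[5])
        assert r == pytest.approx(10.0, abs=2.0)

    @pytest.mark.parametrize("sigma", [2.0, 5.0, 10.0])
    def test_straight_edge_half_crossing(self, fine_grid, sigma):
        # 1-D profile oracle: blurring a half-plane leaves the 0.5 crossing
        # on the ideal edge (within 1 px) by symmetry
        spec = PolygonSpec(vertices=((-190, -190), (0, -190), (0, 190), (-190, 190)))
        mask = rasterize(spec, fine_grid)
        dose = apply_optical_blur(mask, sigma_um=sigma)
        mid_row = fine_grid.dmd_shape[0] // 2
        profile = dose[mid_row]
        edge_col = fine_grid.center_pixel[1]  # right edge of the slab at x=0
        # find the 0.5 crossing on the right edge only
        search = slice(edge_col - 50, edge_col + 50)
        crossing_col = int(np.argmin(np.abs(profile[search] - 0.5))) + search.start
        assert abs(crossing_col - edge_col) <= 1

    def test_unknown_objective_needs_sigma(self, fine_grid):
        mask = rasterize(Disk((0, 0), 60), fine_grid)
        with pytest.raises(KeyError):
            apply_optical_blur(mask, objective=7)
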