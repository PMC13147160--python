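"""Motility metric oracles: set-difference areas, centroids, shape indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from coldmotility import (
    CellTrack,
    centroid,
    centroid_displacement,
    circularity_index,
    compute_motility,
    deformation_area,
    perimeter,
)
from conftest import disk_mask


def brute_force_gained(a, b):
    """Exhaustive pixel enumeration of |B \\ A|."""
    count = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            if b[r, c] and not a[r, c]:
                count += 1
    return count


class TestDeformationArea:
    def test_identical_masks_zero(self, make_disk):
        m = make_disk(10)
        assert deformation_area(m, m) == 0.0

    def test_translated_square_gained_equals_lost(self):
        a = np.zeros((30, 30), dtype=bool)
        a[10:20, 5:15] = True
        b = np.roll(a, 3, axis=1)
        assert deformation_area(a, b, 1.0) == 30.0
        assert deformation_area(b, a, 1.0) == 30.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            a = rng.random((50, 50)) > 0.5
            b = rng.random((50, 50)) > 0.5
            assert deformation_area(a, b) == brute_force_gained(a, b)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        a=arrays(bool, (12, 12), elements=st.booleans()),
        b=arrays(bool, (12, 12), elements=st.booleans()),
    )
    def test_set_identities(self, a, b):
        """A_CD(A,B) = |B| - |A n B|, hence A_CD(A,B) + |A n B| = |B|."""
        gained = deformation_area(a, b)
        assert gained >= 0
        assert gained + np.count_nonzero(a & b) == np.count_nonzero(b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            deformation_area(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_pixel_size_scales_area(self):
        a = np.zeros((10, 10), bool)
        b = a.copy()
        b[2:4, 2:4] = True
        assert deformation_area(a, b, 0.5) == 4 * 0.25


class TestCentroid:
    def test_single_pixel_definition(self):
        m = np.zeros((8, 8), bool)
        m[3, 5] = True
        assert np.allclose(centroid(m, 2.0), [(5 + 0.5) * 2, (3 + 0.5) * 2])

    def test_centered_disk_at_field_center(self, make_disk):
        m = make_disk(20, shape=(81, 81), center=(40, 40))
        c = centroid(m, 1.0)
        assert np.linalg.norm(c - [40.5, 40.5]) < 0.5

    def test_union_linearity(self, make_disk):
        shape = (60, 120)
        a = disk_mask(10, shape, (30, 30))
        b = disk_mask(10, shape, (30, 90))
        ca, cb = centroid(a), centroid(b)
        assert np.allclose(centroid(a | b), (ca + cb) / 2, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centroid(np.zeros((4, 4), bool))


def track_from_centers(centers, radius=8, shape=(200, 200)):
    masks = {t: disk_mask(radius, shape, c) for t, c in enumerate(centers)}
    return CellTrack(cell_id=0, masks=masks)


class TestCentroidDisplacement:
    def test_stationary_all_zero(self):
        tr = track_from_centers([(50, 50)] * 19)
        assert centroid_displacement(tr, 20.0) == pytest.approx([0.0, 0.0])

    def test_ballistic_cell_speed_times_interval(self):
        # 1 um/min at 1 um/px, 20-s frames -> 1/3 px per frame, 3 px per 3 min
        centers = [(50, 30 + t) for t in range(0, 19)]  # 1 px/frame = 3 um/min
        tr = track_from_centers(centers)
        disp = centroid_displacement(tr, 20.0, pixel_size_um=1.0)
        assert disp == pytest.approx([9.0, 9.0], abs=0.05)

    def test_non_divisible_interval_rejected(self):
        tr = track_from_centers([(50, 50)] * 19)
        with pytest.raises(ValueError, match="divisible"):
            centroid_displacement(tr, 25.0, interval_s=180.0)

    def test_short_track_rejected(self):
        tr = track_from_centers([(50, 50)] * 5)
        with pytest.raises(ValueError, match="shorter"):
            centroid_displacement(tr, 20.0)


class TestPerimeter:
    def test_disk_within_3pct_of_analytic(self, make_disk):
        m = make_disk(50, shape=(120, 120))
        assert perimeter(m, 1.0) == pytest.approx(100 * np.pi, rel=0.03)

    def test_square_within_10pct_of_analytic(self):
        m = np.zeros((40, 40), bool)
        m[15:25, 15:25] = True
        assert perimeter(m, 1.0) == pytest.approx(40.0, rel=0.10)

    def test_scaling_doubles_length(self, make_disk):
        m = make_disk(30, shape=(120, 120))
        m2 = np.kron(m, np.ones((2, 2), dtype=bool))  # nearest-neighbor x2
        ratio = perimeter(m2) / perimeter(m)
        assert 1.9 <= ratio <= 2.1

    def test_multi_component_rejected(self):
        m = np.zeros((40, 80), bool)
        m[disk_mask(8, (40, 80), (20, 20))] = True
        m[disk_mask(8, (40, 80), (20, 60))] = True
        with pytest.raises(ValueError, match="components"):
            perimeter(m)

    def test_crofton_option(self, make_disk):
        m = make_disk(50, shape=(120, 120))
        assert perimeter(m, 1.0, method="crofton") == pytest.approx(100 * np.pi, rel=0.03)


class TestCircularity:
    def test_disk_near_one(self, make_disk):
        assert circularity_index(make_disk(50, (120, 120))) == pytest.approx(1.0, rel=0.06)

    def test_square_closed_form(self):
        m = np.zeros((140, 140), bool)
        m[20:120, 20:120] = True
        assert circularity_index(m) == pytest.approx(4 / np.pi, rel=0.10)

    def test_rectangle_closed_form(self):
        m = np.zeros((140, 260), bool)
        m[20:120, 20:220] = True
        assert circularity_index(m) == pytest.approx(9 / (2 * np.pi), rel=0.10)

    def test_pixel_size_invariance_exact(self, make_disk):
        m = make_disk(25)
        assert circularity_index(m, 0.25) == pytest.approx(circularity_index(m, 2.0), rel=1e-12)


class TestComputeMotility:
    def test_translation_gained_equals_lost_per_pair(self):
        centers = [(60, 30 + 2 * t) for t in range(19)]
        tr = track_from_centers(centers)
        rec = compute_motility(tr, frame_interval_s=20.0, pixel_size_um=1.0)
        for (t0, t1), gained in zip(rec.interval_pairs, rec.acd_um2):
            lost = deformation_area(tr.masks[t1], tr.masks[t0], 1.0)
            assert gained == lost

    def test_summaries_are_means_of_listed_values(self):
        centers = [(60, 30 + 2 * t) for t in range(19)]
        rec = compute_motility(track_from_centers(centers), 20.0, pixel_size_um=1.0)
        assert rec.summaries["mean_acd_um2"] == pytest.approx(np.mean(rec.acd_um2))
        assert rec.summaries["mean_displacement_um"] == pytest.approx(np.mean(rec.displacement_um))
        assert rec.summaries["mean_circularity"] == pytest.approx(np.mean(rec.circularity))
        assert rec.summaries["n_pairs"] == len(rec.interval_pairs)

    def test_px_units_when_pixel_size_absent(self):
        rec = compute_motility(track_from_centers([(50, 50)] * 19), 20.0, pixel_size_um=None)
        assert rec.units == "px"

    def test_excluded_track_rejected_without_override(self):
        tr = track_from_centers([(50, 50)] * 19)
        tr.inclusion_flags = {"full_duration": False, "in_field": True, "non_overlapping": True}
        with pytest.raises(ValueError, match="inclusion"):
            compute_motility(tr, 20.0)
        rec = compute_motility(tr, 20.0, require_included=False)
        assert rec.summaries["n_pairs"] == 2

    def test_mean_acd_increases_with_protrusion_amplitude(self):
        """Parameter recovery at small n: stronger protrusions, larger A_CD."""
        from coldmotility import MotilitySimConfig, rasterize_movie

        means = []
        for amp in (0.1, 0.4):
            cfg = MotilitySimConfig(
                n_cells=6, n_frames=19, field_size_px=(420, 420),
                protrusion_amplitude=amp, seed=31,
            )
            stack, truth = rasterize_movie(cfg)
            vals = []
            for cid, lab in truth.labels.items():
                masks = {t: stack[t] == lab for t in range(cfg.n_frames)}
                rec = compute_motility(
                    CellTrack(cell_id=cid, masks=masks),
                    cfg.frame_interval_s,
                    cfg.pixel_size_um,
                )
                vals.append(rec.summaries["mean_acd_um2"])
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_mean_displacement_increases_with_speed(self):
        from coldmotility import MotilitySimConfig, rasterize_movie

        means = []
        for speed in (0.5, 2.5):
            cfg = MotilitySimConfig(
                n_cells=6, n_frames=19, field_size_px=(420, 420),
                mean_speed_um_per_min=speed, seed=32,
            )
            stack, truth = rasterize_movie(cfg)
            vals = []
            for cid, lab in truth.labels.items():
                masks = {t: stack[t] == lab for t in range(cfg.n_frames)}
                rec = compute_motility(
                    CellTrack(cell_id=cid, masks=masks), cfg.frame_interval_s, cfg.pixel_size_um
                )
                vals.append(rec.summaries["mean_displacement_um"])
            means.append(np.mean(vals))
        assert means[1] > means[0]
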