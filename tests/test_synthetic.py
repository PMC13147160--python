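"""Generator contracts: determinism, ballistic limit, shape/area calibration."""

import numpy as np
import pytest

from coldmotility import (
    MotilitySimConfig,
    bh_adjust,
    rasterize_movie,
    simulate_de_table,
    simulate_flux_trace,
    simulate_shape_series,
    simulate_track,
)
from coldmotility.motility import centroid


def polygon_area_by_integration(contour: np.ndarray) -> float:
    """Independent oracle: numerically integrate r(theta)^2 / 2 dtheta."""
    r2 = (contour**2).sum(axis=1)
    dtheta = 2 * np.pi / len(contour)
    return 0.5 * float(r2.sum()) * dtheta


class TestShapeSeries:
    def test_zero_amplitude_is_exact_circle(self):
        cfg = MotilitySimConfig(n_cells=1, protrusion_amplitude=0.0, seed=3)
        contours = simulate_shape_series(cfg, 0)
        radii = np.linalg.norm(contours, axis=2)
        assert np.allclose(radii, cfg.base_radius_um)

    def test_determinism(self):
        cfg = MotilitySimConfig(n_cells=2, protrusion_amplitude=0.3, seed=1)
        assert np.array_equal(simulate_shape_series(cfg, 0), simulate_shape_series(cfg, 0))

    def test_adding_cells_does_not_perturb_earlier_cells(self):
        small = MotilitySimConfig(n_cells=2, seed=9)
        big = MotilitySimConfig(n_cells=5, seed=9)
        assert np.array_equal(simulate_shape_series(small, 1), simulate_shape_series(big, 1))
        assert np.array_equal(simulate_track(small, 1), simulate_track(big, 1))

    def test_time_averaged_area_matches_integration_oracle(self):
        cfg = MotilitySimConfig(n_cells=1, protrusion_amplitude=0.3, n_frames=60, seed=11)
        contours = simulate_shape_series(cfg, 0)
        areas = [polygon_area_by_integration(c) for c in contours]
        expected = np.pi * cfg.base_radius_um**2
        assert np.mean(areas) == pytest.approx(expected, rel=0.10)

    def test_extreme_amplitude_clamps_radius_with_warning(self):
        cfg = MotilitySimConfig(n_cells=1, protrusion_amplitude=3.0, seed=5)
        with pytest.warns(RuntimeWarning, match="clamp"):
            contours = simulate_shape_series(cfg, 0)
        radii = np.linalg.norm(contours, axis=2)
        assert radii.min() >= 0.2 * cfg.base_radius_um - 1e-12
        for c in contours:  # every contour still encloses positive area
            assert polygon_area_by_integration(c) > 0


class TestTrack:
    def test_zero_speed_constant_path(self):
        cfg = MotilitySimConfig(n_cells=1, mean_speed_um_per_min=0.0, seed=2)
        path = simulate_track(cfg, 0)
        assert np.allclose(path, path[0])

    def test_ballistic_limit_exact(self):
        cfg = MotilitySimConfig(n_cells=1, persistence=1.0, mean_speed_um_per_min=2.5, seed=4)
        path = simulate_track(cfg, 0)
        T = (cfg.n_frames - 1) * cfg.frame_interval_s / 60.0  # minutes
        assert np.linalg.norm(path[-1] - path[0]) == pytest.approx(2.5 * T, abs=1e-9)
        # collinear: all segments parallel
        steps = np.diff(path, axis=0)
        cross = steps[:-1, 0] * steps[1:, 1] - steps[:-1, 1] * steps[1:, 0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_pooled_mean_speed_matches_configured(self):
        cfg = MotilitySimConfig(n_cells=200, mean_speed_um_per_min=2.0, persistence=0.5, seed=6)
        speeds = []
        for i in range(cfg.n_cells):
            path = simulate_track(cfg, i)
            d = np.linalg.norm(np.diff(path, axis=0), axis=1)
            speeds.append(d / (cfg.frame_interval_s / 60.0))
        assert np.mean(np.concatenate(speeds)) == pytest.approx(2.0, rel=0.05)


class TestRasterize:
    def test_single_disk_area(self):
        # radius 10 px at 0.25 um/px -> base radius 2.5 um
        cfg = MotilitySimConfig(
            n_cells=1, n_frames=2, protrusion_amplitude=0.0,
            mean_speed_um_per_min=0.0, base_radius_um=2.5, field_size_px=(64, 64), seed=8,
        )
        stack, _ = rasterize_movie(cfg)
        assert stack[0].astype(bool).sum() == pytest.approx(np.pi * 100, rel=0.04)

    def test_no_touching_labels(self):
        cfg = MotilitySimConfig(n_cells=4, n_frames=10, field_size_px=(300, 300), seed=12)
        stack, _ = rasterize_movie(cfg)
        from scipy.ndimage import binary_dilation

        for frame in stack:
            for lab in np.unique(frame)[1:]:
                grown = binary_dilation(frame == lab, structure=np.ones((3, 3)))
                assert not np.any(grown & (frame != 0) & (frame != lab))

    def test_mask_centroid_matches_ground_truth(self):
        cfg = MotilitySimConfig(
            n_cells=1, n_frames=5, protrusion_amplitude=0.0,
            mean_speed_um_per_min=1.0, field_size_px=(128, 128), seed=13,
        )
        stack, truth = rasterize_movie(cfg)
        for t in range(cfg.n_frames):
            c = centroid(stack[t] == truth.labels[0], cfg.pixel_size_um)
            err_px = np.linalg.norm(c - truth.paths_um[0][t]) / cfg.pixel_size_um
            assert err_px <= 1.0

    def test_overcrowded_field_raises(self):
        cfg = MotilitySimConfig(n_cells=6, n_frames=5, field_size_px=(48, 48), seed=14)
        with pytest.raises(ValueError, match="field|place"):
            rasterize_movie(cfg, max_placement_retries=20)


class TestFluxTrace:
    LEVELS = {"basal": 50.0, "oligomycin": 20.0, "FCCP": 120.0, "rotAA": 10.0}

    def test_noiseless_trace_equals_levels(self):
        tr = simulate_flux_trace(self.LEVELS, noise_sd=0.0)
        for phase, lvl in self.LEVELS.items():
            assert np.allclose(tr.loc[tr.phase == phase, "ocr"], lvl)

    def test_determinism(self):
        a = simulate_flux_trace(self.LEVELS, noise_sd=2.0, seed=3)
        b = simulate_flux_trace(self.LEVELS, noise_sd=2.0, seed=3)
        assert a.equals(b)

    def test_phase_means_within_3_se(self):
        n = 5
        traces = [
            simulate_flux_trace(self.LEVELS, n_cycles_per_phase=n, noise_sd=2.0, seed=s)
            for s in range(40)
        ]
        pooled = {p: np.concatenate([t.loc[t.phase == p, "ocr"] for t in traces]) for p in self.LEVELS}
        for phase, lvl in self.LEVELS.items():
            se = 2.0 / np.sqrt(len(pooled[phase]))
            assert abs(pooled[phase].mean() - lvl) < 3 * se

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            simulate_flux_trace({**self.LEVELS, "FCCP": -1.0})


class TestDETable:
    def test_determinism(self):
        assert simulate_de_table(500, 20, 20, seed=1).equals(simulate_de_table(500, 20, 20, seed=1))

    def test_spiked_genes_clear_thresholds(self):
        tab = simulate_de_table(1000, 50, 40, lfc_effect=2.5, seed=2)
        strong = tab[tab.pvalue < 1e-6]
        assert (strong.log2fc.abs() >= 2.5).all()
        assert (strong.log2fc > 0).sum() == 50 and (strong.log2fc < 0).sum() == 40

    def test_null_tables_are_fdr_controlled(self):
        """Over 20 seeded null replicates, <= 8% of genes pass BH at 0.05."""
        fracs = []
        for s in range(20):
            tab = simulate_de_table(2000, 0, 0, seed=s)
            padj = bh_adjust(tab.pvalue.to_numpy())
            fracs.append(np.mean(padj < 0.05))
        assert np.mean(fracs) <= 0.08

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_de_table(10, 6, 6)
        with pytest.raises(ValueError):
            simulate_de_table(10, 1, 1, lfc_effect=0.5)
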