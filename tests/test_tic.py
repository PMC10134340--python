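import numpy as np
import pytest

from ceustic import phantom as ph
from ceustic import tic as ctic
from ceustic.io import ROIMask, VideoSequence


def square_mask(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return ROIMask(m)


class TestSubdivideRoi:
    def test_exact_tiling_square(self):
        grid = ctic.subdivide_roi(square_mask((128, 128), 10, 10, 64, 64),
                                  cell_side=32, min_coverage=0.5)
        assert len(grid) == 4
        assert all(c.n_pixels == 32 * 32 for c in grid.cells)

    def test_partial_cells_dropped_above_half_coverage(self):
        # 48x32 rectangle, s=32: second row of tiles covers 16/32 rows = 0.5
        mask = square_mask((128, 128), 10, 10, 48, 32)
        grid_strict = ctic.subdivide_roi(mask, 32, min_coverage=0.6)
        assert len(grid_strict) == 1  # the fully covered cell only
        grid_half = ctic.subdivide_roi(mask, 32, min_coverage=0.5)
        assert len(grid_half) == 2  # >= rule keeps the exactly-half cell

    def test_disk_matches_brute_force(self):
        shape = (128, 128)
        rr, cc = np.mgrid[:128, :128]
        disk = (rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2
        s, cov = 16, 0.5
        grid = ctic.subdivide_roi(ROIMask(disk), s, cov)
        # brute force: same anchored tiling, count covered cells directly
        rows = np.flatnonzero(disk.any(axis=1))
        cols = np.flatnonzero(disk.any(axis=0))
        expected = 0
        for r0 in range(rows[0], rows[-1] + 1, s):
            for c0 in range(cols[0], cols[-1] + 1, s):
                if disk[r0:r0 + s, c0:c0 + s].sum() / s**2 >= cov:
                    expected += 1
        assert len(grid) == expected

    def test_cells_disjoint_and_inside_roi(self):
        rr, cc = np.mgrid[:96, :96]
        disk = (rr - 48) ** 2 + (cc - 48) ** 2 <= 30**2
        grid = ctic.subdivide_roi(ROIMask(disk), 16, 0.5)
        seen = set()
        for cell in grid.cells:
            for p in zip(cell.rows.tolist(), cell.cols.tolist()):
                assert p not in seen  # disjoint
                assert disk[p]  # inside ROI 1
                seen.add(p)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ctic.subdivide_roi(ROIMask(np.zeros((32, 32), bool)), 8)

    def test_unreachable_coverage_advises_smaller_cell(self):
        with pytest.raises(ValueError, match="smaller cell_side"):
            ctic.subdivide_roi(square_mask((64, 64), 5, 5, 6, 6), 32, 0.5)


class TestExtractTic:
    def test_constant_video(self):
        video = VideoSequence(np.full((10, 8, 8), 7.0), np.arange(10) / 5.0)
        curve = ctic.extract_tic(video, square_mask((8, 8), 2, 2, 4, 4))
        np.testing.assert_allclose(curve.intensities, 7.0)

    def test_two_pixel_mean(self):
        frames = np.zeros((5, 4, 4))
        frames[:, 1, 1] = 4.0
        frames[:, 2, 2] = 6.0
        video = VideoSequence(frames, np.arange(5) / 5.0)
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        curve = ctic.extract_tic(video, m)
        np.testing.assert_allclose(curve.intensities, 5.0)

    def test_noiseless_phantom_region_equals_bolus(self, noiseless_phantom):
        video = noiseless_phantom["video"]
        mass = noiseless_phantom["masks"]["mass"]
        cls = noiseless_phantom["mass_class"]
        curve = ctic.extract_tic(video, mass)
        expected = ph.bolus_intensity(curve.times, cls)
        np.testing.assert_allclose(curve.intensities, expected, atol=1e-4)

    def test_times_injection_relative(self):
        video = VideoSequence(np.zeros((5, 4, 4)), 10.0 + np.arange(5) / 5.0,
                              t_inject=10.0)
        curve = ctic.extract_tic(video, square_mask((4, 4), 0, 0, 2, 2))
        np.testing.assert_allclose(curve.times, np.arange(5) / 5.0)

    def test_empty_region_rejected(self):
        video = VideoSequence(np.zeros((2, 4, 4)), [0.0, 0.2])
        with pytest.raises(ValueError, match="empty"):
            ctic.extract_tic(video, np.zeros((4, 4), bool))

    def test_per_cell_conservation(self, noiseless_phantom):
        # exact tiling: pixel-count-weighted cell means == whole-ROI mean
        video = noiseless_phantom["video"]
        mask = square_mask((64, 64), 8, 8, 32, 32)
        grid = ctic.subdivide_roi(mask, 16, 0.5)
        whole = ctic.extract_tic(video, mask)
        weighted = np.zeros(video.n_frames)
        total = 0
        for cell in grid.cells:
            weighted += ctic.extract_tic(video, cell).intensities * cell.n_pixels
            total += cell.n_pixels
        assert total == mask.n_pixels
        np.testing.assert_allclose(weighted / total, whole.intensities, rtol=1e-6)


class TestPreprocess:
    def test_flat_curve_maps_to_zero(self):
        c = ctic.TICCurve(np.arange(20.0), np.full(20, 5.0))
        out = ctic.preprocess_tic(c, baseline_window=(0, 4), smoothing_window=3)
        np.testing.assert_allclose(out.intensities, 0.0)
        assert out.baseline == 5.0

    def test_window_one_is_baseline_subtraction_only(self):
        y = np.array([5.0, 5.0, 8.0, 12.0, 6.0])
        c = ctic.TICCurve(np.arange(5.0), y)
        out = ctic.preprocess_tic(c, baseline_window=(0, 1), smoothing_window=1)
        np.testing.assert_allclose(out.intensities, y - 5.0)

    def test_triangle_moving_average_hand_computed(self):
        y = np.array([0.0, 5.0, 10.0, 5.0, 0.0])
        c = ctic.TICCurve(np.arange(5.0), y + 2.0)
        out = ctic.preprocess_tic(c, baseline_window=(0, 0), smoothing_window=3)
        # baseline = 2; interior: moving averages of [0,5,10,5,0]
        np.testing.assert_allclose(out.intensities, [2.5, 5.0, 20 / 3, 5.0, 2.5])

    def test_clipped_at_zero(self):
        c = ctic.TICCurve(np.arange(4.0), np.array([5.0, 3.0, 2.0, 1.0]))
        out = ctic.preprocess_tic(c, baseline_window=(0, 0), smoothing_window=1)
        assert (out.intensities >= 0).all()

    def test_idempotent_on_processed_flat_curve(self):
        c = ctic.TICCurve(np.arange(10.0), np.zeros(10), preprocessed=True,
                          baseline_window=(0.0, 2.0), smoothing_window=1)
        out = ctic.preprocess_tic(c, baseline_window=(0, 2), smoothing_window=1)
        np.testing.assert_allclose(out.intensities, c.intensities)

    def test_baseline_window_outside_support_rejected(self):
        c = ctic.TICCurve(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="baseline window"):
            ctic.preprocess_tic(c, baseline_window=(-10, -6))


def _processed(times, values, **kw):
    defaults = dict(preprocessed=True, baseline_window=(0.0, 1.0),
                    smoothing_window=1)
    defaults.update(kw)
    return ctic.TICCurve(np.asarray(times, float), np.asarray(values, float),
                         **defaults)


class TestTicFeatures:
    def test_identical_curves_zero_difference(self):
        t = np.arange(0.0, 91.0)
        y = np.interp(t, [0, 30, 90], [0, 20, 0])
        f = ctic.tic_features(_processed(t, y), _processed(t, y))
        assert f.pd == 0.0 and f.rpd == 0.0

    def test_triangle_worked_example(self):
        # mass: 0 -> 10 over [0, 20], back to 0 at 90; parenchyma peak 25
        t = np.arange(0.0, 91.0)
        mass = np.interp(t, [0, 20, 90], [0.0, 10.0, 0.0])
        paren = np.interp(t, [0, 20, 90], [0.0, 25.0, 0.0])
        f = ctic.tic_features(_processed(t, mass), _processed(t, paren))
        assert f.ttp_s == 20.0
        assert f.pi == 10.0
        assert f.pd == -15.0
        assert f.rpd == pytest.approx(-0.6)
        assert f.auc == pytest.approx(0.5 * 90.0 * 10.0)  # triangle area 450

    def test_noiseless_phantom_recovers_analytic_peak(self, noiseless_phantom):
        video = noiseless_phantom["video"]
        masks = noiseless_phantom["masks"]
        mass = ctic.preprocess_tic(ctic.extract_tic(video, masks["mass"]),
                                   baseline_window=(0, 5))
        paren = ctic.preprocess_tic(ctic.extract_tic(video, masks["parenchyma"]),
                                    baseline_window=(0, 5))
        f = ctic.tic_features(mass, paren, t_end=90.0)
        assert abs(f.ttp_s - 25.0) <= 0.2  # one frame interval at 5 fps
        assert f.pi == pytest.approx(100.0, abs=1e-4)

    def test_hypoenhanced_mass_negative_pd_rpd(self, default_phantom_small):
        # default malignant kinetics: amplitude ratio 0.5 vs parenchyma
        video = default_phantom_small["video"]
        masks = default_phantom_small["masks"]
        mass = ctic.preprocess_tic(ctic.extract_tic(video, masks["mass"]),
                                   baseline_window=(0, 5))
        paren = ctic.preprocess_tic(ctic.extract_tic(video, masks["parenchyma"]),
                                    baseline_window=(0, 5))
        f = ctic.tic_features(mass, paren)
        assert f.pd < 0 and f.rpd < 0

    def test_ttp_tie_breaks_to_first(self):
        t = np.arange(0.0, 10.0)
        y = np.array([0, 1, 5, 5, 5, 2, 1, 0, 0, 0.0])
        f = ctic.tic_features(_processed(t, y), _processed(t, y))
        assert f.ttp_s == 2.0

    def test_zero_parenchyma_peak_flags_rpd(self):
        t = np.arange(0.0, 10.0)
        f = ctic.tic_features(_processed(t, np.ones(10)),
                              _processed(t, np.zeros(10)))
        assert np.isnan(f.rpd)
        assert not f.rpd_defined

    def test_time_shift_invariance(self):
        t = np.arange(0.0, 60.0)
        mass = np.interp(t, [0, 15, 60], [0.0, 8.0, 0.0])
        paren = np.interp(t, [0, 10, 60], [0.0, 12.0, 0.0])
        f1 = ctic.tic_features(_processed(t, mass), _processed(t, paren), t_end=60)
        # consistent shift of both time axes beyond t=0 keeps PI/PD/RPD
        f2 = ctic.tic_features(_processed(t + 5, mass), _processed(t + 5, paren),
                               t_end=65)
        assert f2.pi == f1.pi and f2.pd == f1.pd and f2.rpd == f1.rpd
        assert f2.ttp_s == f1.ttp_s + 5.0

    def test_unpreprocessed_curves_rejected(self):
        t = np.arange(0.0, 5.0)
        raw = ctic.TICCurve(t, np.ones(5))
        with pytest.raises(ValueError, match="preprocessed"):
            ctic.tic_features(raw, raw)

    def test_mismatched_preprocessing_rejected(self):
        t = np.arange(0.0, 5.0)
        a = _processed(t, np.ones(5), baseline_window=(0.0, 1.0))
        b = _processed(t, np.ones(5), baseline_window=(0.0, 2.0))
        with pytest.raises(ValueError, match="different preprocessing"):
            ctic.tic_features(a, b)


class TestTrapezoidAuc:
    def test_matches_analytic_integral_within_one_percent(self, noiseless_phantom):
        video = noiseless_phantom["video"]
        masks = noiseless_phantom["masks"]
        cls = noiseless_phantom["mass_class"]
        mass = ctic.preprocess_tic(ctic.extract_tic(video, masks["mass"]),
                                   baseline_window=(0, 5))
        paren = ctic.preprocess_tic(ctic.extract_tic(video, masks["parenchyma"]),
                                    baseline_window=(0, 5))
        f = ctic.tic_features(mass, paren, t_end=90.0)
        analytic = ph.gamma_variate_auc(cls, 90.0)
        assert abs(f.auc - analytic) / analytic < 0.01
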