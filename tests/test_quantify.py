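"""CRET quantification: hot-pixel repair, ROI flux, ratios, statistics."""

import numpy as np
import pytest
from scipy import stats

from cret.imaging import AcquisitionMeta, FilteredImage, filter_set, read_acquisition
from cret.quantify import (
    BandFluxPair,
    Roi,
    calculated_cret_image,
    correct_hot_pixels,
    cret_ratio,
    cret_ratio_replicates,
    linear_fit,
    ratio_image,
    roi_flux,
    roi_ratio_mean,
    two_sample_t,
)


def _image(pixels):
    return FilteredImage(np.asarray(pixels, dtype=float),
                         filter_set()["blue"], AcquisitionMeta(exposure_s=1.0))


class TestHotPixelCorrection:
    def test_single_spike_on_constant_background(self):
        pixels = np.full((16, 16), 5.0)
        pixels[7, 9] = 500.0
        fixed, coords = correct_hot_pixels(_image(pixels))
        assert coords.tolist() == [[7, 9]]
        assert fixed.pixels[7, 9] == pytest.approx(5.0)
        untouched = np.delete(fixed.pixels.ravel(), 7 * 16 + 9)
        assert np.all(untouched == 5.0)

    def test_smooth_gradient_untouched(self):
        rr, cc = np.mgrid[0:32, 0:32]
        pixels = 3.0 + 0.5 * rr + 0.25 * cc
        fixed, coords = correct_hot_pixels(_image(pixels))
        assert coords.shape[0] == 0
        assert np.array_equal(fixed.pixels, pixels)

    def test_recovery_on_simulator_fixture(self, hot_pixel_fixture):
        clean, corrupted, injected = hot_pixel_fixture
        fixed, flagged = correct_hot_pixels(corrupted)
        injected_set = set(map(tuple, injected.tolist()))
        flagged_set = set(map(tuple, flagged.tolist()))
        assert len(injected_set & flagged_set) >= 0.95 * len(injected_set)
        rmse_before = np.sqrt(((corrupted.pixels - clean.pixels) ** 2).mean())
        rmse_after = np.sqrt(((fixed.pixels - clean.pixels) ** 2).mean())
        assert rmse_after <= 0.1 * rmse_before

    def test_no_false_positives_on_clean_fixture(self, hot_pixel_fixture):
        clean, _, _ = hot_pixel_fixture
        _, flagged = correct_hot_pixels(clean)
        assert flagged.shape[0] == 0

    def test_idempotent_on_own_output(self, hot_pixel_fixture):
        _, corrupted, _ = hot_pixel_fixture
        once, _ = correct_hot_pixels(corrupted)
        twice, flagged = correct_hot_pixels(once)
        assert flagged.shape[0] == 0
        assert np.array_equal(twice.pixels, once.pixels)

    def test_window_validation(self):
        img = _image(np.ones((8, 8)))
        with pytest.raises(ValueError):
            correct_hot_pixels(img, window=4)
        with pytest.raises(ValueError):
            correct_hot_pixels(_image(np.ones((2, 2))), window=3)


class TestRoiFlux:
    def test_unit_image_counts_mask_pixels(self):
        img = _image(np.ones((10, 10)))
        roi = Roi("r", np.argwhere(np.ones((5, 5), dtype=bool)))
        assert roi_flux(img, roi) == 25.0

    def test_disjoint_roi_additivity(self):
        rng = np.random.default_rng(0)
        img = _image(rng.random((12, 12)))
        a = Roi("a", np.argwhere(np.zeros((12, 12)) == 0)[:40])
        b = Roi("b", np.argwhere(np.zeros((12, 12)) == 0)[40:90])
        ab = Roi("ab", np.vstack([a.mask, b.mask]))
        assert roi_flux(img, ab) == pytest.approx(
            roi_flux(img, a) + roi_flux(img, b), rel=1e-12)

    def test_out_of_bounds_rejected(self):
        img = _image(np.ones((10, 10)))
        with pytest.raises(ValueError):
            roi_flux(img, Roi("bad", np.array([[9, 9], [10, 3]])))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            Roi("empty", np.empty((0, 2)))

    def test_recovers_simulated_well_flux(self, concentration_plate):
        """Noisy ROI flux agrees with noise-free truth within counting error."""
        path, manifest = concentration_plate
        import cret.io as cio

        noisy = read_acquisition(path)
        clean = read_acquisition(path / "noise_free")
        rois = cio.load_rois(path / "rois.json", noisy["blue"].pixels.shape)
        exposure = noisy["blue"].meta.exposure_s
        corrected, _ = correct_hot_pixels(noisy["blue"])
        for well in manifest["wells"][:6]:
            roi = rois[well["well_id"]]
            truth = roi_flux(clean["blue"], roi)
            got = roi_flux(corrected, roi)
            sem = np.sqrt(truth * exposure) / exposure
            assert abs(got - truth) < 4.0 * sem


class TestCretRatio:
    @pytest.mark.parametrize("sample,control,expected", [
        ((5.5, 1.0), (2.0, 1.0), 3.5),   # 500 nM, 5 min
        ((4.8, 1.0), (3.0, 1.0), 1.8),   # 200 nM, 30 min
        ((4.8, 1.0), (2.6, 1.0), 2.2),   # 500 nM, 30 min
    ])
    def test_worked_red_blue_ratio_examples(self, sample, control, expected):
        result = cret_ratio(BandFluxPair(*sample), BandFluxPair(*control))
        assert round(result.cret_ratio, 1) == expected

    def test_sample_equal_control_gives_zero(self):
        pair = BandFluxPair(3.7, 1.9)
        assert cret_ratio(pair, pair).cret_ratio == 0.0

    def test_antisymmetry(self):
        a, b = BandFluxPair(5.0, 2.0), BandFluxPair(3.0, 4.0)
        assert (cret_ratio(a, b).cret_ratio
                + cret_ratio(b, a).cret_ratio) == pytest.approx(0.0)

    def test_zero_donor_flux_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cret_ratio(BandFluxPair(1.0, 0.0), BandFluxPair(1.0, 1.0))

    def test_identity_sample_minus_control(self):
        r = cret_ratio(BandFluxPair(7.0, 2.0), BandFluxPair(1.0, 2.0))
        assert r.cret_ratio == r.sample_ratio - r.control_ratio


class TestCretReplicates:
    def test_identical_replicates_have_zero_sem(self):
        s = [BandFluxPair(6.0, 2.0)] * 3
        c = [BandFluxPair(2.0, 2.0)] * 3
        result = cret_ratio_replicates(s, c)
        assert result.cret_ratio == pytest.approx(2.0)
        assert result.uncertainty == 0.0

    def test_single_pair_each_arm_has_no_sem(self):
        result = cret_ratio_replicates([BandFluxPair(6.0, 2.0)],
                                       [BandFluxPair(2.0, 2.0)])
        assert result.cret_ratio == pytest.approx(2.0)
        assert result.uncertainty is None

    def test_sem_matches_root_sum_square_of_arm_sems(self):
        s = [BandFluxPair(x, 1.0) for x in (5.0, 6.0, 7.0)]
        c = [BandFluxPair(x, 1.0) for x in (1.0, 2.0, 3.0)]
        result = cret_ratio_replicates(s, c)
        sem = np.sqrt(np.std([5, 6, 7], ddof=1) ** 2 / 3
                      + np.std([1, 2, 3], ddof=1) ** 2 / 3)
        assert result.uncertainty == pytest.approx(sem)
        assert result.mean_of_differences == pytest.approx(4.0)

    def test_noisy_replicates_bracket_noise_free_truth(self, concentration_plate):
        path, manifest = concentration_plate
        import cret.io as cio

        noisy = read_acquisition(path)
        rois = cio.load_rois(path / "rois.json", noisy["red"].pixels.shape)
        red, _ = correct_hot_pixels(noisy["red"])
        blue, _ = correct_hot_pixels(noisy["blue"])

        def pairs(conc):
            return [BandFluxPair(roi_flux(red, rois[w["well_id"]]),
                                 roi_flux(blue, rois[w["well_id"]]))
                    for w in manifest["wells"]
                    if w["concentration_nm"] == conc]

        result = cret_ratio_replicates(pairs(200.0), pairs(0.0))
        truth = [r["cret_ratio"] for r in manifest["cret_noise_free"]
                 if r["concentration_nm"] == 200.0][0]
        assert result.uncertainty is not None and result.uncertainty > 0.0
        assert abs(result.cret_ratio - truth) < 3.0 * result.uncertainty


class TestRatioImage:
    def test_identical_images_give_unit_ratio(self):
        img = _image(np.full((8, 8), 4.0))
        out = ratio_image(img, img)
        assert np.all(out.valid)
        assert np.allclose(out.pixels, 1.0)

    def test_zero_denominator_marks_invalid(self):
        num = _image(np.ones((6, 6)))
        den = _image(np.zeros((6, 6)))
        out = ratio_image(num, den)
        assert not out.valid.any()
        assert np.all(np.isnan(out.pixels))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ratio_image(_image(np.ones((4, 4))), _image(np.ones((5, 5))))

    def test_phantom_qdot_roi_exceeds_pbs_roi(self, mouse_500):
        path, manifest = mouse_500
        import cret.io as cio

        tdir = path / "t005min"
        clean = read_acquisition(tdir / "noise_free")
        rois = cio.load_rois(tdir / "rois.json", clean["red"].pixels.shape)
        ratio = ratio_image(clean["red"], clean["blue"])
        assert (roi_ratio_mean(ratio, rois["qdot_tumor"])
                > roi_ratio_mean(ratio, rois["pbs_tumor"]))


class TestCalculatedCretImage:
    def test_control_roi_mean_becomes_zero(self, mouse_500):
        path, _ = mouse_500
        import cret.io as cio

        tdir = path / "t005min"
        clean = read_acquisition(tdir / "noise_free")
        rois = cio.load_rois(tdir / "rois.json", clean["red"].pixels.shape)
        ratio = ratio_image(clean["red"], clean["blue"])
        calc = calculated_cret_image(ratio, rois["pbs_tumor"])
        assert roi_ratio_mean(calc, rois["pbs_tumor"]) == pytest.approx(0.0,
                                                                        abs=1e-9)

    def test_constant_ratio_image_maps_to_zero(self):
        img = _image(np.full((8, 8), 3.0))
        ratio = ratio_image(img, _image(np.ones((8, 8))))
        roi = Roi("ctl", np.argwhere(np.ones((3, 3), dtype=bool)))
        calc = calculated_cret_image(ratio, roi)
        assert np.allclose(calc.pixels, 0.0)

    def test_image_domain_tracks_flux_domain_cret(self, mouse_500):
        """Mean-of-ratios over the acceptor ROI approximates the
        ratio-of-means CRET scalar; both aggregations are reported."""
        path, manifest = mouse_500
        import cret.io as cio

        tdir = path / "t005min"
        clean = read_acquisition(tdir / "noise_free")
        rois = cio.load_rois(tdir / "rois.json", clean["red"].pixels.shape)
        ratio = ratio_image(clean["red"], clean["blue"])
        calc = calculated_cret_image(ratio, rois["pbs_tumor"])
        image_domain = roi_ratio_mean(calc, rois["qdot_tumor"])
        flux_domain = manifest["timepoints"][0]["cret_ratio"]
        assert image_domain > 0.0
        # mean-of-ratios vs ratio-of-means: same sign, same scale
        assert image_domain == pytest.approx(flux_domain, rel=0.5)

    def test_fully_invalid_control_roi_rejected(self):
        num = _image(np.ones((6, 6)))
        den = _image(np.zeros((6, 6)))
        out = ratio_image(num, den)
        roi = Roi("ctl", np.array([[1, 1], [2, 2]]))
        with pytest.raises(ValueError):
            calculated_cret_image(out, roi)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swapping_negates_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 5.0, 6.0]
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_longhand_pooled_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        t, p = two_sample_t(a, b)
        sp2 = (np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (0.25 + 0.25))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 6), rel=1e-12)

    def test_degenerate_equal_constants(self):
        t, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(6.0)
        slope, intercept, r2 = linear_fit(x, 2.0 * x + 1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_invariant_under_point_reordering(self):
        rng = np.random.default_rng(3)
        x = rng.random(20)
        y = 0.5 * x + rng.normal(0, 0.05, 20)
        perm = rng.permutation(20)
        assert linear_fit(x, y) == pytest.approx(linear_fit(x[perm], y[perm]))

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_concentration_ladder_fit_quality(self, concentration_plate):
        """OLS of noisy per-well CRET on concentration is strongly linear."""
        path, manifest = concentration_plate
        import cret.io as cio

        noisy = read_acquisition(path)
        rois = cio.load_rois(path / "rois.json", noisy["red"].pixels.shape)
        red, _ = correct_hot_pixels(noisy["red"])
        blue, _ = correct_hot_pixels(noisy["blue"])
        control_ratios = [
            roi_flux(red, rois[w["well_id"]]) / roi_flux(blue, rois[w["well_id"]])
            for w in manifest["wells"] if w["concentration_nm"] == 0.0]
        xs, ys = [], []
        for w in manifest["wells"]:
            ratio = (roi_flux(red, rois[w["well_id"]])
                     / roi_flux(blue, rois[w["well_id"]]))
            xs.append(w["concentration_nm"])
            ys.append(ratio - np.mean(control_ratios))
        slope, intercept, r2 = linear_fit(xs, ys)
        assert slope > 0.0
        assert r2 > 0.8
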