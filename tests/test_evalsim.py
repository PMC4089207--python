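import numpy as np
import pytest

from ultraspeckle import (GrayImage, NoiseSpec, PhantomSpec, Ridge, Spot,
                          Truth, baseline_gaussian, baseline_median,
                          make_phantom, multiplicative_rayleigh, psnr,
                          run_benchmark, ssim)


class TestMultiplicativeRayleigh:
    def test_sigma_zero_is_exact_identity(self, rng):
        img = GrayImage(rng.uniform(0, 255, size=(32, 32)))
        out = multiplicative_rayleigh(img, NoiseSpec(0.0, seed=1))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_field_moments(self):
        img = GrayImage(np.full((512, 512), 128.0))
        out = multiplicative_rayleigh(img, NoiseSpec(0.3, seed=2))
        n = out.pixels / 128.0
        assert abs(n.mean() - 1.0) < 0.01
        assert abs(n.std() - 0.3) < 0.01

    def test_reproducible_and_seed_sensitive(self):
        img = GrayImage(np.full((64, 64), 100.0))
        a = multiplicative_rayleigh(img, NoiseSpec(0.2, seed=5))
        b = multiplicative_rayleigh(img, NoiseSpec(0.2, seed=5))
        c = multiplicative_rayleigh(img, NoiseSpec(0.2, seed=6))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(-0.1)


class TestPhantom:
    def test_no_structures_gives_constant_bands(self):
        img, truth = make_phantom(
            PhantomSpec(size=(64, 64), background_levels=(90.0,)))
        np.testing.assert_array_equal(img.pixels, 90.0)
        assert np.all(truth == Truth.FLAT)

    def test_horizontal_ridge_marks_crest_rows(self):
        ridge = Ridge(points=((32.0, 0.0), (32.0, 63.0)),
                      amplitude=80.0, width=1.8)
        img, truth = make_phantom(
            PhantomSpec(size=(64, 64), background_levels=(80.0,),
                        ridges=(ridge,)))
        assert np.all(truth[32, :] == Truth.CREST_BRIGHT)
        assert img.pixels[32, 30] == pytest.approx(160.0, abs=1e-6)
        # rows far from the ridge stay flat truth
        assert np.all(truth[:16, :] == Truth.FLAT)

    def test_dark_curve_marks_boundary_crest(self):
        ridge = Ridge(points=((32.0, 0.0), (32.0, 63.0)),
                      amplitude=-50.0, width=2.0)
        _, truth = make_phantom(
            PhantomSpec(size=(64, 64), background_levels=(120.0,),
                        ridges=(ridge,)))
        assert np.all(truth[32, :] == Truth.CREST_DARK)

    def test_spot_center_marked(self):
        spot = Spot(center=(20.0, 40.0), amplitude=80.0, radius=3.0)
        img, truth = make_phantom(
            PhantomSpec(size=(64, 64), background_levels=(60.0,),
                        spots=(spot,)))
        assert truth[20, 40] == Truth.SPOT_CENTER
        assert img.pixels[20, 40] == pytest.approx(140.0, abs=1e-6)

    def test_overlapping_structures_become_dont_care(self):
        ridge = Ridge(points=((20.0, 0.0), (20.0, 63.0)),
                      amplitude=60.0, width=2.0)
        spot = Spot(center=(20.0, 32.0), amplitude=60.0, radius=2.5)
        img, truth = make_phantom(
            PhantomSpec(size=(64, 64), background_levels=(60.0,),
                        ridges=(ridge,), spots=(spot,)))
        # intensities add; the overlap region is excluded from scoring
        assert truth[20, 32] == Truth.DONT_CARE
        assert img.pixels[20, 32] == pytest.approx(180.0, abs=1e-3)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(size=(32, 32))


class TestPsnr:
    def test_identical_capped_at_100(self, rng):
        img = GrayImage(rng.uniform(0, 255, size=(16, 16)))
        assert psnr(img, img) == 100.0

    def test_full_scale_difference_is_zero(self):
        a = GrayImage(np.zeros((16, 16)))
        b = GrayImage(np.full((16, 16), 255.0))
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_one_level_difference(self):
        a = GrayImage(np.full((32, 32), 100.0))
        b = GrayImage(np.full((32, 32), 101.0))
        assert psnr(a, b) == pytest.approx(20 * np.log10(255), abs=1e-9)

    def test_symmetry(self, rng):
        a = GrayImage(rng.uniform(0, 255, size=(16, 16)))
        b = GrayImage(rng.uniform(0, 255, size=(16, 16)))
        assert psnr(a, b) == psnr(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(GrayImage(np.zeros((8, 8))), GrayImage(np.zeros((8, 9))))


class TestSsim:
    def test_identical_is_exactly_one(self, rng):
        img = GrayImage(rng.uniform(0, 255, size=(32, 32)))
        assert ssim(img, img) == 1.0

    def test_inversion_scores_low(self, rng):
        a = np.clip(rng.normal(128, 40, size=(64, 64)), 0, 255)
        assert ssim(GrayImage(a), GrayImage(255.0 - a)) < 0.5

    def test_small_offset_scores_high_but_below_one(self, rng):
        a = np.clip(rng.uniform(40, 200, size=(64, 64)), 0, 255)
        b = a + 5.0
        val = ssim(GrayImage(a), GrayImage(np.clip(b, 0, 255)))
        assert 0.9 < val < 1.0

    def test_matches_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(5):
            a = rng.uniform(0, 255, size=(48, 64))
            b = np.clip(a + rng.normal(0, 25, size=a.shape), 0, 255)
            mine = ssim(GrayImage(a), GrayImage(b))
            ref = structural_similarity(
                a, b, data_range=255, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(GrayImage(np.zeros((8, 8))), GrayImage(np.zeros((8, 8))))


class TestBaselines:
    def test_constants_unchanged(self):
        img = GrayImage(np.full((24, 24), 99.0))
        np.testing.assert_allclose(baseline_gaussian(img).pixels, 99.0,
                                   atol=1e-9)
        np.testing.assert_array_equal(baseline_median(img).pixels,
                                      img.pixels)

    def test_impulse_removed_by_7x7_median(self):
        data = np.zeros((16, 16))
        data[8, 8] = 255.0
        out = baseline_median(GrayImage(data))
        assert out.pixels[8, 8] == 0.0

    def test_ramp_through_gaussian_unchanged_in_interior(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        img = GrayImage(3.0 * xx + 5.0)
        out = baseline_gaussian(img, sigma=1.0)
        np.testing.assert_allclose(out.pixels[8:-8, 8:-8],
                                   img.pixels[8:-8, 8:-8], atol=1e-9)


@pytest.fixture(scope="module")
def small_phantom():
    from ultraspeckle import default_phantom_spec

    clean, _ = make_phantom(default_phantom_spec(size=(96, 96), seed=0))
    return clean


class TestBenchmark:
    def test_identity_reports_noisy_image_quality(self, small_phantom):
        df = run_benchmark([("ph", small_phantom)], [0.2], ["identity"],
                           seed=3)
        assert len(df) == 1
        noisy = multiplicative_rayleigh(small_phantom, NoiseSpec(0.2, 3))
        assert df.psnr_db.iloc[0] == pytest.approx(psnr(small_phantom, noisy))
        assert df.ssim.iloc[0] == pytest.approx(ssim(small_phantom, noisy))

    def test_row_count_and_columns(self, small_phantom):
        df = run_benchmark(
            [("ph", small_phantom)], [0.1, 0.3],
            ["identity", "gaussian", "median", "proposed"],
            passes=2, seed=1)
        # per sigma: 3 single-pass methods + 2 proposed passes
        assert len(df) == 2 * (3 + 2)
        assert list(df.columns) == ["image", "sigma", "method", "pass",
                                    "psnr_db", "ssim"]
        assert df.psnr_db.notna().all() and df.ssim.between(-1, 1).all()

    def test_external_callable_method(self, small_phantom):
        df = run_benchmark([("ph", small_phantom)], [0.1],
                           [("box", lambda im: baseline_median(im, 3))],
                           seed=1)
        assert df.method.tolist() == ["box"]

    def test_unknown_method_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            run_benchmark([("ph", small_phantom)], [0.1], ["bogus"])

    def test_proposed_improves_with_second_pass_at_high_noise(
            self, small_phantom):
        df = run_benchmark([("ph", small_phantom)], [0.3], ["proposed"],
                           passes=2, seed=7)
        p = df.set_index("pass")
        assert p.loc[2, "psnr_db"] >= p.loc[1, "psnr_db"]
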