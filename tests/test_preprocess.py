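import numpy as np
import pytest

from connmap.preprocess import (
    NuisanceSet,
    bandpass,
    normalize_intensity,
    read_censor_column,
    residualize,
    smooth,
)
from connmap.stats import pearson_r

from conftest import make_run


def sine_run(freq_hz, tr_s=0.5, n=200, shape=(2, 2, 2)):
    t = np.arange(n) * tr_s
    series = np.sin(2 * np.pi * freq_hz * t)
    data = np.broadcast_to(series, shape + (n,)).copy()
    return make_run(data, tr_s=tr_s)


class TestBandpass:
    def test_in_band_sine_amplitude_preserved(self):
        run = sine_run(0.05)
        out = bandpass(run, 0.01, 0.1)
        ratio = out.data[0, 0, 0].std() / run.data[0, 0, 0].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_constant_series_removed(self):
        run = make_run(np.full((2, 2, 2, 100), 7.0))
        out = bandpass(run, 0.01, 0.1)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_out_of_band_sine_suppressed_by_fft_power(self):
        run = sine_run(0.2, tr_s=0.5)
        out = bandpass(run, 0.01, 0.1)
        p_in = np.abs(np.fft.rfft(run.data[0, 0, 0])) ** 2
        p_out = np.abs(np.fft.rfft(out.data[0, 0, 0])) ** 2
        assert p_out.sum() < 0.01 * p_in.sum()

    def test_band_outside_nyquist_rejected(self):
        run = sine_run(0.05, tr_s=2.0)  # Nyquist 0.25 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(run, 0.01, 0.3)


class TestResidualize:
    def test_design_regressor_annihilated(self, rng):
        T = 120
        reg = rng.standard_normal(T)
        data = np.broadcast_to(reg, (3, 3, 2, T)).copy()
        run = make_run(data)
        nuis = NuisanceSet(regressors=reg[:, None], names=["motion"])
        out = residualize(run, nuisance=nuis, band=None)
        assert np.max(np.abs(out.data)) < 1e-8 * np.max(np.abs(run.data))

    def test_residuals_orthogonal_to_motion(self, rng):
        T = 150
        motion = rng.standard_normal(T)
        signal = rng.standard_normal((2, 2, 2, T))
        run = make_run(signal + 2.5 * motion)
        nuis = NuisanceSet(regressors=motion[:, None], names=["motion"])
        out = residualize(run, nuisance=nuis, band=None)
        resid = out.data[1, 1, 1]
        rc = resid - resid.mean()
        mc = motion - motion.mean()
        assert abs(float(rc @ mc) / (np.linalg.norm(rc) * np.linalg.norm(mc))) < 1e-10

    def test_empty_nuisance_wide_band_detrends_only(self, rng):
        T = 100
        y = rng.standard_normal((1, 1, 1, T))
        run = make_run(y, tr_s=0.5)
        out = residualize(run, band=None)
        t = np.arange(T)
        X = np.column_stack([np.ones(T), t])
        beta, *_ = np.linalg.lstsq(X, y[0, 0, 0], rcond=None)
        assert np.allclose(out.data[0, 0, 0], y[0, 0, 0] - X @ beta, atol=1e-10)

    def test_idempotent(self, rng):
        T = 120
        run = make_run(rng.standard_normal((2, 2, 2, T)), tr_s=0.5)
        nuis = NuisanceSet(regressors=rng.standard_normal((T, 2)), names=["a", "b"])
        once = residualize(run, nuisance=nuis, band=(0.01, 0.1), censored={3, 50})
        twice = residualize(once, nuisance=nuis, band=(0.01, 0.1), censored={3, 50})
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_censored_frames_zeroed_and_flagged(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 80)), tr_s=0.5)
        out = residualize(run, band=(0.01, 0.1), censored={5, 6})
        assert out.censored_frames == frozenset({5, 6})
        assert np.all(out.data[..., [5, 6]] == 0)

    def test_rank_deficient_design_warns(self, rng):
        T = 90
        reg = rng.standard_normal(T)
        nuis = NuisanceSet(regressors=np.column_stack([reg, reg]), names=["a", "a_copy"])
        run = make_run(rng.standard_normal((1, 1, 1, T)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            residualize(run, nuisance=nuis, band=None)


class TestSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        assert np.array_equal(smooth(vol, 0.0, 2.0), vol)

    def test_delta_matches_discrete_kernel_and_conserves_mass(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth(vol, 4.0, 2.0)
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        assert out[7, 7, 7] == pytest.approx(float(w.max() ** 3), rel=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=0.01)

    def test_constant_volume_unchanged_in_interior(self):
        vol = np.ones((16, 16, 16))
        out = smooth(vol, 4.0, 2.0)
        assert np.allclose(out[4:12, 4:12, 4:12], 1.0, atol=1e-8)

    def test_4d_series_smoothed_per_frame(self, rng):
        data = rng.standard_normal((8, 8, 8, 3))
        out = smooth(data, 4.0, 2.0)
        frame = smooth(data[..., 1], 4.0, 2.0)
        assert np.allclose(out[..., 1], frame)


class TestNormalizeIntensity:
    def test_scales_mean_to_100(self):
        run = make_run(np.full((2, 2, 2, 50), 50.0))
        out = normalize_intensity(run)
        assert np.allclose(out.data, 100.0)

    def test_all_zero_voxel_untouched(self, rng):
        data = np.abs(rng.standard_normal((2, 2, 2, 40))) + 1.0
        data[0, 0, 0] = 0.0
        out = normalize_intensity(make_run(data))
        assert np.all(out.data[0, 0, 0] == 0.0)

    def test_noncensored_mean_exactly_100(self, rng):
        data = np.abs(rng.standard_normal((3, 3, 3, 60))) + 5.0
        data[..., [2, 9]] = 0.0
        run = make_run(data, censored=(2, 9))
        out = normalize_intensity(run)
        means = out.data[..., out.valid_frames].mean(axis=-1)
        assert np.allclose(means, 100.0, atol=1e-6)

    def test_downstream_correlation_invariant(self, rng):
        data = np.abs(rng.standard_normal((2, 2, 2, 60))) + 5.0
        run = make_run(data)
        out = normalize_intensity(run)
        r0 = pearson_r(run.data[0, 0, 0], run.data[1, 1, 1])
        r1 = pearson_r(out.data[0, 0, 0], out.data[1, 1, 1])
        assert r1 == pytest.approx(r0, abs=1e-12)


def test_censor_column_reader(tmp_path):
    path = tmp_path / "censor.txt"
    path.write_text("1\n0\n1\n0\n1\n")
    assert read_censor_column(path) == frozenset({1, 3})
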