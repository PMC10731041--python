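"""Frame bookkeeping, motion QC, despiking, filtering and static FNC."""

import numpy as np
import pytest

from dfncstates import (
    ComponentTimeSeries,
    TimecoursePreprocessor,
    despike,
    discard_initial_frames,
    frame_displacement,
    load_motion_tsv,
    lowpass_filter,
    motion_exclude,
    motion_qc_report,
    static_fnc,
)


def series(data, tr=2.5, sid="sub-x"):
    return ComponentTimeSeries(sid, np.asarray(data, dtype=float), tr)


class TestDiscardFrames:
    def test_acquisition_bookkeeping(self, rng):
        s = series(rng.standard_normal((240, 4)))
        assert discard_initial_frames(s, 10).n_timepoints == 230

    def test_zero_discard_is_identity(self, noise_series):
        out = discard_initial_frames(noise_series, 0)
        assert np.array_equal(out.data, noise_series.data)

    def test_exact_slicing_of_ramp(self):
        ramp = np.arange(240, dtype=float)[:, None]
        out = discard_initial_frames(series(ramp), 10)
        assert np.array_equal(out.data, ramp[10:])

    def test_discarding_everything_rejected(self, noise_series):
        with pytest.raises(ValueError):
            discard_initial_frames(noise_series, 230)


class TestFrameDisplacement:
    def test_still_subject_has_zero_fd(self):
        assert np.array_equal(frame_displacement(np.zeros((8, 6))), np.zeros(8))

    def test_single_translation_step(self):
        m = np.zeros((4, 6))
        m[1:, 0] = 0.1  # +0.1 mm in x from frame 2 on
        fd = frame_displacement(m)
        assert np.allclose(fd, [0.0, 0.1, 0.0, 0.0])

    def test_rotation_scaled_by_sphere_radius(self):
        m = np.zeros((2, 6))
        m[1, 4] = 0.002  # radians
        assert np.isclose(frame_displacement(m)[1], 50.0 * 0.002)

    def test_matches_successive_difference_oracle(self, rng):
        m = np.cumsum(rng.normal(0, 0.05, (100, 6)), axis=0)
        fd = frame_displacement(m)
        # brute-force oracle: frame-by-frame absolute parameter differences
        expected = [0.0]
        for t in range(1, 100):
            dt = dr = 0.0
            for j in range(3):
                dt += abs(m[t, j] - m[t - 1, j])
            for j in range(3, 6):
                dr += abs(m[t, j] - m[t - 1, j])
            expected.append(dt + 50.0 * dr)
        assert np.array_equal(fd, np.array(expected))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            frame_displacement(np.zeros((5, 4)))


class TestMotionExclude:
    def test_typical_low_motion_subject_kept(self, rng):
        m = np.column_stack(
            [rng.normal(0, 0.05, (230, 3)), rng.normal(0, 0.0005, (230, 3))]
        )
        fd = frame_displacement(m)
        keep, reasons = motion_exclude(fd, m)
        assert keep and reasons == []

    def test_large_translation_dropped_with_reason(self):
        m = np.zeros((10, 6))
        m[5, 1] = 3.1
        keep, reasons = motion_exclude(frame_displacement(m), m)
        assert not keep
        assert any("translation" in r for r in reasons)

    def test_rotation_over_three_degrees_dropped(self):
        m = np.zeros((10, 6))
        m[5, 3] = np.radians(3.2)
        keep, reasons = motion_exclude(frame_displacement(m), m)
        assert not keep
        assert any("rotation" in r for r in reasons)

    def test_thresholds_are_strict_inequalities(self):
        m = np.zeros((10, 6))
        m[5, 0] = 3.0  # exactly at the translation limit
        fd = np.full(10, 0.5)  # mean FD exactly at the limit
        keep, reasons = motion_exclude(fd, m)
        assert keep and reasons == []


class TestDespike:
    def test_spike_free_series_unchanged(self, rng):
        # uniform noise keeps every residual well inside c1 robust-sigmas
        x = rng.uniform(-1, 1, (100, 3))
        out = despike(series(x))
        assert np.allclose(out.data, x, atol=1e-12)

    def test_huge_spike_compressed_below_ceiling(self, rng):
        x = rng.normal(0, 1, 200)
        x[50] += 100.0
        out = despike(series(x[:, None])).data[:, 0]
        resid = x - np.median(x)
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        assert out[50] < 4.0 * sigma + abs(np.median(x)) + 1.0
        assert out[50] < x[50] / 2

    def test_non_spike_samples_untouched(self, rng):
        x = rng.normal(0, 1, 200)
        x[50] += 100.0
        out = despike(series(x[:, None])).data[:, 0]
        changed = np.flatnonzero(out != x)
        assert 50 in changed
        assert np.all(np.abs(x[changed]) > 2.0)  # only outlying samples move

    def test_constant_component_returned_unchanged(self):
        x = np.full((50, 1), 3.14)
        out = despike(series(x))
        assert np.array_equal(out.data, x)

    def test_trend_preserved(self, rng):
        t = np.arange(200, dtype=float)
        x = 0.05 * t + rng.normal(0, 0.5, 200)
        x[100] += 50.0
        out = despike(series(x[:, None])).data[:, 0]
        # spike pulled toward the fitted line; almost all samples untouched
        # (a few normal-tail residuals legitimately exceed the c1 flag)
        assert abs(out[100] - 0.05 * 100) < 5.0
        assert np.mean(out != x) < 0.05


class TestLowpassFilter:
    @staticmethod
    def _sine(freq_hz, tr=2.5, n=500):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq_hz * t)

    def test_passband_sinusoid_retained(self):
        x = self._sine(0.05)
        y = lowpass_filter(series(x[:, None])).data[:, 0]
        assert y.std() / x.std() >= 0.95

    def test_stopband_sinusoid_attenuated(self):
        x = self._sine(0.19)
        y = lowpass_filter(series(x[:, None])).data[:, 0]
        assert y.std() / x.std() < 0.5

    def test_constant_series_maps_to_zero(self):
        y = lowpass_filter(series(np.full((100, 2), 7.0))).data
        assert np.allclose(y, 0.0, atol=1e-9)

    def test_shape_preserved(self, noise_series):
        assert lowpass_filter(noise_series).data.shape == noise_series.data.shape

    def test_cutoff_above_nyquist_rejected(self, noise_series):
        with pytest.raises(ValueError):
            lowpass_filter(noise_series, cutoff_hz=0.25)  # Nyquist at TR 2.5 is 0.2


class TestStaticFNC:
    def test_duplicate_component_hits_clamp_with_warning(self, rng):
        x = rng.standard_normal(100)
        data = np.column_stack([x, x, rng.standard_normal(100)])
        with pytest.warns(UserWarning, match="clamp"):
            z = static_fnc(series(data))
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-12))

    def test_independent_noise_has_small_correlation(self, rng):
        z = static_fnc(series(rng.standard_normal((1000, 6))))
        r = np.tanh(z)
        off = r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_constant_component_pairs_zeroed(self, rng):
        data = np.column_stack([np.full(50, 2.0), rng.standard_normal(50)])
        with pytest.warns(UserWarning, match="constant"):
            z = static_fnc(series(data))
        assert z[0, 1] == 0.0

    def test_symmetric_zero_diagonal(self, noise_series):
        z = static_fnc(noise_series)
        assert np.array_equal(z, z.T)
        assert np.all(np.diag(z) == 0.0)


class TestPreprocessor:
    def test_pipeline_order_and_shape(self, rng):
        raw = series(rng.standard_normal((240, 5)))
        prep = TimecoursePreprocessor(n_discard=10).fit()
        out = prep.transform_series(raw)
        assert out.data.shape == (230, 5)
        assert prep.stages_ == ["discard", "despike", "detrend+lowpass"]

    def test_array_roundtrip(self, rng):
        prep = TimecoursePreprocessor().fit()
        out = prep.transform(rng.standard_normal((100, 3)))
        assert out.shape == (100, 3)

    def test_sklearn_param_interface(self):
        prep = TimecoursePreprocessor(lowpass_hz=0.1)
        assert prep.get_params()["lowpass_hz"] == 0.1
        prep.set_params(n_discard=5)
        assert prep.n_discard == 5


class TestMotionIO:
    def test_degree_rotations_converted(self, tmp_path, rng):
        m = np.zeros((5, 6))
        m[2, 4] = 3.0  # degrees
        path = tmp_path / "motion.tsv"
        np.savetxt(path, m, delimiter="\t")
        loaded = load_motion_tsv(path, rotation_unit="deg")
        assert loaded[2, 4] == pytest.approx(np.radians(3.0))
        assert np.array_equal(load_motion_tsv(path, rotation_unit="rad"), m)

    def test_rotation_unit_required_valid(self, tmp_path):
        path = tmp_path / "motion.tsv"
        np.savetxt(path, np.zeros((5, 6)), delimiter="\t")
        with pytest.raises(ValueError):
            load_motion_tsv(path, rotation_unit="arcmin")

    def test_qc_report_fields(self, rng):
        m = np.column_stack(
            [rng.normal(0, 0.05, (100, 3)), rng.normal(0, 0.0005, (100, 3))]
        )
        rep = motion_qc_report(m)
        assert rep["kept"] is True
        assert rep["mean_fd"] >= 0
        assert set(rep) == {"mean_fd", "max_translation", "max_rotation_deg", "kept", "reasons"}
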