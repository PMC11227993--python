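"""Temporal-cleaning contracts: discard, FD, confound regression, band-pass."""

import numpy as np
import pandas as pd
import pytest

from ntpipe import (CohortSpec, SubjectRecord, bandpass_filter,
                    discard_initial_volumes, framewise_displacement,
                    qc_filter_subjects, regress_confounds, simulate_ar1)
from ntpipe.preprocess import (HEAD_RADIUS_MM, MOTION_COLUMNS, bandpass_gain,
                               expand_motion_24, motion_summary, preprocess_bold)
from ntpipe.synthetic import CONFOUND_COLUMNS, _gen_confounds

from conftest import make_bold


def _rand_bold(rng, dims=(2, 2, 1), t=160, tr=2.2):
    return make_bold(rng.standard_normal(dims + (t,)), tr_s=tr)


def _rand_confounds(rng, t=160):
    return pd.DataFrame(rng.standard_normal((t, len(CONFOUND_COLUMNS))),
                        columns=list(CONFOUND_COLUMNS))


class TestDiscard:
    def test_five_of_165_leaves_160(self):
        bold = make_bold(np.random.default_rng(0).standard_normal((2, 2, 1, 165)))
        out = discard_initial_volumes(bold, 5)
        assert out.n_timepoints == 160
        np.testing.assert_array_equal(out.values, bold.values[..., 5:])
        assert out.tr_s == bold.tr_s and out.geometry == bold.geometry

    def test_zero_is_identity(self):
        bold = make_bold(np.random.default_rng(1).standard_normal((2, 2, 1, 10)))
        out = discard_initial_volumes(bold, 0)
        np.testing.assert_array_equal(out.values, bold.values)

    def test_discarding_everything_rejected(self):
        bold = make_bold(np.random.default_rng(2).standard_normal((1, 1, 1, 10)))
        with pytest.raises(ValueError, match="empty"):
            discard_initial_volumes(bold, 10)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        motion = np.tile([0.3, -0.2, 0.1, 0.01, 0.0, -0.02], (20, 1))
        np.testing.assert_allclose(framewise_displacement(motion), 0.0)

    def test_translation_step_registers_once(self):
        motion = np.zeros((10, 6))
        motion[4:, 0] = 1.0  # +1 mm in trans_x at frame 4
        fd = framewise_displacement(motion)
        assert fd[4] == pytest.approx(1.0)
        assert np.all(np.delete(fd, 4) == 0)

    def test_rotation_step_converts_to_arc_length(self):
        # oracle: 50 mm * 0.02 rad = 1.0 mm
        motion = np.zeros((10, 6))
        motion[6:, 3] = 0.02
        fd = framewise_displacement(motion, radius_mm=HEAD_RADIUS_MM)
        assert fd[6] == pytest.approx(1.0)

    def test_first_frame_is_zero_and_length_matches(self):
        motion = np.random.default_rng(3).standard_normal((17, 6))
        fd = framewise_displacement(motion)
        assert fd.shape == (17,) and fd[0] == 0.0 and np.all(fd >= 0)

    def test_nonfinite_rejected(self):
        motion = np.zeros((5, 6))
        motion[2, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            framewise_displacement(motion)

    def test_summary_fields(self):
        motion = np.zeros((10, 6))
        motion[5:, 2] = 2.0
        ms = motion_summary(motion)
        assert ms.max_fd_mm == pytest.approx(2.0)
        assert ms.mean_fd_mm == pytest.approx(0.2)


class TestRegressConfounds:
    def test_voxel_equal_to_wm_column_vanishes(self):
        rng = np.random.default_rng(4)
        conf = _rand_confounds(rng)
        vals = np.zeros((1, 1, 1, 160))
        vals[0, 0, 0] = conf["wm"].to_numpy()
        out = regress_confounds(make_bold(vals), conf)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self):
        rng = np.random.default_rng(5)
        conf = _rand_confounds(rng)
        X = np.column_stack([np.ones(160), conf.to_numpy()])
        y = rng.standard_normal(160)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]  # project out the design
        out = regress_confounds(make_bold(y.reshape(1, 1, 1, -1)), conf)
        np.testing.assert_allclose(out.values.ravel(), y, atol=1e-10)

    def test_residuals_orthogonal_to_every_confound(self):
        rng = np.random.default_rng(6)
        conf = _rand_confounds(rng)
        bold = _rand_bold(rng, dims=(3, 2, 2))
        out = regress_confounds(bold, conf)
        resid = out.values.reshape(-1, 160)
        C = conf.to_numpy()
        rel = np.abs(resid @ C) / (np.linalg.norm(resid, axis=1, keepdims=True)
                                   * np.linalg.norm(C, axis=0) + 1e-300)
        assert rel.max() < 1e-8

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(7)
        conf = _rand_confounds(rng)
        conf["csf"] = 2.0 * conf["wm"]
        with pytest.raises(ValueError, match="wm.*csf|csf.*wm"):
            regress_confounds(_rand_bold(rng), conf)

    def test_row_count_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="rows"):
            regress_confounds(_rand_bold(rng, t=150), _rand_confounds(rng, t=160))

    def test_24_parameter_expansion_shape(self):
        rng = np.random.default_rng(9)
        conf = _rand_confounds(rng)
        big = expand_motion_24(conf)
        assert big.shape[1] == len(CONFOUND_COLUMNS) + 3 * len(MOTION_COLUMNS)


class TestBandpass:
    def _tone(self, freq, n=512, tr=2.2):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq * t)

    def _gain(self, freq):
        x = self._tone(freq)
        out = bandpass_filter(make_bold(x.reshape(1, 1, 1, -1)), 0.01, 0.1)
        mid = slice(100, 412)  # avoid edge transients
        return float(np.std(out.values.ravel()[mid]) / np.std(x[mid]))

    def test_passband_tone_survives(self):
        # oracle: analytic |H|^2 at 0.05 Hz is ~0.995
        assert bandpass_gain(0.05, 0.01, 0.1, 2.2) > 0.9
        assert self._gain(0.05) == pytest.approx(1.0, abs=0.1)

    def test_stopband_tone_attenuated(self):
        assert bandpass_gain(0.2, 0.01, 0.1, 2.2) < 0.2
        assert self._gain(0.2) < 0.2

    def test_dc_removed(self):
        x = np.full((1, 1, 1, 300), 7.0) + 1e-6 * np.random.default_rng(0).standard_normal(300)
        out = bandpass_filter(make_bold(x), 0.01, 0.1)
        assert abs(out.values.mean()) < 1e-3

    def test_band_above_nyquist_rejected(self):
        x = _rand_bold(np.random.default_rng(1))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(x, 0.01, 0.25)  # Nyquist at TR 2.2 is ~0.227

    def test_reversed_band_rejected(self):
        x = _rand_bold(np.random.default_rng(2))
        with pytest.raises(ValueError, match="low"):
            bandpass_filter(x, 0.1, 0.01)


class TestPipelineOrderAndLinearity:
    def test_cleaning_is_linear(self):
        rng = np.random.default_rng(10)
        conf = _rand_confounds(rng)
        x = _rand_bold(rng)
        y = _rand_bold(rng)
        combo = make_bold(2.0 * x.values + 3.0 * y.values)
        out_combo = bandpass_filter(regress_confounds(combo, conf), 0.01, 0.1)
        out_parts = (2.0 * bandpass_filter(regress_confounds(x, conf), 0.01, 0.1).values
                     + 3.0 * bandpass_filter(regress_confounds(y, conf), 0.01, 0.1).values)
        np.testing.assert_allclose(out_combo.values, out_parts, rtol=1e-8, atol=1e-10)

    def test_cleaning_recovers_bandpassed_ar1_acf(self):
        """Confound regression + band-pass on AR(1)+confounds should give the
        same lag-1 autocorrelation as band-passing a clean AR(1) draw."""
        rng = np.random.default_rng(11)
        n = 800
        conf = _gen_confounds(np.random.default_rng(12), n, 2.2)
        sig = simulate_ar1(0.7, n, 1.0, seed=13)
        mixed = sig + 1.5 * conf["wm"].to_numpy() + 1.0 * conf["csf"].to_numpy()
        cleaned = bandpass_filter(
            regress_confounds(make_bold(mixed.reshape(1, 1, 1, -1)), conf), 0.01, 0.1)
        ref = bandpass_filter(make_bold(sig.reshape(1, 1, 1, -1)), 0.01, 0.1)

        def lag1(v):
            v = v.ravel() - v.mean()
            return float(np.sum(v[:-1] * v[1:]) / np.sum(v * v))

        assert lag1(cleaned.values) == pytest.approx(lag1(ref.values), abs=0.05)

    def test_preprocess_bold_composition(self, small_cohort):
        bold, conf = small_cohort.bold_for("CN003")
        out = preprocess_bold(bold, conf)
        assert out.n_timepoints == 160
        out24 = preprocess_bold(bold, conf, motion_model="24")
        assert out24.n_timepoints == 160
        with pytest.raises(ValueError, match="motion_model"):
            preprocess_bold(bold, conf, motion_model="12")


class TestQc:
    def _subjects(self, motions):
        return [SubjectRecord(id=f"S{i}", group="CN", age=70, sex="F", mmse=30,
                              mean_motion_mm=m) for i, m in enumerate(motions)]

    def test_three_mm_rule(self):
        kept, excluded = qc_filter_subjects(self._subjects([1.0, 3.5]), 3.0)
        assert [s.mean_motion_mm for s in kept] == [1.0]
        assert [s.mean_motion_mm for s in excluded] == [3.5]

    def test_all_below_threshold(self):
        kept, excluded = qc_filter_subjects(self._subjects([0.1, 0.2, 2.9]), 3.0)
        assert len(kept) == 3 and excluded == []

    def test_partition_is_exhaustive(self):
        subs = self._subjects([0.5, 3.1, 2.0, 4.0])
        kept, excluded = qc_filter_subjects(subs, 3.0)
        assert sorted(s.id for s in kept + excluded) == sorted(s.id for s in subs)

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            qc_filter_subjects(self._subjects([1.0]), 0.0)
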