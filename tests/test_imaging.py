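"""Imaging analysis chain: preprocessing, fits, correlations, similarity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beeal.imaging import (delta_ratio, normalize, blocker_difference,
                           peak_time, fit_gain_curve, count_recruited,
                           pattern_correlation, pool_by_ratio, ratio_bin,
                           framewise_correlation, fisher_z, similarity_index,
                           CONCENTRATION_LADDER, ONSET_FRAME, GainFit)


class TestDeltaRatio:
    def test_constant_signal_is_zero(self):
        f340 = np.full(80, 200.0)
        f380 = np.full(80, 100.0)
        np.testing.assert_allclose(delta_ratio(f340, f380), 0.0)

    def test_step_response(self):
        f340 = np.full(80, 100.0)
        f340[16:] = 110.0
        f380 = np.full(80, 100.0)
        d = delta_ratio(f340, f380)
        assert d[:16] == pytest.approx(0.0)
        assert d[20] == pytest.approx(10.0)

    def test_ratio_invariance_under_common_gain(self):
        rng = np.random.default_rng(0)
        f340 = 100 + rng.random(80)
        f380 = 90 + rng.random(80)
        np.testing.assert_allclose(delta_ratio(f340, f380),
                                   delta_ratio(2 * f340, 2 * f380))

    def test_nonpositive_f380_rejected(self):
        with pytest.raises(ValueError):
            delta_ratio(np.ones(80), np.zeros(80))


class TestNormalize:
    @staticmethod
    def table():
        rows = []
        for cond, series, peak in (("saline", 1, 4.0), ("PTX", 2, 6.0)):
            for frame in range(4):
                rows.append({"bee": 0, "series": series, "condition": cond,
                             "concentration": "1e-2", "glomerulus": 0,
                             "frame": frame,
                             "value": peak if frame == 2 else 1.0})
        return pd.DataFrame(rows)

    def test_saline_max_maps_to_one(self):
        out = normalize(self.table())
        sal = out[out.condition == "saline"]
        assert sal.value.max() == pytest.approx(1.0)

    def test_divides_by_saline_max(self):
        out = normalize(self.table())
        assert out[(out.condition == "saline") & (out.frame == 0)
                   ].value.iloc[0] == pytest.approx(0.25)

    def test_blocker_may_exceed_one(self):
        out = normalize(self.table())
        assert out[out.condition == "PTX"].value.max() == pytest.approx(1.5)

    def test_missing_saline_rejected(self):
        t = self.table()
        with pytest.raises(ValueError):
            normalize(t[t.condition != "saline"])


class TestBlockerDifference:
    def test_identical_traces_zero(self):
        a = np.arange(80.0)
        np.testing.assert_allclose(blocker_difference(a, a), 0.0)

    def test_constant_offset(self):
        a = np.random.default_rng(0).random(80)
        np.testing.assert_allclose(blocker_difference(a, a + 0.3), 0.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            blocker_difference(np.ones(80), np.ones(79))


class TestPeakTime:
    def test_below_criterion_is_excluded(self):
        d = np.zeros(80)
        d[20] = 0.15
        assert peak_time(d) is None

    def test_three_frames_after_onset_is_375_ms(self):
        d = np.zeros(80)
        d[ONSET_FRAME + 3] = 0.9
        assert peak_time(d) == 375.0

    def test_eleven_frames_after_onset_is_1375_ms(self):
        d = np.zeros(80)
        d[ONSET_FRAME + 11] = 0.5
        assert peak_time(d) == 1375.0


class TestGainFit:
    LADDER = np.asarray(CONCENTRATION_LADDER)

    def test_noiseless_recovery(self):
        a, b, c = 1.0, 2.0, -4.0
        y = a / (1 + np.exp(c - b * self.LADDER))
        fit = fit_gain_curve(self.LADDER, y)
        assert fit.converged
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)

    def test_dr_closed_form(self):
        fit = GainFit(a=1.0, b=2.0, c=0.0, converged=True)
        assert fit.DR == pytest.approx(math.log(9.0), rel=1e-12)

    def test_sens_closed_form(self):
        fit = GainFit(a=1.0, b=2.0, c=0.0, converged=True)
        assert fit.Sens == pytest.approx(0.8 / math.log(9.0), rel=1e-12)

    def test_dr_is_ec90_minus_ec10(self):
        """DR = 2 ln 9 / b equals the spread between the 10% and 90%
        crossing points of the fitted curve."""
        fit = fit_gain_curve(self.LADDER,
                             0.7 / (1 + np.exp(-3.0 - 1.8 * self.LADDER)))
        x = np.linspace(-8, 4, 200001)
        y = fit.predict(x)
        ec10 = x[np.searchsorted(y, 0.1 * fit.a)]
        ec90 = x[np.searchsorted(y, 0.9 * fit.a)]
        assert fit.DR == pytest.approx(ec90 - ec10, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gain_curve(np.array([-3, -2, -1.0]), np.array([0.1, 0.5, 0.9]))

    def test_noisy_recovery_within_ten_percent(self):
        """At 5% amplitude noise on the 9-point design the Monte-Carlo
        mean of each fitted parameter over 100 replicates recovers the
        truth within 10%; the amplitude is tight per replicate."""
        a, b, c = 1.0, 2.0, -4.0
        y0 = a / (1 + np.exp(c - b * self.LADDER))
        fits = []
        a_ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_gain_curve(self.LADDER,
                                 y0 + 0.05 * a * rng.standard_normal(9))
            assert fit.converged
            fits.append((fit.a, fit.b, fit.c))
            a_ok += abs(fit.a - a) / a < 0.1
        am, bm, cm = np.mean(fits, axis=0)
        assert abs(am - a) / a < 0.1
        assert abs(bm - b) / b < 0.1
        assert abs(cm - c) / abs(c) < 0.1
        assert a_ok >= 90


class TestRecruitment:
    def test_construction_six_of_eleven(self, rng):
        traces = rng.normal(0.0, 0.01, size=(11, 80))
        traces[:6, 16:48] += 1.0
        assert count_recruited(traces) == pytest.approx(6 / 11)

    def test_all_subthreshold(self, rng):
        traces = rng.normal(0.0, 0.01, size=(11, 80))
        assert count_recruited(traces) == 0.0

    def test_zero_variance_baseline_rejected(self):
        with pytest.raises(ValueError):
            count_recruited(np.zeros((3, 80)))


class TestPatternCorrelation:
    def test_identical_patterns_r_one(self, rng):
        p = rng.random(11)
        pats = np.tile(p, (9, 1))
        cs = pattern_correlation(pats)
        off = cs.r[~np.isnan(cs.r)]
        np.testing.assert_allclose(off, 1.0)

    def test_nine_concentrations_make_36_pairs(self, rng):
        cs = pattern_correlation(rng.random((9, 11)))
        assert len(cs.pair_values()) == 36

    def test_symmetry(self, rng):
        cs = pattern_correlation(rng.random((9, 11)))
        np.testing.assert_allclose(cs.r, cs.r.T)

    def test_fisher_z_values(self):
        assert fisher_z(0.0) == pytest.approx(0.0)
        assert fisher_z(0.9) == pytest.approx(1.472, abs=1e-3)
        assert np.isfinite(fisher_z(1.0))

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_fisher_z_monotone(self, r):
        assert fisher_z(r + 1e-4) > fisher_z(r)

    def test_constant_pattern_gives_nan(self):
        pats = np.ones((2, 11))
        pats[1] = np.arange(11)
        cs = pattern_correlation(pats, concentrations=(-2.0, -1.0))
        assert np.isnan(cs.r[0, 1])


class TestRatioPooling:
    def test_known_bins(self):
        assert ratio_bin(-2.0, -4.0) == 100    # 1e-2 vs 1e-4
        assert ratio_bin(-0.52, -2.52) == 100  # 3e-1 vs 3e-3
        assert ratio_bin(-1.0, -1.52) == 3     # 1e-1 vs 3e-2

    def test_partitions_all_36_pairs(self, rng):
        cs = pattern_correlation(rng.random((9, 11)))
        pooled = pool_by_ratio(cs)
        assert pooled.n_pairs.sum() == 36
        assert set(pooled.ratio) <= {3, 10, 30, 100, 300, 1000, 3000,
                                     10000, 30000}

    def test_off_ladder_pair_rejected(self):
        with pytest.raises(ValueError):
            ratio_bin(-2.0, -2.2)


class TestFramewiseCorrelation:
    def test_identical_series_r_one_on_response(self, rng):
        tr = rng.random((11, 80)) + 1
        r = framewise_correlation(tr, tr)
        np.testing.assert_allclose(r, 1.0)

    def test_independent_noise_near_zero(self, rng):
        a = rng.normal(size=(11, 80))
        b = rng.normal(size=(11, 80))
        r = framewise_correlation(a, b)
        assert abs(np.nanmean(r)) < 0.2


class TestSimilarityIndex:
    def test_self_similarity_is_one(self, rng):
        traces = rng.random((11, 80))
        assert similarity_index(traces, traces) == pytest.approx(1.0)

    def test_subset_of_model_traces(self, rng):
        model = rng.random((20, 80))
        standard = model[[3, 7, 11]]
        assert similarity_index(model, standard) == pytest.approx(1.0)

    def test_independent_noise_gives_only_selection_bias(self, rng):
        model = rng.normal(size=(20, 80))
        standard = rng.normal(size=(11, 80))
        assert abs(similarity_index(model, standard)) < 0.3

    def test_greedy_matching_is_bijective(self, rng):
        model = rng.random((20, 80))
        standard = rng.random((11, 80))
        _, pairs = similarity_index(model, standard, return_matching=True)
        s_used = [i for i, _ in pairs]
        m_used = [j for _, j in pairs]
        assert sorted(s_used) == list(range(11))
        assert len(set(m_used)) == 11

    def test_permutation_invariance(self, rng):
        model = rng.random((20, 80))
        standard = rng.random((11, 80))
        perm = rng.permutation(20)
        assert similarity_index(model[perm], standard) == pytest.approx(
            similarity_index(model, standard))

    def test_fewer_model_traces_rejected(self, rng):
        with pytest.raises(ValueError):
            similarity_index(rng.random((5, 80)), rng.random((11, 80)))
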