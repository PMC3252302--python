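import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from conftest import brute_force_lag_scan
from rsnflow.fnc import (DEFAULT_SUBSYSTEMS, FncResult, SubsystemPartition,
                         bandpass, fnc_age_correlation, fnc_between_groups,
                         fnc_cohort, fnc_group_test, fnc_subject,
                         interpolate_tc, max_lagged_corr, n_lags,
                         subsystem_summary)
from rsnflow.synthetic_data import (CohortSpec, CouplingSpec,
                                    make_coupled_timecourses)


def _band_signal(rng, n=400, dt=1.0):
    from scipy.signal import butter, filtfilt
    b, a = butter(5, [0.01 / (0.5 / dt), 0.1 / (0.5 / dt)], btype="band")
    x = filtfilt(b, a, rng.standard_normal(n + 400))[200:200 + n]
    return (x - x.mean()) / x.std()


class TestInterpolation:
    def test_linear_ramp_reproduced_exactly(self):
        tc = np.arange(30, dtype=float) * 0.7 + 3
        out = interpolate_tc(tc, tr_s=2.0)
        np.testing.assert_allclose(out, np.arange(0, 58.001) * 0.35 + 3,
                                   atol=1e-10)

    def test_slow_sinusoid_matches_analytic_curve(self):
        t_orig = np.arange(200) * 2.0
        out = interpolate_tc(np.sin(2 * np.pi * 0.05 * t_orig), tr_s=2.0)
        t_new = np.arange(0, t_orig[-1] + 1e-9)
        err = np.abs(out - np.sin(2 * np.pi * 0.05 * t_new))
        # not-a-knot end conditions leave a small boundary error
        assert err[4:-4].max() < 1e-3
        assert err.max() < 5e-3

    def test_constant_preserved(self):
        out = interpolate_tc(np.full(50, 2.5), tr_s=2.0)
        np.testing.assert_allclose(out, 2.5)

    def test_sub_second_tr_passes_through_with_warning(self):
        x = np.arange(20, dtype=float)
        with pytest.warns(UserWarning):
            out = interpolate_tc(x, tr_s=0.5)
        np.testing.assert_array_equal(out, x)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t = np.arange(600)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, dt_s=1.0)
        assert y[100:-100].std() / x[100:-100].std() > 0.95

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(600)
        x = np.sin(2 * np.pi * 0.4 * t)
        y = bandpass(x, dt_s=1.0)
        # steady-state section; filtfilt start-up transients excluded
        assert y[150:450].std() / x[150:450].std() < 0.05

    def test_dc_offset_removed(self, rng):
        y = bandpass(rng.normal(size=300) + 10.0, dt_s=1.0)
        assert abs(y.mean()) < 1e-6

    def test_invalid_band_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpass(rng.normal(size=100), dt_s=1.0, low_hz=0.2, high_hz=0.1)


class TestMaxLaggedCorr:
    def test_identical_series_peak_at_zero_lag(self, rng):
        x = _band_signal(rng)
        r, lag = max_lagged_corr(x, x)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_eleven_lags_in_window(self):
        assert n_lags(5.0, 1.0) == 11

    def test_circular_shift_recovered_exactly(self, rng):
        x = _band_signal(rng)
        y = np.roll(x, 3)                     # y lags x by 3 s on the 1 s grid
        r, lag = max_lagged_corr(x, y)
        assert lag == 3.0
        assert r > 0.99

    @pytest.mark.parametrize("delta", range(-5, 6))
    def test_noise_free_lag_recovered_for_every_window_position(self, rng,
                                                                delta):
        x = _band_signal(rng, n=500)
        _, lag = max_lagged_corr(x, np.roll(x, delta))
        assert lag == float(delta)

    def test_agrees_with_brute_force_oracle(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=60), r.normal(size=60)
            got = max_lagged_corr(x, y)
            want = brute_force_lag_scan((x - x.mean()) / x.std(),
                                        (y - y.mean()) / y.std(), 1.0, 5.0)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == want[1]

    def test_maximum_dominates_zero_lag(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=80), rng.normal(size=80)
            r, _ = max_lagged_corr(x, y)
            r0 = np.corrcoef(x, y)[0, 1]
            assert abs(r) >= abs(r0) - 1e-12

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            max_lagged_corr(np.ones(50), rng.normal(size=50))


class TestFncSubject:
    def test_eight_components_give_28_pairs(self, rng):
        tcs = rng.normal(size=(200, 8))
        r, lag = fnc_subject(tcs, tr_s=2.0)
        iu = np.triu_indices(8, 1)
        assert np.isfinite(r[iu]).sum() == 28

    def test_two_components_give_one_pair(self, rng):
        r, lag = fnc_subject(rng.normal(size=(200, 2)), tr_s=2.0)
        assert np.isfinite(r[0, 1])

    def test_symmetry_and_lag_antisymmetry(self, rng):
        r, lag = fnc_subject(rng.normal(size=(150, 5)), tr_s=2.0)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(lag, -lag.T, atol=1e-12)

    def test_max_statistic_null_is_inflated(self, rng):
        """Mean |r_max| over independent pairs exceeds the lag-0 null: the
        max over 11 lags is biased upward, checked against the empirical
        zero-lag distribution."""
        rmaxs, r0s = [], []
        for _ in range(60):
            tcs = rng.normal(size=(200, 2))
            r, _ = fnc_subject(tcs, tr_s=2.0)
            rmaxs.append(abs(r[0, 1]))
            a = bandpass(interpolate_tc(tcs[:, 0], 2.0), 1.0)
            b = bandpass(interpolate_tc(tcs[:, 1], 2.0), 1.0)
            r0s.append(abs(np.corrcoef(a, b)[0, 1]))
        assert np.mean(rmaxs) > np.mean(r0s)

    def test_planted_coupling_recovered_through_full_chain(self):
        """Generator couplings at rho 0.7 survive interpolate + bandpass +
        lag scan with the exact planted lag."""
        cohort = CohortSpec(n_volumes=200, tr_s=2.0, seed=0)
        tc = make_coupled_timecourses(cohort, [CouplingSpec((0, 1), 0.7, 4.0)],
                                      K=2, rng=np.random.default_rng(0))
        r, lag = fnc_subject(tc, tr_s=2.0)
        assert lag[0, 1] == 4.0
        assert r[0, 1] == pytest.approx(0.7, abs=0.15)


def _make_fnc_result(rng, n_subjects, K, pair_r, jitter=0.02):
    """FncResult with specified mean correlation per pair plus jitter."""
    r = np.zeros((n_subjects, K, K))
    for s in range(n_subjects):
        m = np.zeros((K, K)) + np.diag([np.nan] * K)
        for (i, j), rho in pair_r.items():
            m[i, j] = m[j, i] = rho + jitter * rng.standard_normal()
        for i, j in combinations(range(K), 2):
            if (i, j) not in pair_r:
                m[i, j] = m[j, i] = jitter * rng.standard_normal()
        r[s] = m
    return FncResult(subjects=[f"s{i}" for i in range(n_subjects)],
                     r_max=r, lag_s=np.zeros_like(r),
                     component_ids=list(range(K)))


class TestGroupInference:
    def test_single_planted_edge_is_the_only_significant_pair(self, rng):
        fr = _make_fnc_result(rng, 10, 4, {(0, 1): 0.5})
        sig = fnc_group_test(fr).significant_pairs()
        assert sig == {(0, 1)}

    def test_tiny_null_sample_not_significant(self, rng):
        fr = _make_fnc_result(rng, 3, 2, {(0, 1): 0.0}, jitter=0.1)
        table = fnc_group_test(fr).table
        assert not table.significant.any()

    def test_extreme_correlation_is_clipped_not_infinite(self, rng):
        fr = _make_fnc_result(rng, 5, 2, {(0, 1): 1.0}, jitter=0.0)
        table = fnc_group_test(fr).table
        assert np.isfinite(table.mean_z).all()

    def test_identical_groups_show_no_difference(self, rng):
        fr = _make_fnc_result(rng, 8, 4, {(0, 1): 0.5})
        table = fnc_between_groups(fr, fr).table
        np.testing.assert_allclose(table.t, 0.0, atol=1e-10)

    def test_group_swap_negates_between_group_t(self, rng):
        fa = _make_fnc_result(rng, 8, 4, {(0, 1): 0.6})
        fb = _make_fnc_result(rng, 9, 4, {(0, 1): 0.1})
        np.testing.assert_allclose(fnc_between_groups(fa, fb).table.t,
                                   -fnc_between_groups(fb, fa).table.t,
                                   atol=1e-10)

    def test_severed_coupling_detected_between_groups(self):
        """rho 0.6 vs 0 on one pair at n = 14 vs 16 is detected in at least
        80% of planted-simulation repeats."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            coh_a = CohortSpec(n_volumes=200, tr_s=2.0, seed=seed)
            tcs_a = {f"a{s}": make_coupled_timecourses(
                coh_a, [CouplingSpec((0, 1), 0.6, 0.0)], K=2,
                rng=np.random.default_rng(1000 + seed * 40 + s))
                for s in range(14)}
            tcs_b = {f"b{s}": make_coupled_timecourses(
                coh_a, [], K=2,
                rng=np.random.default_rng(5000 + seed * 40 + s))
                for s in range(16)}
            res = fnc_between_groups(fnc_cohort(tcs_a, 2.0),
                                     fnc_cohort(tcs_b, 2.0))
            if bool(res.table.significant.iloc[0]):
                hits += 1
        assert hits >= 0.8 * n_rep


class TestSubsystems:
    def test_default_partition_classification(self):
        part = SubsystemPartition()
        assert part.is_intra(0, 1)        # both DMN halves: integration
        assert not part.is_intra(0, 4)    # DMN vs frontoparietal

    def test_intra_and_inter_pair_counts(self):
        part = SubsystemPartition()
        pairs = list(combinations(range(8), 2))
        intra = sum(part.is_intra(i, j) for i, j in pairs)
        assert intra == 7 and len(pairs) - intra == 21

    def test_identical_sets_lose_and_gain_nothing(self):
        sig = {"hc": {(0, 1), (0, 4)}, "pat": {(0, 1), (0, 4)}}
        table = subsystem_summary(sig, SubsystemPartition(), "hc")
        pat = table[table.group == "pat"].set_index("status")
        assert pat.loc["lost", "total"] == 0
        assert pat.loc["gained", "total"] == 0

    def test_losing_all_inter_edges_counts_21(self):
        part = SubsystemPartition()
        all_pairs = set(combinations(range(8), 2))
        intra_only = {p for p in all_pairs if part.is_intra(*p)}
        table = subsystem_summary({"hc": all_pairs, "pat": intra_only},
                                  part, "hc")
        pat = table[(table.group == "pat") & (table.status == "lost")].iloc[0]
        assert pat.inter == 21 and pat.intra == 0

    def test_unmapped_component_errors(self):
        with pytest.raises(KeyError):
            subsystem_summary({"hc": {(0, 9)}}, SubsystemPartition(), "hc")


class TestAgeCorrelation:
    def test_perfectly_correlated_pair(self, rng):
        fr = _make_fnc_result(rng, 6, 2, {}, jitter=0.0)
        ages = np.array([10, 14, 18, 22, 26, 30], dtype=float)
        fr.r_max[:, 0, 1] = fr.r_max[:, 1, 0] = ages / 40
        table = fnc_age_correlation(fr, ages)
        assert table.r.iloc[0] == pytest.approx(1.0)

    def test_constant_ages_rejected(self, rng):
        fr = _make_fnc_result(rng, 5, 2, {(0, 1): 0.3})
        with pytest.raises(ValueError, match="constant"):
            fnc_age_correlation(fr, np.full(5, 20.0))

    def test_independent_ages_rarely_significant(self):
        """Ages drawn independently of connectivity: no significant pair in
        at least 90% of repeats."""
        clean = 0
        n_rep = 50
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            fr = _make_fnc_result(r, 14, 6, {(0, 1): 0.5}, jitter=0.1)
            ages = r.uniform(8, 35, size=14)
            if not fnc_age_correlation(fr, ages).significant.any():
                clean += 1
        assert clean >= 0.9 * n_rep
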