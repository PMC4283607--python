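"""Tp estimation: objective geometry, recovery, bounds and weights."""

import numpy as np
import pytest

import mabsim as ms

TP_TRUE = 397.0


def make_noiseless_obs(drive, dis, tp, weeks=8):
    times = ms.weekly_sample_times(weeks)
    values = ms.predict_pasi(tp, drive, dis, times)
    return ms.ObservedSeries(times=times, values=values)


class TestObjective:
    def test_zero_at_generating_value(self, escalating_drive, disease_p):
        obs = make_noiseless_obs(escalating_drive, disease_p, TP_TRUE)
        assert ms.objective(TP_TRUE, obs, escalating_drive,
                            disease_p) < 1e-10

    def test_positive_away_from_truth(self, escalating_drive, disease_p):
        obs = make_noiseless_obs(escalating_drive, disease_p, TP_TRUE)
        assert ms.objective(100.0, obs, escalating_drive, disease_p) > 1e-2

    def test_locally_convex_around_truth(self, escalating_drive, disease_p):
        """21-point grid spanning +-50%: single minimum at the center."""
        obs = make_noiseless_obs(escalating_drive, disease_p, TP_TRUE)
        grid = np.linspace(0.5 * TP_TRUE, 1.5 * TP_TRUE, 21)
        vals = np.array([ms.objective(tp, obs, escalating_drive, disease_p)
                         for tp in grid])
        imin = int(np.argmin(vals))
        assert grid[imin] == pytest.approx(TP_TRUE, rel=0.06)
        assert np.all(np.diff(vals[:imin]) < 0)
        assert np.all(np.diff(vals[imin:]) > 0)


class TestFit:
    @pytest.mark.parametrize("tp_true", [100.0, 397.0, 1000.0])
    def test_noiseless_recovery_within_1pct(self, escalating_drive,
                                            disease_p, tp_true):
        obs = make_noiseless_obs(escalating_drive, disease_p, tp_true,
                                 weeks=8)
        fit = ms.fit_tp(obs, escalating_drive, disease_p)
        assert fit.converged
        assert fit.estimate == pytest.approx(tp_true, rel=0.01)

    def test_mean_noisy_recovery(self, escalating_truth, escalating_drive,
                                 disease_p):
        """20 replicate series at 5% proportional noise: the mean
        estimate recovers the generating half-life within 5%."""
        times = ms.weekly_sample_times(8)
        noise = ms.NoiseModel(kind="proportional", cv=0.05, seed=1234)
        reps = ms.generate_observations(escalating_truth, times, noise,
                                        n_replicates=20)
        ests = [ms.fit_tp(o, escalating_drive, disease_p).estimate
                for o in reps]
        assert np.mean(ests) == pytest.approx(TP_TRUE, rel=0.05)

    def test_consistency_as_noise_shrinks(self, escalating_truth,
                                          escalating_drive, disease_p):
        times = ms.weekly_sample_times(8)
        errs = []
        for cv in (0.10, 0.02):
            noise = ms.NoiseModel(kind="proportional", cv=cv, seed=55)
            reps = ms.generate_observations(escalating_truth, times, noise,
                                            n_replicates=12)
            ests = np.array([ms.fit_tp(o, escalating_drive,
                                       disease_p).estimate for o in reps])
            errs.append(np.mean(np.abs(ests - TP_TRUE)))
        assert errs[1] < errs[0]

    def test_bounds_excluding_truth_pin_at_bound(self, escalating_drive,
                                                 disease_p):
        obs = make_noiseless_obs(escalating_drive, disease_p, TP_TRUE)
        fit = ms.fit_tp(obs, escalating_drive, disease_p,
                        bounds=(24.0, 48.0))
        assert fit.at_bound and not fit.converged
        assert fit.estimate == pytest.approx(48.0, rel=0.01)

    def test_weight_rescaling_invariance(self, escalating_truth,
                                         escalating_drive, disease_p):
        times = ms.weekly_sample_times(8)
        noise = ms.NoiseModel(kind="proportional", cv=0.05, seed=9)
        obs = ms.generate_observations(escalating_truth, times, noise)[0]
        w = np.linspace(1.0, 2.0, len(times))
        obs_w = ms.ObservedSeries(times=times, values=obs.values, weights=w)
        obs_10w = ms.ObservedSeries(times=times, values=obs.values,
                                    weights=10.0 * w)
        f1 = ms.fit_tp(obs_w, escalating_drive, disease_p)
        f2 = ms.fit_tp(obs_10w, escalating_drive, disease_p)
        assert f1.estimate == pytest.approx(f2.estimate, rel=1e-6)

    def test_standard_error_is_reported(self, escalating_truth,
                                        escalating_drive, disease_p):
        times = ms.weekly_sample_times(8)
        noise = ms.NoiseModel(kind="proportional", cv=0.05, seed=3)
        obs = ms.generate_observations(escalating_truth, times, noise)[0]
        fit = ms.fit_tp(obs, escalating_drive, disease_p)
        assert np.isfinite(fit.std_error) and fit.std_error > 0

    def test_too_few_points_rejected(self, escalating_drive, disease_p):
        obs = ms.ObservedSeries(times=[0.0, 168.0], values=[24.8, 23.0])
        with pytest.raises(ms.InvalidArgumentError):
            ms.fit_tp(obs, escalating_drive, disease_p)


class TestObservedSeries:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ms.InvalidArgumentError):
            ms.ObservedSeries(times=[0.0, 10.0, 5.0],
                              values=[1.0, 2.0, 3.0])

    def test_negative_values_rejected(self):
        with pytest.raises(ms.InvalidArgumentError):
            ms.ObservedSeries(times=[0.0, 1.0], values=[1.0, -2.0])
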