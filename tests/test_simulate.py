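"""Simulator: Gompertz identities, random profiles, measurement noise."""

import numpy as np
import pytest

import kinrates as kr
from kinrates.simulate import gompertz_instance, simulate_controls

from conftest import euler_oracle


class TestRandomExpressionProfile:
    def test_normalized_to_unit_interval(self):
        prof = kr.random_expression_profile(101, seed=3)
        assert prof.min() == 0.0
        assert prof.max() == 1.0

    def test_seed_reproducibility(self):
        a = kr.random_expression_profile(101, seed=42)
        b = kr.random_expression_profile(101, seed=42)
        assert np.array_equal(a, b)

    def test_zero_variance_walk_is_constant_before_normalization(self):
        cfg = kr.SimConfig(rw_sigma2=1e-30)
        rng = np.random.default_rng(0)
        steps = np.exp(rng.normal(0, np.sqrt(cfg.rw_sigma2), 101))
        assert np.allclose(np.cumprod(steps), 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kr.random_expression_profile(21, seed=0)


class TestGompertz:
    def test_late_time_limit_is_b_max(self, gomp):
        assert kr.gompertz_biomass(gomp, 1e3) == pytest.approx(gomp.b_max, rel=1e-9)

    def test_value_at_lag(self, gomp):
        expected = gomp.b0 * np.exp(gomp.a * np.exp(-np.e))
        assert kr.gompertz_biomass(gomp, gomp.lag) == pytest.approx(expected)

    def test_biomass_monotone_for_random_params(self, rng):
        t = np.linspace(0, 24, 500)
        for _ in range(100):
            p = kr.sample_gompertz(rng)
            B = kr.gompertz_biomass(p, t)
            assert np.all(np.diff(B) >= 0)

    def test_peak_rate_equals_mu_star_at_analytic_time(self, rng):
        for _ in range(20):
            p = kr.sample_gompertz(rng)
            t_pk = p.lag + p.a / (p.mu_star * np.e)
            assert kr.gompertz_growth_rate(p, t_pk) == pytest.approx(p.mu_star)
            t = np.linspace(0, 24, 2000)
            assert np.max(kr.gompertz_growth_rate(p, t)) <= p.mu_star + 1e-12

    def test_rate_is_log_derivative_of_biomass(self, rng):
        """Growth-rate formula vs centered finite difference of log B."""
        h = 1e-4
        t = np.linspace(2 * h, 24, 400)
        for _ in range(20):
            p = kr.sample_gompertz(rng)
            fd = (np.log(kr.gompertz_biomass(p, t + h))
                  - np.log(kr.gompertz_biomass(p, t - h))) / (2 * h)
            mu = kr.gompertz_growth_rate(p, t)
            assert np.allclose(mu, fd, rtol=1e-4, atol=1e-9)

    def test_rate_vanishes_in_stationary_phase(self, gomp):
        assert kr.gompertz_growth_rate(gomp, 1e3) == pytest.approx(0.0, abs=1e-12)


class TestSampleGompertz:
    def test_fixed_constants_and_support(self):
        draws = [kr.sample_gompertz(np.random.default_rng(s)) for s in range(500)]
        assert all(p.a == pytest.approx(np.log(100.0)) for p in draws)
        mu = np.array([p.mu_star for p in draws])
        lag = np.array([p.lag for p in draws])
        assert mu.min() >= 0.5 and mu.max() <= 1.0
        assert lag.min() >= 0.0 and lag.max() <= 4.0

    def test_seed_reproducibility(self):
        assert kr.sample_gompertz(5) == kr.sample_gompertz(5)


class TestSimulateWell:
    def test_sigma_zero_measurements_are_truth_plus_background(self, gomp):
        noise = kr.NoiseSpec(sigma=0.0)
        well = kr.simulate_well(
            lambda t: kr.gompertz_growth_rate(gomp, t),
            lambda t: np.zeros_like(np.asarray(t, float)),
            noise=noise,
            b0=float(kr.gompertz_biomass(gomp, 0.0)),
            seed=0,
        )
        assert np.allclose(well.biomass.values, well.true_biomass + 0.1)
        assert np.allclose(well.fluorescence.values, 0.1)

    def test_euler_vs_closed_form_biomass(self, rng):
        """Euler at the production step size vs the closed-form Gompertz.

        Forward Euler's first-order bias at dt = 0.024 h reaches a few
        percent where mu approaches 1/h (relative error ~ dt * int(mu^2)/2),
        so the bound is 5% — this bias is part of the simulated data, as the
        study design prescribes.
        """
        for _ in range(10):
            p = kr.sample_gompertz(rng)
            well = kr.simulate_well(
                lambda t: kr.gompertz_growth_rate(p, t),
                lambda t: np.zeros_like(np.asarray(t, float)),
                noise=kr.NoiseSpec(sigma=0.0),
                b0=float(kr.gompertz_biomass(p, 0.0)),
                seed=0,
            )
            ref = kr.gompertz_biomass(p, well.times)
            assert np.allclose(well.true_biomass, ref, rtol=5e-2)

    def test_fluorescence_euler_vs_independent_oracle(self, rng):
        p = kr.sample_gompertz(rng)
        phi_vals = kr.random_expression_profile(101, seed=9)
        phi = kr.GriddedProfile(np.linspace(0, 24, 101), phi_vals)
        well = kr.simulate_well(
            lambda t: kr.gompertz_growth_rate(p, t), phi,
            noise=kr.NoiseSpec(sigma=0.0),
            b0=float(kr.gompertz_biomass(p, 0.0)), seed=0,
        )
        _, _, y = euler_oracle(
            lambda t: kr.gompertz_growth_rate(p, t), phi,
            float(kr.gompertz_biomass(p, 0.0)), 0.0, 0.0, 24.0, 1e-4,
        )
        ref = y[:: int(round(0.24 / 1e-4))]
        # Euler bias in B propagates into y; same few-percent scale
        assert np.allclose(well.true_fluorescence, ref, rtol=5e-2, atol=1e-3)

    def test_noise_streams_independent(self):
        noise = kr.NoiseSpec(sigma=0.05)
        cfg = kr.SimConfig(horizon=24.0, dt=0.024, sample_every=1)  # 1001 samples
        eps, zeta = [], []
        for s in range(10):
            well = kr.simulate_well(
                lambda t: np.zeros_like(np.asarray(t, float)),
                lambda t: np.zeros_like(np.asarray(t, float)),
                noise=noise, config=cfg, b0=0.5, y0=0.5, seed=s,
            )
            eps.append(well.biomass.values / (well.true_biomass + 0.1) - 1)
            zeta.append(well.fluorescence.values / (well.true_fluorescence + 0.1) - 1)
        eps, zeta = np.concatenate(eps), np.concatenate(zeta)
        corr = np.corrcoef(eps, zeta)[0, 1]
        assert abs(corr) < 0.05


class TestSimulateControls:
    def test_sigma_zero_blank_is_constant_background(self):
        recs = simulate_controls(kr.NoiseSpec(sigma=0.0), kr.SimConfig(),
                                 n_wells=1, kind="media_blank", seed=0)
        import pandas as pd

        df = pd.DataFrame(recs)
        od = df[df.channel == "OD"]["value"]
        assert np.allclose(od, 0.1)

    def test_mean_over_many_wells_near_background(self):
        recs = simulate_controls(kr.NoiseSpec(sigma=0.05), kr.SimConfig(),
                                 n_wells=100, kind="media_blank", seed=1)
        import pandas as pd

        df = pd.DataFrame(recs)
        od = df[df.channel == "OD"]
        means = od.groupby("time_h")["value"].mean()
        se = 0.1 * 0.05 / np.sqrt(100)
        assert np.all(np.abs(means - 0.1) < 3.5 * se + 1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_controls(n_wells=0)
        with pytest.raises(ValueError):
            simulate_controls(kind="nonsense")


class TestDeterminism:
    def test_instance_replay_is_identical(self):
        a = gompertz_instance(np.random.default_rng([7, 1, 2]),
                              noise=kr.NoiseSpec(sigma=0.05), with_expression=True)
        b = gompertz_instance(np.random.default_rng([7, 1, 2]),
                              noise=kr.NoiseSpec(sigma=0.05), with_expression=True)
        assert np.array_equal(a[0].biomass.values, b[0].biomass.values)
        assert np.array_equal(a[0].fluorescence.values, b[0].fluorescence.values)
        assert a[1] == b[1]
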