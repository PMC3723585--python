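"""Spline-based ODE inversion: running totals, smoothing, rate recovery,
smoothing-parameter calibration, maturation and decay fits."""

import math

import numpy as np
import pytest

from cyclescope import infer
from cyclescope.infer import (RunningTotalTrace, build_running_total,
                              check_decay, estimate_maturation,
                              fit_smoothing_spline, infer_rates, select_beta)
from cyclescope.simkit import (SimConfig, constant_generator, simulate_cell,
                               simulate_chase, simulate_running_total,
                               square_pulse_generator,
                               cycle_modulated_generator)


class TestRunningTotalConstruction:
    def test_no_progeny_is_volume_times_concentration(self, cfg_noiseless):
        gen = constant_generator(cfg_noiseless.gamma_M * 5)
        tr = simulate_cell(cfg_noiseless, gen, n_cycles=1)
        rt = build_running_total(tr)
        assert np.allclose(rt.P, tr.volume * tr.concentration["cfp"])

    def test_continuous_at_division_and_tracks_truth(self, cfg_noiseless):
        """Noiseless lineage: running total equals the lineage's cumulative
        mature protein, with no jump at divisions."""
        gen = cycle_modulated_generator(cfg_noiseless)
        tr = simulate_cell(cfg_noiseless, gen, n_cycles=3)
        rt = build_running_total(tr, tr.progeny)
        truth = tr.truth["Pm"].copy()
        for d in tr.progeny:
            idx = np.searchsorted(tr.times, d.times[0] - 1e-9)
            truth[idx:idx + d.times.size] += d.truth["Pm"]
        scale = max(truth.max(), 1.0)
        assert np.max(np.abs(rt.P - truth)) / scale < 1e-9
        # no division-sized discontinuities
        steps = np.abs(np.diff(rt.P))
        assert steps.max() < 3 * np.median(steps) + 1e-9

    def test_duplicate_progeny_rejected(self, cfg_noiseless):
        gen = constant_generator(0.1)
        tr = simulate_cell(cfg_noiseless, gen, n_cycles=2)
        with pytest.raises(ValueError):
            build_running_total(tr, [tr.progeny[0], tr.progeny[0]])


class TestSmoothingSpline:
    def test_linear_data_reproduced_for_any_beta(self):
        """Straight lines are in the roughness-penalty null space, so they
        are reproduced exactly at every beta."""
        t = np.arange(0.0, 200.0, 5.0)
        y = 3.0 + 2.5 * t
        for beta in (1e-3, 1.0, 3e3, 1e9):
            fit = fit_smoothing_spline(RunningTotalTrace("c", t, y), beta)
            assert np.allclose(fit.value(t), y, rtol=1e-8, atol=1e-6)

    def test_cubic_data_reproduced_as_beta_vanishes(self):
        t = np.arange(0.0, 200.0, 5.0)
        y = 1.0 + 0.5 * t + 0.02 * t ** 2 + 1e-4 * t ** 3
        fit = fit_smoothing_spline(RunningTotalTrace("c", t, y), 1e-8)
        assert np.max(np.abs(fit.value(t) - y) / np.abs(y)) < 1e-6

    def test_large_beta_tends_to_least_squares_line(self, rng):
        t = np.arange(0.0, 200.0, 5.0)
        y = 10.0 * t + rng.normal(0, 50, t.size)
        fit = fit_smoothing_spline(RunningTotalTrace("c", t, y), 1e12)
        assert np.max(np.abs(fit.d2(t))) < 1e-6

    def test_too_few_points_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_smoothing_spline(RunningTotalTrace("c", t, t), 1.0)

    def test_json_round_trip(self, rng):
        t = np.arange(0.0, 100.0, 5.0)
        y = t ** 2 + rng.normal(0, 1, t.size)
        fit = fit_smoothing_spline(RunningTotalTrace("c", t, y), 10.0)
        fit2 = infer.SplineFit.from_json(fit.to_json())
        assert np.allclose(fit.value(t), fit2.value(t))
        assert fit2.beta == fit.beta


class TestRateInversion:
    def test_linear_total_gives_constant_rates(self):
        """P = 10 t with gamma_M = 0.05 inverts to M = 10, A = 0.5."""
        t = np.arange(0.0, 200.0, 5.0)
        fit = fit_smoothing_spline(RunningTotalTrace("c", t, 10.0 * t), 1.0)
        r = infer_rates(fit, gamma_M=0.05, k_t=1.0, times=t)
        assert np.allclose(r.M, 10.0, atol=1e-6)
        assert np.allclose(r.A, 0.5, atol=1e-6)

    def test_constant_total_gives_zero_rates(self):
        t = np.arange(0.0, 200.0, 5.0)
        fit = fit_smoothing_spline(RunningTotalTrace("c", t,
                                                     np.full(t.size, 7.0)), 1.0)
        r = infer_rates(fit, gamma_M=0.05, times=t)
        assert np.allclose(r.M, 0.0, atol=1e-9)
        assert np.allclose(r.A, 0.0, atol=1e-9)

    def test_linearity_in_the_trace(self, rng):
        """Scaling P by c scales M and A by c exactly."""
        t = np.arange(0.0, 300.0, 5.0)
        y = np.cumsum(rng.random(t.size)) * 10
        c = 3.7
        r1 = infer_rates(fit_smoothing_spline(RunningTotalTrace("a", t, y),
                                              50.0), 0.03, times=t)
        r2 = infer_rates(fit_smoothing_spline(RunningTotalTrace("a", t, c * y),
                                              50.0), 0.03, times=t)
        assert np.allclose(r2.M, c * r1.M, rtol=1e-6, atol=1e-9)
        assert np.allclose(r2.A, c * r1.A, rtol=1e-6, atol=1e-8)

    def test_out_of_domain_evaluation_rejected(self):
        t = np.arange(0.0, 100.0, 5.0)
        fit = fit_smoothing_spline(RunningTotalTrace("c", t, t), 1.0)
        with pytest.raises(ValueError):
            infer_rates(fit, 0.03, times=np.array([-10.0]))

    def test_noiseless_pulse_recovered_within_two_percent(self, cfg_noiseless):
        """Without noise or maturation, the inferred A matches the square
        pulse within 2% away from the pulse edges."""
        cfg = cfg_noiseless
        amp = cfg.gamma_M * cfg.mu
        gen = square_pulse_generator(amp, 40.0, 160.0)
        sim = simulate_running_total(cfg, gen, 0.0, 250.0,
                                     include_maturation=False,
                                     add_noise=False)
        fit = fit_smoothing_spline(RunningTotalTrace("c", sim.times, sim.P),
                                   1.0)
        r = infer_rates(fit, cfg.gamma_M, cfg.k_t, times=sim.times)
        plateau = (sim.times > 60) & (sim.times < 140)
        assert np.max(np.abs(r.A[plateau] - amp)) / amp < 0.02
        pre = (sim.times > 5) & (sim.times < 25)
        assert np.max(np.abs(r.A[pre])) / amp < 0.02


class TestPerCycleRates:
    def test_two_level_generator_recovered_per_cycle(self, cfg_noiseless):
        """Noiseless cycle-modulated lineage: per-cycle inference recovers
        the trough and peak rates within 10% away from the transitions."""
        from cyclescope.infer import per_cycle_rates
        from cyclescope.simkit import cycle_modulated_generator, simulate_cell

        cfg = cfg_noiseless
        gen = cycle_modulated_generator(cfg)
        cell = simulate_cell(cfg, gen, n_cycles=3)
        rates = per_cycle_rates(cell, cell.progeny, gamma_M=cfg.gamma_M,
                                k_t=cfg.k_t, beta=1.0)
        assert len(rates) == 3
        trough = gen.params["trough"]
        peak = gen.params["peak"]
        r = rates[1]  # middle cycle, clear of trace endpoints
        age = r.times - r.times[0]
        pre = r.A[(age > 5) & (age < 22)]
        post = r.A[(age > 47) & (age < 90)]
        assert np.allclose(pre, trough, rtol=0.10)
        assert np.allclose(post, peak, rtol=0.10)


class TestBetaSelection:
    def test_noiseless_residual_decreases_toward_small_beta(self, cfg):
        grid = (10.0, 300.0, 3000.0)
        _, table = select_beta(grid, [cfg], n_reps=3, seed=5, noiseless=True)
        col = table.iloc[:, 0].to_numpy()
        assert col[0] <= col[1] <= col[2]

    def test_deterministic_and_order_invariant(self):
        sets = [SimConfig(t_cyc=100.0), SimConfig(t_cyc=70.0)]
        grid = (100.0, 1000.0)
        b1, t1 = select_beta(grid, sets, n_reps=2, seed=9)
        b2, t2 = select_beta(grid, sets[::-1], n_reps=2, seed=9)
        assert b1 == b2
        assert np.allclose(np.sort(t1.to_numpy(), axis=1),
                           np.sort(t2.to_numpy(), axis=1))

    def test_identical_sets_give_identical_columns(self):
        sets = [SimConfig(), SimConfig()]
        _, table = select_beta((100.0, 1000.0), sets, n_reps=2, seed=3)
        assert np.allclose(table.iloc[:, 0], table.iloc[:, 1])


class TestMaturationFit:
    def test_noiseless_half_life_recovered(self):
        tr = simulate_chase(k_m=math.log(2) / 10.0, duration=120.0,
                            noise_sd=0.0)
        fit = estimate_maturation(tr.times, tr.concentration)
        assert fit.converged
        assert fit.half_life == pytest.approx(10.0, rel=1e-3)

    def test_free_gamma_p_recovers_both_rates(self):
        tr = simulate_chase(k_m=0.05, gamma_P=0.004, duration=400.0,
                            noise_sd=0.0)
        fit = estimate_maturation(tr.times, tr.concentration,
                                  fix_gamma_P=False)
        assert fit.k_m == pytest.approx(0.05, rel=0.02)
        assert fit.gamma_P == pytest.approx(0.004, rel=0.05)

    def test_flat_trace_flagged(self):
        t = np.arange(0.0, 100.0, 5.0)
        fit = estimate_maturation(t, np.full(t.size, 50.0))
        assert not fit.converged
        assert "flat" in fit.flag

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_maturation(np.arange(5.0), np.arange(5.0))


class TestDecayCheck:
    def test_exact_exponential_recovered(self):
        t = np.arange(0.0, 200.0, 5.0)
        g = 0.0347
        M = 20.0 * np.exp(-g * np.maximum(t - 50.0, 0.0))
        rates = infer.ExpressionRates("c", t, M, np.zeros_like(t), g, 1.0)
        res = check_decay(rates, off_time=50.0, gamma_M_expected=g)
        assert res.gamma == pytest.approx(g, rel=1e-6)
        assert res.consistent

    def test_constant_m_flagged_inconsistent(self):
        t = np.arange(0.0, 200.0, 5.0)
        rates = infer.ExpressionRates("c", t, np.full(t.size, 5.0),
                                      np.zeros_like(t), 0.0347, 1.0)
        res = check_decay(rates, off_time=50.0, gamma_M_expected=0.0347)
        assert abs(res.gamma) < 1e-3
        assert not res.consistent

    def test_pipeline_decay_matches_configured_gamma(self, cfg_noiseless):
        """Noiseless pulse through the full inference chain: post-pulse M(t)
        decays at the configured gamma_M within 10%."""
        cfg = cfg_noiseless
        gen = square_pulse_generator(cfg.gamma_M * cfg.mu, 20.0, 120.0)
        sim = simulate_running_total(cfg, gen, 0.0, 260.0,
                                     include_maturation=False,
                                     add_noise=False)
        fit = fit_smoothing_spline(RunningTotalTrace("c", sim.times, sim.P),
                                   1.0)
        r = infer_rates(fit, cfg.gamma_M, cfg.k_t, times=sim.times)
        res = check_decay(r, off_time=135.0, gamma_M_expected=cfg.gamma_M,
                          rel_tol=0.10)
        assert res.consistent
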