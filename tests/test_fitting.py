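"""Parameter estimation: dictionary inversion, tail fits, annealing."""

import numpy as np
import pytest

from tetherkin.fitting import (
    ExperimentConditions,
    FitResult,
    PhysicalParams,
    best_of,
    from_physical,
    initial_guess,
    initial_koff,
    objective,
    polish,
    simulated_annealing,
    to_physical,
)
from tetherkin.io import SPRTrace
from tetherkin.mpdpde import NondimParams
from tetherkin.synthetic import (
    DEFAULT_CONDITIONS,
    NoiseModel,
    generate_trace,
    table2_fixtures,
)

COND = ExperimentConditions(shp1_conc=0.1, peptide_conc=10.0)


class TestPhysicalDictionary:
    def test_pd1_affinity(self):
        # k_off 2.4, k_on 0.21 -> K_D ~ 11 uM
        p = PhysicalParams(k_on=0.21, k_off=2.4, k_cat_tethered=0.04,
                           k_cat_solution=0.023, sigma_star=400.0)
        assert p.KD == pytest.approx(11.0, abs=0.5)

    def test_slam_allosteric_activation_ratio(self):
        slam = table2_fixtures()["SLAM"]["physical"]
        assert slam.k_cat_tethered / slam.k_cat_solution == pytest.approx(6.2, abs=0.1)

    def test_round_trip_identity(self):
        phys = PhysicalParams(k_on=0.34, k_off=1.8, k_cat_tethered=0.042,
                              k_cat_solution=0.031, sigma_star=210.0)
        params = from_physical(phys, COND, n_ns=0.1, p_start=0.2, amplitude=50.0)
        back = to_physical(params, COND)
        for name in ("k_on", "k_off", "k_cat_tethered", "k_cat_solution", "sigma_star"):
            assert getattr(back, name) == pytest.approx(getattr(phys, name), rel=1e-12)

    def test_zero_p3_flags_missing_sigma(self):
        params = NondimParams(p1=0.1, p2=1.0, p3=0.0, p4=0.0)
        with pytest.warns(UserWarning):
            phys = to_physical(params, COND)
        assert phys.sigma_star is None and phys.reach is None


class TestInitialKoff:
    def _tail_trace(self, k, sd=0.0, seed=0):
        t = np.linspace(0, 60, 301)
        z = np.where(t <= 45.0, 5.0, 5.0 * np.exp(-k * (t - 45.0)))
        if sd:
            z = z + np.random.default_rng(seed).normal(0, sd, t.shape)
        return SPRTrace(t, z)

    def test_pure_exponential_recovery(self):
        assert initial_koff(self._tail_trace(1.8), 45.0) == pytest.approx(1.8, rel=0.01)

    def test_flat_tail_fallback(self):
        t = np.linspace(0, 60, 301)
        tr = SPRTrace(t, np.full_like(t, 3.0))
        with pytest.warns(UserWarning):
            assert initial_koff(tr, 45.0) == 1.0

    def test_full_model_tail_within_15_percent(self, default_grid):
        fx = table2_fixtures()["PEG28"]["physical"]
        tr = generate_trace(fx, noise=NoiseModel(additive_sd=0.0), grid=default_grid)
        k = initial_koff(tr, p_stop=45.1)
        assert k == pytest.approx(fx.k_off, rel=0.15)

    def test_too_short_tail_rejected(self):
        t = np.linspace(0, 46, 47)
        with pytest.raises(ValueError):
            initial_koff(SPRTrace(t, np.ones_like(t)), 45.0)


class TestObjective:
    def test_self_consistency_noiseless(self, fit_grid):
        p = NondimParams(0.3, 1.8, p3=0.4, p4=8.0, p5=0.03, n_ns=0.05,
                         p_start=0.1, p_stop=45.1, amplitude=100.0)
        from tetherkin.mpdpde import predict_signal

        t = np.linspace(0, 55, 111)
        tr = SPRTrace(t, predict_signal(p, fit_grid, t))
        assert objective(p, tr, fit_grid) < 1e-8 * float(np.max(tr.signal)) ** 2

    def test_perturbation_increases_sse(self, fit_grid):
        from dataclasses import replace

        from tetherkin.mpdpde import predict_signal

        p = NondimParams(0.3, 1.8, p3=0.4, p4=8.0, p5=0.03, amplitude=100.0)
        t = np.linspace(0, 55, 111)
        tr = SPRTrace(t, predict_signal(p, fit_grid, t))
        base = objective(p, tr, fit_grid)
        assert objective(replace(p, p2=3.6), tr, fit_grid) > base + 1.0

    def test_solver_failure_is_rejected_move(self, fit_grid):
        tr = SPRTrace(np.linspace(0, 10, 21), np.zeros(21))
        bad = NondimParams(p1=np.inf, p2=1.0)
        assert objective(bad, tr, fit_grid) == np.inf


class TestAnnealing:
    @pytest.fixture(scope="class")
    def noiseless_trace(self, request):
        fx = table2_fixtures()["PEG28"]["physical"]
        return generate_trace(
            fx,
            noise=NoiseModel(additive_sd=0.0, sampling_rate=2.5),
            dissociation_window=10.0,
        )

    def test_greedy_descent_at_zero_temperature(self, noiseless_trace):
        init = initial_guess(noiseless_trace, DEFAULT_CONDITIONS, amplitude=100.0)
        fit = simulated_annealing(
            noiseless_trace, init, DEFAULT_CONDITIONS, n_steps=1000, seed=0,
            do_polish=False, t0=0.0,
        )
        sses = [s for _, s in fit.history]
        assert all(b <= a + 1e-12 for a, b in zip(sses, sses[1:]))

    def test_noiseless_recovery_best_of_three(self, noiseless_trace):
        # the published protocol: anneal three times (scaled-down here,
        # with a polish), keep the lowest SSE; that fit recovers the
        # binding and reach parameters on a noiseless trace
        from tetherkin.fitting import screened_fit

        truth = table2_fixtures()["PEG28"]["physical"]
        fits = [
            screened_fit(noiseless_trace, DEFAULT_CONDITIONS, n_steps=1000,
                         seed=seed, amplitude=100.0)
            for seed in (0, 1, 2)
        ]
        best = best_of(fits)
        assert best.sse == min(f.sse for f in fits)
        assert best.physical.k_off == pytest.approx(truth.k_off, rel=0.05)
        assert best.physical.reach == pytest.approx(truth.reach, rel=0.05)

    def test_n_steps_floor(self, noiseless_trace):
        init = initial_guess(noiseless_trace, DEFAULT_CONDITIONS, amplitude=100.0)
        with pytest.raises(ValueError):
            simulated_annealing(noiseless_trace, init, DEFAULT_CONDITIONS, n_steps=10)


class TestBestOf:
    def _fit(self, sse, seed):
        params = NondimParams(0.1, 1.0, p3=0.1, p4=1.0)
        phys = to_physical(params, COND)
        return FitResult(params, phys, sse, 1000, seed, True, COND)

    def test_lowest_sse_wins(self):
        fits = [self._fit(3.0, 0), self._fit(1.0, 1), self._fit(2.0, 2)]
        assert best_of(fits).sse == 1.0

    def test_single_fit(self):
        f = self._fit(5.0, 0)
        assert best_of([f]) is f

    def test_tie_broken_by_seed(self):
        fits = [self._fit(1.0, 3), self._fit(1.0, 1), self._fit(1.0, 2)]
        assert best_of(fits).seed == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_of([])
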