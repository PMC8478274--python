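"""Folding threshold, first-passage runs, survival curves and fits."""

import numpy as np
import pytest
from scipy import stats

from barofold.kinetics import (
    FirstPassageRecord,
    SurvivalCurve,
    fit_kinetic_model,
    folding_threshold,
    folding_threshold_from_traces,
    population_histogram,
    run_first_passage,
    survival_curve,
)
from barofold.model import Conformation


def records_from_times(times, cap=None):
    out = []
    for k, t in enumerate(times):
        censored = cap is not None and t > cap
        out.append(
            FirstPassageRecord(
                trajectory_id=k, seed=k,
                cycles_to_fold=-1 if censored else int(t),
                censored=censored,
            )
        )
    return out


class TestFoldingThreshold:
    def test_constant_samples_give_that_value(self):
        assert folding_threshold(np.full(200, 1.3)) == pytest.approx(1.3)

    def test_uniform_quantile(self, rng):
        x = rng.random(50_000)
        assert folding_threshold(x, 0.9) == pytest.approx(0.9, abs=0.01)

    def test_fraction_one_gives_max(self, rng):
        x = rng.random(500)
        assert folding_threshold(x, 1.0) == x.max()

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            folding_threshold(np.ones(50))

    def test_from_traces_picks_nearest_rung(self, compact_pt):
        from barofold.thermo import pool_runs

        traces = pool_runs(compact_pt.traces)
        thr = folding_threshold_from_traces(traces, t_r=0.33)
        rung = min(traces, key=lambda tr: abs(tr.temperature - 0.33))
        assert thr == pytest.approx(np.quantile(rung.rmsd, 0.9))

    def test_separates_folded_from_unfolded(self, compact_pt):
        """Threshold at T_r sits below the mean unfolded-state RMSD."""
        from barofold.thermo import pool_runs

        traces = pool_runs(compact_pt.traces)
        thr = folding_threshold_from_traces(traces, t_r=0.33)
        hottest = max(traces, key=lambda tr: tr.temperature)
        assert thr < hottest.rmsd.mean()


class TestRunFirstPassage:
    def test_native_start_folds_at_cycle_zero(self, compact_model):
        s, cm, p, nat = compact_model
        rec, _, _ = run_first_passage(
            nat.copy(), cm, p, s.ca, threshold=0.5, t_r=0.3, cap=100, seed=1
        )
        assert rec.cycles_to_fold == 0 and not rec.censored

    def test_cap_zero_censors_nonnative_start(self, compact_model, rng):
        s, cm, p, nat = compact_model
        start = Conformation(nat.coords + rng.normal(scale=3.0, size=nat.coords.shape))
        rec, _, _ = run_first_passage(
            start, cm, p, s.ca, threshold=0.1, t_r=0.3, cap=0, seed=1
        )
        assert rec.censored

    def test_reproducible_in_seed(self, compact_pt, compact_model):
        s, cm, p, nat = compact_model
        start = Conformation(compact_pt.unfolded_pool[0].copy())
        out = [
            run_first_passage(start.copy(), cm, p, s.ca, threshold=3.5, t_r=0.33,
                              cap=20_000, seed=77, mirror_symmetric=True)[0]
            for _ in range(2)
        ]
        assert out[0].cycles_to_fold == out[1].cycles_to_fold


class TestSurvivalCurve:
    def test_step_function_when_all_fold_together(self):
        recs = records_from_times([50] * 40)
        c = survival_curve(recs, grid=np.array([1.0, 49, 50, 51, 100]))
        assert list(c.surviving) == [1.0, 1.0, 0.0, 0.0, 0.0]

    def test_survival_at_zero_is_one(self):
        recs = records_from_times([10, 20, 30])
        c = survival_curve(recs, grid=np.array([0.0, 15.0]))
        assert c.surviving[0] == 1.0

    def test_monotone_and_bounded_by_censored_fraction(self, rng):
        times = rng.integers(1, 1000, size=200)
        recs = records_from_times(times, cap=500)
        c = survival_curve(recs)
        assert np.all(np.diff(c.surviving) <= 1e-12)
        assert c.surviving[-1] >= c.censored / c.n_trajectories - 1e-12

    def test_matches_exponential_law(self, rng):
        k, n = 1e-3, 4000
        times = rng.exponential(1 / k, size=n)
        recs = records_from_times(np.ceil(times))
        grid = np.geomspace(10, 5000, 20)
        c = survival_curve(recs, grid=grid)
        expected = np.exp(-k * grid)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(c.surviving - expected) < 4 * se + 2e-3)


class TestFitKineticModel:
    def test_exact_single_exponential_recovered(self):
        k = 2e-4
        grid = np.geomspace(10, 40_000, 40)
        curve = SurvivalCurve(grid=grid, surviving=np.exp(-k * grid),
                              n_trajectories=10_000)
        fit = fit_kinetic_model(curve)
        assert fit.n_components == 1
        assert fit.rates[0] == pytest.approx(k, rel=0.01)

    def test_two_component_mixture_recovered(self):
        k1, k2 = 1e-3, 1e-4
        grid = np.geomspace(10, 100_000, 60)
        s = 0.5 * np.exp(-k1 * grid) + 0.5 * np.exp(-k2 * grid)
        curve = SurvivalCurve(grid=grid, surviving=s, n_trajectories=10_000)
        fit = fit_kinetic_model(curve)
        assert fit.n_components == 2
        assert fit.rates[0] == pytest.approx(k1, rel=0.10)
        assert fit.rates[1] == pytest.approx(k2, rel=0.10)
        assert fit.amplitudes == pytest.approx([0.5, 0.5], abs=0.05)
        # the 1-exponential chi2 is reported, and is much worse
        assert fit.single_exponential_chi2 > 10 * fit.chi2

    def test_constant_curve_flagged(self):
        grid = np.geomspace(1, 100, 20)
        curve = SurvivalCurve(grid=grid, surviving=np.ones(20),
                              n_trajectories=100, censored=100)
        with pytest.raises(ValueError, match="nothing folds"):
            fit_kinetic_model(curve)


class TestPopulationHistogram:
    def test_single_state_single_bin(self):
        h, _, _ = population_histogram(np.full(50, 0.4), np.full(50, 2.0),
                                       q_edges=10, rmsd_edges=10)
        assert h.max() == pytest.approx(100.0)
        assert (h > 0).sum() == 1

    def test_mass_sums_to_hundred(self, rng):
        h, _, _ = population_histogram(rng.random(1000), rng.random(1000) * 8)
        assert h.sum() == pytest.approx(100.0)

    def test_uniform_cloud_is_flat(self, rng):
        n = 40_000
        h, _, _ = population_histogram(
            rng.random(n), rng.random(n), q_edges=np.linspace(0, 1, 5),
            rmsd_edges=np.linspace(0, 1, 5),
        )
        counts = h.ravel() * n / 100.0
        chi2 = ((counts - n / 16) ** 2 / (n / 16)).sum()
        assert stats.chi2.sf(chi2, df=15) > 1e-3

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            population_histogram(np.zeros(3), np.zeros(4))
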