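"""Heat capacity, melting temperature, WHAM and free-energy profiles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from barofold.engine import EnergyTrace, PTConfig, run_parallel_tempering
from barofold.thermo import (
    CvCurve,
    cv_from_wham,
    free_energy_profile,
    heat_capacity,
    melting_temperature,
    pool_runs,
    reweighted_mean_energy,
    wham,
)

from test_engine import BOND, block_se, exact_mean_energy, three_bead_system


def make_trace(energies, t=1.0, q=None):
    e = np.asarray(energies, dtype=float)
    return EnergyTrace(
        temperature=t,
        cycles=np.arange(1, len(e) + 1),
        energies=e,
        q=np.asarray(q, dtype=float) if q is not None else np.zeros_like(e),
        rmsd=np.zeros_like(e),
    )


@pytest.fixture(scope="module")
def three_bead_pt():
    c0, cmap, params = three_bead_system()
    cfg = PTConfig(
        temperatures=np.array([0.25, 0.4, 0.6, 0.9]),
        n_cycles=40_000, n_thermalization=8_000, thin=10, swap_every=5,
        p_collective=0.0, seed=17,
    )
    res = run_parallel_tempering(cfg, cmap, params, c0)
    return res, cmap, params


class TestHeatCapacity:
    def test_constant_energy_gives_zero(self):
        assert heat_capacity(make_trace([-5.0] * 50)) == 0.0

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            heat_capacity(make_trace([-5.0]))

    def test_energy_scaling_quadruples_cv(self, rng):
        e = rng.normal(size=2000)
        assert heat_capacity(make_trace(2 * e)) == pytest.approx(
            4 * heat_capacity(make_trace(e))
        )

    def test_two_level_schottky_value(self, rng):
        """Sampled Cv of a two-level system matches the closed form."""
        t = 1.0
        p1 = math.exp(1 / t) / (1 + math.exp(1 / t))  # weight of E = -1
        n = 100_000
        e = np.where(rng.random(n) < p1, -1.0, 0.0)
        cv_exact = p1 * (1 - p1) / t**2
        cv = heat_capacity(make_trace(e, t=t))
        # delta method: Cv is the sample variance of Bernoulli draws
        se = math.sqrt(p1 * (1 - p1) * (1 - 2 * p1) ** 2 / n + 2 * (p1 * (1 - p1)) ** 2 / n)
        assert abs(cv - cv_exact) < 4 * se + 1e-4


class TestMeltingTemperature:
    def test_synthetic_parabolic_peak_recovered(self):
        t = np.linspace(0.8, 1.8, 11)
        cv = 10 - 40 * (t - 1.3) ** 2
        assert melting_temperature(CvCurve(t, cv)) == pytest.approx(1.3, abs=1e-6)

    def test_two_state_analytic_oracle(self):
        """Schottky-type Cv of a folded/unfolded pair peaks at T_eq to <1%."""
        delta, t_eq = 400.0, 1.0  # unfolded entropy ln g = delta / t_eq
        t = np.linspace(0.9, 1.1, 2001)
        x = np.exp(delta * (1 / t_eq - 1 / t))
        cv = (delta / t) ** 2 * x / (1 + x) ** 2
        tm = melting_temperature(CvCurve(t, cv))
        assert abs(tm - t_eq) / t_eq < 0.01

    def test_monotone_curve_raises(self):
        t = np.linspace(0.5, 1.5, 9)
        with pytest.raises(ValueError, match="edge"):
            melting_temperature(CvCurve(t, t**2))

    def test_plateau_returns_lower_peak_with_warning(self):
        t = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        cv = np.array([1.0, 5.0, 3.0, 5.0, 1.0])
        with pytest.warns(UserWarning, match="duplicate"):
            tm = melting_temperature(CvCurve(t, cv))
        assert tm <= 1.5

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            melting_temperature(CvCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestWham:
    def test_single_temperature_degenerates_to_histogram(self, rng):
        e = rng.normal(loc=-10, scale=2, size=5000)
        tr = make_trace(e, t=0.8)
        w = wham([tr], bin_width=0.5)
        h, _ = np.histogram(e, bins=w.bin_edges)
        occupied = h > 0
        # recovered weights exp(g - E/T) must be proportional to the histogram
        logw = w.log_dos[occupied] - w.bin_centers[occupied] / 0.8
        ratio = np.exp(logw) / h[occupied]
        assert ratio.max() / ratio.min() == pytest.approx(1.0, rel=1e-6)

    def test_density_of_states_vs_exact_enumeration(self, three_bead_pt):
        """3-bead toy: WHAM dos vs quadrature over the bend angle."""
        res, cmap, params = three_bead_pt
        traces = pool_runs(res.traces)
        w = wham(traces, bin_width=0.1)
        assert w.converged

        dn = cmap.d_nat[(0, 2)]
        a = params.well_halfwidth_a
        sigma = params.hardsphere_diameter

        def u(theta):
            r = 2 * BOND * math.sin(theta / 2)
            if r < sigma and r < dn - a:
                return math.inf
            x = r - dn
            return (x / a) ** 2 - 1.0 if abs(x) <= a else 0.0

        omega = np.zeros(len(w.bin_centers))
        for b, (lo, hi) in enumerate(zip(w.bin_edges[:-1], w.bin_edges[1:])):
            omega[b], _ = quad(
                lambda th: math.sin(th) if lo <= u(th) < hi and not math.isinf(u(th)) else 0.0,
                0, math.pi, limit=400,
            )
        occ = np.isfinite(w.log_dos) & (omega > 0)
        p_wham = np.exp(w.log_dos[occ])
        p_wham /= p_wham.sum()
        p_exact = omega[occ] / omega[occ].sum()
        assert np.abs(p_wham - p_exact).max() < 0.05

    def test_reweighted_means_match_direct_traces(self, three_bead_pt):
        res, cmap, params = three_bead_pt
        traces = pool_runs(res.traces)
        # bin width must resolve the toy's narrow energy range
        w = wham(traces, bin_width=0.02)
        for tr in traces:
            direct = tr.energies.mean()
            rew = reweighted_mean_energy(w, traces, tr.temperature)
            assert abs(rew - direct) < 4 * block_se(tr.energies) + 0.02

    def test_cv_consistent_with_energy_derivative(self, three_bead_pt):
        """Fluctuation Cv vs d<E>/dT across the ladder (thermodynamic identity)."""
        res, cmap, params = three_bead_pt
        for tr in pool_runs(res.traces):
            t = tr.temperature
            cv_fluct = heat_capacity(tr)
            dt = 0.01 * t
            dedt = (exact_mean_energy(t + dt, cmap, params)
                    - exact_mean_energy(t - dt, cmap, params)) / (2 * dt)
            se_cv = block_se(tr.energies**2) / t**2 + block_se(tr.energies) / t
            assert abs(cv_fluct - dedt) < 5 * se_cv + 0.02

    def test_trace_order_invariance(self, three_bead_pt):
        res, _, _ = three_bead_pt
        traces = pool_runs(res.traces)
        w1 = wham(traces)
        w2 = wham(list(reversed(traces)))
        g1, g2 = w1.log_dos, w2.log_dos
        occ = np.isfinite(g1) & np.isfinite(g2)
        diff = g1[occ] - g2[occ]
        assert np.ptp(diff) < 1e-5  # equal up to an additive constant

    def test_nonoverlapping_histograms_raise(self):
        t1 = make_trace(np.full(100, 0.0) + np.linspace(0, 0.5, 100), t=0.5)
        t2 = make_trace(np.full(100, -50.0) + np.linspace(0, 0.5, 100), t=1.5)
        with pytest.raises(ValueError, match="overlap"):
            wham([t1, t2])


class TestFreeEnergyProfile:
    def test_low_temperature_minimum_at_high_q(self, compact_pt):
        traces = pool_runs(compact_pt.traces)
        w = wham(traces)
        prof = free_energy_profile(w, traces, t=0.15, q_bins=25)
        assert np.nanmin(prof.f) == 0.0
        k_min = np.nanargmin(prof.f)
        populated = np.nonzero(~prof.empty_bins)[0]
        assert k_min >= populated.max() - 1

    def test_offset_convention_and_empty_bins(self, compact_pt):
        traces = pool_runs(compact_pt.traces)
        w = wham(traces)
        prof = free_energy_profile(w, traces, t=0.35, q_bins=50)
        assert np.nanmin(prof.f) == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.isnan(prof.f[prof.empty_bins]))

    def test_cv_fine_grid_has_interior_peak(self, compact_pt):
        traces = pool_runs(compact_pt.traces)
        w = wham(traces)
        fine = cv_from_wham(w, np.linspace(0.28, 0.5, 60))
        tm = melting_temperature(fine)
        assert 0.3 < tm < 0.45
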