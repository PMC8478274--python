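"""Monte Carlo moves, Metropolis sampling and replica exchange."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from barofold.contacts import ContactMap
from barofold.engine import (
    PTConfig,
    ReplicaSet,
    collective_move,
    local_move,
    metropolis_accept,
    replica_exchange_step,
    run_mc,
    run_parallel_tempering,
)
from barofold.model import OVERLAP, Conformation, ModelParams, pair_energy

BOND = 3.8


def three_bead_system(d_nat=5.0):
    """Analytically tractable toy: one contact across a 3-bead chain.

    The only internal degree of freedom is the bend angle theta at the
    middle bead; r02 = 2 b sin(theta/2) and the equilibrium measure on
    theta is sin(theta) dtheta, so every average reduces to a 1D
    quadrature.
    """
    coords = np.array([[0.0, 0, 0], [BOND, 0, 0], [2 * BOND, 0, 0]])
    cmap = ContactMap(
        n_residues=3, pairs={(0, 2)}, d_nat={(0, 2): d_nat}, min_separation=2
    )
    params = ModelParams(bond_lengths=np.full(2, BOND))
    return Conformation(coords), cmap, params


def exact_mean_energy(t, cmap, params):
    dn = cmap.d_nat[(0, 2)]
    sigma = params.hardsphere_diameter
    a = params.well_halfwidth_a

    def u(theta):
        r = 2 * BOND * math.sin(theta / 2)
        if r < sigma and r < dn - a:
            return math.inf
        return pair_energy(max(r, 1e-9), dn, params)

    def boltz(theta):
        e = u(theta)
        return 0.0 if math.isinf(e) else math.sin(theta) * math.exp(-e / t)

    def e_boltz(theta):
        e = u(theta)
        return 0.0 if math.isinf(e) else e * math.sin(theta) * math.exp(-e / t)

    z, _ = quad(boltz, 0, math.pi, limit=200)
    ez, _ = quad(e_boltz, 0, math.pi, limit=200)
    return ez / z


def block_se(x, n_blocks=10):
    blocks = np.array_split(np.asarray(x), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestLocalMove:
    def test_preserves_adjacent_bonds(self, compact_model, rng):
        _, _, p, nat = compact_model
        for i in (0, 1, 10, 20, 21):
            prop = local_move(nat, i, max_angle=math.pi / 3, rng=rng)
            new = prop.new_coords
            assert np.array_equal(np.delete(new, i, axis=0), np.delete(nat.coords, i, axis=0))
            if i > 0:
                assert np.linalg.norm(new[i] - new[i - 1]) == pytest.approx(
                    np.linalg.norm(nat.coords[i] - nat.coords[i - 1]), abs=1e-9
                )
            if i < nat.n_beads - 1:
                assert np.linalg.norm(new[i] - new[i + 1]) == pytest.approx(
                    np.linalg.norm(nat.coords[i] - nat.coords[i + 1]), abs=1e-9
                )

    def test_zero_angle_is_identity(self, compact_model, rng):
        _, _, _, nat = compact_model
        prop = local_move(nat, 7, max_angle=0.0, rng=rng)
        assert np.allclose(prop.new_coords, nat.coords, atol=1e-12)

    def test_out_of_range_raises(self, compact_model, rng):
        _, _, _, nat = compact_model
        with pytest.raises(ValueError):
            local_move(nat, nat.n_beads, 0.5, rng)

    def test_crankshaft_angle_distribution_uniform(self, compact_model, rng):
        """Recovered rotation angles follow U(-max_angle, max_angle)."""
        _, _, _, nat = compact_model
        i, max_angle = 10, math.pi / 4
        axis = nat.coords[i + 1] - nat.coords[i - 1]
        axis = axis / np.linalg.norm(axis)
        v_old = nat.coords[i] - nat.coords[i - 1]
        p_old = v_old - axis * (v_old @ axis)
        angles = []
        for _ in range(4000):
            prop = local_move(nat, i, max_angle, rng)
            v_new = prop.new_coords[i] - nat.coords[i - 1]
            p_new = v_new - axis * (v_new @ axis)
            dot = p_old @ p_new
            det = axis @ np.cross(p_old, p_new)
            angles.append(math.atan2(det, dot))
        res = stats.kstest(
            angles, stats.uniform(loc=-max_angle, scale=2 * max_angle).cdf
        )
        assert res.pvalue > 1e-3


class TestCollectiveMove:
    def test_tail_vectors_preserved(self, compact_model, rng):
        _, _, _, nat = compact_model
        k = 8
        prop = collective_move(nat, k, rng)
        old_vecs = np.diff(nat.coords[k:], axis=0)
        new_vecs = np.diff(prop.new_coords[k:], axis=0)
        assert np.abs(new_vecs - old_vecs).max() < 1e-12

    def test_end_to_end_change_equals_pivot_displacement(self, compact_model, rng):
        _, _, _, nat = compact_model
        k = 5
        prop = collective_move(nat, k, rng)
        disp = prop.new_coords[k] - nat.coords[k]
        e2e_change = (prop.new_coords[-1] - prop.new_coords[0]) - (
            nat.coords[-1] - nat.coords[0]
        )
        assert np.allclose(e2e_change, disp, atol=1e-12)

    def test_zero_angle_is_identity(self, compact_model, rng):
        _, _, _, nat = compact_model
        prop = collective_move(nat, 5, rng, max_angle=0.0)
        assert np.allclose(prop.new_coords, nat.coords, atol=1e-12)

    def test_pivot_range(self, compact_model, rng):
        _, _, _, nat = compact_model
        with pytest.raises(ValueError):
            collective_move(nat, nat.n_beads - 1, rng)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.1 * k, 1.0, rng) for k in range(100))

    def test_overlap_always_rejected(self, rng):
        assert not any(metropolis_accept(OVERLAP, 1.0, rng) for _ in range(10))

    def test_nonpositive_temperature_raises(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)

    def test_half_acceptance_at_t_ln2(self, rng):
        t = 0.7
        n = 20000
        acc = sum(metropolis_accept(t * math.log(2), t, rng) for _ in range(n))
        se = math.sqrt(0.25 / n)
        assert abs(acc / n - 0.5) < 3 * se

    @pytest.mark.parametrize("de", [0.25, 0.5, 1.0, 2.0])
    def test_acceptance_matches_boltzmann_factor(self, de, rng):
        t = 1.0
        n = 20000
        p = math.exp(-de / t)
        acc = sum(metropolis_accept(de, t, rng) for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * se


class TestRunMc:
    def test_native_frozen_at_low_temperature(self, compact_model):
        _, cm, p, nat = compact_model
        trace, _ = run_mc(nat, cm, p, t=1e-8, n_cycles=300, thin=10, seed=4)
        assert np.all(trace.energies == -cm.n_contacts)

    def test_same_seed_bit_identical(self, compact_model):
        _, cm, p, nat = compact_model
        t1, _ = run_mc(nat, cm, p, t=0.4, n_cycles=500, thin=10, seed=99)
        t2, _ = run_mc(nat, cm, p, t=0.4, n_cycles=500, thin=10, seed=99)
        assert np.array_equal(t1.energies, t2.energies)
        assert np.array_equal(t1.rmsd, t2.rmsd)
        t3, _ = run_mc(nat, cm, p, t=0.4, n_cycles=500, thin=10, seed=100)
        assert not np.array_equal(t1.energies, t3.energies)

    @pytest.mark.parametrize("t", [0.3, 0.6])
    def test_three_bead_mean_energy_matches_quadrature(self, t):
        """Sampled <E> equals the exact 1D Boltzmann integral (detailed balance)."""
        c0, cmap, params = three_bead_system()
        trace, _ = run_mc(c0, cmap, params, t=t, n_cycles=60_000, thin=10,
                          p_collective=0.0, seed=12)
        burn = len(trace.energies) // 5
        e = trace.energies[burn:]
        exact = exact_mean_energy(t, cmap, params)
        assert abs(e.mean() - exact) < 4 * block_se(e) + 0.01


class TestReplicaExchange:
    def _replica_set(self, energies, temps, seed=0):
        n = len(temps)
        confs = [Conformation(np.zeros((2, 3)), e) for e in energies]
        return ReplicaSet(
            temperatures=np.array(temps, dtype=float),
            conformations=confs,
            energies=np.array(energies, dtype=float),
            rng=np.random.default_rng(seed),
        )

    def test_equal_energies_always_swap(self):
        r = self._replica_set([-5.0, -5.0], [0.5, 1.0])
        ids_before = r.replica_ids.copy()
        replica_exchange_step(r)
        assert r.swap_accepts[0] == 1
        assert not np.array_equal(r.replica_ids, ids_before)

    def test_equal_temperatures_always_swap(self):
        r = self._replica_set([-9.0, -2.0], [1.0, 1.0])
        for _ in range(4):
            replica_exchange_step(r)
        # even-parity attempts happen on every other call
        assert r.swap_accepts[0] == r.swap_attempts[0] == 2

    def test_swapping_preserves_marginals_on_toy(self):
        """With exchange on, each rung still matches its own Boltzmann average."""
        c0, cmap, params = three_bead_system()
        temps = np.array([0.3, 0.6])
        cfg = PTConfig(temperatures=temps, n_cycles=60_000, n_thermalization=10_000,
                       thin=10, swap_every=5, p_collective=0.0, seed=21)
        res = run_parallel_tempering(cfg, cmap, params, c0)
        for trace in res.traces[0]:
            exact = exact_mean_energy(trace.temperature, cmap, params)
            e = trace.energies
            assert abs(e.mean() - exact) < 4 * block_se(e) + 0.01


class TestParallelTempering:
    def test_scaled_down_run_mixes(self, compact_model):
        _, cm, p, nat = compact_model
        cfg = PTConfig(
            temperatures=np.array([0.28, 0.33, 0.40, 0.50]),
            n_cycles=20_000, n_thermalization=5_000, thin=20, swap_every=5, seed=8,
        )
        res = run_parallel_tempering(cfg, cm, p, nat)
        assert res.ladder_span_counts[0] > 0
        assert all(len(tr) > 0 for tr in res.traces[0])
        assert len(res.unfolded_pool) > 0
        for tr in res.traces[0]:
            assert np.all(tr.energies >= -cm.n_contacts - 1e-9)

    def test_zero_production_rejected(self, compact_model):
        _, cm, p, nat = compact_model
        cfg = PTConfig(
            temperatures=np.array([0.3, 0.5]), n_cycles=0, n_thermalization=1000,
            seed=1,
        )
        with pytest.raises(ValueError):
            cfg.validate()

    def test_distinct_seeds_distinct_traces(self, compact_model):
        _, cm, p, nat = compact_model
        cfg1 = PTConfig(temperatures=np.array([0.3, 0.5]), n_cycles=2000,
                        n_thermalization=500, thin=20, seed=1)
        cfg2 = PTConfig(temperatures=np.array([0.3, 0.5]), n_cycles=2000,
                        n_thermalization=500, thin=20, seed=2)
        r1 = run_parallel_tempering(cfg1, cm, p, nat)
        r2 = run_parallel_tempering(cfg2, cm, p, nat)
        assert not np.array_equal(r1.traces[0][0].energies, r2.traces[0][0].energies)
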