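import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from metadesk.constants import KB_KCAL, eyring_prefactor, kbt
from metadesk.core import Selection, Trajectory
from metadesk.fes import (
    Axis,
    FesGrid,
    Stage,
    barrier_to_rate,
    cluster_frames,
    compose_energy_ledger,
    convergence_profile,
    eyring_convert,
    find_states,
    marginalize_fes,
    rate_to_barrier,
)
from metadesk.sampling import BiasState, Hill, run_metadynamics
from metadesk.synth import LandscapeSpec, TwoDomainSpec, gen_landscape, gen_two_domain

from oracles import exhaustive_clusters, flood_minima, naive_marginal


def grid2d(values, n=None):
    values = np.asarray(values, dtype=float)
    nx, ny = values.shape
    return FesGrid([Axis("x", -1, 1, nx), Axis("y", -1, 1, ny)], values)


class TestMarginalize:
    def test_separable_surface_reduces_to_component(self, rng):
        f = rng.uniform(0, 5, size=40)
        g = rng.uniform(0, 5, size=30)
        f2 = f[:, None] + g[None, :]
        out = marginalize_fes(grid2d(f2), "x", T=300.0)
        expected = f - f.min()
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_uniform_other_axis_is_exact(self, rng):
        f = rng.uniform(0, 4, size=25)
        f2 = np.repeat(f[:, None], 12, axis=1)
        out = marginalize_fes(grid2d(f2), "x", T=300.0)
        np.testing.assert_allclose(out.values, f - f.min(), atol=1e-12)

    def test_random_grid_matches_naive_summation(self, rng):
        f2 = rng.uniform(0, 8, size=(21, 17))
        grid = grid2d(f2)
        out = marginalize_fes(grid, "x", T=300.0)
        oracle = naive_marginal(f2, grid.axes[1].width, kbt(300.0), axis=1)
        np.testing.assert_allclose(out.values, oracle - oracle.min(), atol=1e-10)
        out_y = marginalize_fes(grid, "y", T=300.0)
        oracle_y = naive_marginal(f2, grid.axes[0].width, kbt(300.0), axis=0)
        np.testing.assert_allclose(out_y.values, oracle_y - oracle_y.min(), atol=1e-10)

    def test_constant_shift_invariance(self, rng):
        f2 = rng.uniform(0, 6, size=(15, 15))
        a = marginalize_fes(grid2d(f2), "x")
        b = marginalize_fes(grid2d(f2 + 7.5), "x")
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_one_dimensional_input_rejected(self):
        g = FesGrid([Axis("x", 0, 1, 5)], np.zeros(5))
        with pytest.raises(ValueError):
            marginalize_fes(g, "x")


def profile(values):
    values = np.asarray(values, dtype=float)
    return FesGrid([Axis("s", 0, len(values), len(values))], values)


class TestFindStates:
    def test_symmetric_double_well(self):
        x = np.linspace(-1.5, 1.5, 121)
        f = 3.0 * ((x) ** 2 - 1) ** 2
        f = f - f.min()
        grid = FesGrid([Axis("s", -1.5, 1.5, 121)], f)
        states = find_states(grid, min_depth=1.0, smooth_window=1)
        assert len(states.minima) == 2
        np.testing.assert_allclose(
            [m.position for m in states.minima], [-1.0, 1.0], atol=0.02
        )
        assert len(states.barriers) == 1
        assert states.barriers[0].energy == pytest.approx(3.0, abs=0.01)

    def test_min_depth_prunes_to_global_minimum(self):
        x = np.linspace(-1.5, 1.5, 121)
        f = 3.0 * (x**2 - 1) ** 2 + 0.5 * x
        grid = FesGrid([Axis("s", -1.5, 1.5, 121)], f - f.min())
        states = find_states(grid, min_depth=50.0, smooth_window=1)
        assert len(states.minima) == 1
        assert not states.barriers

    def test_monotone_profile_has_no_states(self):
        states = find_states(profile(np.linspace(0, 5, 50)), min_depth=0.1)
        assert not states.minima and not states.barriers

    @pytest.mark.parametrize("seed", range(12))
    def test_random_rough_profiles_match_flooding_oracle(self, seed):
        r = np.random.default_rng(seed)
        f = np.cumsum(r.normal(size=60))
        f = f - f.min()
        grid = profile(f)
        for depth in (0.2, 1.0, 2.5):
            states = find_states(grid, min_depth=depth, smooth_window=1)
            idx, barriers = flood_minima(f, depth)
            got = [m.position for m in states.minima]
            expected = [grid.axes[0].centers[i] for i in idx]
            np.testing.assert_allclose(got, expected, atol=1e-12)
            np.testing.assert_allclose(
                [b.energy for b in states.barriers], barriers, atol=1e-12
            )

    def test_barriers_never_below_adjacent_minima(self):
        for seed in range(8):
            r = np.random.default_rng(100 + seed)
            f = np.abs(np.cumsum(r.normal(size=80)))
            states = find_states(profile(f), min_depth=0.3)
            by_label = {m.label: m.energy for m in states.minima}
            for b in states.barriers:
                assert b.energy >= max(by_label[b.from_label], by_label[b.to_label]) - 1e-12


class TestConvergence:
    @staticmethod
    def _bias():
        hills = [Hill([0.1 * (i % 7) - 0.3], [0.1], 0.2, float(i + 1)) for i in range(40)]
        return BiasState(10.0, ["x"], hills)

    def test_all_hills_before_first_checkpoint_is_flat_zero(self):
        bias = self._bias()
        series = convergence_profile(bias, [Axis("x", -1, 1, 51)], [100.0, 200.0, 300.0])
        np.testing.assert_allclose(series, 0.0, atol=1e-15)

    def test_final_checkpoint_is_exactly_zero(self):
        bias = self._bias()
        series = convergence_profile(bias, [Axis("x", -1, 1, 51)], [10.0, 25.0, 40.0])
        assert series[-1] == 0.0
        assert np.all(series >= 0.0)

    def test_converged_run_decreases(self):
        land = gen_landscape(LandscapeSpec())
        land.system.timestep = 0.01
        res = run_metadynamics(
            land.system, [lambda x: (float(x[0]), np.array([1.0]))],
            steps=20_000, walkers=2, pace=50, h0=0.3, sigma=0.1,
            bias_factor=10.0, seed=17,
        )
        checkpoints = np.linspace(20.0, 200.0, 10)
        series = convergence_profile(res.bias, list(land.fes.axes), checkpoints)
        rho, _ = spearmanr(checkpoints, series)
        assert rho < 0


class TestClustering:
    @staticmethod
    def _traj_from_frames(frames):
        pair = gen_two_domain(TwoDomainSpec(beads_per_domain=4, linker_beads=0, seed=1)).pair
        n = pair.inactive.n_atoms
        assert frames.shape[1] == n
        return Trajectory(pair.inactive, frames, np.arange(len(frames), dtype=float))

    def test_identical_frames_form_one_cluster(self):
        base = gen_two_domain(TwoDomainSpec(beads_per_domain=4, linker_beads=0, seed=1))
        frames = np.repeat(base.pair.inactive.coords[None], 5, axis=0)
        traj = self._traj_from_frames(frames)
        sel = Selection(np.arange(frames.shape[1]))
        clusters = cluster_frames(traj, sel, cutoff=0.1)
        assert len(clusters) == 1
        assert clusters[0].centroid == 0
        assert clusters[0].members == [0, 1, 2, 3, 4]

    def test_two_separated_conformers(self, rng):
        base = gen_two_domain(TwoDomainSpec(beads_per_domain=4, linker_beads=0, seed=1))
        a = base.pair.inactive.coords
        b = a + rng.normal(scale=1.0, size=a.shape)  # far from a
        frames = np.stack([a, a + 0.001, b, b + 0.001, a - 0.001])
        traj = self._traj_from_frames(frames)
        sel = Selection(np.arange(a.shape[0]))
        clusters = cluster_frames(traj, sel, cutoff=0.05)
        assert len(clusters) == 2
        assert sorted(clusters[0].members) == [0, 1, 4]
        assert sorted(clusters[1].members) == [2, 3]

    @pytest.mark.parametrize("seed", range(6))
    def test_small_instances_match_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        base = gen_two_domain(TwoDomainSpec(beads_per_domain=4, linker_beads=0, seed=2))
        ref = base.pair.inactive.coords
        frames = ref[None] + r.normal(scale=0.15, size=(8, *ref.shape))
        traj = self._traj_from_frames(frames)
        sel = Selection(np.arange(ref.shape[0]))
        cutoff = 0.2
        clusters = cluster_frames(traj, sel, cutoff)
        oracle = exhaustive_clusters(frames, sel.atom_indices, cutoff)
        assert [(c.centroid, c.members) for c in clusters] == oracle

    def test_empty_trajectory(self):
        base = gen_two_domain(TwoDomainSpec(beads_per_domain=4, linker_beads=0, seed=1))
        traj = Trajectory(
            base.pair.inactive,
            np.zeros((0, base.pair.inactive.n_atoms, 3)),
            np.zeros(0),
        )
        assert cluster_frames(traj, Selection(np.arange(4)), 0.1) == []


class TestEnergyLedger:
    def test_single_stage_passthrough(self):
        res = compose_energy_ledger([Stage("conformational", 16.0, 10.0)])
        assert res.overall_barrier == pytest.approx(16.0)
        assert res.overall_delta_g == pytest.approx(10.0)

    def test_two_stage_composition(self):
        res = compose_energy_ledger(
            [Stage("conformational", 16.0, 10.0), Stage("chemical", 8.0, -20.0)]
        )
        assert res.overall_barrier == pytest.approx(18.0)
        assert res.overall_delta_g == pytest.approx(-10.0)
        assert res.per_stage_barriers == pytest.approx([16.0, 18.0])

    def test_identity_stage_changes_nothing(self):
        stages = [Stage("a", 16.0, 10.0), Stage("b", 8.0, -20.0)]
        base = compose_energy_ledger(stages)
        for pos in range(3):
            with_id = list(stages)
            with_id.insert(pos, Stage("id", 0.0, 0.0))
            res = compose_energy_ledger(with_id)
            assert res.overall_barrier == pytest.approx(base.overall_barrier)
            assert res.overall_delta_g == pytest.approx(base.overall_delta_g)

    def test_profile_stage_equivalent_to_summary(self):
        x = np.linspace(0, 1, 101)
        # sharp transition-state bump on a downhill profile: barrier ≈ 8, ΔG −20
        prof = 12.0 * np.exp(-(((x - 0.2) / 0.05) ** 2)) - 20.0 * x
        grid = FesGrid([Axis("s", 0, 1, 101)], prof - prof.min())
        st = Stage("chemical", profile=grid)
        assert st.delta_g == pytest.approx(-20.0)
        res = compose_energy_ledger([Stage("conf", 16.0, 10.0), st])
        assert res.overall_delta_g == pytest.approx(-10.0)
        assert res.overall_barrier == pytest.approx(10.0 + st.barrier)

    def test_overall_barrier_dominates_stage_barriers(self, rng):
        for _ in range(10):
            stages = [
                Stage(f"s{i}", float(rng.uniform(0, 10)), float(rng.uniform(-8, 8)))
                for i in range(4)
            ]
            res = compose_energy_ledger(stages)
            assert res.overall_barrier >= max(res.per_stage_barriers) - 1e-12


class TestEyring:
    def test_prefactor_rate_has_zero_barrier(self):
        assert rate_to_barrier(eyring_prefactor(300.0), 300.0) == pytest.approx(0.0, abs=1e-12)

    def test_experimental_rate_converts_to_22_kcal(self):
        ea = rate_to_barrier(0.027 / 60.0, 300.0)
        assert round(ea) == 22

    def test_round_trip(self):
        for barrier in (5.0, 18.0, 22.0):
            k = barrier_to_rate(barrier, 300.0)
            assert rate_to_barrier(k, 300.0) == pytest.approx(barrier, rel=1e-12)

    def test_strictly_decreasing_in_rate(self):
        rates = np.logspace(-8, 6, 30)
        barriers = [rate_to_barrier(r, 300.0) for r in rates]
        assert all(a > b for a, b in zip(barriers, barriers[1:]))

    def test_dispatcher_and_domain_errors(self):
        assert eyring_convert("rate_to_barrier", 1.0) == pytest.approx(
            KB_KCAL * 300 * math.log(eyring_prefactor(300.0))
        )
        with pytest.raises(ValueError):
            rate_to_barrier(-1.0)
        with pytest.raises(ValueError):
            eyring_convert("sideways", 1.0)
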