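import numpy as np
import pytest

from ercoupler.metadynamics import (
    CollectiveVariableSpec, FreeEnergySurface, GaussianHill, HarmonicWall,
    MetadynamicsConfig, MetadynamicsState, aggregate_replicas, bias_potential,
    com_distance, coordination_number, deposit_hill, estimate_barrier,
    harmonic_wall_energy, read_hills, reconstruct_fes, run_langevin_mtd,
    write_hills,
)
from ercoupler.synthetic import ToyPotentialSpec, make_toy_potential
from ercoupler.units import kj_to_kcal, kt_kj


def pair_spec(r0=3.0, n=6, m=12):
    return CollectiveVariableSpec(
        kind="coordination_number", group_a=(0,), group_b=(1,), r0=r0, n=n, m=m
    )


class TestCollectiveVariables:
    def test_coordination_limits(self):
        spec = pair_spec()
        near = np.array([[0.0, 0, 0], [1e-9, 0, 0]])
        far = np.array([[0.0, 0, 0], [1e4, 0, 0]])
        assert coordination_number(near, spec) == pytest.approx(1.0)
        assert coordination_number(far, spec) == pytest.approx(0.0, abs=1e-12)

    def test_coordination_at_switch_radius_is_n_over_m(self):
        spec = pair_spec(r0=3.0, n=6, m=12)
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert coordination_number(frame, spec) == pytest.approx(0.5)

    def test_coordination_is_continuous_through_r0(self):
        spec = pair_spec(r0=3.0)
        eps = 1e-8
        lo = coordination_number(np.array([[0.0, 0, 0], [3.0 - eps, 0, 0]]), spec)
        hi = coordination_number(np.array([[0.0, 0, 0], [3.0 + eps, 0, 0]]), spec)
        assert abs(lo - hi) < 1e-6

    def test_com_distance_basics_and_oracle(self, rng):
        spec = CollectiveVariableSpec(
            kind="com_distance", group_a=(0, 1), group_b=(2, 3)
        )
        same = np.zeros((4, 3))
        assert com_distance(same, np.ones(4), spec) == 0.0
        frame = np.zeros((4, 3))
        frame[2:, 0] = 30.0  # 30 Å apart -> 3 nm
        assert com_distance(frame, np.ones(4), spec) == pytest.approx(3.0)
        # mass-weighted oracle on a random system
        frame = rng.random((4, 3)) * 20
        masses = rng.uniform(1, 16, size=4)
        coma = np.average(frame[:2], axis=0, weights=masses[:2])
        comb = np.average(frame[2:], axis=0, weights=masses[2:])
        expected = np.linalg.norm(coma - comb) / 10.0
        assert com_distance(frame, masses, spec) == pytest.approx(expected, abs=1e-12)

    def test_group_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            CollectiveVariableSpec(kind="com_distance", group_a=(0,), group_b=(0, 1))
        with pytest.raises(ValueError, match="m > n > 0"):
            CollectiveVariableSpec(
                kind="coordination_number", group_a=(0,), group_b=(1,), n=12, m=6
            )


class TestHillsAndWall:
    def test_bias_at_center_equals_height(self):
        cfg = MetadynamicsConfig(hill_height=0.6, hill_widths=(0.06, 0.015))
        state = MetadynamicsState(2)
        deposit_hill(state, (0.3, 1.2), cfg)
        assert state.bias(np.array([0.3, 1.2])) == pytest.approx(0.6)

    def test_bias_far_from_hills_vanishes(self):
        cfg = MetadynamicsConfig(hill_height=0.6, hill_widths=(0.1,))
        state = MetadynamicsState(1)
        deposit_hill(state, (0.0,), cfg)
        assert state.bias(np.array([0.9])) < 1e-10  # 9 sigma out

    def test_grid_bias_matches_per_hill_summation_oracle(self, rng):
        hills = [
            GaussianHill(
                center=(rng.uniform(-2, 2), rng.uniform(-2, 2)),
                widths=(0.3, 0.2), height=0.6, deposit_step=i,
            )
            for i in range(50)
        ]
        pts = np.stack(
            np.meshgrid(np.linspace(-2, 2, 21), np.linspace(-2, 2, 21), indexing="ij"),
            axis=-1,
        )
        got = bias_potential(hills, pts)
        expected = np.zeros(pts.shape[:-1])
        for h in hills:
            expo = sum(
                (pts[..., k] - h.center[k]) ** 2 / (2 * h.widths[k] ** 2)
                for k in range(2)
            )
            expected += h.height * np.exp(-expo)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bias_gradient_matches_finite_differences(self, rng):
        state = MetadynamicsState(2)
        cfg = MetadynamicsConfig(hill_widths=(0.3, 0.2))
        for _ in range(10):
            deposit_hill(state, rng.uniform(-1, 1, 2), cfg)
        s = np.array([0.1, -0.2])
        grad = state.bias_gradient(s)
        eps = 1e-6
        for k in range(2):
            dp = s.copy(); dp[k] += eps
            dm = s.copy(); dm[k] -= eps
            fd = (state.bias(dp) - state.bias(dm)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, abs=1e-6)

    def test_harmonic_wall_piecewise_form(self):
        wall = HarmonicWall(cv_index=1, position=3.5, force_constant=1000.0)
        assert harmonic_wall_energy(2.0, wall) == (0.0, 0.0)
        assert harmonic_wall_energy(3.5, wall) == (0.0, 0.0)
        e, g = harmonic_wall_energy(3.6, wall)
        assert e == pytest.approx(1000.0 * 0.1**2)
        assert g == pytest.approx(2 * 1000.0 * 0.1)

    def test_bias_is_nondecreasing_in_time(self, rng):
        state = MetadynamicsState(1)
        cfg = MetadynamicsConfig(hill_widths=(0.2,))
        grid = np.linspace(-2, 2, 41)[:, None]
        prev = state.bias(grid) if state.hills else np.zeros(41)
        for _ in range(20):
            deposit_hill(state, rng.uniform(-1.5, 1.5, 1), cfg)
            cur = state.bias(grid)
            assert np.all(cur >= prev - 1e-12)
            prev = cur


class TestLangevinEngine:
    def test_zero_temperature_run_stays_at_minimum(self):
        sys_ = make_toy_potential(ToyPotentialSpec(kind="double_well_1d", barrier_kj=10))
        cfg = MetadynamicsConfig(temperature=1e-12, total_steps=2000, pace=10**9,
                                 seed=1, dt_ps=0.004)
        run = run_langevin_mtd(sys_, cfg, np.array([1.0]), sample_stride=100,
                               bias_enabled=False)
        assert np.allclose(run.cv_trajectory, 1.0, atol=1e-6)

    def test_equipartition_in_harmonic_well(self):
        """CV variance of a long unbiased run approaches kT/k."""

        class Harmonic:
            n_dof = 1
            n_cvs = 1
            masses = np.array([1.0])
            k = 80.0  # kJ/mol per unit²

            def energy(self, x):
                return 0.5 * self.k * x[0] ** 2

            def gradient(self, x):
                return self.k * x

            def cv_values(self, x):
                return np.asarray(x, float)

            def cv_jacobian(self, x):
                return np.eye(1)

        sys_ = Harmonic()
        cfg = MetadynamicsConfig(temperature=310.0, total_steps=1_000_000,
                                 pace=10**9, seed=11, dt_ps=0.002, friction=2.0)
        run = run_langevin_mtd(sys_, cfg, np.array([0.0]), sample_stride=10,
                               bias_enabled=False)
        var = run.cv_trajectory.var()
        expected = kt_kj(310.0) / sys_.k
        assert var == pytest.approx(expected, rel=0.05)

    def test_fixed_seed_reproduces_hill_list_exactly(self):
        sys_ = make_toy_potential(ToyPotentialSpec(kind="double_well_1d", barrier_kj=10))
        cfg = MetadynamicsConfig(total_steps=5000, pace=100, seed=42, dt_ps=0.004)
        r1 = run_langevin_mtd(sys_, cfg, np.array([-1.0]))
        r2 = run_langevin_mtd(sys_, cfg, np.array([-1.0]))
        assert r1.hills == r2.hills

    def test_host_guest_chain_rule_gradients(self, rng):
        """CV Jacobian and potential gradient agree with finite differences."""
        hg = make_toy_potential(ToyPotentialSpec(kind="host_guest", barrier_kj=8.0))
        x = np.array([0.1, -0.2, 0.05, 4.2, 1.0, -0.5])
        eps = 1e-6
        g = hg.gradient(x)
        jac = hg.cv_jacobian(x)
        for k in range(6):
            dp = x.copy(); dp[k] += eps
            dm = x.copy(); dm[k] -= eps
            assert g[k] == pytest.approx((hg.energy(dp) - hg.energy(dm)) / (2 * eps),
                                         abs=1e-5)
            fd_cv = (hg.cv_values(dp) - hg.cv_values(dm)) / (2 * eps)
            np.testing.assert_allclose(jac[:, k], fd_cv, atol=1e-5)

    def test_wall_confines_host_guest_separation(self):
        """With an upper wall on the COM distance the pair cannot escape."""
        hg = make_toy_potential(ToyPotentialSpec(kind="host_guest", barrier_kj=4.0))
        cfg = MetadynamicsConfig(
            hill_height=0.6, hill_widths=(0.1, 0.05), pace=100, total_steps=30_000,
            seed=2, dt_ps=0.002, temperature=310.0,
            wall=HarmonicWall(cv_index=1, position=1.5, force_constant=2000.0),
        )
        x0 = np.array([0.0, 0.0, 0.0, 4.0, 0.0, 0.0])
        run = run_langevin_mtd(hg, cfg, x0, sample_stride=50)
        assert run.cv_trajectory[:, 1].max() < 1.8  # nm; soft wall overshoot only


class TestFesAndBarrier:
    def test_single_hill_closed_form(self):
        hill = GaussianHill(center=(0.0,), widths=(0.1,), height=0.6, deposit_step=0)
        fes = reconstruct_fes([hill], [(-1.0, 1.0, 201)])
        x = fes.axes[0]
        expected = 0.6 * (1.0 - np.exp(-(x**2) / (2 * 0.1**2)))
        np.testing.assert_allclose(fes.values, expected, atol=1e-12)
        assert fes.values.min() == 0.0
        assert fes.values.max() == pytest.approx(0.6, abs=1e-9)

    def test_uniform_hill_carpet_gives_flat_fes(self):
        hills = [
            GaussianHill(center=(c,), widths=(0.2,), height=0.6, deposit_step=i)
            for i, c in enumerate(np.arange(-3, 3.01, 0.05))
        ]
        fes = reconstruct_fes(hills, [(-1.0, 1.0, 101)])
        assert fes.values.max() - fes.values.min() < 0.05 * 0.6

    def test_empty_hill_list_rejected(self):
        with pytest.raises(ValueError, match="empty hill list"):
            reconstruct_fes([], [(-1, 1, 11)])

    def test_1d_single_maximum_barrier(self):
        ax = np.linspace(-2, 2, 81)
        vals = 10.0 * np.exp(-((ax) ** 2) / 0.1)  # single bump at 0
        fes = FreeEnergySurface((ax,), vals)
        b = estimate_barrier(fes, [(-2.0, -1.5)], [(1.5, 2.0)])
        assert b == pytest.approx(kj_to_kcal(10.0))

    def test_flat_fes_has_zero_barrier(self):
        ax = np.linspace(0, 1, 11)
        fes = FreeEnergySurface((ax,), np.zeros(11))
        assert estimate_barrier(fes, [(0.0, 0.2)], [(0.8, 1.0)]) == 0.0

    def test_two_channel_saddle_selection_is_exact(self):
        """With channels at 10 and 20 kJ/mol the lower saddle sets the barrier."""
        tc = make_toy_potential(
            ToyPotentialSpec(kind="two_channel_2d", saddle_heights_kj=(10.0, 20.0))
        )
        ax = np.linspace(-1.5, 1.5, 121)
        ay = np.linspace(-2.0, 2.0, 161)
        vals = np.array([[tc.energy(np.array([x, y])) for y in ay] for x in ax])
        fes = FreeEnergySurface((ax, ay), vals - vals.min())
        b = estimate_barrier(fes, [(-1.2, -0.8), (-2.0, 2.0)], [(0.8, 1.2), (-2.0, 2.0)])
        assert b == pytest.approx(kj_to_kcal(10.0), abs=1e-12)
        assert b == pytest.approx(2.390057, abs=1e-5)

    def test_overlapping_regions_rejected(self):
        ax = np.linspace(0, 1, 11)
        fes = FreeEnergySurface((ax,), np.zeros(11))
        with pytest.raises(ValueError, match="overlap"):
            estimate_barrier(fes, [(0.0, 0.5)], [(0.4, 1.0)])


class TestReplicas:
    def test_closed_form_mean_and_sd(self):
        est = aggregate_replicas([12.0, 14.0, 16.0])
        assert est.mean == 14.0
        assert est.sd == pytest.approx(2.0)

    def test_single_replica_sd_undefined(self):
        est = aggregate_replicas([9.5])
        assert est.mean == 9.5
        assert np.isnan(est.sd)

    def test_matches_textbook_oracle(self, rng):
        vals = rng.uniform(5, 20, size=5).tolist()
        est = aggregate_replicas(vals)
        assert est.mean == pytest.approx(np.mean(vals))
        assert est.sd == pytest.approx(np.std(vals, ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicas([])


class TestConfigAndHillsIo:
    def test_reference_protocol_round_trips_through_serialization(self):
        cfg = MetadynamicsConfig(
            hill_height=0.6, hill_widths=(0.06, 0.015), pace=1000,
            temperature=310.0, dt_ps=0.004,
            wall=HarmonicWall(cv_index=1, position=3.5, force_constant=1000.0),
        )
        back = MetadynamicsConfig.from_dict(cfg.to_dict())
        assert back.hill_height == 0.6
        assert back.hill_widths == (0.06, 0.015)
        assert back.pace * back.dt_ps == pytest.approx(4.0)  # deposit every 4 ps
        assert back.wall.position == 3.5
        assert back.temperature == 310.0

    def test_hills_file_round_trip(self, tmp_path, rng):
        hills = [
            GaussianHill(
                center=(rng.uniform(-1, 1), rng.uniform(0, 3)),
                widths=(0.06, 0.015), height=0.6, deposit_step=1000 * (i + 1),
            )
            for i in range(5)
        ]
        p = tmp_path / "HILLS"
        write_hills(hills, p, dt_ps=0.004)
        back = read_hills(p, dt_ps=0.004)
        assert len(back) == 5
        for a, b in zip(hills, back):
            assert a.center == pytest.approx(b.center, abs=1e-8)
            assert a.widths == pytest.approx(b.widths, abs=1e-9)
            assert a.height == b.height
            assert a.deposit_step == b.deposit_step

    def test_fes_tsv_round_trip(self, tmp_path):
        hill = GaussianHill(center=(0.2, 1.0), widths=(0.3, 0.4), height=0.6,
                            deposit_step=0)
        fes = reconstruct_fes([hill], [(-1, 1, 21), (0, 2, 31)])
        p = tmp_path / "fes.tsv"
        fes.write_tsv(p)
        back = FreeEnergySurface.read_tsv(p)
        np.testing.assert_allclose(back.values, fes.values, atol=1e-9)


def test_double_well_barrier_recovery_within_tolerance():
    """Standard metadynamics on a 5 k_BT double well recovers the analytic
    barrier within 15% when averaged over three replicas."""
    h = 5 * kt_kj(310.0)
    dw = make_toy_potential(ToyPotentialSpec(kind="double_well_1d", barrier_kj=h))
    barriers = []
    for seed in (1, 2, 3):
        cfg = MetadynamicsConfig(
            hill_height=0.6, hill_widths=(0.1,), pace=200, total_steps=150_000,
            seed=seed, dt_ps=0.004, temperature=310.0, friction=5.0,
        )
        run = run_langevin_mtd(dw, cfg, np.array([-1.0]), sample_stride=10**9)
        fes = reconstruct_fes(run.hills, [(-1.6, 1.6, 161)])
        barriers.append(estimate_barrier(fes, [(-1.2, -0.8)], [(0.8, 1.2)]))
    est = aggregate_replicas(barriers)
    assert est.mean * 4.184 == pytest.approx(h, rel=0.15)
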