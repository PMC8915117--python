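"""IPSO mechanics: schedules, mutation, particle updates, optimisation."""

import numpy as np
import pytest
from scipy import stats

from ecgid.ipso import (
    Particle,
    SwarmConfig,
    inertia_at,
    learning_factor_at,
    mutate,
    optimize,
    update_particle,
)


class TestSchedules:
    def test_inertia_endpoints_and_midpoint(self):
        assert inertia_at(0, 50) == pytest.approx(0.9)
        assert inertia_at(50, 50) == pytest.approx(0.4)
        assert inertia_at(25, 50) == pytest.approx(0.65)

    def test_learning_factor_endpoints_and_midpoint(self):
        assert learning_factor_at(0, 50) == pytest.approx(2.0)
        assert learning_factor_at(50, 50) == pytest.approx(0.5)
        assert learning_factor_at(25, 50) == pytest.approx(1.25)

    def test_schedules_monotone_decreasing(self):
        om = [inertia_at(i, 50) for i in range(51)]
        cf = [learning_factor_at(i, 50) for i in range(51)]
        assert all(a > b for a, b in zip(om, om[1:]))
        assert all(a > b for a, b in zip(cf, cf[1:]))

    def test_zero_max_iter_rejected(self):
        with pytest.raises(ValueError):
            inertia_at(0, 0)
        with pytest.raises(ValueError):
            learning_factor_at(0, 0)


class TestMutate:
    def test_samples_stay_in_bounds_and_look_uniform(self):
        rng = np.random.default_rng(0)
        draws = np.array([mutate((2.0, 5.0), rng) for _ in range(10_000)])
        assert draws.min() >= 2.0 and draws.max() <= 5.0
        ks = stats.kstest(draws, stats.uniform(loc=2.0, scale=3.0).cdf)
        assert ks.pvalue > 0.01

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            mutate((5.0, 2.0), np.random.default_rng(0))


class FixedRng:
    """Generator stub returning fixed uniforms for hand-checked updates."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self, size=None):
        if size is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(size)])


class TestUpdateParticle:
    def test_fixed_point_at_shared_best(self):
        x = np.array([100.0, 1.0])
        p = Particle(position=x.copy(), velocity=np.zeros(2), best_position=x.copy(), best_fitness=1.0)
        update_particle(
            p, x.copy(), 0.9, 2.0, 2.0,
            vmax=np.array([10.0, 1.0]), lo=np.array([0.0, 0.0]),
            hi=np.array([2048.0, 8.0]), rng=np.random.default_rng(0),
        )
        assert np.allclose(p.position, x)

    def test_hand_computed_velocity(self):
        p = Particle(
            position=np.array([10.0, 2.0]),
            velocity=np.array([1.0, -0.5]),
            best_position=np.array([12.0, 3.0]),
            best_fitness=0.0,
        )
        pbest = np.array([20.0, 1.0])
        update_particle(
            p, pbest, 0.9, 1.5, 0.5,
            vmax=np.array([100.0, 100.0]), lo=np.array([0.0, 0.0]),
            hi=np.array([2048.0, 8.0]), rng=FixedRng([1.0, 1.0]),
        )
        # v = 0.9*v + 1.5*1*(ibest-x) + 0.5*1*(pbest-x)
        v_expected = np.array(
            [0.9 * 1.0 + 1.5 * 2.0 + 0.5 * 10.0, 0.9 * -0.5 + 1.5 * 1.0 + 0.5 * -1.0]
        )
        assert np.allclose(p.velocity, v_expected, atol=1e-12)
        assert np.allclose(p.position, np.array([10.0, 2.0]) + v_expected)

    def test_velocity_clamped_to_vmax(self):
        p = Particle(
            position=np.array([0.0, 0.0]),
            velocity=np.zeros(2),
            best_position=np.array([1e6, 1e6]),
            best_fitness=0.0,
        )
        vmax = np.array([3.0, 0.5])
        update_particle(
            p, np.array([1e6, 1e6]), 0.9, 2.0, 2.0,
            vmax=vmax, lo=np.array([-10.0, -10.0]), hi=np.array([1e7, 1e7]),
            rng=FixedRng([1.0, 1.0]),
        )
        assert np.array_equal(np.abs(p.velocity), vmax)


class TestOptimize:
    @staticmethod
    def quadratic(c, g):
        return -((c - 500.0) ** 2 / 2044.0**2 + (g - 2.0) ** 2 / 7.9375**2)

    def test_recovers_known_optimum_within_1pct_of_diagonal(self):
        cfg = SwarmConfig(seed=3)
        c, g, f, hist = optimize(self.quadratic, cfg)
        span = np.array([2048.0 - 4.0, 8.0 - 0.0625])
        dist = np.hypot((c - 500.0) / 1.0, (g - 2.0) * span[0] / span[1])
        assert dist <= 0.01 * np.hypot(*span)

    def test_history_monotone_and_full_length(self):
        cfg = SwarmConfig(seed=1)
        *_, hist = optimize(self.quadratic, cfg)
        assert len(hist) == cfg.max_iter
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_reference_configuration_evaluation_count(self):
        count = [0]

        def counting(c, g):
            count[0] += 1
            return self.quadratic(c, g)

        optimize(counting, SwarmConfig(seed=0))
        assert count[0] == 20 * 50  # population x iterations, one eval each

    def test_identical_seeds_identical_trajectories(self):
        a = optimize(self.quadratic, SwarmConfig(seed=9))
        b = optimize(self.quadratic, SwarmConfig(seed=9))
        assert a == b

    def test_positions_remain_in_box(self):
        seen = []

        def recording(c, g):
            seen.append((c, g))
            return self.quadratic(c, g)

        cfg = SwarmConfig(seed=5, n_particles=10, max_iter=20)
        optimize(recording, cfg)
        cs, gs = np.array([s[0] for s in seen]), np.array([s[1] for s in seen])
        assert cs.min() >= 4.0 and cs.max() <= 2048.0
        assert gs.min() >= 0.0625 and gs.max() <= 8.0

    def test_non_finite_fitness_reported_with_position(self):
        with pytest.raises(FloatingPointError, match="position"):
            optimize(lambda c, g: np.nan, SwarmConfig(seed=0, max_iter=2))

    def test_faster_median_convergence_than_plain_pso(self):
        """Time-varying schedules + mutation should not converge slower than
        a plain swarm (fixed inertia 0.9, fixed factors 2) on the toy."""

        def iters_to_tol(config):
            *_, hist = optimize(self.quadratic, config)
            target = -1e-4
            for i, h in enumerate(hist):
                if h >= target:
                    return i
            return len(hist)

        ipso, plain = [], []
        for seed in range(20):
            ipso.append(iters_to_tol(SwarmConfig(seed=seed)))
            plain.append(
                iters_to_tol(
                    SwarmConfig(
                        seed=seed,
                        omega_start=0.9,
                        omega_end=0.899999,
                        c_max=2.0,
                        c_min=1.999999,
                        mutation_prob=0.0,
                    )
                )
            )
        assert np.median(ipso) <= np.median(plain)


class TestSwarmConfigValidation:
    def test_bad_schedules_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(omega_start=0.4, omega_end=0.9)
        with pytest.raises(ValueError):
            SwarmConfig(c_max=0.5, c_min=2.0)
        with pytest.raises(ValueError):
            SwarmConfig(mutation_prob=1.5)
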