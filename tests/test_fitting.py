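"""Basin-hopping fitting: objective, acceptance rule, bounds and recovery."""

import numpy as np
import pytest

from fixfit import datagen, fitting, kepler, sensitivity
from fixfit.fitting import FitProblem


def _quadratic_problem(**kwargs):
    target = np.array([0.3, 0.7])
    problem = FitProblem(
        forward=lambda x: x,
        target=target,
        bounds=np.array([[0.0, 1.0], [0.0, 1.0]]),
        **kwargs,
    )
    return problem, target


class TestObjective:
    def test_zero_at_generating_point_and_nonnegative(self):
        problem, target = _quadratic_problem()
        assert fitting.objective(target, problem) == pytest.approx(0.0, abs=1e-15)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert fitting.objective(rng.random(2), problem) >= 0.0

    def test_matches_bruteforce_sum(self):
        problem, target = _quadratic_problem()
        z = np.array([0.9, 0.1])
        expected = sum((z[i] - target[i]) ** 2 for i in range(2))
        assert fitting.objective(z, problem) == pytest.approx(expected, rel=1e-12)

    def test_forward_failure_returns_penalty(self):
        def bad(_x):
            raise ValueError("outside domain")
        problem = FitProblem(forward=bad, target=np.zeros(2), bounds=[[0, 1], [0, 1]])
        assert fitting.objective(np.array([0.5, 0.5]), problem) == fitting.FORWARD_FAILURE_PENALTY


class TestAcceptanceProbability:
    def test_equal_energies_always_accept(self):
        assert fitting.acceptance_probability(1.0, 1.0, 2.0) == 1.0

    def test_improving_step_always_accepted(self):
        assert fitting.acceptance_probability(0.1, 5.0, 0.3) == 1.0

    def test_one_temperature_gap_gives_inverse_e(self):
        assert fitting.acceptance_probability(1.5, 0.5, 1.0) == pytest.approx(np.exp(-1.0))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            fitting.acceptance_probability(1.0, 0.0, 0.0)


class TestLatentBounds:
    def test_contains_pool_and_pads_five_percent(self):
        rng = np.random.default_rng(1)
        latents = rng.normal(size=(500, 3)) * np.array([1.0, 5.0, 0.1])
        bounds = fitting.latent_bounds(latents)
        assert np.all(latents >= bounds[:, 0]) and np.all(latents <= bounds[:, 1])
        observed = latents.max(axis=0) - latents.min(axis=0)
        np.testing.assert_allclose(bounds[:, 1] - bounds[:, 0], 1.1 * observed, rtol=1e-12)

    def test_normalize_roundtrip(self):
        latents = np.random.default_rng(2).normal(size=(100, 2))
        bounds = fitting.latent_bounds(latents)
        problem = FitProblem(forward=lambda x: x, target=np.zeros(2), bounds=bounds)
        z = np.random.default_rng(3).random(2)
        np.testing.assert_allclose(problem.normalize(problem.denormalize(z)), z, atol=1e-12)

    def test_degenerate_coordinate_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            fitting.latent_bounds(np.ones((10, 2)))


class TestBasinHop:
    def test_double_well_matches_grid_oracle(self):
        # residuals r = (a (x-0.3)(x-0.8), b (x-0.8)) give a quartic RSS with a
        # local minimum near 0.3 and the global minimum at 0.8
        def forward(x):
            return np.array([6.0 * (x[0] - 0.3) * (x[0] - 0.8), 0.35 * (x[0] - 0.8)])

        problem = FitProblem(forward=forward, target=np.zeros(2), bounds=[[0.0, 1.0]],
                             T=0.05, niter=60, seed=4)
        result = fitting.basin_hop(problem)
        grid = np.linspace(0, 1, 200001)
        rss = (6.0 * (grid - 0.3) * (grid - 0.8)) ** 2 + (0.35 * (grid - 0.8)) ** 2
        x_oracle = grid[np.argmin(rss)]
        assert result.x_best_denorm[0] == pytest.approx(x_oracle, abs=1e-4)

    def test_same_seed_identical_trace(self):
        problem_a, _ = _quadratic_problem(seed=9, niter=20)
        problem_b, _ = _quadratic_problem(seed=9, niter=20)
        a = fitting.basin_hop(problem_a)
        b = fitting.basin_hop(problem_b)
        assert a.fun == b.fun
        np.testing.assert_array_equal(a.hops_frame().to_numpy(), b.hops_frame().to_numpy())

    def test_running_best_is_monotone(self):
        problem, _ = _quadratic_problem(seed=0, niter=30)
        result = fitting.basin_hop(problem)
        best = np.minimum.accumulate([f for _z, f, _a in result.hops])
        assert np.all(np.diff(best) <= 0)
        assert result.fun == pytest.approx(min(f for _z, f in result.trace), abs=1e-12)


class TestLatentFitting:
    def test_recovery_of_decoder_generated_targets(self, kepler_batch, kepler_k2_model):
        latents = sensitivity.encode(kepler_batch.norm_params, kepler_k2_model)
        bounds = fitting.latent_bounds(latents)
        rng = np.random.default_rng(0)
        errors = []
        for _ in range(20):
            z_true = rng.random(2)
            target = kepler_k2_model.decode(bounds[:, 0] + z_true * (bounds[:, 1] - bounds[:, 0]))[0]
            problem = fitting.decoder_problem(kepler_k2_model, target, bounds,
                                              niter=30, seed=int(rng.integers(2**31)), T=0.5)
            result = fitting.basin_hop(problem)
            errors.append(np.max(np.abs(result.x_best - z_true)))
        assert np.median(errors) < 1e-2

    def test_native_fit_degenerate_latent_fit_unique(self, kepler_batch, kepler_k2_model):
        """Native 4-parameter fits admit many distinct optima (m1 is free and
        (m2, w0) trade off); latent-space fits collapse to a single solution."""
        space = datagen.ParameterSpace.kepler()
        grid = kepler.default_theta_grid(100)
        true_raw = kepler_batch.raw_params[10]
        e, l = [], []

        def forward(raw):
            p = kepler.KeplerParams(*raw)
            return np.log(kepler.orbit_radii(kepler.composite_params(p), grid).r)

        target = forward(true_raw)
        native = FitProblem(
            forward=forward, target=target,
            bounds=np.column_stack([space.lows, space.highs]),
            T=0.01, niter=80, seed=21,
        )
        res_native = fitting.basin_hop(native)
        # near-optimal accepted hops spread widely in parameter space
        hops = res_native.hops_frame()
        good = hops[hops["objective"] <= res_native.fun * 1.01 + 1e-9]
        pts = good[[c for c in good.columns if c.startswith("z")]].to_numpy()
        d_max = max(np.linalg.norm(a - b) for a in pts for b in pts)
        assert len(pts) >= 2 and d_max > 0.1

        # latent-space fit on the same sample: all near-optimal hops cluster
        latents = sensitivity.encode(kepler_batch.norm_params, kepler_k2_model)
        bounds = fitting.latent_bounds(latents)
        target_latent = kepler_k2_model.decode(
            sensitivity.encode(kepler_batch.norm_params[10], kepler_k2_model))[0]
        latent_problem = fitting.decoder_problem(kepler_k2_model, target_latent, bounds,
                                                 T=0.5, niter=80, seed=22)
        res_latent = fitting.basin_hop(latent_problem)
        hops_l = res_latent.hops_frame()
        good_l = hops_l[hops_l["objective"] <= res_latent.fun * 1.01 + 1e-9]
        pts_l = good_l[[c for c in good_l.columns if c.startswith("z")]].to_numpy()
        spread = max(np.linalg.norm(p - res_latent.x_best) for p in pts_l)
        assert spread < 0.05
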