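"""MML-EM machinery: likelihood, E-step tables, gradients, M-step and the
EM driver, checked against brute-force oracles on toy instances."""

import numpy as np
import pytest

from unfoldirt import (
    CategoryScale,
    GgumItemParams,
    ModelSpec,
    ParamSet,
    ResponseData,
    build_grid,
    default_starts,
    fit_mml_em,
    ggum_probs,
    marginal_loglik,
)
from unfoldirt.estimate import (
    complete_data_gradient,
    estep,
    item_logprob_matrix,
    mstep,
    _cd_value_grad,
)
from unfoldirt.exceptions import ConfigurationError, DataError
from conftest import random_paramset


def _probs_scalar(spec, params, theta):
    """Independent scalar route to the category probabilities."""
    out = np.exp(item_logprob_matrix(spec, params, np.array([theta]))[:, 0, :])
    return out


class TestResponseData:
    def test_out_of_range_code_named(self):
        with pytest.raises(DataError, match="person 1, item 2"):
            ResponseData(np.array([[0, 1, 2], [1, 0, 7]]), 3)

    def test_pattern_counts_sum_to_persons(self, rng):
        codes = rng.integers(0, 4, (50, 4))
        data = ResponseData(codes, 3)
        _, counts = data.collapse()
        assert counts.sum() == 50


class TestMarginalLoglik:
    def test_matches_brute_force_double_sum(self, small_grid):
        """3 persons x 2 binary GGUM items against a direct node-item sum."""
        spec = ModelSpec.from_kernel("UM8", 2, 1)
        params = ParamSet(
            delta=np.array([-0.7, 0.9]), alpha=np.array([1.2, 0.8]),
            thresh=np.array([[-0.5], [-1.1]]),
        )
        data = ResponseData(np.array([[0, 1], [1, 1], [1, 0]]), 1)
        sc = CategoryScale(1)
        w = small_grid.weights
        ll_oracle = 0.0
        for row in data.codes:
            tot = 0.0
            for q, v in enumerate(small_grid.nodes[:, 0]):
                prod = 1.0
                for i, z in enumerate(row):
                    p = ggum_probs(
                        v,
                        GgumItemParams(params.alpha[i], params.delta[i],
                                       tau=np.r_[0.0, params.thresh[i]]),
                        sc,
                    )
                    prod *= p[z]
                tot += w[q] * prod
            ll_oracle += np.log(tot)
        assert marginal_loglik(data, spec, params, small_grid) == pytest.approx(
            ll_oracle, abs=1e-10
        )

    def test_all_missing_person_contributes_zero(self, toy_ggum, small_grid):
        spec, params, data = toy_ggum
        augmented = ResponseData(
            np.vstack([data.codes, [[-1, -1, -1]]]), data.C
        )
        assert marginal_loglik(augmented, spec, params, small_grid) == \
            pytest.approx(marginal_loglik(data, spec, params, small_grid), abs=1e-10)

    def test_duplicating_persons_doubles_loglik(self, toy_ggum, small_grid):
        spec, params, data = toy_ggum
        doubled = ResponseData(np.vstack([data.codes, data.codes]), data.C)
        assert marginal_loglik(doubled, spec, params, small_grid) == pytest.approx(
            2 * marginal_loglik(data, spec, params, small_grid), abs=1e-9
        )


class TestEStep:
    def test_conservation(self, toy_ggum, small_grid):
        """sum_z sum_q r_izq equals the non-missing count per item."""
        spec, params, data = toy_ggum
        codes = data.codes.copy()
        codes[0, 1] = -1
        codes[3, 0] = -1
        data = ResponseData(codes, data.C)
        tables = estep(data, spec, params, small_grid)
        for i in range(spec.n_items):
            expected = int((codes[:, i] >= 0).sum())
            assert tables.r[i].sum() == pytest.approx(expected, abs=1e-9)

    def test_near_flat_likelihood_returns_prior(self, small_grid):
        """With a nearly non-discriminating item the posterior is the prior."""
        spec = ModelSpec.from_kernel("UM8", 1, 3)
        params = ParamSet(
            delta=np.array([0.3]), alpha=np.array([1e-3]),
            thresh=np.array([[-1.0, -0.6, -0.2]]),
        )
        data = ResponseData(np.array([[2]]), 3)
        tables = estep(data, spec, params, small_grid)
        np.testing.assert_allclose(
            tables.r[0, 2], small_grid.weights, rtol=2e-3
        )

    def test_matches_brute_force_expected_counts(self, small_grid):
        """2 persons x 2 items against the expected-frequency ratio formula."""
        spec = ModelSpec.from_kernel("UM8", 2, 2)
        params = ParamSet(
            delta=np.array([-0.5, 0.7]), alpha=np.array([1.0, 1.3]),
            thresh=np.array([[-0.9, -0.3], [-1.2, -0.4]]),
        )
        data = ResponseData(np.array([[0, 2], [2, 1]]), 2)
        tables = estep(data, spec, params, small_grid)
        P = np.exp(item_logprob_matrix(spec, params, small_grid.nodes))
        w = small_grid.weights
        r_oracle = np.zeros_like(tables.r)
        for row in data.codes:
            lik = w * np.prod([P[i, :, z] for i, z in enumerate(row)], axis=0)
            post = lik / lik.sum()
            for i, z in enumerate(row):
                r_oracle[i, z] += post
        np.testing.assert_allclose(tables.r, r_oracle, atol=1e-12)


@pytest.mark.parametrize("kernel,kw", [
    ("UM8", {}), ("UM3", {}), ("UM6", {}), ("UM1", {}),
    ("HCM", {}), ("GUM", {}), ("ALM", {}), ("SSLM", {}),
    ("GUM", {"threshold_mode": "item"}),
    ("MUM-HCM", {"n_dims": 2, "item_dimension": [0, 0, 1, 1]}),
])
def test_complete_data_gradient_matches_central_difference(kernel, kw, rng):
    """Analytic complete-data gradients agree with a numerical oracle."""
    spec = ModelSpec.from_kernel(kernel, 4, 3, **kw)
    params = random_paramset(spec, rng)
    grid = build_grid((-4, 4), 9, spec.n_dims)
    r = rng.random((4, 4, grid.n_nodes))
    x0 = params.pack(spec, include_density=False)
    f0, g = _cd_value_grad(x0, spec, params, r, grid.nodes)
    h = 1e-6
    for j in range(x0.size):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        num = (_cd_value_grad(xp, spec, params, r, grid.nodes)[0]
               - _cd_value_grad(xm, spec, params, r, grid.nodes)[0]) / (2 * h)
        assert g[j] == pytest.approx(num, abs=2e-5), f"param {j}"


class TestCompleteDataGradient:
    def test_linear_in_expected_counts(self, toy_ggum, small_grid):
        spec, params, data = toy_ggum
        tables = estep(data, spec, params, small_grid)
        g1 = complete_data_gradient(1, tables, spec, params, small_grid)
        tables.r *= 3.0
        g3 = complete_data_gradient(1, tables, spec, params, small_grid)
        np.testing.assert_allclose(g3, 3 * g1, rtol=1e-12)

    def test_small_at_mstep_optimum(self, toy_ggum, small_grid, rng):
        spec, params, _ = toy_ggum
        from unfoldirt.simulate import gen_responses
        data, _ = gen_responses(params, spec, 120, seed=31)
        fit = fit_mml_em(data, spec, grid=small_grid, starts=params, tol=1e-8,
                         max_iter=300)
        tables = estep(data, spec, fit.estimates, small_grid)
        opt = mstep(tables, spec, fit.estimates, small_grid, maxiter=200)
        lo = np.array([b[0] for b in spec.bounds(include_density=False)])
        hi = np.array([b[1] for b in spec.bounds(include_density=False)])
        vec = opt.pack(spec, include_density=False)
        interior = (vec - lo > 1e-4) & (hi - vec > 1e-4)
        # per-item layout: delta_i, alpha_i, tau_i1..tau_iC
        for i in range(spec.n_items):
            g = complete_data_gradient(i, tables, spec, opt, small_grid)
            sel = np.array([interior[i], interior[3 + i],
                            *interior[6 + 3 * i: 6 + 3 * (i + 1)]])
            assert np.max(np.abs(g[sel])) < 1e-3


class TestMStep:
    def test_fixed_point_at_optimum(self, toy_ggum, small_grid):
        spec, params, data = toy_ggum
        tables = estep(data, spec, params, small_grid)
        once = mstep(tables, spec, params, small_grid, maxiter=200)
        twice = mstep(tables, spec, once, small_grid, maxiter=200)
        assert np.max(np.abs(once.pack(spec) - twice.pack(spec))) < 1e-5

    def test_objective_never_decreases_over_random_starts(self, toy_ggum,
                                                          small_grid, rng):
        spec, _, data = toy_ggum
        base = estep(data, spec, random_paramset(spec, rng), small_grid)
        for _ in range(100):
            start = random_paramset(spec, rng)
            f_before = _cd_value_grad(
                start.pack(spec, include_density=False), spec, start, base.r,
                small_grid.nodes,
            )[0]
            updated = mstep(base, spec, start, small_grid, update_density=False)
            f_after = _cd_value_grad(
                updated.pack(spec, include_density=False), spec, updated,
                base.r, small_grid.nodes,
            )[0]
            assert f_after <= f_before + 1e-9

    def test_constrained_alpha_stays_one(self, small_grid, rng):
        spec = ModelSpec.from_kernel("UM3", 3, 3)
        codes = rng.integers(0, 4, (40, 3))
        data = ResponseData(codes, 3)
        params = default_starts(data, spec)
        tables = estep(data, spec, params, small_grid)
        new = mstep(tables, spec, params, small_grid)
        np.testing.assert_array_equal(new.alpha, 1.0)


class TestFitMmlEm:
    @pytest.mark.parametrize("kernel", ["UM3", "UM8", "HCM", "GUM", "UM2"])
    def test_em_ascent_on_random_toys(self, kernel, small_grid):
        """Observed log-likelihood is nondecreasing on random toy datasets."""
        spec = ModelSpec.from_kernel(kernel, 4, 3)
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            truth = random_paramset(spec, rng)
            data = ResponseData(rng.integers(0, 4, (30, 4)), 3)
            fit = fit_mml_em(data, spec, grid=small_grid, max_iter=8,
                             seed=s)
            ll = fit.trace["loglik"].to_numpy()
            slack = 1e-8 * np.maximum(1.0, np.abs(ll[:-1]))
            assert np.all(np.diff(ll) >= -slack), f"{kernel} seed {s}"

    def test_matches_lattice_search_on_tiny_problem(self, small_grid):
        """EM optimum dominates a brute-force coarse-lattice search."""
        spec = ModelSpec.from_kernel(
            "UM4", 2, 1, sigma2_free=False
        )  # alpha fixed, item tau, sigma fixed: 4 free parameters
        data = ResponseData(
            np.array([[0, 1], [1, 1], [1, 0], [0, 0], [1, 1]]), 1
        )
        deltas = np.arange(-2.0, 2.01, 0.5)
        taus = np.arange(-2.0, 1.01, 0.5)
        best, best_par = -np.inf, None
        for d1 in deltas:
            for d2 in deltas:
                for t1 in taus:
                    for t2 in taus:
                        p = ParamSet(np.array([d1, d2]), np.ones(2),
                                     np.array([[t1], [t2]]))
                        ll = marginal_loglik(data, spec, p, small_grid)
                        if ll > best:
                            best, best_par = ll, p
        fit = fit_mml_em(data, spec, grid=small_grid, starts=best_par,
                         tol=1e-6, max_iter=400)
        assert fit.loglik >= best - 1e-8

    def test_constraint_reduction_reproduces_um3(self, rng):
        """UM8 with alpha=1 and common tau constraints is the UM3 fit."""
        from unfoldirt.simulate import example1_design, gen_items, gen_responses
        design = example1_design("UM3", n_persons=120, n_items=4)
        truth = gen_items(design, seed=5)
        spec3 = design.spec()
        data, _ = gen_responses(truth, spec3, 120, seed=6)
        spec8c = ModelSpec.from_kernel(
            "UM8", 4, 3, alpha_free=False, threshold_mode="common",
            sigma2_free=True,
        )
        grid = build_grid((-4, 4), 31, 1)
        f3 = fit_mml_em(data, spec3, grid=grid, delta_signs=np.sign(truth.delta))
        f8 = fit_mml_em(data, spec8c, grid=grid, delta_signs=np.sign(truth.delta))
        assert f3.loglik == pytest.approx(f8.loglik, abs=1e-6)
        np.testing.assert_allclose(f3.packed(), f8.packed(), atol=1e-6)

    def test_collapsed_patterns_identical_to_raw(self, rng, small_grid):
        """Shuffling persons (same multiset of patterns) changes nothing."""
        spec = ModelSpec.from_kernel("GUM", 3, 3)
        codes = rng.integers(0, 4, (60, 3))
        codes[10:20] = codes[:10]          # force duplicates
        data1 = ResponseData(codes, 3)
        data2 = ResponseData(codes[rng.permutation(60)], 3)
        f1 = fit_mml_em(data1, spec, grid=small_grid, max_iter=25)
        f2 = fit_mml_em(data2, spec, grid=small_grid, max_iter=25)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.packed(), f2.packed())

    def test_degenerate_data_flagged_not_crashing(self, small_grid):
        """Constant responses (zero-variance traits) yield a flagged fit."""
        spec = ModelSpec.from_kernel("UM3", 3, 3)
        data = ResponseData(np.full((40, 3), 2), 3)
        fit = fit_mml_em(data, spec, grid=small_grid, max_iter=60)
        assert not (fit.converged and not fit.boundary)

    def test_spec_data_mismatch_rejected(self, toy_ggum, small_grid):
        spec, params, data = toy_ggum
        other = ModelSpec.from_kernel("UM8", 5, 3)
        with pytest.raises(ConfigurationError):
            fit_mml_em(data, other, grid=small_grid)


class TestDefaultStarts:
    def test_sign_mapping(self, toy_ggum):
        spec, _, data = toy_ggum
        starts = default_starts(data, spec, delta_signs=[+1, -1, +1])
        np.testing.assert_array_equal(starts.delta, [1.0, -1.0, 1.0])

    def test_reproducible_without_signs(self, toy_ggum):
        spec, _, data = toy_ggum
        s1 = default_starts(data, spec, seed=7)
        s2 = default_starts(data, spec, seed=7)
        s3 = default_starts(data, spec, seed=8)
        np.testing.assert_array_equal(s1.delta, s2.delta)
        assert not np.array_equal(s1.delta, s3.delta)

    def test_starts_respect_constraints(self, rng):
        data = ResponseData(rng.integers(0, 4, (30, 4)), 3)
        spec = ModelSpec.from_kernel("UM3", 4, 3)
        starts = default_starts(data, spec)
        np.testing.assert_array_equal(starts.alpha, 1.0)
        assert starts.thresh.shape == (3,)
        lo = np.array([b[0] for b in spec.bounds()])
        hi = np.array([b[1] for b in spec.bounds()])
        vec = starts.pack(spec)
        assert np.all(vec >= lo) and np.all(vec <= hi)
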