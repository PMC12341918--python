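"""REML engine: closed forms, dense-criterion oracle, EM, LR tests."""

import numpy as np
import pytest

from triploidcross.lmm import (AbsorbedTerm, ConvergenceError, MixedModel,
                               RandomTerm, lr_test)


def one_way_layout(n_groups, reps, sg2, se2, rng):
    eff = rng.normal(0, np.sqrt(sg2), n_groups)
    y = np.repeat(eff, reps) + rng.normal(0, np.sqrt(se2), n_groups * reps)
    n = n_groups * reps
    term = RandomTerm("grp", levels=list(range(n_groups)),
                      z=np.repeat(np.arange(n_groups), reps))
    model = MixedModel(y, np.ones((n, 1)), np.arange(n),
                       np.ones(n, dtype=int), random=[term], n_cycles=1)
    return y, model


def anova_reml(y, n_groups, reps):
    """Closed-form REML for the balanced one-way layout."""
    ym = y.reshape(n_groups, reps)
    gm = ym.mean(1)
    msb = reps * np.sum((gm - y.mean()) ** 2) / (n_groups - 1)
    mse = np.sum((ym - gm[:, None]) ** 2) / (n_groups * (reps - 1))
    return max((msb - mse) / reps, 0.0), mse


def messy_model(rng, n_hybrids=25, n_par=4, n_cross=6):
    """Unbalanced 3-cycle design with a GRM term, iid term and absorbed term."""
    G = np.eye(n_par) + 0.3
    par_of = rng.integers(0, n_par, n_hybrids)
    cross_of = rng.integers(0, n_cross, n_hybrids)
    rows = [(h, c) for h in range(n_hybrids)
            for c in sorted(rng.choice([1, 2, 3], size=rng.integers(2, 4),
                                       replace=False))]
    rows = np.array(rows)
    y = rng.normal(0, 1, len(rows))
    X = np.column_stack([np.ones(len(rows)), rng.normal(0, 1, len(rows))])
    terms = [
        RandomTerm("par", levels=list(range(n_par)), z=par_of[rows[:, 0]],
                   G=G),
        RandomTerm("cross", levels=list(range(n_cross)),
                   z=cross_of[rows[:, 0]]),
    ]
    absorbed = AbsorbedTerm("hyb", group=np.array(["all"] * len(rows),
                                                  dtype=object))
    return MixedModel(y, X, rows[:, 0], rows[:, 1], random=terms,
                      absorbed=absorbed, n_cycles=3)


class TestReml:
    def test_balanced_one_way_matches_closed_form(self, rng):
        y, model = one_way_layout(20, 5, 1.0, 1.0, rng)
        fit = model.fit()
        sg2, se2 = anova_reml(y, 20, 5)
        assert fit.variances["sigma2_grp"] == pytest.approx(sg2, abs=1e-6)
        assert fit.R[0, 0] == pytest.approx(se2, abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        m = messy_model(rng)
        theta = m.pack({p: 0.4 + 0.1 * i for i, p in enumerate(m.param_names)},
                       np.array([[1.0, 0.2, 0.1], [0.2, 0.9, 0.3],
                                 [0.1, 0.3, 1.1]]))
        _, grad = m._neg2_and_grad(theta)
        num = np.zeros_like(theta)
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            num[i] = (m._neg2_and_grad(theta + e)[0]
                      - m._neg2_and_grad(theta - e)[0]) / 2e-6
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-5)

    def test_criterion_agrees_with_dense_evaluation_on_a_grid(self, rng):
        """Profile criterion equals a direct dense REML evaluation."""
        m = messy_model(rng, n_hybrids=15)
        fit = m.fit()
        base_v = dict(fit.variances)
        for mult in (0.6, 1.0, 1.7):
            v = {k: max(val * mult, 1e-6) for k, val in base_v.items()}
            fast = m.neg2_reml(v, fit.R)
            dense = m.neg2_reml_dense(v, fit.R)
            assert fast == pytest.approx(dense, rel=1e-10)

    def test_restart_from_solution_is_stationary(self, rng):
        m = messy_model(rng)
        fit = m.fit()
        fit2 = m.fit(start=(fit.variances, fit.R))
        assert abs(fit2.loglik - fit.loglik) < 1e-6

    def test_zero_variance_is_pinned_at_the_boundary(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            y, model = one_way_layout(12, 4, 0.0, 1.0, rng)
            fit = model.fit()
            hits += fit.boundary["sigma2_grp"]
        assert hits / reps > 0.4

    def test_unstructured_r_recovers_sample_covariance(self, rng):
        """With only an intercept, REML R equals the sample cross-cycle
        covariance of the residuals."""
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.2, 0.6], [0.2, 0.6, 1.5]])
        L = np.linalg.cholesky(R)
        n_pl = 300
        e = rng.standard_normal((n_pl, 3)) @ L.T
        y = (5.0 + e).ravel()
        plant = np.repeat(np.arange(n_pl), 3)
        cycle = np.tile([1, 2, 3], n_pl)
        m = MixedModel(y, np.ones((3 * n_pl, 1)), plant, cycle, n_cycles=3)
        fit = m.fit()
        emat = e - e.mean(axis=0)
        sample = emat.T @ emat / (n_pl - 1)
        # the single intercept (instead of per-cycle means) leaves a small
        # discrepancy relative to the cycle-centered sample covariance
        np.testing.assert_allclose(fit.R, sample, atol=0.02)

    def test_blups_sum_to_zero_in_balanced_identity_design(self, rng):
        y, model = one_way_layout(15, 6, 1.0, 1.0, rng)
        fit = model.fit()
        assert fit.blups["grp"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_rank_deficient_design_names_aliased_columns(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="dup"):
            MixedModel(rng.normal(size=n), X, np.arange(n),
                       np.ones(n, dtype=int), n_cycles=1,
                       x_names=["intercept", "dup"])

    def test_duplicate_plant_cycle_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            MixedModel(rng.normal(size=4), np.ones((4, 1)), [0, 0, 1, 1],
                       [1, 1, 1, 2], n_cycles=3)


class TestEm:
    def test_em_iterations_are_monotone_in_likelihood(self, rng):
        m = messy_model(rng, n_hybrids=20)
        # complete cycles so the residual matrix is EM-updatable
        rows = np.array([(h, c) for h in range(20) for c in (1, 2, 3)])
        terms = [RandomTerm("grp", levels=list(range(5)),
                            z=rng.integers(0, 5, 20)[rows[:, 0]])]
        m = MixedModel(rng.normal(0, 1, 60), np.ones((60, 1)), rows[:, 0],
                       rows[:, 1], random=terms, n_cycles=3)
        v = {p: 0.5 for p in m.param_names}
        R = np.eye(3)
        prev = m.neg2_reml(v, R)
        for _ in range(20):
            v, R = m.em_step(v, R)
            cur = m.neg2_reml(v, R)
            assert cur <= prev + 1e-8
            prev = cur

    def test_em_only_fit_approaches_quasi_newton_solution(self, rng):
        y, model = one_way_layout(10, 5, 1.0, 0.5, rng)
        qn = model.fit()
        em = model.fit(method="em", max_iter=500)
        assert em.loglik == pytest.approx(qn.loglik, abs=1e-4)


class TestLrTest:
    def test_identical_models_give_zero_statistic(self, rng):
        _, model = one_way_layout(10, 4, 1.0, 1.0, rng)
        fit = model.fit()
        stat, df, p = lr_test(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_mismatched_fixed_effects_rejected(self, rng):
        _, m1 = one_way_layout(10, 4, 1.0, 1.0, rng)
        f1 = m1.fit()
        y2, m2 = one_way_layout(10, 4, 1.0, 1.0, rng)
        m2.x_names = ["other"]
        f2 = m2.fit()
        with pytest.raises(ValueError, match="fixed effects"):
            lr_test(f1, f2)

    def test_boundary_mixture_halves_the_tail(self):
        from types import SimpleNamespace

        full = SimpleNamespace(loglik=-10.0, n_params=2,
                               x_names=["intercept"])
        red = SimpleNamespace(loglik=-12.0, n_params=1,
                              x_names=["intercept"])
        stat, df, p_plain = lr_test(full, red, boundary=False)
        _, _, p_mix = lr_test(full, red, boundary=True)
        assert p_mix == pytest.approx(p_plain / 2)

    def test_type_i_error_of_boundary_test_is_calibrated(self, rng):
        """Dropping a truly-absent variance rejects at ~alpha under the
        50:50 chi-square mixture."""
        reps, rejections = 200, 0
        for _ in range(reps):
            y, model = one_way_layout(10, 4, 0.0, 1.0, rng)
            full = model.fit()
            null = MixedModel(y, np.ones((40, 1)), np.arange(40),
                              np.ones(40, dtype=int), n_cycles=1)
            reduced = null.fit()
            _, _, p = lr_test(full, reduced, boundary=True)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 2 * se

    def test_power_to_separate_unequal_gca_variances(self, rng):
        """With sigma_T^2 = 4 sigma_D^2 the common-variance model is
        rejected in most replicates."""
        from triploidcross.models import build_model, _refit_without
        from triploidcross.simulate import SimulationConfig, simulate_dataset

        reps, rejections = 30, 0
        for r in range(reps):
            cfg = SimulationConfig(
                n_parents2x=20, n_parents4x=20, n_crosses=50, family_sizes=12,
                sigma2_D=0.25, sigma2_T=1.0, sigma2_DT=0.05, sigma2_H=0.3,
                seed=3000 + r)
            data = simulate_dataset(cfg)
            bundle = build_model("PHENO", data.tables, "trait")
            full = bundle.fit()
            tied = _refit_without(bundle, tie_gca=True)
            _, _, p = lr_test(full, tied)
            rejections += p < 0.05
        assert rejections / reps > 0.5
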