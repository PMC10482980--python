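"""ML fitting, G² goodness of fit, nested tests, effect sizes, standard errors."""

import numpy as np
import pytest

from punishmpt.inference import (
    CooperationPunishmentMLE,
    EqualityConstraint,
    FitOptions,
    ModelSpec,
    effect_size_w,
    fit,
    nested_test,
    standard_errors,
)
from punishmpt.model import (
    PARAM_NAMES,
    FrequencyTable,
    ParameterVector,
    category_probabilities,
    expected_counts,
)

THETA_A = ParameterVector(0.5, 0.5, 0.0, 0.0, 0.5)


def integer_table(theta, n_defect, n_coop) -> FrequencyTable:
    counts = expected_counts(theta, n_defect, n_coop)
    assert np.allclose(counts, np.round(counts)), "construction must be integer-valued"
    return FrequencyTable(np.round(counts).astype(int))


class TestFit:
    def test_saturated_agreement(self, saturated_table):
        """Counts equal to expected counts are recovered exactly with G² = 0."""
        theta, table = saturated_table
        result = fit(ModelSpec(groups=("g",)), {"g": table})
        assert result.g_squared == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            result.estimates["g"].to_array(), theta.to_array(), atol=1e-6
        )
        assert result.converged

    def test_two_group_df(self, saturated_table):
        _, table = saturated_table
        result = fit(ModelSpec(groups=("a", "b")), {"a": table, "b": table})
        assert result.df == 2

    def test_three_group_df(self, saturated_table):
        _, table = saturated_table
        tables = {g: table for g in ("a", "b", "c")}
        result = fit(ModelSpec(groups=("a", "b", "c")), tables)
        assert result.df == 3

    def test_constraint_reduces_free_parameters(self, saturated_table):
        _, table = saturated_table
        spec = ModelSpec(
            groups=("a", "b"), constraints=(EqualityConstraint("C", ("a", "b")),)
        )
        result = fit(spec, {"a": table, "b": table})
        assert result.n_free == 9
        assert result.df == 3
        assert result.estimates["a"].c == result.estimates["b"].c

    def test_optimum_beats_grid_search(self):
        """Optimizer log-likelihood >= best value on a 0.05-step grid."""
        table = FrequencyTable([3, 2, 1, 4, 1, 5, 2, 2])  # totals 10 / 10
        result = fit(ModelSpec(groups=("g",)), {"g": table})

        grid = np.linspace(0, 1, 21)
        counts = table.counts.astype(float)
        pm, ph, pa, b = np.meshgrid(grid, grid, grid, grid, indexing="ij")
        pm, ph, pa, b = (x.ravel() for x in (pm, ph, pa, b))
        best = -np.inf
        for c in grid:
            probs = np.stack(
                [
                    c * (pm + (1 - pm) * b),
                    c * (1 - pm) * (1 - b),
                    (1 - c) * (ph + (1 - ph) * b),
                    (1 - c) * (1 - ph) * (1 - b),
                    np.full_like(pm, c * b),
                    np.full_like(pm, c * (1 - b)),
                    (1 - c) * (pa + (1 - pa) * b),
                    (1 - c) * (1 - pa) * (1 - b),
                ]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(counts[:, None] > 0, counts[:, None] * np.log(probs), 0.0)
            ll = np.where(np.isnan(ll), -np.inf, ll).sum(axis=0)
            best = max(best, float(ll.max()))
        assert result.log_likelihood >= best - 1e-9

    def test_deterministic_given_seed(self, saturated_table):
        _, table = saturated_table
        opts = FitOptions(seed=123)
        a = fit(ModelSpec(groups=("g",)), {"g": table}, opts)
        b = fit(ModelSpec(groups=("g",)), {"g": table}, opts)
        assert a.log_likelihood == b.log_likelihood
        assert a.g_squared == b.g_squared
        assert np.array_equal(
            a.estimates["g"].to_array(), b.estimates["g"].to_array()
        )

    def test_empty_tree_rejected(self):
        table = FrequencyTable([1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="empty tree"):
            fit(ModelSpec(groups=("g",)), {"g": table})

    def test_missing_table_rejected(self, saturated_table):
        _, table = saturated_table
        with pytest.raises(ValueError, match="no frequency table"):
            fit(ModelSpec(groups=("a", "b")), {"a": table})

    def test_nonconvergence_is_flagged(self, saturated_table):
        _, table = saturated_table
        result = fit(
            ModelSpec(groups=("g",)), {"g": table}, FitOptions(max_iter=1)
        )
        assert not result.converged  # flagged, never a silent answer

    def test_nesting_monotonicity(self):
        """Adding a constraint never decreases G² (up to optimizer noise)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            tables = {
                g: FrequencyTable(
                    np.concatenate(
                        [
                            rng.multinomial(60, rng.dirichlet(np.ones(4)))
                            for _ in range(2)
                        ]
                    )
                )
                for g in ("a", "b")
            }
            spec = ModelSpec(groups=("a", "b"))
            base = fit(spec, tables)
            param = PARAM_NAMES[rng.integers(5)]
            restricted = fit(
                spec.with_constraint(EqualityConstraint(param, ("a", "b"))), tables
            )
            assert restricted.g_squared >= base.g_squared - 1e-6


class TestEstimator:
    def test_sklearn_interface(self, saturated_table):
        theta, table = saturated_table
        est = CooperationPunishmentMLE(random_state=5)
        assert est.get_params()["n_restarts"] == 10
        est.set_params(n_restarts=4)
        est.fit({"g": table})
        assert est.g_squared_ == pytest.approx(0.0, abs=1e-8)
        assert est.df_ == 1
        assert est.n_total_ == 160
        np.testing.assert_allclose(
            est.estimates_["g"].to_array(), theta.to_array(), atol=1e-6
        )

    def test_clone_compatible(self, saturated_table):
        from sklearn.base import clone

        _, table = saturated_table
        est = CooperationPunishmentMLE(constraints=[("C", ("a", "b"))])
        cloned = clone(est)
        cloned.fit({"a": table, "b": table})
        assert cloned.estimates_["a"].c == cloned.estimates_["b"].c

    def test_score_is_loglik_at_estimates(self, saturated_table):
        _, table = saturated_table
        est = CooperationPunishmentMLE().fit({"g": table})
        assert est.score({"g": table}) == pytest.approx(est.log_likelihood_)

    def test_rejects_non_mapping(self):
        with pytest.raises(TypeError, match="mapping"):
            CooperationPunishmentMLE().fit([1, 2, 3])


class TestNestedTest:
    def test_identical_tables_give_zero_delta(self, saturated_table):
        _, table = saturated_table
        result = nested_test(
            ModelSpec(groups=("a", "b")),
            {"a": table, "b": table},
            EqualityConstraint("P_Moral", ("a", "b")),
        )
        assert result.delta_g_squared == pytest.approx(0.0, abs=1e-6)
        assert result.p_value == pytest.approx(1.0, abs=1e-4)
        assert result.df == 1

    def test_three_group_omnibus_df(self, saturated_table):
        _, table = saturated_table
        tables = {g: table for g in ("a", "b", "c")}
        result = nested_test(
            ModelSpec(groups=("a", "b", "c")),
            tables,
            EqualityConstraint("P_Antisocial", ("a", "b", "c")),
        )
        assert result.df == 2

    def test_redundant_constraint_rejected(self, saturated_table):
        _, table = saturated_table
        con = EqualityConstraint("C", ("a", "b"))
        spec = ModelSpec(groups=("a", "b"), constraints=(con,))
        with pytest.raises(ValueError, match="does not restrict"):
            nested_test(spec, {"a": table, "b": table}, con)

    def test_detects_true_difference(self):
        """A large moral-punishment difference produces a significant ΔG²."""
        t_hi = integer_table(ParameterVector(0.5, 0.75, 0.0, 0.0, 0.0), 400, 400)
        t_lo = integer_table(ParameterVector(0.5, 0.25, 0.0, 0.0, 0.0), 400, 400)
        result = nested_test(
            ModelSpec(groups=("hi", "lo")),
            {"hi": t_hi, "lo": t_lo},
            EqualityConstraint("P_Moral", ("hi", "lo")),
        )
        assert result.delta_g_squared > 10
        assert result.p_value < 0.01
        assert result.w == pytest.approx(
            np.sqrt(result.delta_g_squared / 1600), abs=1e-12
        )


class TestEffectSizeW:
    def test_moral_punishment_exp1(self):
        assert effect_size_w(5.11, 4060) == pytest.approx(0.0355, abs=5e-4)

    def test_zero_delta(self):
        assert effect_size_w(0.0, 100) == 0.0

    def test_large_sample_exp2(self):
        assert round(effect_size_w(25.73, 33620), 2) == 0.03

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            effect_size_w(1.0, 0)
        with pytest.raises(ValueError):
            effect_size_w(-0.5, 10)


class TestStandardErrors:
    def test_binomial_closed_form_for_cooperation(self, saturated_table):
        """SE(C) equals sqrt(C(1-C)/n): cooperation is a binomial margin
        orthogonal to the punishment parameters."""
        theta, table = saturated_table
        result = fit(ModelSpec(groups=("g",)), {"g": table})
        c_hat = result.estimates["g"].c
        n = table.n_total
        assert result.standard_errors["g"]["C"] == pytest.approx(
            np.sqrt(c_hat * (1 - c_hat) / n), abs=1e-8
        )

    def test_doubling_counts_scales_se(self, theta_interior):
        table = integer_table(theta_interior, 2000, 2000)
        doubled = FrequencyTable(table.counts * 2)
        se1 = fit(ModelSpec(groups=("g",)), {"g": table}).standard_errors["g"]
        se2 = fit(ModelSpec(groups=("g",)), {"g": doubled}).standard_errors["g"]
        for name in PARAM_NAMES:
            assert se2[name] == pytest.approx(se1[name] / np.sqrt(2), abs=1e-6)

    def test_matches_finite_difference_hessian(self, theta_interior):
        """Expected info equals the observed Hessian when obs = expected."""
        counts = expected_counts(theta_interior, 2000, 2000)
        table = FrequencyTable(np.round(counts).astype(int))
        spec = ModelSpec(groups=("g",))
        result = fit(spec, tables={"g": table})
        theta_hat = result.estimates["g"].to_array()

        def loglik(th):
            p = category_probabilities(th)
            obs = table.counts
            return float(np.sum(obs[obs > 0] * np.log(p[obs > 0])))

        h = 1e-5
        hess = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                pp, pm_, mp, mm = (theta_hat.copy() for _ in range(4))
                pp[[i, j]] += h
                pm_[i] += h
                pm_[j] -= h
                mp[i] -= h
                mp[j] += h
                mm[[i, j]] -= h
                if i == j:
                    pp = theta_hat.copy()
                    pp[i] += 2 * h
                    mm = theta_hat.copy()
                    mm[i] -= 2 * h
                    hess[i, i] = (
                        loglik(pp) - 2 * loglik(theta_hat) + loglik(mm)
                    ) / (4 * h * h)
                else:
                    hess[i, j] = (loglik(pp) - loglik(pm_) - loglik(mp) + loglik(mm)) / (
                        4 * h * h
                    )

        from punishmpt.inference import _expected_information, _free_index

        index, _ = _free_index(spec)
        info = _expected_information(theta_hat, index, [table])
        np.testing.assert_allclose(
            -hess, info, rtol=1e-4, atol=1e-4 * np.abs(info).max()
        )

    def test_boundary_estimate_undefined(self):
        """A parameter estimated at 0 gets an undefined (NaN) standard error."""
        theta = ParameterVector(0.5, 0.5, 0.0, 0.0, 0.5)
        table = integer_table(theta, 80, 80)
        result = fit(ModelSpec(groups=("g",)), {"g": table})
        ses = standard_errors(result.estimates, {"g": table}, ModelSpec(groups=("g",)))
        assert np.isnan(ses["g"]["P_Hypocritical"])
        assert np.isfinite(ses["g"]["C"])
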