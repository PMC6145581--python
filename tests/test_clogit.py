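"""Conditional likelihood, Newton fitting, Wald inference, elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from nsaidcc import clogit
from nsaidcc.errors import ContractError, EstimationError


def random_design(rng, n_sets=5, m_controls=3, p=2, binary=True):
    rows = []
    for s in range(n_sets):
        for j in range(m_controls + 1):
            x = rng.integers(0, 2, p) if binary else rng.normal(size=p)
            rows.append([s, 1 if j == 0 else 0, *x])
    df = pd.DataFrame(rows, columns=["set_id", "is_case"]
                      + [f"x{k}" for k in range(p)])
    return clogit.design_from_frame(df, [f"x{k}" for k in range(p)])


def brute_loglik(design, beta):
    """Row-by-row independent evaluation of the conditional likelihood."""
    beta = np.asarray(beta, float)
    ll = 0.0
    for g in np.unique(design.group):
        sel = design.group == g
        eta = design.X[sel] @ beta
        ll += eta[design.y[sel] == 1][0] - np.log(np.sum(np.exp(eta)))
    return ll


def discordant_design(n_case_exposed, n_control_exposed, n_concordant):
    """1:1 sets with binary exposure."""
    rows, s = [], 0
    for _ in range(n_case_exposed):
        rows += [[s, 1, 1], [s, 0, 0]]; s += 1
    for _ in range(n_control_exposed):
        rows += [[s, 1, 0], [s, 0, 1]]; s += 1
    for _ in range(n_concordant):
        rows += [[s, 1, 1], [s, 0, 1]]; s += 1
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "x0"])
    return clogit.design_from_frame(df, ["x0"])


class TestLikelihood:
    def test_null_value_closed_form(self):
        rng = np.random.default_rng(1)
        d = random_design(rng, n_sets=7, m_controls=4)
        sizes = d.set_sizes()
        assert clogit.conditional_loglik(d, np.zeros(d.X.shape[1])) \
            == pytest.approx(-np.sum(np.log(sizes)), abs=1e-12)

    def test_identical_rows_make_loglik_constant(self):
        df = pd.DataFrame({"set_id": [0] * 4, "is_case": [1, 0, 0, 0],
                           "x0": [1.0] * 4})
        d = clogit.design_from_frame(df, ["x0"])
        vals = [clogit.conditional_loglik(d, np.array([b])) for b in (-2, 0, 3.5)]
        assert np.allclose(vals, -np.log(4))

    def test_matches_brute_force_evaluation(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, n_sets=4, m_controls=3, p=2)
        beta = np.array([0.3, -0.2])
        assert clogit.conditional_loglik(d, beta) \
            == pytest.approx(brute_loglik(d, beta), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        d = random_design(rng, n_sets=6, m_controls=2, p=3, binary=False)
        beta = rng.normal(size=3) * 0.5
        _, grad = clogit.conditional_loglik(d, beta, order=1)
        num = optimize.approx_fprime(
            beta, lambda b: clogit.conditional_loglik(d, b), 1e-7)
        assert np.allclose(grad, num, atol=1e-5)

    def test_information_is_psd_everywhere(self):
        rng = np.random.default_rng(6)
        d = random_design(rng, n_sets=5, m_controls=3, p=2)
        for _ in range(10):
            beta = rng.normal(size=2) * 2
            _, _, info = clogit.conditional_loglik(d, beta, order=2)
            ev = np.linalg.eigvalsh(info)
            assert ev.min() >= -1e-10

    def test_nonfinite_beta_raises(self):
        d = random_design(np.random.default_rng(0))
        with pytest.raises(ValueError):
            clogit.conditional_loglik(d, [np.nan, 0.0])

    def test_two_cases_in_a_set_rejected(self):
        df = pd.DataFrame({"set_id": [0, 0, 0], "is_case": [1, 1, 0],
                           "x0": [1.0, 0.0, 0.0]})
        with pytest.raises(ContractError):
            clogit.design_from_frame(df, ["x0"])


class TestFitting:
    def test_discordant_pair_closed_form(self):
        d = discordant_design(10, 5, 20)
        fit = clogit.fit_clogit(d)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-8)
        or_, _, _ = clogit.wald_interval(fit.beta[0], fit.se[0])
        assert or_ == pytest.approx(2.00, abs=1e-6)

    def test_discordant_fit_matches_grid_search_oracle(self):
        d = discordant_design(10, 5, 20)
        fit = clogit.fit_clogit(d)
        grid = np.arange(0.0, 2.0, 1e-6)
        # closed-form 1:1 likelihood: a*(b - log(1+e^b)) - c*log(1+e^b)
        ll = 10 * (grid - np.logaddexp(0, grid)) - 5 * np.logaddexp(0, grid)
        assert abs(grid[np.argmax(ll)] - fit.beta[0]) < 1e-5

    def test_constant_within_set_column_dropped(self):
        rng = np.random.default_rng(2)
        d = random_design(rng, n_sets=6, m_controls=3, p=2)
        X = np.column_stack([d.X, np.ones(len(d.y))])
        d2 = clogit.MatchedDesign(X, d.y, d.group, ["x0", "x1", "const"])
        fit = clogit.fit_clogit(d2)
        assert fit.dropped_columns == ["const"]
        ref = clogit.fit_clogit(d)
        assert np.allclose(fit.beta, ref.beta, atol=1e-10)

    def test_relabeling_sets_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(3)
        d = random_design(rng, n_sets=6, m_controls=3, p=2)
        relabel = {g: 100 - g for g in np.unique(d.group)}
        d2 = clogit.MatchedDesign(
            d.X, d.y, np.array([relabel[g] for g in d.group]), d.columns)
        f1, f2 = clogit.fit_clogit(d), clogit.fit_clogit(d2)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert np.allclose(f1.se, f2.se, atol=1e-10)

    def test_newton_matches_derivative_free_oracle(self):
        rng = np.random.default_rng(11)
        d = random_design(rng, n_sets=5, m_controls=3, p=2)
        fit = clogit.fit_clogit(d)
        res = optimize.minimize(lambda b: -clogit.conditional_loglik(d, b),
                                np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        assert np.allclose(fit.beta, res.x, atol=1e-6)

    def test_unmatched_sets_excluded_with_count(self):
        df = pd.DataFrame({
            "set_id": [0, 0, 1, 2, 2], "is_case": [1, 0, 1, 1, 0],
            "x0": [1.0, 0.0, 1.0, 0.0, 1.0]})
        d = clogit.design_from_frame(df, ["x0"])
        fit = clogit.fit_clogit(d)
        assert fit.n_sets_unmatched == 1 and fit.n_sets_used == 2

    def test_all_sets_unmatched_raises(self):
        df = pd.DataFrame({"set_id": [0, 1], "is_case": [1, 1], "x0": [1.0, 0.0]})
        d = clogit.design_from_frame(df, ["x0"])
        with pytest.raises(EstimationError):
            clogit.fit_clogit(d)

    def test_separation_flagged_not_converged(self):
        # exposure perfectly predicts the case in every set
        d = discordant_design(12, 0, 0)
        fit = clogit.fit_clogit(d)
        assert not fit.converged

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit
        rng = np.random.default_rng(21)
        d = random_design(rng, n_sets=40, m_controls=5, p=3)
        fit = clogit.fit_clogit(d)
        res = ConditionalLogit(d.y, d.X, groups=d.group).fit(disp=False)
        # statsmodels' default optimizer stops looser than the Newton fit
        assert np.allclose(fit.beta, res.params, atol=5e-4)
        assert np.allclose(fit.se, res.bse, atol=1e-4)
        assert fit.loglik >= res.llf - 1e-9


class TestWald:
    def test_interval_arithmetic(self):
        or_, lcl, ucl = clogit.wald_interval(0.6931, 0.2)
        assert round(or_, 2) == 2.00
        assert round(lcl, 2) == 1.35 and round(ucl, 2) == 2.96

    def test_zero_se_degenerate(self):
        or_, lcl, ucl = clogit.wald_interval(0.5, 0.0)
        assert lcl == or_ == ucl

    def test_wider_at_higher_level(self):
        _, l95, u95 = clogit.wald_interval(0.3, 0.1, 0.95)
        _, l99, u99 = clogit.wald_interval(0.3, 0.1, 0.99)
        assert l99 < l95 and u99 > u95

    def test_bad_level_raises(self):
        with pytest.raises(ValueError):
            clogit.wald_interval(0.0, 0.1, level=1.0)

    def test_point_estimate_from_ci(self):
        assert clogit.point_estimate_from_ci(1.19, 1.78) == 1.46
        assert clogit.point_estimate_from_ci(1.20, 1.32) == 1.26
        assert clogit.point_estimate_from_ci(1.5, 1.5) == 1.5

    def test_point_estimate_bad_limits(self):
        with pytest.raises(ValueError):
            clogit.point_estimate_from_ci(-1.0, 2.0)
        with pytest.raises(ValueError):
            clogit.point_estimate_from_ci(2.0, 1.0)

    def test_round_half_up(self):
        assert clogit.round_half_up(0.125, 2) == 0.13
        assert clogit.round_half_up(50.25, 1) == 50.3
        assert clogit.round_half_up(2.675, 2) == 2.68


class TestBackwardElimination:
    def make(self, rng, n_sets=60, m=3):
        # x0: real effect; z_null: pure noise candidate
        rows = []
        for s in range(n_sets):
            for j in range(m + 1):
                x0 = rng.integers(0, 2)
                z = rng.integers(0, 2)
                lin = 1.2 * x0
                rows.append([s, x0, z, lin])
            rows_set = rows[-(m + 1):]
            w = np.exp([r[3] for r in rows_set])
            case = rng.choice(m + 1, p=w / w.sum())
            for j, r in enumerate(rows_set):
                r.append(1 if j == case else 0)
        df = pd.DataFrame(rows, columns=["set_id", "x0", "z_null", "_lin",
                                         "is_case"])
        return clogit.design_from_frame(df, ["x0", "z_null"])

    def test_null_candidate_usually_removed(self):
        removed = 0
        for seed in range(12):
            d = self.make(np.random.default_rng(seed))
            _, trace = clogit.backward_eliminate(d, [], ["z_null"])
            removed += any(name == "z_null" for name, _ in trace.removed)
        assert removed >= 10  # removal prob is 1 - alpha = 0.95 per run

    def test_exposure_never_removed(self):
        d = self.make(np.random.default_rng(5))
        fit, trace = clogit.backward_eliminate(d, [], ["z_null"])
        assert "x0" in fit.columns
        assert all(name != "x0" for name, _ in trace.removed)

    def test_alpha_one_never_removes(self):
        # p-values are < 1 almost surely, so the stay threshold 1.0 keeps all
        d = self.make(np.random.default_rng(6))
        fit_full = clogit.fit_clogit(d)
        fit, trace = clogit.backward_eliminate(d, [], ["z_null"], alpha_stay=1.0)
        assert not trace.removed
        assert np.allclose(fit.beta, fit_full.beta)

    def test_all_below_threshold_keeps_full_model(self):
        d = self.make(np.random.default_rng(7))
        fit_full = clogit.fit_clogit(d)
        fit, trace = clogit.backward_eliminate(d, [], ["z_null"],
                                               alpha_stay=1.0 - 1e-12)
        if not trace.removed:  # p(z_null) < 1 always, so usually kept
            assert np.allclose(fit.beta, fit_full.beta)

    def test_a_priori_protected(self):
        d = self.make(np.random.default_rng(8))
        fit, trace = clogit.backward_eliminate(d, ["z_null"], [])
        assert "z_null" in fit.columns and not trace.removed
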