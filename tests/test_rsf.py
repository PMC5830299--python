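import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trackrsf import final_model_fixture, synthetic
from trackrsf.errors import IncompleteProfileError, InsufficientReplicatesError
from trackrsf.rsf import (
    INTERACTIONS,
    SINGLE_EFFECTS,
    ModelFormula,
    ReplicateFit,
    RSFResult,
    design_matrix,
    fit_single_rsf,
    mc_inference,
    odds_of_selection,
    peak_from_coefficients,
    peak_ice_concentration,
    stepwise_eliminate,
)


def make_rows(x_case, x_control, column="sqrt_d2ice", replicate=1):
    """Covariate rows with a single numeric covariate."""
    n1, n0 = len(x_case), len(x_control)
    df = pd.DataFrame(
        {
            "animal_id": "a",
            "replicate": [0] * n1 + [replicate] * n0,
            "case": [1] * n1 + [0] * n0,
            "sex": "F",
            column: np.concatenate([x_case, x_control]),
        }
    )
    return df


# ------------------------------------------------------------- formula


class TestModelFormula:
    def test_initial_has_17_terms(self):
        f = ModelFormula.initial()
        assert len(f.terms) == 17
        assert set(SINGLE_EFFECTS) <= set(f.terms)
        assert set(INTERACTIONS) <= set(f.terms)

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="hierarchy"):
            ModelFormula(terms=["sex", "sex:sqrt_d2ice"])

    def test_quadratic_requires_linear(self):
        with pytest.raises(ValueError, match="ice_conc"):
            ModelFormula(terms=["ice_conc2"])

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelFormula(terms=["banana"])

    def test_removable_protects_main_under_interaction(self):
        f = ModelFormula(terms=["sex", "sqrt_d2ice", "sex:sqrt_d2ice", "sqrt_d2coast"])
        rem = f.removable()
        assert "sex" not in rem and "sqrt_d2ice" not in rem
        assert "sex:sqrt_d2ice" in rem and "sqrt_d2coast" in rem

    def test_removable_protects_linear_under_quadratic(self):
        f = ModelFormula(terms=["ice_conc", "ice_conc2"])
        rem = f.removable()
        assert "ice_conc" not in rem and "ice_conc2" in rem

    def test_interactions_always_removable(self):
        # a two-way interaction may leave while a three-way containing it stays
        f = ModelFormula(terms=["sex", "sea_ice", "sqrt_d2ice", "sex:sea_ice", "sea_ice:sqrt_d2ice",
                                "sex:sqrt_d2ice", "sex:sea_ice:sqrt_d2ice"])
        assert "sex:sea_ice" in f.removable()


# ------------------------------------------------------------- single fit


class TestFitSingleRSF:
    def test_two_by_two_closed_form(self):
        # exposed cases 30, unexposed cases 20, exposed controls 10,
        # unexposed controls 40 -> slope = log(30*40/(20*10)) = log 6
        x_case = np.array([1.0] * 30 + [0.0] * 20)
        x_control = np.array([1.0] * 10 + [0.0] * 40)
        fit = fit_single_rsf(make_rows(x_case, x_control), ModelFormula(terms=["sqrt_d2ice"]))
        assert fit.coef["sqrt_d2ice"] == pytest.approx(np.log(6.0), abs=1e-6)
        assert fit.converged

    def test_constant_covariate_dropped(self):
        rows = make_rows(np.full(30, 2.0), np.full(30, 2.0))
        fit = fit_single_rsf(rows, ModelFormula(terms=["sqrt_d2ice"]))
        assert "sqrt_d2ice" in fit.dropped
        assert np.isnan(fit.coef["sqrt_d2ice"])

    def test_score_equation_intercept_identity(self, rng):
        # sum of fitted probabilities equals the case count (IRLS score
        # identity for the intercept)
        rows = make_rows(rng.normal(1.0, 1.0, 80), rng.normal(0.0, 1.0, 80))
        formula = ModelFormula(terms=["sqrt_d2ice"])
        fit = fit_single_rsf(rows, formula)
        X = design_matrix(rows, formula)
        eta = X.values @ np.array([fit.coef["intercept"], fit.coef["sqrt_d2ice"]])
        p = 1.0 / (1.0 + np.exp(-eta))
        assert p.sum() == pytest.approx(rows["case"].sum(), abs=1e-6)

    def test_matches_brute_force_newton(self, rng):
        # independent oracle: Newton iteration on the exact log-likelihood
        for trial in range(5):
            n = 60
            x1 = rng.normal(0, 1, 2 * n)
            x2 = rng.uniform(0, 4, 2 * n)
            y = np.array([1.0] * n + [0.0] * n)
            rows = pd.DataFrame(
                {
                    "animal_id": "a",
                    "replicate": np.r_[np.zeros(n), np.ones(n)].astype(int),
                    "case": y.astype(int),
                    "sex": "F",
                    "sqrt_d2ice": x1,
                    "ice_conc": x2,
                }
            )
            formula = ModelFormula(terms=["sqrt_d2ice", "ice_conc"])
            fit = fit_single_rsf(rows, formula)
            X = np.column_stack([np.ones(2 * n), x1, x2])
            beta = np.zeros(3)
            for _ in range(50):
                p = 1.0 / (1.0 + np.exp(-X @ beta))
                grad = X.T @ (y - p)
                hess = X.T @ (X * (p * (1 - p))[:, None])
                step = np.linalg.solve(hess, grad)
                beta = beta + step
                if np.abs(step).max() < 1e-12:
                    break
            got = np.array([fit.coef["intercept"], fit.coef["sqrt_d2ice"], fit.coef["ice_conc"]])
            np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_single_class_rejected(self):
        rows = make_rows(np.array([1.0, 2.0]), np.array([]))
        rows = rows[rows.case == 1]
        with pytest.raises(ValueError):
            fit_single_rsf(rows, ModelFormula(terms=["sqrt_d2ice"]))


# ------------------------------------------------------------- MC inference


def fits_from_matrix(coefs, term="sqrt_d2ice"):
    return [
        ReplicateFit(replicate=i + 1, coef={"intercept": 0.0, term: float(c)}, converged=True, llf=0.0)
        for i, c in enumerate(coefs)
    ]


class TestMCInference:
    def test_sample_moment_oracle(self, rng):
        coefs = rng.normal(1.0, 0.5, 20)
        stats = mc_inference(fits_from_matrix(coefs))
        assert stats.loc["sqrt_d2ice", "mean"] == pytest.approx(coefs.mean(), rel=1e-12)
        assert stats.loc["sqrt_d2ice", "se"] == pytest.approx(coefs.std(ddof=1), rel=1e-12)
        z = coefs.mean() / coefs.std(ddof=1)
        assert stats.loc["sqrt_d2ice", "z"] == pytest.approx(z, rel=1e-12)
        assert stats.loc["sqrt_d2ice", "p"] == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)
        # sanity: near nominal values for N(1, 0.5)
        assert stats.loc["sqrt_d2ice", "mean"] == pytest.approx(1.0, abs=0.4)
        assert stats.loc["sqrt_d2ice", "se"] == pytest.approx(0.5, abs=0.3)

    def test_zero_variance_flagged(self):
        stats = mc_inference(fits_from_matrix([0.7] * 20))
        row = stats.loc["sqrt_d2ice"]
        assert row["degenerate_se"]
        assert 0 < row["p"] < 1e-300

    def test_insufficient_replicates(self):
        fits = fits_from_matrix([1.0, 2.0])
        fits[0].converged = False
        with pytest.raises(InsufficientReplicatesError):
            mc_inference(fits)

    def test_nonconverged_excluded(self):
        fits = fits_from_matrix([1.0, 2.0, 3.0, 100.0])
        fits[3].converged = False
        stats = mc_inference(fits)
        assert stats.loc["sqrt_d2ice", "mean"] == pytest.approx(2.0)
        assert stats.loc["sqrt_d2ice", "n_reps"] == 3


# ------------------------------------------------------------- stepwise


@pytest.fixture(scope="module")
def selective_rows(small_env, small_sampler):
    truth = synthetic.TruthRSF({"sqrt_d2ice": -0.2})
    return synthetic.make_selective_rows(
        small_env, truth, n_case=1000, n_rep=20, seed=77, sampler=small_sampler
    )


class TestStepwise:
    def test_recovery_keeps_active_term(self, selective_rows):
        initial = ModelFormula(terms=["sqrt_d2ice", "ice_conc", "sqrt_depth_m", "sqrt_d2coast"])
        res = stepwise_eliminate(selective_rows, initial, alpha=0.05)
        assert "sqrt_d2ice" in res.formula.terms
        # inert bathymetry/coast terms go (concentration correlates with
        # edge distance by construction, so only require the truth term kept
        # and at least one inert removal)
        assert len(res.trace) >= 1
        assert set(res.trace["term"]).isdisjoint(res.formula.terms)

    def test_sign_convention_proximity_selection(self, selective_rows):
        res = stepwise_eliminate(selective_rows, ModelFormula(terms=["sqrt_d2ice"]), alpha=0.05)
        assert res.coefficient("sqrt_d2ice") < 0  # selection for edge proximity

    def test_all_significant_empty_trace(self, selective_rows):
        res = stepwise_eliminate(selective_rows, ModelFormula(terms=["sqrt_d2ice"]), alpha=0.05)
        assert res.trace.empty
        assert res.formula.terms == ["sqrt_d2ice"]

    def test_hierarchy_main_outlives_interaction(self, small_env, small_sampler):
        # no selection at all: everything should be eliminated, and sex must
        # leave only after (never before) sex:sqrt_d2ice
        rows = synthetic.make_selective_rows(
            small_env, synthetic.TruthRSF({}), n_case=300, n_rep=8, seed=5, sampler=small_sampler
        )
        # give sexes to rows at random so sex terms are estimable
        rng = np.random.default_rng(0)
        rows["sex"] = np.where(rng.random(len(rows)) < 0.5, "F", "M")
        initial = ModelFormula(terms=["sex", "sqrt_d2ice", "sex:sqrt_d2ice"])
        res = stepwise_eliminate(rows, initial, alpha=0.05)
        trace_terms = list(res.trace["term"])
        if "sex" in trace_terms and "sex:sqrt_d2ice" in trace_terms:
            assert trace_terms.index("sex:sqrt_d2ice") < trace_terms.index("sex")
        for removed in trace_terms:
            # replay: a removed main effect was removable at its step
            assert ":" in removed or removed in ("sex", "sqrt_d2ice")

    def test_trace_disjoint_from_final(self, selective_rows):
        initial = ModelFormula(terms=["sqrt_d2ice", "sqrt_depth_m"])
        res = stepwise_eliminate(selective_rows, initial, alpha=0.05)
        assert set(res.trace["term"]).isdisjoint(set(res.formula.terms))


class TestAutocorrelationRobustness:
    def test_mc_se_exceeds_naive_se_on_autocorrelated_tracks(self, small_env, small_sampler):
        # null-selection tracks are strongly autocorrelated; the replicate
        # spread should exceed the independence-assuming model-based SE
        import statsmodels.api as sm

        from trackrsf import movement
        from trackrsf.covariates import build_covariate_table
        from trackrsf.rsf import design_matrix

        tracks = synthetic.make_selective_tracks(
            small_env, synthetic.TruthRSF({}), synthetic.MovementParams(),
            n_animals=3, seed=31, n_steps=80, n_candidates=1, sampler=small_sampler,
        )
        steps = pd.concat([movement.decompose_steps(t) for t in tracks], ignore_index=True)
        model = movement.fit_movement_model(steps, movement.MovementFitConfig(min_steps=50))
        sims = movement.simulate_ensemble(model, tracks, small_env, n_rep=10, seed=32)
        table, _ = build_covariate_table(tracks, sims, small_sampler)
        formula = ModelFormula(terms=["sqrt_d2ice"])
        case = table[table.case == 1]
        fits, naive_ses = [], []
        for r in range(1, 11):
            sub = pd.concat([case, table[table.replicate == r]], ignore_index=True)
            fits.append(fit_single_rsf(sub, formula, replicate=r))
            X = design_matrix(sub, formula)
            res = sm.GLM(sub["case"].astype(float), X, family=sm.families.Binomial()).fit()
            naive_ses.append(res.bse["sqrt_d2ice"])
        mc_se = mc_inference(fits).loc["sqrt_d2ice", "se"]
        assert mc_se > np.mean(naive_ses)


# ------------------------------------------------------------- curves & peak


def result_from_fixture() -> RSFResult:
    fm = final_model_fixture()
    stats = (
        fm.rename(columns={"estimate": "mean", "std_err": "se", "z_value": "z", "p_value": "p"})
        .set_index("term")[["mean", "se", "z", "p"]]
        .assign(n_reps=20, degenerate_se=False)
    )
    formula = ModelFormula(
        terms=["sea_ice", "ice_conc", "ice_conc2", "sqrt_d2ice", "sea_ice:sqrt_d2ice"]
    )
    return RSFResult(stats=stats, trace=pd.DataFrame(columns=["step", "term", "p_at_removal"]),
                     formula=formula, n_replicates=20)


PROFILE = {"sex": "F", "d2ice": 25.0, "ice_conc": 50.0, "sea_ice": "yes"}


class TestOddsOfSelection:
    def test_flat_when_coefficients_zero(self):
        res = result_from_fixture()
        res.stats.loc[:, "mean"] = 0.0
        curve = odds_of_selection(res, PROFILE, "d2ice", np.linspace(0, 100, 11))
        np.testing.assert_allclose(curve.odds, 1.0)

    def test_decreasing_within_ice(self):
        res = result_from_fixture()
        curve = odds_of_selection(res, PROFILE, "d2ice", np.linspace(0, 200, 41))
        assert np.all(np.diff(curve.odds) < 0)

    def test_open_water_slope_arithmetic(self):
        # published coefficients: open-water slope on sqrt(d2ice) is the
        # within-ice slope plus the interaction: -0.206333 + 0.185093
        res = result_from_fixture()
        grid = np.array([25.0, 36.0])  # sqrt gap of exactly 1
        prof = dict(PROFILE, sea_ice="no")
        curve = odds_of_selection(res, prof, "d2ice", grid)
        slope = np.diff(np.log(curve.odds))[0]  # per unit sqrt(d2ice)
        assert slope == pytest.approx(-0.206333 + 0.185093, abs=1e-9)
        within = odds_of_selection(res, PROFILE, "d2ice", grid)
        assert np.diff(np.log(within.odds))[0] == pytest.approx(-0.206333, abs=1e-9)

    def test_incomplete_profile_raises(self):
        res = result_from_fixture()
        with pytest.raises(IncompleteProfileError):
            odds_of_selection(res, {"sex": "F"}, "d2ice", np.linspace(0, 10, 3))

    def test_availability_weights(self, rng):
        res = result_from_fixture()
        controls = pd.DataFrame({"d2ice": rng.gamma(4.0, 10.0, 2000)})
        curve = odds_of_selection(res, PROFILE, "d2ice", np.linspace(0, 150, 31), control_rows=controls)
        assert curve.availability is not None
        assert curve.availability.max() == pytest.approx(1.0)
        assert curve.availability.min() >= 0.0


class TestPeakIceConcentration:
    def test_published_coefficients(self):
        peak = peak_from_coefficients(0.058692, -0.000370)
        assert peak == pytest.approx(79.3, abs=0.05)
        # grid-search oracle at 0.01% resolution
        grid = np.arange(0.0, 100.0001, 0.01)
        vals = 0.058692 * grid - 0.000370 * grid**2
        assert abs(grid[np.argmax(vals)] - peak) <= 0.01

    def test_analytic_vertex(self):
        assert peak_from_coefficients(1.0, -0.01) == pytest.approx(50.0)

    def test_convex_returns_none(self):
        assert peak_from_coefficients(1.0, 0.001) is None

    def test_from_result(self):
        res = result_from_fixture()
        assert peak_ice_concentration(res) == pytest.approx(79.31, abs=0.05)

    def test_clipped_to_range(self):
        assert peak_from_coefficients(500.0, -0.1) == 100.0
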