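"""Population SAEM fit and npde adequacy checks."""

import copy

import numpy as np
import pytest
from scipy import optimize

from permquant import (
    CohortDesign,
    ExcretionCurveParams,
    FitSettings,
    GeneratorTruth,
    PopulationFitResult,
    PopulationModel,
    UrineSeries,
    compute_npde,
    evaluate_curve,
    fit_population,
    generate_cohort,
    individual_curve,
)

TRUE = GeneratorTruth()
TIMES_D = np.array([1, 3, 6, 8, 12, 18, 24, 30, 36]) / 24.0


def _make_truth_fit(model_truth: GeneratorTruth, seed: int = 0) -> PopulationFitResult:
    """A PopulationFitResult carrying the generating model itself (no estimation)."""
    model = PopulationModel(
        mu=np.asarray(model_truth.log_mu, float),
        omega=np.asarray(model_truth.omega, float),
        sigma=np.array([model_truth.sigma]),
        error_model=model_truth.error_model,
    )
    return PopulationFitResult(
        model=model, individual_params={}, loglik_trace=np.zeros(1),
        converged=True, seed=seed, settings=FitSettings(seed=seed),
    )


class TestFitPopulation:
    def test_noiseless_homogeneous_cohort_recovers_truth(self):
        """With omega=0 and near-zero noise every animal shares the true curve
        and the fixed effects must come back within 1%."""
        truth = GeneratorTruth(omega=(0, 0, 0, 0), sigma=1e-6)
        series, _, rec = generate_cohort(CohortDesign(), truth, seed=3)
        fit = fit_population(series, FitSettings(seed=3))
        est = fit.model.fixed_effects_natural()
        for k, v in rec["fixed_effects"].items():
            assert est[k] == pytest.approx(v, rel=0.01)
        # every individual curve equals the population curve within 1%
        for p in fit.individual_params.values():
            for k, v in rec["fixed_effects"].items():
                assert getattr(p, k) == pytest.approx(v, rel=0.01)

    def test_seeded_determinism_is_bit_identical(self, default_cohort):
        series, _, _ = default_cohort
        f1 = fit_population(series, FitSettings(seed=11, n_explore=60, n_smooth=30))
        f2 = fit_population(series, FitSettings(seed=11, n_explore=60, n_smooth=30))
        assert np.array_equal(f1.model.mu, f2.model.mu)
        assert np.array_equal(f1.model.omega, f2.model.omega)
        assert np.array_equal(f1.loglik_trace, f2.loglik_trace)
        for aid in f1.individual_params:
            assert f1.individual_params[aid] == f2.individual_params[aid]

    def test_animal_order_does_not_change_estimates(self, default_cohort):
        """Per-animal random streams are keyed by animal_id, so permuting the
        cohort leaves the stochastic path (hence estimates) unchanged up to
        floating-point summation order."""
        series, _, _ = default_cohort
        st = FitSettings(seed=5, n_explore=60, n_smooth=30)
        f1 = fit_population(series, st)
        f2 = fit_population(series[::-1], copy.deepcopy(st))
        np.testing.assert_allclose(f1.model.mu, f2.model.mu, rtol=1e-6)
        np.testing.assert_allclose(f1.model.omega, f2.model.omega, rtol=1e-4, atol=1e-10)

    def test_requires_two_animals(self, default_cohort):
        series, _, _ = default_cohort
        with pytest.raises(ValueError, match="2 animals"):
            fit_population(series[:1])

    def test_all_zero_animal_excluded_with_flag(self, default_cohort):
        series, _, _ = default_cohort
        dead = UrineSeries(
            animal_id="Z0-1", breed="Holstein", treatment=0.0, bw_kg=300.0,
            times_d=TIMES_D, ratios=np.zeros_like(TIMES_D),
        )
        fit = fit_population(list(series) + [dead],
                             FitSettings(seed=2, n_explore=60, n_smooth=30))
        assert fit.excluded_animals == ["Z0-1"]
        assert "Z0-1" not in fit.individual_params

    def test_degenerate_objective_matches_direct_least_squares(self):
        """Homogeneous-cohort oracle equivalence: with no real heterogeneity the
        population-typical curve must reach the same residual sum of squares as
        an independent direct nonlinear least-squares fit (additive error), and
        sigma must match sqrt(RSS/N)."""
        truth = GeneratorTruth(omega=(0, 0, 0, 0), sigma=2e-4, error_model="additive")
        series, _, _ = generate_cohort(CohortDesign(n_per_cell=1), truth, seed=9)
        t = np.concatenate([s.times_d[1:] for s in series])
        y = np.concatenate([s.ratios[1:] for s in series])

        def model_f(tt, a, b, r1, r2):
            return a * np.exp(-r1 * tt) * np.exp(-b * np.exp(-r2 * tt))

        popt, _ = optimize.curve_fit(
            model_f, t, y, p0=[0.1, 4, 3, 14], maxfev=20000
        )
        rss_nls = float(((y - model_f(t, *popt)) ** 2).sum())

        fit = fit_population(series, FitSettings(seed=9, error_model="additive"))
        fe = fit.model.fixed_effects_natural()
        rss_saem = float(((y - model_f(t, fe["A"], fe["B"], fe["k1"], fe["k2"])) ** 2).sum())
        assert rss_saem <= rss_nls * 1.10 + 1e-12
        assert fit.model.sigma[0] == pytest.approx(np.sqrt(rss_nls / len(y)), rel=0.25)

    def test_loglik_trace_length_matches_iterations(self, default_fit):
        st = default_fit.settings
        assert len(default_fit.loglik_trace) == st.n_explore + st.n_smooth


class TestIndividualCurve:
    def test_lookup_and_invariants(self, default_fit, default_cohort):
        series, _, _ = default_cohort
        for s in series:
            p = individual_curve(default_fit, s.animal_id)
            assert p.A > 0 and p.B >= 0 and p.k1 > 0 and p.k2 > 0

    def test_unknown_animal_raises(self, default_fit):
        with pytest.raises(KeyError, match="nope"):
            individual_curve(default_fit, "nope")

    def test_outlier_animal_is_shrunk_toward_population(self):
        """An animal generated 3 population SDs above the typical amplitude gets
        an empirical-Bayes estimate between the population mean and its own
        least-squares fit (shrinkage)."""
        truth = GeneratorTruth()
        series, _, rec = generate_cohort(CohortDesign(), truth, seed=21)
        rng = np.random.default_rng(99)
        a_hi = float(np.exp(truth.log_mu[0] + 3 * np.sqrt(truth.omega[0])))
        p_ext = ExcretionCurveParams(a_hi, *np.exp(truth.log_mu[1:]))
        clean = evaluate_curve(p_ext, TIMES_D)
        outlier = UrineSeries(
            animal_id="X0-1", breed="Holstein", treatment=0.0, bw_kg=350.0,
            times_d=TIMES_D, ratios=clean * (1 + truth.sigma * rng.standard_normal(len(TIMES_D))),
        )
        fit = fit_population(list(series) + [outlier], FitSettings(seed=21))

        def resid(logp):
            a, b, r1, r2 = np.exp(logp)
            return a * np.exp(-r1 * TIMES_D) * np.exp(-b * np.exp(-r2 * TIMES_D)) - outlier.ratios

        ls = optimize.least_squares(resid, truth.log_mu, method="lm").x
        a_ls = float(np.exp(ls[0]))
        a_pop = fit.model.fixed_effects_natural()["A"]
        a_eb = individual_curve(fit, "X0-1").A
        lo, hi = sorted((a_pop, a_ls))
        assert lo - 0.02 * lo <= a_eb <= hi + 0.02 * hi


class TestNpde:
    def test_well_specified_data_passes_adequacy(self, default_fit, default_cohort):
        series, _, _ = default_cohort
        rep = compute_npde(default_fit, series, n_sim=400, seed=1)
        assert len(rep.npde) == 12 * 9  # post-dose observations only
        assert rep.passes(alpha=0.05)
        for p in (rep.shapiro_p, rep.wilcoxon_p, rep.fisher_var_p):
            assert 0 <= p <= 1

    def test_median_trajectory_gives_centered_residuals(self):
        """Observations equal to the noiseless typical trajectory sit at the
        center of the predictive distribution: signed-rank p near 1."""
        truth = GeneratorTruth()
        design = CohortDesign()
        series, _, _ = generate_cohort(design, truth, seed=4)
        typical = ExcretionCurveParams(*np.exp(truth.log_mu))
        centered = [
            UrineSeries(
                animal_id=s.animal_id, breed=s.breed, treatment=s.treatment,
                bw_kg=s.bw_kg, times_d=s.times_d,
                ratios=np.where(s.times_d > 0, evaluate_curve(typical, s.times_d), 0.0),
            )
            for s in series
        ]
        rep = compute_npde(_make_truth_fit(truth), centered, n_sim=400, seed=8)
        assert rep.wilcoxon_p > 0.5
        assert abs(float(np.mean(rep.npde))) < 0.15

    def test_gross_misspecification_inflates_variance(self):
        """Doubling the late ratios breaks the fitted variance structure: the
        variance test must reject in most replicates."""
        rejections = 0
        n_rep = 20
        for rep_i in range(n_rep):
            series, _, _ = generate_cohort(CohortDesign(), TRUE, seed=100 + rep_i)
            broken = [
                UrineSeries(
                    animal_id=s.animal_id, breed=s.breed, treatment=s.treatment,
                    bw_kg=s.bw_kg, times_d=s.times_d,
                    ratios=np.where(s.times_d > 0.5, 2.0 * s.ratios, s.ratios),
                )
                for s in series
            ]
            rep = compute_npde(_make_truth_fit(TRUE), broken, n_sim=300, seed=rep_i)
            rejections += rep.fisher_var_p < 0.05
        assert rejections > n_rep / 2

    def test_requires_converged_fit_and_enough_sims(self, default_fit, default_cohort):
        series, _, _ = default_cohort
        bad = copy.copy(default_fit)
        bad.converged = False
        with pytest.raises(ValueError, match="converged"):
            compute_npde(bad, series, n_sim=300, seed=0)
        with pytest.raises(ValueError, match="n_sim"):
            compute_npde(default_fit, series, n_sim=50, seed=0)
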