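"""Random-search ensemble calibration: sampling, scoring, recovery, summaries."""

import numpy as np
import pytest

from hpadyn import ModelParams, SubjectProfile
from hpadyn.fitting import (
    FitEnsemble, FitResult, ParamRanges, compare_ensembles, fit_ensemble,
    fit_error, sample_parameter_sets, summarize_ensemble,
)
from hpadyn.synth import gen_model_cortisol, gen_pulsatile_acth

from conftest import make_ts

TRUE = ModelParams(p_f=30.0, p_s=4.0, lambda_f=12.0, lambda_s=200.0,
                   K_A=50.28, m=2.0)


@pytest.fixture(scope="module")
def recovery_profile():
    acth = gen_pulsatile_acth(n_pulses=5, duration=720.0, seed=11)
    cort = gen_model_cortisol(TRUE, acth, noise_sd_frac=0.0, seed=0)
    return SubjectProfile("recov", acth, cort)


class TestSampling:
    def test_seeded_determinism(self):
        r = ParamRanges()
        a = sample_parameter_sets(r, 10, seed=5)
        b = sample_parameter_sets(r, 10, seed=5)
        assert a == b

    def test_all_fixed_gives_identical_sets(self):
        r = ParamRanges(fixed={"p_f": 1.0, "p_s": 2.0, "lambda_f": 5.0,
                               "lambda_s": 50.0, "K_A": 40.0, "m": 2.0})
        sets = sample_parameter_sets(r, 5, seed=0)
        assert len(set(sets)) == 1

    def test_loguniform_median_is_geometric_mean(self):
        """Median of 1e5 log-uniform lambda_s draws ~= sqrt(30*600)."""
        sets = sample_parameter_sets(ParamRanges(), 100_000, seed=1)
        med = np.median([p.lambda_s for p in sets])
        assert med == pytest.approx(np.sqrt(30.0 * 600.0), rel=0.05)

    def test_compartment_order_constraint(self):
        sets = sample_parameter_sets(ParamRanges(), 2000, seed=2)
        assert all(p.lambda_f < p.lambda_s for p in sets)

    def test_hill_coefficient_integer_range(self):
        sets = sample_parameter_sets(ParamRanges(), 2000, seed=3)
        ms = {p.m for p in sets}
        assert ms <= {1.0, 2.0, 3.0, 4.0, 5.0} and len(ms) == 5

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamRanges(bounds={"p_f": (10.0, 1.0), "p_s": (1e-2, 1e2),
                                "lambda_f": (1.0, 60.0), "lambda_s": (30.0, 600.0),
                                "K_A": (1.0, 500.0), "m": (1, 5)})


class TestFitError:
    def test_perfect_prediction(self, gauss_pulses):
        assert fit_error(gauss_pulses, gauss_pulses) == 0.0

    def test_constant_offset_over_range(self):
        obs = make_ts([0.0, 10.0])
        pred = make_ts([1.0, 11.0])
        assert fit_error(pred, obs) == pytest.approx(0.1)

    def test_constant_observation_infinite(self):
        assert fit_error(make_ts([1.0, 2.0]), make_ts([5.0, 5.0])) == np.inf

    def test_invariant_under_joint_affine_rescaling(self, gauss_pulses):
        pred = make_ts(gauss_pulses.v + 0.1)
        base = fit_error(pred, gauss_pulses)
        scaled = fit_error(make_ts(7.0 * pred.v - 3.0),
                           make_ts(7.0 * gauss_pulses.v - 3.0))
        assert scaled == pytest.approx(base, rel=1e-12)


class TestEnsemble:
    def test_determinism(self, recovery_profile):
        a = fit_ensemble(recovery_profile, n=2000, seed=9)
        b = fit_ensemble(recovery_profile, n=2000, seed=9)
        assert [r.epsilon for r in a.results] == [r.epsilon for r in b.results]
        assert a.results[0].params == b.results[0].params

    def test_results_sorted_ascending(self, recovery_profile):
        ens = fit_ensemble(recovery_profile, n=2000, seed=1)
        eps = [r.epsilon for r in ens.results]
        assert eps == sorted(eps)

    def test_keep_larger_than_n_rejected(self, recovery_profile):
        with pytest.raises(ValueError):
            fit_ensemble(recovery_profile, n=10, keep=20, seed=0)

    def test_monotone_improvement_with_more_draws(self, recovery_profile):
        """Best epsilon never worsens when the same seed samples more."""
        small = fit_ensemble(recovery_profile, n=5000, seed=4, chunk=5000)
        large = fit_ensemble(recovery_profile, n=20000, seed=4, chunk=5000)
        assert large.best.epsilon <= small.best.epsilon + 1e-12

    def test_fixed_KA_scenario_pins_value(self, recovery_profile):
        ens = fit_ensemble(recovery_profile, n=3000, seed=2, scenario="fixed_KA")
        assert all(r.params.K_A == 50.28 for r in ens.results)

    def test_fixed_m_scenario_pins_value(self, recovery_profile):
        ens = fit_ensemble(recovery_profile, n=3000, seed=2, scenario="fixed_m")
        assert all(r.params.m == 2.0 for r in ens.results)

    def test_identifiability_composite_gain_vs_individuals(self, recovery_profile):
        """p_f*lambda_f + p_s*lambda_s is far better determined than p_f alone."""
        from hpadyn.model import hill_drive
        ens = fit_ensemble(recovery_profile, n=50_000, seed=6, scenario="fixed_both")
        df = ens.to_frame()
        acth_v = recovery_profile.acth.v
        gains = np.array([
            (row.p_f * row.lambda_f + row.p_s * row.lambda_s)
            * float(np.mean(hill_drive(acth_v, row.K_A, row.m)))
            for row in df.itertuples()])

        def rel_iqr(x):
            return (np.percentile(x, 75) - np.percentile(x, 25)) / np.median(x)

        assert rel_iqr(df["p_f"].to_numpy()) / rel_iqr(gains) > 2.0


class TestSummaries:
    def _ensemble_from(self, values):
        results = [FitResult(ModelParams(1.0, 1.0, 0.5, v, 50.0, 2.0), 0.01 * i)
                   for i, v in enumerate(values)]
        return FitEnsemble(results, n_sampled=len(values),
                           selection_rule="all", seed=0)

    def test_identical_sets_degenerate_quantiles(self):
        ens = self._ensemble_from([100.0] * 5)
        q = summarize_ensemble(ens)["quantiles"]
        assert (q["lambda_s"] == 100.0).all()

    def test_median_of_1_to_100(self):
        ens = self._ensemble_from(list(range(1, 101)))
        q = summarize_ensemble(ens)["quantiles"]
        assert q.loc["50%", "lambda_s"] == pytest.approx(50.5)

    def test_quantiles_match_direct_sort(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(30.0, 600.0, 57)
        ens = self._ensemble_from(vals.tolist())
        q = summarize_ensemble(ens)["quantiles"]
        assert q.loc["25%", "lambda_s"] == pytest.approx(np.quantile(vals, 0.25))
        assert q.loc["95%", "lambda_s"] == pytest.approx(np.quantile(vals, 0.95))

    def test_empty_ensemble_rejected(self):
        ens = self._ensemble_from([1.0])
        ens.results = []
        with pytest.raises(RuntimeError):
            summarize_ensemble(ens)

    def test_scenario_comparison_shifts(self):
        a = self._ensemble_from([100.0] * 10)
        b = self._ensemble_from([150.0] * 10)
        cmp = compare_ensembles(a, b)
        assert cmp.loc["lambda_s", "median_shift"] == pytest.approx(50.0)
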