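import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from ystrkit.abc_pipeline import (
    EXTRA_SUMMARY_NAMES,
    PriorSpec,
    ReferenceTable,
    SUMMARY_NAMES,
    build_reference,
    estimate_parameters,
    fit,
    gof_pca,
    model_choice_regression,
    model_choice_rejection,
    summarize_matrix,
)
from ystrkit.haplotype_io import MutationRateTable
from ystrkit.synthetic_data import DemographicModel, simulate_alleles


def toy_table(models, summaries, params=None, priors=None,
              names=SUMMARY_NAMES):
    frame = pd.DataFrame(np.asarray(summaries, dtype=float), columns=list(names))
    frame.insert(0, "model", models)
    for col in ("Na", "Nc", "Tstart", "p_geom"):
        frame[col] = params.get(col, np.nan) if params else np.nan
    return ReferenceTable(frame, n_sample=10, loci=("L1",),
                          priors=priors or PriorSpec(), summary_names=names)


class TestPriorSpec:
    def test_size_draws_within_bounds(self):
        rng = np.random.default_rng(0)
        priors = PriorSpec()
        draws = [priors.sample_size(rng) for _ in range(2000)]
        assert min(draws) >= 100 and max(draws) <= 100000

    def test_loguniform_is_uniform_in_log(self):
        rng = np.random.default_rng(1)
        priors = PriorSpec()
        logs = np.log([priors.sample_size(rng) for _ in range(4000)])
        stat = kstest(logs, "uniform",
                      args=(np.log(100), np.log(100000) - np.log(100)))
        assert stat.pvalue > 0.01

    def test_growth_conditioning(self):
        rng = np.random.default_rng(2)
        priors = PriorSpec()
        for _ in range(500):
            draw = priors.sample_growth(rng)
            assert draw["Na"] < draw["Nc"]
            assert 50 <= draw["Tstart"] <= 350
            assert 0 <= draw["p_geom"] <= 0.8

    def test_truncated_lognormal_respects_bounds(self):
        rng = np.random.default_rng(3)
        priors = PriorSpec(size_prior="truncated-lognormal")
        draws = [priors.sample_size(rng) for _ in range(2000)]
        assert min(draws) >= 100 and max(draws) <= 100000


class TestSummarize:
    def test_hand_example_single_locus(self):
        # {12, 13, 15}: K=3, R=3, M=3/4, H=(3/2)(1 - 3*(1/3)^2) = 1
        with pytest.warns(UserWarning, match="single locus"):
            s = summarize_matrix(np.array([[12], [13], [15]]))
        assert s[0] == 3.0
        assert s[2] == pytest.approx(1.0)
        assert s[4] == 3.0
        assert s[6] == pytest.approx(0.75)
        assert np.isnan(s[1]) and np.isnan(s[7])

    def test_monomorphic(self):
        s = summarize_matrix(np.full((6, 4), 14))
        assert s[0] == 1.0 and s[2] == 0.0 and s[4] == 0.0 and s[6] == 1.0
        assert s[1] == s[3] == s[5] == s[7] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        alleles = rng.integers(10, 16, size=(30, 5))
        s = summarize_matrix(alleles)
        rows = rng.permutation(30)
        cols = rng.permutation(5)
        assert summarize_matrix(alleles[rows][:, cols]) == pytest.approx(s)

    def test_extra_haplotype_components(self):
        alleles = np.array([[12, 10], [12, 10], [13, 10], [14, 11]])
        s = summarize_matrix(alleles, extra_haplotype_stats=True)
        assert len(s) == 10
        assert s[8] == 3  # distinct haplotypes
        freqs = np.array([2, 1, 1]) / 4
        assert s[9] == pytest.approx(4 / 3 * (1 - np.sum(freqs**2)))

    def test_summary_invariants_on_simulated_data(self):
        alleles = simulate_alleles(40, DemographicModel.constant(500),
                                   np.full(6, 0.003), 0.3, 20, (5, 6))
        s = summarize_matrix(alleles)
        k_mean, h_mean, m_mean = s[0], s[2], s[6]
        assert np.isfinite(s).all()
        assert k_mean >= 1 and 0 <= h_mean <= 1 and 0 < m_mean <= 1


@pytest.fixture(scope="module")
def small_rates():
    return MutationRateTable({f"L{j}": 0.003 for j in range(5)})


@pytest.fixture(scope="module")
def small_reference(small_rates):
    return build_reference(["constant", "growth"], PriorSpec(), 300, 30,
                           small_rates, rng_seed=11)


class TestBuildReference:
    def test_deterministic_under_seed(self, small_rates):
        a = build_reference(["constant"], PriorSpec(), 10, 12, small_rates, 5)
        b = build_reference(["constant"], PriorSpec(), 10, 12, small_rates, 5)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_constant_rows_have_no_tstart(self, small_reference):
        const = small_reference.frame.query("model == 'constant'")
        assert const["Tstart"].isna().all()
        assert (const["Na"] == const["Nc"]).all()

    def test_tstart_prior_uniform(self, small_rates):
        ref = build_reference(["growth"], PriorSpec(), 400, 10, small_rates, 21)
        stat = kstest(ref.frame["Tstart"], "uniform", args=(50, 300))
        assert stat.pvalue > 0.01

    def test_row_counts_per_model(self, small_reference):
        counts = small_reference.frame["model"].value_counts()
        assert counts["constant"] == 300 and counts["growth"] == 300

    def test_no_missing_summary_components(self, small_reference):
        assert small_reference.summaries.shape == (600, 8)
        assert np.isfinite(small_reference.summaries).all()


class TestModelChoiceRejection:
    def test_degenerate_single_model(self):
        summaries = np.tile(np.arange(8.0), (6, 1))
        table = toy_table(["A"] * 3 + ["B"] * 3,
                          np.vstack([summaries[:3], summaries[3:] + 100.0]))
        probs = model_choice_rejection(table, np.arange(8.0), 0.5)
        assert probs["A"] == 1.0 and probs["B"] == 0.0

    def test_hand_computed_toy(self):
        # 6 rows; retention of the closest 3 = {A, A, B} -> P(A) = 2/3
        base = np.zeros(8)
        rows = [base + d for d in (0.1, 0.2, 0.3, 5.0, 6.0, 7.0)]
        table = toy_table(["A", "A", "B", "B", "A", "B"], rows)
        probs = model_choice_rejection(table, base, 0.5)
        assert probs["A"] == pytest.approx(2 / 3)
        assert probs["B"] == pytest.approx(1 / 3)

    def test_probabilities_sum_to_one(self, small_reference):
        observed = small_reference.summaries[7]
        for tol in (0.05, 0.1, 0.5):
            probs = model_choice_rejection(small_reference, observed, tol)
            assert sum(probs.values()) == pytest.approx(1.0)

    def test_invalid_tolerance(self, small_reference):
        with pytest.raises(ValueError):
            model_choice_rejection(small_reference,
                                   small_reference.summaries[0], 0.0)


class TestModelChoiceRegression:
    def test_single_model_retained_falls_back(self):
        rows = np.vstack([np.zeros((4, 8)), np.full((4, 8), 50.0)])
        table = toy_table(["A"] * 4 + ["B"] * 4, rows)
        with pytest.warns(UserWarning, match="falling back"):
            probs = model_choice_regression(table, np.zeros(8), 0.5)
        assert probs["A"] == 1.0

    def test_symmetric_two_model_toy(self):
        rng = np.random.default_rng(8)
        offsets = rng.normal(0, 1.0, size=(60, 8))
        rows = np.vstack([offsets, -offsets])  # mirror image summaries
        table = toy_table(["A"] * 60 + ["B"] * 60, rows)
        probs = model_choice_regression(table, np.zeros(8), 1.0)
        assert probs["A"] == pytest.approx(0.5, abs=0.02)

    def test_agrees_with_rejection_when_separated(self):
        # clouds separated enough that A dominates, with some B retained
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, size=(300, 8))
        b = rng.normal(1.0, 1.0, size=(300, 8))
        table = toy_table(["A"] * 300 + ["B"] * 300, np.vstack([a, b]))
        obs = np.full(8, -0.5)
        rej = model_choice_rejection(table, obs, 0.25)
        reg = model_choice_regression(table, obs, 0.25)
        assert rej["A"] > 0.9  # both models present among retained
        assert abs(rej["A"] - reg["A"]) < 0.05


class TestEstimateParameters:
    def test_zero_slope_regression_returns_prior_draws(self):
        rng = np.random.default_rng(13)
        n = 1200
        tstart = rng.uniform(50, 350, size=n)
        summaries = np.tile(np.arange(8.0), (n, 1))  # all rows identical
        table = toy_table(["growth"] * n, summaries,
                          params={"Na": 200.0, "Nc": 5000.0, "p_geom": 0.1})
        table.frame["Tstart"] = tstart
        out = estimate_parameters(table, np.arange(8.0), "growth", 0.05)
        kept = np.sort(tstart)  # ties: argsort stable, first 60 rows
        assert 50 <= out["Tstart"]["hpd_low"] <= out["Tstart"]["hpd_high"] <= 350

    def test_linear_toy_recovery(self):
        # summary = parameter + small noise: median within 2% of truth
        rng = np.random.default_rng(14)
        n = 4000
        theta = rng.uniform(50, 350, size=n)
        noise = rng.normal(0, 2.0, size=(n, 8))
        summaries = theta[:, None] + noise
        table = toy_table(["growth"] * n, summaries,
                          params={"Na": 200.0, "Nc": 5000.0, "p_geom": 0.1})
        table.frame["Tstart"] = theta
        truth = 200.0
        out = estimate_parameters(table, np.full(8, truth), "growth", 0.05)
        assert out["Tstart"]["median"] == pytest.approx(truth, rel=0.02)

    def test_posteriors_respect_prior_bounds(self, small_reference):
        observed = small_reference.summaries[3]
        sub = small_reference.subset(
            small_reference.frame["model"].to_numpy() == "growth")
        out = estimate_parameters(sub, observed, "growth", retain_fraction=0.5)
        priors = PriorSpec()
        for param, (low, high) in priors.bounds_for("growth").items():
            assert low <= out[param]["hpd_low"] <= out[param]["hpd_high"] <= high
            assert out[param]["hpd_low"] <= out[param]["median"] \
                <= out[param]["hpd_high"]

    def test_small_retention_rejected(self, small_reference):
        with pytest.raises(ValueError, match="50"):
            estimate_parameters(small_reference,
                                small_reference.summaries[0], "growth", 0.01)


class TestGofPca:
    def test_observed_on_a_row_is_inside(self):
        rng = np.random.default_rng(15)
        rows = np.vstack([rng.normal(0, 1, size=(50, 8)),
                          rng.normal(5, 1, size=(50, 8))])
        table = toy_table(["A"] * 50 + ["B"] * 50, rows)
        _, _, inside = gof_pca(table, rows[3], best_k=50, favoured="A")
        assert inside

    def test_distant_observed_is_outside(self):
        rng = np.random.default_rng(16)
        rows = rng.normal(0, 1, size=(60, 8))
        table = toy_table(["A"] * 30 + ["B"] * 30, rows)
        _, _, inside = gof_pca(table, np.full(8, 10.0) * rng.standard_normal(8).std() * 10,
                               best_k=30, favoured="A")
        assert not inside

    def test_embedding_deterministic_and_sign_canonical(self):
        rng = np.random.default_rng(17)
        rows = rng.normal(0, 1, size=(80, 8))
        table = toy_table(["A"] * 40 + ["B"] * 40, rows)
        f1, o1, _ = gof_pca(table, np.zeros(8), best_k=40)
        f2, o2, _ = gof_pca(table, np.zeros(8), best_k=40)
        pd.testing.assert_frame_equal(f1, f2)
        assert o1 == pytest.approx(o2)


class TestFitOrchestration:
    def test_fit_returns_consistent_result(self, small_reference):
        observed = small_reference.summaries[450]  # a growth row
        result = fit(small_reference, observed, tolerances=(0.1, 0.2),
                     retain_fraction=0.5)
        for method in ("rejection", "regression"):
            for tol, probs in result.model_probs[method].items():
                assert sum(probs.values()) == pytest.approx(1.0)
        assert result.chosen_model in ("constant", "growth")
        assert set(result.parameters) == set(
            PriorSpec().bounds_for(result.chosen_model))
        payload = result.to_dict()
        assert "model_probabilities" in payload and "parameters" in payload
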