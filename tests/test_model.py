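import math

import numpy as np
import pandas as pd
import pytest

import decaydet as d
from decaydet.io_core import AnalysisMatrix, assemble_complete_matrix
from decaydet.model import (CollinearityError, Design, DesignSpec, ModelFit,
                            build_design_matrix, fit_ols, selection_criterion,
                            stepwise_select)

from oracles import exhaustive_best_subset, ols_normal_equations


def _toy_matrix(table: pd.DataFrame, response: np.ndarray) -> AnalysisMatrix:
    ids = [f"g{i}" for i in range(len(table))]
    table = table.copy()
    table.index = ids
    return AnalysisMatrix(gene_ids=ids, response=response, table=table,
                          growth_rate="0.10")


class TestBuildDesignMatrix:
    def test_two_point_column_standardizes_to_plus_minus_one(self):
        table = pd.DataFrame({"cai": [1.0, math.exp(2)],
                              "essential": [True, False]})
        matrix = _toy_matrix(table, np.array([0.0, 1.0]))
        spec = DesignSpec("halflife", ("cai",), ("essential",), "0.10")
        design = build_design_matrix(matrix, spec)
        # ln values {0, 2} center to {-1, +1} with the population SD
        np.testing.assert_allclose(design.X["cai"], [-1.0, 1.0])

    def test_multi_membership_cog_sets_both_indicators(self):
        table = pd.DataFrame({"cog": ["D;J", "J", ""],
                              "essential": [True, False, False]})
        matrix = _toy_matrix(table, np.zeros(3))
        spec = DesignSpec("halflife", (), ("cog", "essential"), "0.10")
        design = build_design_matrix(matrix, spec)
        assert design.X.loc["g0", "cog[D]"] == 1.0
        assert design.X.loc["g0", "cog[J]"] == 1.0
        assert design.X.loc["g1", "cog[D]"] == 0.0
        assert design.X.loc["g2", "cog[J]"] == 0.0

    def test_hand_expanded_toy_design(self):
        """Three genes expanded against an explicit hand-coded design."""
        table = pd.DataFrame({
            "mrna": [1.0, math.e, math.e ** 2],
            "operon_size": [1, 2, 2],
            "second_nt": ["purine", "pyrimidine", "purine"],
        })
        matrix = _toy_matrix(table, np.array([1.0, 2.0, 3.0]))
        spec = DesignSpec("halflife", ("mrna",),
                          ("operon_size", "second_nt"), "0.10")
        X = build_design_matrix(matrix, spec).X
        sd = math.sqrt(2 / 3)                     # population SD of {0,1,2}
        np.testing.assert_allclose(X["mrna"], [-1 / sd, 0.0, 1 / sd])
        np.testing.assert_allclose(X["operon_size[2]"], [0.0, 1.0, 1.0])
        np.testing.assert_allclose(X["second_nt[purine]"], [1.0, 0.0, 1.0])
        np.testing.assert_allclose(X["intercept"], 1.0)

    def test_zero_variance_column_error_names_term(self):
        table = pd.DataFrame({"cai": [0.5, 0.5, 0.5],
                              "essential": [True, False, True]})
        matrix = _toy_matrix(table, np.zeros(3))
        spec = DesignSpec("halflife", ("cai",), ("essential",), "0.10")
        with pytest.raises(ValueError, match="cai"):
            build_design_matrix(matrix, spec)

    def test_response_is_natural_log_and_unstandardized(self, small_dataset):
        records, truth, feats, ref = small_dataset
        matrix, _ = assemble_complete_matrix(records, feats, "0.20")
        expected = [math.log(r.half_life["0.20"]) for r in records
                    if r.gene_id in matrix.gene_ids]
        np.testing.assert_allclose(matrix.response, expected)

    def test_rescaling_raw_covariate_leaves_coefficients_unchanged(
            self, small_dataset):
        """Lengths in codons vs nt give identical standardized fits."""
        records, truth, feats, ref = small_dataset
        matrix, _ = assemble_complete_matrix(records, feats, "0.10")
        spec = DesignSpec.halflife("0.10")
        fit1 = fit_ols(build_design_matrix(matrix, spec))
        matrix.table = matrix.table.assign(orf_length=matrix.table.orf_length / 3)
        fit2 = fit_ols(build_design_matrix(matrix, spec))
        pd.testing.assert_series_equal(fit1.coef, fit2.coef, rtol=1e-9)


class TestFitOLS:
    def _design(self, X: pd.DataFrame, y) -> Design:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
        return Design(y=np.asarray(y, dtype=float), X=X,
                      term_columns={c: [c] for c in X.columns[1:]},
                      growth_rate="0.10", response_kind="halflife")

    def test_exact_line_recovered(self):
        x = np.array([0.0, 1, 2, 3, 4])
        design = self._design(pd.DataFrame({"x": x}), 2 * x)
        fit = fit_ols(design)
        assert fit.coef["x"] == pytest.approx(2.0)
        assert fit.coef["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        y = rng.normal(size=6)
        design = self._design(X, y)
        fit = fit_ols(design)
        expected = ols_normal_equations(design.X.to_numpy(), y)
        np.testing.assert_allclose(fit.coef.to_numpy(), expected, rtol=1e-9)

    def test_row_permutation_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        design = self._design(X, y)
        fit1 = fit_ols(design)
        perm = rng.permutation(20)
        design2 = self._design(X.iloc[perm].reset_index(drop=True), y[perm])
        fit2 = fit_ols(design2)
        np.testing.assert_allclose(fit1.coef, fit2.coef, rtol=1e-9)
        assert fit1.rss == pytest.approx(fit2.rss)
        np.testing.assert_allclose(fit1.pvalue, fit2.pvalue, rtol=1e-9)

    def test_collinear_design_rejected_with_columns_listed(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        X["c"] = X["a"] + X["b"]
        with pytest.raises(CollinearityError):
            fit_ols(self._design(X, rng.normal(size=10)))


class TestSelectionCriterion:
    def _fit(self, n, rss, N):
        s = pd.Series(dtype=float)
        return ModelFit([], s, s, s, rss, n, N, 0.0)

    def test_printed_arithmetic_cases(self):
        assert selection_criterion(self._fit(100, 100.0, 3)) == pytest.approx(6.0)
        assert selection_criterion(self._fit(4, 4 * math.e, 2)) == pytest.approx(8.0)

    def test_useless_column_costs_exactly_two(self):
        a = selection_criterion(self._fit(50, 10.0, 3))
        b = selection_criterion(self._fit(50, 10.0, 4))
        assert b - a == pytest.approx(2.0)

    def test_zero_rss_yields_minus_infinity_with_warning(self):
        with pytest.warns(UserWarning, match="RSS"):
            assert selection_criterion(self._fit(10, 0.0, 2)) == -math.inf


def _synthetic_design(rng, n=200, k=6, true_terms=(0, 2), beta=0.6,
                      sigma=1.0) -> Design:
    X = pd.DataFrame(rng.normal(size=(n, k)),
                     columns=[f"t{i}" for i in range(k)])
    y = sigma * rng.normal(size=n)
    for i in true_terms:
        y = y + beta * X.iloc[:, i].to_numpy()
    X.insert(0, "intercept", 1.0)
    return Design(y=y, X=X, term_columns={c: [c] for c in X.columns[1:]},
                  growth_rate="0.10", response_kind="halflife")


class TestStepwise:
    def test_matches_exhaustive_best_subset_on_fixed_instance(self, rng):
        design = _synthetic_design(rng)
        result = stepwise_select(design)
        oracle_terms, oracle_crit = exhaustive_best_subset(
            design, design.terms)
        assert result.selected_terms == oracle_terms
        assert selection_criterion(result.final_fit) == \
            pytest.approx(oracle_crit)

    def test_all_noise_response_selects_intercept_only(self, rng):
        design = _synthetic_design(rng, n=500, k=3, true_terms=(), beta=0.0)
        result = stepwise_select(design)
        oracle_terms, _ = exhaustive_best_subset(design, design.terms)
        assert result.selected_terms == oracle_terms == []
        assert result.final_fit.N == 1

    def test_empty_scope_returns_intercept_only_fit(self, rng):
        design = _synthetic_design(rng)
        result = stepwise_select(design, scope=[])
        assert result.selected_terms == []
        assert result.final_fit.terms == []

    def test_trace_is_strictly_decreasing(self, rng):
        design = _synthetic_design(rng, n=150, k=8, true_terms=(0, 3, 5))
        result = stepwise_select(design)
        crits = [c for _, _, _, c in result.criterion_trace]
        assert all(b < a for a, b in zip(crits, crits[1:]))

    def test_agrees_with_exhaustive_oracle_on_most_random_instances(self):
        """Stepwise is a heuristic; it must match best-subset >= 95% here."""
        rng = np.random.default_rng(77)
        agree = 0
        trials = 30
        for _ in range(trials):
            k = int(rng.integers(4, 8))
            n_true = int(rng.integers(0, 4))
            true_terms = tuple(rng.choice(k, size=n_true, replace=False))
            design = _synthetic_design(rng, n=120, k=k, true_terms=true_terms,
                                       beta=float(rng.uniform(0.2, 0.8)))
            result = stepwise_select(design)
            oracle_terms, _ = exhaustive_best_subset(design, design.terms)
            agree += result.selected_terms == oracle_terms
        assert agree >= math.ceil(0.95 * trials)


class TestRunModels:
    def test_protein_run_without_protein_data_refused(self, small_dataset):
        records, truth, feats, ref = small_dataset
        stripped = [r.copy(protein_conc={}) for r in records]
        with pytest.raises(ValueError, match="protein"):
            d.run_models(stripped, feats, response="protein")

    def test_protein_model_recovers_cai_effect(self):
        truth = d.SyntheticTruth(
            seed=31, protein_truth={"coef_halflife": -0.14, "coef_cai": 0.5,
                                    "sigma_p": 0.6, "alpha_p": 5.0})
        recs, truth, feats, ref = d.generate_dataset(
            d.GenomeConfig(n_genes=700, utr_len_range=(20, 100)),
            truth=truth, seed=31)
        results = d.run_models(recs, feats, response="protein")
        for mu, res in results.items():
            assert "cai" in res.selected_terms, mu
            assert res.final_fit.coef["cai"] > 0, mu
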