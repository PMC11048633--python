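import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wetlandnbn import (
    MetamodelDAG,
    conditionalize,
    fit_marginal,
    fit_nbn,
    load_model,
    predict_target,
    product_moment_to_rank,
    rank_to_product_moment,
    sample_joint,
    save_model,
    spearman_rho,
)
from wetlandnbn.copula import build_joint_correlation
from wetlandnbn.exceptions import DegenerateMarginalError, SchemaError
from conftest import build_toy_nbn


class TestEmpiricalMarginal:
    def test_middle_order_statistic(self):
        m = fit_marginal([1, 2, 3])
        assert m.cdf(2) == pytest.approx(0.5)

    def test_average_rank_with_ties(self):
        # rank/(n+1) with average ranks: F(0) = 1.5/5
        m = fit_marginal([0, 0, 1, 3], discrete=True)
        assert m.cdf(0) == pytest.approx(0.3)
        assert m.cdf(1) == pytest.approx(0.6)
        assert m.cdf(3) == pytest.approx(0.8)

    def test_quantile_inverts_cdf_on_atoms(self):
        values = [0.5, 1.7, 2.2, 9.0, 4.4]
        m = fit_marginal(values)
        for x in values:
            assert m.quantile(m.cdf(x)) == pytest.approx(x)

    def test_discrete_quantile_stays_on_support(self):
        m = fit_marginal([0, 0, 1, 1, 2, 3], discrete=True)
        u = np.linspace(0.001, 0.999, 97)
        assert set(np.unique(m.quantile(u))) <= {0, 1, 2, 3}

    def test_cdf_open_interval(self):
        m = fit_marginal([1, 2, 3, 4])
        assert 0 < m.cdf(-100) < 1
        assert 0 < m.cdf(100) < 1

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateMarginalError):
            fit_marginal([2.0, 2.0, 2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=30, unique=True))
    def test_cdf_monotone_quantile_in_support(self, values):
        m = fit_marginal(values)
        grid = np.linspace(min(values) - 1, max(values) + 1, 41)
        f = m.cdf(grid)
        assert np.all(np.diff(f) >= -1e-12)
        q = m.quantile(np.linspace(0.01, 0.99, 21))
        assert q.min() >= min(values) and q.max() <= max(values)


class TestRankCorrelation:
    def test_identical_rankings(self):
        assert spearman_rho([1, 5, 9, 2], [1, 5, 9, 2]) == pytest.approx(1.0)

    def test_antitone_rankings(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_printed_formula_by_hand(self):
        # ranks (1,2,3,4) vs (2,1,4,3): sum d^2 = 4 -> 1 - 24/60 = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            spearman_rho([1, 2, 3], [1, 2, 3, 4])

    def test_constant_vector_undefined(self):
        with pytest.raises(DegenerateMarginalError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestCopulaConversion:
    @pytest.mark.parametrize(
        "rho_s, expected",
        [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0), (0.5, 2 * np.sin(np.pi / 12))],
    )
    def test_known_values(self, rho_s, expected):
        assert rank_to_product_moment(rho_s) == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(SchemaError):
            rank_to_product_moment(1.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-1, 1))
    def test_round_trip_and_expansion(self, rho_s):
        r = rank_to_product_moment(rho_s)
        assert product_moment_to_rank(r) == pytest.approx(rho_s, abs=1e-12)
        if 0.01 < abs(rho_s) < 0.99:  # away from the fixed points 0 and +-1
            assert abs(r) > abs(rho_s)


class TestFit:
    def test_independent_columns_near_zero_arcs(self):
        rng = np.random.default_rng(21)
        n = 10_000
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "m": rng.normal(size=n), "AD": rng.normal(size=n)}
        )
        dag = MetamodelDAG(
            nodes=["x", "m", "AD"], arcs=[("x", "AD", "+"), ("m", "AD", "+")], sink="AD"
        )
        nbn = fit_nbn(df, dag)
        for rho in nbn.dependence.arc_corr.values():
            assert abs(rho) < 0.03

    def test_chain_copula_recovery(self):
        rng = np.random.default_rng(5)
        dag = MetamodelDAG(
            nodes=["x", "m", "AD"], arcs=[("x", "m", "+"), ("m", "AD", "+")], sink="AD"
        )
        R = build_joint_correlation(dag, {("x", "m"): 0.6, ("m", "AD"): 0.5})
        z = rng.multivariate_normal(np.zeros(3), R, size=10_000)
        df = pd.DataFrame({"x": z[:, 0], "m": np.exp(z[:, 1]), "AD": z[:, 2] ** 3})
        nbn = fit_nbn(df, dag)
        assert nbn.dependence.arc_corr[("x", "m")] == pytest.approx(0.6, abs=0.03)
        assert nbn.dependence.arc_corr[("m", "AD")] == pytest.approx(0.5, abs=0.03)

    def test_perfect_agreement_boundary(self):
        x = np.arange(1.0, 9.0)
        df = pd.DataFrame({"x": x, "AD": 2 * x + 1})
        dag = MetamodelDAG(nodes=["x", "AD"], arcs=[("x", "AD", "+")], sink="AD")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            nbn = fit_nbn(df, dag)
        assert nbn.dependence.arc_corr[("x", "AD")] == pytest.approx(1.0)
        assert np.allclose(nbn.dependence.R, np.ones((2, 2)))
        assert any("boundary" in str(w.message) for w in caught)

    def test_dag_node_missing_from_table(self, chain_nbn):
        df = pd.DataFrame({"x": [1.0, 2, 3], "AD": [1.0, 2, 3]})
        with pytest.raises(SchemaError, match="m"):
            fit_nbn(df, chain_nbn.dag)


class TestConditionalize:
    def test_empty_evidence_is_unconditional(self, chain_nbn):
        law = conditionalize(chain_nbn, {})
        assert law.free == ["x", "m", "AD"]
        assert np.allclose(law.mean, 0)
        assert np.allclose(law.cov, chain_nbn.dependence.R)

    def test_bivariate_closed_form(self):
        nbn = build_toy_nbn(["x", "AD"], {("x", "AD"): 0.7}, sink="AD")
        x_star = float(nbn.marginals["x"].values[200])
        z = nbn.marginals["x"].normal_score(x_star)
        law = conditionalize(nbn, {"x": x_star})
        mu, sd = law.marginal_normal("AD")
        assert mu == pytest.approx(0.7 * z, abs=1e-12)
        assert sd**2 == pytest.approx(1 - 0.49, abs=1e-12)

    def test_markov_chain_conditional_independence(self, chain_nbn):
        m_star = float(np.median(chain_nbn.marginals["m"].values))
        law = conditionalize(chain_nbn, {"m": m_star})
        i, j = law.index("x"), law.index("AD")
        assert law.cov[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_sink_cannot_be_evidence(self, chain_nbn):
        from wetlandnbn.exceptions import ScenarioError

        with pytest.raises(ScenarioError):
            conditionalize(chain_nbn, {"AD": 1.0})

    def test_out_of_support_evidence_warns_and_saturates(self, chain_nbn):
        hi = chain_nbn.marginals["x"].support[1]
        with pytest.warns(UserWarning, match="outside observed support"):
            law_out = conditionalize(chain_nbn, {"x": hi + 100})
        law_max = conditionalize(chain_nbn, {"x": hi})
        assert np.allclose(law_out.mean, law_max.mean)


class TestPredictAndSample:
    def test_same_seed_bitwise_identical(self, exact_nbn):
        a = predict_target(exact_nbn, {"water_salinity": 3}, n_samples=20_000, seed=9)
        b = predict_target(exact_nbn, {"water_salinity": 3}, n_samples=20_000, seed=9)
        assert a == b

    def test_deterministic_limit_single_perfect_parent(self):
        nbn = build_toy_nbn(["x", "AD"], {("x", "AD"): 0.999999}, sink="AD")
        x_star = float(np.median(nbn.marginals["x"].values))
        _, sd = predict_target(nbn, {"x": x_star}, n_samples=5_000, seed=0)
        assert sd < 0.05

    def test_sample_joint_single_row_in_support(self, exact_nbn):
        row = sample_joint(exact_nbn, 1, seed=4)
        assert len(row) == 1
        for var in exact_nbn.dependence.order:
            lo, hi = exact_nbn.marginals[var].support
            assert lo <= float(row[var].iloc[0]) <= hi

    def test_sample_joint_ordinal_support(self, exact_nbn):
        draws = sample_joint(exact_nbn, 500, seed=8)
        assert set(np.unique(draws["water_salinity"])) <= {0, 1, 2, 3}

    def test_rank_correlation_round_trip(self, chain_nbn):
        draws = sample_joint(chain_nbn, 100_000, seed=12)
        implied = product_moment_to_rank(float(chain_nbn.dependence.R[0, 1]))
        observed = spearman_rho(draws["x"], draws["m"])
        assert observed == pytest.approx(implied, abs=0.01)

    def test_monotone_propagation_along_positive_path(self, chain_nbn):
        xs = np.quantile(chain_nbn.marginals["x"].values, np.linspace(0.05, 0.95, 7))
        means = [
            predict_target(chain_nbn, {"x": float(v)}, n_samples=20_000, seed=3)[0]
            for v in xs
        ]
        assert np.all(np.diff(means) >= -1e-9)


class TestSerialization:
    def test_model_json_round_trip(self, fitted16, tmp_path):
        path = tmp_path / "model.json"
        save_model(fitted16, path)
        back = load_model(path)
        assert back.dependence.order == fitted16.dependence.order
        assert np.allclose(back.dependence.R, fitted16.dependence.R)
        assert back.dependence.arc_corr == pytest.approx(fitted16.dependence.arc_corr)
        m0, s0 = predict_target(fitted16, {}, n_samples=10_000, seed=1)
        m1, s1 = predict_target(back, {}, n_samples=10_000, seed=1)
        assert (m0, s0) == (m1, s1)
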