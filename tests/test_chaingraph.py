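"""The sequences-of-regressions engine: fitting, selection, graph, prediction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycograph.chaingraph import (
    Box,
    PredictionQuery,
    Term,
    Variable,
    VariableOrdering,
    build_graph,
    export_graph,
    fit_full_model,
    fit_response,
    predict_outcome_ratio,
    screen_interactions,
    select_model,
    symmetric_associations,
    validate_ordering,
    variance_explained,
)
from glycograph.chaingraph import _fit_terms
from glycograph.errors import CollinearityError, ConfigurationError, DomainError

from conftest import make_ordering
from helpers import ols_oracle, parse_dot


class TestOrdering:
    def test_default_config_ordering_is_accepted(self):
        from glycograph.config import default_config, ordering_from_config

        ordering = ordering_from_config(default_config())
        cols = ordering.all_variables
        assert validate_ordering(ordering, cols) is ordering
        assert ordering.responses() == [
            "d_log_homa_ir", "d_log_homa_b", "d_log_glucose", "d_log_hba1c",
            "d_weight", "d_satfat_pct", "d_steps_k",
        ]
        # treatment arm is a source only, never modelled
        assert "arm" not in ordering.responses()

    def test_variable_in_two_boxes_rejected(self):
        with pytest.raises(ConfigurationError):
            VariableOrdering(
                [Box(("y",)), Box(("x", "x"))],
                {"y": Variable("y"), "x": Variable("x")},
            )

    def test_response_must_be_leftmost(self):
        with pytest.raises(ConfigurationError):
            VariableOrdering(
                [Box(("y",)), Box(("x",))],
                {"y": Variable("y"), "x": Variable("x", role="response")},
            )

    def test_missing_data_column_rejected(self, ordering3):
        with pytest.raises(ConfigurationError):
            validate_ordering(ordering3, ["y", "x1", "x2"])  # x3 absent

    def test_empty_rightmost_box_warns_but_passes(self):
        ordering = VariableOrdering(
            [Box(("y",)), Box(("x",)), Box(())],
            {"y": Variable("y", role="response"), "x": Variable("x")},
        )
        with pytest.warns(UserWarning):
            validate_ordering(ordering, ["y", "x"])


class TestFullModel:
    def test_single_covariate_slope_is_cov_over_var(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1, 7.2, 7.7, 9.3, 9.8, 11.4])
        ordering = make_ordering(covars=("x1",))
        data = pd.DataFrame({"y": y, "x1": x})
        fit = fit_full_model("y", ordering, data)
        xc = x - x.mean()
        expected = float(xc @ (y - y.mean()) / (xc @ xc))
        assert fit.params.loc["x1", "coef"] == pytest.approx(expected, abs=1e-12)

    def test_response_identical_to_covariate_is_exact(self):
        x = np.linspace(0, 1, 30)
        ordering = make_ordering(covars=("x1",))
        fit = fit_full_model("y", ordering, pd.DataFrame({"y": x, "x1": x}))
        assert fit.params.loc["x1", "coef"] == pytest.approx(1.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_noise_response_has_small_t_and_r2(self, rng):
        n = 1000
        data = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        fit = fit_full_model("y", make_ordering(), data)
        assert np.abs(fit.params.drop("Intercept")["t"]).max() < 4.0
        assert fit.r_squared < 0.02

    def test_rank_deficient_design_names_aliased_columns(self, rng):
        x = rng.normal(size=50)
        data = pd.DataFrame({"y": rng.normal(size=50), "x1": x, "x2": 2 * x, "x3": rng.normal(size=50)})
        with pytest.raises(CollinearityError) as err:
            fit_full_model("y", make_ordering(), data)
        assert err.value.aliased

    def test_response_in_rightmost_box_rejected(self, ordering3, rng):
        data = pd.DataFrame({c: rng.normal(size=10) for c in ("y", "x1", "x2", "x3")})
        with pytest.raises(ConfigurationError):
            fit_full_model("x1", ordering3, data)

    def test_matches_normal_equations_oracle(self, rng):
        n, k = 40, 4
        X = rng.normal(size=(n, k))
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        covars = tuple(f"x{i + 1}" for i in range(k))
        data = pd.DataFrame(X, columns=covars).assign(y=y)
        fit = fit_full_model("y", make_ordering(covars=covars), data)
        beta, se, _, p, rss, _ = ols_oracle(np.column_stack([np.ones(n), X]), y)
        names = ["Intercept", *covars]
        np.testing.assert_allclose(fit.params.loc[names, "coef"], beta, atol=1e-10)
        np.testing.assert_allclose(fit.params.loc[names, "se"], se, atol=1e-10)
        np.testing.assert_allclose(fit.params.loc[names, "p"], p, atol=1e-10)
        assert fit.rss == pytest.approx(rss, rel=1e-12)


class TestSelection:
    def test_strong_signal_kept_noise_dropped(self, rng):
        n = 500
        x1, x2, x3 = rng.normal(size=(3, n))
        data = pd.DataFrame(
            {"y": 2.0 * x1 + rng.normal(size=n), "x1": x1, "x2": x2, "x3": x3}
        )
        ordering = make_ordering()
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        assert [t.name for t in selected.terms] == ["x1"]

    def test_selected_model_nested_with_smaller_r2(self, rng):
        n = 300
        x1, x2, x3 = rng.normal(size=(3, n))
        data = pd.DataFrame(
            {"y": 0.5 * x1 + 0.1 * x2 + rng.normal(size=n), "x1": x1, "x2": x2, "x3": x3}
        )
        ordering = make_ordering()
        full = fit_full_model("y", ordering, data)
        selected = select_model(full, data, ordering)
        assert {t.name for t in selected.terms} <= {t.name for t in full.terms}
        assert selected.r_squared <= full.r_squared + 1e-12

    def test_minimal_model_is_fixed_point(self, rng):
        n = 400
        x1 = rng.normal(size=n)
        data = pd.DataFrame({"y": 3.0 * x1 + rng.normal(size=n), "x1": x1})
        ordering = make_ordering(covars=("x1",))
        full = fit_full_model("y", ordering, data)
        selected = select_model(full, data, ordering)
        assert [t.name for t in selected.terms] == ["x1"]
        pd.testing.assert_frame_equal(selected.params, full.params)

    def test_all_noise_usually_reduces_to_intercept_only(self, rng):
        hits = 0
        reps = 100
        ordering = make_ordering()
        for _ in range(reps):
            data = pd.DataFrame(
                {c: rng.normal(size=120) for c in ("y", "x1", "x2", "x3")}
            )
            selected = select_model(fit_full_model("y", ordering, data), data, ordering)
            hits += not selected.terms
        # approx (1 - alpha)^3 ~ 0.86 of replicates keep nothing
        assert hits / reps >= 0.75

    def test_categorical_blocks_dropped_whole(self, rng):
        n = 300
        g = rng.choice(["a", "b", "c"], size=n)
        x1 = rng.normal(size=n)
        data = pd.DataFrame({"y": 2 * x1 + rng.normal(size=n), "x1": x1, "g": g})
        ordering = make_ordering(covars=("x1", "g"), categorical={"g": "a"})
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        names = [t.name for t in selected.terms]
        assert "x1" in names and "g" not in names


class TestInteractionScreening:
    def test_planted_interaction_recovered_with_hierarchy(self, rng):
        n = 500
        x1, x2, x3 = rng.normal(size=(3, n))
        y = x1 + x2 + 1.5 * x1 * x2 + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})
        ordering = make_ordering()
        fit = fit_response("y", ordering, data, interaction_candidates=[("x1", "x2")])
        names = {t.name for t in fit.terms}
        assert "x1:x2" in names and {"x1", "x2"} <= names

    def test_null_interaction_rarely_added(self, rng):
        added = 0
        reps = 100
        ordering = make_ordering(covars=("x1", "x2"))
        for _ in range(reps):
            x1, x2 = rng.normal(size=(2, 200))
            y = x1 + x2 + rng.normal(size=200)
            data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            fit = fit_response("y", ordering, data, interaction_candidates=[("x1", "x2")])
            added += any(t.is_interaction for t in fit.terms)
        assert added / reps <= 0.12  # ~selection alpha of replicates

    def test_empty_candidate_list_is_identity(self, rng):
        data = pd.DataFrame({c: rng.normal(size=100) for c in ("y", "x1", "x2", "x3")})
        ordering = make_ordering()
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        screened = screen_interactions(selected, [], data, ordering)
        assert screened is selected

    def test_candidate_referencing_response_rejected(self, rng):
        data = pd.DataFrame({c: rng.normal(size=100) for c in ("y", "x1", "x2", "x3")})
        ordering = make_ordering()
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        with pytest.raises(ConfigurationError):
            screen_interactions(selected, [("y", "x1")], data, ordering)


class TestSymmetricAssociations:
    def _ordering(self, names, categorical=()):
        variables = {
            "y": Variable("y", role="response"),
            **{
                n: Variable(n, vtype="categorical", reference=categorical[n], role="intrinsic")
                if n in categorical
                else Variable(n, role="intrinsic")
                for n in names
            },
        }
        return VariableOrdering([Box(("y",)), Box(tuple(names))], variables)

    def test_identical_variables_get_edge(self, rng):
        z = rng.normal(size=200)
        data = pd.DataFrame({"y": rng.normal(size=200), "a": z, "b": z})
        edges = symmetric_associations(self._ordering(("a", "b")), data, 0.10)
        assert [e.key for e in edges] == [("a", "b")]

    def test_single_variable_no_pairs(self, rng):
        data = pd.DataFrame({"y": rng.normal(size=50), "a": rng.normal(size=50)})
        assert symmetric_associations(self._ordering(("a",)), data, 0.10) == []

    def test_mixed_and_categorical_pairs(self, rng):
        n = 400
        g = rng.choice(["m", "f"], size=n)
        x = np.where(g == "m", 1.0, 0.0) * 2 + rng.normal(size=n)
        h = np.where(rng.random(n) < np.where(g == "m", 0.8, 0.2), "hi", "lo")
        data = pd.DataFrame({"y": rng.normal(size=n), "g": g, "x": x, "h": h})
        edges = symmetric_associations(
            self._ordering(("g", "x", "h"), categorical={"g": "f", "h": "lo"}), data, 0.10
        )
        keys = {e.key for e in edges}
        assert ("g", "x") in keys  # anova
        assert ("g", "h") in keys  # chi-square

    def test_independent_variables_rarely_connected(self, rng):
        hits = 0
        reps = 100
        ordering = self._ordering(("a", "b"))
        for _ in range(reps):
            data = pd.DataFrame(
                {"y": rng.normal(size=1000), "a": rng.normal(size=1000), "b": rng.normal(size=1000)}
            )
            hits += bool(symmetric_associations(ordering, data, 0.10))
        assert hits / reps <= 0.20  # ~edge alpha


class TestGraphAssembly:
    def test_intercept_only_fits_give_empty_graph(self, rng):
        data = pd.DataFrame({c: rng.normal(size=200) for c in ("y", "x1", "x2", "x3")})
        ordering = make_ordering()
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        if selected.terms:  # fall back to a forced intercept-only fit
            selected = _fit_terms("y", [], data, ordering)
        graph = build_graph({"y": selected}, [], ordering)
        assert graph.directed_edges == []

    def test_single_retained_term_gives_single_edge(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        data = pd.DataFrame(
            {"y": 2 * x1 + rng.normal(size=n), "x1": x1, "x2": rng.normal(size=n), "x3": rng.normal(size=n)}
        )
        ordering = make_ordering()
        selected = select_model(fit_full_model("y", ordering, data), data, ordering)
        graph = build_graph({"y": selected}, [], ordering)
        assert len(graph.directed_edges) == 1
        edge = graph.directed_edges[0]
        assert edge.sources == ("x1",) and edge.target == "y"
        assert edge.coef == pytest.approx(2.0, abs=0.2)

    def test_edges_only_point_leftward(self):
        from glycograph.config import default_config, interaction_candidates_from_config, ordering_from_config
        from glycograph.pipeline import fit_synthetic
        from glycograph.synthetic import SyntheticConfig

        estimated, _, _, _ = fit_synthetic(SyntheticConfig(n=500, seed=77))
        ordering = ordering_from_config(default_config())
        for edge in estimated.directed_edges:
            for src in edge.sources:
                assert ordering.box_of(src) > ordering.box_of(edge.target)
        for edge in estimated.directed_edges:
            assert edge.p < estimated.edge_alpha

    def test_fit_outside_ordering_rejected(self, rng):
        data = pd.DataFrame({c: rng.normal(size=100) for c in ("y", "x1", "x2", "x3")})
        ordering = make_ordering()
        fit = fit_full_model("y", ordering, data)
        other = make_ordering(response="z", covars=("w",))
        with pytest.raises(ConfigurationError):
            build_graph({"y": fit}, [], other)


class TestVarianceExplained:
    def test_perfect_and_null_fits(self, rng):
        x = np.linspace(0, 1, 40)
        ordering = make_ordering(covars=("x1",))
        perfect = fit_full_model("y", ordering, pd.DataFrame({"y": 2 * x, "x1": x}))
        assert variance_explained(perfect) == pytest.approx(1.0)
        data = pd.DataFrame({"y": rng.normal(size=200), "x1": rng.normal(size=200)})
        intercept_only = _fit_terms("y", [], data, ordering)
        assert variance_explained(intercept_only) == pytest.approx(0.0, abs=1e-12)

    def test_equal_signal_and_noise_gives_half(self, rng):
        n = 50_000
        x = rng.normal(size=n)
        data = pd.DataFrame({"y": x + rng.normal(size=n), "x1": x})
        fit = fit_full_model("y", make_ordering(covars=("x1",)), data)
        assert variance_explained(fit) == pytest.approx(0.5, abs=0.02)

    def test_zero_variance_response_undefined(self):
        ordering = make_ordering(covars=("x1",))
        data = pd.DataFrame({"y": np.ones(30), "x1": np.linspace(0, 1, 30)})
        fit = _fit_terms("y", [Term.main("x1")], data, ordering)
        with pytest.raises(DomainError):
            variance_explained(fit)


class TestPrediction:
    def test_null_model_predicts_no_change(self, rng):
        data = pd.DataFrame({"y": rng.normal(scale=1e-12, size=60), "x1": rng.normal(size=60)})
        ordering = make_ordering(covars=("x1",))
        fit = _fit_terms("y", [], data, ordering)
        res = predict_outcome_ratio(fit, PredictionQuery("y", {}))
        assert res.ratio == pytest.approx(1.0, abs=1e-9)
        assert res.percent_change == pytest.approx(0.0, abs=1e-6)

    def test_intercept_log_ratio_translates_to_percent(self, rng):
        y = np.full(50, np.log(0.9)) + rng.normal(scale=1e-9, size=50)
        data = pd.DataFrame({"y": y, "x1": rng.normal(size=50)})
        ordering = make_ordering(covars=("x1",))
        fit = _fit_terms("y", [], data, ordering)
        res = predict_outcome_ratio(fit, PredictionQuery("y", {}))
        assert res.percent_change == pytest.approx(-10.0, abs=1e-4)

    def test_log_linearity_in_covariate_differences(self, rng):
        n = 200
        x1, x2 = rng.normal(size=(2, n))
        data = pd.DataFrame({"y": 0.3 * x1 - 0.2 * x2 + rng.normal(size=n), "x1": x1, "x2": x2})
        fit = fit_full_model("y", make_ordering(covars=("x1", "x2")), data)

        def lr(v1, v2):
            return predict_outcome_ratio(
                fit, PredictionQuery("y", {"x1": v1, "x2": v2})
            ).log_ratio

        # ratio(A)/ratio(B) depends only on A - B for a main-effects fit
        d1 = lr(1.0, 0.5) - lr(0.2, 0.1)
        d2 = lr(1.3, 0.9) - lr(0.5, 0.5)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_missing_covariate_rejected_and_extrapolation_warns(self, rng):
        n = 100
        x1 = rng.normal(size=n)
        data = pd.DataFrame({"y": x1 + rng.normal(size=n), "x1": x1})
        fit = fit_full_model("y", make_ordering(covars=("x1",)), data)
        with pytest.raises(ConfigurationError):
            predict_outcome_ratio(fit, PredictionQuery("y", {}))
        with pytest.warns(UserWarning):
            res = predict_outcome_ratio(fit, PredictionQuery("y", {"x1": 25.0}))
        assert res.extrapolated == ["x1"]


class TestDotExport:
    def test_empty_graph_is_valid_dot(self, rng):
        data = pd.DataFrame({c: rng.normal(size=100) for c in ("y", "x1", "x2", "x3")})
        ordering = make_ordering()
        fit = _fit_terms("y", [], data, ordering)
        dot = build_graph({"y": fit}, [], ordering).to_dot()
        assert dot.startswith("digraph") and '"y";' in dot
        directed, undirected = parse_dot(dot)
        assert directed == set() and undirected == set()

    def test_round_trip_recovers_edge_sets(self):
        from glycograph.pipeline import fit_synthetic
        from glycograph.synthetic import SyntheticConfig

        estimated, _, _, _ = fit_synthetic(SyntheticConfig(n=800, seed=3))
        dot = export_graph(estimated)
        directed, undirected = parse_dot(dot)
        expected = {(":".join(e.sources), e.target) for e in estimated.directed_edges}
        assert directed == expected
        assert undirected == {e.key for e in estimated.undirected_edges}

    def test_export_is_deterministic(self):
        from glycograph.pipeline import fit_synthetic
        from glycograph.synthetic import SyntheticConfig

        a, _, _, _ = fit_synthetic(SyntheticConfig(n=400, seed=9))
        b, _, _, _ = fit_synthetic(SyntheticConfig(n=400, seed=9))
        assert export_graph(a) == export_graph(b)
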