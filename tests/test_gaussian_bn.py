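import math

import numpy as np
import pandas as pd
import pytest

import traitnet as tn
from traitnet.gaussian_bn import _ScoreCache


def matrix(values: dict, tiers=None) -> tn.AnalysisMatrix:
    df = pd.DataFrame(values)
    tiers = tiers or {c: "trait" for c in df.columns}
    return tn.AnalysisMatrix(data=df, tiers=tiers)


class TestTransform:
    def test_identity(self):
        raw = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = tn.transform(raw, {"a": "trait", "b": "trait"})
        pd.testing.assert_frame_equal(out.data, raw)

    def test_log_of_powers_of_e(self):
        raw = pd.DataFrame({"SV": [1.0, math.e, math.e**2]})
        out = tn.transform(raw, {"SV": "trait"}, log_vars=["SV"], offsets={})
        assert np.allclose(out.data["SV"], [0.0, 1.0, 2.0])

    def test_zero_with_zero_offset_errors(self):
        raw = pd.DataFrame({"mort": [0.0, 0.01, 0.02]})
        with pytest.raises(ValueError, match="mort"):
            tn.transform(raw, {"mort": "demographic"}, log_vars=["mort"], offsets={})

    def test_half_min_positive_policy(self):
        raw = pd.DataFrame({"mort": [0.0, 0.01, 0.02]})
        out = tn.transform(
            raw, {"mort": "demographic"}, log_vars=["mort"],
            offsets="half_min_positive",
        )
        assert out.data["mort"].iloc[0] == pytest.approx(math.log(0.005))


class TestDag:
    def test_rejects_cycles_and_unknown_nodes(self):
        with pytest.raises(ValueError):
            tn.Dag.from_edges("AB", [("A", "B"), ("B", "A")])
        with pytest.raises(ValueError):
            tn.Dag.from_edges("AB", [("A", "C")])

    def test_json_round_trip(self):
        dag = tn.Dag.from_edges("ABC", [("A", "B"), ("B", "C")])
        assert tn.Dag.from_json(dag.to_json()) == dag

    def test_dot_export_lists_edges(self):
        dag = tn.Dag.from_edges("AB", [("A", "B")])
        assert '"A" -> "B";' in dag.to_dot()

    def test_enumerate_dags_counts(self):
        # 3 labelled nodes admit exactly 25 DAGs
        assert len(tn.enumerate_dags("ABC")) == 25
        assert len(tn.enumerate_dags("AB")) == 3


class TestTierConstraints:
    def test_banned_hierarchy(self, default_spec):
        cons = tn.TierConstraints(default_spec.tiers)
        assert cons.is_banned("lambda", "rec")   # performance -> anything
        assert cons.is_banned("lambda", "WD")
        assert cons.is_banned("rec", "WD")       # demographic -> trait
        assert cons.is_banned("WD", "lambda")    # trait -> performance
        assert not cons.is_banned("WD", "rec")   # trait -> demographic ok
        assert not cons.is_banned("rec", "mort")  # within-tier ok
        assert not cons.is_banned("rec", "lambda")

    def test_default_dag_respects_bans(self, default_spec):
        assert tn.TierConstraints(default_spec.tiers).allows(default_spec.dag)


class TestFitNode:
    def test_exact_linear_relation(self):
        x = np.linspace(-1, 1, 20)
        data = matrix({"p": x, "c": 2 * x})
        m = tn.fit_node(data, "c", ["p"])
        assert m.coefficients["p"] == pytest.approx(2.0)
        assert m.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert m.r2 == pytest.approx(1.0)

    def test_marginal_fit_uses_mle_variance(self):
        data = matrix({"x": [-1.5, -0.5, 0.5, 1.5]})
        m = tn.fit_node(data, "x", [])
        assert m.intercept == pytest.approx(0.0)
        assert m.sigma2 == pytest.approx(1.25)
        assert m.r2 == 0.0

    def test_consistency_on_simulated_data(self, rng):
        n = 2000
        p1, p2 = rng.normal(size=n), rng.normal(size=n)
        y = 0.5 * p1 - 0.3 * p2 + rng.normal(0, 0.1, size=n)
        data = matrix({"p1": p1, "p2": p2, "y": y})
        m = tn.fit_node(data, "y", ["p1", "p2"])
        assert m.coefficients["p1"] == pytest.approx(0.5, abs=0.02)
        assert m.coefficients["p2"] == pytest.approx(-0.3, abs=0.02)

    def test_collinear_parents_raise(self):
        x = np.linspace(0, 1, 10)
        data = matrix({"a": x, "b": 2 * x, "y": x**2})
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            tn.fit_node(data, "y", ["a", "b"])


class TestFamilyScore:
    def test_bic_marginal_value(self):
        data = matrix({"x": [-1.5, -0.5, 0.5, 1.5]})
        n, s2 = 4, 1.25
        expected = -0.5 * n * (math.log(2 * math.pi * s2) + 1) - math.log(n)
        assert tn.family_score(data, "x", []) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(-7.508, abs=1e-3)

    def test_row_order_invariance(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        data = matrix({"x": x, "y": y})
        perm = rng.permutation(50)
        shuffled = matrix({"x": x[perm], "y": y[perm]})
        for cfg in (tn.SearchConfig(), tn.SearchConfig(score_type="bayes_cg")):
            assert tn.family_score(data, "y", ["x"], cfg) == pytest.approx(
                tn.family_score(shuffled, "y", ["x"], cfg), rel=1e-12
            )

    def test_independent_parent_penalized_on_average(self, rng):
        # BIC gain from an unrelated parent should be negative in the bulk
        # of replicates: the ln(n)/2 penalty exceeds the expected 0.5 gain
        worse = 0
        for _ in range(40):
            data = matrix(
                {"x": rng.normal(size=200), "z": rng.normal(size=200)}
            )
            gain = tn.family_score(data, "x", ["z"]) - tn.family_score(
                data, "x", []
            )
            worse += gain < 0
        assert worse >= 35

    def test_degenerate_family_raises(self):
        data = matrix({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="degenerate"):
            tn.family_score(data, "x", [])


class TestNetworkScore:
    def test_empty_dag_is_sum_of_marginals(self, rng):
        data = matrix({c: rng.normal(size=30) for c in "abc"})
        dag = tn.Dag.from_edges("abc")
        total = sum(tn.family_score(data, v, []) for v in "abc")
        assert tn.network_score(data, dag) == pytest.approx(total, rel=1e-12)

    @pytest.mark.parametrize("score_type", ["bic", "bayes_cg"])
    def test_markov_equivalent_dags_score_equal(self, rng, score_type):
        cfg = tn.SearchConfig(score_type=score_type)
        x = rng.normal(size=100)
        y = 0.6 * x + rng.normal(size=100)
        data = matrix({"A": x, "B": y})
        ab = tn.Dag.from_edges("AB", [("A", "B")])
        ba = tn.Dag.from_edges("AB", [("B", "A")])
        assert tn.network_score(data, ab, cfg) == pytest.approx(
            tn.network_score(data, ba, cfg), abs=1e-9
        )

    @pytest.mark.parametrize("score_type", ["bic", "bayes_cg"])
    def test_chain_and_fork_score_equal(self, rng, score_type):
        cfg = tn.SearchConfig(score_type=score_type)
        b = rng.normal(size=200)
        data = matrix(
            {"A": 0.5 * b + rng.normal(size=200), "B": b,
             "C": -0.5 * b + rng.normal(size=200)}
        )
        chain = tn.Dag.from_edges("ABC", [("A", "B"), ("B", "C")])
        fork = tn.Dag.from_edges("ABC", [("B", "A"), ("B", "C")])
        assert tn.network_score(data, chain, cfg) == pytest.approx(
            tn.network_score(data, fork, cfg), abs=1e-9
        )


class TestLearnStructure:
    def test_independent_variables_give_empty_dag(self, rng):
        data = matrix({c: rng.normal(size=1000) for c in "abc"})
        fit = tn.learn_structure(data, config=tn.SearchConfig(restarts=3, seed=0))
        assert fit.dag.edges == frozenset()

    def test_strong_edge_recovered_under_constraints(self, rng):
        trait = rng.normal(size=1000)
        rate = 0.9 * trait + rng.normal(0, 0.3, size=1000)
        data = matrix(
            {"WD": trait, "rec": rate},
            tiers={"WD": "trait", "rec": "demographic"},
        )
        cons = tn.TierConstraints(data.tiers)
        fit = tn.learn_structure(data, cons, tn.SearchConfig(restarts=3, seed=1))
        assert fit.dag.edges == frozenset({("WD", "rec")})

    def test_learned_dag_respects_bans(self, default_spec):
        data = tn.simulate_sem(default_spec, n=300, seed=7)
        cons = tn.TierConstraints(default_spec.tiers)
        fit = tn.learn_structure(data, cons, tn.SearchConfig(restarts=5, seed=7))
        assert cons.allows(fit.dag)
        lam_parents = set(fit.dag.parents("lambda"))
        assert lam_parents <= {"rec", "mort"}

    def test_attains_exhaustive_optimum_on_three_nodes(self, trivariate_chain):
        _, data = trivariate_chain
        fit = tn.learn_structure(data, config=tn.SearchConfig(restarts=5, seed=2))
        _, best_score = tn.exhaustive_search(data)
        assert fit.score == pytest.approx(best_score, abs=1e-9)

    def test_deterministic_given_seed(self, default_spec):
        data = tn.simulate_sem(default_spec, n=200, seed=8)
        cons = tn.TierConstraints(default_spec.tiers)
        cfg = tn.SearchConfig(restarts=5, seed=11)
        fit1 = tn.learn_structure(data, cons, cfg)
        fit2 = tn.learn_structure(data, cons, cfg)
        assert fit1.dag == fit2.dag
        assert fit1.score == fit2.score

    def test_hill_climb_trace_non_decreasing_within_climbs(self, default_data,
                                                           default_spec):
        cons = tn.TierConstraints(default_spec.tiers)
        fit = tn.learn_structure(
            default_data, cons, tn.SearchConfig(restarts=1, seed=3)
        )
        trace = np.asarray(fit.score_trace)
        assert np.all(np.diff(trace) > 0)


class TestDecomposability:
    def test_local_rescoring_equals_full_rescoring(self, default_data):
        cfg = tn.SearchConfig()
        cache = _ScoreCache(default_data, cfg)
        dag = tn.Dag.from_edges(
            default_data.variables, [("WD", "LPC"), ("LNC", "LPC"), ("rec", "lambda")]
        )
        full_before = tn.network_score(default_data, dag, cfg)
        from traitnet.gaussian_bn import _apply_move, _move_delta

        for move in [("add", "LPC", "rec"), ("delete", "WD", "LPC"),
                     ("reverse", "LNC", "LPC")]:
            delta = _move_delta(cache, dag, move)
            moved = _apply_move(dag, move)
            full_after = tn.network_score(default_data, moved, cfg)
            assert full_before + delta == pytest.approx(full_after, abs=1e-9)
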