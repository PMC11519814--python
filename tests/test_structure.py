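"""BIC scoring and constrained hill-climbing."""

import math

import numpy as np
import pandas as pd
import pytest

from cmbnet import (
    DAG,
    ArcConstraintSet,
    VariableSchema,
    family_score,
    hill_climb,
    total_score,
)
from cmbnet.schema import InvalidInputError, Variable
from cmbnet.structure import ScoreCache

BIN = ("no", "yes")


def _schema(*names: str) -> VariableSchema:
    return VariableSchema(tuple(Variable(n, BIN, 1) for n in names))


def _df(**cols) -> pd.DataFrame:
    return pd.DataFrame({k: [BIN[x] for x in v] for k, v in cols.items()})


class TestFamilyScore:
    def test_binary_root_counts_6_4(self):
        # 6*ln(0.6) + 4*ln(0.4) - 0.5*ln(10)
        data = _df(X=[1] * 6 + [0] * 4)
        score = family_score("X", (), data, _schema("X"))
        assert score == pytest.approx(-7.8814092156, abs=1e-9)

    def test_deterministic_child_penalty_only(self):
        # Y == X on 8 balanced records: likelihood term 0, penalty ln(8)
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        data = _df(X=x, Y=x)
        score = family_score("Y", ("X",), data, _schema("X", "Y"))
        assert score == pytest.approx(-0.5 * math.log(8) * 2, abs=1e-12)

    def test_uniform_binary_closed_form(self):
        data = _df(X=[0, 1] * 4)
        score = family_score("X", (), data, _schema("X"))
        assert score == pytest.approx(8 * math.log(0.5) - 0.5 * math.log(8),
                                      abs=1e-12)

    def test_matches_naive_recount_oracle(self):
        """Direct pandas group-by recount of the BIC closed form."""
        rng = np.random.default_rng(11)
        schema = _schema("A", "B", "C")
        for _ in range(10):
            data = _df(
                A=rng.integers(0, 2, 60), B=rng.integers(0, 2, 60),
                C=rng.integers(0, 2, 60),
            )
            for node, parents in [("A", ()), ("B", ("A",)), ("C", ("A", "B"))]:
                n = len(data)
                ll = 0.0
                if parents:
                    grouped = data.groupby(list(parents), observed=False)[node]
                else:
                    grouped = data.groupby(lambda _: 0)[node]
                for _, grp in grouped:
                    nij = len(grp)
                    for nijk in grp.value_counts():
                        if nijk:
                            ll += nijk * math.log(nijk / nij)
                q = 2 ** len(parents)
                expected = ll - 0.5 * math.log(n) * q * 1
                assert family_score(node, parents, data, schema) == \
                    pytest.approx(expected, abs=1e-9)

    def test_empty_dataset_rejected(self):
        with pytest.raises(InvalidInputError):
            family_score("X", (), pd.DataFrame({"X": []}), _schema("X"))


class TestTotalScore:
    def test_empty_graph_is_sum_of_marginal_families(self):
        rng = np.random.default_rng(5)
        schema = _schema("X", "Y")
        data = _df(X=rng.integers(0, 2, 50), Y=rng.integers(0, 2, 50))
        dag = DAG(schema.names)
        expected = family_score("X", (), data, schema) + \
            family_score("Y", (), data, schema)
        assert total_score(dag, data, schema) == pytest.approx(expected)

    def test_adding_arc_changes_only_target_family(self):
        rng = np.random.default_rng(6)
        schema = _schema("X", "Y")
        data = _df(X=rng.integers(0, 2, 50), Y=rng.integers(0, 2, 50))
        empty, with_arc = DAG(schema.names), DAG(schema.names, {("X", "Y")})
        delta = total_score(with_arc, data, schema) - \
            total_score(empty, data, schema)
        family_delta = family_score("Y", ("X",), data, schema) - \
            family_score("Y", (), data, schema)
        assert delta == pytest.approx(family_delta)

    def test_independent_coins_prefer_empty_graph(self):
        rng = np.random.default_rng(1)
        schema = _schema("X", "Y")
        data = _df(X=rng.integers(0, 2, 1000), Y=rng.integers(0, 2, 1000))
        assert total_score(DAG(schema.names), data, schema) > \
            total_score(DAG(schema.names, {("X", "Y")}), data, schema)

    def test_node_mismatch_rejected(self):
        data = _df(X=[0, 1])
        with pytest.raises(InvalidInputError):
            total_score(DAG(("X", "Z")), data, _schema("X"))


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self, no_constraints):
        rng = np.random.default_rng(2)
        schema = _schema("A", "B", "C")
        data = _df(**{n: rng.integers(0, 2, 500) for n in schema.names})
        dag, trace = hill_climb(data, no_constraints, schema)
        assert dag.arcs == set()
        assert trace.moves == []

    def test_whitelisted_arc_retained_despite_independence(self):
        rng = np.random.default_rng(2)
        schema = _schema("A", "B")
        data = _df(A=rng.integers(0, 2, 500), B=rng.integers(0, 2, 500))
        constraints = ArcConstraintSet(frozenset(), frozenset({("A", "B")}))
        dag, _ = hill_climb(data, constraints, schema)
        assert ("A", "B") in dag.arcs

    def test_perfect_copy_yields_single_arc(self, no_constraints):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 100)
        schema = _schema("X", "Y")
        data = _df(X=x, Y=x)
        dag, _ = hill_climb(data, no_constraints, schema)
        assert dag.arcs in ({("X", "Y")}, {("Y", "X")})
        assert len(dag.arcs) == 1

    def test_trace_strictly_increasing_and_replayable(self, no_constraints):
        rng = np.random.default_rng(9)
        schema = _schema("A", "B", "C", "D")
        a = rng.integers(0, 2, 800)
        b = (a ^ (rng.random(800) < 0.1)).astype(int)
        c = (b ^ (rng.random(800) < 0.1)).astype(int)
        data = _df(A=a, B=b, C=c, D=rng.integers(0, 2, 800))
        dag, trace = hill_climb(data, no_constraints, schema)
        assert all(m.delta > 0 for m in trace.moves)
        assert trace.replay(schema.names).arcs == dag.arcs

    def test_output_is_single_move_local_optimum(self, no_constraints):
        """No legal add/delete/reverse strictly improves the final score."""
        rng = np.random.default_rng(10)
        schema = _schema("A", "B", "C")
        a = rng.integers(0, 2, 600)
        b = (a ^ (rng.random(600) < 0.2)).astype(int)
        data = _df(A=a, B=b, C=rng.integers(0, 2, 600))
        dag, _ = hill_climb(data, no_constraints, schema)
        base = total_score(dag, data, schema)
        for u in schema.names:
            for v in schema.names:
                if u == v:
                    continue
                if not dag.has_arc(u, v) and not dag.has_arc(v, u) and \
                        not dag.would_create_cycle(u, v):
                    trial = dag.copy(); trial.add_arc(u, v)
                    assert total_score(trial, data, schema) <= base + 1e-9
        for u, v in list(dag.arcs):
            trial = dag.copy(); trial.remove_arc(u, v)
            assert total_score(trial, data, schema) <= base + 1e-9
            if not dag.reversal_creates_cycle(u, v):
                trial = dag.copy(); trial.remove_arc(u, v); trial.add_arc(v, u)
                assert total_score(trial, data, schema) <= base + 1e-9

    def test_deterministic_given_data(self, no_constraints):
        rng = np.random.default_rng(12)
        schema = _schema("A", "B", "C")
        a = rng.integers(0, 2, 400)
        data = _df(A=a, B=(a ^ (rng.random(400) < 0.3)).astype(int),
                   C=rng.integers(0, 2, 400))
        dag1, t1 = hill_climb(data, no_constraints, schema)
        dag2, t2 = hill_climb(data, no_constraints, schema)
        assert dag1.arcs == dag2.arcs
        assert [m.arc for m in t1.moves] == [m.arc for m in t2.moves]


class TestScoreCache:
    def test_cached_values_equal_recomputation(self):
        rng = np.random.default_rng(8)
        schema = _schema("A", "B")
        data = _df(A=rng.integers(0, 2, 100), B=rng.integers(0, 2, 100))
        cache = ScoreCache(data, schema)
        first = cache.family("B", ("A",))
        assert cache.family("B", ("A",)) == first
        assert first == pytest.approx(family_score("B", ("A",), data, schema))

    def test_bdeu_option_runs_and_differs_from_bic(self):
        rng = np.random.default_rng(8)
        schema = _schema("A", "B")
        data = _df(A=rng.integers(0, 2, 100), B=rng.integers(0, 2, 100))
        bic = ScoreCache(data, schema, score="bic").family("A", ())
        bdeu = ScoreCache(data, schema, score="bdeu").family("A", ())
        assert bic != bdeu
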