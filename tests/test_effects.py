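"""Walk-based effect indices: worked-example values, invariants, oracles."""

from fractions import Fraction

import numpy as np
import pytest

from medianet import (
    InteractionNetwork,
    brute_force_effect,
    effect_matrix,
    mediator_contribution,
    mediator_table,
    mutual_dependence,
    one_step_effect,
    pathway_effect,
    set_effect,
    topological_importance,
)


class TestOneStepEffect:
    @pytest.mark.parametrize(
        "source,receiver,expected",
        [
            ("red", "green", Fraction(1, 2)),
            ("green", "black", Fraction(1, 7)),
            ("green", "red", Fraction(1, 3)),
            ("red", "yellow", Fraction(1, 5)),
        ],
    )
    def test_toy_values(self, toy_net, source, receiver, expected):
        assert one_step_effect(toy_net, source, receiver) == pytest.approx(
            float(expected), abs=1e-12
        )

    def test_non_adjacent_is_zero(self, toy_net):
        assert one_step_effect(toy_net, "red", "black") == 0.0

    def test_unknown_node_errors(self, toy_net):
        with pytest.raises(KeyError):
            one_step_effect(toy_net, "red", "nope")


class TestPathwayEffect:
    @pytest.mark.parametrize(
        "mediator,expected",
        [("green", Fraction(1, 14)), ("yellow", Fraction(1, 35))],
    )
    def test_toy_red_to_black_pathways(self, toy_net, mediator, expected):
        assert pathway_effect(toy_net, "red", mediator, "black") == pytest.approx(
            float(expected), abs=1e-12
        )

    def test_half_adjacent_mediator_is_zero(self, toy_net):
        # blue1 touches red only, so it mediates nothing toward black
        assert pathway_effect(toy_net, "red", "blue1", "black") == 0.0

    def test_distinctness_enforced(self, toy_net):
        with pytest.raises(ValueError):
            pathway_effect(toy_net, "red", "red", "black")


class TestEffectMatrix:
    def test_toy_two_step_directed_values(self, toy_net):
        m = effect_matrix(toy_net, 2)
        assert m.loc("black", "red") == pytest.approx(1 / 10, abs=1e-12)
        assert m.loc("red", "black") == pytest.approx(7 / 30, abs=1e-12)

    def test_one_step_matrix_definition(self, toy_net):
        m = effect_matrix(toy_net, 1)
        for i in toy_net.nodes:
            for j in toy_net.nodes:
                expected = (
                    1 / toy_net.degree(i) if toy_net.has_edge(i, j) else 0.0
                )
                assert m.loc(i, j) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_row_conservation(self, toy_net, random_cases, n):
        nets = [toy_net] + [net for net, _ in random_cases]
        for net in nets:
            m = effect_matrix(net, n)
            sums = m.values.sum(axis=1)
            for idx, node in enumerate(m.nodes):
                if net.degree(node) >= 1:
                    assert sums[idx] == pytest.approx(1.0, abs=1e-12)
                else:
                    assert sums[idx] == 0.0

    def test_values_in_unit_interval(self, toy_net, random_cases):
        for net in [toy_net] + [net for net, _ in random_cases]:
            for n in (1, 2, 3):
                v = effect_matrix(net, n).values
                assert (v >= 0).all() and (v <= 1 + 1e-12).all()

    def test_matches_walk_enumeration(self, random_cases):
        for net, _ in random_cases[:6]:
            for n in (1, 2, 3):
                m = effect_matrix(net, n)
                for i in net.nodes:
                    for j in net.nodes:
                        assert m.loc(i, j) == pytest.approx(
                            brute_force_effect(net, j, i, n), abs=1e-12
                        )

    def test_invalid_step_count(self, toy_net):
        with pytest.raises(ValueError):
            effect_matrix(toy_net, 0)

    def test_tsv_round_trip(self, tmp_path, toy_net):
        import pandas as pd

        m = effect_matrix(toy_net, 2)
        out = tmp_path / "m.tsv"
        m.write_tsv(out)
        back = pd.read_csv(out, sep="\t", index_col=0)
        assert back.loc["black", "red"] == pytest.approx(1 / 10)


class TestMutualDependence:
    def test_toy_red_black(self, toy_net):
        assert mutual_dependence(toy_net, "red", "black", 2) == pytest.approx(
            1 / 3, abs=1e-12
        )

    def test_symmetric_in_vertex_transitive_graph(self):
        ring = InteractionNetwork.from_edges(
            [(f"n{k}", f"n{(k + 1) % 5}") for k in range(5)]
        )
        m = effect_matrix(ring, 2)
        assert mutual_dependence(ring, "n0", "n2", 2) == pytest.approx(
            2 * m.loc("n0", "n2")
        )

    def test_disconnected_pair_is_zero(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("X", "Y")])
        assert mutual_dependence(net, "A", "X", 2) == 0.0

    def test_same_node_rejected(self, toy_net):
        with pytest.raises(ValueError):
            mutual_dependence(toy_net, "red", "red", 2)


class TestTopologicalImportance:
    def test_toy_green_one_step(self, toy_net):
        # green's receivers are red (D=3) and black (D=7)
        assert topological_importance(toy_net, "green", 1) == pytest.approx(
            1 / 3 + 1 / 7, abs=1e-12
        )

    def test_isolated_node_zero(self):
        net = InteractionNetwork.from_edges([("A", "B")], nodes=["A", "B", "Z"])
        for n in (1, 2, 3):
            assert topological_importance(net, "Z", n) == 0.0

    def test_matches_walk_oracle(self, random_cases):
        for net, _ in random_cases[:4]:
            for j in net.nodes:
                for n in (1, 2):
                    expected = sum(
                        brute_force_effect(net, j, i, n)
                        for i in net.nodes
                        if i != j
                    )
                    assert topological_importance(net, j, n) == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_cumulative_mean_mode(self, toy_net):
        ti1 = topological_importance(toy_net, "green", 1)
        ti2 = topological_importance(toy_net, "green", 2)
        cum = topological_importance(toy_net, "green", 2, mode="cumulative_mean")
        assert cum == pytest.approx((ti1 + ti2) / 2, abs=1e-12)

    def test_edge_to_isolated_node_raises_ti(self):
        before = InteractionNetwork.from_edges([("A", "B")], nodes=["A", "B", "Z"])
        after = InteractionNetwork.from_edges([("A", "B"), ("Z", "A")])
        assert topological_importance(after, "Z", 1) > topological_importance(
            before, "Z", 1
        )

    def test_unknown_mode_rejected(self, toy_net):
        with pytest.raises(ValueError):
            topological_importance(toy_net, "green", 2, mode="bogus")


class TestSetEffect:
    def test_toy_red_to_black(self, toy_net):
        pe = set_effect(toy_net, sources={"red"}, receivers={"black"}, n=2)
        assert pe.value == pytest.approx(1 / 10, abs=1e-12)

    def test_symmetric_option_adds_reverse(self, toy_net):
        pe = set_effect(
            toy_net, sources={"red"}, receivers={"black"}, n=2, symmetric=True
        )
        assert pe.value == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_without_linking_walks(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("X", "Y")])
        pe = set_effect(net, sources={"A"}, receivers={"X"}, n=2)
        assert pe.value == 0.0

    def test_self_pairs_excluded(self, toy_net):
        pe = set_effect(toy_net, sources={"red"}, receivers={"red", "black"}, n=2)
        assert pe.contributions.loc["red", "red"] == 0.0
        assert pe.value == pytest.approx(1 / 10, abs=1e-12)

    def test_empty_set_rejected(self, toy_net):
        with pytest.raises(ValueError):
            set_effect(toy_net, sources=set(), receivers={"black"})


class TestMediatorContribution:
    @pytest.mark.parametrize(
        "k,expected",
        [("yellow", Fraction(2, 21)), ("green", Fraction(5, 21))],
    )
    def test_toy_mediators(self, toy_net, k, expected):
        assert mediator_contribution(toy_net, k, "red", "black") == pytest.approx(
            float(expected), abs=1e-12
        )

    def test_non_common_neighbor_is_zero(self, toy_net):
        assert mediator_contribution(toy_net, "blue1", "red", "black") == 0.0

    def test_distinctness_enforced(self, toy_net):
        with pytest.raises(ValueError):
            mediator_contribution(toy_net, "red", "red", "black")


class TestMediatorTable:
    def test_toy_table(self, toy_net):
        table = mediator_table(toy_net, {"red"}, {"black"})
        assert set(table.mediators()) == {"green", "yellow"}
        assert table.totals["green"] == pytest.approx(5 / 21, abs=1e-12)
        assert table.totals["yellow"] == pytest.approx(2 / 21, abs=1e-12)

    def test_mediators_adjacent_to_both(self, random_cases):
        for net, ann in random_cases:
            xs, ys = ann.proteins_with("X"), ann.proteins_with("Y")
            table = mediator_table(net, xs, ys)
            for _, row in table.records.iterrows():
                assert net.has_edge(row["k"], row["i"])
                assert net.has_edge(row["k"], row["j"])

    def test_decomposition_identity(self, toy_net, random_cases):
        nets = [(toy_net, {"red"}, {"black"})] + [
            (net, ann.proteins_with("X"), ann.proteins_with("Y"))
            for net, ann in random_cases
        ]
        for net, s1, s2 in nets:
            table = mediator_table(net, s1, s2)
            m2 = effect_matrix(net, 2)
            for _, row in table.pair_effects.iterrows():
                i, j = row["i"], row["j"]
                med_sum = table.records.query("i == @i and j == @j")["m2"].sum()
                assert med_sum == pytest.approx(
                    m2.loc(i, j) + m2.loc(j, i), abs=1e-12
                )
                assert row["a2_ij"] == pytest.approx(m2.loc(i, j), abs=1e-12)
                assert row["a2_ji"] == pytest.approx(m2.loc(j, i), abs=1e-12)

    def test_distant_sets_give_empty_table(self):
        # distance >= 3 between endpoints: no common neighbor, no 2-walk
        chain = InteractionNetwork.from_edges(
            [("A", "m1"), ("m1", "m2"), ("m2", "B")]
        )
        table = mediator_table(chain, {"A"}, {"B"})
        assert table.records.empty
        assert len(table.totals) == 0

    def test_overlapping_sets_skip_self_pairs(self, toy_net):
        table = mediator_table(toy_net, {"red", "green"}, {"green", "black"})
        assert not (
            (table.pair_effects["i"] == table.pair_effects["j"]).any()
        )

    def test_writes_all_four_tsvs(self, tmp_path, toy_net):
        table = mediator_table(toy_net, {"red"}, {"black"})
        table.write(tmp_path)
        for stem in (
            "mediators_ids",
            "mediators_strength",
            "mediators_long",
            "mediators_ranking",
        ):
            assert (tmp_path / f"{stem}.tsv").exists()
        ids = (tmp_path / "mediators_ids.tsv").read_text()
        assert "green,yellow" in ids


def test_dense_and_sparse_paths_agree(monkeypatch, toy_net):
    """Forcing the sparse code path must reproduce the dense matrix power."""
    import medianet.effects as eff

    dense = effect_matrix(toy_net, 3).values
    monkeypatch.setattr(eff, "_DENSE_LIMIT", 2)
    sparse = effect_matrix(toy_net, 3).values
    np.testing.assert_allclose(dense, sparse, atol=1e-12)
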