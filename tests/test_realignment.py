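"""Switch features, logistic model, weighted toposort, final assignment."""

import math

import numpy as np
import pytest

from omixalign import (
    DEFAULT_BETAS,
    DataNode,
    FeatureVector,
    PairEdge,
    SwitchModel,
    assign_final_ids,
    compute_features,
    edge_weight,
    extract_training_pairs,
    fit_switch_model,
    predict_switch,
    realign_groups,
    topo_scores,
)
from omixalign.pair_graph import Group
from omixalign.realignment import read_model, write_model
from .conftest import make_group

PRIO = {f"omics{i}": 0.5 for i in range(1, 7)}


def first_mismatched(group):
    return next(e for e in group.edges if e.status == "mismatched")


class TestComputeFeatures:
    def test_relationship_support_worked_example(self):
        """Two extra nodes carry b's ID, none a's, N=5 -> x1 = 2/3."""
        g = make_group(["a", "b", "b", "b"])
        edge = next(
            e for e in g.edges
            if {e.a.data_id, e.b.data_id} == {"a", "b"}
        )
        if edge.a.data_id != "a":
            edge.a, edge.b = edge.b, edge.a
        fv = compute_features(edge, g, n_omics=5, priorities=PRIO)
        assert fv.x1 == pytest.approx(2 / 3)

    def test_sex_symmetry_gives_zero_x2(self):
        g = make_group(
            ["a", "b", "b"],
            sexes=[("male", "male"), ("male", "male"), ("male", "male")],
        )
        fv = compute_features(first_mismatched(g), g, 3, PRIO)
        assert fv.x2 == 0.0

    def test_unknown_sex_gets_neutral_quarter(self):
        g = make_group(
            ["a", "b", "b"],
            sexes=[("unknown", "male"), ("female", "female"), ("male", "male")],
        )
        edge = first_mismatched(g)
        a, b = (edge.a, edge.b) if edge.a.data_id == "a" else (edge.b, edge.a)
        fv = compute_features(edge, g, 3, PRIO)
        # S for the unknown-reported side is 0.25 + 0.25
        s_a = 0.5
        s_b = (0.5 if b.reported_sex == b.snp_sex else 0.0) + (
            0.5 if b.reported_sex == a.snp_sex else 0.0
        )
        expected = s_b - s_a if edge.a is a else s_a - s_b
        assert fv.x2 == pytest.approx(expected)

    def test_priority_difference(self):
        g = make_group(["a", "b", "b"])
        prio = {"omics1": 1.0, "omics2": 0.25, "omics3": 0.25}
        edge = first_mismatched(g)
        fv = compute_features(edge, g, 3, prio)
        expected = prio[edge.b.omics_type] - prio[edge.a.omics_type]
        assert fv.x3 == pytest.approx(expected)

    def test_antisymmetry_under_swap(self, rng):
        """Swapping (a, b) negates every feature, on 1000 random pairs."""
        sexes = ["male", "female", "unknown"]
        for _ in range(1000):
            n = int(rng.integers(3, 7))
            ids = [f"s{rng.integers(0, 4)}" for _ in range(n)]
            groups_sexes = [
                (sexes[rng.integers(0, 3)], sexes[rng.integers(0, 3)])
                for _ in range(n)
            ]
            prio = {f"omics{i + 1}": float(rng.random()) for i in range(n)}
            g = make_group(ids, sexes=groups_sexes)
            mis = [e for e in g.edges if e.status == "mismatched"]
            if not mis:
                continue
            e = mis[int(rng.integers(0, len(mis)))]
            fv = compute_features(e, g, n, prio)
            swapped = PairEdge(e.b, e.a, score=e.score)
            fw = compute_features(swapped, g, n, prio)
            assert fw.x1 == pytest.approx(-fv.x1)
            assert fw.x2 == pytest.approx(-fv.x2)
            assert fw.x3 == pytest.approx(-fv.x3)

    def test_requires_three_omics(self):
        g = make_group(["a", "b", "b"])
        with pytest.raises(ValueError, match="3 omics"):
            compute_features(first_mismatched(g), g, 2, PRIO)

    def test_missing_priority_rejected(self):
        g = make_group(["a", "b", "b"])
        with pytest.raises(ValueError, match="priority"):
            compute_features(first_mismatched(g), g, 3, {"omics1": 1.0})


class TestTrainingExtraction:
    def test_single_deviant_with_sex_support(self):
        """Group {a,a,a,b}: b's genetic sex matches a's reported sex, so all
        edges incident to the deviant become training pairs toward a."""
        g = make_group(
            ["a", "a", "a", "b"],
            sexes=[("male", "male")] * 3 + [("female", "male")],
        )
        training = extract_training_pairs([g], 4, PRIO)
        assert len(training) == 3  # deviant touches 3 mismatched edges
        for fv, label in training:
            edge = fv.pair
            toward = edge.b if label == 1 else edge.a
            assert toward.data_id == "a"

    def test_two_deviants_yield_nothing(self):
        g = make_group(["a", "a", "b", "b"])
        assert extract_training_pairs([g], 4, PRIO) == []

    def test_sex_contradiction_blocks_training(self):
        g = make_group(
            ["a", "a", "a", "b"],
            sexes=[("male", "male")] * 3 + [("female", "female")],
        )
        assert extract_training_pairs([g], 4, PRIO) == []

    def test_discarded_groups_skipped(self):
        g = make_group(
            ["a", "a", "a", "b"],
            sexes=[("male", "male")] * 3 + [("female", "male")],
        )
        g.discarded = True
        assert extract_training_pairs([g], 4, PRIO) == []


class TestFit:
    def _training(self, n=24, seed=5):
        rng = np.random.default_rng(seed)
        training = []
        for _ in range(n):
            x1 = rng.uniform(0.2, 1.0)
            fv = FeatureVector(x1, rng.normal(0, 0.1), rng.normal(0, 0.1))
            training.append((fv, 1))
        return training

    def test_symmetrized_fit_has_zero_intercept(self):
        model = fit_switch_model(self._training())
        assert abs(model.beta0) < 1e-6
        assert model.source == "fitted"
        assert model.n_training_pairs == 24

    def test_x1_dominates_when_it_predicts_labels(self):
        model = fit_switch_model(self._training())
        assert model.beta1 > 0
        assert math.isfinite(model.beta1)

    def test_fallback_below_min_training(self):
        model = fit_switch_model(self._training(n=5), min_training=10)
        assert model.source == "default"
        assert model.betas == DEFAULT_BETAS
        assert model.n_training_pairs == 0

    def test_degenerate_design_rejected(self):
        training = [(FeatureVector(0, 0, 0), 1)] * 12
        with pytest.raises(ValueError, match="degenerate"):
            fit_switch_model(training)

    def test_model_file_roundtrip(self, tmp_path):
        model = fit_switch_model(self._training())
        write_model(model, tmp_path / "m.txt")
        back = read_model(tmp_path / "m.txt")
        assert back.betas == pytest.approx(model.betas)
        assert back.source == "fitted"


class TestPredict:
    def test_neutral_features_are_uncertain(self):
        model = SwitchModel(0, 1, 1, 1)
        direction, p = predict_switch(model, FeatureVector(0, 0, 0))
        assert direction == "uncertain" and p == pytest.approx(0.5)

    def test_closed_form_probability(self):
        model = SwitchModel(0, 1, 1, 1)
        direction, p = predict_switch(model, FeatureVector(1, 1, 1))
        assert direction == "a_to_b"
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-3.0)))

    def test_probability_complementarity(self, rng):
        """With beta0 = 0, swapping the pair gives p' = 1 - p exactly."""
        model = SwitchModel(0, 2.3, -1.1, 0.7)
        for _ in range(200):
            fv = FeatureVector(*rng.uniform(-1, 1, size=3))
            neg = FeatureVector(-fv.x1, -fv.x2, -fv.x3)
            d1, p1 = predict_switch(model, fv)
            d2, p2 = predict_switch(model, neg)
            assert p1 + p2 == pytest.approx(1.0, abs=1e-12)
            if d1 != "uncertain":
                assert {d1, d2} == {"a_to_b", "b_to_a"}

    @pytest.mark.parametrize("p, w", [(0.5, 0.0), (1.0, 1.0), (0.75, 0.5)])
    def test_edge_weight_rescaling(self, p, w):
        assert edge_weight(p) == pytest.approx(w)

    def test_edge_weight_range_check(self):
        with pytest.raises(ValueError):
            edge_weight(1.5)


class TestToposort:
    def _directed_group(self):
        a, b, c = DataNode("a", "omics1"), DataNode("b", "omics2"), DataNode("c", "omics3")
        e1 = PairEdge(a, b, status="mismatched", direction="a_to_b", weight=0.8)
        e2 = PairEdge(c, b, status="mismatched", direction="a_to_b", weight=0.6)
        return Group(1, [a, b, c], [e1, e2]), (a, b, c)

    def test_hand_summation(self):
        g, (a, b, c) = self._directed_group()
        scores = topo_scores(g)
        assert scores[id(b)] == pytest.approx(1.4)
        assert scores[id(a)] == pytest.approx(-0.8)
        assert scores[id(c)] == pytest.approx(-0.6)

    def test_matched_only_group_scores_zero(self):
        g = make_group(["a", "a", "a"])
        assert all(v == 0.0 for v in topo_scores(g).values())

    def test_score_conservation(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 8))
            g = make_group([f"s{rng.integers(0, 3)}" for _ in range(n)])
            for e in g.edges:
                if e.status == "mismatched":
                    e.direction = "a_to_b" if rng.random() < 0.5 else "b_to_a"
                    e.weight = float(rng.random())
            assert sum(topo_scores(g).values()) == pytest.approx(0.0, abs=1e-12)


class TestAssign:
    def test_top_score_wins(self):
        a, b, c = DataNode("s1", "omics1"), DataNode("s7", "omics2"), DataNode("s3", "omics3")
        e1 = PairEdge(a, b, status="mismatched", direction="a_to_b", weight=0.8)
        e2 = PairEdge(c, b, status="mismatched", direction="a_to_b", weight=0.6)
        g = Group(1, [a, b, c], [e1, e2])
        asg = assign_final_ids(g)
        assert asg.final_id == "s7"
        assert asg.verdict_of(b) == "unchanged"
        assert asg.verdict_of(a) == "corrected"
        assert asg.verdict_of(c) == "corrected"

    def test_matched_only_group_unchanged(self):
        g = make_group(["a", "a", "a"])
        asg = assign_final_ids(g)
        assert asg.final_id == "a"
        assert all(asg.verdict_of(n) == "unchanged" for n in g.nodes)

    def test_tie_broken_by_carrier_count(self):
        g = make_group(["a", "a", "b"])  # all scores 0 (no directed edges)
        asg = assign_final_ids(g)
        assert asg.final_id == "a"

    def test_tie_broken_by_priority_then_lexicographic(self):
        g = make_group(["b", "a"], priorities=[0.9, 0.2], complete=True)
        asg = assign_final_ids(g)
        assert asg.final_id == "b"  # higher-priority node wins the tie
        g2 = make_group(["b", "a"], priorities=[0.5, 0.5])
        assert assign_final_ids(g2).final_id == "a"  # lexicographic fallback

    def test_discarded_group_unresolved(self):
        g = make_group(["a", "b"])
        g.discarded = True
        asg = assign_final_ids(g)
        assert asg.final_id is None
        assert all(asg.verdict_of(n) == "unresolved" for n in g.nodes)

    def test_scores_sum_to_zero_in_assignment(self):
        g, _ = TestToposort()._directed_group()
        asg = assign_final_ids(g)
        assert sum(asg.node_scores.values()) == pytest.approx(0.0, abs=1e-12)


class TestRealignPipeline:
    def test_orientation_invariance_of_assignment(self, rng):
        """Flipping the stored orientation of edges never changes the
        assigned final ID (probability complementarity with beta0 = 0)."""
        model = SwitchModel(0, 4, 2, 1)
        for trial in range(20):
            n = int(rng.integers(3, 7))
            ids = [f"s{rng.integers(0, 3)}" for _ in range(n)]
            g1 = make_group(ids)
            g2 = make_group(ids)
            for e in g2.edges:
                if rng.random() < 0.5:
                    e.a, e.b = e.b, e.a
            a1, _ = realign_groups([g1], n, PRIO, model=model)
            a2, _ = realign_groups([g2], n, PRIO, model=model)
            assert a1[0].final_id == a2[0].final_id

    def test_majority_recovery_with_default_model(self):
        g = make_group(["a", "a", "a", "b", "c"])
        assignments, model = realign_groups([g], 5, PRIO)
        assert model.source == "default"  # too few training pairs to fit
        assert assignments[0].final_id == "a"
        corrected = [
            n.data_id for n in g.nodes
            if assignments[0].verdict_of(n) == "corrected"
        ]
        assert sorted(corrected) == ["b", "c"]
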