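"""PRA relation-path enumeration and feature-vector contracts."""

import numpy as np
import pytest

from pacnn.kg import KnowledgeGraph, TripletRecord, UnknownEntityError
from pacnn.pra import (
    PathFeaturizer,
    compute_h,
    enumerate_relation_paths,
    feature_vector,
    sample_negatives,
    triplet_features,
)

from conftest import oracle_h, random_graph


class TestEnumerate:
    def test_two_relations_length_two(self):
        paths = enumerate_relation_paths(["r1", "r2"], 2)
        assert paths == [
            ("r1",), ("r2",),
            ("r1", "r1"), ("r1", "r2"), ("r2", "r1"), ("r2", "r2"),
        ]

    def test_single_relation(self):
        assert enumerate_relation_paths(["r1"], 3) == [
            ("r1",), ("r1", "r1"), ("r1", "r1", "r1")
        ]

    def test_52_relation_scale(self):
        # 52 relation types at path length 2 give 52 + 52^2 = 2756 per leg
        rels = [f"rel{i}" for i in range(52)]
        assert len(enumerate_relation_paths(rels, 2)) == 2756

    def test_invalid_l_max(self):
        with pytest.raises(ValueError):
            enumerate_relation_paths(["r1"], 0)


class TestComputeH:
    def test_empty_path_is_point_mass(self, g1):
        assert compute_h(g1, "A", ()) == {"A": 1.0}

    def test_two_step_diamond(self, g1):
        # both A->B->D and A->C->D carry 0.5 * 1.0
        assert compute_h(g1, "A", ("r1", "r2")) == pytest.approx({"D": 1.0})

    def test_dead_end_gives_empty(self, g1):
        assert compute_h(g1, "A", ("r2",)) == {}

    def test_unknown_source(self, g1):
        with pytest.raises(UnknownEntityError):
            compute_h(g1, "Z", ("r1",))

    def test_matches_walk_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_graph(rng, n_nodes=8, n_edges=40, n_relations=3)
            paths = enumerate_relation_paths(g.relation_types, 3)
            src = g.entities[rng.integers(g.n_entities)]
            for k in rng.choice(len(paths), size=10, replace=False):
                got = compute_h(g, src, paths[k])
                want = oracle_h(g, src, paths[k])
                assert set(got) == set(want)
                for node, p in want.items():
                    assert got[node] == pytest.approx(p, abs=1e-12)

    def test_mass_bound(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = random_graph(rng, n_nodes=6, n_edges=25, n_relations=2)
            for path in enumerate_relation_paths(g.relation_types, 2):
                for src in g.entities:
                    assert sum(compute_h(g, src, path).values()) <= 1 + 1e-12

    def test_prefix_consistency(self):
        # h(P) equals one recursion step applied to h(P[:-1])
        rng = np.random.default_rng(17)
        g = random_graph(rng, n_nodes=7, n_edges=30, n_relations=3)
        for path in enumerate_relation_paths(g.relation_types, 3)[-9:]:
            for src in g.entities[:3]:
                prev = compute_h(g, src, path[:-1])
                rel = path[-1]
                stepped: dict[str, float] = {}
                for node, p in prev.items():
                    deg = g.out_degree(node, rel)
                    for obj in g.objects(node, rel):
                        stepped[obj] = stepped.get(obj, 0.0) + p / deg
                assert compute_h(g, src, path) == pytest.approx(stepped, abs=1e-12)


class TestFeatureVectors:
    def test_only_connecting_path_is_set(self, g1):
        paths = enumerate_relation_paths(g1.relation_types, 2)
        vec = feature_vector(g1, "A", "D", paths)
        np.testing.assert_allclose(vec, [0, 0, 0, 1.0, 0, 0])

    def test_unreachable_pairs_are_zero(self, g1):
        paths = enumerate_relation_paths(g1.relation_types, 2)
        assert not feature_vector(g1, "A", "A", paths).any()
        assert not feature_vector(g1, "D", "A", paths).any()  # sink source

    def test_triplet_concatenation(self, g1):
        paths = enumerate_relation_paths(g1.relation_types, 2)
        feat = triplet_features(g1, TripletRecord("A", "B", "D", True), paths)
        assert feat.vector.shape == (12,)
        assert feat.vector[0] == 0.5        # drug->target leg, path (r1)
        assert feat.vector[6 + 1] == 1.0    # target->disease leg, path (r2)
        assert feat.label is True

    def test_missing_entity_names_leg(self, g1):
        paths = enumerate_relation_paths(g1.relation_types, 2)
        with pytest.raises(UnknownEntityError, match="target"):
            triplet_features(g1, TripletRecord("A", "X", "D"), paths)

    def test_featurizer_matches_direct_computation(self):
        rng = np.random.default_rng(23)
        g = random_graph(rng, n_nodes=9, n_edges=45, n_relations=3)
        fz = PathFeaturizer(g, l_max=2)
        for src in g.entities[:4]:
            for dst in g.entities[-4:]:
                direct = feature_vector(g, src, dst, fz.paths)
                np.testing.assert_array_equal(fz.pair_vector(src, dst), direct)


class TestNegativeSampling:
    POS = [TripletRecord(f"d{i}", f"t{i}", f"s{i}", True) for i in range(10)]
    DRUGS = [f"d{i}" for i in range(15)]
    TARGETS = [f"t{i}" for i in range(15)]
    DISEASES = [f"s{i}" for i in range(15)]

    def test_count_disjointness_and_determinism(self):
        negs = sample_negatives(self.POS, self.DRUGS, self.TARGETS, self.DISEASES, seed=7)
        assert len(negs) == 10
        assert len({n.key for n in negs}) == 10
        assert not {n.key for n in negs} & {p.key for p in self.POS}
        assert all(n.label is False for n in negs)
        again = sample_negatives(self.POS, self.DRUGS, self.TARGETS, self.DISEASES, seed=7)
        assert negs == again

    def test_different_seed_differs(self):
        a = sample_negatives(self.POS, self.DRUGS, self.TARGETS, self.DISEASES, seed=1)
        b = sample_negatives(self.POS, self.DRUGS, self.TARGETS, self.DISEASES, seed=2)
        assert a != b

    def test_exhausted_pool_errors(self):
        pos = [TripletRecord("d0", "t0", "s0", True)]
        with pytest.raises(ValueError, match="pool"):
            sample_negatives(pos, ["d0"], ["t0"], ["s0"], seed=0)

    def test_no_positives_gives_empty(self):
        assert sample_negatives([], self.DRUGS, self.TARGETS, self.DISEASES, seed=0) == []
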