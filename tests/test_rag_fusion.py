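import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epifuse.io_formats import PeptideRecord
from epifuse.kg_store import KnowledgeGraph
from epifuse.rag_fusion import (
    M_HUMAN,
    M_MOUSE,
    ContextWeights,
    RelationshipMap,
    compute_context_weights,
    enrich_dataset,
    fuse,
    l2_distance,
    retrieve_top_k,
    weighted_average,
)

from conftest import make_emb, random_embs


class TestL2Distance:
    def test_zero_for_identical(self, rng):
        a = make_emb("a", rng.standard_normal((4, 3)))
        b = make_emb("b", a.values.copy())
        assert l2_distance(a, b) == 0.0

    def test_pythagorean(self):
        a = make_emb("a", [[0.0, 0.0]])
        b = make_emb("b", [[3.0, 4.0]])
        assert l2_distance(a, b) == pytest.approx(5.0)

    def test_matches_elementwise_bruteforce(self, rng):
        q = make_emb("q", rng.standard_normal((20, 1280)))
        e = make_emb("e", rng.standard_normal((20, 1280)))
        acc = 0.0
        for row_q, row_e in zip(q.values, e.values):
            for x, y in zip(row_q, row_e):
                acc += (x - y) ** 2
        assert l2_distance(q, e) == pytest.approx(np.sqrt(acc), rel=1e-9)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            l2_distance(
                make_emb("a", rng.standard_normal((4, 3))),
                make_emb("b", rng.standard_normal((3, 4))),
            )


class TestRetrieveTopK:
    def test_exact_match_first_with_zero_distance(self, rng):
        db = random_embs(6, 4, 3, seed=1)
        q = make_emb("query", db[3].values.copy())
        result = retrieve_top_k(q, db, k=3)
        assert result.neighbour_ids[0] == db[3].epitope_id
        assert result.distances[0] == 0.0

    def test_matches_exhaustive_argsort(self, rng):
        db = random_embs(10, 4, 3, seed=2)
        q = make_emb("query", rng.standard_normal((4, 3)))
        result = retrieve_top_k(q, db, k=5)
        brute = sorted(
            (l2_distance(q, e), i) for i, e in enumerate(db)
        )
        assert result.neighbour_ids == [db[i].epitope_id for _, i in brute[:5]]
        assert result.distances == pytest.approx([d for d, _ in brute[:5]])

    def test_ties_break_by_database_index(self):
        shared = np.ones((2, 2))
        db = [make_emb("far", 5 * np.ones((2, 2)))] + [
            make_emb(f"tied{i}", shared.copy()) for i in range(3)
        ]
        result = retrieve_top_k(make_emb("q", np.zeros((2, 2))), db, k=3)
        assert result.neighbour_ids == ["tied0", "tied1", "tied2"]

    def test_self_excluded(self):
        db = [make_emb("q", np.zeros((2, 2))), make_emb("other", np.ones((2, 2)))]
        result = retrieve_top_k(make_emb("q", np.zeros((2, 2))), db, k=1)
        assert result.neighbour_ids == ["other"]

    def test_database_too_small_after_exclusion(self):
        db = [make_emb("q", np.zeros((2, 2)))]
        with pytest.raises(ValueError):
            retrieve_top_k(make_emb("q", np.zeros((2, 2))), db, k=1)

    def test_distances_nondecreasing(self, rng):
        db = random_embs(50, 3, 4, seed=9)
        result = retrieve_top_k(make_emb("q", rng.standard_normal((3, 4))), db, k=10)
        assert result.distances == sorted(result.distances)


class TestRelationshipMap:
    def test_builtin_values(self):
        assert M_HUMAN.increments == {
            "host": 1.0,
            "source_molecule": 0.5,
            "source_organism": 0.6,
            "molecule_parent": 0.4,
        }
        assert M_MOUSE.increments == {
            "host": 1.0,
            "source_molecule": 0.6,
            "source_organism": 0.5,
            "molecule_parent": 0.4,
        }

    def test_negative_increment_rejected(self):
        with pytest.raises(Exception):
            RelationshipMap({"host": -0.1})

    def test_unknown_category_rejected(self):
        with pytest.raises(Exception):
            RelationshipMap({"colour": 1.0})

    def test_from_name(self):
        assert RelationshipMap.from_name("Human") is M_HUMAN
        with pytest.raises(ValueError):
            RelationshipMap.from_name("rat")


class TestContextWeights:
    def test_worked_example_scores_and_weights(self, worked_example_kg):
        cw = compute_context_weights(
            ["E1", "E2", "E3", "E4", "E5"], worked_example_kg, M_HUMAN
        )
        np.testing.assert_allclose(cw.scores, [2.5, 2.5, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(
            cw.weights, [0.3125, 0.3125, 0.125, 0.125, 0.125]
        )
        assert abs(cw.weights.sum() - 1.0) < 1e-9

    def test_uniform_fallback_when_no_properties(self):
        kg = KnowledgeGraph()
        cw = compute_context_weights(["a", "b", "c", "d", "e"], kg, M_HUMAN)
        np.testing.assert_allclose(cw.weights, [0.2] * 5)

    def test_needs_at_least_two(self, worked_example_kg):
        with pytest.raises(ValueError):
            compute_context_weights(["E1"], worked_example_kg, M_HUMAN)

    def test_zero_increments_give_uniform_exactly(self, worked_example_kg):
        zero = RelationshipMap({c: 0.0 for c in M_HUMAN.increments})
        cw = compute_context_weights(
            ["E1", "E2", "E3", "E4", "E5"], worked_example_kg, zero
        )
        np.testing.assert_array_equal(cw.weights, np.full(5, 0.2))

    def test_permutation_equivariance(self, worked_example_kg):
        ids = ["E1", "E2", "E3", "E4", "E5"]
        base = compute_context_weights(ids, worked_example_kg, M_HUMAN)
        perm = [3, 0, 4, 1, 2]
        shuffled = compute_context_weights(
            [ids[i] for i in perm], worked_example_kg, M_HUMAN
        )
        np.testing.assert_allclose(shuffled.weights, base.weights[perm])

    def test_extra_shared_category_is_monotone(self):
        base_records = [
            PeptideRecord("E1", "ACDEFGHI", host="human", source_organism="virusA"),
            PeptideRecord("E2", "KLMNPQRS", host="human", source_organism="virusB"),
            PeptideRecord("E3", "ACDEFGHL", host="mouse"),
            PeptideRecord("E4", "ACDEFGHK", host="rat"),
            PeptideRecord("E5", "ACDEFGHV", host="pig"),
        ]
        more_records = [
            PeptideRecord("E1", "ACDEFGHI", host="human", source_organism="virusA"),
            PeptideRecord("E2", "KLMNPQRS", host="human", source_organism="virusA"),
            *base_records[2:],
        ]
        ids = ["E1", "E2", "E3", "E4", "E5"]
        before = compute_context_weights(
            ids, KnowledgeGraph.from_records(base_records), M_HUMAN
        )
        after = compute_context_weights(
            ids, KnowledgeGraph.from_records(more_records), M_HUMAN
        )
        assert after.weights[0] >= before.weights[0]
        assert after.weights[1] >= before.weights[1]
        assert np.all(after.weights[2:] <= before.weights[2:])

    def test_label_not_used_by_default(self):
        records = [
            PeptideRecord(f"E{i}", "ACDEFGHI", label=1 if i < 3 else 0)
            for i in range(5)
        ]
        kg = KnowledgeGraph.from_records(records)
        cw = compute_context_weights([f"E{i}" for i in range(5)], kg, M_HUMAN)
        np.testing.assert_allclose(cw.weights, [0.2] * 5)
        cw_leaky = compute_context_weights(
            [f"E{i}" for i in range(5)], kg, M_HUMAN, include_label_increment=1.0
        )
        assert not np.allclose(cw_leaky.weights, 0.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        hosts=st.lists(
            st.one_of(st.none(), st.sampled_from(["human", "mouse", "rat"])),
            min_size=5,
            max_size=5,
        ),
        molecules=st.lists(
            st.one_of(st.none(), st.sampled_from(["m1", "m2"])), min_size=5, max_size=5
        ),
    )
    def test_weights_always_convex(self, hosts, molecules):
        records = [
            PeptideRecord(f"E{i}", "ACDEFGHI", host=h, source_molecule=m)
            for i, (h, m) in enumerate(zip(hosts, molecules))
        ]
        kg = KnowledgeGraph.from_records(records)
        cw = compute_context_weights([r.epitope_id for r in records], kg, M_HUMAN)
        assert np.all(cw.weights >= 0)
        assert abs(cw.weights.sum() - 1.0) < 1e-9
        assert np.all(cw.scores >= 1.0)


class TestWeightedAverageAndFuse:
    def test_convex_fixed_point(self, rng):
        values = rng.standard_normal((4, 3))
        neighbours = [make_emb(f"n{i}", values.copy()) for i in range(5)]
        cw = ContextWeights(np.full(5, 0.2), np.ones(5))
        np.testing.assert_allclose(weighted_average(neighbours, cw).values, values)

    def test_two_point_average(self):
        cw = ContextWeights(np.array([0.5, 0.5]), np.ones(2))
        out = weighted_average([make_emb("a", [[2.0]]), make_emb("b", [[4.0]])], cw)
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_matches_loop_accumulation(self, rng):
        neighbours = random_embs(5, 6, 4, seed=3)
        weights = rng.dirichlet(np.ones(5))
        cw = ContextWeights(weights, np.ones(5))
        expected = np.zeros((6, 4))
        for w, e in zip(weights, neighbours):
            expected += w * e.values
        np.testing.assert_allclose(
            weighted_average(neighbours, cw).values, expected, atol=1e-9
        )

    def test_fuse_degenerate_fraction(self, rng):
        q = make_emb("q", rng.standard_normal((4, 3)))
        c = make_emb("c", rng.standard_normal((4, 3)))
        np.testing.assert_array_equal(fuse(q, c, 1.0).values, q.values)

    def test_fuse_identical_inputs(self, rng):
        q = make_emb("q", rng.standard_normal((4, 3)))
        c = make_emb("c", q.values.copy())
        np.testing.assert_allclose(fuse(q, c, 0.3).values, q.values)

    def test_fuse_nine_to_one(self):
        out = fuse(make_emb("q", [[10.0]]), make_emb("c", [[0.0]]), 0.9)
        assert out.values[0, 0] == pytest.approx(9.0)

    def test_fuse_is_linear_in_inputs(self, rng):
        q = make_emb("q", rng.standard_normal((4, 3)))
        c = make_emb("c", rng.standard_normal((4, 3)))
        scaled = fuse(make_emb("q", 3.0 * q.values), make_emb("c", 3.0 * c.values), 0.9)
        np.testing.assert_allclose(scaled.values, 3.0 * fuse(q, c, 0.9).values)

    def test_fuse_invalid_fraction(self, rng):
        q = make_emb("q", rng.standard_normal((2, 2)))
        with pytest.raises(ValueError):
            fuse(q, q, 1.5)


class TestEnrichDataset:
    def test_empty_queries(self):
        assert enrich_dataset([], [], KnowledgeGraph(), M_HUMAN) == []

    def test_propertyless_database_gives_uniform_mean(self, rng):
        db = random_embs(5, 4, 3, seed=4, prefix="db")
        q = make_emb("q", rng.standard_normal((4, 3)))
        fused = enrich_dataset([q], db, KnowledgeGraph(), M_HUMAN)[0]
        mean = np.mean([e.values for e in db], axis=0)
        np.testing.assert_allclose(fused.values, 0.9 * q.values + 0.1 * mean)

    def test_composition_equals_manual_pipeline(self, rng):
        records = [
            PeptideRecord(
                f"db{i}",
                "ACDEFGHI",
                host=["human", "mouse"][i % 2],
                source_molecule=f"m{i % 3}",
            )
            for i in range(20)
        ]
        kg = KnowledgeGraph.from_records(records)
        db = random_embs(20, 4, 3, seed=5, prefix="db")
        queries = random_embs(20, 4, 3, seed=6, prefix="q")
        fused = enrich_dataset(queries, db, kg, M_HUMAN, k=5, query_fraction=0.9)
        by_id = {e.epitope_id: e for e in db}
        for q, f in zip(queries, fused):
            result = retrieve_top_k(q, db, k=5)
            cw = compute_context_weights(result.neighbour_ids, kg, M_HUMAN)
            ctx = weighted_average([by_id[i] for i in result.neighbour_ids], cw)
            np.testing.assert_allclose(f.values, fuse(q, ctx, 0.9).values, atol=1e-12)

    def test_audit_log_written(self, rng, tmp_path):
        db = random_embs(6, 4, 3, seed=4, prefix="db")
        q = make_emb("q", rng.standard_normal((4, 3)))
        audit = tmp_path / "audit.tsv"
        enrich_dataset([q], db, KnowledgeGraph(), M_HUMAN, audit_path=audit)
        lines = audit.read_text().strip().splitlines()
        assert lines[0].split("\t") == [
            "query_id", "neighbour_id", "rank", "distance", "score", "weight",
        ]
        assert len(lines) == 6
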