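import numpy as np
import pytest

import ppsnet as pn
from ppsnet.gsf import FeatureKind, delta_ge
from ppsnet.pyramid import NO_DECISION, k_max_candidates, pyramid_search

from conftest import random_family, random_attachment


def k2_family(label, weight=30.0):
    table = pn.SimilarityTable()
    table.set(f"{label}_a", f"{label}_b", weight)
    return pn.build_family_graph(label, [f"{label}_a", f"{label}_b"], table)


def flat_config(ladder=(10.0, 20.0, 30.0), **kw):
    defaults = dict(t_ac=0.0, t_rc=0.0, p=2, r_low=1, r_high=1, k=3)
    defaults.update(kw)
    return pn.PyramidConfig(global_ladder=tuple(ladder),
                            ladders={kind: tuple(ladder) for kind in FeatureKind},
                            **defaults)


class TestBuildThresholds:
    def test_uniform_quantization(self):
        table = pn.SimilarityTable()
        table.set("a", "b", 100.0)
        g = pn.build_family_graph("c", ["a", "b"], table)
        cfg = pn.build_thresholds([g], n_levels=10)
        assert cfg.global_ladder == pytest.approx(tuple(range(10, 101, 10)))

    def test_single_edge_spans_range(self):
        table = pn.SimilarityTable()
        table.set("a", "b", 7.0)
        g = pn.build_family_graph("c", ["a", "b"], table)
        cfg = pn.build_thresholds([g], n_levels=5)
        assert cfg.global_ladder[-1] == pytest.approx(7.0)
        assert cfg.global_ladder[0] > 0

    @pytest.mark.parametrize("n_levels", [2, 3, 5, 10, 16])
    def test_slices_cover_every_level(self, n_levels):
        table = pn.SimilarityTable()
        table.set("a", "b", 50.0)
        g = pn.build_family_graph("c", ["a", "b"], table)
        cfg = pn.build_thresholds([g], n_levels=n_levels)
        covered = set()
        for ladder in cfg.ladders.values():
            assert all(b > a for a, b in zip(ladder, ladder[1:]))
            covered.update(cfg.level_index(t) for t in ladder)
        assert covered == set(range(1, n_levels + 1))

    def test_all_zero_weights_rejected(self):
        g = pn.build_family_graph("c", ["a", "b"], pn.SimilarityTable())
        with pytest.raises(ValueError, match="no pyramid"):
            pn.build_thresholds([g])


class TestPyramidSearch:
    def test_demo_queries(self, pyramid_demo):
        model, queries = pyramid_demo
        cfg = model.config
        expected = {
            "q1": ({"c2", "c3"}, 20.0),   # first qualifies one level down
            "q2": ({"c1"}, 30.0),         # strong match at the top
            "q3": (set(), 10.0),          # interacts nowhere
            "q4": ({"c3"}, 10.0),
            "q5": ({"c2", "c3"}, 30.0),
        }
        for qid, (labels, t_star) in expected.items():
            cs = pyramid_search(model.families, queries[qid], model.families,
                                FeatureKind.AC, cfg.ladders[FeatureKind.AC],
                                cfg.t_ac, cfg)
            assert set(cs.labels) == labels, qid
            assert cs.t_star == pytest.approx(t_star), qid

    def test_unknown_class_rejected(self, pyramid_demo):
        model, queries = pyramid_demo
        with pytest.raises(KeyError):
            pyramid_search(model.families, queries["q1"], ["nope"],
                           FeatureKind.AC, (10.0,), 0.0, model.config)


class TestKMax:
    def test_positive_deltas_only(self):
        # q closes a triangle in c1 and c2 but not c3 -> only they are eligible
        fams = {c: k2_family(c) for c in ("c1", "c2", "c3")}
        atts = {
            "c1": pn.QueryAttachment("q", np.array([30.0, 30.0])),
            "c2": pn.QueryAttachment("q", np.array([30.0, 30.0])),
            "c3": pn.QueryAttachment("q", np.array([30.0, 0.0])),
        }
        cfg = flat_config()
        cs = k_max_candidates(fams, atts, fams, FeatureKind.TR, 10.0, 2, cfg)
        assert set(cs.labels) == {"c1", "c2"}

    def test_no_interaction_no_vote(self):
        fams = {c: k2_family(c) for c in ("c1", "c2")}
        atts = {c: pn.QueryAttachment("q", np.zeros(2)) for c in fams}
        cs = k_max_candidates(fams, atts, fams, FeatureKind.TR, 10.0, 2, flat_config())
        assert not cs.labels

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fams = {f"c{i}": random_family(rng, 6, label=f"c{i}", weight_scale=30.0)
                for i in range(5)}
        atts = {c: random_attachment(rng, g, weight_scale=30.0)
                for c, g in fams.items()}
        cfg = flat_config(ladder=(5.0, 15.0, 25.0))
        k = int(rng.integers(1, 5))
        cs = k_max_candidates(fams, atts, fams, FeatureKind.GE, 5.0, k, cfg)
        deltas = {c: delta_ge(fams[c], atts[c], 5.0, weighted=cfg.weighted_ge)
                  for c in fams}
        expected = sorted((c for c, d in deltas.items() if d > 0),
                          key=lambda c: (-deltas[c], c))[:k]
        assert cs.sorted_labels() == tuple(sorted(expected))


class TestClassify:
    def two_family_model(self):
        fams = {c: k2_family(c) for c in ("c1", "c2")}
        return pn.TrainedModel(fams, flat_config())

    def test_clear_membership(self):
        model = self.two_family_model()
        atts = {"c1": pn.QueryAttachment("q", np.array([30.0, 30.0])),
                "c2": pn.QueryAttachment("q", np.zeros(2))}
        res = pn.classify(model, atts, "q")
        assert res.predicted == "c1"
        assert res.tie_path == ()
        assert res.candidates["AC"].labels == frozenset({"c1"})

    def test_zero_scores_give_no_decision(self):
        model = self.two_family_model()
        atts = {c: pn.QueryAttachment("q", np.zeros(2)) for c in ("c1", "c2")}
        res = pn.classify(model, atts, "q")
        assert res.predicted is NO_DECISION

    def test_energy_fallback_breaks_persistent_tie(self):
        # c1 is edgeless and the query bridges its two vertices; c2 has an
        # internal edge and the query hangs off one vertex.  AC/RC tie the
        # vote, SM (p=3) and TR abstain, and only the energy gain -- much
        # larger for c1 -- can arbitrate.
        c1 = pn.FamilyGraph("c1", ("c1_a", "c1_b"), np.zeros((2, 2)))
        c2 = k2_family("c2")
        model = pn.TrainedModel({"c1": c1, "c2": c2}, flat_config(p=3))
        atts = {"c1": pn.QueryAttachment("q", np.array([20.0, 20.0])),
                "c2": pn.QueryAttachment("q", np.array([20.0, 0.0]))}
        res = pn.classify(model, atts, "q")
        assert "ge_fallback" in res.tie_path
        assert res.predicted == "c1"
        ge_t = model.config.ladders[FeatureKind.GE][0]
        d1 = delta_ge(c1, atts["c1"], ge_t, weighted=True)
        d2 = delta_ge(c2, atts["c2"], ge_t, weighted=True)
        assert d1 > d2

    def test_deterministic(self, small_benchmark):
        model, table, queries = small_benchmark
        qid = queries[0][0]
        atts = model.attachments_for(qid, table)
        assert pn.classify(model, atts, qid) == pn.classify(model, atts, qid)

    def test_funnel_property(self, small_benchmark):
        model, table, queries = small_benchmark
        for qid, _ in queries:
            res = pn.classify(model, model.attachments_for(qid, table), qid)
            if "ac_empty_ge_only" in res.tie_path:
                continue  # degenerate funnel: only the energy arbiter ran
            c = res.candidates
            assert c["RC"].labels <= c["AC"].labels
            assert c["SM"].labels <= c["RC"].labels
            assert c["TR"].labels <= c["RC"].labels
            assert c["GE"].labels <= (c["SM"].labels | c["TR"].labels)

    def test_separable_benchmark_recovers_families(self, small_benchmark):
        model, table, queries = small_benchmark
        upper = model.config.global_ladder[model.config.n_levels // 2]
        correct = 0
        for qid, true in queries:
            res = pn.classify(model, model.attachments_for(qid, table), qid)
            if res.predicted == true:
                correct += 1
                if res.candidates["AC"].labels:
                    # strong matches are global features: found high up
                    assert res.candidates["AC"].t_star >= upper
        assert correct / len(queries) >= 0.95


class TestMajorityVoting:
    def test_agrees_on_easy_case(self, small_benchmark):
        model, table, queries = small_benchmark
        agree = sum(
            pn.classify(model, model.attachments_for(q, table), q).predicted ==
            pn.majority_classify(model, model.attachments_for(q, table), q).predicted
            for q, _ in queries)
        assert agree / len(queries) >= 0.9

    def test_mode_of_votes(self):
        fams = {c: k2_family(c) for c in ("c1", "c2")}
        model = pn.TrainedModel(fams, flat_config())
        atts = {"c1": pn.QueryAttachment("q", np.array([30.0, 30.0])),
                "c2": pn.QueryAttachment("q", np.array([30.0, 0.0]))}
        res = pn.majority_classify(model, atts, "q")
        assert res.predicted == "c1"

    def test_single_family_costs_match(self):
        model = pn.TrainedModel({"c1": k2_family("c1")}, flat_config())
        atts = {"c1": pn.QueryAttachment("q", np.array([30.0, 30.0]))}
        hier = pn.classify(model, atts, "q")
        flat = pn.majority_classify(model, atts, "q")
        assert hier.feature_evaluations == flat.feature_evaluations

    def test_hierarchy_prunes_evaluations(self, small_benchmark):
        model, table, queries = small_benchmark
        total_h = total_m = 0
        pruned = False
        for qid, _ in queries:
            atts = model.attachments_for(qid, table)
            res_h = pn.classify(model, atts, qid)
            res_m = pn.majority_classify(model, atts, qid)
            total_h += res_h.feature_evaluations
            total_m += res_m.feature_evaluations
            if res_h.candidates["AC"].labels and \
                    res_h.candidates["AC"].labels != frozenset(model.families):
                pruned = True
                assert res_h.feature_evaluations < res_m.feature_evaluations
        assert pruned and total_h < total_m


class TestIncrementalUpdate:
    def test_rebuild_equivalence(self, small_benchmark):
        model, table, queries = small_benchmark
        qid, true = queries[0]
        atts = model.attachments_for(qid, table)
        updated = pn.incremental_update(model, qid, true, atts)
        rebuilt = pn.build_family_graph(
            true, list(model.families[true].vertices) + [qid], table)
        assert np.array_equal(updated.families[true].weights, rebuilt.weights)
        assert updated.families[true].vertices == rebuilt.vertices

    def test_other_families_untouched(self, small_benchmark):
        model, table, queries = small_benchmark
        qid, true = queries[0]
        updated = pn.incremental_update(model, qid, true,
                                        model.attachments_for(qid, table))
        for label, g in model.families.items():
            if label != true:
                assert updated.families[label] is g
        assert updated.families[true].n_vertices == model.families[true].n_vertices + 1

    def test_twin_query_follows_added_member(self, small_benchmark):
        model, table, queries = small_benchmark
        qid, true = queries[0]
        atts = model.attachments_for(qid, table)
        updated = pn.incremental_update(model, qid, true, atts)
        twin_atts = {}
        for label, g in updated.families.items():
            vec = np.array([table.get(qid, v) if v != qid else max(atts[label].eb_to_member)
                            for v in g.vertices])
            twin_atts[label] = pn.QueryAttachment("twin", vec)
        assert pn.classify(updated, twin_atts, "twin").predicted == true

    def test_no_decision_update_rejected(self, small_benchmark):
        model, table, queries = small_benchmark
        qid = queries[0][0]
        with pytest.raises(ValueError):
            pn.incremental_update(model, qid, NO_DECISION,
                                  model.attachments_for(qid, table))


class TestMaxEbBaseline:
    def test_strongest_match_wins(self):
        fams = {c: k2_family(c) for c in ("c1", "c2")}
        model = pn.TrainedModel(fams, flat_config())
        atts = {"c1": pn.QueryAttachment("q", np.array([10.0, 0.0])),
                "c2": pn.QueryAttachment("q", np.array([11.0, 0.0]))}
        assert pn.max_eb_classify(model, atts, "q").predicted == "c2"

    def test_no_match_no_decision(self):
        model = pn.TrainedModel({"c1": k2_family("c1")}, flat_config())
        atts = {"c1": pn.QueryAttachment("q", np.zeros(2))}
        assert pn.max_eb_classify(model, atts, "q").predicted is NO_DECISION


class TestPersistence:
    def test_round_trip(self, tmp_path, small_benchmark):
        model, table, queries = small_benchmark
        pn.save_model(model, tmp_path / "model")
        loaded = pn.load_model(tmp_path / "model")
        assert loaded.labels == model.labels
        assert loaded.config == model.config
        for label in model.families:
            assert np.array_equal(loaded.families[label].weights,
                                  model.families[label].weights)
        qid = queries[0][0]
        atts = model.attachments_for(qid, table)
        assert pn.classify(loaded, atts, qid) == pn.classify(model, atts, qid)
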