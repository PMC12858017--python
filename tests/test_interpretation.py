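"""Feature importance, fuzzy SOC matching, and drug/ATC cross-referencing."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv


@pytest.fixture(scope="module")
def fitted_forest():
    rng = np.random.default_rng(0)
    X = rng.random((80, 4))
    X[:, 3] = 0.0  # constant feature: never used in any split
    y = (X[:, 0] > 0.5).astype(int)
    model = pv.train_classifier(X, y, "forest", seed=0)
    return model, X, y


class TestFeatureImportance:
    def test_single_feature_has_importance_one(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 1))
        y = (X[:, 0] > 0.5).astype(int)
        model = pv.train_classifier(X, y, "forest", seed=0)
        for mode in ("global", "positive"):
            table = pv.feature_importance(model, ["t0"], mode=mode, X=X)
            assert table.frame["importance"].iloc[0] == pytest.approx(1.0)

    def test_unused_feature_importance_zero_in_both_modes(self, fitted_forest):
        model, X, y = fitted_forest
        ids = ["t0", "t1", "t2", "t_const"]
        for mode in ("global", "positive"):
            table = pv.feature_importance(model, ids, mode=mode, X=X)
            row = table.frame.set_index("target_id").loc["t_const"]
            assert row["importance"] == 0.0

    def test_positive_mode_deterministic_and_normalized(self, fitted_forest):
        model, X, y = fitted_forest
        ids = ["t0", "t1", "t2", "t3"]
        a = pv.feature_importance(model, ids, mode="positive", X=X)
        b = pv.feature_importance(model, ids, mode="positive", X=X)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.frame["importance"].sum() == pytest.approx(1.0)
        assert list(a.frame["rank"]) == list(range(1, 5))

    def test_no_positive_predictions_falls_back_to_global(self, fitted_forest):
        model, X, y = fitted_forest
        X_neg = X[y == 0][:5]
        with pytest.warns(UserWarning, match="falling back"):
            table = pv.feature_importance(
                model, ["t0", "t1", "t2", "t3"], mode="positive", X=X_neg
            )
        assert table.mode == "global"

    def test_causal_targets_outrank_decoys(self):
        # planted worlds over three seeds: the causal targets of a planted
        # SOC should sit above non-causal ones in both importance modes
        rank_gap = {"global": [], "positive": []}
        for seed in (0, 1, 2):
            # six SOCs so the focal drug's other-SOC report mass keeps
            # PRR sensitive to the planted mechanism
            cfg = pv.SyntheticConfig(
                n_drugs=150, n_targets=60,
                causal_targets_per_soc=4, interaction_density=0.08,
                relative_risk=6.0, seed=seed,
            )
            world = pv.generate_world(cfg)
            matrix = pv.filter_confidence(world.interactions)
            _, labels = pv.label_signals(world.reports, drugs=matrix.drug_ids)
            soc = cfg.planted_socs[0]
            y = labels.column(soc)
            model = pv.train_classifier(matrix.scores, y, "forest", seed=seed)
            causal = set(world.truth[soc])
            for mode in rank_gap:
                table = pv.feature_importance(
                    model, matrix.target_ids, mode=mode, X=matrix.scores
                )
                ranks = table.frame.set_index("target_id")["rank"]
                mean_causal = np.mean([ranks[t] for t in causal])
                mean_other = np.mean(
                    [ranks[t] for t in matrix.target_ids if t not in causal]
                )
                rank_gap[mode].append(mean_other - mean_causal)
        for mode, gaps in rank_gap.items():
            assert np.mean(gaps) > 0, mode


class TestTopK:
    @pytest.fixture
    def table(self):
        frame = pd.DataFrame(
            {"target_id": [f"t{i}" for i in range(30)],
             "importance": np.linspace(1, 0, 30),
             "rank": np.arange(1, 31)}
        )
        return pv.ImportanceTable(frame)

    def test_default_ten(self, table):
        assert len(pv.top_k(table)) == 10

    def test_k_exceeding_table(self, table):
        assert len(pv.top_k(table, 100)) == 30

    def test_k_one_is_argmax(self, table):
        top = pv.top_k(table, 1)
        assert top.frame["target_id"].iloc[0] == "t0"

    def test_invalid_k(self, table):
        with pytest.raises(ValueError):
            pv.top_k(table, 0)


class TestFuzzyMatching:
    def test_identical_term_scores_100(self):
        assert pv.similarity_ratio(
            "Psychiatric disorders", "Psychiatric disorders"
        ) == 100.0

    def test_singular_plural_above_90(self):
        assert pv.similarity_ratio(
            "psychiatric disorder", "Psychiatric disorders"
        ) >= 90.0

    def test_case_and_whitespace_invariance(self):
        vocab = ("Cardiac disorders", "Eye disorders")
        assoc = pd.DataFrame(
            {"target_id": ["t1", "t1"],
             "disease_term": ["  CARDIAC   DISORDERS ", "cardiac disorders"]}
        )
        summary = pv.match_associations(["t1"], assoc, vocab)
        assert summary.per_target["t1"] == {"Cardiac disorders": 2}

    def test_no_data_target_flagged(self):
        assoc = pd.DataFrame({"target_id": ["t1"], "disease_term": ["eye disorders"]})
        summary = pv.match_associations(["t1", "t2"], assoc, ("Eye disorders",))
        assert summary.no_data == {"t2"}
        assert summary.per_target["t2"] == {}

    def test_below_min_similarity_counts_unmatched(self):
        assoc = pd.DataFrame(
            {"target_id": ["t1"], "disease_term": ["completely unrelated thing"]}
        )
        summary = pv.match_associations(
            ["t1"], assoc, ("Cardiac disorders",), min_similarity=80
        )
        assert summary.unmatched["t1"] == 1
        assert summary.per_target["t1"] == {}

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        vocab = pv.SOC_VOCABULARY[:8]
        terms = [v.lower() for v in vocab] + ["noise term xyz"]
        rows = [
            ("t1", terms[int(rng.integers(len(terms)))]) for _ in range(20)
        ]
        assoc = pd.DataFrame(rows, columns=["target_id", "disease_term"])
        summary = pv.match_associations(["t1"], assoc, vocab)
        assert summary.total_rows("t1") == 20

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            pv.match_associations(
                ["t1"], pd.DataFrame(columns=["target_id", "disease_term"]), ()
            )


class TestSocAlignment:
    def test_focal_absent_everywhere(self):
        assoc = pd.DataFrame(
            {"target_id": ["t1"], "disease_term": ["cardiac disorders"]}
        )
        summary = pv.match_associations(
            ["t1"], assoc, ("Cardiac disorders", "Eye disorders")
        )
        rep = pv.soc_alignment(summary, "Eye disorders")
        assert rep.aligned_count == 0

    def test_all_no_data(self):
        summary = pv.match_associations(
            ["t1", "t2"],
            pd.DataFrame(columns=["target_id", "disease_term"]),
            ("Eye disorders",),
        )
        rep = pv.soc_alignment(summary, "Eye disorders")
        assert rep.aligned_count == 0
        assert rep.no_data == ["t1", "t2"]

    def test_groups_cover_focal_next_two_other(self):
        vocab = ("A disorders", "B disorders", "C disorders", "D disorders")
        rows = (
            [("t", "a disorders")] * 4
            + [("t", "b disorders")] * 3
            + [("t", "c disorders")] * 2
            + [("t", "d disorders")] * 1
        )
        assoc = pd.DataFrame(rows, columns=["target_id", "disease_term"])
        summary = pv.match_associations(["t"], assoc, vocab)
        rep = pv.soc_alignment(summary, "A disorders")
        assert rep.groups["focal"] == 4
        assert rep.groups["B disorders"] == 3
        assert rep.groups["C disorders"] == 2
        assert rep.groups["other"] == 1


class TestRelationsAndAtc:
    @pytest.fixture
    def matrix(self):
        scores = np.array(
            [[0.9, 0.0, 0.5],
             [0.0, 0.0, 0.7],
             [0.0, 0.0, 0.0]]
        )
        return pv.InteractionMatrix(["d1", "d2", "d3"], ["t1", "t2", "t3"], scores)

    def test_all_zero_target_has_no_edges(self, matrix):
        frame = pv.drug_target_relations(["t2"], matrix)
        assert len(frame) == 0

    def test_edge_count_equals_nonzero_cells(self, matrix):
        frame = pv.drug_target_relations(["t1", "t3"], matrix)
        assert len(frame) == 3

    def test_unknown_target_rejected(self, matrix):
        with pytest.raises(KeyError):
            pv.drug_target_relations(["missing"], matrix)

    def test_all_n_prefix_fraction_one(self):
        relations = pd.DataFrame({"drug_id": ["d1", "d2"], "target_id": "t", "score": 0.5})
        atc = pd.DataFrame({"drug_id": ["d1", "d2"], "atc_code": ["N05BA01", "N06AB03"]})
        out = pv.atc_enrichment(relations, atc)
        frame = out["prefixes"].set_index("prefix")
        assert frame.loc["N", "fraction"] == 1.0

    def test_46_of_49_fraction(self):
        # synthetic analogue of a 46-of-49 nervous-system enrichment
        drugs = [f"d{i}" for i in range(49)]
        codes = ["N02BE01"] * 46 + ["A01AB02", "C07AB07", "J01CA04"]
        relations = pd.DataFrame({"drug_id": drugs, "target_id": "t", "score": 0.6})
        atc = pd.DataFrame({"drug_id": drugs, "atc_code": codes})
        out = pv.atc_enrichment(relations, atc)
        frame = out["prefixes"].set_index("prefix")
        assert frame.loc["N", "n_drugs"] == 46
        assert frame.loc["N", "fraction"] == pytest.approx(46 / 49, abs=1e-9)

    def test_unclassified_excluded_from_denominator(self):
        relations = pd.DataFrame({"drug_id": ["d1", "d2", "d3"], "target_id": "t",
                                  "score": 0.5})
        atc = pd.DataFrame({"drug_id": ["d1", "d2"], "atc_code": ["N05BA01", "C01AA05"]})
        out = pv.atc_enrichment(relations, atc)
        assert out["n_classified"] == 2
        assert out["unclassified"] == ["d3"]
        frame = out["prefixes"].set_index("prefix")
        assert frame.loc["N", "fraction"] == pytest.approx(0.5)

    def test_empty_relation_table(self):
        out = pv.atc_enrichment(
            pd.DataFrame(columns=["drug_id", "target_id", "score"]),
            pd.DataFrame(columns=["drug_id", "atc_code"]),
        )
        assert out["n_classified"] == 0
        assert len(out["prefixes"]) == 0
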