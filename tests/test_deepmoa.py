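import numpy as np
import pandas as pd
import pytest

import ontovnn as ov
from ontovnn import deepmoa
from ontovnn.attribution import AttributionTensor

from conftest import make_model


def tensor_for(drug, node_scores, nodes, virtual, genes=2):
    n_cells, n_nodes, k = node_scores.shape
    return AttributionTensor(
        drug_id=drug, cells=[f"c{i}" for i in range(n_cells)], nodes=list(nodes),
        node_layer=np.ones(n_nodes, dtype=int), is_virtual=np.asarray(virtual),
        node_scores=node_scores, gene_scores=np.zeros((n_cells, genes)),
        drug_scores=np.zeros((n_cells, 4)), genes=[f"g{i}" for i in range(genes)],
    )


class TestAggregateFeatures:
    def test_six_features_per_term_under_default_k(self, small_hierarchy, small_cohort):
        model = make_model(small_hierarchy, k=6, vnn_output=4)
        ref = ov.ReferenceInput(cell=np.median(small_cohort.features.values, axis=0),
                                drug=np.zeros(64))
        tensors = {
            d: ov.deeplift_vnn(model, small_cohort.features.values, fp.bits, ref, drug_id=d)
            for d, fp in small_cohort.fingerprints.items()
        }
        feats = deepmoa.aggregate_features(tensors)
        assert feats.k == 6
        assert feats.values.shape == (len(tensors), len(feats.terms) * 6)
        assert set(feats.terms) == small_hierarchy.terms  # virtual nodes excluded

    def test_two_drug_column_normalized_by_population_std(self):
        a = 3.7
        scores = {"d1": a, "d2": -a}
        tensors = {
            d: tensor_for(d, np.full((1, 1, 2), v), ["T"], [False])
            for d, v in scores.items()
        }
        feats = deepmoa.aggregate_features(tensors)
        assert np.allclose(np.sort(feats.values[:, 0]), [-1.0, 1.0])

    def test_single_drug_rejected(self):
        t = tensor_for("d1", np.ones((2, 1, 2)), ["T"], [False])
        with pytest.raises(ValueError, match="2 drugs"):
            deepmoa.aggregate_features({"d1": t})

    def test_zero_spread_column_flagged_unscaled(self):
        tensors = {
            d: tensor_for(d, np.ones((1, 1, 2)), ["T"], [False]) for d in ["d1", "d2"]
        }
        with pytest.warns(UserWarning, match="zero-spread"):
            feats = deepmoa.aggregate_features(tensors)
        assert np.allclose(feats.values, 1.0)
        assert ("T", 1) in feats.zero_spread_terms


class TestLabelMatrix:
    def test_closure_reaches_all_ancestors(self, diamond_graph):
        ann = pd.DataFrame({"drug": ["d1"], "term": ["C"]})
        lm = deepmoa.build_label_matrix(ann, diamond_graph)
        assert lm.labels.loc["d1", ["C", "A", "B", "R"]].tolist() == [1, 1, 1, 1]

    def test_root_annotation_stays_single_positive(self, diamond_graph):
        ann = pd.DataFrame({"drug": ["d1"], "term": ["R"]})
        lm = deepmoa.build_label_matrix(ann, diamond_graph)
        assert int(lm.labels.loc["d1"].sum()) == 1

    def test_closure_is_idempotent(self, diamond_graph):
        ann = pd.DataFrame({"drug": ["d1", "d2"], "term": ["C", "A"]})
        lm1 = deepmoa.build_label_matrix(ann, diamond_graph)
        # feed the closed labels back as annotations: nothing may change
        closed = lm1.labels.stack()
        closed = closed[closed == 1].reset_index()
        ann2 = closed.rename(columns={"level_0": "drug", "level_1": "term"})[["drug", "term"]]
        lm2 = deepmoa.build_label_matrix(ann2, diamond_graph)
        pd.testing.assert_frame_equal(lm1.labels, lm2.labels)

    def test_unknown_terms_rejected_with_warning(self, diamond_graph):
        ann = pd.DataFrame({"drug": ["d1", "d1"], "term": ["C", "NOPE"]})
        with pytest.warns(UserWarning, match="rejected 1"):
            lm = deepmoa.build_label_matrix(ann, diamond_graph)
        assert "NOPE" not in lm.labels.columns

    def test_unannotated_drugs_marked_unknown(self, diamond_graph):
        ann = pd.DataFrame({"drug": ["d1"], "term": ["C"]})
        lm = deepmoa.build_label_matrix(ann, diamond_graph, drugs=["d1", "d2"])
        assert bool(lm.known["d1"]) and not bool(lm.known["d2"])


def separable_setup(n_pos=20, n_neg=20, k=2, seed=0, flip=0):
    """Features where term X's first coordinate separates the classes."""
    rng = np.random.default_rng(seed)
    drugs = [f"d{i:02d}" for i in range(n_pos + n_neg)]
    y = np.array([1] * n_pos + [0] * n_neg)
    if flip:
        y[:flip] = 1 - y[:flip]
    X = rng.normal(0, 0.1, size=(len(drugs), k))
    X[:, 0] += np.where(y == 1, 1.0, -1.0)
    feats = deepmoa.MoAFeatureMatrix(values=X, drugs=drugs, terms=["X"], k=k)
    labels = deepmoa.MoALabelMatrix(
        labels=pd.DataFrame({"X": y}, index=drugs),
        known=pd.Series(True, index=drugs),
    )
    return feats, labels


class TestTermSVMs:
    def test_term_under_16_drugs_gets_no_model(self):
        feats, labels = separable_setup(n_pos=15, n_neg=30)
        with pytest.raises(ValueError, match="16 drugs"):
            deepmoa.train_term_svms(feats, labels, folds=4, seed=0)

    def test_separable_classes_recovered_out_of_fold(self):
        feats, labels = separable_setup(n_pos=20, n_neg=20)
        svms = deepmoa.train_term_svms(feats, labels, folds=4, seed=0)
        au = deepmoa.auroc_by_term(labels.labels["X"], svms.probabilities["X"])
        assert au == 1.0

    def test_probabilities_strictly_inside_unit_interval(self):
        feats, labels = separable_setup(n_pos=18, n_neg=22, seed=3)
        svms = deepmoa.train_term_svms(feats, labels, folds=4, seed=1)
        p = svms.probabilities["X"].to_numpy()
        assert np.all((p > 0.0) & (p < 1.0))

    def test_unknown_drugs_predicted_without_training_on_them(self):
        feats, labels = separable_setup(n_pos=20, n_neg=20)
        labels.known.iloc[-4:] = False
        labels.labels.iloc[-4:] = 0
        svms = deepmoa.train_term_svms(feats, labels, folds=4, seed=0)
        unknown = labels.known[~labels.known].index
        assert svms.probabilities.loc[unknown, "X"].notna().all()
        assert not set(unknown) & set(svms.fold_of.index)

    def test_single_class_folds_skipped_and_flagged(self):
        # 16 positives and only 2 negatives: every split leaves some training
        # fold with fewer than 2 negatives
        feats, labels = separable_setup(n_pos=16, n_neg=2)
        svms = deepmoa.train_term_svms(feats, labels, folds=4, seed=0, min_drugs=16)
        assert len(svms.skipped) > 0
        for term, fold in svms.skipped:
            assert svms.models[term][fold] is None

    def test_label_closure_untouched_by_fold_splitting(self, diamond_graph):
        ann = pd.DataFrame({"drug": [f"d{i}" for i in range(20)],
                            "term": ["C"] * 16 + ["A"] * 4})
        lm = deepmoa.build_label_matrix(ann, diamond_graph)
        before = lm.labels.copy()
        rng = np.random.default_rng(0)
        feats = deepmoa.MoAFeatureMatrix(
            values=rng.normal(size=(20, 2 * len(before.columns))),
            drugs=list(before.index), terms=list(before.columns), k=2,
        )
        deepmoa.train_term_svms(feats, lm, folds=4, seed=0, min_drugs=16)
        pd.testing.assert_frame_equal(lm.labels, before)


def brute_force_auroc(labels, probs):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_hand_example(self):
        au = deepmoa.auroc_by_term([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert au == pytest.approx(0.75)

    def test_perfect_separation_is_one(self):
        assert deepmoa.auroc_by_term([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_class_flagged_undefined(self):
        assert np.isnan(deepmoa.auroc_by_term([1, 1, 1], [0.1, 0.5, 0.9]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = np.round(rng.random(n), 2)  # ties likely
        assert deepmoa.auroc_by_term(labels, probs) == pytest.approx(
            brute_force_auroc(labels, probs)
        )

    def test_by_drug_single_discordant_pair(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        probs = np.array([0.9, 0.8, 0.7, 0.35, 0.4, 0.3, 0.2, 0.1])  # one swap
        au, confusion = deepmoa.auroc_by_drug(labels, probs)
        assert au == pytest.approx(15 / 16)
        assert confusion.sum() == 8
        assert confusion[1, 0] == 1  # the positive predicted below 0.5

    def test_random_probabilities_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=4000)
        probs = rng.random(4000)
        assert deepmoa.auroc_by_term(labels, probs) == pytest.approx(0.5, abs=0.03)


class TestLogitDifferenceRanking:
    def test_concordant_annotation_scores_near_zero(self):
        probs = pd.Series({"A": 0.998, "B": 0.5})
        labels = pd.Series({"A": 1, "B": 0})
        out = deepmoa.rank_by_logit_difference(probs, labels)
        a = out.set_index("term")
        assert abs(a.loc["A", "logit_difference"]) < 1.0
        assert a.loc["B", "logit_difference"] > a.loc["A", "logit_difference"]

    def test_unannotated_high_probability_ranks_top(self):
        probs = pd.Series({"known": 0.95, "novel": 0.9, "quiet": 0.05})
        labels = pd.Series({"known": 1, "novel": 0, "quiet": 0})
        out = deepmoa.rank_by_logit_difference(probs, labels, top_n=2)
        assert out.iloc[0]["term"] == "novel"
        assert len(out) == 2

    def test_ordering_invariant_to_monotone_probability_rescaling(self):
        rng = np.random.default_rng(1)
        probs = pd.Series(rng.uniform(0.05, 0.95, size=12),
                          index=[f"t{i}" for i in range(12)])
        labels = pd.Series(rng.integers(0, 2, size=12), index=probs.index)
        base = deepmoa.rank_by_logit_difference(probs, labels, top_n=12)["term"].tolist()
        # logit-scale shift: strictly monotone map through the same logit
        shifted = 1 / (1 + np.exp(-(np.log(probs / (1 - probs)) + 0.7)))
        out = deepmoa.rank_by_logit_difference(shifted, labels, top_n=12)["term"].tolist()
        assert out == base
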