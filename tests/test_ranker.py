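"""Naive-Bayes evidence scoring: closed forms, oracle equivalence, metrics."""

import itertools
import math

import numpy as np
import pytest

from dgmine.corpus import EvidenceTriple, assemble_triples
from dgmine.ranker import (
    BayesModel,
    evaluate_ranking,
    extract_features,
    fit_model,
    score_evidence,
)

from conftest import make_sentence


def _binary_model(n_pos_f1=7, n_pos=8, n_neg_f1=1, n_neg=8, alpha=1.0, copies=1):
    """Model with P(f=1|+)=(n_pos_f1+1)/(n_pos+2) etc. on `copies` iid features."""
    labeled = []
    for i in range(n_pos):
        labeled.append(({f"f{k}": "1" if i < n_pos_f1 else "0" for k in range(copies)}, "+"))
    for i in range(n_neg):
        labeled.append(({f"f{k}": "1" if i < n_neg_f1 else "0" for k in range(copies)}, "-"))
    return fit_model(labeled, alpha=alpha)


class TestFitModel:
    def test_identical_single_examples_give_symmetric_model(self):
        model = fit_model([({"f": "a"}, "+"), ({"f": "a"}, "-")], alpha=1.0)
        assert model.priors == {"+": 0.5, "-": 0.5}
        raw, norm = score_evidence(model, {"f": "a"})
        assert raw == pytest.approx(0.0)
        assert norm == pytest.approx(0.5)

    def test_separating_feature_approaches_certainty_as_alpha_vanishes(self):
        labeled = [({"f": "1"}, "+")] * 5 + [({"f": "0"}, "-")] * 5
        model = fit_model(labeled, alpha=1e-9)
        assert model.conditional("f", "1", "+") == pytest.approx(1.0, abs=1e-8)
        assert model.conditional("f", "1", "-") == pytest.approx(0.0, abs=1e-8)

    def test_laplace_smoothing_of_category_unseen_in_one_class(self):
        # category "b" seen only in the negative class; K=2 categories
        model = fit_model(
            [({"f": "a"}, "+"), ({"f": "a"}, "+"), ({"f": "a"}, "-"), ({"f": "b"}, "-")],
            alpha=1.0,
        )
        assert model.conditional("f", "b", "+") == pytest.approx((0 + 1) / (2 + 2))

    def test_single_class_training_set_is_fit_error(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_model([({"f": "a"}, "+")])

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_model([({"f": "a"}, "+"), ({"f": "a"}, "-")], alpha=0.0)


class TestScoreEvidence:
    def test_single_informative_feature_closed_form(self):
        # equal priors, P(f=1|+)=0.8, P(f=1|-)=0.2 => raw=ln4, norm=0.8
        model = _binary_model()
        assert model.conditional("f0", "1", "+") == pytest.approx(0.8)
        assert model.conditional("f0", "1", "-") == pytest.approx(0.2)
        raw, norm = score_evidence(model, {"f0": "1"})
        assert raw == pytest.approx(math.log(4))
        assert norm == pytest.approx(0.8)

    def test_two_independent_copies_multiply_odds(self):
        model = _binary_model(copies=2)
        raw, norm = score_evidence(model, {"f0": "1", "f1": "1"})
        assert raw == pytest.approx(2 * math.log(4))
        assert norm == pytest.approx(16 / 17)

    def test_unknown_category_is_smoothed_not_an_error(self):
        model = _binary_model()
        raw, norm = score_evidence(model, {"f0": "never-seen"})
        assert 0.0 < norm < 1.0

    def test_norm_is_sigmoid_of_raw_and_order_preserving(self):
        model = _binary_model(copies=3)
        vectors = [
            {f"f{k}": v for k, v in zip(range(3), bits)}
            for bits in itertools.product("01", repeat=3)
        ]
        scored = [score_evidence(model, fv) for fv in vectors]
        for raw, norm in scored:
            assert norm == pytest.approx(1.0 / (1.0 + math.exp(-raw)))
            assert 0.0 < norm < 1.0
        by_raw = sorted(range(8), key=lambda i: scored[i][0])
        by_norm = sorted(range(8), key=lambda i: scored[i][1])
        assert by_raw == by_norm

    def test_posterior_matches_exhaustive_joint_table(self):
        """Independent oracle: enumerate the full joint P(class, f1..f3)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            labeled = []
            for _ in range(30):
                labeled.append(
                    (
                        {f"f{k}": str(rng.integers(2)) for k in range(3)},
                        "+" if rng.random() < 0.6 else "-",
                    )
                )
            if len({l for _, l in labeled}) < 2:
                continue
            model = fit_model(labeled, alpha=1.0)
            priors = model.priors
            for bits in itertools.product("01", repeat=3):
                fv = {f"f{k}": b for k, b in zip(range(3), bits)}
                joint = {
                    cls: priors[cls]
                    * math.prod(model.conditional(f, fv[f], cls) for f in fv)
                    for cls in "+-"
                }
                posterior = joint["+"] / (joint["+"] + joint["-"])
                _, norm = score_evidence(model, fv)
                assert norm == pytest.approx(posterior, rel=1e-12)

    def test_json_round_trip_preserves_scores(self, tmp_path):
        model = _binary_model(copies=2)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = BayesModel.from_json(p)
        fv = {"f0": "1", "f1": "0"}
        assert score_evidence(back, fv) == score_evidence(model, fv)


class TestEvaluateRanking:
    def test_perfect_separation_gives_auc_one(self):
        ev = evaluate_ranking([0.9, 0.8, 0.3], ["+", "+", "-"])
        assert ev.auc == pytest.approx(1.0)

    def test_interleaved_scores_give_three_quarters(self):
        ev = evaluate_ranking([0.9, 0.4, 0.6, 0.1], ["+", "+", "-", "-"])
        assert ev.auc == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        ev = evaluate_ranking([0.5] * 6, ["+", "-", "+", "-", "+", "-"])
        assert ev.auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(3)
        scores = list(np.round(rng.random(40), 1))  # coarse grid forces ties
        labels = ["+" if rng.random() < 0.5 else "-" for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[1] = "+", "-"
        pos = [s for s, l in zip(scores, labels) if l == "+"]
        neg = [s for s, l in zip(scores, labels) if l == "-"]
        oracle = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        ) / (len(pos) * len(neg))
        assert evaluate_ranking(scores, labels).auc == pytest.approx(oracle)

    def test_f_precision_recall_at_half_cutoff(self):
        ev = evaluate_ranking([0.9, 0.6, 0.4, 0.7], ["+", "-", "+", "+"])
        assert ev.precision == pytest.approx(2 / 3)
        assert ev.recall == pytest.approx(2 / 3)
        assert ev.f_score == pytest.approx(2 / 3)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate_ranking([0.1, 0.2], ["+", "+"])


class TestExtractFeatures:
    KW = {"carcinoma", "tumor"}
    HALLMARK = {"proliferation"}

    def _sentence(self, text, **kw):
        return make_sentence(text, **kw)

    def test_keyword_counts_bin_and_cap(self):
        s = self._sentence(
            "EGFR overexpression drives tumor growth in carcinoma",
            genes=[("EGFR", "1956")],
            diseases=[("carcinoma", "D002277")],
            events=[("gene_expression", "overexpression", "1956")],
        )
        (triple,) = assemble_triples(s)
        fv = extract_features(s, triple, self.KW, self.HALLMARK)
        assert fv["disease_keyword_count_bin"] == "2"
        fv5 = extract_features(
            s, triple, self.KW | {"growth", "drives", "in"}, self.HALLMARK
        )
        assert fv5["disease_keyword_count_bin"] == "3+"

    def test_adjacent_gene_and_trigger_have_zero_distance(self):
        s = self._sentence(
            "EGFR overexpression drives tumor growth in carcinoma",
            genes=[("EGFR", "1956")],
            diseases=[("carcinoma", "D002277")],
            events=[("gene_expression", "overexpression", "1956")],
        )
        (triple,) = assemble_triples(s)
        fv = extract_features(s, triple, self.KW, self.HALLMARK)
        assert fv["gene_event_token_distance_bin"] == "0"
        assert fv["disease_event_token_distance_bin"] == "3+"
        assert fv["negation_cue"] == "0"
        assert fv["etype"] == "gene_expression"
        assert fv["sentence_position_bin"] == "first"

    def test_negation_cue_detected(self):
        s = self._sentence(
            "EGFR mutation was not linked to carcinoma",
            genes=[("EGFR", "1956")],
            diseases=[("carcinoma", "D002277")],
            events=[("mutation", "mutation", "1956")],
        )
        (triple,) = assemble_triples(s)
        fv = extract_features(s, triple, self.KW, self.HALLMARK)
        assert fv["negation_cue"] == "1"

    def test_mismatched_triple_is_consistency_error(self, evidence_sentence):
        foreign = EvidenceTriple("7157", "D001943", "mutation", "OTHER", 3)
        with pytest.raises(ValueError, match="originate"):
            extract_features(evidence_sentence, foreign, self.KW, self.HALLMARK)
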