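"""Bayesian ranking of candidate evidence sentences.

Each (sentence, triple) pair is mapped to a small vector of discrete
features — keyword counts, token distances between mentions and the event
trigger, the event type, a negation cue, and simple positional features —
and scored by a naive-Bayes classifier trained on labelled examples.

The raw score is the log posterior odds

    raw = log P(+) + sum_f log P(f|+) - log P(-) - sum_f log P(f|-)

and the normalized score is its sigmoid, a value in (0, 1) that orders
sentences identically to the raw score.  Laplace smoothing with pseudo-count
``alpha`` keeps every conditional strictly positive; a feature category never
seen in training is treated as an extra smoothed-unseen category rather than
an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .corpus import EvidenceTriple, Sentence

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_NEGATION_CUES",
    "FeatureVector",
    "BayesModel",
    "ScoredEvidence",
    "RankingEvaluation",
    "extract_features",
    "fit_model",
    "score_evidence",
    "evaluate_ranking",
]

FeatureVector = dict  # feature name -> category (strings throughout)

FEATURE_NAMES: tuple[str, ...] = (
    "disease_keyword_count_bin",
    "hallmark_keyword_count_bin",
    "gene_event_token_distance_bin",
    "disease_event_token_distance_bin",
    "etype",
    "negation_cue",
    "gene_mention_count_bin",
    "sentence_position_bin",
)

DEFAULT_NEGATION_CUES = frozenset(
    {"no", "not", "without", "absent", "lack", "neither", "nor"}
)

_COUNT_BINS = ("0", "1", "2", "3+")


def _bin_count(n: int) -> str:
    return _COUNT_BINS[n] if n < 3 else "3+"


def _tokenize_with_spans(text: str) -> list[tuple[int, int, str]]:
    spans = []
    i = 0
    for tok in text.split():
        start = text.index(tok, i)
        end = start + len(tok)
        spans.append((start, end, tok))
        i = end
    return spans


def _token_distance(
    spans: list[tuple[int, int, str]], a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Whitespace tokens lying strictly between two character spans."""
    lo, hi = (a, b) if a[0] <= b[0] else (b, a)
    if hi[0] < lo[1]:  # overlapping spans
        return 0
    return sum(1 for s, e, _ in spans if s >= lo[1] and e <= hi[0])


def _count_keywords(tokens: list[str], keywords: set[str]) -> int:
    kw = {k.lower() for k in keywords}
    return sum(1 for t in tokens if t.lower().strip(".,;:()[]") in kw)


def extract_features(
    sentence: Sentence,
    triple: EvidenceTriple,
    disease_keywords: set[str],
    hallmark_keywords: set[str],
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES,
    n_doc_sentences: int | None = None,
) -> FeatureVector:
    """Extract the discrete feature vector for one (sentence, triple) pair.

    Keyword counting is case-insensitive whole-token matching.  Token
    distances are whitespace tokens strictly between the nearest boundaries of
    the mention span and the trigger span of the triple's event (minimum over
    matching events/mentions).  The sentence position bin is ``first`` for
    sid 0, ``last`` for the final sentence when the document length is known,
    else ``middle``.
    """
    if (triple.doc_id, triple.sid) != (sentence.doc_id, sentence.sid):
        raise ValueError(
            f"triple {triple} does not originate from sentence "
            f"({sentence.doc_id}, {sentence.sid})"
        )
    spans = _tokenize_with_spans(sentence.text)
    tokens = [t for _, _, t in spans]

    events = [
        e for e in sentence.events if e.etype == triple.etype and e.theme_gene == triple.gene
    ]
    gene_spans = [
        (m.start, m.end) for m in sentence.gene_mentions if m.norm_id == triple.gene
    ]
    dz_spans = [
        (m.start, m.end) for m in sentence.disease_mentions if m.norm_id == triple.disease
    ]
    if not events or not gene_spans or not dz_spans:
        raise ValueError("triple's gene/disease/event annotations not found in sentence")

    gene_dist = min(
        _token_distance(spans, g, (e.trigger_start, e.trigger_end))
        for e in events
        for g in gene_spans
    )
    dz_dist = min(
        _token_distance(spans, d, (e.trigger_start, e.trigger_end))
        for e in events
        for d in dz_spans
    )

    if sentence.sid == 0:
        pos = "first"
    elif n_doc_sentences is not None and sentence.sid == n_doc_sentences - 1:
        pos = "last"
    else:
        pos = "middle"

    return {
        "disease_keyword_count_bin": _bin_count(_count_keywords(tokens, disease_keywords)),
        "hallmark_keyword_count_bin": _bin_count(_count_keywords(tokens, hallmark_keywords)),
        "gene_event_token_distance_bin": _bin_count(gene_dist),
        "disease_event_token_distance_bin": _bin_count(dz_dist),
        "etype": triple.etype,
        "negation_cue": (
            "1" if any(t.lower().strip(".,;:()[]") in negation_cues for t in tokens) else "0"
        ),
        "gene_mention_count_bin": _bin_count(len(sentence.gene_mentions)),
        "sentence_position_bin": pos,
    }


# ---------------------------------------------------------------------------
# naive-Bayes model

POS, NEG = "+", "-"


@dataclass
class BayesModel:
    """Naive-Bayes classifier over discrete features with Laplace smoothing.

    ``feature_counts[f][cls][cat]`` holds training counts; ``categories[f]``
    is the set of categories observed for feature ``f`` across both classes.
    Conditionals are (count + alpha) / (n_cls + alpha * K_f) with K_f the
    category count; a category absent from training uses K_f + 1 in the
    denominator for both classes (one shared unseen slot).
    """

    alpha: float
    class_counts: dict[str, int]
    feature_counts: dict[str, dict[str, dict[str, int]]]
    categories: dict[str, list[str]] = field(default_factory=dict)

    @property
    def priors(self) -> dict[str, float]:
        n = sum(self.class_counts.values())
        return {c: self.class_counts[c] / n for c in (POS, NEG)}

    def conditional(self, feature: str, category: str, cls: str) -> float:
        cats = self.categories[feature]
        k = len(cats) if category in cats else len(cats) + 1
        cnt = self.feature_counts[feature][cls].get(category, 0)
        return (cnt + self.alpha) / (self.class_counts[cls] + self.alpha * k)

    def log_odds(self, fv: FeatureVector) -> float:
        pr = self.priors
        raw = math.log(pr[POS]) - math.log(pr[NEG])
        for f in self.feature_counts:
            if f not in fv:
                continue
            raw += math.log(self.conditional(f, fv[f], POS))
            raw -= math.log(self.conditional(f, fv[f], NEG))
        return raw

    # -- JSON serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "class_counts": self.class_counts,
            "feature_counts": self.feature_counts,
            "categories": self.categories,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BayesModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            alpha=payload["alpha"],
            class_counts=payload["class_counts"],
            feature_counts=payload["feature_counts"],
            categories=payload["categories"],
        )


def fit_model(labeled: list[tuple[FeatureVector, str]], alpha: float = 1.0) -> BayesModel:
    """Fit priors and smoothed per-feature conditionals from labelled vectors."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    labels = {lbl for _, lbl in labeled}
    if labels != {POS, NEG}:
        raise ValueError(f"training set must contain both classes, got {sorted(labels)}")
    class_counts = {POS: 0, NEG: 0}
    feature_counts: dict[str, dict[str, dict[str, int]]] = {}
    categories: dict[str, set[str]] = {}
    features = sorted({f for fv, _ in labeled for f in fv})
    for f in features:
        feature_counts[f] = {POS: {}, NEG: {}}
        categories[f] = set()
    for fv, lbl in labeled:
        class_counts[lbl] += 1
        for f in features:
            if f in fv:
                cat = str(fv[f])
                tbl = feature_counts[f][lbl]
                tbl[cat] = tbl.get(cat, 0) + 1
                categories[f].add(cat)
    return BayesModel(
        alpha=alpha,
        class_counts=class_counts,
        feature_counts=feature_counts,
        categories={f: sorted(c) for f, c in categories.items()},
    )


@dataclass(frozen=True)
class ScoredEvidence:
    """An evidence triple with its raw (log-odds) and sigmoid-normalized score."""

    triple: EvidenceTriple
    raw_score: float
    norm_score: float


def score_evidence(model: BayesModel, fv: FeatureVector, triple: EvidenceTriple | None = None):
    """Score a feature vector; returns (raw, norm) or a ScoredEvidence.

    norm = sigmoid(raw) lies strictly in (0, 1) and is monotone in raw, so
    either score induces the same ranking.
    """
    raw = model.log_odds(fv)
    norm = float(expit(raw))
    if triple is None:
        return raw, norm
    return ScoredEvidence(triple, raw, norm)


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class RankingEvaluation:
    auc: float
    f_score: float
    precision: float
    recall: float


def evaluate_ranking(scores: list[float], labels: list[str]) -> RankingEvaluation:
    """AUC plus F/precision/recall at the 0.5 normalized-score cutoff.

    AUC is the probability that a positive outranks a negative, ties counting
    one half.  Predicted-positive means score >= 0.5; precision is 0 when
    nothing is predicted positive.
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    labelset = set(labels)
    if labelset != {POS, NEG}:
        raise ValueError("evaluation requires both positive and negative labels")
    y = [1 if l == POS else 0 for l in labels]
    auc = float(roc_auc_score(y, scores))
    tp = sum(1 for s, l in zip(scores, y) if s >= 0.5 and l == 1)
    fp = sum(1 for s, l in zip(scores, y) if s >= 0.5 and l == 0)
    fn = sum(1 for s, l in zip(scores, y) if s < 0.5 and l == 1)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return RankingEvaluation(auc=auc, f_score=f, precision=precision, recall=recall)
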