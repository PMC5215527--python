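"""Ranking disease-related genes by aggregating scored evidence.

Five measures rank the genes of a disease:

1. ``n_abstracts``  — number of distinct abstracts with evidence sentences;
2. ``n_sentences``  — number of distinct evidence sentences;
3. ``max_score``    — highest normalized evidence score;
4. ``sum_norm``     — sum of normalized scores;
5. ``mean_norm``    — mean of normalized scores.

Sentence identity is (doc_id, sid) and abstract identity is doc_id: several
triples of one gene inside one sentence (e.g. two event types) count that
sentence once, and the score kept for it is the maximum over its triples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ranker import ScoredEvidence

__all__ = [
    "MEASURES",
    "GeneEvidenceSummary",
    "summarize_gene_evidence",
    "rank_genes",
    "filter_evidence_by_threshold",
    "write_ranking_tsv",
]

MEASURES: tuple[str, ...] = ("n_abstracts", "n_sentences", "max_score", "sum_norm", "mean_norm")


@dataclass
class GeneEvidenceSummary:
    """Per-(disease, gene) evidence aggregation feeding the five measures."""

    disease: str
    gene: str
    abstract_ids: set[str]
    norm_scores: list[float]  # one per distinct evidence sentence

    @property
    def n_abstracts(self) -> int:
        return len(self.abstract_ids)

    @property
    def n_sentences(self) -> int:
        return len(self.norm_scores)

    @property
    def max_score(self) -> float:
        return max(self.norm_scores)

    @property
    def sum_norm(self) -> float:
        return sum(self.norm_scores)

    @property
    def mean_norm(self) -> float:
        return sum(self.norm_scores) / len(self.norm_scores)

    def value(self, measure: str) -> float:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; valid: {', '.join(MEASURES)}")
        return float(getattr(self, measure))


def summarize_gene_evidence(
    evidence: list[ScoredEvidence], disease: str
) -> list[GeneEvidenceSummary]:
    """Aggregate scored evidence of one disease into per-gene summaries."""
    per_gene_sentences: dict[str, dict[tuple[str, int], float]] = {}
    for ev in evidence:
        if ev.triple.disease != disease:
            raise ValueError(
                f"evidence for disease {ev.triple.disease!r}, expected {disease!r}"
            )
        key = ev.triple.sentence_key
        tbl = per_gene_sentences.setdefault(ev.triple.gene, {})
        tbl[key] = max(tbl.get(key, 0.0), ev.norm_score)
    out = []
    for gene in sorted(per_gene_sentences):
        tbl = per_gene_sentences[gene]
        out.append(
            GeneEvidenceSummary(
                disease=disease,
                gene=gene,
                abstract_ids={doc for doc, _ in tbl},
                norm_scores=[tbl[k] for k in sorted(tbl)],
            )
        )
    return out


def rank_genes(
    summaries: list[GeneEvidenceSummary], measure: str
) -> list[tuple[str, float, int]]:
    """Rank genes descending by one measure.

    Ties on the measure value are broken by (n_sentences descending, gene id
    lexicographic) for a deterministic order, and tied values share the
    minimum rank (competition ranking).
    """
    if not summaries:
        raise ValueError("summaries must be non-empty")
    scored = [(s.gene, s.value(measure), s.n_sentences) for s in summaries]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    out: list[tuple[str, float, int]] = []
    for i, (gene, val, _) in enumerate(scored):
        rank = out[i - 1][2] if i > 0 and val == out[i - 1][1] else i + 1
        out.append((gene, val, rank))
    return out


def filter_evidence_by_threshold(
    evidence: list[ScoredEvidence], t: float
) -> list[ScoredEvidence]:
    """Keep evidence with norm_score >= t, preserving order.  t in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [ev for ev in evidence if ev.norm_score >= t]


def write_ranking_tsv(path, disease: str, summaries: list[GeneEvidenceSummary], measure: str) -> None:
    """Write the per-gene ranking table for one disease and one measure."""
    ranked = rank_genes(summaries, measure)
    by_gene = {s.gene: s for s in summaries}
    with open(path, "a", encoding="utf-8") as fh:
        if fh.tell() == 0:
            fh.write(
                "disease_id\tgene_id\trank\tmeasure\tvalue\tn_abstracts\t"
                "n_sentences\tmax_score\tsum_norm\tmean_norm\n"
            )
        for gene, value, rank in ranked:
            s = by_gene[gene]
            fh.write(
                f"{disease}\t{gene}\t{rank}\t{measure}\t{value:.6f}\t"
                f"{s.n_abstracts}\t{s.n_sentences}\t{s.max_score:.6f}\t"
                f"{s.sum_norm:.6f}\t{s.mean_norm:.6f}\n"
            )
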