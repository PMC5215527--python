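"""Glue between the corpus, the sentence classifier and the gene ranker."""

from __future__ import annotations

from .corpus import Sentence, EvidenceTriple, assemble_triples
from .ranker import BayesModel, ScoredEvidence, extract_features, score_evidence

__all__ = ["score_corpus", "write_evidence_tsv", "read_evidence_tsv"]

#: small default keyword lists used when no expanded lists are supplied
DEFAULT_DISEASE_KEYWORDS = frozenset(
    {"patients", "tumor", "carcinoma", "syndrome", "disease", "disorder"}
)
DEFAULT_HALLMARK_KEYWORDS = frozenset(
    {"proliferation", "apoptosis", "angiogenesis", "metastasis", "outcome", "increased"}
)


def score_corpus(
    sentences: list[Sentence],
    model: BayesModel,
    disease_keywords: set[str] = DEFAULT_DISEASE_KEYWORDS,
    hallmark_keywords: set[str] = DEFAULT_HALLMARK_KEYWORDS,
) -> list[ScoredEvidence]:
    """Assemble all evidence triples of a corpus and score each one."""
    doc_len: dict[str, int] = {}
    for s in sentences:
        doc_len[s.doc_id] = max(doc_len.get(s.doc_id, 0), s.sid + 1)
    out: list[ScoredEvidence] = []
    for s in sentences:
        for triple in assemble_triples(s):
            fv = extract_features(
                s,
                triple,
                disease_keywords,
                hallmark_keywords,
                n_doc_sentences=doc_len[s.doc_id],
            )
            out.append(score_evidence(model, fv, triple))
    out.sort(key=lambda ev: (ev.triple, -ev.norm_score))
    return out


def write_evidence_tsv(evidence: list[ScoredEvidence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdisease\tetype\tdoc_id\tsid\traw_score\tnorm_score\n")
        for ev in evidence:
            t = ev.triple
            fh.write(
                f"{t.gene}\t{t.disease}\t{t.etype}\t{t.doc_id}\t{t.sid}\t"
                f"{ev.raw_score:.6f}\t{ev.norm_score:.6f}\n"
            )


def read_evidence_tsv(path) -> list[ScoredEvidence]:
    out: list[ScoredEvidence] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["gene", "disease", "etype", "doc_id", "sid"]:
            raise ValueError(f"unexpected evidence table header: {header}")
        for line in fh:
            g, d, e, doc, sid, raw, norm = line.rstrip("\n").split("\t")
            out.append(
                ScoredEvidence(
                    EvidenceTriple(g, d, e, doc, int(sid)), float(raw), float(norm)
                )
            )
    return out
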