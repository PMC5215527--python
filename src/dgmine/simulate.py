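"""Seeded generators for every input the pipeline consumes.

The generators make the whole system exercisable without any external
download: an annotated sentence corpus with *planted* gene-disease-event
associations and a truth table of their expected sentence counts; labelled
feature vectors with controlled class separation for the evidence
classifier; interaction networks; GO annotations optionally concentrated on
network modules; reference gene sets with controlled overlap; word
embeddings with planted analogy structure; and a disease vocabulary.

Every generator is a pure function of its arguments: the same seed yields
byte-identical files.  Sentence text is templated natural-language-like
filler — downstream features are offset- and count-based, not parsed, so
surface realism is not required and real-literature token statistics are
not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .corpus import (
    EVENT_TYPES,
    DiseaseVocabulary,
    EventAnnotation,
    Mention,
    Sentence,
)
from .keywords import EmbeddingTable
from .network import GOAnnotationTable, InteractionNetwork
from .refsets import DiseaseGeneSet

__all__ = [
    "GeneratorConfig",
    "TRIGGER_WORDS",
    "gene_name",
    "disease_id",
    "generate_corpus",
    "write_truth_tsv",
    "generate_labeled_sentences",
    "generate_network",
    "generate_go_annotations",
    "generate_reference_sets",
    "generate_module_study",
    "generate_embeddings",
    "generate_disease_vocabulary",
]

#: one single-token trigger word per event type
TRIGGER_WORDS: dict[str, str] = {
    "gene_expression": "overexpression",
    "transcription": "transcription",
    "regulation": "dysregulation",
    "binding": "binding",
    "localization": "mislocalization",
    "phosphorylation": "phosphorylation",
    "protein_catabolism": "degradation",
    "hydroxylation": "hydroxylation",
    "ubiquitination": "ubiquitination",
    "dna_methylation": "hypermethylation",
    "glycosylation": "glycosylation",
    "acetylation": "acetylation",
    "methylation": "methylation",
    "catalysis": "catalysis",
    "mutation": "mutation",
}


def gene_name(i: int) -> str:
    return f"G{i:03d}"


def disease_id(i: int) -> str:
    return f"D{i:06d}"


def disease_name(i: int) -> str:
    return f"disease{i}"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    The default planted associations form a frequency gradient: ten genes on
    the first disease with intensities 2, 4, ..., 20 evidence sentences
    (event types cycling through the vocabulary), plus three moderate
    associations for every other disease so that each disease carries an
    event distribution.  ``n_noise_events`` adds untracked random event
    sentences; ``decoy_fraction`` controls sentences that can never yield a
    triple (gene-only, disease-only, or gene+disease without an event).
    """

    seed: int = 0
    n_genes: int = 40
    n_diseases: int = 6
    n_documents: int = 150
    planted: list[tuple[str, str, str, int]] | None = None
    decoy_fraction: float = 0.4
    n_noise_events: int = 0
    gradient_size: int = 10
    gradient_step: int = 2

    def resolved_planted(self) -> list[tuple[str, str, str, int]]:
        if self.planted is not None:
            return list(self.planted)
        rng = np.random.default_rng(self.seed + 1)
        planted: list[tuple[str, str, str, int]] = []
        for i in range(self.gradient_size):
            planted.append(
                (
                    gene_name(i),
                    disease_id(0),
                    EVENT_TYPES[i % len(EVENT_TYPES)],
                    self.gradient_step * (i + 1),
                )
            )
        for d in range(1, self.n_diseases):
            genes = rng.choice(
                np.arange(self.n_genes), size=min(3, self.n_genes), replace=False
            )
            for g in genes:
                planted.append(
                    (
                        gene_name(int(g)),
                        disease_id(d),
                        EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))],
                        int(rng.integers(1, 7)),
                    )
                )
        return planted


# ---------------------------------------------------------------------------
# sentence templating

class _Builder:
    """Concatenates text parts while recording mention/trigger spans."""

    def __init__(self) -> None:
        self.text = ""
        self.genes: list[Mention] = []
        self.diseases: list[Mention] = []
        self.events: list[EventAnnotation] = []

    def lit(self, s: str) -> "_Builder":
        self.text += s
        return self

    def gene(self, symbol: str) -> "_Builder":
        start = len(self.text)
        self.text += symbol
        self.genes.append(Mention("gene", start, len(self.text), symbol, symbol))
        return self

    def disease(self, name: str, did: str) -> "_Builder":
        start = len(self.text)
        self.text += name
        self.diseases.append(Mention("disease", start, len(self.text), name, did))
        return self

    def trigger(self, etype: str, theme_gene: str) -> "_Builder":
        word = TRIGGER_WORDS[etype]
        start = len(self.text)
        self.text += word
        self.events.append(EventAnnotation(etype, start, len(self.text), theme_gene))
        return self


def _planted_sentence(g: str, did: str, etype: str, template: int) -> _Builder:
    b = _Builder()
    dn = disease_name(int(did[1:]))
    if template == 0:
        b.gene(g).lit(" ").trigger(etype, g).lit(" is associated with ").disease(dn, did)
    elif template == 1:
        b.lit("Aberrant ").trigger(etype, g).lit(" of ").gene(g).lit(
            " was observed in "
        ).disease(dn, did).lit(" patients")
    else:
        b.lit("In ").disease(dn, did).lit(" , increased ").trigger(etype, g).lit(
            " of "
        ).gene(g).lit(" correlates with outcome")
    return b


def _decoy_sentence(rng: np.random.Generator, n_genes: int, n_diseases: int) -> _Builder:
    kind = int(rng.integers(3))
    b = _Builder()
    g = gene_name(int(rng.integers(n_genes)))
    d = int(rng.integers(n_diseases))
    if kind == 0:  # gene + event, no disease
        etype = EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))]
        b.gene(g).lit(" ").trigger(etype, g).lit(" was measured in cell lines")
    elif kind == 1:  # disease only
        b.lit("Patients with ").disease(disease_name(d), disease_id(d)).lit(" were enrolled")
    else:  # gene + disease, no event
        b.gene(g).lit(" was studied in ").disease(disease_name(d), disease_id(d))
    return b


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Sentence], list[dict]]:
    """Emit a corpus with planted associations plus decoys and noise.

    Returns (sentences, truth) where the truth table rows
    ``{"gene", "disease", "etype", "n_sentences"}`` list each planted
    association and the number of sentences actually emitted for it.
    """
    if cfg.n_documents < 1:
        raise ValueError("n_documents must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    planted = cfg.resolved_planted()
    builders: list[_Builder] = []
    truth = []
    for g, did, etype, intensity in planted:
        if intensity < 1:
            raise ValueError("planted intensity must be >= 1")
        for _ in range(intensity):
            builders.append(_planted_sentence(g, did, etype, int(rng.integers(3))))
        truth.append({"gene": g, "disease": did, "etype": etype, "n_sentences": intensity})
    for _ in range(cfg.n_noise_events):
        g = gene_name(int(rng.integers(cfg.n_genes)))
        d = disease_id(int(rng.integers(cfg.n_diseases)))
        etype = EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))]
        builders.append(_planted_sentence(g, d, etype, int(rng.integers(3))))
    n_decoys = int(round(cfg.decoy_fraction * len(builders)))
    for _ in range(n_decoys):
        builders.append(_decoy_sentence(rng, cfg.n_genes, cfg.n_diseases))

    order = rng.permutation(len(builders))
    doc_of = rng.integers(0, cfg.n_documents, size=len(builders))
    next_sid: dict[int, int] = {}
    sentences: list[Sentence] = []
    for pos in order:
        b = builders[int(pos)]
        doc = int(doc_of[int(pos)])
        sid = next_sid.get(doc, 0)
        next_sid[doc] = sid + 1
        sentences.append(
            Sentence(
                doc_id=f"PM{doc:06d}",
                sid=sid,
                text=b.text,
                gene_mentions=b.genes,
                disease_mentions=b.diseases,
                events=b.events,
            )
        )
    sentences.sort(key=lambda s: (s.doc_id, s.sid))
    for s in sentences:
        s.validate()
    return sentences, truth


def write_truth_tsv(truth: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdisease\tetype\tn_sentences\n")
        for row in truth:
            fh.write(f"{row['gene']}\t{row['disease']}\t{row['etype']}\t{row['n_sentences']}\n")


# ---------------------------------------------------------------------------
# labelled feature vectors for the evidence classifier

_COUNT_CATS = ("0", "1", "2", "3+")

#: class-conditional categorical distributions for the *separated* condition
SEPARATED_POSITIVE: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "disease_keyword_count_bin": (_COUNT_CATS, (0.10, 0.20, 0.30, 0.40)),
    "hallmark_keyword_count_bin": (_COUNT_CATS, (0.15, 0.25, 0.30, 0.30)),
    "gene_event_token_distance_bin": (_COUNT_CATS, (0.50, 0.30, 0.15, 0.05)),
    "disease_event_token_distance_bin": (_COUNT_CATS, (0.40, 0.30, 0.20, 0.10)),
    "negation_cue": (("0", "1"), (0.90, 0.10)),
    "etype": (EVENT_TYPES, tuple([1 / 15] * 15)),
    "gene_mention_count_bin": (_COUNT_CATS, (0.05, 0.60, 0.25, 0.10)),
    "sentence_position_bin": (("first", "middle", "last"), (0.25, 0.60, 0.15)),
}

SEPARATED_NEGATIVE: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "disease_keyword_count_bin": (_COUNT_CATS, (0.60, 0.25, 0.10, 0.05)),
    "hallmark_keyword_count_bin": (_COUNT_CATS, (0.55, 0.25, 0.12, 0.08)),
    "gene_event_token_distance_bin": (_COUNT_CATS, (0.10, 0.20, 0.30, 0.40)),
    "disease_event_token_distance_bin": (_COUNT_CATS, (0.15, 0.25, 0.30, 0.30)),
    "negation_cue": (("0", "1"), (0.60, 0.40)),
    "etype": (EVENT_TYPES, tuple([1 / 15] * 15)),
    "gene_mention_count_bin": (_COUNT_CATS, (0.05, 0.60, 0.25, 0.10)),
    "sentence_position_bin": (("first", "middle", "last"), (0.25, 0.60, 0.15)),
}


def generate_labeled_sentences(
    n: int,
    seed: int,
    separation: str = "separated",
    pos_dists=None,
    neg_dists=None,
) -> list[tuple[dict, str]]:
    """Draw ``n`` labelled feature vectors (balanced classes, shuffled).

    ``separation="separated"`` uses the module's class-separated default
    distributions; ``"identical"`` draws both classes from the negative
    distributions, making the classes indistinguishable.  Explicit
    ``pos_dists``/``neg_dists`` override either choice.
    """
    if n == 0:
        return []
    if separation not in ("separated", "identical"):
        raise ValueError("separation must be 'separated' or 'identical'")
    pos = pos_dists or (SEPARATED_POSITIVE if separation == "separated" else SEPARATED_NEGATIVE)
    neg = neg_dists or SEPARATED_NEGATIVE
    rng = np.random.default_rng(seed)
    labels = ["+"] * (n // 2 + n % 2) + ["-"] * (n // 2)
    rng.shuffle(labels)
    out = []
    for lbl in labels:
        dists = pos if lbl == "+" else neg
        fv = {
            f: cats[int(rng.choice(len(cats), p=np.asarray(probs) / np.sum(probs)))]
            for f, (cats, probs) in dists.items()
        }
        out.append((fv, lbl))
    return out


# ---------------------------------------------------------------------------
# networks, GO annotations, reference sets

def generate_network(
    n: int,
    seed: int,
    model: str = "er",
    p: float = 0.1,
    m: int = 2,
    names=gene_name,
) -> InteractionNetwork:
    """Seeded Erdos-Renyi (``model="er"``) or Barabasi-Albert (``"ba"``) graph."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if model == "er":
        if not 0.0 <= p <= 1.0:
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif model == "ba":
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError("model must be 'er' or 'ba'")
    g = nx.relabel_nodes(g, {i: names(i) for i in g.nodes})
    g.add_nodes_from(names(i) for i in range(n))
    return InteractionNetwork(graph=g)


def generate_go_annotations(
    genes: list[str],
    seed: int,
    n_terms_per_aspect: int = 6,
    term_size_range: tuple[int, int] = (2, 8),
    modules: list[list[str]] | None = None,
    aspects=("BP", "CC", "MF"),
) -> GOAnnotationTable:
    """Assign genes to GO terms with a uniform term-size distribution.

    With ``modules`` given, each term draws its genes from a single module,
    which concentrates functional similarity inside network modules.
    """
    lo, hi = term_size_range
    if lo < 1:
        raise ValueError("term sizes must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    term_idx = 0
    for aspect in aspects:
        for _ in range(n_terms_per_aspect * (len(modules) if modules else 1)):
            pool = list(modules[term_idx % len(modules)]) if modules else list(genes)
            size = min(int(rng.integers(lo, hi + 1)), len(pool))
            members = rng.choice(np.asarray(pool, dtype=object), size=size, replace=False)
            term = f"GO:{term_idx:07d}"
            rows.extend((str(g), term, aspect) for g in members)
            term_idx += 1
    return GOAnnotationTable(rows)


def generate_reference_sets(
    disease_sets: dict[str, set[str]],
    overlap_fraction: float,
    seed: int,
    novel_prefix: str = "REF",
) -> list[DiseaseGeneSet]:
    """Reference gene sets sharing a controlled fraction with each disease set.

    Each reference keeps round(overlap_fraction * |set|) genes of the disease
    set and pads with novel identifiers to the original size.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    novel_i = 0
    for d in sorted(disease_sets):
        genes = sorted(disease_sets[d])
        n_shared = int(round(overlap_fraction * len(genes)))
        shared = list(
            rng.choice(np.asarray(genes, dtype=object), size=n_shared, replace=False)
        )
        ref = set(map(str, shared))
        while len(ref) < len(genes):
            ref.add(f"{novel_prefix}{novel_i:04d}")
            novel_i += 1
        out.append(DiseaseGeneSet(d, "synthetic reference", ref))
    return out


# ---------------------------------------------------------------------------
# module-structured study (disease modules on a planted-partition network)

def generate_module_study(
    seed: int,
    n_modules: int = 6,
    module_size: int = 25,
    p_in: float = 0.25,
    p_out: float = 0.01,
    genes_per_disease: int = 12,
    pair_overlap: float = 0.5,
    terms_per_module: int = 5,
) -> dict:
    """Planted-partition network with module-resident disease pairs.

    Per module, two diseases share ``pair_overlap`` of their genes (a
    high-overlap pair); diseases from different modules are disjoint.  GO
    terms are concentrated on modules, so functional similarity is high
    exactly where network separation is low.  Returns a dict with keys
    ``network``, ``disease_sets``, ``go``, ``high_c_pairs``,
    ``disjoint_pairs``, ``modules``.
    """
    rng = np.random.default_rng(seed)
    g = nx.planted_partition_graph(n_modules, module_size, p_in, p_out, seed=seed)
    mapping = {i: gene_name(i) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    modules = [
        [gene_name(i) for i in range(k * module_size, (k + 1) * module_size)]
        for k in range(n_modules)
    ]
    net = InteractionNetwork(graph=g)

    disease_sets: dict[str, set[str]] = {}
    high_c_pairs: list[tuple[str, str]] = []
    for k, module in enumerate(modules):
        pool = np.asarray(module, dtype=object)
        first = set(map(str, rng.choice(pool, size=genes_per_disease, replace=False)))
        n_shared = int(round(pair_overlap * genes_per_disease))
        shared = rng.choice(np.asarray(sorted(first), dtype=object), size=n_shared, replace=False)
        rest_pool = np.asarray(sorted(set(module) - first), dtype=object)
        rest = rng.choice(rest_pool, size=genes_per_disease - n_shared, replace=False)
        second = set(map(str, shared)) | set(map(str, rest))
        da, db = disease_id(2 * k), disease_id(2 * k + 1)
        disease_sets[da] = first
        disease_sets[db] = second
        high_c_pairs.append((da, db))
    disjoint_pairs = [
        (disease_id(2 * k), disease_id(2 * ((k + 1) % n_modules)))
        for k in range(n_modules)
    ]
    go = generate_go_annotations(
        [n for m in modules for n in m],
        seed=seed + 7,
        n_terms_per_aspect=terms_per_module,
        modules=modules,
    )
    return {
        "network": net,
        "disease_sets": disease_sets,
        "go": go,
        "high_c_pairs": high_c_pairs,
        "disjoint_pairs": disjoint_pairs,
        "modules": modules,
    }


# ---------------------------------------------------------------------------
# embeddings and disease vocabulary

def generate_embeddings(
    seed: int,
    seed_pairs: tuple[tuple[str, str], ...] = (("cancer", "proliferation"),),
    disease_word: str = "hypertension",
    planted_terms: tuple[str, ...] = ("vasoconstriction",),
    dim: int = 16,
    n_background: int = 30,
) -> EmbeddingTable:
    """Embeddings whose planted terms sit exactly at their analogy points.

    For seed pair i, ``planted_terms[i]`` receives the vector
    v(source) - v(related) + v(disease_word), so the printed analogy query
    recovers it with cosine similarity 1.
    """
    if len(planted_terms) != len(seed_pairs):
        raise ValueError("one planted term per seed pair required")
    rng = np.random.default_rng(seed)
    words: list[str] = []
    vecs: list[np.ndarray] = []

    def add(word: str, vec: np.ndarray) -> None:
        words.append(word)
        vecs.append(vec)

    base: dict[str, np.ndarray] = {}
    for src, rel in seed_pairs:
        for w in (src, rel):
            if w not in base:
                base[w] = rng.normal(size=dim)
                add(w, base[w])
    base[disease_word] = rng.normal(size=dim)
    add(disease_word, base[disease_word])
    for (src, rel), term in zip(seed_pairs, planted_terms):
        add(term, base[src] - base[rel] + base[disease_word])
    for i in range(n_background):
        add(f"term{i:03d}", rng.normal(size=dim))
    return EmbeddingTable(words, np.vstack(vecs))


def generate_disease_vocabulary(
    n_diseases: int, seed: int, include_animal: bool = False
) -> DiseaseVocabulary:
    """MeSH-style vocabulary with random top-level tree numbers (C22 optional)."""
    rng = np.random.default_rng(seed)
    tops = [f"C{i:02d}" for i in range(1, 27) if include_animal or i != 22]
    entries: dict[str, dict] = {}
    for i in range(n_diseases):
        n_trees = int(rng.integers(1, 3))
        trees = [
            f"{tops[int(rng.integers(len(tops)))]}.{int(rng.integers(100, 999))}"
            for _ in range(n_trees)
        ]
        entries[disease_id(i)] = {
            "name": disease_name(i),
            "synonyms": [f"{disease_name(i)} syndrome"],
            "parent_id": None,
            "tree_numbers": trees,
        }
    return DiseaseVocabulary(entries)
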