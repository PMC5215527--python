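"""Domain model for annotated sentence corpora and evidence-triple assembly.

A corpus is a set of abstract sentences annotated with gene mentions, disease
mentions and biological events.  A sentence supports a gene-disease
relationship when a gene mention is the *theme* of a biological event and a
disease mention co-occurs in the same sentence; such sentences are the unit of
evidence throughout the package.  Fifteen event types are recognised: the
seven core BioNLP types, seven epigenetics/post-translational-modification
types (each merged with its reverse reaction), and mutation.

The on-disk corpus format is JSON Lines, one document-sentence record per
line; the disease vocabulary is a flat TSV keyed by MeSH-style identifiers
with tree numbers driving the mapping onto top-level disease categories.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "EVENT_TYPES",
    "CORE_EVENT_TYPES",
    "EPI_EVENT_TYPES",
    "ANIMAL_DISEASE_CATEGORY",
    "Mention",
    "EventAnnotation",
    "Sentence",
    "EvidenceTriple",
    "DiseaseVocabulary",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "annotate_sentence",
    "assemble_triples",
    "map_to_general_categories",
]

CORE_EVENT_TYPES: tuple[str, ...] = (
    "gene_expression",
    "transcription",
    "regulation",
    "binding",
    "localization",
    "phosphorylation",
    "protein_catabolism",
)

EPI_EVENT_TYPES: tuple[str, ...] = (
    "hydroxylation",
    "ubiquitination",
    "dna_methylation",
    "glycosylation",
    "acetylation",
    "methylation",
    "catalysis",
)

#: The closed 15-type event vocabulary (7 core + 7 EPI + mutation).
EVENT_TYPES: tuple[str, ...] = CORE_EVENT_TYPES + EPI_EVENT_TYPES + ("mutation",)

_EVENT_TYPE_SET = frozenset(EVENT_TYPES)

#: MeSH top-level code for the animal-disease category, excluded from analyses.
ANIMAL_DISEASE_CATEGORY = "C22"


class CorpusError(ValueError):
    """Raised for malformed corpus files or invariant violations."""


@dataclass(frozen=True)
class Mention:
    """A gene or disease name occurrence in a sentence.

    Offsets are 0-based, half-open, character-based.  ``norm_id`` is the
    normalized identifier (an opaque gene id or a disease vocabulary id).
    """

    kind: str  # "gene" | "disease"
    start: int
    end: int
    text: str
    norm_id: str

    def validate(self, sentence_text: str) -> None:
        if self.kind not in ("gene", "disease"):
            raise CorpusError(f"unknown mention kind {self.kind!r}")
        if not (0 <= self.start < self.end <= len(sentence_text)):
            raise CorpusError(
                f"mention offsets [{self.start},{self.end}) outside sentence "
                f"of length {len(sentence_text)}"
            )
        if sentence_text[self.start : self.end] != self.text:
            raise CorpusError(
                f"mention text {self.text!r} does not match sentence slice "
                f"{sentence_text[self.start:self.end]!r}"
            )
        if not self.norm_id:
            raise CorpusError("mention norm_id must be non-empty")


@dataclass(frozen=True)
class EventAnnotation:
    """A biological event whose theme is a gene mentioned in the sentence."""

    etype: str
    trigger_start: int
    trigger_end: int
    theme_gene: str

    def validate(self, sentence: "Sentence") -> None:
        if self.etype not in _EVENT_TYPE_SET:
            raise CorpusError(f"unknown event type {self.etype!r}")
        if not (0 <= self.trigger_start < self.trigger_end <= len(sentence.text)):
            raise CorpusError(
                f"trigger offsets [{self.trigger_start},{self.trigger_end}) "
                f"outside sentence of length {len(sentence.text)}"
            )
        gene_ids = {m.norm_id for m in sentence.gene_mentions}
        if self.theme_gene not in gene_ids:
            raise CorpusError(
                f"event theme gene {self.theme_gene!r} has no matching gene "
                f"mention in the sentence"
            )


@dataclass
class Sentence:
    """One sentence of one abstract, with its entity and event annotations."""

    doc_id: str
    sid: int
    text: str
    gene_mentions: list[Mention] = field(default_factory=list)
    disease_mentions: list[Mention] = field(default_factory=list)
    events: list[EventAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        if self.sid < 0:
            raise CorpusError(f"sid must be >= 0, got {self.sid}")
        for m in self.gene_mentions:
            if m.kind != "gene":
                raise CorpusError(f"gene mention with kind {m.kind!r}")
            m.validate(self.text)
        for m in self.disease_mentions:
            if m.kind != "disease":
                raise CorpusError(f"disease mention with kind {m.kind!r}")
            m.validate(self.text)
        for ev in self.events:
            ev.validate(self)


@dataclass(frozen=True, order=True)
class EvidenceTriple:
    """One (gene, disease, event type) co-occurrence in one sentence."""

    gene: str
    disease: str
    etype: str
    doc_id: str
    sid: int

    @property
    def sentence_key(self) -> tuple[str, int]:
        return (self.doc_id, self.sid)


# ---------------------------------------------------------------------------
# corpus I/O (JSON Lines)

def _sentence_to_record(s: Sentence) -> dict:
    return {
        "doc_id": s.doc_id,
        "sid": s.sid,
        "text": s.text,
        "genes": [
            {"start": m.start, "end": m.end, "text": m.text, "id": m.norm_id}
            for m in s.gene_mentions
        ],
        "diseases": [
            {"start": m.start, "end": m.end, "text": m.text, "id": m.norm_id}
            for m in s.disease_mentions
        ],
        "events": [
            {
                "etype": e.etype,
                "trigger_start": e.trigger_start,
                "trigger_end": e.trigger_end,
                "theme_gene": e.theme_gene,
            }
            for e in s.events
        ],
    }


def _record_to_sentence(rec: dict) -> Sentence:
    genes = [
        Mention("gene", m["start"], m["end"], m["text"], str(m["id"]))
        for m in rec.get("genes", [])
    ]
    diseases = [
        Mention("disease", m["start"], m["end"], m["text"], str(m["id"]))
        for m in rec.get("diseases", [])
    ]
    events = [
        EventAnnotation(
            e["etype"], e["trigger_start"], e["trigger_end"], str(e["theme_gene"])
        )
        for e in rec.get("events", [])
    ]
    return Sentence(
        doc_id=str(rec["doc_id"]),
        sid=int(rec["sid"]),
        text=rec["text"],
        gene_mentions=genes,
        disease_mentions=diseases,
        events=events,
    )


def read_corpus(path) -> list[Sentence]:
    """Read a JSON-Lines corpus, validating every record.

    Raises :class:`CorpusError` naming the offending line on malformed JSON,
    unknown event types, or any mention/event invariant violation.
    """
    sentences: list[Sentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON: {exc}") from exc
            try:
                sent = _record_to_sentence(rec)
                sent.validate()
            except (KeyError, TypeError) as exc:
                raise CorpusError(f"line {lineno}: missing/invalid field: {exc}") from exc
            except CorpusError as exc:
                raise CorpusError(f"line {lineno}: {exc}") from exc
            sentences.append(sent)
    return sentences


def write_corpus(sentences: list[Sentence], path) -> None:
    """Write sentences as JSON Lines.  ``read_corpus`` inverts this exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            s.validate()
            fh.write(json.dumps(_sentence_to_record(s), ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# lexicon-based annotation (stand-in for external NER upstream)

def _find_lexicon_matches(text: str, lexicon: dict[str, str], kind: str) -> list[Mention]:
    """Case-insensitive, token-boundary-aware, longest-match-first matching."""
    candidates: list[tuple[int, int, str, str]] = []  # (start, end, surface, id)
    lowered = text.lower()
    for name, norm_id in lexicon.items():
        pat = name.lower()
        start = 0
        while True:
            i = lowered.find(pat, start)
            if i < 0:
                break
            j = i + len(pat)
            before_ok = i == 0 or not lowered[i - 1].isalnum()
            after_ok = j == len(lowered) or not lowered[j].isalnum()
            if before_ok and after_ok:
                candidates.append((i, j, text[i:j], str(norm_id)))
            start = i + 1
    # longest match wins; no overlapping mentions of the same kind
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int, str, str]] = []
    for c in candidates:
        if all(c[1] <= o[0] or c[0] >= o[1] for o in chosen):
            chosen.append(c)
    chosen.sort()
    return [Mention(kind, s, e, t, i) for s, e, t, i in chosen]


def annotate_sentence(
    text: str,
    gene_lexicon: dict[str, str],
    disease_lexicon: dict[str, str],
    doc_id: str = "NA",
    sid: int = 0,
) -> Sentence:
    """Annotate raw text with gene/disease mentions by dictionary lookup.

    Matching is case-insensitive, requires token boundaries (a lexicon entry
    never matches inside a longer alphanumeric run) and prefers the longest
    match at overlapping positions.  Event annotation is not attempted here;
    events come from the upstream extraction system or the simulator.
    """
    return Sentence(
        doc_id=doc_id,
        sid=sid,
        text=text,
        gene_mentions=_find_lexicon_matches(text, gene_lexicon, "gene"),
        disease_mentions=_find_lexicon_matches(text, disease_lexicon, "disease"),
    )


# ---------------------------------------------------------------------------
# evidence assembly

def assemble_triples(sentence: Sentence) -> list[EvidenceTriple]:
    """Pair every gene-theme event with every disease mentioned in the sentence.

    A sentence with no disease mention or no event yields nothing.  Duplicate
    (gene, disease, etype) combinations within one sentence collapse to a
    single triple, so downstream sentence counting is never inflated by
    repeated annotations.
    """
    sentence.validate()
    disease_ids = {m.norm_id for m in sentence.disease_mentions}
    out: set[EvidenceTriple] = set()
    for ev in sentence.events:
        for dz in disease_ids:
            out.add(
                EvidenceTriple(ev.theme_gene, dz, ev.etype, sentence.doc_id, sentence.sid)
            )
    return sorted(out)


# ---------------------------------------------------------------------------
# disease vocabulary

@dataclass
class DiseaseVocabulary:
    """Flat MeSH-style disease vocabulary.

    Each entry carries a preferred name, synonyms, an optional parent and a
    list of tree numbers; the first dot-separated segment of a tree number is
    the top-level category code (C01..C26).
    """

    entries: dict[str, dict]

    @classmethod
    def from_tsv(cls, path) -> "DiseaseVocabulary":
        entries: dict[str, dict] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["disease_id", "name", "synonyms", "parent_id", "tree_numbers"]
            if header != expected:
                raise CorpusError(
                    f"disease vocabulary header {header!r}, expected {expected!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 5:
                    raise CorpusError(f"line {lineno}: expected 5 fields, got {len(fields)}")
                did, name, syn, parent, trees = fields
                entries[did] = {
                    "name": name,
                    "synonyms": [s for s in syn.split("|") if s],
                    "parent_id": parent or None,
                    "tree_numbers": [t for t in trees.split("|") if t],
                }
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("disease_id\tname\tsynonyms\tparent_id\ttree_numbers\n")
            for did in sorted(self.entries):
                e = self.entries[did]
                fh.write(
                    "\t".join(
                        [
                            did,
                            e["name"],
                            "|".join(e["synonyms"]),
                            e["parent_id"] or "",
                            "|".join(e["tree_numbers"]),
                        ]
                    )
                    + "\n"
                )

    def name_lexicon(self) -> dict[str, str]:
        """Map every preferred name and synonym to its disease id."""
        lex: dict[str, str] = {}
        for did, e in self.entries.items():
            lex[e["name"]] = did
            for s in e["synonyms"]:
                lex[s] = did
        return lex


_TREE_TOP = re.compile(r"^(C\d{2})(?:\.|$)")


def map_to_general_categories(
    disease_id: str, vocab: DiseaseVocabulary, exclude_animal: bool = True
) -> set[str]:
    """Map a disease to its top-level MeSH category codes via tree numbers.

    The animal-disease category (C22) is dropped by default; a disease whose
    only tree numbers fall under it maps to the empty set with a warning.
    """
    if disease_id not in vocab.entries:
        raise KeyError(f"unknown disease id {disease_id!r}")
    cats: set[str] = set()
    for tn in vocab.entries[disease_id]["tree_numbers"]:
        m = _TREE_TOP.match(tn)
        if m:
            cats.add(m.group(1))
    if exclude_animal and ANIMAL_DISEASE_CATEGORY in cats:
        cats.discard(ANIMAL_DISEASE_CATEGORY)
        if not cats:
            warnings.warn(
                f"disease {disease_id} maps only to the excluded animal-disease "
                f"category",
                stacklevel=2,
            )
    return cats
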