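import pytest

from dgmine.corpus import EventAnnotation, Mention, Sentence


def make_sentence(
    text: str,
    genes=(),
    diseases=(),
    events=(),
    doc_id: str = "PM000001",
    sid: int = 0,
) -> Sentence:
    """Build a Sentence from (surface, id) mention specs located by str.find."""

    def mention(kind, surface, norm_id):
        start = text.find(surface)
        assert start >= 0, f"{surface!r} not in {text!r}"
        return Mention(kind, start, start + len(surface), surface, norm_id)

    def event(etype, trigger, theme):
        start = text.find(trigger)
        assert start >= 0
        return EventAnnotation(etype, start, start + len(trigger), theme)

    s = Sentence(
        doc_id=doc_id,
        sid=sid,
        text=text,
        gene_mentions=[mention("gene", t, i) for t, i in genes],
        disease_mentions=[mention("disease", t, i) for t, i in diseases],
        events=[event(e, tr, th) for e, tr, th in events],
    )
    s.validate()
    return s


@pytest.fixture
def evidence_sentence():
    """One canonical evidence sentence: gene-theme event + disease mention."""
    return make_sentence(
        "TP53 mutation is associated with breast cancer in patients",
        genes=[("TP53", "7157")],
        diseases=[("breast cancer", "D001943")],
        events=[("mutation", "mutation", "7157")],
    )
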