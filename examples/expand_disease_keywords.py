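"""Predict disease-related terms by word-vector analogy.

Builds a small embedding table in which the term "vasoconstriction" is
planted exactly at the analogy point v(cancer) - v(proliferation) +
v(hypertension), then expands keywords for hypertension.
"""

from dgmine import SeedPairList, expand_keywords
from dgmine.simulate import generate_embeddings

emb = generate_embeddings(seed=42)
seeds = SeedPairList([("cancer", "proliferation")])

for term, score in expand_keywords(emb, seeds, "hypertension", k=5):
    print(f"{term:20s} cosine={score:+.3f}")

# The top term scores cosine ~1.0: it sits exactly where the analogy
# "proliferation is to cancer as ? is to hypertension" points.  Lower
# entries are background words that happen to lie near the query.
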