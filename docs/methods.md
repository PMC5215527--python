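# Methods

This note documents the models and procedures implemented in `dgmine`, the
defaults they use, the design decisions taken where the design was open,
and what the synthetic data does and does not demonstrate.

## Evidence model

The unit of evidence is the sentence.  A sentence supports a
(gene, disease, event type) triple when it contains a gene mention that is
the theme of a biological event of that type and a disease mention.  The
event vocabulary is closed at 15 types: gene_expression, transcription,
regulation, binding, localization, phosphorylation, protein_catabolism
(the BioNLP core), hydroxylation, ubiquitination, dna_methylation,
glycosylation, acetylation, methylation, catalysis (the EPI task, each
type merged with its reverse reaction since directionality does not affect
gene ranking), and mutation.  A sentence mentioning several diseases
yields one triple per (theme gene, disease, event type) combination —
Cartesian pairing; duplicated combinations within one sentence collapse,
so sentence-level counting is never inflated by repeated annotations.

Offsets are 0-based, half-open and character-based throughout.  Entity and
event recognition are upstream concerns: corpora arrive annotated
(JSON Lines), and the bundled dictionary annotator (case-insensitive,
token-boundary-aware, longest-match-first) exists for fixture construction,
not as a serious NER system.  Gene identifiers are opaque strings; no
normalization is attempted.  Disease vocabulary entries carry MeSH-style
tree numbers whose first segment (C01..C26) is the general category; the
animal-disease category C22 is excluded from category analyses.

## Sentence classifier

A naive-Bayes model over discrete features.  The feature set is a
documented default behind a plain feature-dictionary interface (any
mapping of feature name to category works): disease-keyword and
hallmark-keyword counts binned {0, 1, 2, 3+}; token distances (whitespace
tokens strictly between nearest span boundaries) from the gene mention and
the disease mention to the event trigger, same bins; the event type; a
negation cue flag (cue list: no, not, without, absent, lack, neither,
nor); the gene-mention count bin; and the sentence position (first /
middle / last).  Keyword matching is case-insensitive whole-token.

Fitting uses maximum-likelihood priors and Laplace smoothing with
pseudo-count α = 1 by default: P(f = c | y) = (n_{c,y} + α) / (n_y + αK)
with K the number of categories observed for the feature.  A category
never seen in training is scored with K+1 in the denominator for both
classes (one shared unseen slot) — never an error.  The raw score is the
log posterior odds; the normalized score is its sigmoid, strictly inside
(0, 1) and order-equivalent to the raw score.  The decision threshold for
the F score is 0.5 on the normalized score.  Evaluation reports AUC
(probability a positive outranks a negative, ties half) plus
precision/recall/F at that cutoff.

Keyword lists are produced disease-independently by embedding analogy.
The default query direction is q = v(source) − v(related term) +
v(disease); the reversed direction (v(related) − v(source) + v(disease))
is exposed as a flag because both anchorings appear in the analogy
literature and the choice is not decidable from first principles.
Similarity is cosine (zero-norm vectors score 0); candidates from
different seed pairs merge by maximum score; default k = 20 per pair.
Embedding training is out of scope — the module consumes the word2vec
text format from any producer.

## Gene ranking

Evidence for a disease is aggregated per gene.  Sentence identity is
(doc_id, sid) and abstract identity is doc_id; when several triples of one
gene share a sentence, the sentence counts once and the maximum normalized
score among its triples is kept (best evidence in the sentence).  The five
measures are n_abstracts, n_sentences, max_score, sum_norm and mean_norm.
Ranking is descending by value with deterministic tie-breaking
(n_sentences descending, then gene id); tied values share the minimum rank.
Score thresholds (e.g. 0.2/0.4/0.6/0.8) filter evidence by normalized
score before aggregation; raising the threshold can only shrink counts.

## Reference comparison

Reference sets are read from GMT.  The top-K overlap ratio is pooled by
default — Σ_d |top-min(K, len_d) ∩ ref_d| / Σ_d min(K, len_d) — with a
macro-averaged variant available, since pooling weighs diseases by list
length and the right choice depends on the question.  Overlap significance
is the one-sided hypergeometric upper tail P(X ≥ k) with the universe
defaulting to the union of all ranked and reference genes (overridable).
Coverage bins quartile the recall |found ∩ ref| / |ref|; the 0.75 boundary
belongs to the top bin.

## Disease–disease relationships

Overlap coefficient C = |A∩B| / min(|A|,|B|), Jaccard J = |A∩B| / |A∪B|,
and the four-way pair grouping (identical / complete subset / partial
overlap / complete separation).  The separation coefficient follows the
nearest-neighbor convention: ⟨d_AB⟩ averages, over every gene of each set,
the unweighted shortest-path (BFS) distance to the nearest gene of the
*other* set, with shared genes contributing 0; ⟨d_AA⟩ averages each gene's
distance to the nearest *other* gene of its own set, 0 for singletons; and
S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2.  Genes absent from the network are
dropped and counted (`n_dropped`); unreachable nearest-neighbor distances
are excluded from the means and counted (`n_unreachable`) rather than
imputed with a large constant, so the effect of incompleteness is
auditable.  If every cross-set distance is unreachable the result is
undefined and an error is raised.

GO similarity needs only per-term annotated-gene counts, not the ontology
DAG: S_GO(a, b) = 2 / min n_i over terms shared by the two genes within
one aspect (BP/CC/MF) — the shared term with the fewest annotated genes is
the most specific — and 0 with no shared term.  Annotations are assumed
pre-propagated by their producer.  Disease-pair similarity is the mean of
S_GO over all |A|·|B| cross pairs.

## Event statistics

Per-disease event distributions count evidence sentences, deduplicated by
(disease, event type, doc_id, sid), so a sentence supporting one disease
through several genes counts once per event type.  A disease is enriched
for an event type when its ratio strictly exceeds μ + 1σ across diseases;
σ is the population standard deviation by default (sample form behind a
flag).  Group comparisons: real-valued attributes use a two-sided
Mann–Whitney rank test whose p-value is computed by full enumeration of
group labelings when C(n_a+n_b, n_a) ≤ 200,000 (exact even under ties;
the null U distribution is symmetric about n_a·n_b/2 under
exchangeability) and by the tie-corrected normal approximation otherwise;
binary attributes use Fisher's exact test.  All-tied input returns p = 1
with a warning.  Transcription-factor and housekeeping flags are input
lists, not computed.

## Synthetic data: what it emulates

The generators are pure functions of their arguments — identical seeds
give byte-identical files — and every expected value needed downstream is
recorded in truth tables at generation time.

* **Corpus**: planted (gene, disease, event, intensity) associations are
  emitted as templated sentences ("G009 mutation is associated with
  disease0", three template variants), mixed with decoys (gene-only with
  event, disease-only, gene+disease without event) and optional untracked
  noise events, and distributed over documents at random.  Default study
  conditions: 40 genes, 6 diseases, 150 documents; a gradient of ten genes
  on the first disease at intensities 2, 4, …, 20; decoy fraction 0.4;
  the noisy condition adds 40 random event sentences.
* **Labelled feature vectors**: balanced classes drawn from categorical
  distributions; the separated condition makes four features informative
  (keyword counts, distances, negation), the identical condition draws
  both classes from one distribution.
* **Networks**: seeded Erdős–Rényi or Barabási–Albert graphs; the module
  study uses a planted-partition graph (6 modules × 25 genes, p_in = 0.25,
  p_out = 0.01) hosting per-module disease pairs with 50% gene overlap
  (12 genes per disease) and cross-module disjoint pairs.
* **GO annotations**: uniform term sizes (2–8 genes per term by default),
  optionally concentrated on network modules so functional similarity is
  high exactly where network separation is low.
* **References**: per-disease sets sharing a controlled fraction
  (default 50%) of the planted genes, padded with novel identifiers.

Templated text has none of the lexical, syntactic or distributional
properties of real abstracts, and planted associations are cleaner than
real literature signal.  Passing tests therefore demonstrate that the
*computations* are correct and that planted structure is recovered under
controlled noise — not that any particular accuracy would be achieved on
real Medline-scale input, which additionally depends on upstream NER and
event-extraction quality outside this package's scope.

## Numerical and scale choices

Problem sizes are chosen so the full suite and the acceptance script run
in seconds: oracle checks use 200 random graphs of at most 30 nodes,
exhaustive hypergeometric enumeration up to a 12-element universe, full
permutation enumeration for rank-test groups of at most 8, classifier
evaluation at n = 2000 labelled vectors, and the 12-pair module study.
Floating-point comparisons in tests use absolute tolerances of 1e-9 or
tighter for oracle equivalence; statistical direction checks use one-sided
tests at the 0.05 level at fixed seeds.

## Known limitations

* The feature inventory of the sentence classifier is a documented default,
  not a faithful reconstruction of any particular production system.
* The dictionary annotator is fixture-grade; no real NER or normalization.
* S_GO ignores the GO DAG by construction; unpropagated annotation files
  will understate similarity.
* The exact rank-test enumerator is exponential and falls back to the
  normal approximation beyond small groups.
* Cross-disease score calibration is out of scope: normalized scores are
  comparable within a disease's evidence list, not across corpora.
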