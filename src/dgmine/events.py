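"""Distribution of biological event types across diseases and group tests.

Per disease, evidence sentences are counted by event type (deduplicated at
the sentence level, so a sentence annotated twice with the same event type
for a disease counts once).  A disease is *enriched* for an event type —
e.g. mutation-enriched or expression-enriched — when its ratio of that
event type exceeds the across-disease mean plus one standard deviation
(mu + 1*sigma, population form by default).

Gene groups (for instance the genes of mutation-enriched vs
expression-enriched diseases) are compared on a per-gene attribute: a
real-valued attribute such as network degree uses a two-sided Mann-Whitney
rank test (exact by full enumeration of group labelings when feasible), a
binary attribute such as a transcription-factor flag uses Fisher's exact
test on the 2x2 table.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu, rankdata

from .corpus import EVENT_TYPES, EvidenceTriple

__all__ = [
    "EventDistribution",
    "EnrichmentThresholds",
    "GroupComparison",
    "per_disease_event_ratios",
    "classify_event_enrichment",
    "compare_group_attribute",
    "write_event_stats_tsv",
]


@dataclass
class EventDistribution:
    """Per-disease sentence counts and ratios over the 15 event types."""

    disease: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ratios(self) -> dict[str, float]:
        tot = self.total
        return {e: c / tot for e, c in self.counts.items()} if tot else {}

    def ratio(self, etype: str) -> float:
        return self.ratios.get(etype, 0.0)


@dataclass
class EnrichmentThresholds:
    etype: str
    mu: float
    sigma: float

    @property
    def threshold(self) -> float:
        return self.mu + self.sigma


def per_disease_event_ratios(triples: list[EvidenceTriple]) -> list[EventDistribution]:
    """Count evidence sentences per (disease, event type).

    Counting is sentence-level: duplicates by (disease, etype, doc_id, sid)
    collapse, so one sentence read through several genes still counts once
    per event type for the disease.
    """
    if not triples:
        raise ValueError("no evidence triples supplied")
    seen: set[tuple[str, str, str, int]] = set()
    counts: dict[str, dict[str, int]] = {}
    for t in triples:
        key = (t.disease, t.etype, t.doc_id, t.sid)
        if key in seen:
            continue
        seen.add(key)
        tbl = counts.setdefault(t.disease, {})
        tbl[t.etype] = tbl.get(t.etype, 0) + 1
    return [EventDistribution(d, counts[d]) for d in sorted(counts)]


def classify_event_enrichment(
    dists: list[EventDistribution], etype: str, population_sd: bool = True
) -> tuple[dict[str, bool], EnrichmentThresholds]:
    """Label diseases whose etype ratio exceeds mu + 1*sigma across diseases."""
    if len(dists) < 2:
        raise ValueError("enrichment classification needs >= 2 diseases")
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event type {etype!r}")
    ratios = np.array([d.ratio(etype) for d in dists])
    mu = float(ratios.mean())
    sigma = float(ratios.std(ddof=0 if population_sd else 1))
    thr = EnrichmentThresholds(etype=etype, mu=mu, sigma=sigma)
    labels = {d.disease: bool(d.ratio(etype) > thr.threshold) for d in dists}
    return labels, thr


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def to_json(self, path, group_a: str = "A", group_b: str = "B") -> None:
        payload = {
            "groups": [group_a, group_b],
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


_EXACT_ENUM_LIMIT = 200_000


def _u_statistic(pooled_ranks: np.ndarray, idx_a: tuple[int, ...], n_a: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def _exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of the C(n_a+n_b, n_a) labelings.

    p = fraction of labelings whose U deviates from its null mean n_a*n_b/2
    at least as much as the observed U (the null distribution of U is
    symmetric about that mean under exchangeability, with or without ties).
    """
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n = len(a), len(pooled)
    center = n_a * (n - n_a) / 2.0
    u_obs = _u_statistic(ranks, tuple(range(n_a)), n_a)
    dev = abs(u_obs - center)
    hits = total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(_u_statistic(ranks, idx, n_a) - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def compare_group_attribute(
    values_a, values_b, binary: bool = False
) -> GroupComparison:
    """Compare a per-gene attribute between two gene groups.

    Real-valued attributes: two-sided Mann-Whitney rank test; the p-value is
    exact (full labeling enumeration) when C(n_a+n_b, n_a) <= 200,000, else
    the normal approximation with tie correction.  Binary attributes (pass
    ``binary=True`` with 0/1 values): two-sided Fisher's exact test.
    Degenerate all-tied input returns p = 1 with a warning.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all attribute values tied; no test performed", stacklevel=2)
        test = "fisher_exact" if binary else "mann_whitney"
        return GroupComparison(test, math.nan, 1.0, a.size, b.size)

    if binary:
        table = [
            [int((a == 1).sum()), int((a == 0).sum())],
            [int((b == 1).sum()), int((b == 0).sum())],
        ]
        odds, p = fisher_exact(table, alternative="two-sided")
        return GroupComparison("fisher_exact", float(odds), float(p), a.size, b.size)

    if math.comb(a.size + b.size, a.size) <= _EXACT_ENUM_LIMIT:
        u, p = _exact_mannwhitney_p(a, b)
        return GroupComparison("mann_whitney_exact", u, p, a.size, b.size)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison("mann_whitney_asymptotic", float(res.statistic), float(res.pvalue), a.size, b.size)


def write_event_stats_tsv(
    path,
    dists: list[EventDistribution],
    mutation_labels: dict[str, bool],
    expression_labels: dict[str, bool],
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tetype\tcount\tratio\tenriched_mutation\tenriched_expression\n")
        for d in dists:
            for etype in EVENT_TYPES:
                if etype not in d.counts:
                    continue
                fh.write(
                    f"{d.disease}\t{etype}\t{d.counts[etype]}\t{d.ratio(etype):.6f}\t"
                    f"{int(mutation_labels.get(d.disease, False))}\t"
                    f"{int(expression_labels.get(d.disease, False))}\n"
                )
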