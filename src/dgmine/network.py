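"""Disease-disease relationship statistics.

Two diseases are compared through their gene sets A and B in three ways:

* set overlap — the overlap coefficient C = |A∩B| / min(|A|,|B|) and the
  Jaccard index J = |A∩B| / |A∪B|, plus a four-way classification of the
  pair (complete separation, partial overlap, complete subset, identical);
* network separation — the separation coefficient
  S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2, where <d_AB> is the mean
  shortest-path distance from each gene of one set to its nearest gene of
  the other set in an undirected protein-interaction network (a gene shared
  by both diseases contributes 0) and <d_AA> is the mean distance from each
  gene of A to its nearest other gene of A.  Negative S_AB means the two
  disease modules overlap in the network; positive means they are separated;
* functional similarity — S_GO(a, b) = 2 / min(n_i) over GO terms shared by
  genes a and b, where n_i is the number of genes annotated to term i (the
  smallest shared term is the most specific); the disease-pair similarity is
  the mean of S_GO over all cross pairs.

Distances are unweighted shortest paths.  Genes absent from the network are
dropped (and counted); gene pairs with no connecting path are excluded from
the means (and counted) rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "SeparationResult",
    "GOAnnotationTable",
    "overlap_coefficient",
    "jaccard_index",
    "classify_pair",
    "separation_coefficient",
    "go_pair_similarity",
    "disease_go_similarity",
    "write_pair_report",
]

GO_ASPECTS = ("BP", "CC", "MF")


class InteractionNetwork:
    """Undirected simple gene graph (no self-loops, duplicate edges collapsed)."""

    def __init__(self, edges=None, graph: nx.Graph | None = None):
        g = nx.Graph()
        if graph is not None:
            g = nx.Graph(graph)
        if edges is not None:
            g.add_edges_from((str(a), str(b)) for a, b in edges)
        g.remove_edges_from(nx.selfloop_edges(g))
        self.graph = g

    @classmethod
    def from_tsv(cls, path) -> "InteractionNetwork":
        """Read a 2-column TSV edge list; '#' lines are comments."""
        edges = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"line {lineno}: expected 2 tab-separated gene ids")
                edges.append((fields[0], fields[1]))
        return cls(edges=edges)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# gene_a\tgene_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}\t{b}\n")

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """C = |A∩B| / min(|A|,|B|); 1 iff one set contains the other."""
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return len(a & b) / min(len(a), len(b))


def jaccard_index(a: set[str], b: set[str]) -> float:
    """J = |A∩B| / |A∪B|; 1 iff the sets are identical."""
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return len(a & b) / len(a | b)


def classify_pair(a: set[str], b: set[str]) -> str:
    """Four-way disease-pair grouping by set relation."""
    if a == b:
        return "identical"
    if a < b or b < a:
        return "complete_subset"
    if not a & b:
        return "complete_separation"
    return "partial_overlap"


@dataclass
class SeparationResult:
    d_ab: float
    d_aa: float
    d_bb: float
    s_ab: float
    n_dropped: int  # genes absent from the network
    n_unreachable: int  # excluded infinite nearest-neighbor distances


def separation_coefficient(
    a: set[str], b: set[str], net: InteractionNetwork
) -> SeparationResult:
    """Network separation S_AB of two disease gene sets.

    <d_AB> averages, over every gene of A and every gene of B, the shortest
    distance to the nearest gene of the *other* set (0 for shared genes);
    <d_AA> (resp. <d_BB>) averages each gene's distance to the nearest other
    gene of its own set, 0 for a singleton set.  Unreachable nearest-neighbor
    distances are excluded from the means and counted.
    """
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    g = net.graph
    a_in = {x for x in a if x in g}
    b_in = {x for x in b if x in g}
    n_dropped = (len(a) - len(a_in)) + (len(b) - len(b_in))
    if not a_in or not b_in:
        raise ValueError("a gene set is empty after dropping genes absent from the network")

    n_unreachable = 0

    def _mean(vals: list[float]) -> float:
        nonlocal n_unreachable
        finite = [v for v in vals if math.isfinite(v)]
        n_unreachable += len(vals) - len(finite)
        if not finite:
            return math.nan
        return sum(finite) / len(finite)

    cross: list[float] = []
    for x in a_in:
        cross.append(0.0 if x in b_in else _min_dist(g, x, b_in))
    for x in b_in:
        cross.append(0.0 if x in a_in else _min_dist(g, x, a_in))
    d_ab = _mean(cross)
    if math.isnan(d_ab):
        raise ValueError("all cross-set distances are unreachable; S_AB undefined")

    d_aa = _within_mean(g, a_in, _mean)
    d_bb = _within_mean(g, b_in, _mean)
    return SeparationResult(
        d_ab=d_ab,
        d_aa=d_aa,
        d_bb=d_bb,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        n_dropped=n_dropped,
        n_unreachable=n_unreachable,
    )


def _min_dist(g: nx.Graph, source: str, targets: set[str]) -> float:
    dist = nx.single_source_shortest_path_length(g, source)
    return min((dist[t] for t in targets if t in dist), default=math.inf)


def _within_mean(g: nx.Graph, genes: set[str], mean_fn) -> float:
    if len(genes) == 1:
        return 0.0
    vals = [_min_dist(g, x, genes - {x}) for x in genes]
    m = mean_fn(vals)
    return 0.0 if math.isnan(m) else m


# ---------------------------------------------------------------------------
# GO-annotation functional similarity

class GOAnnotationTable:
    """Flat (gene, GO term, aspect) annotation table with per-term gene counts.

    Annotations are assumed pre-propagated by the producer; the similarity
    needs only per-term annotated-gene counts, not the GO DAG.
    """

    def __init__(self, rows: list[tuple[str, str, str]]):
        for _, _, aspect in rows:
            if aspect not in GO_ASPECTS:
                raise ValueError(f"unknown GO aspect {aspect!r}; expected one of {GO_ASPECTS}")
        self._terms_of: dict[tuple[str, str], set[str]] = {}
        genes_of: dict[tuple[str, str], set[str]] = {}
        for gene, term, aspect in rows:
            self._terms_of.setdefault((gene, aspect), set()).add(term)
            genes_of.setdefault((term, aspect), set()).add(gene)
        self.term_sizes: dict[tuple[str, str], int] = {
            k: len(v) for k, v in genes_of.items()
        }

    @classmethod
    def from_tsv(cls, path) -> "GOAnnotationTable":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["gene", "go_id", "aspect"],
            dtype=str,
        )
        return cls(list(df.itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        rows = sorted(
            (gene, term, aspect)
            for (gene, aspect), terms in self._terms_of.items()
            for term in terms
        )
        with open(path, "w", encoding="utf-8") as fh:
            for gene, term, aspect in rows:
                fh.write(f"{gene}\t{term}\t{aspect}\n")

    def terms(self, gene: str, aspect: str) -> set[str]:
        return self._terms_of.get((gene, aspect), set())


def go_pair_similarity(a: str, b: str, go: GOAnnotationTable, aspect: str) -> float:
    """S_GO(a,b) = 2 / min(n_i) over shared terms of the aspect; 0 if none."""
    shared = go.terms(a, aspect) & go.terms(b, aspect)
    if not shared:
        return 0.0
    return 2.0 / min(go.term_sizes[(t, aspect)] for t in shared)


def disease_go_similarity(
    a: set[str], b: set[str], go: GOAnnotationTable, aspect: str
) -> float:
    """Mean S_GO over all |A|x|B| cross gene pairs."""
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    total = sum(go_pair_similarity(x, y, go, aspect) for x in a for y in b)
    return total / (len(a) * len(b))


def write_pair_report(
    path,
    disease_sets: dict[str, set[str]],
    pairs: list[tuple[str, str]],
    net: InteractionNetwork,
    go: GOAnnotationTable | None = None,
) -> pd.DataFrame:
    """Full per-pair TSV report: C, J, group, distances, S_AB, S_GO per aspect."""
    records = []
    for da, db in pairs:
        a, b = disease_sets[da], disease_sets[db]
        sep = separation_coefficient(a, b, net)
        rec = {
            "disease_a": da,
            "disease_b": db,
            "C": overlap_coefficient(a, b),
            "J": jaccard_index(a, b),
            "group": classify_pair(a, b),
            "d_AB": sep.d_ab,
            "d_AA": sep.d_aa,
            "d_BB": sep.d_bb,
            "S_AB": sep.s_ab,
        }
        for aspect in GO_ASPECTS:
            rec[f"S_GO_{aspect}"] = (
                disease_go_similarity(a, b, go, aspect) if go is not None else float("nan")
            )
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
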