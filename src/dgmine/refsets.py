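"""Comparison of mined gene rankings against reference disease gene sets.

Reference catalogs (OMIM/GWAS-style) are read from GMT files.  Three
comparisons are provided: the overlap ratio of top-K ranked genes with the
reference, the one-sided hypergeometric significance of a gene-set overlap,
and per-disease recall binned into coverage quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = [
    "DiseaseGeneSet",
    "GmtFormatError",
    "read_gmt",
    "write_gmt",
    "topk_overlap_ratio",
    "overlap_pvalue",
    "coverage_bins",
    "COVERAGE_BIN_LABELS",
]


class GmtFormatError(ValueError):
    """Raised for malformed GMT lines."""


@dataclass
class DiseaseGeneSet:
    """A named non-empty set of gene identifiers."""

    name: str
    description: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} must be non-empty")


def read_gmt(path) -> list[DiseaseGeneSet]:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ...

    Duplicate genes within a line collapse with a warning; a line with fewer
    than three fields is a format error naming the line.
    """
    out: list[DiseaseGeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"line {lineno}: duplicate genes in set {name!r} collapsed",
                    stacklevel=2,
                )
            out.append(DiseaseGeneSet(name, desc, set(genes)))
    return out


def write_gmt(sets: list[DiseaseGeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def topk_overlap_ratio(
    ranked: dict[str, list[str]],
    refs: dict[str, set[str]],
    k: int,
    macro: bool = False,
) -> float:
    """Overlap ratio of top-K ranked genes with per-disease reference sets.

    Pooled (default): sum over diseases of |top-min(K,len) ∩ ref| divided by
    the summed denominators min(K, len).  ``macro=True`` instead averages the
    per-disease ratios.  Diseases absent from ``refs`` are skipped; no common
    disease is an error.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    common = [d for d in ranked if d in refs]
    if not common:
        raise ValueError("no disease shared between rankings and references")
    hits, denom, ratios = 0, 0, []
    for d in common:
        top = ranked[d][: min(k, len(ranked[d]))]
        n_hit = len(set(top) & refs[d])
        hits += n_hit
        denom += len(top)
        ratios.append(n_hit / len(top) if top else 0.0)
    if macro:
        return sum(ratios) / len(ratios)
    return hits / denom


def overlap_pvalue(found: set[str], ref: set[str], universe_size: int) -> float:
    """One-sided hypergeometric upper-tail P(X >= |found ∩ ref|).

    X counts reference genes in a draw of |found| genes from a universe of
    ``universe_size`` containing |ref| reference genes.
    """
    if len(found | ref) > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    k = len(found & ref)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, universe_size, len(ref), len(found)))


#: Bin labels, top first; the 0.75 boundary belongs to the top bin.
COVERAGE_BIN_LABELS: tuple[str, ...] = (
    "1.00-0.75",
    "0.75-0.50",
    "0.50-0.25",
    "0.25-0.00",
)


def _bin_label(recall: float) -> str:
    if recall >= 0.75:
        return COVERAGE_BIN_LABELS[0]
    if recall >= 0.50:
        return COVERAGE_BIN_LABELS[1]
    if recall >= 0.25:
        return COVERAGE_BIN_LABELS[2]
    return COVERAGE_BIN_LABELS[3]


def coverage_bins(
    found: dict[str, set[str]], refs: dict[str, set[str]]
) -> dict[str, tuple[float, str]]:
    """Per-disease recall of the reference set, with its coverage-bin label.

    recall = |found ∩ ref| / |ref|.  Diseases with an empty reference set are
    skipped with a warning.
    """
    out: dict[str, tuple[float, str]] = {}
    for d in found:
        if d not in refs:
            continue
        ref = refs[d]
        if not ref:
            warnings.warn(f"disease {d}: empty reference set skipped", stacklevel=2)
            continue
        recall = len(found[d] & ref) / len(ref)
        out[d] = (recall, _bin_label(recall))
    return out


def write_overlap_report(
    path,
    found: dict[str, set[str]],
    refs: dict[str, set[str]],
    universe_size: int,
) -> None:
    """TSV report per disease: sizes, overlap, recall, bin, hypergeometric p."""
    bins = coverage_bins(found, refs)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tn_found\tn_ref\tn_overlap\trecall\tbin\tp_value\n")
        for d in sorted(bins):
            recall, label = bins[d]
            n_overlap = len(found[d] & refs[d])
            p = overlap_pvalue(found[d], refs[d], universe_size)
            fh.write(
                f"{d}\t{len(found[d])}\t{len(refs[d])}\t{n_overlap}\t"
                f"{recall:.6f}\t{label}\t{p:.6g}\n"
            )
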