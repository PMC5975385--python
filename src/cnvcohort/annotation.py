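"""Consequence annotation of CNVs against gene models, QTL overlap and
term-enrichment testing.

Each CNV receives exactly one of six consequence categories, ranked by
severity: ``coding_sequence`` > ``non_coding_exon`` > ``intron`` >
``upstream`` > ``downstream`` > ``intergenic``.  The first three are genic,
the last three non-genic — the binary collapse used for the genic-fraction
summaries.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import CNVCall, CNVCluster

CATEGORIES = (
    "coding_sequence",
    "non_coding_exon",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}
GENIC_CATEGORIES = frozenset({"coding_sequence", "non_coding_exon", "intron"})

DEFAULT_FLANK = 5000


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon intervals; exons carry a coding flag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int, bool], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise ValueError("gene end < start")
        for s, e, _ in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon {s}-{e} outside gene span of {self.gene_id}")
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))


@dataclass(frozen=True)
class ConsequenceAnnotation:
    call: CNVCall
    category: str
    gene_id: Optional[str]
    genic: bool


def classify_genic(category: str) -> bool:
    """Collapse a consequence category to the genic / non-genic dichotomy."""
    if category not in _SEVERITY:
        raise ValueError(f"unknown category {category!r}")
    return category in GENIC_CATEGORIES


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _category_for_gene(call: CNVCall, gene: GeneModel, flank: int) -> Optional[str]:
    """Most severe category the call attains against one gene, or None."""
    if call.chrom != gene.chrom:
        return None
    if _overlaps(call.start, call.end, gene.start, gene.end):
        coding = noncoding = False
        for s, e, is_coding in gene.exons:
            if _overlaps(call.start, call.end, s, e):
                if is_coding:
                    coding = True
                else:
                    noncoding = True
        if coding:
            return "coding_sequence"
        if noncoding:
            return "non_coding_exon"
        return "intron"
    # flanks, strand-aware: upstream lies before the gene start on + strand
    if call.end < gene.start and gene.start - call.end <= flank:
        return "upstream" if gene.strand == "+" else "downstream"
    if call.start > gene.end and call.start - gene.end <= flank:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def annotate_call(
    call: CNVCall, genes: Sequence[GeneModel], flank: int = DEFAULT_FLANK
) -> ConsequenceAnnotation:
    """Assign the single most severe consequence category to *call*.

    A call overlapping several genes is annotated against the gene giving
    the most severe category; ties break to the smaller gene start.  The
    result is independent of gene input order.
    """
    best: Optional[Tuple[int, int, str, str]] = None  # (severity, gene start, category, gene)
    for gene in genes:
        cat = _category_for_gene(call, gene, flank)
        if cat is None:
            continue
        key = (_SEVERITY[cat], gene.start, cat, gene.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return ConsequenceAnnotation(call, "intergenic", None, False)
    _, _, category, gene_id = best
    return ConsequenceAnnotation(call, category, gene_id, classify_genic(category))


def category_counts(
    annotations: Iterable[ConsequenceAnnotation],
) -> Tuple[Dict[str, int], Optional[float]]:
    """Per-category tallies and the genic percentage (None when empty)."""
    counts = Counter({c: 0 for c in CATEGORIES})
    total = genic = 0
    for a in annotations:
        counts[a.category] += 1
        total += 1
        genic += a.genic
    genic_pct = 100.0 * genic / total if total else None
    return dict(counts), genic_pct


# --- free-text consequence labels ----------------------------------------

def parse_location_label(label: str) -> str:
    """Map a free-text genomic-location description to a category.

    Understands the phrasing of annotation summaries such as
    "intron of the ENSBTAG... gene", "upstream gene variant of ...",
    "coding sequence variant and intron of ...", "start lost, coding
    sequence, 5' UTR, intron of ..." (reported at top severity), "non coding
    transcript exon of ..." and "transcript amplification in ..." (a gain
    spanning a non-protein-coding gene's transcript, treated as a
    non-coding-exon overlap).
    """
    text = label.strip().lower()
    if not text:
        raise ValueError("empty location label")
    if "coding sequence" in text and "non coding" not in text and "non-coding" not in text:
        return "coding_sequence"
    if "start lost" in text or "stop lost" in text:
        return "coding_sequence"
    if "non coding transcript exon" in text or "non-coding transcript exon" in text:
        return "non_coding_exon"
    if "transcript amplification" in text:
        return "non_coding_exon"
    if "intron" in text:
        return "intron"
    if "upstream" in text:
        return "upstream"
    if "downstream" in text:
        return "downstream"
    if "intergenic" in text or "between genes" in text:
        return "intergenic"
    raise ValueError(f"unrecognized location label {label!r}")


# --- QTL overlap ----------------------------------------------------------

def qtl_overlap(clusters: Sequence[CNVCluster], qtl: pd.DataFrame) -> pd.DataFrame:
    """Intersect cluster representatives with QTL intervals (>=1 bp).

    *qtl* needs columns chrom, start, end (1-based closed), trait_class.
    A cluster hitting several trait classes yields several rows.
    """
    rows: List[dict] = []
    if qtl is None or qtl.empty:
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "cnv_type", "trait_class"])
    trees: Dict[str, IntervalTree] = {}
    for r in qtl.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r.trait_class)
    for cl in clusters:
        rep = cl.representative
        tree = trees.get(rep.chrom)
        if tree is None:
            continue
        classes = sorted({iv.data for iv in tree.overlap(rep.start, rep.end + 1)})
        for tc in classes:
            rows.append(
                {
                    "chrom": rep.chrom,
                    "start": rep.start,
                    "end": rep.end,
                    "cnv_type": rep.cnv_type,
                    "trait_class": tc,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cnv_type", "trait_class"])


# --- term enrichment ------------------------------------------------------

def term_enrichment(
    selected_genes: Set[str],
    universe_genes: Set[str],
    terms: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Hypergeometric over/under-representation test per term.

    *terms* maps gene_id → set of term labels.  For each term with at least
    one universe gene: with N universe genes, K term genes, n selected and k
    selected term genes, the over tail is P(X >= k), the under tail
    P(X <= k); the reported two-sided p is ``min(1, 2 * min(tails))`` and the
    direction is the smaller tail.  Benjamini–Hochberg adjustment across
    terms.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    if not selected_genes <= universe_genes:
        raise ValueError("selected genes must be a subset of the universe")
    term_genes: Dict[str, Set[str]] = {}
    for gene, gene_terms in terms.items():
        if gene not in universe_genes:
            continue
        for t in gene_terms:
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(universe_genes), len(selected_genes)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        K = len(genes)
        k = len(genes & selected_genes)
        p_over = float(hypergeom.sf(k - 1, N, K, n))
        p_under = float(hypergeom.cdf(k, N, K, n))
        p_two = min(1.0, 2.0 * min(p_over, p_under))
        direction = "over" if p_over <= p_under else "under"
        rows.append(
            {
                "term": term,
                "direction": direction,
                "k_selected": k,
                "k_universe": K,
                "expected": n * K / N,
                "p_value": p_two,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "direction", "k_selected", "k_universe", "expected", "p_value"],
    )
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df
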