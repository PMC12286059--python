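"""Genomic context of age-associated CpGs and GO over-representation.

A CpG is intragenic when it falls inside the gene-body span of any ``gene``
feature (strand-blind, any biotype), else intergenic.  Biotype tallies count
each site once per distinct overlapping biotype.  Over-representation of GO
terms in the genes hit by selected CpGs is scored with the upper-tail
hypergeometric test and Benjamini-Hochberg correction within each namespace
(BP / MF / CC).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .io import CpGSite, GeneFeature

# Fig-6-style precedence for the single representative biotype label
BIOTYPE_PRECEDENCE = (
    "protein_coding",
    "lncRNA",
    "transcribed_unprocessed_pseudogene",
    "unprocessed_pseudogene",
)


@dataclass(frozen=True)
class AnnotationRow:
    site: CpGSite
    category: str  # intragenic | intergenic
    gene_ids: tuple[str, ...]
    biotypes: tuple[str, ...]
    primary_biotype: str

    def __post_init__(self) -> None:
        if (self.category == "intergenic") != (len(self.gene_ids) == 0):
            raise ValueError("intergenic iff no overlapping genes")


@dataclass(frozen=True)
class OraResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # selected genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # selected gene count
    N: int  # universe gene count
    p_hyper: float
    q_bh: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def _primary_biotype(biotypes: Sequence[str]) -> str:
    for b in BIOTYPE_PRECEDENCE:
        if b in biotypes:
            return b
    return sorted(biotypes)[0]


def classify_sites(
    sites: Sequence[CpGSite], genes: Sequence[GeneFeature]
) -> list[AnnotationRow]:
    """Intragenic/intergenic classification by gene-body overlap.

    Genes are indexed per chromosome in an interval tree; a site is intragenic
    iff its position falls in [start, end) of at least one gene, strand
    ignored.  All overlapping genes are reported.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )

    rows: list[AnnotationRow] = []
    for site in sites:
        tree = trees.get(site.chrom)
        hits: list[GeneFeature] = (
            sorted((iv.data for iv in tree.at(site.pos0)),
                   key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
            if tree is not None
            else []
        )
        if hits:
            biotypes = tuple(sorted({g.biotype for g in hits}))
            rows.append(
                AnnotationRow(
                    site=site,
                    category="intragenic",
                    gene_ids=tuple(g.gene_id for g in hits),
                    biotypes=biotypes,
                    primary_biotype=_primary_biotype(biotypes),
                )
            )
        else:
            rows.append(AnnotationRow(site, "intergenic", (), (), "intergenic"))
    return rows


def biotype_counts(annotations: Sequence[AnnotationRow]) -> dict[str, int]:
    """Tally sites per biotype: one count per distinct overlapping biotype per
    site; intergenic sites counted under ``intergenic``."""
    counts: Counter[str] = Counter()
    for row in annotations:
        if row.category == "intergenic":
            counts["intergenic"] += 1
        else:
            for b in row.biotypes:
                counts[b] += 1
    return dict(counts)


def category_fractions(annotations: Sequence[AnnotationRow]) -> tuple[float, float]:
    """(intragenic fraction, intergenic fraction)."""
    if not annotations:
        raise ValueError("no annotations")
    intra = sum(a.category == "intragenic" for a in annotations)
    return intra / len(annotations), 1.0 - intra / len(annotations)


def ora(
    selected_genes: set[str],
    universe_genes: set[str],
    term_map: Mapping[str, Sequence[tuple[str, str, str]]],
) -> list[OraResult]:
    """Hypergeometric over-representation of annotation terms.

    For a term carried by K of the N universe genes and k of the n selected,
    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n) (upper tail, includes
    the observed table).  BH correction runs within each namespace; terms with
    K = 0 in the universe are skipped.  Results sorted by (q, p, term_id).
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    stray = sorted(selected_genes - universe_genes)
    if stray:
        raise ValueError(f"selected genes outside the universe: {', '.join(stray)}")

    N, n = len(universe_genes), len(selected_genes)
    term_genes: dict[tuple[str, str, str], set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in universe_genes:
            continue
        for term in terms:
            term_genes.setdefault(tuple(term), set()).add(gene)

    by_ns: dict[str, list[OraResult]] = {}
    for (term_id, term_name, ns), genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & selected_genes)
        # survival function at k-1 == upper tail including k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        by_ns.setdefault(ns, []).append(
            OraResult(term_id, term_name, ns, k, K, n, N, min(p, 1.0), q_bh=1.0)
        )

    out: list[OraResult] = []
    for ns, results in by_ns.items():
        q = stats.false_discovery_control([r.p_hyper for r in results], method="bh")
        for r, qv in zip(results, q):
            out.append(
                OraResult(r.term_id, r.term_name, ns, r.k, r.K, r.n, r.N, r.p_hyper, float(qv))
            )
    out.sort(key=lambda r: (r.q_bh, r.p_hyper, r.term_id))
    return out


def write_annotations(annotations: Sequence[AnnotationRow], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#site\tpos0\tpos1\tcategory\tgene_ids\tbiotypes\tprimary_biotype\n")
        for a in annotations:
            fh.write(
                f"{a.site.chrom}_{a.site.pos1}\t{a.site.pos0}\t{a.site.pos1}\t{a.category}\t"
                f"{','.join(a.gene_ids) or '.'}\t{','.join(a.biotypes) or '.'}\t{a.primary_biotype}\n"
            )
    return path


def write_ora(results: Sequence[OraResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#term_id\tterm_name\tnamespace\tk\tK\tn\tN\tp_hyper\tq_bh\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.namespace}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p_hyper:.6g}\t{r.q_bh:.6g}\n"
            )
    return path
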