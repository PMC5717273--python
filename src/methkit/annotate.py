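"""DMR-to-gene-component annotation and gene-level summaries.

A DMR is assigned to a gene and to every functional component —
promoter (2 kb upstream of the TSS), 5'UTR, exon, intron, 3'UTR — whose
interval it overlaps by at least 1 bp (1-based inclusive coordinates).
A DMR inside a gene's span that misses every annotated component (for
instance when the annotation carries no UTRs) falls back to a
``gene_body`` hit so the gene association is never silently lost; that
fallback category is excluded from component percentage tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import Dmr, GeneModel, MethylomeError

COMPONENTS = ("promoter", "utr5", "exon", "intron", "utr3")
GENE_BODY = "gene_body"


@dataclass
class GeneComponentIndex:
    """Interval index of gene components, one tree per chromosome.

    Trees store 0-based half-open intervals whose payload is a
    ``(gene_id, component)`` pair; ``gene_trees`` index whole gene
    spans for the gene-body fallback.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    gene_trees: dict[str, IntervalTree] = field(default_factory=dict)
    promoter_length: int = 2000


def promoter_interval(
    gene: GeneModel, chrom_length: int, promoter_length: int = 2000
) -> tuple[int, int] | None:
    """The promoter as [tss - L, tss - 1] on +, [tss + 1, tss + L] on -.

    Clipped to [1, chrom_length]; returns None when clipping leaves
    nothing (a TSS at the very contig edge).
    """
    if not 1 <= gene.tss <= chrom_length:
        raise MethylomeError(
            f"gene {gene.gene_id}: TSS {gene.tss} outside contig of {chrom_length} bp")
    if gene.strand == "+":
        start, end = gene.tss - promoter_length, gene.tss - 1
    else:
        start, end = gene.tss + 1, gene.tss + promoter_length
    start, end = max(1, start), min(chrom_length, end)
    if start > end:
        return None
    return start, end


def build_component_index(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    promoter_length: int = 2000,
) -> GeneComponentIndex:
    """Index every component interval of every gene, promoters derived."""
    index = GeneComponentIndex(promoter_length=promoter_length)
    for gene in genes:
        length = int(chrom_sizes[gene.chrom])
        tree = index.trees.setdefault(gene.chrom, IntervalTree())
        gtree = index.gene_trees.setdefault(gene.chrom, IntervalTree())
        prom = promoter_interval(gene, length, promoter_length)
        parts: list[tuple[str, Iterable[tuple[int, int]]]] = [
            ("utr5", gene.utr5), ("exon", gene.exons),
            ("intron", gene.introns), ("utr3", gene.utr3),
        ]
        if prom is not None:
            parts.append(("promoter", (prom,)))
        for component, intervals in parts:
            for start, end in intervals:
                start, end = max(1, start), min(length, end)
                if start <= end:
                    tree.addi(start - 1, end, (gene.gene_id, component))
        span_start, span_end = gene.span
        gtree.addi(max(1, span_start) - 1, min(length, span_end), gene.gene_id)
    return index


@dataclass(frozen=True)
class AnnotatedDmr:
    """A DMR with its (gene, component) hits; empty hits = intergenic."""

    dmr: Dmr
    hits: frozenset[tuple[str, str]]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.hits}))

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self.hits}))


def annotate_dmrs(
    dmrs: Sequence[Dmr], index: GeneComponentIndex
) -> list[AnnotatedDmr]:
    """Assign each DMR every (gene, component) it overlaps by >= 1 bp."""
    out = []
    for dmr in dmrs:
        hits: set[tuple[str, str]] = set()
        tree = index.trees.get(dmr.chrom)
        if tree is not None:
            for iv in tree.overlap(dmr.start - 1, dmr.end):
                hits.add(iv.data)
        gtree = index.gene_trees.get(dmr.chrom)
        if gtree is not None:
            hit_genes = {g for g, _ in hits}
            for iv in gtree.overlap(dmr.start - 1, dmr.end):
                if iv.data not in hit_genes:
                    hits.add((iv.data, GENE_BODY))
        out.append(AnnotatedDmr(dmr=dmr, hits=frozenset(hits)))
    return out


def component_distribution(annotated: Sequence[AnnotatedDmr]) -> pd.DataFrame:
    """Per-component DMR counts split by direction, with percentages.

    A DMR counts once for each canonical component it touches;
    percentages are normalized by the total number of canonical
    component assignments (``gene_body`` fallback hits are listed but
    excluded from the percentage base).
    """
    counts = {c: {"n_total": 0, "n_hyper": 0, "n_hypo": 0}
              for c in COMPONENTS + (GENE_BODY,)}
    for ann in annotated:
        for component in set(c for _, c in ann.hits):
            counts[component]["n_total"] += 1
            key = "n_hyper" if ann.dmr.direction == "hyper" else "n_hypo"
            counts[component][key] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")
    canonical_total = int(table.loc[list(COMPONENTS), "n_total"].sum())
    pct = [
        100.0 * table.loc[c, "n_total"] / canonical_total
        if c in COMPONENTS and canonical_total else float("nan")
        for c in table.index
    ]
    table["pct"] = pct
    return table


def count_dmgs(annotated: Sequence[AnnotatedDmr]) -> pd.DataFrame:
    """Gene-level table of differentially methylated genes (DMGs)."""
    per_gene: dict[str, dict] = {}
    for ann in annotated:
        for gene_id in {g for g, _ in ann.hits}:
            row = per_gene.setdefault(
                gene_id, {"n_dmrs": 0, "n_hyper": 0, "n_hypo": 0})
            row["n_dmrs"] += 1
            row["n_hyper" if ann.dmr.direction == "hyper" else "n_hypo"] += 1
    if not per_gene:
        return pd.DataFrame(
            columns=["gene_id", "n_dmrs", "n_hyper", "n_hypo",
                     "any_hyper", "any_hypo"])
    table = (
        pd.DataFrame.from_dict(per_gene, orient="index")
        .rename_axis("gene_id").reset_index().sort_values("gene_id")
        .reset_index(drop=True)
    )
    table["any_hyper"] = table["n_hyper"] > 0
    table["any_hypo"] = table["n_hypo"] > 0
    return table


@dataclass(frozen=True)
class VennCounts:
    """Sizes for a two-set intersection diagram (DMG vs DEG)."""

    n_a: int
    n_b: int
    n_overlap: int
    overlap: frozenset[str]


def intersect_dmg_deg(dmg_ids: Iterable[str], deg_ids: Iterable[str]) -> VennCounts:
    """Overlap of differentially methylated and expressed gene sets."""
    a, b = set(dmg_ids), set(deg_ids)
    shared = frozenset(a & b)
    return VennCounts(n_a=len(a), n_b=len(b), n_overlap=len(shared), overlap=shared)
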