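"""Metagene methylation profiles and flanking k-mer preferences.

Two descriptive views of a methylome. The metagene profile averages
per-site corrected methylation levels across length-normalized
instances of each gene component (promoter, 5'UTR, exon, intron,
3'UTR), oriented 5'->3' with respect to gene strand. The k-mer view
characterizes the sequence flanking methylated cytosines: each
methylated site contributes the 9-mer centred on it (3 bases upstream,
5 downstream by default, read on the site's own strand), stratified by
context and by high/low methylation — high means ML > 75% in CG
context and > 25% in non-CG context.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import COMPONENTS, promoter_interval
from .model import GeneModel, MethylomeError

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
_RC = str.maketrans("ACGTN", "TGCAN")


def classify_high_low(ml: float, context: str) -> str:
    """High/low methylation stratum of one site.

    CG sites are high when ML strictly exceeds 0.75; CHG/CHH sites when
    ML strictly exceeds 0.25. An undefined (NaN) level is an error.
    """
    if ml is None or math.isnan(ml):
        raise MethylomeError("methylation level is undefined")
    threshold = 0.75 if context == "CG" else 0.25
    return "high" if ml > threshold else "low"


def extract_flanking_kmers(
    genome: Mapping[str, str],
    sites: pd.DataFrame,
    k: int = 9,
    c_offset: int = 4,
) -> tuple[Counter, int]:
    """k-mers around cytosine sites, read 5'->3' on each site's strand.

    ``c_offset`` is the 1-based position of the C within the k-mer, so
    the default takes 3 bases upstream and 5 downstream. Sites too
    close to a contig end or whose window contains N are skipped; the
    skip count is returned alongside the k-mer multiset. ``sites``
    needs chrom / pos / strand columns.
    """
    if not 1 <= c_offset <= k:
        raise MethylomeError(f"c_offset {c_offset} outside 1..{k}")
    kmers: Counter = Counter()
    skipped = 0
    up, down = c_offset - 1, k - c_offset
    for row in sites.itertuples(index=False):
        seq = genome[row.chrom]
        i = int(row.pos) - 1
        if row.strand == "+":
            lo, hi = i - up, i + down + 1
        else:
            lo, hi = i - down, i + up + 1
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        kmer = seq[lo:hi]
        if row.strand == "-":
            kmer = kmer.translate(_RC)[::-1]
        if "N" in kmer:
            skipped += 1
            continue
        kmers[kmer] += 1
    return kmers, skipped


@dataclass(frozen=True)
class KmerProfile:
    """Position-frequency matrix of a k-mer multiset.

    ``matrix`` has one row per position (1..k) and columns A/C/G/T with
    base fractions; the consensus takes the most frequent base per
    position, falling back to IUPAC ambiguity codes on exact ties.
    """

    k: int
    c_offset: int
    matrix: pd.DataFrame
    n_kmers: int
    consensus: str
    stratum: tuple[str, str] | None = None


def position_frequency_matrix(
    kmers: Counter | Sequence[str],
    c_offset: int = 4,
    stratum: tuple[str, str] | None = None,
) -> KmerProfile:
    """Column-wise base fractions and consensus of a k-mer multiset."""
    if not isinstance(kmers, Counter):
        kmers = Counter(kmers)
    if not kmers:
        raise MethylomeError("empty k-mer multiset")
    lengths = {len(s) for s in kmers}
    if len(lengths) != 1:
        raise MethylomeError(f"mixed k-mer lengths {sorted(lengths)}")
    k = lengths.pop()
    counts = np.zeros((k, 4), dtype=float)
    base_idx = {b: j for j, b in enumerate("ACGT")}
    total = 0
    for kmer, n in kmers.items():
        total += n
        for i, base in enumerate(kmer):
            counts[i, base_idx[base]] += n
    fractions = counts / total
    consensus = []
    for i in range(k):
        top = fractions[i].max()
        tied = frozenset(b for b, j in base_idx.items() if fractions[i, j] == top)
        consensus.append(_IUPAC[tied])
    matrix = pd.DataFrame(fractions, columns=list("ACGT"),
                          index=pd.RangeIndex(1, k + 1, name="position"))
    return KmerProfile(
        k=k, c_offset=c_offset, matrix=matrix, n_kmers=total,
        consensus="".join(consensus), stratum=stratum,
    )


def kmer_strata(
    genome: Mapping[str, str],
    calls: pd.DataFrame,
    k: int = 9,
    c_offset: int = 4,
) -> dict[tuple[str, str], KmerProfile]:
    """Flanking k-mer profiles of methylated sites per (context, level).

    ``calls`` is a site-call table; only rows flagged methylated
    contribute. Strata with no usable k-mer are omitted.
    """
    meth = calls.loc[calls["is_methylated"]]
    out: dict[tuple[str, str], KmerProfile] = {}
    for context, group in meth.groupby("context", observed=True):
        levels = group["ml_corrected"].map(
            lambda ml, c=context: classify_high_low(ml, c))
        for level in ("high", "low"):
            sub = group.loc[levels == level, ["chrom", "pos", "strand"]]
            if not len(sub):
                continue
            kmers, _ = extract_flanking_kmers(genome, sub, k=k, c_offset=c_offset)
            if kmers:
                out[(str(context), level)] = position_frequency_matrix(
                    kmers, c_offset=c_offset, stratum=(str(context), level))
    return out


@dataclass(frozen=True)
class MetageneProfile:
    """Binned mean methylation across instances of one component type."""

    component: str
    context: str
    n_bins: int
    bin_means: np.ndarray   # NaN where no site fell in the bin
    bin_counts: np.ndarray


def metagene_profile(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    context: str,
    chrom_sizes: Mapping[str, int],
    n_bins: int = 20,
    promoter_length: int = 2000,
) -> dict[str, MetageneProfile]:
    """Length-normalized methylation profile per gene component.

    Every instance of a component is split into ``n_bins`` equal-length
    bins oriented 5'->3' relative to the gene's strand; each covered
    site of the requested context contributes its corrected ML to the
    bin holding its fractional position. Means are taken across all
    instances of the component type; empty bins report NaN with count 0.
    """
    sub = calls.loc[calls["context"] == context]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in sub.groupby("chrom", observed=True):
        order = np.argsort(group["pos"].to_numpy(), kind="mergesort")
        by_chrom[str(chrom)] = (
            group["pos"].to_numpy()[order],
            group["ml_corrected"].to_numpy()[order],
        )

    sums = {c: np.zeros(n_bins) for c in COMPONENTS}
    counts = {c: np.zeros(n_bins, dtype=np.int64) for c in COMPONENTS}

    def add_instance(component: str, chrom: str, start: int, end: int, strand: str):
        data = by_chrom.get(chrom)
        if data is None:
            return
        pos, ml = data
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        if hi == lo:
            return
        frac = (pos[lo:hi] - start + 0.5) / (end - start + 1)
        if strand == "-":
            frac = 1.0 - frac
        bins = np.minimum((frac * n_bins).astype(np.int64), n_bins - 1)
        np.add.at(sums[component], bins, ml[lo:hi])
        np.add.at(counts[component], bins, 1)

    for gene in genes:
        length = int(chrom_sizes[gene.chrom])
        prom = promoter_interval(gene, length, promoter_length)
        if prom is not None:
            add_instance("promoter", gene.chrom, prom[0], prom[1], gene.strand)
        for component, intervals in (
            ("utr5", gene.utr5), ("exon", gene.exons),
            ("intron", gene.introns), ("utr3", gene.utr3),
        ):
            for start, end in intervals:
                add_instance(component, gene.chrom, start, end, gene.strand)

    out = {}
    for component in COMPONENTS:
        with np.errstate(invalid="ignore"):
            means = np.where(
                counts[component] > 0,
                sums[component] / np.maximum(counts[component], 1),
                np.nan,
            )
        out[component] = MetageneProfile(
            component=component, context=context, n_bins=n_bins,
            bin_means=means, bin_counts=counts[component],
        )
    return out
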