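"""Readers and writers for every on-disk format the pipeline touches.

Formats: Bismark CX-report-style cytosine TSVs, genome FASTA, gene GFF3,
DMR tables (TSV), truth/interval BED, and plain gene-id lists. Every
writer/reader pair round-trips exactly; readers produce deterministic
ordering regardless of input line order.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CX_COLUMNS,
    Dmr,
    GeneModel,
    MethylomeError,
    MethylomeSample,
    TruthRegion,
    expected_context,
)

_FASTA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# Cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path, label: str | None = None) -> MethylomeSample:
    """Read a 7-column per-cytosine report into a :class:`MethylomeSample`.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context (CG/CHG/CHH), trinucleotide. Rows with
    zero total reads are retained (downstream depth filters drop them).
    Raises :class:`MethylomeError` naming the first offending line for
    malformed rows, duplicate (chrom, pos, strand) keys, or a context
    label inconsistent with its trinucleotide.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=list(CX_COLUMNS),
            dtype={
                "chrom": str, "strand": str, "context": str, "tricontext": str,
            },
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CX_COLUMNS, (str, np.int64, str, np.int64, np.int64, str, str))})
    except pd.errors.ParserError as exc:
        raise MethylomeError(f"{path}: malformed cytosine report: {exc}") from exc

    if len(df):
        _validate_cx_frame(df, path)
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    return MethylomeSample.from_frame(df, label=label if label is not None else path.stem)


def _validate_cx_frame(df: pd.DataFrame, path: Path) -> None:
    def fail(mask, what: str) -> None:
        mask = np.asarray(mask)
        if mask.any():
            line = int(np.flatnonzero(mask)[0]) + 1
            raise MethylomeError(f"{path}, line {line}: {what}")

    fail(df[list(CX_COLUMNS)].isna().any(axis=1), "missing field")
    for col in ("pos", "n_meth", "n_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        fail(numeric.isna() | (numeric != numeric.round()), f"non-integer {col}")
        df[col] = numeric
    fail((df["n_meth"] < 0) | (df["n_unmeth"] < 0), "negative read count")
    fail(df["pos"] < 1, "position must be 1-based")
    fail(~df["strand"].isin(["+", "-"]), "strand must be + or -")
    fail(~df["context"].isin(["CG", "CHG", "CHH"]), "unknown context")
    tri = df["tricontext"].astype(str)
    fail(~tri.str.fullmatch("C[ACGT]{2}"), "trinucleotide must be a C-initial 3-mer")
    implied = np.where(
        tri.str[1] == "G", "CG", np.where(tri.str[2] == "G", "CHG", "CHH")
    )
    fail(df["context"].to_numpy() != implied, "context inconsistent with trinucleotide")


def write_cytosine_report(sample: MethylomeSample, path: str | Path) -> None:
    sample.df[list(CX_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as ``{name: upper-case sequence}``.

    Accepts A/C/G/T/N (any case); any other character is an error.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise MethylomeError(
                f"{path}: sequence {rec.id} contains non-ACGTN characters {sorted(bad)}"
            )
        if rec.id in genome:
            raise MethylomeError(f"{path}: duplicate sequence name {rec.id}")
        genome[rec.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3, one :class:`GeneModel` per gene.

    When a gene carries several mRNAs the representative transcript is
    the one with the longest genomic span. Introns are derived as the
    gaps between that transcript's sorted exons. Genes with no exons on
    any transcript are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True, force=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise MethylomeError(f"gene {gene.id}: unknown strand {gene.strand!r}")
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if transcripts:
            rep = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            exon_parent = rep
        else:
            rep = gene
            exon_parent = gene
        exons = sorted(
            (f.start, f.end) for f in db.children(exon_parent, featuretype="exon")
        )
        if not exons:
            warnings.warn(f"gene {gene.id} has no exons; skipped", stacklevel=2)
            continue
        introns = tuple(
            (prev_end + 1, nxt_start - 1)
            for (_, prev_end), (nxt_start, _) in zip(exons, exons[1:])
            if nxt_start - prev_end > 1
        )
        utr5 = tuple(sorted(
            (f.start, f.end) for f in db.children(exon_parent, featuretype="five_prime_UTR")
        ))
        utr3 = tuple(sorted(
            (f.start, f.end) for f in db.children(exon_parent, featuretype="three_prime_UTR")
        ))
        tss = rep.start if gene.strand == "+" else rep.end
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, tss=tss,
            exons=tuple(exons), introns=introns, utr5=utr5, utr3=utr3,
        ))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tmethkit\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tmethkit\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for kind, ivals in (("exon", g.exons), ("five_prime_UTR", g.utr5),
                                ("three_prime_UTR", g.utr3)):
                for s, e in ivals:
                    fh.write(
                        f"{g.chrom}\tmethkit\t{kind}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# DMR tables
# ---------------------------------------------------------------------------

DMR_HEADER = (
    "chrom", "start", "end", "n_sites", "ml_a", "ml_b", "fold_change",
    "difference", "p_value", "q_value", "direction", "genes", "components",
)


def write_dmr_table(dmrs: Sequence[Dmr], path: str | Path) -> None:
    """Write DMRs as a TSV with the canonical header.

    Floats are serialized with ``repr`` so that write->read round-trips
    bit-exactly. Empty gene/component lists are written as ``.``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(DMR_HEADER) + "\n")
        for d in dmrs:
            fh.write("\t".join((
                d.chrom, str(d.start), str(d.end), str(d.n_sites),
                repr(d.ml_a), repr(d.ml_b), repr(d.fold_change), repr(d.difference),
                repr(d.p), repr(d.q), d.direction,
                ",".join(d.genes) or ".", ",".join(d.components) or ".",
            )) + "\n")


def read_dmr_table(path: str | Path) -> list[Dmr]:
    dmrs: list[Dmr] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != DMR_HEADER:
            raise MethylomeError(f"{path}: unexpected DMR table header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(DMR_HEADER):
                raise MethylomeError(f"{path}, line {lineno}: expected "
                                     f"{len(DMR_HEADER)} fields, got {len(fields)}")
            (chrom, start, end, n_sites, ml_a, ml_b, fold, diff,
             p, q, direction, genes, components) = fields
            dmrs.append(Dmr(
                chrom=chrom, start=int(start), end=int(end), n_sites=int(n_sites),
                ml_a=float(ml_a), ml_b=float(ml_b), fold_change=float(fold),
                difference=float(diff), p=float(p), q=float(q), direction=direction,
                genes=tuple(genes.split(",")) if genes != "." else (),
                components=tuple(components.split(",")) if components != "." else (),
            ))
    return dmrs


# ---------------------------------------------------------------------------
# BED (truth regions / DMR intervals)
# ---------------------------------------------------------------------------

def write_truth_bed(regions: Sequence[TruthRegion], path: str | Path) -> None:
    """Write truth regions as BED6: name=direction, score=1000*delta."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(1000 * r.delta))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.direction}\t{score}\t.\n")


def read_truth_bed(path: str | Path) -> list[TruthRegion]:
    regions: list[TruthRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise MethylomeError(f"{path}, line {lineno}: need >=5 BED fields")
            chrom, start, end, name, score = fields[:5]
            regions.append(TruthRegion(
                chrom=chrom, start=int(start) + 1, end=int(end),
                direction=name, delta=int(score) / 1000.0,
            ))
    return regions


def write_dmr_bed(dmrs: Sequence[Dmr], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.direction}\t0\t.\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain one-identifier-per-line gene list (e.g. a DEG list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
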