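"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All on-disk formats (cytosine reports, GFF3, DMR tables) use 1-based
inclusive coordinates, following Bismark and GFF3. BED output is 0-based
half-open. Internally, interval arithmetic that needs half-open
coordinates converts at the boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: Columns of the per-cytosine table inside a :class:`MethylomeSample`,
#: in on-disk order (Bismark CX-report-compatible).
CX_COLUMNS = ("chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tricontext")


class MethylomeError(ValueError):
    """Raised for malformed or inconsistent methylome inputs."""


@dataclass(frozen=True)
class CytosineRecord:
    """One reference cytosine with strand, context and read counts.

    ``n_meth`` counts reads reporting the cytosine unconverted
    (methylated); ``n_unmeth`` counts reads reporting conversion.
    ``tricontext`` is the 3-mer starting at the cytosine, read 5'->3'
    on the cytosine's own strand, so it always begins with ``C``.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    tricontext: str

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise MethylomeError(f"negative read count at {self.chrom}:{self.pos}")
        if self.strand not in STRANDS:
            raise MethylomeError(f"bad strand {self.strand!r} at {self.chrom}:{self.pos}")
        if self.context != expected_context(self.tricontext):
            raise MethylomeError(
                f"context {self.context!r} inconsistent with tricontext "
                f"{self.tricontext!r} at {self.chrom}:{self.pos}"
            )

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth


def expected_context(tricontext: str) -> str:
    """Context implied by a 3-mer: CG if +1 base is G, CHG if +2 is G, else CHH."""
    if len(tricontext) != 3 or tricontext[0] != "C":
        raise MethylomeError(f"tricontext {tricontext!r} must be a 3-mer starting with C")
    if tricontext[1] == "G":
        return "CG"
    if tricontext[2] == "G":
        return "CHG"
    return "CHH"


@dataclass
class MethylomeSample:
    """A sample's per-cytosine counts, sorted by (chrom, pos, strand).

    The table is a :class:`pandas.DataFrame` with :data:`CX_COLUMNS`.
    ``nonconversion_rate`` (symbol ``r``) is filled in once a lambda
    spike-in estimate is available; ``None`` means not yet estimated.
    """

    df: pd.DataFrame
    label: str = ""
    nonconversion_rate: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CX_COLUMNS if c not in self.df.columns]
        if missing:
            raise MethylomeError(f"sample table missing columns {missing}")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        label: str = "",
        nonconversion_rate: float | None = None,
    ) -> "MethylomeSample":
        """Sort, validate uniqueness and wrap a raw cytosine table."""
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            row = df[dup].iloc[0]
            raise MethylomeError(
                f"duplicate cytosine key {row['chrom']}:{row['pos']}:{row['strand']}"
            )
        return cls(df=df, label=label, nonconversion_rate=nonconversion_rate)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> pd.Series:
        return self.df["n_meth"] + self.df["n_unmeth"]

    def records(self) -> Iterable[CytosineRecord]:
        for row in self.df.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand,
                int(row.n_meth), int(row.n_unmeth), row.context, row.tricontext,
            )

    def with_rate(self, r: float) -> "MethylomeSample":
        return replace(self, nonconversion_rate=float(r))


@dataclass(frozen=True)
class GeneModel:
    """A gene with one representative transcript's component intervals.

    All intervals are 1-based inclusive ``(start, end)`` tuples; exon
    lists are sorted and non-overlapping; introns are the gaps between
    consecutive exons. ``tss`` is the 5'-most transcribed coordinate on
    the + strand and the 3'-most genomic coordinate on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class TruthRegion:
    """A planted differential region: ground truth for recovery tests.

    ``direction`` is hyper/hypo of group A relative to group B.
    """

    chrom: str
    start: int
    end: int
    direction: str
    delta: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise MethylomeError(f"degenerate truth region {self.chrom}:{self.start}-{self.end}")
        if self.direction not in ("hyper", "hypo"):
            raise MethylomeError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Dmr:
    """A differentially methylated region between two samples.

    ``ml_a``/``ml_b`` are unweighted means of per-site corrected
    methylation levels over the sites covered in both samples;
    ``fold_change`` is max/min of the two means with a zero guard, so it
    is always >= 1; ``direction`` is hyper when group A is the higher one.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    ml_a: float
    ml_b: float
    fold_change: float
    difference: float
    p: float
    q: float
    direction: str
    genes: tuple[str, ...] = ()
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise MethylomeError(f"degenerate DMR {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeWideStats:
    """Genome-wide methylation census.

    ``pct_*`` fields are percentages on the 0-100 scale (0.68 means
    0.68% of genomic CG sites are methylated). ``context_shares`` are
    the fractions of methylated sites falling in each context and sum
    to 1 when any site is methylated.
    """

    n_mc: int
    pct_mc_of_c: float
    pct_mcg_of_cg: float
    pct_mchg_of_chg: float
    pct_mchh_of_chh: float
    context_shares: Mapping[str, float] = field(default_factory=dict)

    def share(self, context: str) -> float:
        return float(self.context_shares.get(context, float("nan")))
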