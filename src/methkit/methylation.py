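"""Per-site methylation calling and genome-wide context statistics.

The methylation level of a cytosine is the fraction of aligned reads
reporting it unconverted::

    ML(C) = reads(mC) / (reads(mC) + reads(umC))

Bisulfite treatment fails to convert a small fraction ``r`` of truly
unmethylated cytosines (the non-conversion rate, estimated from an
unmethylated lambda-phage spike-in), so raw levels are corrected as
``(ML - r) / (1 - r)`` clamped at zero, and sites are declared
methylated with a one-sided binomial test of the methylated read count
against ``r``, controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomeWideStats, MethylomeError, MethylomeSample
from .stats import bh_fdr

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N
_BASES = np.array(list("ACGTN"))
_CONTEXT_NAMES = np.array(["CG", "CHG", "CHH"])


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def context_table(seq: str) -> pd.DataFrame:
    """All cytosines of one sequence, both strands, with defined context.

    Context is read 5'->3' on the cytosine's own strand: CG when the +1
    base is G, CHG when the +2 base is G (H = A/C/T), CHH otherwise.
    Sites within 2 bp of the contig's 3' end (per strand) or whose two
    downstream bases include an N have undefined context and are
    omitted. Returns columns pos (1-based), strand, context, tricontext,
    sorted by (pos, strand).
    """
    code = _encode(seq)
    n = len(code)
    frames = []
    for strand in "+-":
        if strand == "+":
            idx = np.flatnonzero(code == 1)
            idx = idx[idx <= n - 3]
            b1, b2 = code[idx + 1], code[idx + 2]
        else:
            idx = np.flatnonzero(code == 2)
            idx = idx[idx >= 2]
            b1, b2 = _COMP[code[idx - 1]], _COMP[code[idx - 2]]
        defined = (b1 != 4) & (b2 != 4)
        idx, b1, b2 = idx[defined], b1[defined], b2[defined]
        ctx = np.where(b1 == 2, 0, np.where(b2 == 2, 1, 2))
        tri = np.char.add(np.char.add("C", _BASES[b1]), _BASES[b2])
        frames.append(pd.DataFrame({
            "pos": idx + 1,
            "strand": strand,
            "context": _CONTEXT_NAMES[ctx],
            "tricontext": tri,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def classify_context(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str
) -> tuple[str | None, str | None]:
    """Classify one cytosine's context; ``(None, None)`` when undefined.

    ``pos`` is 1-based. The base at (chrom, pos) must be a cytosine on
    the requested strand (i.e. a G on the + strand for ``strand='-'``).
    """
    seq = genome[chrom]
    i = pos - 1
    if not 0 <= i < len(seq):
        raise MethylomeError(f"position {pos} outside {chrom}")
    base = seq[i]
    if strand == "+":
        if base != "C":
            raise MethylomeError(f"{chrom}:{pos}:+ is {base}, not C")
        if i + 2 >= len(seq):
            return None, None
        down = seq[i + 1:i + 3]
    elif strand == "-":
        if base != "G":
            raise MethylomeError(f"{chrom}:{pos}:- is {base} on +, not G")
        if i - 2 < 0:
            return None, None
        down = str(_revcomp(seq[i - 2:i]))
    else:
        raise MethylomeError(f"bad strand {strand!r}")
    if "N" in down:
        return None, None
    tri = "C" + down
    if down[0] == "G":
        return "CG", tri
    if down[1] == "G":
        return "CHG", tri
    return "CHH", tri


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def methylation_level(n_meth: int, n_unmeth: int) -> float:
    """Raw methylation level; NaN (not 0.0) when coverage is zero."""
    total = n_meth + n_unmeth
    if n_meth < 0 or n_unmeth < 0:
        raise MethylomeError("negative read count")
    if total == 0:
        return math.nan
    return n_meth / total


def correct_ml(ml_raw: float, r: float) -> float:
    """Non-conversion-corrected level ``max(0, (ml - r) / (1 - r))``."""
    if not 0 <= r < 1:
        raise MethylomeError(f"non-conversion rate {r} outside [0, 1)")
    return max(0.0, (ml_raw - r) / (1.0 - r))


def estimate_nonconversion(lambda_sample: MethylomeSample) -> float:
    """Pooled non-conversion rate from an unmethylated spike-in.

    ``r = sum(n_meth) / sum(n_meth + n_unmeth)`` over every lambda
    cytosine; the bisulfite conversion rate is ``1 - r``.
    """
    df = lambda_sample.df
    total = int(df["n_meth"].sum() + df["n_unmeth"].sum())
    if total == 0:
        raise MethylomeError("lambda spike-in has zero aligned reads")
    return float(df["n_meth"].sum() / total)


def call_methylated_sites(
    sample: MethylomeSample,
    r: float | None = None,
    alpha: float = 0.05,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Binomial site calls for every cytosine with depth >= ``min_depth``.

    For each tested site the one-sided tail ``p = P(X >= n_meth | n, r)``
    asks whether the methylated read count exceeds what conversion
    failure alone would produce; BH-FDR is applied across tested sites
    and a site is methylated when ``q < alpha`` and ``n_meth >= 1``.

    Returns a site-call table with raw and corrected levels, p, q and
    the ``is_methylated`` flag. Sites below ``min_depth`` are excluded.
    """
    if r is None:
        r = sample.nonconversion_rate if sample.nonconversion_rate is not None else 0.0
    if not 0 < alpha < 1:
        raise MethylomeError(f"alpha {alpha} outside (0, 1)")
    if not 0 <= r < 1:
        raise MethylomeError(f"non-conversion rate {r} outside [0, 1)")
    df = sample.df
    depth = (df["n_meth"] + df["n_unmeth"]).to_numpy()
    tested = df.loc[depth >= min_depth].reset_index(drop=True)
    n = (tested["n_meth"] + tested["n_unmeth"]).to_numpy()
    m = tested["n_meth"].to_numpy()
    ml_raw = np.divide(m, n, out=np.full(len(n), np.nan), where=n > 0)
    ml_corr = np.clip((ml_raw - r) / (1.0 - r), 0.0, None)
    # P(X >= m) with X ~ Bin(n, r); sf(m-1) and r=0 both behave correctly.
    p = stats.binom.sf(m - 1, n, r)
    q = bh_fdr(p) if len(p) else np.array([])
    out = tested.copy()
    out["depth"] = n
    out["ml_raw"] = ml_raw
    out["ml_corrected"] = ml_corr
    out["p"] = p
    out["q"] = q
    out["is_methylated"] = (q < alpha) & (m >= 1)
    return out


def context_census(genome: Mapping[str, str]) -> dict[str, int]:
    """Counts of defined-context cytosine sites per context, both strands."""
    census = {"CG": 0, "CHG": 0, "CHH": 0}
    for seq in genome.values():
        counts = context_table(seq)["context"].value_counts()
        for ctx in census:
            census[ctx] += int(counts.get(ctx, 0))
    return census


def genome_wide_stats(
    calls: pd.DataFrame, genome: Mapping[str, str]
) -> GenomeWideStats:
    """Genome-wide methylation percentages per context.

    Percentages are methylated sites over the genome's full context
    census (not only covered sites), on the 0-100 scale; shares are the
    split of methylated sites among CG/CHG/CHH.
    """
    census = context_census(genome)
    meth = calls.loc[calls["is_methylated"]]
    n_by_ctx = {ctx: int((meth["context"] == ctx).sum()) for ctx in census}
    n_mc = sum(n_by_ctx.values())
    total_c = sum(census.values())

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    shares = (
        {ctx: n_by_ctx[ctx] / n_mc for ctx in census} if n_mc else
        {ctx: math.nan for ctx in census}
    )
    return GenomeWideStats(
        n_mc=n_mc,
        pct_mc_of_c=pct(n_mc, total_c),
        pct_mcg_of_cg=pct(n_by_ctx["CG"], census["CG"]),
        pct_mchg_of_chg=pct(n_by_ctx["CHG"], census["CHG"]),
        pct_mchh_of_chh=pct(n_by_ctx["CHH"], census["CHH"]),
        context_shares=shares,
    )


def sliding_window_landscape(
    sample: MethylomeSample,
    window: int = 3000,
    step: int = 600,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled methylated/unmethylated counts in sliding genome windows.

    Windows are tiled per chromosome from position 1 with the given step;
    the last windows are truncated at the contig end. Each row carries
    the pooled counts, the number of covered sites and the pooled level
    ``sum(n_meth) / sum(total)`` (NaN for windows with no reads). Empty
    windows are emitted with zero counts.
    """
    if step <= 0 or window <= 0 or step > window:
        raise MethylomeError(f"bad window/step {window}/{step}")
    df = sample.df
    sizes = dict(chrom_sizes) if chrom_sizes is not None else {
        str(c): int(g["pos"].max()) for c, g in df.groupby("chrom", observed=True)
    }
    rows = []
    for chrom in sorted(sizes):
        length = sizes[chrom]
        sub = df.loc[df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        meth = sub["n_meth"].to_numpy()[order]
        unmeth = sub["n_unmeth"].to_numpy()[order]
        covered = (meth + unmeth) > 0
        cmeth = np.concatenate([[0], np.cumsum(meth)])
        cunmeth = np.concatenate([[0], np.cumsum(unmeth)])
        ccov = np.concatenate([[0], np.cumsum(covered)])
        starts = np.arange(1, length + 1, step)
        ends = np.minimum(starts + window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        wmeth = cmeth[hi] - cmeth[lo]
        wunmeth = cunmeth[hi] - cunmeth[lo]
        wtotal = wmeth + wunmeth
        ml = np.divide(wmeth, wtotal, out=np.full(len(wtotal), np.nan, dtype=float),
                       where=wtotal > 0)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_meth": wmeth, "n_unmeth": wunmeth,
            "n_sites": ccov[hi] - ccov[lo], "ml": ml,
        }))
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_meth", "n_unmeth", "n_sites", "ml"])
    return pd.concat(rows, ignore_index=True)
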