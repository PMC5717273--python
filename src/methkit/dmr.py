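"""Sliding-window differentially-methylated-region (DMR) detection.

The caller scans the genome in 1000 bp windows stepped by 100 bp.
Windows with more than ``min_sites`` cytosines covered in both samples
are scored by (i) the unweighted mean of per-site corrected methylation
levels per sample, giving a fold change and an absolute difference, and
(ii) a two-sided Fisher exact test on the pooled methylated /
unmethylated read counts. Windows with fold change > 2, difference >
0.1 and p < 0.05 are potential DMRs; after BH-FDR (q < 0.05),
overlapping potential DMRs are merged and re-tested until a fixed point
of disjoint regions remains, which receives a final FDR pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation import estimate_nonconversion
from .model import Dmr, MethylomeError, MethylomeSample
from .stats import bh_fdr, fisher_exact_two_sided, five_number_summary


@dataclass(frozen=True)
class DmrParams:
    """Scan and filter parameters of the DMR caller.

    ``min_sites`` is a strict lower bound: a window is retained only
    when strictly more than ``min_sites`` cytosines are covered at
    ``min_depth`` in both samples. Fold-change and difference filters
    are strict ``>``; p and q filters are strict ``<``. ``epsilon``
    guards the fold-change denominator when a group mean is zero.
    """

    window: int = 1000
    step: int = 100
    min_sites: int = 10
    min_fold: float = 2.0
    min_diff: float = 0.1
    p_raw: float = 0.05
    q_final: float = 0.05
    epsilon: float = 1e-6
    min_depth: int = 5
    max_merge_iterations: int = 100

    def __post_init__(self) -> None:
        if self.step > self.window or self.step <= 0:
            raise MethylomeError(f"step {self.step} must be in (0, window]")
        if min(self.min_fold, self.min_diff, self.p_raw, self.q_final) <= 0:
            raise MethylomeError("thresholds must be positive")


@dataclass
class _ChromSites:
    """Sites covered at min_depth in both samples, one chromosome."""

    pos: np.ndarray          # 1-based, sorted (strands interleaved)
    cum_ma: np.ndarray       # cumulative methylated counts, sample A
    cum_ua: np.ndarray
    cum_mb: np.ndarray
    cum_ub: np.ndarray
    cum_mla: np.ndarray      # cumulative corrected site MLs
    cum_mlb: np.ndarray
    length: int

    def window_stats(self, start: int, end: int) -> tuple:
        lo = np.searchsorted(self.pos, start, side="left")
        hi = np.searchsorted(self.pos, end, side="right")
        n = hi - lo
        if n == 0:
            return 0, 0, 0, 0, 0, 0.0, 0.0
        return (
            int(n),
            int(self.cum_ma[hi] - self.cum_ma[lo]),
            int(self.cum_ua[hi] - self.cum_ua[lo]),
            int(self.cum_mb[hi] - self.cum_mb[lo]),
            int(self.cum_ub[hi] - self.cum_ub[lo]),
            float((self.cum_mla[hi] - self.cum_mla[lo]) / n),
            float((self.cum_mlb[hi] - self.cum_mlb[lo]) / n),
        )


def _shared_sites(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    r_a: float,
    r_b: float,
    min_depth: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, _ChromSites]:
    """Intersect the two samples on (chrom, pos, strand) at min_depth."""
    for name, s in (("A", sample_a), ("B", sample_b)):
        key = s.df[["chrom", "pos"]]
        grouped = key.groupby("chrom", observed=True)["pos"]
        if not grouped.apply(lambda x: bool(x.is_monotonic_increasing)).all():
            raise MethylomeError(f"sample {name} is not sorted by (chrom, pos)")
    a = sample_a.df[["chrom", "pos", "strand", "n_meth", "n_unmeth"]]
    b = sample_b.df[["chrom", "pos", "strand", "n_meth", "n_unmeth"]]
    a = a.loc[(a["n_meth"] + a["n_unmeth"]) >= min_depth]
    b = b.loc[(b["n_meth"] + b["n_unmeth"]) >= min_depth]
    merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    merged = merged.sort_values(["chrom", "pos", "strand"], kind="mergesort")

    def corrected(m: np.ndarray, u: np.ndarray, r: float) -> np.ndarray:
        ml = m / (m + u)
        return np.clip((ml - r) / (1.0 - r), 0.0, None)

    out: dict[str, _ChromSites] = {}
    for chrom, g in merged.groupby("chrom", observed=True, sort=True):
        ma = g["n_meth_a"].to_numpy(dtype=np.int64)
        ua = g["n_unmeth_a"].to_numpy(dtype=np.int64)
        mb = g["n_meth_b"].to_numpy(dtype=np.int64)
        ub = g["n_unmeth_b"].to_numpy(dtype=np.int64)
        pos = g["pos"].to_numpy(dtype=np.int64)
        length = int(chrom_sizes[chrom]) if chrom_sizes else int(pos[-1])

        def cum(x: np.ndarray) -> np.ndarray:
            return np.concatenate([[0], np.cumsum(x)])

        out[str(chrom)] = _ChromSites(
            pos=pos,
            cum_ma=cum(ma), cum_ua=cum(ua), cum_mb=cum(mb), cum_ub=cum(ub),
            cum_mla=cum(corrected(ma, ua, r_a)),
            cum_mlb=cum(corrected(mb, ub, r_b)),
            length=length,
        )
    return out


def _effect_sizes(ml_a: float, ml_b: float, epsilon: float) -> tuple[float, float]:
    hi, lo = max(ml_a, ml_b), min(ml_a, ml_b)
    return hi / max(lo, epsilon), abs(ml_a - ml_b)


def scan_windows(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    params: DmrParams | None = None,
    r_a: float = 0.0,
    r_b: float = 0.0,
    chrom_sizes: Mapping[str, int] | None = None,
    _shared: dict[str, _ChromSites] | None = None,
) -> pd.DataFrame:
    """Score every sliding window with enough shared coverage.

    Returns one row per retained window (strictly more than
    ``params.min_sites`` cytosines covered at ``min_depth`` in both
    samples) with per-group mean corrected ML, fold change, absolute
    difference, and the Fisher p on the pooled read counts.
    """
    params = params or DmrParams()
    shared = _shared if _shared is not None else _shared_sites(
        sample_a, sample_b, r_a, r_b, params.min_depth, chrom_sizes)
    rows = []
    for chrom in sorted(shared):
        cs = shared[chrom]
        starts = np.arange(1, cs.length + 1, params.step)
        ends = np.minimum(starts + params.window - 1, cs.length)
        lo = np.searchsorted(cs.pos, starts, side="left")
        hi = np.searchsorted(cs.pos, ends, side="right")
        n = hi - lo
        keep = n > params.min_sites
        lo, hi, n = lo[keep], hi[keep], n[keep]
        starts, ends = starts[keep], ends[keep]
        ma = cs.cum_ma[hi] - cs.cum_ma[lo]
        ua = cs.cum_ua[hi] - cs.cum_ua[lo]
        mb = cs.cum_mb[hi] - cs.cum_mb[lo]
        ub = cs.cum_ub[hi] - cs.cum_ub[lo]
        ml_a = (cs.cum_mla[hi] - cs.cum_mla[lo]) / n
        ml_b = (cs.cum_mlb[hi] - cs.cum_mlb[lo]) / n
        hi_ml = np.maximum(ml_a, ml_b)
        lo_ml = np.minimum(ml_a, ml_b)
        fold = hi_ml / np.maximum(lo_ml, params.epsilon)
        diff = np.abs(ml_a - ml_b)
        p = np.array([
            fisher_exact_two_sided(int(x1), int(x2), int(x3), int(x4))
            for x1, x2, x3, x4 in zip(ma, ua, mb, ub)
        ]) if len(n) else np.array([])
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "n_sites": n,
            "ml_a": ml_a, "ml_b": ml_b, "fold_change": fold,
            "difference": diff, "p": p,
        }))
    if not rows:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "n_sites", "ml_a", "ml_b",
            "fold_change", "difference", "p"])
    return pd.concat(rows, ignore_index=True)


def select_potential_dmrs(windows: pd.DataFrame, params: DmrParams | None = None) -> pd.DataFrame:
    """Apply the effect-size, p and FDR filters to scanned windows.

    Keeps windows with fold change strictly above ``min_fold``,
    difference strictly above ``min_diff`` and raw p strictly below
    ``p_raw``; BH-FDR is then computed over the kept windows and rows
    with q >= ``q_final`` are dropped.
    """
    params = params or DmrParams()
    mask = (
        (windows["fold_change"] > params.min_fold)
        & (windows["difference"] > params.min_diff)
        & (windows["p"] < params.p_raw)
    )
    kept = windows.loc[mask].reset_index(drop=True)
    if not len(kept):
        kept["q"] = pd.Series(dtype=float)
        return kept
    kept["q"] = bh_fdr(kept["p"].to_numpy())
    return kept.loc[kept["q"] < params.q_final].reset_index(drop=True)


def _as_regions(potential) -> list[tuple[str, int, int]]:
    if isinstance(potential, pd.DataFrame):
        items = [
            (str(r.chrom), int(r.start), int(r.end))
            for r in potential.itertuples(index=False)
        ]
    else:
        items = [
            (d[0], int(d[1]), int(d[2])) if isinstance(d, tuple)
            else (d.chrom, int(d.start), int(d.end))
            for d in potential
        ]
    return sorted(set(items))


def _union_overlapping(
    regions: list[tuple[str, int, int]]
) -> tuple[list[tuple[str, int, int]], bool]:
    """Union regions sharing >= 1 bp (1-based inclusive); flag changes."""
    merged: list[tuple[str, int, int]] = []
    changed = False
    for chrom, start, end in regions:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
            changed = True
        else:
            merged.append((chrom, start, end))
    return merged, changed


def merge_and_retest(
    potential,
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    params: DmrParams | None = None,
    r_a: float = 0.0,
    r_b: float = 0.0,
    _shared: dict[str, _ChromSites] | None = None,
) -> list[Dmr]:
    """Merge overlapping potential DMRs and re-test to a fixed point.

    Each round unions regions overlapping by >= 1 bp per chromosome,
    recomputes site counts, group means, fold change, difference and
    Fisher p over every merged span, and drops spans failing the site,
    effect-size or raw-p filters. Rounds repeat until no overlaps
    remain; the surviving regions receive one final BH-FDR pass
    (q < ``q_final``) and a hyper/hypo direction from the group means.
    ``potential`` may be the frame from :func:`select_potential_dmrs`,
    a list of :class:`Dmr`, or plain (chrom, start, end) triples.
    """
    params = params or DmrParams()
    shared = _shared if _shared is not None else _shared_sites(
        sample_a, sample_b, r_a, r_b, params.min_depth)
    regions = _as_regions(potential)

    def retest(chrom: str, start: int, end: int):
        cs = shared.get(chrom)
        if cs is None:
            return None
        n, ma, ua, mb, ub, ml_a, ml_b = cs.window_stats(start, end)
        if n <= params.min_sites:
            return None
        fold, diff = _effect_sizes(ml_a, ml_b, params.epsilon)
        if not (fold > params.min_fold and diff > params.min_diff):
            return None
        p = fisher_exact_two_sided(ma, ua, mb, ub)
        if not p < params.p_raw:
            return None
        return n, ml_a, ml_b, fold, diff, p

    survivors: list[tuple[tuple[str, int, int], tuple]] = []
    for _ in range(params.max_merge_iterations):
        merged, changed = _union_overlapping(regions)
        survivors = []
        for region in merged:
            result = retest(*region)
            if result is not None:
                survivors.append((region, result))
        regions = [region for region, _ in survivors]
        if not changed:
            break
    else:
        raise MethylomeError("merge/retest failed to reach a fixed point")

    if not survivors:
        return []
    q = bh_fdr(np.array([res[5] for _, res in survivors]))
    out = []
    for ((chrom, start, end), (n, ml_a, ml_b, fold, diff, p)), qi in zip(survivors, q):
        if not qi < params.q_final:
            continue
        out.append(Dmr(
            chrom=chrom, start=start, end=end, n_sites=n,
            ml_a=ml_a, ml_b=ml_b, fold_change=fold, difference=diff,
            p=p, q=float(qi), direction="hyper" if ml_a > ml_b else "hypo",
        ))
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def call_dmrs(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    lambda_a: MethylomeSample | None = None,
    lambda_b: MethylomeSample | None = None,
    params: DmrParams | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Dmr]:
    """End-to-end DMR calling between two samples.

    Non-conversion rates come from the lambda spike-ins when given,
    else from rates stored on the samples, else 0. The composition is
    estimate -> correct -> scan -> select -> merge-and-retest, and is
    deterministic for fixed inputs.
    """
    params = params or DmrParams()

    def rate(sample: MethylomeSample, spike: MethylomeSample | None) -> float:
        if spike is not None:
            return estimate_nonconversion(spike)
        return sample.nonconversion_rate or 0.0

    r_a, r_b = rate(sample_a, lambda_a), rate(sample_b, lambda_b)
    shared = _shared_sites(sample_a, sample_b, r_a, r_b, params.min_depth, chrom_sizes)
    windows = scan_windows(sample_a, sample_b, params, _shared=shared)
    potential = select_potential_dmrs(windows, params)
    return merge_and_retest(potential, sample_a, sample_b, params, _shared=shared)


def dmr_level_summary(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    """Five-number summary (min/Q1/median/Q3/max) of DMR MLs per group."""
    if not dmrs:
        raise MethylomeError("no DMRs to summarize")
    rows = {
        "A": five_number_summary([d.ml_a for d in dmrs]),
        "B": five_number_summary([d.ml_b for d in dmrs]),
    }
    return pd.DataFrame.from_dict(rows, orient="index")
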