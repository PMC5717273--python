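"""Synthetic sparse-methylome generator with planted DMRs.

Emulates an invertebrate-style WGBS experiment: a GC-poor genome in
which a small fraction of CG sites is methylated at high level (a Beta
component centred near 0.8), the remaining CG sites and all non-CG
sites are essentially unmethylated, read counts follow a
Poisson-coverage / binomial-conversion model with a configurable
bisulfite non-conversion rate, and an unmethylated lambda-phage contig
is emitted per library as the spike-in control. Differential regions
are planted in CG-dense stretches and returned as ground truth so that
caller sensitivity and precision can be measured.

Randomness is fully determined by ``SimulationConfig.seed``: every
stage draws from its own child stream of that seed, so identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .methylation import context_table
from .model import Dmr, GeneModel, MethylomeError, MethylomeSample, TruthRegion

_STREAMS = {
    "genome": 0, "genes": 1, "methylome": 2, "dmrs": 3,
    "counts_a": 4, "counts_b": 5, "lambda_seq": 6,
    "lambda_a": 7, "lambda_b": 8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Defaults mirror a sparse honeybee-like regime: ~25x coverage,
    non-conversion rate 0.0015 (conversion 99.85%), ~0.68% of CG sites
    methylated so that >99% of methylated cytosines fall in CG context
    and the genome-wide mC/C fraction lands near 0.19%, and planted
    differential regions of 1-3 kb shifting the true level by 0.3.
    """

    genome_length_bp: int = 2_000_000
    n_chroms: int = 4
    gc_fraction: float = 0.33
    cg_meth_high_fraction: float = 0.0068
    high_meth_beta_mean: float = 0.8
    high_meth_beta_conc: float = 10.0
    noncg_meth_rate: float = 0.0002
    mean_coverage: float = 25.0
    coverage_model: str = "poisson"   # or "nbinom"
    nb_dispersion: float = 5.0
    nonconversion_rate: float = 0.0015
    n_dmrs: int = 50
    dmr_length_range: tuple[int, int] = (1000, 3000)
    dmr_delta: float = 0.3
    dmr_hyper_fraction: float = 0.5
    min_cg_per_kb: int = 10
    dmr_min_separation: int = 2000
    gene_fraction: float = 0.4
    lambda_length: int = 48_502
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "gc_fraction": self.gc_fraction,
            "cg_meth_high_fraction": self.cg_meth_high_fraction,
            "noncg_meth_rate": self.noncg_meth_rate,
            "nonconversion_rate": self.nonconversion_rate,
            "dmr_hyper_fraction": self.dmr_hyper_fraction,
            "gene_fraction": self.gene_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise MethylomeError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.dmr_delta <= 1.0:
            raise MethylomeError(f"dmr_delta={self.dmr_delta} outside (0, 1]")
        if self.mean_coverage <= 0:
            raise MethylomeError("mean_coverage must be > 0")
        if self.coverage_model not in ("poisson", "nbinom"):
            raise MethylomeError(f"unknown coverage model {self.coverage_model!r}")
        lo, hi = self.dmr_length_range
        if not 0 < lo <= hi:
            raise MethylomeError(f"bad dmr_length_range {self.dmr_length_range}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dmr_length_range" in raw:
            raw["dmr_length_range"] = tuple(raw["dmr_length_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["dmr_length_range"] = list(data["dmr_length_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class TrueMethylome:
    """True per-site methylation levels for every defined-context C."""

    sites: dict[str, pd.DataFrame]  # pos, strand, context, tricontext, ml

    def copy(self) -> "TrueMethylome":
        return TrueMethylome({c: df.copy() for c, df in self.sites.items()})

    @property
    def n_sites(self) -> int:
        return sum(len(df) for df in self.sites.values())

    def mean_ml(self) -> float:
        total = sum(float(df["ml"].sum()) for df in self.sites.values())
        return total / self.n_sites


@dataclass
class CallEvaluation:
    """Recovery of planted truth regions by called DMRs."""

    sensitivity: float
    precision: float
    n_truth: int
    n_called: int
    hits: pd.DataFrame


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome at the configured GC fraction plus tiled gene models."""
    chrom_len = config.genome_length_bp // config.n_chroms
    if chrom_len < 6000:
        raise MethylomeError(
            f"chromosomes of {chrom_len} bp are too short to host genes")
    rng = config.rng("genome")
    gene_rng = config.rng("genes")
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    at, gc = (1 - config.gc_fraction) / 2, config.gc_fraction / 2
    cuts = np.cumsum([at, gc, gc])
    for ci in range(config.n_chroms):
        name = f"chr{ci + 1}"
        draws = rng.random(chrom_len)
        genome[name] = bases[np.searchsorted(cuts, draws)].tobytes().decode("ascii")
        genes.extend(_tile_genes(name, chrom_len, config, gene_rng))
    return genome, genes


def _tile_genes(
    chrom: str, chrom_len: int, config: SimulationConfig, rng: np.random.Generator
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    cursor = 2500  # promoter headroom for the first gene
    idx = 1
    f = max(config.gene_fraction, 1e-3)
    while True:
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(120, 800, size=n_exons)
        intron_lens = rng.integers(80, 500, size=n_exons - 1)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        if cursor + gene_len > chrom_len - 2500:
            break
        start = cursor
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i]) - 1))
            pos = exons[-1][1] + 1
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        introns = tuple(
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
        )
        strand = "+" if rng.random() < 0.5 else "-"
        first, last = exons[0], exons[-1]
        u5_len = min(150, (first[1] - first[0] + 1) // 2)
        u3_len = min(150, (last[1] - last[0] + 1) // 2)
        if strand == "+":
            utr5 = ((first[0], first[0] + u5_len - 1),)
            utr3 = ((last[1] - u3_len + 1, last[1]),)
            tss = start
        else:
            utr5 = ((last[1] - u5_len + 1, last[1]),)
            utr3 = ((first[0], first[0] + u3_len - 1),)
            tss = exons[-1][1]
        genes.append(GeneModel(
            gene_id=f"{chrom}_g{idx:04d}", chrom=chrom, strand=strand, tss=tss,
            exons=tuple(exons), introns=introns, utr5=utr5, utr3=utr3,
        ))
        idx += 1
        gap = int(gene_len * (1 - f) / f * (0.5 + rng.random()))
        cursor = exons[-1][1] + 1 + max(gap, 500)
    return genes


# ---------------------------------------------------------------------------
# True methylation levels
# ---------------------------------------------------------------------------

def assign_true_methylome(
    genome: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TrueMethylome:
    """Draw true per-site levels: bimodal CG, flat low non-CG.

    Each CG site is independently "methylated" with probability
    ``cg_meth_high_fraction``, in which case its level is drawn from
    Beta(mean*conc, (1-mean)*conc); otherwise its level is exactly 0.
    Every CHG/CHH site gets the constant ``noncg_meth_rate``.
    """
    rng = rng if rng is not None else config.rng("methylome")
    a = config.high_meth_beta_mean * config.high_meth_beta_conc
    b = (1 - config.high_meth_beta_mean) * config.high_meth_beta_conc
    sites: dict[str, pd.DataFrame] = {}
    for chrom in sorted(genome):
        tab = context_table(genome[chrom])
        ml = np.full(len(tab), config.noncg_meth_rate, dtype=float)
        cg = (tab["context"] == "CG").to_numpy()
        n_cg = int(cg.sum())
        high = rng.random(n_cg) < config.cg_meth_high_fraction
        levels = np.zeros(n_cg)
        if high.any():
            levels[high] = rng.beta(a, b, size=int(high.sum()))
        ml[cg] = levels
        tab = tab.copy()
        tab["ml"] = ml
        sites[chrom] = tab
    return TrueMethylome(sites)


def plant_dmrs(
    methylome: TrueMethylome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TrueMethylome, TrueMethylome, list[TruthRegion]]:
    """Plant differential regions; returns (group A, group B, truth).

    Regions are placed in CG-dense stretches (every overlapped kb must
    hold at least ``min_cg_per_kb`` CG sites) and kept at least
    ``dmr_min_separation`` bp apart so neighbouring calls cannot fuse.
    In a hyper region group A's true levels are raised by ``dmr_delta``
    (clamped to 1); in a hypo region group B's are — the baseline of a
    sparse methylome sits at ~0, so a downward shift of group A would
    carry no signal.
    """
    rng = rng if rng is not None else config.rng("dmrs")
    meth_a = methylome.copy()
    meth_b = methylome.copy()
    if config.n_dmrs == 0:
        return meth_a, meth_b, []

    cg_blocks: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, tab in methylome.sites.items():
        pos = tab.loc[tab["context"] == "CG", "pos"].to_numpy()
        length = int(tab["pos"].max()) if len(tab) else 0
        n_blocks = length // 1000 + 1
        counts = np.bincount((pos - 1) // 1000, minlength=n_blocks)
        cg_blocks[chrom] = counts >= config.min_cg_per_kb
        lengths[chrom] = length

    chroms = sorted(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    lo, hi = config.dmr_length_range
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truths: list[TruthRegion] = []
    tries = 0
    while len(truths) < config.n_dmrs:
        tries += 1
        if tries > 500 * config.n_dmrs:
            raise MethylomeError(
                f"could not place {config.n_dmrs} non-overlapping DMRs")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(lo, hi + 1))
        if lengths[chrom] <= length + 2:
            continue
        start = int(rng.integers(1, lengths[chrom] - length))
        end = start + length - 1
        blocks = cg_blocks[chrom][(start - 1) // 1000:(end - 1) // 1000 + 1]
        if not blocks.all():
            continue
        sep = config.dmr_min_separation
        if any(start - sep <= e and end + sep >= s for s, e in placed[chrom]):
            continue
        direction = "hyper" if rng.random() < config.dmr_hyper_fraction else "hypo"
        target = meth_a if direction == "hyper" else meth_b
        tab = target.sites[chrom]
        mask = (tab["pos"] >= start) & (tab["pos"] <= end)
        tab.loc[mask, "ml"] = np.clip(
            tab.loc[mask, "ml"] + config.dmr_delta, 0.0, 1.0)
        placed[chrom].append((start, end))
        truths.append(TruthRegion(chrom, start, end, direction, config.dmr_delta))
    truths.sort(key=lambda t: (t.chrom, t.start))
    return meth_a, meth_b, truths


# ---------------------------------------------------------------------------
# Read-count emission
# ---------------------------------------------------------------------------

def _draw_coverage(
    config: SimulationConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    if config.coverage_model == "poisson":
        return rng.poisson(config.mean_coverage, size=size)
    # negative binomial with mean mu and dispersion k: p = k / (k + mu)
    k = config.nb_dispersion
    p = k / (k + config.mean_coverage)
    return rng.negative_binomial(k, p, size=size)


def emit_counts(
    methylome: TrueMethylome,
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str = "",
) -> MethylomeSample:
    """Observed per-site counts from true levels.

    Coverage n is Poisson (or negative-binomial) around
    ``mean_coverage``; with non-conversion rate r the probability a
    read reports the site unconverted is ``p_obs = ml + (1 - ml) * r``
    and the methylated count is Binomial(n, p_obs).
    """
    r = config.nonconversion_rate
    frames = []
    for chrom in sorted(methylome.sites):
        tab = methylome.sites[chrom]
        n = _draw_coverage(config, len(tab), rng)
        p_obs = tab["ml"].to_numpy() + (1.0 - tab["ml"].to_numpy()) * r
        n_meth = rng.binomial(n, p_obs)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": tab["pos"].to_numpy(),
            "strand": tab["strand"].to_numpy(),
            "n_meth": n_meth,
            "n_unmeth": n - n_meth,
            "context": tab["context"].to_numpy(),
            "tricontext": tab["tricontext"].to_numpy(),
        }))
    df = pd.concat(frames, ignore_index=True)
    return MethylomeSample.from_frame(df, label=label)


def lambda_sequence(config: SimulationConfig) -> str:
    """The (unmethylated) spike-in contig; fixed per config seed."""
    rng = config.rng("lambda_seq")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.integers(0, 4, size=config.lambda_length)
    return bases[draws].tobytes().decode("ascii")


def emit_lambda(
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str = "lambda",
    lambda_length: int | None = None,
) -> MethylomeSample:
    """Spike-in counts: as :func:`emit_counts` with true level 0 everywhere."""
    if lambda_length is not None and lambda_length != config.lambda_length:
        config = dataclasses.replace(config, lambda_length=lambda_length)
    seq = lambda_sequence(config)
    tab = context_table(seq)
    tab = tab.copy()
    tab["ml"] = 0.0
    meth = TrueMethylome({"lambda": tab})
    return emit_counts(meth, config, rng, label=label)


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: list[TruthRegion]
    sample_a: MethylomeSample
    sample_b: MethylomeSample
    lambda_a: MethylomeSample
    lambda_b: MethylomeSample

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full paired experiment: genome, genes, two libraries, spike-ins."""
    genome, genes = simulate_genome(config)
    base = assign_true_methylome(genome, config)
    meth_a, meth_b, truth = plant_dmrs(base, config)
    sample_a = emit_counts(meth_a, config, config.rng("counts_a"), label="groupA")
    sample_b = emit_counts(meth_b, config, config.rng("counts_b"), label="groupB")
    lam_a = emit_lambda(config, config.rng("lambda_a"), label="lambdaA")
    lam_b = emit_lambda(config, config.rng("lambda_b"), label="lambdaB")
    return SimulatedDataset(
        config=config, genome=genome, genes=genes, truth=truth,
        sample_a=sample_a, sample_b=sample_b, lambda_a=lam_a, lambda_b=lam_b,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(dataset.genome, outdir / "genome.fa")
    mio.write_gene_models(dataset.genes, outdir / "genes.gff3")
    mio.write_cytosine_report(dataset.sample_a, outdir / "groupA.cx.tsv")
    mio.write_cytosine_report(dataset.sample_b, outdir / "groupB.cx.tsv")
    mio.write_cytosine_report(dataset.lambda_a, outdir / "lambdaA.cx.tsv")
    mio.write_cytosine_report(dataset.lambda_b, outdir / "lambdaB.cx.tsv")
    mio.write_truth_bed(dataset.truth, outdir / "truth.bed")
    dataset.config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# Evaluation against truth
# ---------------------------------------------------------------------------

def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def evaluate_calls(
    dmrs: Sequence[Dmr],
    truth: Sequence[TruthRegion],
    min_overlap_fraction: float = 0.3,
) -> CallEvaluation:
    """Sensitivity and precision of called DMRs against planted truth.

    A truth region is recovered when some single called DMR covers at
    least ``min_overlap_fraction`` of it; a called DMR is a true
    positive when it overlaps any truth region by >= 1 bp. Precision is
    NaN when nothing was called; empty truth is an error.
    """
    if not truth:
        raise MethylomeError("sensitivity is undefined for empty truth")
    rows = []
    for t in truth:
        best_bp, best = 0, None
        for d in dmrs:
            if d.chrom != t.chrom:
                continue
            ov = _overlap(d.start, d.end, t.start, t.end)
            if ov > best_bp:
                best_bp, best = ov, d
        recovered = best_bp >= min_overlap_fraction * len(t)
        rows.append({
            "chrom": t.chrom, "start": t.start, "end": t.end,
            "direction": t.direction, "best_overlap_bp": best_bp,
            "call_start": best.start if best else pd.NA,
            "call_end": best.end if best else pd.NA,
            "recovered": recovered,
        })
    hits = pd.DataFrame(rows)
    sensitivity = float(hits["recovered"].mean())
    true_pos = sum(
        1 for d in dmrs
        if any(d.chrom == t.chrom and _overlap(d.start, d.end, t.start, t.end) > 0
               for t in truth)
    )
    precision = true_pos / len(dmrs) if dmrs else float("nan")
    return CallEvaluation(
        sensitivity=sensitivity, precision=precision,
        n_truth=len(truth), n_called=len(dmrs), hits=hits,
    )
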