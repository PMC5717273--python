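import dataclasses

import numpy as np
import pandas as pd
import pytest

import methkit as mk


def make_sample(rows, label="test"):
    """Build a MethylomeSample from (chrom, pos, strand, m, u, ctx, tri) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth",
                       "context", "tricontext"])
    return mk.MethylomeSample.from_frame(df, label=label)


def uniform_sample(chrom, positions, n_meth, n_unmeth, strand="+",
                   context="CG", tricontext="CGA"):
    """Sample with identical counts at every given position."""
    return make_sample([
        (chrom, p, strand, n_meth, n_unmeth, context, tricontext)
        for p in positions
    ])


@pytest.fixture(scope="session")
def small_config():
    return mk.SimulationConfig(
        genome_length_bp=300_000, n_chroms=2, n_dmrs=8, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A compact paired experiment reused across unit tests."""
    return mk.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dmrs(small_dataset):
    return mk.call_dmrs(
        small_dataset.sample_a, small_dataset.sample_b,
        small_dataset.lambda_a, small_dataset.lambda_b)


@pytest.fixture()
def toy_genes():
    """Three hand-placed genes on a 20 kb contig (used by annotation tests)."""
    g1 = mk.GeneModel(
        gene_id="g1", chrom="c1", strand="+", tss=5000,
        exons=((5000, 5400), (5801, 6400)), introns=((5401, 5800),),
        utr5=((5000, 5100),), utr3=((6300, 6400),))
    g2 = mk.GeneModel(
        gene_id="g2", chrom="c1", strand="-", tss=12000,
        exons=((11000, 11500), (11801, 12000)), introns=((11501, 11800),),
        utr5=((11901, 12000),), utr3=((11000, 11100),))
    g3 = mk.GeneModel(
        gene_id="g3", chrom="c1", strand="+", tss=100,
        exons=((100, 300),))
    return [g1, g2, g3]


def dummy_dmr(chrom, start, end, direction="hyper", **kw):
    defaults = dict(
        n_sites=20, ml_a=0.4 if direction == "hyper" else 0.1,
        ml_b=0.1 if direction == "hyper" else 0.4,
        fold_change=4.0, difference=0.3, p=1e-6, q=1e-4)
    defaults.update(kw)
    return mk.Dmr(chrom=chrom, start=start, end=end,
                  direction=direction, **defaults)


def replace_config(config, **kw):
    return dataclasses.replace(config, **kw)
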