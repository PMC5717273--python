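# Methods

## Scope and data model

The package compares two WGBS libraries at per-cytosine resolution.
Input is a Bismark-CX-style report per library (chrom, 1-based
position, strand, methylated count, unmethylated count, context,
trinucleotide) plus a lambda spike-in report, a genome FASTA and a
gene GFF3. All on-disk coordinates are 1-based inclusive (Bismark /
GFF3 convention); BED output is 0-based half-open; any half-open
arithmetic happens only inside interval indexing. Zero-coverage rows
are kept on input and removed by depth filters, mirroring CX-report
behaviour. When a gene has several mRNAs the representative transcript
is the one with the longest genomic span, since components are
annotated per gene, not per isoform.

## Site-level model

A site's methylation level is the fraction of reads reporting it
unconverted, `ML = m/(m+u)`; zero coverage yields NaN, which is kept
distinct from a measured 0. The non-conversion rate *r* is the pooled
methylated-read fraction over all lambda cytosines; levels are
corrected by `max(0, (ML − r)/(1 − r))`. The correction is applied
uniformly to every downstream consumer of site levels (window means,
profiles, strata); counts fed to the Fisher test stay raw because the
test models reads, not rates.

Methylation calls use a one-sided binomial tail P(X ≥ m | n, r) —
excess methylation only — with BH-FDR across tested sites; a site is
methylated when q < α (default 0.05) and m ≥ 1. Sidedness and the BH
correction are package choices, standard for sparse methylomes where
only excess methylation is of interest; both are parameters. The depth filter defaults to 5× and is applied per sample.
Sites whose context is undefined (within 2 bp of a contig 3' end, or
with an N among the two downstream bases on the site's strand) are
excluded from every statistic.

Context is read 5'→3' on the cytosine's own strand: CG when the +1
base is G; CHG when the +1 base is A/C/T and the +2 base is G; CHH
otherwise. Genome-wide percentages divide methylated-site counts by
the full genomic context census (both strands), not by covered sites;
the landscape view pools counts in 3000 bp windows stepped by 600 bp.

## DMR caller

Windows of 1000 bp stepped by 100 bp are tiled from position 1. A
window is testable when strictly more than 10 cytosines are covered at
≥5× in both samples (sites must be shared; a window testable in one
sample only is uninterpretable). Per window the caller computes the
unweighted mean of per-site corrected levels per sample, the fold
change max/min of those means with a zero-guard ε = 1e-6 (fold change
is undefined at mean 0; the guard keeps ranking without infinities),
the absolute difference, and the two-sided Fisher exact p on pooled
counts. Filters are read literally: fold > 2, difference > 0.1,
p < 0.05, all strict, then BH-FDR with q < 0.05.

Overlapping (≥1 bp) potential DMRs are unioned per chromosome and each
merged span is re-tested from the underlying sites; spans failing the
site, effect-size or raw-p filters are dropped whole (no splitting —
the simplest rule that reaches a fixed point). Because one union pass
removes all overlaps and dropping cannot create new ones, the loop
terminates in practice after one round; a 100-iteration guard remains.
FDR is applied twice: at window selection and across the final merged
regions; intermediate retests use raw p. The final set is disjoint,
sorted, and idempotent under re-merging. Direction is hyper when group
A's mean exceeds group B's.

The Fisher p sums hypergeometric outcome probabilities no larger than
the observed table's, with a 1e-12 relative tie slack; pmf vectors are
computed from log-gamma and cached per margin triple. BH is the
standard vectorized step-up. Both are validated against independent
oracles (exact integer enumeration; a literal suffix-minimum loop and
statsmodels).

## Annotation and profiles

The promoter is the 2 kb immediately upstream of the TSS ([tss−2000,
tss−1] on +, [tss+1, tss+2000] on −), clipped to the contig. A DMR
receives a (gene, component) hit for every component interval it
overlaps by ≥1 bp and may hit several genes and components. A DMR
inside a gene span that misses every component interval gets a
`gene_body` fallback hit so the gene association survives sparse
annotations; the fallback is excluded from component percentages.
GO/KEGG enrichment is out of scope — the DMG table is exportable to
any enrichment tool.

Metagene profiles split each component instance into 20 equal bins
oriented by gene strand; a site lands in the bin containing its
fractional midpoint (pos − start + 0.5)/length, which also handles
components shorter than the bin count. Flanking k-mer analysis uses
k = 9 with the cytosine at position 4 (3 up, 5 down) — the offset that
reproduces the canonical printed motif shapes — over sites passing the
methylation call, stratified by context and by high/low level
(high: ML > 0.75 for CG, > 0.25 for non-CG, strict). Consensus uses
IUPAC codes on exact ties.

## Synthetic methylome

The generator emulates the study conditions the analysis assumes:

| parameter | default | why |
|---|---|---|
| genome | 2 Mb, 4 chromosomes, GC 0.33 | desk-scale stand-in for a 285 Mb genome at honeybee-like GC |
| CG high fraction | 0.0068 | matches the ~0.68% mCG/CG regime |
| high component | Beta(8, 2) (mean 0.8) | bimodal invertebrate CG pattern |
| low CG / non-CG level | 0 / 0.0002 | keeps >99% of called mCs in CG context |
| coverage | Poisson, mean 25× (negative binomial switchable) | only mean coverage is meaningful for the design |
| non-conversion r | 0.0015 | the 99.85% conversion regime |
| planted DMRs | 50 × 1–3 kb, delta 0.3, hyper:hypo 1:1 | recovery benchmark conditions |

Both strands of a CpG are simulated independently (no strand merging
anywhere in the pipeline). Planted regions are restricted to stretches
with ≥10 CG sites per kb so the caller's site filter is satisfiable,
and kept ≥2 scan-windows apart so neighbouring calls cannot fuse into
one span and distort precision accounting. Hyper regions raise group
A's true levels by delta (clamped at 1); hypo regions raise group B's
instead — on a ~0 baseline a downward shift of group A would carry no
signal, so this is the only way a two-sided benchmark is meaningful.
Each library gets its own lambda spike-in (48,502 bp, level 0). All
randomness derives from named child streams of one seed, so identical
configs are byte-identical.

What the simulator does *not* model: read-level artefacts (sequencing
error, PCR duplicates, mapping bias), autocorrelated coverage,
CpG-island structure, strand-correlated CpG methylation, and
between-replicate biological variance (the design has one pooled
library per group). Passing recovery benchmarks therefore demonstrate
the caller's statistical behaviour under the stated noise model, not
robustness to alignment artefacts or biological heterogeneity.

## Problem sizes and numerical notes

The validation suite runs the full pipeline on 2 Mb genomes (50
planted regions for recovery; 20 null replicates for calibration), a
size at which every rate being checked has comfortable sampling margin
— e.g. the configured 0.68% mCG regime yields ~700 methylated CG
sites, giving a ~4% relative standard error against a ±10% band.
Fisher p-values agree with exact enumeration to better than 1e-13 over
all margins ≤ 30; site-call p-values match a brute-force binomial sum
to 1e-12 for n ≤ 50. Degenerate inputs are explicit: empty lambda is
an error for rate estimation, empty truth is an error for sensitivity,
an empty DMR set is an error for the five-number summary, and empty
windows/bins are emitted with zero counts and NaN means rather than
dropped silently.
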