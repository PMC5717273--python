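"""Call methylated cytosines and summarize genome-wide context statistics.

Estimates the bisulfite non-conversion rate from the unmethylated
lambda spike-in, tests every covered cytosine against it with a
one-sided binomial test under BH-FDR control, and reports the
genome-wide census: what fraction of genomic C / CG / CHG / CHH
sites is methylated, and how methylated sites split across contexts.
"""

import methkit as mk

config = mk.SimulationConfig(
    genome_length_bp=1_000_000, n_chroms=2, n_dmrs=0, seed=3)
dataset = mk.simulate_dataset(config)

r = mk.estimate_nonconversion(dataset.lambda_a)
print(f"non-conversion rate r = {r:.5f}  "
      f"(BS conversion rate {100 * (1 - r):.2f}%)")

calls = mk.call_methylated_sites(dataset.sample_a, r=r, alpha=0.05, min_depth=5)
print(f"tested sites: {len(calls):,}; "
      f"methylated: {int(calls['is_methylated'].sum()):,}")

gw = mk.genome_wide_stats(calls, dataset.genome)
print(f"mC percent of all C sites:   {gw.pct_mc_of_c:.4f}%")
print(f"mCG percent of CG sites:     {gw.pct_mcg_of_cg:.4f}%")
print(f"mCHH percent of CHH sites:   {gw.pct_mchh_of_chh:.4f}%")
print(f"share of mCs in CG context:  {100 * gw.share('CG'):.2f}%")
# A sparse invertebrate-style methylome: well under 1% of cytosines are
# methylated and nearly all methylation falls in CG context.

landscape = mk.sliding_window_landscape(dataset.sample_a)
covered = landscape[landscape["n_sites"] > 0]
print(f"3000/600 landscape: {len(landscape):,} windows, "
      f"median pooled ML {covered['ml'].median():.4f}")
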