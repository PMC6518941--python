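"""Simulate a two-population genome with one inversion and scan it.

Generates Balding-Nichols genotypes at background FST 0.02 with a
segregating inversion on LG02, applies the genotype/site filter chain,
and runs a 100-kb windowed scan.  Windows inside the inversion should show
elevated FST and r² against a flat background.
"""

import numpy as np

from fjordflow import genomescan, genotypes, synthdata

spec = synthdata.InversionSpec(
    chromosome="LG02", start=300_000, end=800_000,
    arrangement_freq_per_pop=[0.15, 0.65], pool_divergence=0.4,
)
cfg = synthdata.GenoSimConfig(
    n_populations=2, n_per_pop=30, n_chromosomes=2, chrom_length_bp=1_200_000,
    n_snps_per_chrom=600, fst_target=0.02, inversion_specs=[spec], seed=1,
)
g, truth = synthdata.simulate_genotypes(cfg)
print(f"simulated {g.n_samples} individuals x {g.n_sites} SNPs")

g = genotypes.apply_genotype_filters(g, min_dp=3, min_gq=20)
g, report = genotypes.apply_site_filters(g)
print(f"site filters: {report.sites_in} -> {report.sites_out} SNPs")

tab = genomescan.scan(g, ["POP1", "POP2"], 100_000)
inside = (tab.chrom == "LG02") & (tab.start0 >= 300_000) & (tab.end <= 800_000)
print(f"median FST inside inversion : {tab.loc[inside, 'fst_POP1_POP2'].median():.3f}")
print(f"median FST elsewhere        : {tab.loc[~inside, 'fst_POP1_POP2'].median():.3f}")
print(f"median r2 inside inversion  : {tab.loc[inside, 'mean_r2'].median():.3f}")
print(f"median r2 elsewhere         : {tab.loc[~inside, 'mean_r2'].median():.3f}")
print("-> the non-recombining inversion stands out as a block of high")
print("   differentiation and high linkage against a weakly structured genome")
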