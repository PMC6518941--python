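"""Karyotype an inversion from region PCA and test arrangement frequencies.

Simulates three populations with different inverted-arrangement
frequencies at one region, calls anc/het/inv states from the
region-restricted PCA, tabulates chromosome-level arrangement counts, and
runs the bootstrap over-representation test against the pooled frequency
plus the exact Hardy-Weinberg test per population.
"""

import numpy as np

from fjordflow import inversions, synthdata
from fjordflow.genotypes import GenotypeMatrix

spec = synthdata.InversionSpec(
    chromosome="LG12", start=400_000, end=13_400_000,
    arrangement_freq_per_pop=[0.10, 0.30, 0.55], pool_divergence=0.4,
)
calls_mat, pos, truth_states = synthdata.simulate_inversion_region(
    spec, [40, 40, 40], seed=2, n_snps=400
)
pops = ["TVEf"] * 40 + ["TVEn"] * 40 + ["NOR"] * 40
g = GenotypeMatrix(
    calls=calls_mat, chrom=np.array(["LG12"] * len(pos), dtype=object), pos=pos,
    samples=[f"S{i}" for i in range(120)], populations=pops,
)

region = inversions.InversionRegion("LG12", 400_000, 13_400_000)
kcalls = inversions.call_region(g, region, seed=0)
acc = np.mean([c.state == truth_states[i] for i, c in enumerate(kcalls)])
print(f"karyotype calls vs simulation truth: {acc:.1%} concordant")

table = inversions.arrangement_frequencies(kcalls, dict(zip(g.samples, pops)))
print(table[["population", "anc", "het", "inv", "inv_chroms"]].to_string(index=False))

results = inversions.bootstrap_overrep_test(table, B=100_000, seed=0)
print("\nover-representation tests (one-sided, Bonferroni-corrected):")
for r in results:
    if r.p_bonferroni < 0.05:
        print(f"  {r.population}: {r.arrangement} arrangement over-represented "
              f"(obs {r.observed}/{r.n_chromosomes} vs pooled {r.pooled_freq:.2f}, "
              f"p_bonf={r.p_bonferroni:.4g})")

print("\nHardy-Weinberg exact p per population (all should be > 0.05):")
for _, row in table.iterrows():
    p = inversions.hwe_exact(int(row["anc"]), int(row["het"]), int(row["inv"]))
    print(f"  {row['population']}: p = {p:.3f}")
print("-> arrangement-frequency shifts between sympatric populations with")
print("   within-population HWE are the signature of an adaptive barrier")
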