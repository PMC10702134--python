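"""Simulate a carrier x carrier family and inspect the ground truth.

Builds the default desk-scale panel (2,000 backbone SNPs per autosome plus
the 407 target-region SNPs around HBA1+HBA2), draws phased carrier parents
and eight embryos under the default WGA noise model, and prints each
embryo's true SEA genotype with its simulated Gap-PCR peaks.
"""

from alphapgt import simulate_family

sim = simulate_family(n_embryos=8, seed=42)
print(f"panel: {len(sim.panel)} SNPs; family: {sim.config.family_id}")
print(f"father risk haplotype index: {sim.father.risk_index}")
for truth in sim.truths:
    peaks = ", ".join(
        f"{p.size_bp}bp/{p.dye}" for p in sim.peaks[truth.embryo_id]
    )
    print(f"  {truth.embryo_id}: true genotype {truth.true_genotype:8s} peaks [{peaks}]")
# '--' alleles carry the SEA deletion; a 178-bp HEX peak reports a deletion
# allele and a 280-bp FAM peak an intact allele, so peaks mirror the truth
# except when PCR allele dropout (1% per allele here) hides one.
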