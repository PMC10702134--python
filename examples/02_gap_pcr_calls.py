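"""Interpret fluorescent Gap-PCR peaks and compare first/retest runs.

The three-primer SEA assay yields a 280-bp FAM product from each intact
allele and a 178-bp HEX product from each deletion allele; the peak pattern
is the genotype. Retesting the same amplified sample exposes allele dropout:
a homozygous first call that turns carrier on retest names the dropped
allele.
"""

from alphapgt import PcrPeak, call_pcr_genotype, compare_pcr_runs

lanes = {
    "normal": [PcrPeak(280, 1200.0, "FAM")],
    "carrier": [PcrPeak(178, 800.0, "HEX"), PcrPeak(280, 1100.0, "FAM")],
    "affected": [PcrPeak(178, 950.0, "HEX")],
    "noise only": [PcrPeak(280, 40.0, "FAM"), PcrPeak(178, 500.0, "HEX")],
}
for name, peaks in lanes.items():
    print(f"{name:11s} -> {call_pcr_genotype(peaks).name}")
# 'noise only': the 280-bp peak is 8% of the lane maximum, below the 10%
# relative threshold, so only the deletion allele is asserted.

first = call_pcr_genotype(lanes["normal"])
retest = call_pcr_genotype(lanes["carrier"])
print(f"first {first.name}, retest {retest.name} -> {compare_pcr_runs(first, retest).value}")
# A NORMAL-then-CARRIER pair means the mutant (deletion) allele dropped out
# in the first amplification.
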