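"""BAF/LRR copy-number screening with origin and meiotic staging.

Simulates a maternal meiosis-I trisomy 16, a maternal monosomy 16 and a
euploid sibling, then screens them. A trisomy shows median LRR ~ +0.585 and
heterozygous-context BAF bands at 1/3 and 2/3; the pericentromeric band
pattern separates meiosis I (both maternal homologs, BPH) from meiosis II
(a duplicated chromatid, SPH).
"""

from alphapgt import AneuploidySpec, genome_screen, simulate_family
from alphapgt.sim import NOISELESS

specs = [
    AneuploidySpec(),
    AneuploidySpec("trisomy", "16", "mother", "MI"),
    AneuploidySpec("monosomy", "16", "mother"),
]
sim = simulate_family(n_embryos=3, noise=NOISELESS, seed=19, aneuploidies=specs)
for e, t in zip(sim.embryos, sim.truths):
    result = genome_screen(e, sim.father_array, sim.mother_array)
    call = result.calls["16"]
    bands = call.evidence["baf_bands"]
    print(f"{e.sample_id}: {call.iscn_like:14s} stage={call.stage} "
          f"euploid={result.euploid} medianLRR={call.evidence['median_lrr']:+.3f} "
          f"BAF mass 1/3+2/3={bands['1/3'] + bands['2/3']:.2f} 1/2={bands['1/2']:.2f}")
# 'arr(16)×3 mat MI' reads: three copies of chromosome 16, extra copy of
# maternal origin, error in the first meiotic division. The monosomy line
# names the lost parent.
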