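# alphapgt

Preimplantation genetic testing (PGT) toolkit for **SEA-type α-thalassemia**,
the Southeast-Asian deletion that removes both α-globin genes (HBA1 + HBA2,
16p13.3). When both partners are carriers (--/αα), each embryo has a 1-in-4
risk of the lethal homozygous state (--/--, Hb Bart's hydrops fetalis). The
package implements a comprehensive embryo-testing workflow that combines
**two independent genotype readouts** and reconciles them:

1. **Fluorescent Gap-PCR** — direct deletion genotyping. A 280-bp FAM product
   amplifies only from an intact allele and a 178-bp HEX product only across
   the deletion breakpoints, so the peak pattern *is* the genotype
   (280 → αα/αα, 178+280 → --/αα, 178 → --/--). Its weakness in single-cell,
   whole-genome-amplified (WGA) material is allele dropout (ADO): a carrier
   can masquerade as homozygous.
2. **SNP-array haplotype linkage analysis** — *informative SNPs* (one parent
   heterozygous AB, the other homozygous) within a 2-Mb region flanking
   HBA1+HBA2 track which parental haplotype each embryo inherited. Phase is
   anchored by a sibling **reference embryo** whose Gap-PCR genotype is
   homozygous (--/-- or αα/αα), or, failing that, by a pair of carrier
   embryos. The same array's B-allele frequency (BAF, bands at k/CN) and
   log R ratio (LRR ≈ log₂(CN/2)) provide genome-wide **aneuploidy
   screening**, including the parental origin of a trisomy and its meiotic
   stage (pericentromeric BPH ⇒ meiosis I, SPH ⇒ meiosis II).

When the two readouts disagree, a **decision engine** resolves the
discordance in a fixed order: chromosome-16 trisomy (both-parental-homolog
patterns scramble the target-region haplotype), chromosome-16 monosomy
(a single hemizygous haplotype remains), poor WGA quality (low SNP call
rate → rebiopsy), and PCR allele dropout (retest of the amplified sample).
Embryos are finally ranked for transfer — homozygous normal before carrier,
affected/unresolved/aneuploid excluded, carriers demoted when a family has no
5′-flank informative SNPs (the telomeric side of HBA is marker-poor, so a
recombination there would be invisible).

Because no clinical data ship with the package, a **synthetic family
simulator** generates the whole study design with retained ground truth:
phased carrier parents, embryo meioses with Poisson recombination (zero
intensity telomeric of HBA, matching the observed hotspot asymmetry),
whole-chromosome trisomy/monosomy with MI/MII mechanics, deletion-aware
BAF/LRR rendering, WGA noise (ADO, miscalls, no-calls, Gaussian BAF/LRR
noise) and Gap-PCR peak simulation.

## Worked example

```python
from alphapgt import AneuploidySpec, analyze_simulated_family, simulate_family

specs = [AneuploidySpec()] * 6 + [
    AneuploidySpec("trisomy", "16", "mother", "MI"),
    AneuploidySpec("monosomy", "16", "mother"),
]
sim = simulate_family(n_embryos=8, seed=5, aneuploidies=specs)
ana = analyze_simulated_family(sim, seed=5)
for r in ana.reports:
    print(r.embryo_id, r.pcr_genotype.name, r.haplotype.value,
          "->", r.final_genotype, r.cause.value)
```

prints (abridged from `examples/05_discordance_resolution.py`):

```
fam1_E1: PCR CARRIER  hap CARRIER      -> final --/αα     [CONCORDANT]
fam1_E7: PCR CARRIER  hap UNDETERMINED -> final --/--/αα  [TRISOMY16_BPH]
fam1_E8: PCR NORMAL   hap UNDETERMINED -> final αα        [MONOSOMY16]
```

The maternal MI trisomy delivers both maternal homologs, so the maternal
haplotype is uncallable ("UNDETERMINED") and the copy-number review explains
the PCR/haplotype conflict: the embryo carries two deletion alleles and one
intact allele (`--/--/αα`, `arr(16)×3 mat`, meiosis I). The monosomic embryo
lost its maternal chromosome 16 and retains a single paternal non-risk
haplotype (hemizygous `αα`), which a Gap-PCR alone would have misread as
homozygous normal.

Each `examples/0*.py` script exercises one capability (simulation, PCR
interpretation, haplotype linkage, aneuploidy screening, resolution) and
prints what the numbers mean.

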