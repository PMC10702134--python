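# The ten discordant Gap-PCR / haplotype cases observed in the 172-embryo
# clinical cohort, encoded as decision-engine inputs.
#
# Field semantics:
#   pcr               first-pass Gap-PCR genotype (peak interpretation)
#   haplotype.value   the first-pass haplotype genotype label as reported
#                     (used for the concordance comparison); UNDETERMINED
#                     encodes a target-region haplotype confused beyond a call
#   haplotype.paternal/.maternal
#                     the post-review per-parent transmission verdicts, i.e.
#                     the evidence available after whole-chromosome review
#                     (a trisomic origin parent's own call is NOCALL: its
#                     region shows both parental homologs at once)
#   chr16             copy-number review of chromosome 16
#   retest            Gap-PCR result of re-amplifying the same biopsy sample
#   rebiopsy          both methods re-run on a second biopsy of the embryo
#   expected          the adjudicated final genotype and cause category
cases:
  - embryo: "1"
    pcr: NORMAL
    haplotype: {value: CARRIER, annotation: maternal heterozygous, paternal: NONRISK, maternal: RISK}
    chr16: {copy_number: 2}
    call_rate: 0.97
    retest: CARRIER
    expected: {final: "--/αα", cause: ADO_MUTANT_ALLELE}
  - embryo: "2"
    pcr: CARRIER
    haplotype: {value: AFFECTED, annotation: abnormal homozygous, paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.96
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "3"
    pcr: CARRIER
    haplotype: {value: UNDETERMINED, annotation: heterozygous (confused), paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.97
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "4"
    pcr: CARRIER
    haplotype: {value: AFFECTED, annotation: abnormal homozygous, paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.95
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "5"
    pcr: CARRIER
    haplotype: {value: AFFECTED, annotation: abnormal homozygous, paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.96
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "6"
    pcr: AFFECTED
    haplotype: {value: CARRIER, annotation: maternal heterozygous, paternal: NONRISK, maternal: RISK}
    chr16: {copy_number: 2}
    call_rate: 0.96
    retest: CARRIER
    expected: {final: "--/αα", cause: ADO_NORMAL_ALLELE}
  - embryo: "7"
    pcr: CARRIER
    haplotype: {value: UNDETERMINED, annotation: heterozygous (confused), paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.97
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "8"
    pcr: AFFECTED
    haplotype: {value: CARRIER, annotation: maternal heterozygous, paternal: NONRISK, maternal: RISK}
    chr16: {copy_number: 2}
    call_rate: 0.88
    retest: AFFECTED
    rebiopsy: {pcr: AFFECTED, haplotype: AFFECTED, call_rate: 0.95}
    expected: {final: "--/--", cause: POOR_WGA_QUALITY}
  - embryo: "9"
    pcr: CARRIER
    haplotype: {value: NORMAL, annotation: normal homozygous, paternal: RISK, maternal: NOCALL}
    chr16: {copy_number: 3, origin: mother, stage: MI}
    call_rate: 0.96
    expected: {final: "--/--/αα", cause: TRISOMY16_BPH}
  - embryo: "10"
    pcr: NORMAL
    haplotype: {value: CARRIER, annotation: heterozygous (confused), paternal: NONRISK, maternal: NOCALL}
    chr16: {copy_number: 1, lost: mother, retained: father, retained_risk: non-risk}
    call_rate: 0.96
    expected: {final: "αα", cause: MONOSOMY16}
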