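# Methods

## Scope and coordinate conventions

All genomic coordinates are GRCh37, 1-based, closed intervals. The target
locus is HBA1+HBA2 at 16:222,846–227,521; the analysed region extends 2 Mb
to each side. Because the genes lie < 0.3 Mb from the 16p terminus, the 5′
(telomeric, lower-coordinate) flank clips to [1, 222,845] while the 3′
(centromeric) flank spans [227,522, 2,227,521]. Genotypes use the Illumina
AB abstraction; BAF is the B-allele fraction and LRR the log₂ R ratio
(0 at two copies). Missing BAF/LRR values are excluded from summaries, never
imputed. The SEA deletion interval defaults to the locus interval and is
configurable; the default is *not* a claim about the true ~19-kb breakpoints,
which the workflow never needs.

## Gap-PCR model

Peak interpretation is purely presence/absence: a peak within ±3 bp of
280 bp asserts an intact allele, within ±3 bp of 178 bp a deletion allele.
The calling threshold defaults to 10% of the tallest peak in the lane — a
relative threshold, since absolute fluorescence units vary by instrument.
Dye identity (280↔FAM, 178↔HEX) is checked when present but a mismatch only
warns, because exported peak tables often omit dye. Primer sequences are
carried as metadata constants; no amplification thermodynamics are modelled.
Within-run peak-height ratios are not used to call ADO; dropout is inferred
only across runs (first vs retest) and across methods (PCR vs haplotype).

## Informative SNPs and phasing

An informative SNP for parent P has P heterozygous (AB) and the other parent
homozygous; a no-call in either parent excludes the SNP. At such a SNP, any
offspring genotype determines P's transmitted allele by Mendelian
subtraction; an offspring call homozygous for the non-obligate allele is
read as P transmitting that allele with the other parent's allele lost to
ADO. Carrier parents are hemizygous across the deletion, so in-gene SNPs can
never be informative — the linkage necessarily brackets the genes from the
flanks.

Phasing uses a sibling reference embryo assumed non-recombinant across the
region and euploid on chromosome 16 (checked against the genome screen when
available): an affected (--/--) reference carries both risk haplotypes, so
its transmitted alleles *are* the risk alleles; a normal (αα/αα) reference
gives the complement. Affected references are preferred over normal ones
(both parents anchored by construction with no complement step), matching
the clinical preference for homozygous probands. A Mendelian-inconsistency
fraction above 5% of informative SNPs aborts phasing as suspected
contamination or aneuploidy.

When no homozygous reference exists, two carrier embryos are phased jointly.
Cross-embryo consistency of the four risk-parent assignments alone always
leaves a two-fold ambiguity (the global risk/non-risk label swap), so the
deletion interval supplies the anchor: a carrier embryo is hemizygous inside
the deletion, and its surviving in-gene alleles must match the blood-array
in-gene (equally hemizygous) alleles of the parent that donated the intact
chromosome. If the parents are indistinguishable at every called in-gene
SNP the result is a no-call, reported as ambiguous.

## Embryo haplotype calls

For one parent, each usable informative SNP votes match/mismatch against the
phased risk allele, ordered by position. Defaults: minimum 3 usable SNPs per
parent (below which the verdict is NOCALL — routine for the 2–3-SNP 5′
flank), majority fraction 0.8, minimum recombination block 3 consecutive
SNPs. Recombination is tested before the majority rule: two or more
alternating concordance blocks of ≥ 3 SNPs, *covering ≥ 90% of usable SNPs*,
yield RECOMBINANT with the breakpoint placed in the inter-block gap. The
coverage requirement is what separates a genuine crossover (two clean blocks
spanning the region) from the scattered ~50% concordance a trisomic or
monosomic chromosome produces, which instead falls through the majority rule
to NOCALL — the "confused haplotype" signature that routes such embryos into
the copy-number review. Testing blocks first is also what lets a crossover
between the sparse 5′ flank and the large 3′ flank be recognised rather than
swallowed by the 3′ majority.

Joint genotype: RISK+RISK → affected, NONRISK+NONRISK → normal, mixed →
carrier annotated with the transmitting parent. A breakpoint interval
overlapping the gene interval leaves the genotype undetermined; a breakpoint
clear of the locus is resolved by the concordance block on the locus side
and flagged low-confidence. Any parental NOCALL propagates to an
undetermined genotype, which the resolution engine treats as a discordance.

## Copy-number calling, origin and stage

Per chromosome, with ≥ 20 usable SNPs: copy number 3 requires median LRR
> +0.3 and heterozygous-context BAF mass concentrated at 1/3+2/3 rather than
1/2; copy number 1 requires median LRR < −0.5 and ≤ 5% mass in the 1/2 band;
anything else is two-copy (an LRR shift without matching BAF bands is
reported as a "non-integer pattern" warning, not a mosaic call). Band
half-width is 0.08. These thresholds are ideal-scale defaults (LRR rendered
as log₂(CN/2)); all live in `CnvParams`.

Trisomy origin is a band-likelihood comparison at informative SNPs. With het
parent P and hom parent of per-allele B-dose x ∈ {0,1}, the expected BAF
bands are: extra from P via MI — the single band (1+x)/3 (both of P's
alleles present: BPH); extra from P via MII — x/3 and (2+x)/3 at ½ each
(duplicated chromatid: SPH); extra from the hom parent — 2x/3 and (2x+1)/3
at ½ each. Observed BAFs are binned to the nearest CN-3 band and a
multinomial log-likelihood with a 5% off-model floor is summed per
hypothesis; the winning parent is reported with a per-SNP margin score.
Meiotic stage is then read within the pericentromeric window (the innermost
20% of each arm's SNPs around the centromere): the BPH band votes MI, the
SPH bands vote MII, majority 0.8, minimum 3 informative SNPs.

Monosomy attribution counts parent-specific alleles: at the retained
parent's informative SNPs the hemizygous embryo shows the allele the other
parent could not have supplied at ≈ 50% of SNPs; at the lost parent's SNPs
essentially never. The retained chromatid is classified risk/non-risk
against the parental phase when one exists. In the ISCN-style display string
the mat/pat suffix names the extra-copy parent for a trisomy but the *lost*
parent for a monosomy, mirroring the clinical-report convention this
follows; the asymmetry is deliberate and documented on `format_iscn_like`.

The euploidy verdict requires every autosome at two copies; sex chromosomes,
when present on a panel, are called but never used for transfer decisions.
Any unanalyzable autosome fails the whole screen.

## Discordance resolution

Concordant PCR/haplotype calls are final as-is. Discordances resolve in
order: (1) chr16 trisomy → the three-allele genotype is derived from the
reviewed evidence (an MI carrier origin parent contributes one risk + one
non-risk chromatid; MII duplicates the chromatid named by that parent's own
haplotype verdict; the other parent's chromatid follows their verdict);
(2) chr16 monosomy → the single retained allele per the retained-parent
analysis; (3) call rate < 0.90 → rebiopsy; a rebiopsy concurring with the
original PCR blames poor WGA quality and keeps the PCR genotype; (4) PCR
retest → a changed retest matching the haplotype is ADO (direction from the
first call: NORMAL-first means the mutant allele dropped, AFFECTED-first the
normal allele), resolved to the haplotype genotype; (5) an unchanged retest
with a clean sample → rebiopsy; persistent conflict stays UNRESOLVED,
excluded from transfer. The call-rate threshold 0.90 sits between the
observed poor (0.88) and good (0.95) samples and is configurable.
Copy-number explanations deliberately precede retesting: an aneuploid
chromosome 16 explains the conflict without consuming sample.

Cohort summaries print consistency and euploidy rates to 1 decimal and the
ADO rate to 2 decimals, matching clinical-report style. Transfer ranking:
homozygous normal before carrier; affected, unresolved and non-euploid
excluded; when either parent has zero 5′-flank informative SNPs, carriers
are flagged with elevated misdiagnosis risk and an only-normal
recommendation is attached; ties break by call rate then embryo id.

## The simulator

The generator reproduces the study design, not any one dataset.

* **Panel.** 2,000 evenly spaced backbone SNPs per autosome (desk-scale
  stand-in for a ~300k genome-wide array) plus the 407 target-region SNPs in
  the documented flank composition 42 / 10 / 355 (5′ / in-gene / 3′).
* **Parents.** Two haplotypes per parent, B alleles i.i.d. Bernoulli(maf)
  per SNP, default maf 0.5; one haplotype per parent flagged as the risk
  (deletion) haplotype. Parent blood arrays render noise-free, hemizygous
  across the deletion (CN 1, LRR −1). At balanced maf the per-parent
  informative expectation in the 3′ flank is 355 · 2p(1−p)(p²+(1−p)²) =
  88.75 — about twice the clinical average of ~42.5, which reflects a
  real-world unbalanced allele-frequency spectrum the default deliberately
  does not model; tests that depend on informative counts use the closed
  form above.
* **Meiosis.** Crossovers are a Poisson process with piecewise-constant
  intensity; the default is one expected crossover per autosome with zero
  intensity telomeric of the HBA locus on chromosome 16 (the observed
  hotspot asymmetry: recombination near the 16p telomere is not expected).
  A variant map with zero intensity across the whole flanked region exists
  for validations that assume non-recombinant transmission.
* **Aneuploidy.** Whole-chromosome only. Trisomy MI transmits both intact
  homologs of the origin parent (BPH everywhere, in particular at the
  pericentromere); MII transmits one recombined chromatid twice (SPH);
  monosomy removes the origin parent's contribution. Segmental and mosaic
  events are out of scope.
* **Rendering.** Ideal BAF = (#B)/CN and LRR = log₂(CN/2) before Gaussian
  noise (defaults: BAF sd 0.04, LRR sd 0.15). SNPs on a risk chromatid
  inside the deletion contribute no allele: carriers are hemizygous there,
  double-risk embryos nullizygous (no-call, missing BAF). WGA allele dropout
  (default 0.05 per allele copy) is applied before genotype calling;
  genotype strings derive from post-dropout alleles while BAF/LRR derive
  from the pre-dropout copy state; miscalls (0.005) and no-calls (0.02)
  follow. The Gap-PCR simulation drops each allele copy independently
  (default 0.01, the order of the clinically estimated 1.16% assay ADO rate)
  and merges surviving copies of a product into one peak. The WGA-level
  noise defaults are free parameters chosen to produce realistic single-cell
  call rates (~0.97) and visible but resolvable haplotype noise; no
  published per-SNP WGA ADO rate exists to calibrate against.
* **Determinism.** One seed feeds a splittable `SeedSequence`; stream 0
  draws the parents, stream i+1 embryo i, so embryo outcomes are independent
  of sibling count. Identical seeds give byte-identical outputs.

## What the synthetic validations do and do not show

The batteries (`alphapgt.validation`) measure: exact caller/truth
equivalence at zero noise over 100 embryos spanning every supported event
type; ≥ 98% final-genotype recovery over 500 embryos at default noise with a
10% aneuploidy mix; zero tolerance for a truth-affected embryo appearing in
any transfer ranking; 1:2:1 segregation at n = 2,000; and the 2ε(1−ε)
carrier-miscall law for PCR dropout. Problem sizes (10×10, 25×20 families,
2,000-embryo ratio runs, 20,000 PCR draws) were chosen as the smallest that
make the binomial error bars meaningfully tighter than the thresholds.
Passing them shows the *implementation* is faithful to its own model; it
does not validate the model against real arrays — cluster-file artefacts,
GC waves, mosaicism, segmental events and the true allele-frequency spectrum
are all absent from the generator, and genotype calling from BAF clustering
(as array software actually does it) is replaced by allele-presence logic.

## Known limitations

* No statistical (population-reference) phasing; phase comes strictly from
  pedigree/reference embryos, as the workflow prescribes.
* No segmental CNV breakpointing, mosaicism quantification or
  uniparental-disomy calling.
* The carrier-pair fallback needs the parents to differ at ≥ 1 called
  in-gene SNP; otherwise it is (correctly) ambiguous.
* A reference embryo recombinant within the 2-Mb region silently violates
  the non-recombination assumption; the workflow partially self-corrects
  through the retest/rebiopsy path of the decision tree, but phasing from such
  a reference is wrong beyond the breakpoint.
* Clinical outcome metrics (pregnancy, miscarriage) are out of scope;
  summaries cover laboratory quantities only.
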