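"""Fluorescent Gap-PCR interpretation for the SEA-type alpha-globin deletion.

The three-primer assay amplifies a 280-bp FAM-labelled product from the intact
allele (internal primer anneals inside the deleted segment) and a 178-bp
HEX-labelled product across the deletion breakpoints, so the two peaks report
the normal and deletion alleles independently:

=============  ==========  ==================
peaks present  genotype    thalassemia status
=============  ==========  ==================
280 only       alpha/alpha x2   homozygous normal
178 + 280      --/alpha    heterozygous carrier
178 only       --/--       homozygous affected
none           (FAIL)      amplification failure
=============  ==========  ==================

Allele dropout (ADO) — the stochastic failure to amplify one allele of a
heterozygote from whole-genome-amplified single-cell material — makes a
carrier look homozygous; it is detected by retesting the amplified sample and
by cross-checking against SNP haplotype analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .model import AlphaPgtError, DomainError

__all__ = [
    "NORMAL_PRODUCT_BP",
    "DELETION_PRODUCT_BP",
    "PRIMERS",
    "PcrPeak",
    "PcrGenotype",
    "RunComparison",
    "call_pcr_genotype",
    "compare_pcr_runs",
]

#: product of the internal primer pair: present only when an intact allele exists
NORMAL_PRODUCT_BP = 280
#: product of the breakpoint-flanking pair: present only when a deletion allele exists
DELETION_PRODUCT_BP = 178

#: primer metadata (sequences 5'->3'); carried as constants, no PCR thermodynamics
PRIMERS = {
    "S1": {"sequence": "gtgttctcagtattggagggaa", "dye": None},
    "S2": {"sequence": "gacacgcttccaatacgctta", "dye": "FAM", "product_bp": 280},
    "S3": {"sequence": "ctactgcagccttgaactcc", "dye": "HEX", "product_bp": 178},
}

_EXPECTED_DYE = {NORMAL_PRODUCT_BP: "FAM", DELETION_PRODUCT_BP: "HEX"}


@dataclass(frozen=True)
class PcrPeak:
    """One called fragment peak from the genetic analyser."""

    size_bp: int
    height: float
    dye: str | None = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise DomainError("peak size must be positive")
        if self.height <= 0:
            raise DomainError("peak height must be positive")


class PcrGenotype(str, Enum):
    """Three-level SEA genotype implied by peak presence, plus failure."""

    NORMAL = "NORMAL"      # alpha-alpha / alpha-alpha, 280-bp peak only
    CARRIER = "CARRIER"    # -- / alpha-alpha, both peaks
    AFFECTED = "AFFECTED"  # -- / --, 178-bp peak only
    FAIL = "FAIL"          # no peak above threshold

    @property
    def genotype_string(self) -> str:
        return {
            PcrGenotype.NORMAL: "αα/αα",
            PcrGenotype.CARRIER: "--/αα",
            PcrGenotype.AFFECTED: "--/--",
            PcrGenotype.FAIL: "fail",
        }[self]

    @property
    def is_homozygous(self) -> bool:
        return self in (PcrGenotype.NORMAL, PcrGenotype.AFFECTED)


class RunComparison(str, Enum):
    """Verdict from comparing a first PCR run against a retest of the sample."""

    CONSISTENT = "consistent"
    ADO_MUTANT_ALLELE = "ado_suspected_mutant_allele"
    ADO_NORMAL_ALLELE = "ado_suspected_normal_allele"
    STILL_SINGLE_PEAK = "still_single_peak"
    DISCORDANT = "discordant"


def call_pcr_genotype(
    peaks: Sequence[PcrPeak],
    min_height: float | None = None,
    size_tolerance: int = 3,
) -> PcrGenotype:
    """Call the SEA genotype from fluorescent Gap-PCR peaks.

    A peak within ``size_tolerance`` bp of 280 asserts a normal allele; one
    within tolerance of 178 asserts a deletion allele. ``min_height`` defaults
    to 10% of the tallest peak in the lane (relative threshold). A dye
    inconsistent with the matched product (280<->FAM, 178<->HEX) raises a
    warning but does not reject the peak, since peak files may omit dye.
    """
    if size_tolerance < 0 or (min_height is not None and min_height <= 0):
        raise DomainError("thresholds must be positive")
    if abs(NORMAL_PRODUCT_BP - DELETION_PRODUCT_BP) <= 2 * size_tolerance:
        raise AlphaPgtError("size tolerance windows overlap between products")
    if not peaks:
        return PcrGenotype.FAIL
    if min_height is None:
        min_height = 0.1 * max(p.height for p in peaks)
    present: set[int] = set()
    for p in peaks:
        if p.height < min_height:
            continue
        for product in (NORMAL_PRODUCT_BP, DELETION_PRODUCT_BP):
            if abs(p.size_bp - product) <= size_tolerance:
                if p.dye is not None and p.dye != _EXPECTED_DYE[product]:
                    warnings.warn(
                        f"peak at {p.size_bp} bp carries dye {p.dye}, expected "
                        f"{_EXPECTED_DYE[product]}",
                        stacklevel=2,
                    )
                present.add(product)
    has_normal = NORMAL_PRODUCT_BP in present
    has_deletion = DELETION_PRODUCT_BP in present
    if has_normal and has_deletion:
        return PcrGenotype.CARRIER
    if has_normal:
        return PcrGenotype.NORMAL
    if has_deletion:
        return PcrGenotype.AFFECTED
    return PcrGenotype.FAIL


def compare_pcr_runs(first: PcrGenotype, retest: PcrGenotype) -> RunComparison:
    """Compare a first-pass call with a retest of the same amplified sample.

    A homozygous first call that becomes CARRIER on retest is the classic ADO
    signature, and the first call identifies which allele dropped: a NORMAL
    first call means the mutant (deletion) allele dropped, an AFFECTED first
    call means the normal allele dropped. Identical homozygous calls are
    reported as ``STILL_SINGLE_PEAK`` — evidence that the single peak is not a
    run-level artefact; whether it reflects the embryo or poor amplification
    is decided downstream with call-rate and haplotype evidence.
    """
    if first == PcrGenotype.FAIL or retest == PcrGenotype.FAIL:
        raise DomainError("cannot compare runs involving a failed PCR")
    if first == retest:
        if first.is_homozygous:
            return RunComparison.STILL_SINGLE_PEAK
        return RunComparison.CONSISTENT
    if first == PcrGenotype.NORMAL and retest == PcrGenotype.CARRIER:
        return RunComparison.ADO_MUTANT_ALLELE
    if first == PcrGenotype.AFFECTED and retest == PcrGenotype.CARRIER:
        return RunComparison.ADO_NORMAL_ALLELE
    return RunComparison.DISCORDANT
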