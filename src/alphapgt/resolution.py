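"""Discordance resolution between Gap-PCR and haplotype genotypes, final
embryo reports, cohort summaries and transfer prioritization.

When the direct PCR genotype and the linkage-derived genotype disagree, the
explanation is sought in a fixed order: a chromosome-16 copy-number event
(trisomy confuses the target-region haplotype into a both-parental-homologs
pattern; monosomy leaves a single hemizygous haplotype), then — for euploid
chromosome 16 — sample-quality triage: a depressed SNP call rate points at
poor whole-genome amplification and triggers a rebiopsy, while a clean
sample triggers a PCR retest to expose allele dropout. Persistent conflicts
stay unresolved and the embryo is excluded from transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

from .aneuploidy import ChromosomeCnvCall, GenomeScreenResult
from .gap_pcr import PcrGenotype, RunComparison, compare_pcr_runs
from .haplotyping import HaplotypeResult, Verdict
from .model import DomainError
from .sim import genotype_string

__all__ = [
    "CauseCategory",
    "RebiopsyOutcome",
    "EmbryoReport",
    "CohortSummary",
    "TransferCandidate",
    "TransferPlan",
    "compare_calls",
    "resolve_discordance",
    "finalize_embryo",
    "cohort_summary",
    "transfer_priority",
]

QC_CALL_RATE = 0.90  # bracketed by the observed poor (0.88) and good (0.95) samples


class CauseCategory(str, Enum):
    CONCORDANT = "CONCORDANT"
    ADO_MUTANT_ALLELE = "ADO_MUTANT_ALLELE"
    ADO_NORMAL_ALLELE = "ADO_NORMAL_ALLELE"
    TRISOMY16_BPH = "TRISOMY16_BPH"
    MONOSOMY16 = "MONOSOMY16"
    POOR_WGA_QUALITY = "POOR_WGA_QUALITY"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class RebiopsyOutcome:
    """What a second biopsy of the embryo showed."""

    pcr: PcrGenotype
    haplotype_value: str | None = None   # NORMAL | CARRIER | AFFECTED | None
    call_rate: float | None = None


def compare_calls(pcr: PcrGenotype, haplo: HaplotypeResult) -> tuple[bool, str]:
    """First-pass concordance of the two methods on the 3-level genotype.

    Annotations are ignored; an undetermined haplotype counts as discordant
    with reason "haplotype unavailable".
    """
    if pcr == PcrGenotype.FAIL:
        return False, "PCR failed"
    if haplo.value == "UNDETERMINED":
        return False, "haplotype unavailable"
    if haplo.value == pcr.name:
        return True, "concordant"
    return False, f"PCR {pcr.name} vs haplotype {haplo.value}"


def _parent_verdict(haplo: HaplotypeResult, parent: str) -> Verdict | None:
    call = haplo.paternal if parent == "father" else haplo.maternal
    return call.verdict if call is not None else None


def _trisomy_final(
    haplo: HaplotypeResult, cnv: ChromosomeCnvCall
) -> tuple[str, list[str]]:
    """Three-allele genotype of a chromosome-16 trisomy from the reviewed
    evidence: an MI origin contributes one risk and one non-risk chromatid
    of the origin parent; an MII origin duplicates the chromatid named by
    that parent's haplotype verdict; the other parent's single chromatid
    follows their haplotype verdict."""
    notes: list[str] = []
    origin = cnv.origin_parent
    other = "mother" if origin == "father" else "father"
    if origin is None:
        notes.append("trisomy origin unknown; copy composition not derivable")
        return "undetermined", notes
    other_v = _parent_verdict(haplo, other)
    d_other = 1 if other_v == Verdict.RISK else 0
    if other_v not in (Verdict.RISK, Verdict.NONRISK):
        notes.append(f"{other} transmission unresolved; assuming non-risk")
    if cnv.stage == "MII":
        origin_v = _parent_verdict(haplo, origin)
        d_origin = 2 if origin_v == Verdict.RISK else 0
        if origin_v not in (Verdict.RISK, Verdict.NONRISK):
            notes.append(f"{origin} duplicated-chromatid status unresolved")
    else:
        if cnv.stage is None:
            notes.append("meiotic stage unknown; assuming MI (both homologs)")
        d_origin = 1  # MI: both homologs of a carrier parent = risk + non-risk
    d = d_origin + d_other
    return genotype_string(3 - d, d), notes


def _monosomy_final(
    haplo: HaplotypeResult, cnv: ChromosomeCnvCall
) -> tuple[str, list[str]]:
    notes: list[str] = []
    mono = cnv.monosomy
    retained = mono.retained_parent if mono else None
    if retained is None and cnv.origin_parent is not None:
        retained = "mother" if cnv.origin_parent == "father" else "father"
    if retained is None:
        return "undetermined", ["monosomy retained parent unknown"]
    risk = mono.retained_risk if mono else None
    if risk is None:
        v = _parent_verdict(haplo, retained)
        if v == Verdict.RISK:
            risk = "risk"
        elif v == Verdict.NONRISK:
            risk = "non-risk"
    if risk is None:
        return "undetermined", ["retained haplotype risk status unresolved"]
    return genotype_string(0, 1) if risk == "risk" else genotype_string(1, 0), notes


@dataclass
class Resolution:
    final_genotype: str
    cause: CauseCategory
    retest: PcrGenotype | None = None
    rebiopsy: RebiopsyOutcome | None = None
    notes: list[str] = field(default_factory=list)


def resolve_discordance(
    pcr: PcrGenotype,
    haplo: HaplotypeResult,
    chr16_cnv: ChromosomeCnvCall | None,
    call_rate: float,
    retest_provider: Callable[[], PcrGenotype | None] | None = None,
    rebiopsy_provider: Callable[[], RebiopsyOutcome | None] | None = None,
    qc_threshold: float = QC_CALL_RATE,
) -> Resolution:
    """Resolve a PCR/haplotype discordance into a final genotype and cause.

    Decision order: (1) chromosome-16 trisomy, (2) chromosome-16 monosomy,
    (3) call rate below QC — rebiopsy; a concurring rebiopsy blames poor WGA
    quality and keeps the PCR genotype, (4) PCR retest — a changed retest
    matching the haplotype is allele dropout, resolved to the haplotype
    genotype, (5) an unchanged retest with good call rate — rebiopsy; a
    rebiopsy concurring with the PCR blames the haplotype (poor WGA on the
    first sample); anything still conflicting stays unresolved and excluded.
    """
    notes: list[str] = []
    if chr16_cnv is not None and chr16_cnv.copy_number == 3:
        final, notes = _trisomy_final(haplo, chr16_cnv)
        return Resolution(final, CauseCategory.TRISOMY16_BPH, notes=notes)
    if chr16_cnv is not None and chr16_cnv.copy_number == 1:
        final, notes = _monosomy_final(haplo, chr16_cnv)
        return Resolution(final, CauseCategory.MONOSOMY16, notes=notes)

    if call_rate < qc_threshold:
        rebiopsy = rebiopsy_provider() if rebiopsy_provider else None
        if rebiopsy is None:
            return Resolution(
                "undetermined",
                CauseCategory.UNRESOLVED,
                notes=["rebiopsy pending (call rate below QC)"],
            )
        if rebiopsy.pcr == pcr and (
            rebiopsy.haplotype_value is None or rebiopsy.haplotype_value == pcr.name
        ):
            return Resolution(
                pcr.genotype_string,
                CauseCategory.POOR_WGA_QUALITY,
                rebiopsy=rebiopsy,
                notes=[f"call rate {call_rate:.2f} below QC; rebiopsy concurs with PCR"],
            )
        return Resolution(
            "undetermined",
            CauseCategory.UNRESOLVED,
            rebiopsy=rebiopsy,
            notes=["rebiopsy conflicts with the original PCR"],
        )

    retest = retest_provider() if retest_provider else None
    if retest is None:
        return Resolution(
            "undetermined", CauseCategory.UNRESOLVED, notes=["PCR retest pending"]
        )
    if retest != pcr and retest.name == haplo.value:
        comparison = compare_pcr_runs(pcr, retest)
        cause = {
            RunComparison.ADO_MUTANT_ALLELE: CauseCategory.ADO_MUTANT_ALLELE,
            RunComparison.ADO_NORMAL_ALLELE: CauseCategory.ADO_NORMAL_ALLELE,
        }.get(comparison)
        if cause is not None:
            return Resolution(haplo.genotype_string, cause, retest=retest)
        notes.append(f"retest changed the call ({comparison.value})")

    rebiopsy = rebiopsy_provider() if rebiopsy_provider else None
    if rebiopsy is None:
        return Resolution(
            "undetermined",
            CauseCategory.UNRESOLVED,
            retest=retest,
            notes=notes + ["rebiopsy pending (persistent conflict)"],
        )
    if rebiopsy.pcr == pcr and rebiopsy.haplotype_value == pcr.name:
        return Resolution(
            pcr.genotype_string,
            CauseCategory.POOR_WGA_QUALITY,
            retest=retest,
            rebiopsy=rebiopsy,
            notes=notes + ["rebiopsy (PCR and haplotype) concurs with original PCR"],
        )
    return Resolution(
        "undetermined",
        CauseCategory.UNRESOLVED,
        retest=retest,
        rebiopsy=rebiopsy,
        notes=notes + ["conflict persists after retest and rebiopsy"],
    )


@dataclass
class EmbryoReport:
    """Joint verdict for one embryo after the full workflow."""

    embryo_id: str
    pcr_genotype: PcrGenotype
    haplotype: HaplotypeResult
    chr16_cnv: ChromosomeCnvCall | None
    call_rate: float
    final_genotype: str
    cause: CauseCategory
    euploid: bool | None
    concordant: bool
    discordance_reason: str = ""
    retest: PcrGenotype | None = None
    rebiopsy: RebiopsyOutcome | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "embryo_id": self.embryo_id,
            "pcr_genotype": self.pcr_genotype.name,
            "haplotype_genotype": self.haplotype.value,
            "haplotype_annotation": self.haplotype.annotation,
            "chr16": self.chr16_cnv.iscn_like if self.chr16_cnv else None,
            "call_rate": round(self.call_rate, 4),
            "final_genotype": self.final_genotype,
            "cause": self.cause.value,
            "euploid": self.euploid,
            "concordant": self.concordant,
            "notes": list(self.notes),
        }


def finalize_embryo(
    embryo_id: str,
    pcr: PcrGenotype,
    haplo: HaplotypeResult,
    screen: GenomeScreenResult | None,
    call_rate: float,
    retest_provider: Callable[[], PcrGenotype | None] | None = None,
    rebiopsy_provider: Callable[[], RebiopsyOutcome | None] | None = None,
    qc_threshold: float = QC_CALL_RATE,
) -> EmbryoReport:
    """Combine PCR, haplotype and aneuploidy evidence into one report."""
    chr16 = screen.calls.get("16") if screen else None
    euploid = screen.euploid if screen else None
    concordant, reason = compare_calls(pcr, haplo)
    if concordant:
        return EmbryoReport(
            embryo_id=embryo_id,
            pcr_genotype=pcr,
            haplotype=haplo,
            chr16_cnv=chr16,
            call_rate=call_rate,
            final_genotype=pcr.genotype_string,
            cause=CauseCategory.CONCORDANT,
            euploid=euploid,
            concordant=True,
        )
    res = resolve_discordance(
        pcr, haplo, chr16, call_rate, retest_provider, rebiopsy_provider, qc_threshold
    )
    return EmbryoReport(
        embryo_id=embryo_id,
        pcr_genotype=pcr,
        haplotype=haplo,
        chr16_cnv=chr16,
        call_rate=call_rate,
        final_genotype=res.final_genotype,
        cause=res.cause,
        euploid=euploid,
        concordant=False,
        discordance_reason=reason,
        retest=res.retest,
        rebiopsy=res.rebiopsy,
        notes=res.notes,
    )


@dataclass
class CohortSummary:
    """Laboratory-level cohort metrics, printed-style percentages."""

    n_embryos: int
    n_concordant: int
    consistency_rate: float       # percent, 1 decimal
    n_ado: int
    ado_rate: float               # percent, 2 decimals
    n_screened: int
    n_euploid: int
    euploid_rate: float | None    # percent, 1 decimal
    pcr_distribution: dict[str, int]
    haplotype_distribution: dict[str, int]
    cause_histogram: dict[str, int]


def cohort_summary(reports: Sequence[EmbryoReport]) -> CohortSummary:
    """Aggregate reports: consistency, ADO and euploidy rates plus genotype
    distributions, rounded the way a clinical summary prints them."""
    if not reports:
        raise DomainError("cohort summary requires at least one report")
    n = len(reports)
    n_concordant = sum(r.concordant for r in reports)
    n_ado = sum(
        r.cause in (CauseCategory.ADO_MUTANT_ALLELE, CauseCategory.ADO_NORMAL_ALLELE)
        for r in reports
    )
    screened = [r for r in reports if r.euploid is not None]
    n_euploid = sum(r.euploid for r in screened)
    pcr_dist: dict[str, int] = {}
    hap_dist: dict[str, int] = {}
    causes: dict[str, int] = {}
    for r in reports:
        pcr_dist[r.pcr_genotype.name] = pcr_dist.get(r.pcr_genotype.name, 0) + 1
        hap_dist[r.haplotype.value] = hap_dist.get(r.haplotype.value, 0) + 1
        causes[r.cause.value] = causes.get(r.cause.value, 0) + 1
    return CohortSummary(
        n_embryos=n,
        n_concordant=n_concordant,
        consistency_rate=round(100.0 * n_concordant / n, 1),
        n_ado=n_ado,
        ado_rate=round(100.0 * n_ado / n, 2),
        n_screened=len(screened),
        n_euploid=n_euploid,
        euploid_rate=(
            round(100.0 * n_euploid / len(screened), 1) if screened else None
        ),
        pcr_distribution=pcr_dist,
        haplotype_distribution=hap_dist,
        cause_histogram=causes,
    )


@dataclass
class TransferCandidate:
    embryo_id: str
    rank: int
    final_genotype: str
    flags: list[str] = field(default_factory=list)


@dataclass
class TransferPlan:
    ranked: list[TransferCandidate]
    excluded: dict[str, str]          # embryo_id -> reason
    only_normal_recommended: bool = False


_TRANSFERABLE = {"αα/αα": 0, "--/αα": 1}  # rank class: normal before carrier


def transfer_priority(
    reports: Sequence[EmbryoReport],
    upstream_informative: Mapping[str, int] | None = None,
) -> TransferPlan:
    """Rank transferable embryos; exclude affected, unresolved and aneuploid.

    Homozygous-normal embryos always precede carriers. When either parent has
    zero informative SNPs in the 5' (telomeric) flank, the target-region
    linkage cannot bracket the genes from both sides, so carriers are flagged
    with elevated misdiagnosis risk and an only-normal recommendation is set.
    Ties break by higher call rate, then embryo id.
    """
    upstream_informative = upstream_informative or {}
    fragile_5p = any(
        upstream_informative.get(p, 1) == 0 for p in ("father", "mother")
    )
    excluded: dict[str, str] = {}
    candidates: list[tuple[tuple, TransferCandidate]] = []
    for r in reports:
        if r.final_genotype not in _TRANSFERABLE:
            if r.cause == CauseCategory.UNRESOLVED or r.final_genotype == "undetermined":
                excluded[r.embryo_id] = "unresolved genotype"
            elif r.final_genotype == "--/--":
                excluded[r.embryo_id] = "homozygous affected"
            else:
                excluded[r.embryo_id] = f"non-transferable genotype {r.final_genotype}"
            continue
        if r.euploid is None:
            excluded[r.embryo_id] = "aneuploidy screening failed"
            continue
        if not r.euploid:
            excluded[r.embryo_id] = "aneuploid"
            continue
        flags = []
        if fragile_5p and r.final_genotype == "--/αα":
            flags.append("elevated misdiagnosis risk: no 5' informative SNPs")
        key = (_TRANSFERABLE[r.final_genotype], -r.call_rate, r.embryo_id)
        candidates.append(
            (key, TransferCandidate(r.embryo_id, 0, r.final_genotype, flags))
        )
    candidates.sort(key=lambda kv: kv[0])
    ranked = []
    for i, (_, cand) in enumerate(candidates):
        cand.rank = i + 1
        ranked.append(cand)
    return TransferPlan(
        ranked=ranked,
        excluded=excluded,
        only_normal_recommended=fragile_5p,
    )
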