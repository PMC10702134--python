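"""Informative-SNP selection, reference-embryo phasing and embryo haplotype calls.

The linkage strategy: an *informative SNP* is one where one parent is
heterozygous (AB) and the other homozygous (AA/BB), so the heterozygous
parent's transmitted allele can be read off any offspring genotype by
Mendelian subtraction of the homozygous parent's allele. A sibling embryo
whose Gap-PCR genotype is homozygous (affected --/-- or normal αα/αα)
anchors the phase: its transmitted alleles sit on both parents' risk (or
both non-risk) haplotypes. When no homozygous reference exists, two carrier
embryos can be phased jointly, with the deletion-interval hemizygous alleles
breaking the residual risk/non-risk labelling symmetry.

Phasing assumes the reference embryo is non-recombinant across the flanked
target region; the region sits so close to the 16p telomere that crossovers
between the 5' flank and the genes are not expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gap_pcr import PcrGenotype
from .model import (
    DomainError,
    FamilyConfig,
    GenomeInterval,
    HBA_LOCUS,
    IntegrityError,
    RegionPartition,
    SampleArray,
    partition_region,
)

__all__ = [
    "find_informative_snps",
    "informative_counts",
    "informative_snp_stats",
    "summarize_informative_counts",
    "ParentalPhase",
    "phase_from_reference",
    "phase_from_carrier_pair",
    "CarrierPairResult",
    "Verdict",
    "HaplotypeCall",
    "call_embryo_haplotype",
    "HaplotypeResult",
    "haplotype_genotype",
]

_OTHER_ALLELE = {"A": "B", "B": "A"}
_PARENTS = ("father", "mother")


def find_informative_snps(
    father: SampleArray,
    mother: SampleArray,
    regions: RegionPartition | Sequence[GenomeInterval] | None = None,
    config: FamilyConfig | None = None,
) -> pd.DataFrame:
    """Select informative SNPs in the flanked target region.

    Returns a DataFrame with one row per informative SNP: ``snp_id``,
    ``chrom``, ``pos``, ``informative_for`` (father/mother),
    ``hom_parent_allele`` (A/B) and ``flank`` (upstream_5p / in_gene /
    downstream_3p, or "" if ``regions`` was a plain interval list).
    A no-call in either parent excludes the SNP; so do double heterozygotes
    and double homozygotes, which carry no linkage information.
    """
    if regions is None:
        regions = partition_region(config or FamilyConfig("fam", "F", "M"))
    panel = father.panel
    if mother.panel is not panel and mother.panel != panel:
        raise IntegrityError("parents must be typed on the same panel")

    if isinstance(regions, RegionPartition):
        intervals = [
            iv
            for iv in (regions.upstream_5p, regions.in_gene, regions.downstream_3p)
            if iv is not None
        ]
        partition = regions
    else:
        intervals = list(regions)
        partition = None
    region_mask = np.zeros(len(panel), dtype=bool)
    for iv in intervals:
        region_mask |= panel.interval_mask(iv)

    fa, mo = father.b_dose, mother.b_dose
    fa_het, mo_het = fa == 1, mo == 1
    fa_hom, mo_hom = (fa == 0) | (fa == 2), (mo == 0) | (mo == 2)
    father_inf = region_mask & fa_het & mo_hom
    mother_inf = region_mask & mo_het & fa_hom

    rows = []
    for parent, mask, hom_dose in (
        ("father", father_inf, mo),
        ("mother", mother_inf, fa),
    ):
        idx = np.flatnonzero(mask)
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": panel.snp_ids[idx],
                    "chrom": panel.chroms[idx],
                    "pos": panel.positions[idx],
                    "informative_for": parent,
                    "hom_parent_allele": np.where(hom_dose[idx] == 0, "A", "B"),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True).sort_values(
        ["chrom", "pos"], kind="stable"
    )
    if partition is not None:
        out["flank"] = partition.label_positions(
            out["chrom"].to_numpy(), out["pos"].to_numpy()
        )
    else:
        out["flank"] = ""
    return out.reset_index(drop=True)


def informative_counts(
    families: Mapping[str, pd.DataFrame],
    flanks: Sequence[str] = RegionPartition.FLANK_LABELS,
) -> pd.DataFrame:
    """Per-family informative-SNP counts, rows = families, columns =
    (parent, flank) MultiIndex — the layout of the clinic's per-family table."""
    index = pd.MultiIndex.from_product(
        [["mother", "father"], list(flanks)], names=["parent", "flank"]
    )
    data = {}
    for fam, table in families.items():
        counts = table.groupby(["informative_for", "flank"]).size()
        data[fam] = [
            int(counts.get((parent, flank), 0)) for parent, flank in index
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=index)


def summarize_informative_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of each count column.

    With a single family the SD is undefined and reported as NaN.
    """
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if len(counts) > 1 else mean * np.nan
    return pd.DataFrame({"n": len(counts), "mean": mean, "sd": sd})


def informative_snp_stats(
    families: Mapping[str, pd.DataFrame],
    flanks: Sequence[str] = RegionPartition.FLANK_LABELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts table plus per-(parent, flank) mean ± sample SD over families."""
    if not families:
        raise DomainError("at least one family is required")
    counts = informative_counts(families, flanks)
    return counts, summarize_informative_counts(counts)


@dataclass
class ParentalPhase:
    """One parent's risk-allele assignment at their informative SNPs."""

    parent: str
    risk_allele: dict[str, str]        # snp_id -> A | B
    source: str                        # reference embryo id or "id1+id2"
    reference_kind: str                # affected | normal | carrier_pair
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.parent not in _PARENTS:
            raise DomainError(f"unknown parent {self.parent!r}")
        bad = set(self.risk_allele.values()) - {"A", "B"}
        if bad:
            raise DomainError(f"risk alleles must be A/B, got {bad}")


def _transmitted_alleles(
    embryo: SampleArray, informative: pd.DataFrame
) -> pd.Series:
    """Allele transmitted by the heterozygous parent at each informative SNP.

    Mendelian subtraction: remove one copy of the homozygous parent's allele
    from the embryo's called genotype; a homozygous embryo call lacking that
    allele is read as the het parent's contribution with the other parent's
    allele lost to ADO. No-call SNPs yield NaN.
    """
    idx = embryo.panel.indexer(informative["snp_id"])
    g = embryo.gtypes[idx]
    hom = informative["hom_parent_allele"].to_numpy()
    out = np.full(len(informative), None, dtype=object)
    for i, (gt, x) in enumerate(zip(g, hom)):
        if gt == "NC":
            continue
        if gt == "AB":
            out[i] = _OTHER_ALLELE[x]
        elif gt[0] == x:      # homozygous for the hom parent's allele
            out[i] = x
        else:                 # homozygous for the opposite allele
            out[i] = gt[0]
    return pd.Series(out, index=informative["snp_id"].to_numpy())


def phase_from_reference(
    reference: SampleArray,
    reference_pcr: PcrGenotype,
    informative: pd.DataFrame,
    config: FamilyConfig,
    mendel_tolerance: float = 0.05,
) -> dict[str, ParentalPhase]:
    """Phase both parents from one homozygous (affected or normal) reference embryo.

    An affected reference carries both risk haplotypes, so its transmitted
    allele at each informative SNP is the het parent's risk allele; a normal
    reference carries both non-risk haplotypes, so the risk allele is the
    other allele of the het parent's AB genotype. The reference is assumed
    non-recombinant across the region and should be euploid on the target
    chromosome. A Mendelian-inconsistency fraction above ``mendel_tolerance``
    aborts phasing (suspect contamination or aneuploidy).
    """
    if reference_pcr not in (PcrGenotype.AFFECTED, PcrGenotype.NORMAL):
        raise DomainError("reference embryo must be PCR-homozygous")
    idx = reference.panel.indexer(informative["snp_id"])
    g = reference.gtypes[idx]
    hom = informative["hom_parent_allele"].to_numpy()
    usable = g != "NC"
    # a homozygous call lacking the other parent's obligate allele is
    # Mendelian-inconsistent in a euploid, uncontaminated reference
    inconsistent = usable & np.array(
        [gt != "NC" and gt != "AB" and gt[0] != x for gt, x in zip(g, hom)]
    )
    n_usable = int(usable.sum())
    if n_usable and inconsistent.sum() / n_usable > mendel_tolerance:
        raise IntegrityError(
            f"reference {reference.sample_id}: "
            f"{int(inconsistent.sum())}/{n_usable} informative SNPs are "
            "Mendelian-inconsistent; suspect contamination or aneuploidy"
        )
    phases: dict[str, ParentalPhase] = {}
    kind = "affected" if reference_pcr == PcrGenotype.AFFECTED else "normal"
    for parent in _PARENTS:
        sel = (informative["informative_for"] == parent).to_numpy()
        risk: dict[str, str] = {}
        for i in np.flatnonzero(sel & usable & ~inconsistent):
            x = hom[i]
            transmitted = _OTHER_ALLELE[x] if g[i] == "AB" else x
            risk[informative["snp_id"].iloc[i]] = (
                transmitted if kind == "affected" else _OTHER_ALLELE[transmitted]
            )
        phases[parent] = ParentalPhase(
            parent=parent,
            risk_allele=risk,
            source=reference.sample_id,
            reference_kind=kind,
        )
    return phases


@dataclass
class CarrierPairResult:
    """Outcome of joint phasing from two carrier embryos."""

    phases: dict[str, ParentalPhase] | None
    reason: str
    assignment: tuple[str, str] | None = None  # risk-parent of embryo 1, 2

    @property
    def ok(self) -> bool:
        return self.phases is not None


def _implied_phases(
    transmitted: pd.Series,
    informative: pd.DataFrame,
    risk_parent: str,
) -> dict[str, dict[str, str]]:
    """Risk-allele maps implied by one carrier embryo under the hypothesis
    that it carries ``risk_parent``'s risk haplotype (and the other parent's
    non-risk haplotype)."""
    maps: dict[str, dict[str, str]] = {p: {} for p in _PARENTS}
    for parent in _PARENTS:
        sel = informative["informative_for"] == parent
        for snp in informative.loc[sel, "snp_id"]:
            t = transmitted.get(snp)
            if t is None:
                continue
            maps[parent][snp] = t if parent == risk_parent else _OTHER_ALLELE[t]
    return maps


def phase_from_carrier_pair(
    embryo1: SampleArray,
    embryo2: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    informative: pd.DataFrame,
    config: FamilyConfig,
    mismatch_tolerance: float = 0.02,
    min_informative: int = 3,
    min_call_rate: float = 0.90,
) -> CarrierPairResult:
    """Phase the parents from two heterozygous-carrier embryos.

    Enumerates the four assignments of which parent's risk haplotype each
    embryo carries, keeps the assignments whose implied parental phases agree
    across the two embryos (mismatch fraction <= ``mismatch_tolerance``), and
    then anchors the risk/non-risk labelling with the deletion-interval
    evidence: a carrier embryo is hemizygous inside the deletion, and its
    surviving in-gene alleles must match the blood-array hemizygous alleles
    of the parent that contributed the *normal* chromosome. A unique
    surviving assignment yields the phases; otherwise the result is a no-call
    with the reason recorded.
    """
    for e in (embryo1, embryo2):
        if e.call_rate < min_call_rate:
            return CarrierPairResult(None, f"{e.sample_id} below call-rate QC")
    t1 = _transmitted_alleles(embryo1, informative)
    t2 = _transmitted_alleles(embryo2, informative)
    n_usable = min(t1.notna().sum(), t2.notna().sum())
    if n_usable < min_informative:
        return CarrierPairResult(None, "too few usable informative SNPs")

    survivors: list[tuple[str, str]] = []
    implied: dict[tuple[str, str], dict[str, dict[str, str]]] = {}
    for a1 in _PARENTS:
        maps1 = _implied_phases(t1, informative, a1)
        for a2 in _PARENTS:
            maps2 = _implied_phases(t2, informative, a2)
            n_shared = n_conflict = 0
            merged: dict[str, dict[str, str]] = {p: {} for p in _PARENTS}
            for parent in _PARENTS:
                for snp, allele in maps1[parent].items():
                    merged[parent][snp] = allele
                for snp, allele in maps2[parent].items():
                    if snp in maps1[parent]:
                        n_shared += 1
                        if maps1[parent][snp] != allele:
                            n_conflict += 1
                    else:
                        merged[parent][snp] = allele
            if n_shared == 0 or n_conflict / n_shared <= mismatch_tolerance:
                survivors.append((a1, a2))
                implied[(a1, a2)] = merged
    if not survivors:
        return CarrierPairResult(None, "no internally consistent assignment")

    # break the global risk/non-risk swap with in-gene hemizygous alleles:
    # the embryo's surviving deletion-interval allele comes from the parent
    # that transmitted the intact chromosome (= the non-risk-parent of the
    # assignment), and must match that parent's own hemizygous in-gene call.
    panel = embryo1.panel
    gene_idx = np.flatnonzero(panel.interval_mask(config.deletion))
    parent_arrays = {"father": father, "mother": mother}
    if len(gene_idx) and len(survivors) > 1:
        scored: list[tuple[int, tuple[str, str]]] = []
        for a1, a2 in survivors:
            score = 0
            for embryo, risk_parent in ((embryo1, a1), (embryo2, a2)):
                donor = parent_arrays["mother" if risk_parent == "father" else "father"]
                other = parent_arrays[risk_parent]
                for i in gene_idx:
                    ge, gd, go = embryo.gtypes[i], donor.gtypes[i], other.gtypes[i]
                    if "NC" in (ge, gd, go) or gd == go:
                        continue  # parents indistinguishable here
                    if ge[0] == gd[0]:
                        score += 1
                    elif ge[0] == go[0]:
                        score -= 1
            scored.append((score, (a1, a2)))
        best = max(s for s, _ in scored)
        top = [a for s, a in scored if s == best]
        if best > 0 and len(top) == 1:
            survivors = top
    if len(survivors) > 1:
        return CarrierPairResult(None, "ambiguous: multiple consistent assignments")

    a1, a2 = survivors[0]
    merged = implied[(a1, a2)]
    source = f"{embryo1.sample_id}+{embryo2.sample_id}"
    phases = {
        parent: ParentalPhase(
            parent=parent,
            risk_allele=merged[parent],
            source=source,
            reference_kind="carrier_pair",
        )
        for parent in _PARENTS
    }
    return CarrierPairResult(phases, "ok", assignment=(a1, a2))


class Verdict(str, Enum):
    RISK = "RISK"
    NONRISK = "NONRISK"
    RECOMBINANT = "RECOMBINANT"
    NOCALL = "NOCALL"


@dataclass
class HaplotypeCall:
    """Which of one parent's haplotypes an embryo inherited across the region."""

    embryo_id: str
    parent: str
    verdict: Verdict
    support: int = 0          # informative SNPs matching the risk allele
    conflict: int = 0         # informative SNPs matching the non-risk allele
    skipped: int = 0          # informative SNPs unusable (NC / unphased)
    per_flank: dict[str, tuple[int, int]] = field(default_factory=dict)
    blocks: list[tuple[int, int, bool, int]] = field(default_factory=list)
    breakpoint_interval: tuple[int, int] | None = None
    reason: str = ""


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of constant runs."""
    breaks = np.flatnonzero(values[1:] != values[:-1])
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(values) - 1]])
    return list(zip(starts, ends))


def call_embryo_haplotype(
    embryo: SampleArray,
    phase: ParentalPhase,
    informative: pd.DataFrame,
    min_informative: int = 3,
    majority: float = 0.8,
    min_block: int = 3,
    block_coverage: float = 0.9,
) -> HaplotypeCall:
    """Call RISK / NONRISK / RECOMBINANT / NOCALL for one parent's transmission.

    At each usable informative SNP the embryo's allele attributable to the
    phased parent is compared with that parent's risk allele. Two or more
    alternating contiguous positional blocks of at least ``min_block``
    concordant SNPs, together covering at least ``block_coverage`` of the
    usable SNPs, mark a recombinant chromatid with the breakpoint placed in
    the gap between blocks — the coverage requirement separates a genuine
    crossover (two clean blocks spanning the region) from the scattered
    half-and-half pattern produced by a trisomic or monosomic chromosome.
    Otherwise a match (or mismatch) fraction of at least ``majority`` yields
    RISK (or NONRISK). Fewer than ``min_informative`` usable SNPs — the
    routine situation in the sparse 5' flank — yields NOCALL rather than an
    error.
    """
    inf = informative[informative["informative_for"] == phase.parent]
    inf = inf.sort_values("pos", kind="stable")
    call = HaplotypeCall(embryo.sample_id, phase.parent, Verdict.NOCALL)
    if inf.empty:
        call.reason = "no informative SNPs for this parent"
        return call
    transmitted = _transmitted_alleles(embryo, inf)
    risk = inf["snp_id"].map(phase.risk_allele)
    usable = transmitted.notna().to_numpy() & risk.notna().to_numpy()
    call.skipped = int((~usable).sum())
    n_usable = int(usable.sum())
    match = (
        transmitted.to_numpy()[usable] == risk.to_numpy()[usable]
    )
    pos = inf["pos"].to_numpy()[usable]
    flank = inf["flank"].to_numpy()[usable]
    call.support = int(match.sum())
    call.conflict = n_usable - call.support
    for fl in np.unique(flank):
        m = flank == fl
        call.per_flank[str(fl)] = (int(match[m].sum()), int((~match[m]).sum()))
    if n_usable < min_informative:
        call.reason = f"only {n_usable} usable informative SNPs"
        return call

    runs = _runs(match)
    qualifying = [
        (int(pos[a]), int(pos[b]), bool(match[a]), b - a + 1)
        for a, b in runs
        if b - a + 1 >= min_block
    ]
    call.blocks = qualifying
    coverage = sum(b[3] for b in qualifying) / n_usable
    if coverage >= block_coverage:
        for (s1, e1, v1, _), (s2, e2, v2, _) in zip(qualifying, qualifying[1:]):
            if v1 != v2:
                call.verdict = Verdict.RECOMBINANT
                call.breakpoint_interval = (e1, s2)
                call.reason = "alternating concordance blocks"
                return call

    frac = call.support / n_usable
    if frac >= majority:
        call.verdict = Verdict.RISK
    elif 1 - frac >= majority:
        call.verdict = Verdict.NONRISK
    else:
        call.reason = "no majority; scattered concordance pattern"
    return call


@dataclass
class HaplotypeResult:
    """Joint SEA genotype inferred from the two parental haplotype calls."""

    value: str                       # NORMAL | CARRIER | AFFECTED | UNDETERMINED
    annotation: str                  # e.g. "maternal heterozygous"
    risk_parents: list[str]
    low_confidence: bool
    paternal: HaplotypeCall | None = None
    maternal: HaplotypeCall | None = None

    @property
    def genotype_string(self) -> str:
        return {
            "NORMAL": "αα/αα",
            "CARRIER": "--/αα",
            "AFFECTED": "--/--",
            "UNDETERMINED": "undetermined",
        }[self.value]


def _effective_verdict(
    call: HaplotypeCall, locus: GenomeInterval
) -> tuple[Verdict, bool]:
    """Resolve a RECOMBINANT call at the locus; flag breakpoints crossing it."""
    if call.verdict != Verdict.RECOMBINANT:
        return call.verdict, False
    lo, hi = call.breakpoint_interval
    if lo <= locus.end and hi >= locus.start:
        return Verdict.NOCALL, True  # breakpoint spans the gene: undetermined
    # the block on the locus side of the breakpoint carries the locus status
    nearest = min(
        call.blocks,
        key=lambda blk: min(
            abs(blk[0] - locus.end), abs(blk[1] - locus.start)
        ),
    )
    return (Verdict.RISK if nearest[2] else Verdict.NONRISK), False


def haplotype_genotype(
    paternal: HaplotypeCall,
    maternal: HaplotypeCall,
    locus: GenomeInterval = HBA_LOCUS,
) -> HaplotypeResult:
    """Combine the parental transmission calls into an SEA genotype.

    RISK+RISK is homozygous affected, NONRISK+NONRISK homozygous normal, and
    mixed calls a heterozygous carrier annotated with the transmitting
    parent. A recombination breakpoint overlapping the gene interval, or any
    parental no-call, leaves the genotype undetermined; recombinants whose
    breakpoint lies clear of the locus are resolved by the concordance block
    on the locus side and flagged low-confidence.
    """
    verdicts = {}
    low_conf = False
    for call in (paternal, maternal):
        v, spans_locus = _effective_verdict(call, locus)
        verdicts[call.parent] = v
        if call.verdict in (Verdict.RECOMBINANT, Verdict.NOCALL) or spans_locus:
            low_conf = True
    pv, mv = verdicts["father"], verdicts["mother"]
    if Verdict.NOCALL in (pv, mv):
        return HaplotypeResult(
            "UNDETERMINED", "parental transmission unresolved", [], True,
            paternal, maternal,
        )
    risk_parents = [p for p, v in verdicts.items() if v == Verdict.RISK]
    if len(risk_parents) == 2:
        value, annotation = "AFFECTED", "abnormal homozygous"
    elif len(risk_parents) == 0:
        value, annotation = "NORMAL", "normal homozygous"
    else:
        value = "CARRIER"
        annotation = (
            "paternal heterozygous"
            if risk_parents[0] == "father"
            else "maternal heterozygous"
        )
    return HaplotypeResult(
        value, annotation, risk_parents, low_conf, paternal, maternal
    )
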