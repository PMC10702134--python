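"""Chromosome copy-number calling from BAF/LRR, with parental origin and
meiotic staging of whole-chromosome errors.

Copy number follows the standard SNP-array signatures: the log R ratio sits
near log2(CN/2) (ideal scale: +0.585 for three copies, -1.0 for one) and the
B-allele frequency of heterozygous-context SNPs forms bands at k/CN — a
middle band at 1/2 for disomy, bands at 1/3 and 2/3 for trisomy, and no
middle band for monosomy.

For a trisomy, the doubled dose betrays its parent: at SNPs where one parent
is heterozygous (AB) and the other homozygous, the band occupancy expected
under "extra copy from the het parent" differs from "extra copy from the hom
parent", and a band-likelihood comparison picks the origin. The meiotic stage
is read at the pericentromere: both parental homologs present (BPH — the
embryo carries both of the origin parent's alleles at an informative SNP)
indicates a meiosis-I error, a duplicated single homolog (SPH) a meiosis-II
error. For a monosomy, the retained parent is the one whose specific alleles
still appear at their informative SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genome import CENTROMERE_MIDPOINTS
from .haplotyping import ParentalPhase
from .model import DomainError, SampleArray

__all__ = [
    "CnvParams",
    "ChromosomeCnvCall",
    "MonosomyCall",
    "GenomeScreenResult",
    "call_chromosome_cnv",
    "trisomy_parental_origin",
    "meiotic_stage",
    "monosomy_retained_parent",
    "format_iscn_like",
    "genome_screen",
    "pericentromeric_mask",
]

_BANDS3 = np.array([0.0, 1 / 3, 2 / 3, 1.0])


@dataclass(frozen=True)
class CnvParams:
    """Tunable thresholds of the copy-number caller (ideal-LRR-scale defaults)."""

    lrr_gain_threshold: float = 0.3    # median LRR above this suggests CN 3
    lrr_loss_threshold: float = -0.5   # median LRR below this suggests CN 1
    band_tolerance: float = 0.08       # half-width of each BAF band
    mid_band_max: float = 0.05         # max 1/2-band mass allowed for CN 1
    min_snps_per_chrom: int = 20
    min_informative: int = 3           # informative SNPs needed for origin/stage
    stage_majority: float = 0.8
    pericentromere_fraction: float = 0.2  # innermost SNP fraction of each arm
    band_floor: float = 0.05           # off-model mass in the origin likelihood


@dataclass
class MonosomyCall:
    retained_parent: str | None
    lost_parent: str | None
    retained_risk: str | None = None   # "risk" | "non-risk" | None
    evidence: dict = field(default_factory=dict)


@dataclass
class ChromosomeCnvCall:
    """Per-chromosome copy-number verdict with its supporting evidence."""

    chromosome: str
    copy_number: int | None            # 1 | 2 | 3, None = unanalyzable
    origin_parent: str | None = None   # trisomy: extra-copy parent; monosomy: lost parent
    stage: str | None = None           # MI | MII (trisomy only)
    monosomy: MonosomyCall | None = None
    evidence: dict = field(default_factory=dict)
    reason: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def iscn_like(self) -> str:
        return format_iscn_like(self)


def format_iscn_like(call: ChromosomeCnvCall) -> str:
    """Render an ISCN-style display string, e.g. ``arr(16)×3 mat``.

    For a trisomy the mat/pat suffix names the parent of the extra copy; for
    a monosomy it names the parent of the *lost* homolog (the convention of
    the clinical report this mirrors — flagged here because ISCN usage
    varies).
    """
    if call.copy_number is None:
        return f"arr({call.chromosome})×?"
    s = f"arr({call.chromosome})×{call.copy_number}"
    if call.copy_number != 2 and call.origin_parent in ("father", "mother"):
        s += " mat" if call.origin_parent == "mother" else " pat"
    return s


def _band_mass(baf: np.ndarray, center: float, tol: float) -> float:
    if len(baf) == 0:
        return 0.0
    return float((np.abs(baf - center) <= tol).mean())


def _het_context_mask(father: SampleArray, mother: SampleArray) -> np.ndarray:
    """SNPs where the embryo can legitimately be heterozygous: at least one
    parent AB, or the parents are opposite homozygotes."""
    fa, mo = father.b_dose, mother.b_dose
    return (fa == 1) | (mo == 1) | ((fa == 0) & (mo == 2)) | ((fa == 2) & (mo == 0))


def _informative_masks(
    father: SampleArray, mother: SampleArray
) -> dict[str, np.ndarray]:
    fa, mo = father.b_dose, mother.b_dose
    return {
        "father": (fa == 1) & ((mo == 0) | (mo == 2)),
        "mother": (mo == 1) & ((fa == 0) | (fa == 2)),
    }


def pericentromeric_mask(
    panel, chromosome: str, fraction: float = 0.2
) -> np.ndarray:
    """Innermost ``fraction`` of each arm's SNPs, around the centromere."""
    chrom_mask = panel.chromosome_mask(chromosome)
    cen = CENTROMERE_MIDPOINTS.get(str(chromosome))
    out = np.zeros(len(panel), dtype=bool)
    if cen is None:
        return out
    idx = np.flatnonzero(chrom_mask)
    pos = panel.positions[idx]
    p_arm = idx[pos < cen]
    q_arm = idx[pos >= cen]
    n_p = int(np.ceil(len(p_arm) * fraction))
    n_q = int(np.ceil(len(q_arm) * fraction))
    if n_p:
        out[p_arm[-n_p:]] = True
    if n_q:
        out[q_arm[:n_q]] = True
    return out


def call_chromosome_cnv(
    embryo: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    chromosome: str,
    params: CnvParams = CnvParams(),
    phases: Mapping[str, ParentalPhase] | None = None,
    resolve_origin: bool = True,
) -> ChromosomeCnvCall:
    """Call the copy number of one chromosome and, for an abnormal call,
    its parental origin (and meiotic stage for a trisomy)."""
    panel = embryo.panel
    chrom = str(chromosome)
    mask = panel.chromosome_mask(chrom)
    lrr = embryo.lrr[mask]
    lrr = lrr[~np.isnan(lrr)]
    call = ChromosomeCnvCall(chromosome=chrom, copy_number=None)
    if len(lrr) < params.min_snps_per_chrom:
        call.reason = f"only {len(lrr)} usable LRR values"
        return call
    med = float(np.median(lrr))
    het_ctx = mask & _het_context_mask(father, mother)
    baf = embryo.baf[het_ctx]
    baf = baf[~np.isnan(baf)]
    tol = params.band_tolerance
    bands = {
        "0": _band_mass(baf, 0.0, tol),
        "1/3": _band_mass(baf, 1 / 3, tol),
        "1/2": _band_mass(baf, 0.5, tol),
        "2/3": _band_mass(baf, 2 / 3, tol),
        "1": _band_mass(baf, 1.0, tol),
    }
    call.evidence = {"median_lrr": med, "baf_bands": bands, "n_het_context": len(baf)}

    third_mass = bands["1/3"] + bands["2/3"]
    if med > params.lrr_gain_threshold and third_mass > bands["1/2"]:
        call.copy_number = 3
    elif med < params.lrr_loss_threshold and bands["1/2"] <= params.mid_band_max:
        call.copy_number = 1
    else:
        call.copy_number = 2
        if med > params.lrr_gain_threshold or med < params.lrr_loss_threshold:
            call.warnings.append(
                "non-integer pattern: LRR shift without matching BAF bands"
            )
        return call

    if not resolve_origin:
        return call
    if call.copy_number == 3:
        origin, score = trisomy_parental_origin(
            embryo, father, mother, chrom, params
        )
        call.origin_parent = origin
        call.evidence["origin_score"] = score
        if origin:
            call.stage = meiotic_stage(embryo, father, mother, chrom, origin, params=params)
    else:
        mono = monosomy_retained_parent(embryo, father, mother, chrom, phases, params)
        call.monosomy = mono
        call.origin_parent = mono.lost_parent
    return call


def trisomy_parental_origin(
    embryo: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    chromosome: str,
    params: CnvParams = CnvParams(),
) -> tuple[str | None, float]:
    """Pick the parent of a trisomy's extra copy by BAF band likelihood.

    At each informative SNP (het parent P, hom parent with per-allele B-dose
    x ∈ {0, 1}), the expected trisomic BAF bands are:

    * extra from P, MI (both homologs): the single band (1 + x)/3;
    * extra from P, MII (duplicated chromatid): x/3 and (2 + x)/3, each 1/2;
    * extra from the hom parent: (0 + 2x)/3 and (1 + 2x)/3, each 1/2.

    Observed BAFs are binned to the nearest trisomy band and a multinomial
    log-likelihood (with a small off-model floor) is summed per hypothesis;
    the winning hypothesis family names the origin. Returns (None, 0.0) when
    fewer than ``min_informative`` SNPs are usable.
    """
    panel = embryo.panel
    chrom_mask = panel.chromosome_mask(str(chromosome))
    inf = _informative_masks(father, mother)
    hom_dose = {"father": mother.b_dose, "mother": father.b_dose}
    floor = params.band_floor
    loglik = {"father_MI": 0.0, "father_MII": 0.0, "mother_MI": 0.0, "mother_MII": 0.0}
    n_used = 0
    for het_parent in ("father", "mother"):
        m = chrom_mask & inf[het_parent]
        baf = embryo.baf[m]
        x = (hom_dose[het_parent][m] == 2).astype(int)  # per-allele B dose of hom parent
        ok = ~np.isnan(baf)
        baf, x = baf[ok], x[ok]
        if len(baf) == 0:
            continue
        n_used += len(baf)
        band_idx = np.argmin(np.abs(baf[:, None] - _BANDS3[None, :]), axis=1)
        other = "mother" if het_parent == "father" else "father"
        for hypo, bands_fn in (
            (f"{het_parent}_MI", lambda xi: {(1 + xi): 1.0}),
            (f"{het_parent}_MII", lambda xi: {xi: 0.5, 2 + xi: 0.5}),
            (f"{other}_MI", lambda xi: {2 * xi: 0.5, 2 * xi + 1: 0.5}),
            (f"{other}_MII", lambda xi: {2 * xi: 0.5, 2 * xi + 1: 0.5}),
        ):
            probs = np.full(len(baf), 0.0)
            for i, (bi, xi) in enumerate(zip(band_idx, x)):
                model = bands_fn(int(xi))
                p = model.get(int(bi), 0.0)
                probs[i] = p * (1 - floor) + floor / 4
            loglik[hypo] += float(np.log(probs).sum())
    if n_used < params.min_informative:
        return None, 0.0
    by_parent = {
        "father": max(loglik["father_MI"], loglik["father_MII"]),
        "mother": max(loglik["mother_MI"], loglik["mother_MII"]),
    }
    origin = max(by_parent, key=by_parent.get)
    other = "mother" if origin == "father" else "father"
    score = (by_parent[origin] - by_parent[other]) / max(n_used, 1)
    if score <= 0:
        return None, 0.0
    return origin, score


def meiotic_stage(
    embryo: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    chromosome: str,
    origin_parent: str,
    window: np.ndarray | None = None,
    params: CnvParams = CnvParams(),
) -> str | None:
    """Stage a trisomy as MI or MII from pericentromeric BAF bands.

    Within the pericentromeric window, at SNPs where the origin parent is AB
    and the other parent homozygous (per-allele B-dose x): a BAF at
    (1 + x)/3 means the embryo carries *both* of the origin parent's alleles
    (BPH) — a meiosis-I signature; BAFs at x/3 or (2 + x)/3 mean a duplicated
    single homolog (SPH) — meiosis II. The majority pattern (fraction >=
    ``stage_majority``) decides; mixed or sparse evidence returns None.
    """
    if origin_parent not in ("father", "mother"):
        raise DomainError(f"unknown origin parent {origin_parent!r}")
    panel = embryo.panel
    if window is None:
        window = pericentromeric_mask(
            panel, str(chromosome), params.pericentromere_fraction
        )
    inf = _informative_masks(father, mother)[origin_parent]
    hom_dose = mother.b_dose if origin_parent == "father" else father.b_dose
    m = window & inf & panel.chromosome_mask(str(chromosome))
    baf = embryo.baf[m]
    x = (hom_dose[m] == 2).astype(int)
    ok = ~np.isnan(baf)
    baf, x = baf[ok], x[ok]
    if len(baf) == 0:
        return None
    band_idx = np.argmin(np.abs(baf[:, None] - _BANDS3[None, :]), axis=1)
    n_mi = int((band_idx == 1 + x).sum())
    n_mii = int(((band_idx == x) | (band_idx == 2 + x)).sum())
    n = n_mi + n_mii
    if n < params.min_informative:
        return None
    if n_mi / n >= params.stage_majority:
        return "MI"
    if n_mii / n >= params.stage_majority:
        return "MII"
    return None


def monosomy_retained_parent(
    embryo: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    chromosome: str,
    phases: Mapping[str, ParentalPhase] | None = None,
    params: CnvParams = CnvParams(),
) -> MonosomyCall:
    """Identify which parent's homolog survives a monosomy.

    At the retained parent's informative SNPs the hemizygous embryo shows
    that parent's specific allele about half the time (a homozygous call for
    the allele the other parent could not have supplied); at the lost
    parent's informative SNPs no such specific allele can appear. When a
    parental phase is supplied, the retained chromatid is additionally
    classified risk / non-risk by concordance with the phased risk alleles.
    """
    panel = embryo.panel
    chrom_mask = panel.chromosome_mask(str(chromosome))
    inf = _informative_masks(father, mother)
    hom_dose = {"father": mother.b_dose, "mother": father.b_dose}
    specific_frac: dict[str, float] = {}
    n_usable: dict[str, int] = {}
    for parent in ("father", "mother"):
        m = chrom_mask & inf[parent]
        g = embryo.gtypes[m]
        hom_allele = np.where(hom_dose[parent][m] == 0, "AA", "BB")
        usable = g != "NC"
        n = int(usable.sum())
        n_usable[parent] = n
        if n == 0:
            specific_frac[parent] = 0.0
            continue
        # a call that is neither NC nor the hom parent's homozygote must
        # contain the het parent's specific allele
        specific = usable & (g != hom_allele)
        specific_frac[parent] = float(specific.sum()) / n
    evidence = {"specific_fraction": specific_frac, "n_usable": n_usable}
    if min(n_usable.values()) < params.min_informative:
        return MonosomyCall(None, None, evidence=evidence)
    f, m_ = specific_frac["father"], specific_frac["mother"]
    if f >= 0.2 and m_ < 0.1:
        retained, lost = "father", "mother"
    elif m_ >= 0.2 and f < 0.1:
        retained, lost = "mother", "father"
    else:
        return MonosomyCall(None, None, evidence=evidence)

    retained_risk = None
    if phases and retained in phases:
        phase = phases[retained]
        mask = chrom_mask & inf[retained]
        idx = np.flatnonzero(mask)
        matches = n_def = 0
        for i in idx:
            snp = panel.snp_ids[i]
            risk = phase.risk_allele.get(snp)
            g = embryo.gtypes[i]
            if risk is None or g == "NC":
                continue
            x = "A" if hom_dose[retained][i] == 0 else "B"
            transmitted = (
                ({"A", "B"} - {x}).pop() if g == "AB" else g[0]
            )
            n_def += 1
            matches += transmitted == risk
        if n_def >= params.min_informative:
            frac = matches / n_def
            if frac >= 0.8:
                retained_risk = "risk"
            elif frac <= 0.2:
                retained_risk = "non-risk"
        evidence["risk_concordance"] = (matches, n_def)
    return MonosomyCall(retained, lost, retained_risk, evidence)


@dataclass
class GenomeScreenResult:
    """Per-chromosome calls plus the embryo-level euploidy verdict."""

    calls: dict[str, ChromosomeCnvCall]
    euploid: bool | None               # None = screening failed
    failed_chromosomes: list[str] = field(default_factory=list)
    abnormal_chromosomes: list[str] = field(default_factory=list)

    @property
    def screening_failed(self) -> bool:
        return self.euploid is None


def genome_screen(
    embryo: SampleArray,
    father: SampleArray,
    mother: SampleArray,
    params: CnvParams = CnvParams(),
    phases: Mapping[str, ParentalPhase] | None = None,
) -> GenomeScreenResult:
    """Screen every panel chromosome; euploid iff all autosomes are two-copy.

    Sex chromosomes, when present on the panel, are called and reported but
    excluded from the euploidy verdict. Any unanalyzable autosome marks the
    whole screen as failed (euploid = None).
    """
    chroms = list(dict.fromkeys(embryo.panel.chroms))
    calls: dict[str, ChromosomeCnvCall] = {}
    failed: list[str] = []
    abnormal: list[str] = []
    for chrom in chroms:
        call = call_chromosome_cnv(embryo, father, mother, chrom, params, phases)
        calls[chrom] = call
        if chrom in ("X", "Y"):
            continue
        if call.copy_number is None:
            failed.append(chrom)
        elif call.copy_number != 2:
            abnormal.append(chrom)
    euploid = None if failed else not abnormal
    return GenomeScreenResult(calls, euploid, failed, abnormal)
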