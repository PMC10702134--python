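"""Synthetic carrier-family generator with retained ground truth.

Emulates the study design end to end: two carrier parents with phased
haplotypes (one haplotype each bearing the SEA deletion), embryo meioses with
Poisson-process recombination, optional whole-chromosome aneuploidy (trisomy
with a meiosis-I or meiosis-II origin, or monosomy), rendering of SNP-array
observations (AB genotype calls, B-allele frequency, log R ratio) under a
whole-genome-amplification noise model, and fluorescent Gap-PCR peak
simulation. Every embryo carries an :class:`EmbryoTruth` record so that each
downstream caller can be tested against ground truth.

The default panel mirrors the array used in the clinic at desk scale: a
uniform genome-wide backbone (2,000 SNPs per autosome rather than the real
~300,000 total) plus the 407 target-region SNPs in their printed flank
composition — 42 in the 5' (telomeric) flank, 10 inside HBA1+HBA2, 355 in the
3' (centromeric) flank. The default recombination map places zero crossover
intensity between the 16p terminus and the HBA locus, reflecting the absence
of recombination hotspots telomeric of the genes; all other intensity on
chromosome 16 sits downstream of the locus.

Copy-number rendering is on the ideal scale: LRR = log2(CN/2) (+0.585 for
trisomy, -1.0 for monosomy) and BAF = (#B alleles)/CN, before Gaussian noise.
Meiotic-error rendering follows the pericentromeric diagnostic logic: an MI
error transmits both homologs of the origin parent; an MII error transmits
one recombined chromatid twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gap_pcr import DELETION_PRODUCT_BP, NORMAL_PRODUCT_BP, PcrPeak
from .genome import AUTOSOME_LENGTHS
from .model import (
    DomainError,
    FamilyConfig,
    SampleArray,
    SnpPanel,
    partition_region,
)

__all__ = [
    "NoiseModel",
    "PhasedParent",
    "MeiosisEvent",
    "AneuploidySpec",
    "EmbryoTruth",
    "RecombinationMap",
    "FamilySim",
    "build_default_panel",
    "default_recomb_map",
    "recomb_map_outside_flanks",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_embryo",
    "simulate_gap_pcr",
    "simulate_family",
    "genotype_string",
]

_GT = np.array(["AA", "AB", "BB"], dtype=object)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic degradation applied when rendering embryo observations.

    WGA of a handful of trophectoderm cells loses alleles (ADO), miscalls and
    fails to call genotypes, and blurs the array's BAF/LRR channels; the
    Gap-PCR assay has its own per-allele dropout. All probabilities are per
    SNP (or per allele copy, for the dropout rates).
    """

    ado_rate: float = 0.05        # per-allele WGA dropout before genotype calling
    miscall_rate: float = 0.005   # called genotype replaced by a wrong one
    nocall_rate: float = 0.02     # called genotype erased to NC
    baf_sd: float = 0.04          # Gaussian sd on B-allele frequency
    lrr_sd: float = 0.15          # Gaussian sd on log R ratio
    pcr_ado_rate: float = 0.01    # per-allele dropout in fluorescent Gap-PCR

    def __post_init__(self) -> None:
        for name in ("ado_rate", "miscall_rate", "nocall_rate", "pcr_ado_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {p}")
        if self.baf_sd < 0 or self.lrr_sd < 0:
            raise DomainError("noise standard deviations must be non-negative")


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def build_default_panel(
    n_backbone_per_chrom: int = 2000,
    flank_counts: tuple[int, int, int] = (42, 10, 355),
    config: FamilyConfig | None = None,
) -> SnpPanel:
    """Desk-scale default panel: uniform autosomal backbone + target-region SNPs.

    ``flank_counts`` is (5' upstream, in-gene, 3' downstream); the default
    reproduces the array's printed 407-SNP composition around HBA1+HBA2.
    """
    config = config or FamilyConfig("fam", "F", "M")
    part = partition_region(config)
    rows: list[pd.DataFrame] = []
    for chrom, length in AUTOSOME_LENGTHS.items():
        pos = np.linspace(1_000_000, length - 1_000_000, n_backbone_per_chrom)
        pos = np.unique(pos.astype(np.int64))
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": [f"bb{chrom}_{i:05d}" for i in range(len(pos))],
                    "chrom": chrom,
                    "pos": pos,
                }
            )
        )
    for tag, interval, count in (
        ("up", part.upstream_5p, flank_counts[0]),
        ("gene", part.in_gene, flank_counts[1]),
        ("dn", part.downstream_3p, flank_counts[2]),
    ):
        if interval is None or count == 0:
            continue
        pos = np.linspace(interval.start, interval.end, count + 2)[1:-1]
        pos = np.unique(pos.astype(np.int64))
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": [f"hba_{tag}_{i:04d}" for i in range(len(pos))],
                    "chrom": interval.chrom,
                    "pos": pos,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table = table.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return SnpPanel(table)


@dataclass
class RecombinationMap:
    """Per-chromosome crossover intensity as piecewise-constant segments.

    ``segments[chrom]`` is a list of (start, end, expected_crossovers); the
    expected crossover count of a chromosome is the sum over its segments, and
    crossover positions are drawn uniformly within each segment.
    """

    segments: Mapping[str, Sequence[tuple[int, int, float]]]

    def total_intensity(self, chrom: str) -> float:
        return sum(s[2] for s in self.segments.get(chrom, ()))


def default_recomb_map(
    intensity_per_chrom: float = 1.0,
    config: FamilyConfig | None = None,
) -> RecombinationMap:
    """One expected crossover per autosome; zero intensity telomeric of HBA.

    On chromosome 16 all intensity is placed downstream (centromeric) of the
    target locus, so no simulated crossover ever separates the 5' flank from
    the genes — the observed hotspot asymmetry around HBA.
    """
    config = config or FamilyConfig("fam", "F", "M")
    segs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in AUTOSOME_LENGTHS.items():
        if chrom == config.locus.chrom:
            segs[chrom] = [
                (1, config.locus.start - 1, 0.0),
                (config.locus.start, length, intensity_per_chrom),
            ]
        else:
            segs[chrom] = [(1, length, intensity_per_chrom)]
    return RecombinationMap(segs)


def recomb_map_outside_flanks(
    intensity_per_chrom: float = 1.0,
    config: FamilyConfig | None = None,
) -> RecombinationMap:
    """Like :func:`default_recomb_map`, but with zero crossover intensity
    across the whole flanked target region (not just telomeric of the locus).

    Used when an analysis assumes non-recombinant transmission across the
    region — e.g. validating phasing exactness, where an in-flank crossover
    in the reference embryo would invalidate the assumption rather than the
    caller."""
    config = config or FamilyConfig("fam", "F", "M")
    rmap = default_recomb_map(intensity_per_chrom, config)
    segs = dict(rmap.segments)
    chrom = config.locus.chrom
    flank_end = config.locus.end + config.flank_bp
    length = AUTOSOME_LENGTHS[chrom]
    segs[chrom] = [
        (1, flank_end, 0.0),
        (flank_end + 1, length, intensity_per_chrom),
    ]
    return RecombinationMap(segs)


@dataclass
class PhasedParent:
    """A carrier parent: two phased haplotypes over the panel, one flagged risk.

    ``haplotypes`` is a (2, n_snps) uint8 array of B-allele indicators;
    ``risk_index`` names the haplotype that carries the SEA deletion.
    """

    sample_id: str
    role: str
    panel: SnpPanel
    haplotypes: np.ndarray
    risk_index: int

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (2, len(self.panel)):
            raise DomainError("haplotypes must be a (2, n_snps) array")
        if self.risk_index not in (0, 1):
            raise DomainError("risk_index must be 0 or 1")

    def risk_haplotype(self) -> np.ndarray:
        return self.haplotypes[self.risk_index]

    def to_sample_array(self, config: FamilyConfig) -> SampleArray:
        """Render the parent's own (blood-DNA, noise-free) array observations.

        Inside the deletion interval the risk haplotype contributes nothing:
        the carrier parent is hemizygous there (CN 1, BAF at 0/1, LRR -1).
        """
        dose = self.haplotypes.sum(axis=0).astype(np.int8)
        deleted = self.panel.interval_mask(config.deletion)
        gtype = _GT[dose].copy()
        baf = dose / 2.0
        lrr = np.zeros(len(self.panel))
        if deleted.any():
            surviving = self.haplotypes[1 - self.risk_index, deleted].astype(float)
            gtype[deleted] = _GT[(2 * surviving).astype(np.int8)]
            baf[deleted] = surviving
            lrr[deleted] = np.log2(0.5)
        data = pd.DataFrame({"gtype": gtype, "baf": baf, "lrr": lrr})
        return SampleArray(self.sample_id, self.role, self.panel, data)


def simulate_parents(
    panel: SnpPanel,
    maf: float | np.ndarray = 0.5,
    rng: np.random.Generator | int | None = None,
    father_id: str = "father",
    mother_id: str = "mother",
) -> tuple[PhasedParent, PhasedParent]:
    """Draw two phased carrier parents with per-SNP B-allele frequency ``maf``."""
    rng = np.random.default_rng(rng)
    maf_arr = np.broadcast_to(np.asarray(maf, float), (len(panel),))
    if ((maf_arr < 0) | (maf_arr > 1)).any():
        raise DomainError("allele frequencies must lie in [0, 1]")
    parents = []
    for sample_id, role in ((father_id, "father"), (mother_id, "mother")):
        haps = (rng.random((2, len(panel))) < maf_arr).astype(np.uint8)
        risk = int(rng.integers(2))
        parents.append(PhasedParent(sample_id, role, panel, haps, risk))
    return parents[0], parents[1]


@dataclass
class MeiosisEvent:
    """One gamete's recombination outcome: per-chromosome crossover positions
    (strictly increasing) and the haplotype chosen at the chromosome start."""

    parent_role: str
    crossovers: dict[str, np.ndarray]
    start_hap: dict[str, int]

    def source_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Haplotype index transmitted at each position (0/1)."""
        xs = self.crossovers.get(chrom, np.empty(0))
        start = self.start_hap.get(chrom, 0)
        parity = np.searchsorted(xs, positions, side="right") % 2
        return (start + parity) % 2


def simulate_meiosis(
    parent: PhasedParent,
    recomb_map: RecombinationMap,
    rng: np.random.Generator | int | None = None,
) -> MeiosisEvent:
    """Draw one gamete: Poisson crossover counts per chromosome, positions
    uniform within segments (weighted by segment intensity), and a random
    starting haplotype. Zero intensity transmits one haplotype intact."""
    rng = np.random.default_rng(rng)
    crossovers: dict[str, np.ndarray] = {}
    start_hap: dict[str, int] = {}
    for chrom, segs in recomb_map.segments.items():
        lam = sum(s[2] for s in segs)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n > 0:
            weights = np.array([s[2] for s in segs], float)
            weights /= weights.sum()
            idx = rng.choice(len(segs), size=n, p=weights)
            pos = np.array(
                [rng.uniform(segs[i][0], segs[i][1]) for i in idx]
            )
            crossovers[chrom] = np.sort(pos)
        else:
            crossovers[chrom] = np.empty(0)
        start_hap[chrom] = int(rng.integers(2))
    return MeiosisEvent(parent.role, crossovers, start_hap)


@dataclass(frozen=True)
class AneuploidySpec:
    """A whole-chromosome copy-number event to impose on one embryo."""

    kind: str = "none"              # none | trisomy | monosomy
    chromosome: str | None = None
    origin_parent: str | None = None  # father | mother
    stage: str | None = None          # MI | MII (trisomy only)

    def __post_init__(self) -> None:
        if self.kind == "none":
            if self.chromosome or self.origin_parent or self.stage:
                raise DomainError("kind='none' admits no other fields")
            return
        if self.kind not in ("trisomy", "monosomy"):
            raise DomainError(f"unknown aneuploidy kind {self.kind!r}")
        if self.chromosome is None or self.origin_parent not in ("father", "mother"):
            raise DomainError("aneuploidy needs a chromosome and an origin parent")
        if self.kind == "trisomy":
            if self.stage not in ("MI", "MII"):
                raise DomainError("trisomy requires stage MI or MII")
        elif self.stage is not None:
            raise DomainError("stage applies to trisomy only")


EUPLOID = AneuploidySpec()


@dataclass
class EmbryoTruth:
    """Ground truth retained for every simulated embryo."""

    embryo_id: str
    paternal_meiosis: MeiosisEvent
    maternal_meiosis: MeiosisEvent
    aneuploidy: AneuploidySpec
    true_genotype: str                 # e.g. "--/αα", "--/--/αα", "αα"
    n_normal_copies: int               # intact-allele copies at the locus
    n_deletion_copies: int             # deletion-allele copies at the locus
    inherited_risk: dict[str, list[bool]]  # per parent, per transmitted chromatid

    @property
    def pcr_level(self) -> str:
        """Collapse the copy composition to the three-level assay readout."""
        if self.n_normal_copies and self.n_deletion_copies:
            return "CARRIER"
        if self.n_normal_copies:
            return "NORMAL"
        if self.n_deletion_copies:
            return "AFFECTED"
        return "NULL"


def genotype_string(n_normal: int, n_deletion: int) -> str:
    """Render a copy composition in deletion-first typography, e.g. '--/--/αα'."""
    if n_normal + n_deletion == 0:
        return "null"
    return "/".join(["--"] * n_deletion + ["αα"] * n_normal)


def _chromatids_for(
    parent: PhasedParent,
    meiosis: MeiosisEvent,
    chrom: str,
    aneuploidy: AneuploidySpec,
) -> list[np.ndarray | int]:
    """Transmitted chromatid descriptors for one parent on one chromosome.

    Each entry is either a fixed haplotype index (int, MI whole homolog) or
    ``None`` meaning 'the recombined chromatid of this meiosis'; duplication
    is expressed by repetition.
    """
    if (
        aneuploidy.kind != "none"
        and aneuploidy.chromosome == chrom
        and aneuploidy.origin_parent == parent.role
    ):
        if aneuploidy.kind == "monosomy":
            return []
        if aneuploidy.stage == "MI":
            return [0, 1]          # both homologs, intact
        return [None, None]        # one recombined chromatid, twice
    return [None]


def simulate_embryo(
    embryo_id: str,
    father: PhasedParent,
    mother: PhasedParent,
    config: FamilyConfig,
    aneuploidy: AneuploidySpec = EUPLOID,
    noise: NoiseModel = NoiseModel(),
    recomb_map: RecombinationMap | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SampleArray, EmbryoTruth]:
    """Simulate one embryo biopsy: meiosis, copy-state assembly, array rendering.

    Disomic chromosomes carry one recombined chromatid per parent. A trisomy
    of MI origin replaces the origin parent's contribution with both intact
    homologs; MII duplicates the recombined chromatid; monosomy removes the
    origin parent's contribution. SNPs inside the deletion interval on a risk
    chromatid contribute no allele, so the ideal BAF/LRR reflect the locally
    reduced copy number. WGA allele dropout is applied per allele copy before
    genotype calling; BAF/LRR derive from the pre-dropout copy state plus
    Gaussian noise; the truth record stores the pre-noise state.
    """
    rng = np.random.default_rng(rng)
    panel = father.panel
    recomb_map = recomb_map or default_recomb_map(config=config)
    pat_meiosis = simulate_meiosis(father, recomb_map, rng)
    mat_meiosis = simulate_meiosis(mother, recomb_map, rng)

    n = len(panel)
    positions = panel.positions
    chroms = panel.chroms
    deleted_interval = panel.interval_mask(config.deletion)

    allele_cols: list[np.ndarray] = []
    present_cols: list[np.ndarray] = []
    locus_mid = (config.locus.start + config.locus.end) // 2
    inherited_risk: dict[str, list[bool]] = {"father": [], "mother": []}

    for parent, meiosis in ((father, pat_meiosis), (mother, mat_meiosis)):
        # assemble per-chromosome chromatid source vectors
        source_default = np.empty(n, dtype=np.int8)
        for chrom in AUTOSOME_LENGTHS:
            m = chroms == chrom
            if m.any():
                source_default[m] = meiosis.source_at(chrom, positions[m])
        specs_by_chrom = {
            chrom: _chromatids_for(parent, meiosis, chrom, aneuploidy)
            for chrom in AUTOSOME_LENGTHS
        }
        max_copies = max(len(v) for v in specs_by_chrom.values())
        for slot in range(max_copies):
            allele = np.zeros(n, dtype=np.uint8)
            present = np.zeros(n, dtype=bool)
            source = np.full(n, -1, dtype=np.int8)
            for chrom, specs in specs_by_chrom.items():
                if slot >= len(specs):
                    continue
                m = chroms == chrom
                spec = specs[slot]
                src = (
                    source_default[m]
                    if spec is None
                    else np.full(int(m.sum()), spec, dtype=np.int8)
                )
                source[m] = src
                allele[m] = parent.haplotypes[src, np.flatnonzero(m)]
                present[m] = True
            # risk chromatids contribute nothing inside the deletion interval
            risk_copy = deleted_interval & present & (source == parent.risk_index)
            present &= ~risk_copy
            allele_cols.append(allele)
            present_cols.append(present)
            # truth at the locus: which chromatids carried the deletion there
            if slot < len(specs_by_chrom[config.locus.chrom]):
                spec = specs_by_chrom[config.locus.chrom][slot]
                if spec is None:
                    xs = meiosis.crossovers.get(config.locus.chrom, np.empty(0))
                    start = meiosis.start_hap.get(config.locus.chrom, 0)
                    src_at_locus = (start + int((xs < locus_mid).sum())) % 2
                else:
                    src_at_locus = spec
                inherited_risk[parent.role].append(
                    src_at_locus == parent.risk_index
                )

    alleles = np.stack(allele_cols)          # (n_chromatids, n_snps)
    present = np.stack(present_cols)
    copy_number = present.sum(axis=0)
    b_sum = (alleles * present).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ideal_baf = np.where(copy_number > 0, b_sum / np.maximum(copy_number, 1), np.nan)
        ideal_lrr = np.where(copy_number > 0, np.log2(np.maximum(copy_number, 1) / 2.0), np.nan)

    baf = ideal_baf + rng.normal(0.0, noise.baf_sd, n) if noise.baf_sd else ideal_baf.copy()
    baf = np.clip(baf, 0.0, 1.0)
    lrr = ideal_lrr + rng.normal(0.0, noise.lrr_sd, n) if noise.lrr_sd else ideal_lrr.copy()

    # WGA allele dropout on each present allele copy, then genotype calling
    survived = present & (rng.random(present.shape) >= noise.ado_rate)
    n_surv = survived.sum(axis=0)
    b_surv = (alleles * survived).sum(axis=0)
    gtype = np.full(n, "NC", dtype=object)
    called = n_surv > 0
    has_b = b_surv > 0
    has_a = b_surv < n_surv
    gtype[called & has_a & ~has_b] = "AA"
    gtype[called & has_b & ~has_a] = "BB"
    gtype[called & has_a & has_b] = "AB"

    if noise.miscall_rate:
        flip = called & (rng.random(n) < noise.miscall_rate)
        if flip.any():
            idx = np.flatnonzero(flip)
            current = gtype[idx]
            offsets = rng.integers(1, 3, size=len(idx))
            order = {"AA": 0, "AB": 1, "BB": 2}
            gtype[idx] = _GT[
                (np.array([order[g] for g in current]) + offsets) % 3
            ]
    if noise.nocall_rate:
        gtype[rng.random(n) < noise.nocall_rate] = "NC"

    data = pd.DataFrame({"gtype": gtype, "baf": baf, "lrr": lrr})
    sample = SampleArray(embryo_id, "embryo", panel, data)

    n_del = sum(inherited_risk["father"]) + sum(inherited_risk["mother"])
    n_total = len(inherited_risk["father"]) + len(inherited_risk["mother"])
    truth = EmbryoTruth(
        embryo_id=embryo_id,
        paternal_meiosis=pat_meiosis,
        maternal_meiosis=mat_meiosis,
        aneuploidy=aneuploidy,
        true_genotype=genotype_string(n_total - n_del, n_del),
        n_normal_copies=n_total - n_del,
        n_deletion_copies=n_del,
        inherited_risk=inherited_risk,
    )
    return sample, truth


def simulate_gap_pcr(
    truth: EmbryoTruth,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int | None = None,
) -> list[PcrPeak]:
    """Simulate fluorescent Gap-PCR peaks from the true locus copy state.

    Each intact-allele copy independently yields (or drops, with
    ``pcr_ado_rate``) a 280-bp FAM product; each deletion-allele copy a
    178-bp HEX product. Surviving copies of a product merge into one peak
    whose height scales with the surviving copy count.
    """
    rng = np.random.default_rng(rng)
    peaks: list[PcrPeak] = []
    for copies, size, dye in (
        (truth.n_normal_copies, NORMAL_PRODUCT_BP, "FAM"),
        (truth.n_deletion_copies, DELETION_PRODUCT_BP, "HEX"),
    ):
        surviving = int((rng.random(copies) >= noise.pcr_ado_rate).sum())
        if surviving > 0:
            height = surviving * float(rng.uniform(600.0, 1400.0))
            peaks.append(PcrPeak(size_bp=size, dye=dye, height=height))
    return sorted(peaks, key=lambda p: p.size_bp)


@dataclass
class FamilySim:
    """A fully simulated family: phased parents, rendered arrays, embryos."""

    config: FamilyConfig
    panel: SnpPanel
    father: PhasedParent
    mother: PhasedParent
    father_array: SampleArray
    mother_array: SampleArray
    embryos: list[SampleArray] = field(default_factory=list)
    truths: list[EmbryoTruth] = field(default_factory=list)
    peaks: dict[str, list[PcrPeak]] = field(default_factory=dict)

    def truth_by_id(self, embryo_id: str) -> EmbryoTruth:
        for t in self.truths:
            if t.embryo_id == embryo_id:
                return t
        raise KeyError(embryo_id)


def simulate_family(
    config: FamilyConfig | None = None,
    n_embryos: int = 8,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.SeedSequence = 0,
    panel: SnpPanel | None = None,
    maf: float | np.ndarray = 0.5,
    aneuploidies: Sequence[AneuploidySpec] | None = None,
    recomb_map: RecombinationMap | None = None,
) -> FamilySim:
    """Simulate one carrier x carrier family with ``n_embryos`` biopsies.

    Randomness flows from one seed through a splittable SeedSequence: stream 0
    draws the parents, stream i+1 draws embryo i, so embryo outcomes are
    reproducible independently of how many siblings are simulated.
    ``aneuploidies`` optionally fixes each embryo's copy-number event
    (default: all euploid).
    """
    config = config or FamilyConfig("fam1", "father", "mother")
    panel = panel or build_default_panel(config=config)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(n_embryos + 1)
    father, mother = simulate_parents(
        panel,
        maf=maf,
        rng=np.random.default_rng(streams[0]),
        father_id=config.father_id,
        mother_id=config.mother_id,
    )
    if aneuploidies is None:
        aneuploidies = [EUPLOID] * n_embryos
    if len(aneuploidies) != n_embryos:
        raise DomainError("one AneuploidySpec per embryo is required")
    embryo_ids = list(config.embryo_ids) or [
        f"{config.family_id}_E{i + 1}" for i in range(n_embryos)
    ]
    if len(embryo_ids) < n_embryos:
        raise DomainError("fewer embryo ids than embryos requested")
    sim = FamilySim(
        config=config.with_embryos(embryo_ids[:n_embryos]),
        panel=panel,
        father=father,
        mother=mother,
        father_array=father.to_sample_array(config),
        mother_array=mother.to_sample_array(config),
    )
    for i in range(n_embryos):
        rng = np.random.default_rng(streams[i + 1])
        sample, truth = simulate_embryo(
            embryo_ids[i],
            father,
            mother,
            config,
            aneuploidy=aneuploidies[i],
            noise=noise,
            recomb_map=recomb_map,
            rng=rng,
        )
        sim.embryos.append(sample)
        sim.truths.append(truth)
        sim.peaks[truth.embryo_id] = simulate_gap_pcr(truth, noise, rng)
    return sim
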