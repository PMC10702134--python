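"""End-to-end family workflow: PCR calls, reference selection, phasing,
per-embryo haplotype calls, genome-wide aneuploidy screening, discordance
resolution and transfer prioritization.

This is the orchestration layer over the per-step modules; each step can
also be driven individually (see examples/).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aneuploidy import CnvParams, GenomeScreenResult, genome_screen
from .gap_pcr import PcrGenotype, PcrPeak, call_pcr_genotype
from .haplotyping import (
    HaplotypeResult,
    ParentalPhase,
    call_embryo_haplotype,
    find_informative_snps,
    haplotype_genotype,
    phase_from_carrier_pair,
    phase_from_reference,
)
from .model import FamilyConfig, IntegrityError, SampleArray, partition_region
from .resolution import (
    EmbryoReport,
    QC_CALL_RATE,
    RebiopsyOutcome,
    TransferPlan,
    finalize_embryo,
    transfer_priority,
)
from .sim import FamilySim, NoiseModel, simulate_embryo, simulate_gap_pcr

__all__ = [
    "FamilyAnalysis",
    "analyze_family",
    "simulation_providers",
    "analyze_simulated_family",
]


@dataclass
class FamilyAnalysis:
    """Everything the workflow produced for one family."""

    config: FamilyConfig
    informative: pd.DataFrame
    phases: dict[str, ParentalPhase] | None
    reference_id: str | None
    reference_kind: str | None
    pcr: dict[str, PcrGenotype]
    haplotypes: dict[str, HaplotypeResult]
    screens: dict[str, GenomeScreenResult]
    reports: list[EmbryoReport]
    transfer: TransferPlan
    upstream_informative: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _reference_candidates(
    embryos: Sequence[SampleArray],
    pcr: Mapping[str, PcrGenotype],
    screens: Mapping[str, GenomeScreenResult],
    qc_threshold: float,
) -> tuple[list[SampleArray], list[str]]:
    """Rank reference candidates: affected before normal homozygotes.

    An affected reference carries both risk haplotypes at once, anchoring
    both parents in a single sample. Candidates must pass the call-rate QC
    and, when screening data exist, be two-copy on the target chromosome.
    """
    notes: list[str] = []
    ranked: list[tuple[int, float, SampleArray]] = []
    for e in embryos:
        p = pcr.get(e.sample_id)
        if p not in (PcrGenotype.AFFECTED, PcrGenotype.NORMAL):
            continue
        if e.call_rate < qc_threshold:
            notes.append(f"{e.sample_id}: homozygous but below call-rate QC")
            continue
        screen = screens.get(e.sample_id)
        chr16 = screen.calls.get("16") if screen else None
        if chr16 is not None and chr16.copy_number != 2:
            notes.append(f"{e.sample_id}: homozygous but chr16 not two-copy")
            continue
        if chr16 is None:
            notes.append(f"{e.sample_id}: chr16 copy number unknown for reference")
        ranked.append((0 if p == PcrGenotype.AFFECTED else 1, -e.call_rate, e))
    ranked.sort(key=lambda t: (t[0], t[1], t[2].sample_id))
    return [t[2] for t in ranked], notes


def analyze_family(
    config: FamilyConfig,
    father: SampleArray,
    mother: SampleArray,
    embryos: Sequence[SampleArray],
    peaks: Mapping[str, Sequence[PcrPeak]] | None = None,
    pcr: Mapping[str, PcrGenotype] | None = None,
    cnv_params: CnvParams = CnvParams(),
    qc_threshold: float = QC_CALL_RATE,
    min_informative: int = 3,
    majority: float = 0.8,
    min_block: int = 3,
    provider_factory: Callable[[str], tuple[Callable, Callable]] | None = None,
) -> FamilyAnalysis:
    """Run the complete workflow on one family's arrays and PCR data.

    ``provider_factory(embryo_id)`` supplies the (retest, rebiopsy) callbacks
    used when a discordance needs wet-lab follow-up; omitted callbacks leave
    such embryos unresolved/pending.
    """
    if pcr is None:
        if peaks is None:
            raise ValueError("either peaks or pcr calls are required")
        pcr = {eid: call_pcr_genotype(p) for eid, p in peaks.items()}
    pcr = dict(pcr)

    partition = partition_region(config)
    informative = find_informative_snps(father, mother, partition)
    upstream = {
        parent: int(
            (
                (informative["informative_for"] == parent)
                & (informative["flank"] == "upstream_5p")
            ).sum()
        )
        for parent in ("father", "mother")
    }

    screens = {
        e.sample_id: genome_screen(e, father, mother, cnv_params) for e in embryos
    }

    notes: list[str] = []
    candidates, sel_notes = _reference_candidates(embryos, pcr, screens, qc_threshold)
    notes.extend(sel_notes)
    phases: dict[str, ParentalPhase] | None = None
    reference_id = reference_kind = None
    for reference in candidates:
        try:
            phases = phase_from_reference(
                reference, pcr[reference.sample_id], informative, config
            )
        except IntegrityError as exc:
            # failed the Mendelian QC: try the next-ranked sibling
            notes.append(str(exc))
            continue
        reference_id = reference.sample_id
        reference_kind = phases["father"].reference_kind
        break
    if phases is None:
        carriers = [
            e
            for e in embryos
            if pcr.get(e.sample_id) == PcrGenotype.CARRIER
            and e.call_rate >= qc_threshold
        ]
        for i in range(len(carriers)):
            for j in range(i + 1, len(carriers)):
                result = phase_from_carrier_pair(
                    carriers[i], carriers[j], father, mother, informative, config,
                    min_informative=min_informative, min_call_rate=qc_threshold,
                )
                if result.ok:
                    phases = result.phases
                    reference_id = phases["father"].source
                    reference_kind = "carrier_pair"
                    break
            if phases:
                break
        if phases is None:
            notes.append("no usable reference embryo or carrier pair; haplotype analysis unavailable")

    haplotypes: dict[str, HaplotypeResult] = {}
    for e in embryos:
        if phases is None:
            haplotypes[e.sample_id] = HaplotypeResult(
                "UNDETERMINED", "no parental phase", [], True
            )
            continue
        paternal = call_embryo_haplotype(
            e, phases["father"], informative, min_informative, majority, min_block
        )
        maternal = call_embryo_haplotype(
            e, phases["mother"], informative, min_informative, majority, min_block
        )
        haplotypes[e.sample_id] = haplotype_genotype(
            paternal, maternal, config.locus
        )

    reports: list[EmbryoReport] = []
    for e in embryos:
        eid = e.sample_id
        retest_provider = rebiopsy_provider = None
        if provider_factory is not None:
            retest_provider, rebiopsy_provider = provider_factory(eid)
        reports.append(
            finalize_embryo(
                eid,
                pcr.get(eid, PcrGenotype.FAIL),
                haplotypes[eid],
                screens.get(eid),
                e.call_rate,
                retest_provider,
                rebiopsy_provider,
                qc_threshold,
            )
        )

    transfer = transfer_priority(reports, upstream)
    return FamilyAnalysis(
        config=config,
        informative=informative,
        phases=phases,
        reference_id=reference_id,
        reference_kind=reference_kind,
        pcr=pcr,
        haplotypes=haplotypes,
        screens=screens,
        reports=reports,
        transfer=transfer,
        upstream_informative=upstream,
        notes=notes,
    )


def simulation_providers(
    sim: FamilySim,
    noise: NoiseModel,
    seed: int = 0,
    cnv_params: CnvParams = CnvParams(),
) -> Callable[[str], tuple[Callable, Callable]]:
    """Retest/rebiopsy callbacks backed by the simulator's ground truth.

    A retest re-runs the Gap-PCR simulation on the same embryo (a second
    amplification of the same WGA product, so a new independent ADO draw).
    A rebiopsy re-renders the embryo sample with fresh WGA noise and re-runs
    both methods on it.
    """

    def factory(embryo_id: str) -> tuple[Callable, Callable]:
        truth = sim.truth_by_id(embryo_id)
        ss = np.random.SeedSequence([seed, zlib.crc32(embryo_id.encode())])
        retest_rng, rebiopsy_rng = (
            np.random.default_rng(s) for s in ss.spawn(2)
        )

        def retest() -> PcrGenotype:
            return call_pcr_genotype(simulate_gap_pcr(truth, noise, retest_rng))

        def rebiopsy() -> RebiopsyOutcome:
            sample, _ = simulate_embryo(
                embryo_id,
                sim.father,
                sim.mother,
                sim.config,
                aneuploidy=truth.aneuploidy,
                noise=noise,
                rng=rebiopsy_rng,
            )
            new_pcr = call_pcr_genotype(simulate_gap_pcr(truth, noise, rebiopsy_rng))
            return RebiopsyOutcome(
                pcr=new_pcr,
                haplotype_value=truth.pcr_level if truth.pcr_level != "NULL" else None,
                call_rate=sample.call_rate,
            )

        return retest, rebiopsy

    return factory


def analyze_simulated_family(
    sim: FamilySim,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    cnv_params: CnvParams = CnvParams(),
    **kwargs,
) -> FamilyAnalysis:
    """Convenience wrapper: run :func:`analyze_family` on a simulated family
    with truth-backed retest/rebiopsy providers."""
    return analyze_family(
        sim.config,
        sim.father_array,
        sim.mother_array,
        sim.embryos,
        peaks=sim.peaks,
        cnv_params=cnv_params,
        provider_factory=simulation_providers(sim, noise, seed, cnv_params),
        **kwargs,
    )
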