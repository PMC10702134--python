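"""Shipped in-repo fixtures: the 25-family informative-SNP count table and
the ten discordant embryo cases, with helpers to replay them through the
decision engine."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .aneuploidy import ChromosomeCnvCall, MonosomyCall
from .gap_pcr import PcrGenotype
from .haplotyping import HaplotypeCall, HaplotypeResult, Verdict
from .resolution import EmbryoReport, RebiopsyOutcome, finalize_embryo
from .aneuploidy import GenomeScreenResult

__all__ = [
    "load_informative_counts",
    "load_discordant_cases",
    "DiscordantCase",
    "replay_discordant_case",
]


def _data(name: str):
    return resources.files("alphapgt.data").joinpath(name)


def load_informative_counts() -> pd.DataFrame:
    """The per-family informative-SNP counts of the 25 clinical families.

    Columns: (parent, flank) MultiIndex over mother/father x
    upstream_5p/in_gene/downstream_3p; index = family number.
    """
    raw = pd.read_csv(_data("table4_counts.tsv"), sep="\t", index_col="family")
    columns = pd.MultiIndex.from_tuples(
        [
            ("mother", "upstream_5p"),
            ("mother", "in_gene"),
            ("mother", "downstream_3p"),
            ("father", "upstream_5p"),
            ("father", "in_gene"),
            ("father", "downstream_3p"),
        ],
        names=["parent", "flank"],
    )
    raw.columns = columns
    return raw


@dataclass
class DiscordantCase:
    """One encoded discordant embryo: engine inputs plus adjudicated outcome."""

    embryo_id: str
    pcr: PcrGenotype
    haplotype: HaplotypeResult
    chr16: ChromosomeCnvCall
    call_rate: float
    retest: PcrGenotype | None
    rebiopsy: RebiopsyOutcome | None
    expected_final: str
    expected_cause: str


def _haplotype_from(raw: dict, embryo_id: str) -> HaplotypeResult:
    def call(parent: str) -> HaplotypeCall:
        verdict = Verdict[raw.get(parent, "NOCALL")]
        return HaplotypeCall(embryo_id, "father" if parent == "paternal" else "mother", verdict)

    value = raw["value"]
    risk_parents = []
    if raw.get("paternal") == "RISK":
        risk_parents.append("father")
    if raw.get("maternal") == "RISK":
        risk_parents.append("mother")
    return HaplotypeResult(
        value=value,
        annotation=raw.get("annotation", ""),
        risk_parents=risk_parents,
        low_confidence="NOCALL" in (raw.get("paternal"), raw.get("maternal")),
        paternal=call("paternal"),
        maternal=call("maternal"),
    )


def _cnv_from(raw: dict) -> ChromosomeCnvCall:
    cn = int(raw["copy_number"])
    call = ChromosomeCnvCall(chromosome="16", copy_number=cn)
    if cn == 3:
        call.origin_parent = raw.get("origin")
        call.stage = raw.get("stage")
    elif cn == 1:
        call.origin_parent = raw.get("lost")
        call.monosomy = MonosomyCall(
            retained_parent=raw.get("retained"),
            lost_parent=raw.get("lost"),
            retained_risk=raw.get("retained_risk"),
        )
    return call


def load_discordant_cases() -> list[DiscordantCase]:
    """The ten discordant cases as replayable decision-engine inputs."""
    raw = yaml.safe_load(_data("table3_cases.yaml").read_text())
    cases = []
    for c in raw["cases"]:
        rb = c.get("rebiopsy")
        cases.append(
            DiscordantCase(
                embryo_id=str(c["embryo"]),
                pcr=PcrGenotype[c["pcr"]],
                haplotype=_haplotype_from(c["haplotype"], str(c["embryo"])),
                chr16=_cnv_from(c["chr16"]),
                call_rate=float(c["call_rate"]),
                retest=PcrGenotype[c["retest"]] if c.get("retest") else None,
                rebiopsy=(
                    RebiopsyOutcome(
                        pcr=PcrGenotype[rb["pcr"]],
                        haplotype_value=rb.get("haplotype"),
                        call_rate=rb.get("call_rate"),
                    )
                    if rb
                    else None
                ),
                expected_final=c["expected"]["final"],
                expected_cause=c["expected"]["cause"],
            )
        )
    return cases


def replay_discordant_case(case: DiscordantCase) -> EmbryoReport:
    """Run one encoded case through the full finalization path."""
    screen = GenomeScreenResult(
        calls={"16": case.chr16},
        euploid=case.chr16.copy_number == 2,
        abnormal_chromosomes=[] if case.chr16.copy_number == 2 else ["16"],
    )
    return finalize_embryo(
        case.embryo_id,
        case.pcr,
        case.haplotype,
        screen,
        case.call_rate,
        retest_provider=(lambda: case.retest) if case.retest else None,
        rebiopsy_provider=(lambda: case.rebiopsy) if case.rebiopsy else None,
    )
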