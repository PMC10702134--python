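"""Truth-recovery batteries over the simulator.

These routines quantify how faithfully the full workflow (phasing, haplotype
calls, copy-number/origin/stage calling, discordance resolution, transfer
ranking) recovers the simulator's ground truth, under zero noise and under
the default whole-genome-amplification noise model. They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aneuploidy import CnvParams
from .gap_pcr import PcrGenotype, call_pcr_genotype
from .model import FamilyConfig, SnpPanel
from .pipeline import analyze_simulated_family
from .sim import (
    AneuploidySpec,
    EUPLOID,
    NOISELESS,
    NoiseModel,
    build_default_panel,
    recomb_map_outside_flanks,
    simulate_family,
    simulate_gap_pcr,
)

__all__ = [
    "EVENT_TYPES",
    "OracleBatteryResult",
    "TruthRecoveryResult",
    "zero_noise_oracle_battery",
    "truth_recovery_run",
    "genotype_ratio_run",
    "pcr_ado_run",
    "collapse_genotype",
]

#: every whole-chromosome event type the simulator and callers support
EVENT_TYPES = (
    AneuploidySpec("trisomy", "16", "mother", "MI"),
    AneuploidySpec("trisomy", "16", "mother", "MII"),
    AneuploidySpec("trisomy", "16", "father", "MI"),
    AneuploidySpec("trisomy", "16", "father", "MII"),
    AneuploidySpec("monosomy", "16", "mother"),
    AneuploidySpec("monosomy", "16", "father"),
    AneuploidySpec("trisomy", "7", "mother", "MI"),
    AneuploidySpec("trisomy", "4", "father", "MII"),
    AneuploidySpec("monosomy", "21", "mother"),
    AneuploidySpec("monosomy", "13", "father"),
)


def collapse_genotype(final: str) -> str | None:
    """Collapse a final genotype string to its three-level transfer reading:
    any intact + any deleted allele = CARRIER, only intact = NORMAL, only
    deleted = AFFECTED; undetermined collapses to None."""
    if final in ("undetermined", "null", None):
        return None
    has_normal = "αα" in final
    has_deletion = "--" in final
    if has_normal and has_deletion:
        return "CARRIER"
    if has_normal:
        return "NORMAL"
    if has_deletion:
        return "AFFECTED"
    return None


def _family_specs(n_embryos: int, n_events: int, offset: int) -> list[AneuploidySpec]:
    """n_embryos specs: euploid except the last ``n_events``, which cycle
    through the global event list starting at ``offset``."""
    specs = [EUPLOID] * (n_embryos - n_events)
    for k in range(n_events):
        specs.append(EVENT_TYPES[(offset + k) % len(EVENT_TYPES)])
    return specs


def _truth_risk_map(sim, parent_role: str, informative) -> dict[str, str]:
    parent = sim.father if parent_role == "father" else sim.mother
    sel = informative["informative_for"] == parent_role
    idx = sim.panel.indexer(informative.loc[sel, "snp_id"])
    risk = parent.risk_haplotype()[idx]
    return dict(zip(informative.loc[sel, "snp_id"], np.where(risk == 1, "B", "A")))


@dataclass
class OracleBatteryResult:
    n_embryos: int = 0
    n_events: int = 0
    phase_mismatches: int = 0
    haplotype_mismatches: int = 0
    cnv_mismatches: int = 0
    origin_mismatches: int = 0
    stage_mismatches: int = 0
    failures: list[str] = field(default_factory=list)

    @property
    def all_correct(self) -> bool:
        return not self.failures


def zero_noise_oracle_battery(
    seed: int = 0,
    n_families: int = 10,
    embryos_per_family: int = 10,
    events_per_family: int = 6,
    panel: SnpPanel | None = None,
) -> OracleBatteryResult:
    """Noise-free equivalence check of every caller against simulator truth.

    For each family: the recovered parental phases must equal the true risk
    haplotypes at every phased SNP; every euploid embryo's haplotype genotype
    must equal its true genotype; every embryo's target-chromosome copy
    number — and for aneuploid embryos the origin parent and meiotic stage —
    must equal the simulated event.

    Crossovers are suppressed inside the flanked target region here: the
    phasing model assumes a non-recombinant reference across the region, so
    an in-flank crossover would violate the model's premise rather than test
    the caller (recombinant transmission is exercised by dedicated tests).
    """
    panel = panel or build_default_panel()
    out = OracleBatteryResult()
    for f in range(n_families):
        config = FamilyConfig(f"fam{f}", "father", "mother")
        sim = simulate_family(
            config,
            n_embryos=embryos_per_family,
            noise=NOISELESS,
            seed=np.random.SeedSequence([seed, f]),
            panel=panel,
            recomb_map=recomb_map_outside_flanks(config=config),
            aneuploidies=_family_specs(
                embryos_per_family, events_per_family, f * events_per_family
            ),
        )
        ana = analyze_simulated_family(sim, noise=NOISELESS, seed=seed)
        out.n_embryos += embryos_per_family
        if ana.phases is not None:
            for parent in ("father", "mother"):
                truth_map = _truth_risk_map(sim, parent, ana.informative)
                got = ana.phases[parent].risk_allele
                bad = sum(truth_map[s] != a for s, a in got.items())
                if bad or not got:
                    out.phase_mismatches += max(bad, 1)
                    out.failures.append(f"fam{f}: {parent} phase mismatch")
        else:
            out.failures.append(f"fam{f}: phasing unavailable")
        for e, t in zip(sim.embryos, sim.truths):
            spec = t.aneuploidy
            chrom = spec.chromosome or "16"
            screen = ana.screens[e.sample_id]
            call = screen.calls[chrom]
            expected_cn = {"none": 2, "trisomy": 3, "monosomy": 1}[spec.kind]
            if call.copy_number != expected_cn:
                out.cnv_mismatches += 1
                out.failures.append(f"{t.embryo_id}: CN {call.copy_number}")
            if spec.kind == "trisomy":
                out.n_events += 1
                if call.origin_parent != spec.origin_parent:
                    out.origin_mismatches += 1
                    out.failures.append(f"{t.embryo_id}: origin {call.origin_parent}")
                if call.stage != spec.stage:
                    out.stage_mismatches += 1
                    out.failures.append(f"{t.embryo_id}: stage {call.stage}")
            elif spec.kind == "monosomy":
                out.n_events += 1
                if call.origin_parent != spec.origin_parent:
                    out.origin_mismatches += 1
                    out.failures.append(f"{t.embryo_id}: lost {call.origin_parent}")
            if spec.kind == "none":
                hap = ana.haplotypes[e.sample_id]
                if hap.value != t.pcr_level:
                    out.haplotype_mismatches += 1
                    out.failures.append(f"{t.embryo_id}: haplotype {hap.value}")
    return out


@dataclass
class TruthRecoveryResult:
    n_embryos: int
    n_correct: int
    safety_violations: int
    n_affected_truth: int
    n_unresolved: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_embryos


def truth_recovery_run(
    seed: int = 0,
    n_families: int = 25,
    embryos_per_family: int = 20,
    events_per_family: int = 2,
    noise: NoiseModel = NoiseModel(),
    panel: SnpPanel | None = None,
    cnv_params: CnvParams = CnvParams(),
) -> TruthRecoveryResult:
    """Final-genotype recovery under the default noise model.

    ``events_per_family / embryos_per_family`` sets the aneuploidy mix (the
    default is 10%, cycling through every event type). An embryo counts as
    correct when its resolved final genotype collapses to the same
    three-level reading as the truth. The safety counter tallies
    truth-affected embryos that appear anywhere in a transfer ranking.
    """
    panel = panel or build_default_panel()
    n_correct = n_embryos = violations = n_affected = n_unresolved = 0
    for f in range(n_families):
        sim = simulate_family(
            FamilyConfig(f"fam{f}", "father", "mother"),
            n_embryos=embryos_per_family,
            noise=noise,
            seed=np.random.SeedSequence([seed, 1000 + f]),
            panel=panel,
            aneuploidies=_family_specs(
                embryos_per_family, events_per_family, f * events_per_family
            ),
        )
        ana = analyze_simulated_family(sim, noise=noise, seed=seed)
        ranked_ids = {c.embryo_id for c in ana.transfer.ranked}
        for r in ana.reports:
            t = sim.truth_by_id(r.embryo_id)
            n_embryos += 1
            truth_level = t.pcr_level
            got_level = collapse_genotype(r.final_genotype)
            if got_level is None:
                n_unresolved += 1
            if got_level == truth_level:
                n_correct += 1
            if truth_level == "AFFECTED":
                n_affected += 1
                if r.embryo_id in ranked_ids:
                    violations += 1
    return TruthRecoveryResult(
        n_embryos=n_embryos,
        n_correct=n_correct,
        safety_violations=violations,
        n_affected_truth=n_affected,
        n_unresolved=n_unresolved,
    )


def genotype_ratio_run(
    seed: int = 0, n_embryos: int = 2000, panel: SnpPanel | None = None
) -> dict[str, int]:
    """True genotype counts of carrier x carrier embryos (expected 1:2:1)."""
    panel = panel or build_default_panel(n_backbone_per_chrom=50)
    sim = simulate_family(
        n_embryos=n_embryos, noise=NOISELESS, seed=seed, panel=panel
    )
    counts = {"--/--": 0, "--/αα": 0, "αα/αα": 0}
    for t in sim.truths:
        counts[t.true_genotype] += 1
    return counts


def pcr_ado_run(
    seed: int = 0, ado_rate: float = 0.01, n_trials: int = 20_000
) -> float:
    """Fraction of true-carrier Gap-PCRs miscalled homozygous; the small-ε
    expectation is 2ε(1-ε) ≈ 2ε."""
    from .sim import AneuploidySpec, EmbryoTruth, MeiosisEvent

    ev = MeiosisEvent("father", {}, {})
    truth = EmbryoTruth("e", ev, ev, AneuploidySpec(), "--/αα", 1, 1, {})
    noise = NoiseModel(pcr_ado_rate=ado_rate)
    rng = np.random.default_rng(seed)
    miscalled = 0
    for _ in range(n_trials):
        g = call_pcr_genotype(simulate_gap_pcr(truth, noise, rng))
        miscalled += g in (PcrGenotype.NORMAL, PcrGenotype.AFFECTED)
    return miscalled / n_trials
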