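"""Informative SNPs, reference/carrier-pair phasing and haplotype calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from alphapgt import (
    FamilyConfig,
    HaplotypeCall,
    PcrGenotype,
    SampleArray,
    SnpPanel,
    Verdict,
    call_embryo_haplotype,
    call_pcr_genotype,
    find_informative_snps,
    haplotype_genotype,
    informative_snp_stats,
    phase_from_carrier_pair,
    phase_from_reference,
    simulate_family,
    simulate_gap_pcr,
    summarize_informative_counts,
)
from alphapgt.haplotyping import ParentalPhase
from alphapgt.model import IntegrityError
from alphapgt.sim import NOISELESS, RecombinationMap


def _panel(positions, chrom="16"):
    return SnpPanel(
        pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
            }
        )
    )


def _sample(panel, gtypes, sample_id="S", role="embryo"):
    return SampleArray(
        sample_id,
        role,
        panel,
        pd.DataFrame({"gtype": gtypes, "baf": np.nan, "lrr": np.nan}),
    )


@pytest.fixture(scope="module")
def zero_recomb_family(default_panel):
    """Noiseless family with no recombination anywhere: phases are exact."""
    cfg = FamilyConfig("zr", "father", "mother")
    rmap = RecombinationMap({c: [(1, 2, 0.0)] for c in map(str, range(1, 23))})
    return simulate_family(
        cfg, n_embryos=10, noise=NOISELESS, seed=5, panel=default_panel,
        recomb_map=rmap,
    )


def _truth_risk_map(sim, parent_role, informative):
    """Ground-truth risk alleles of one parent at their informative SNPs."""
    parent = sim.father if parent_role == "father" else sim.mother
    sel = informative["informative_for"] == parent_role
    idx = sim.panel.indexer(informative.loc[sel, "snp_id"])
    risk = parent.risk_haplotype()[idx]
    return dict(
        zip(informative.loc[sel, "snp_id"], np.where(risk == 1, "B", "A"))
    )


class TestFindInformative:
    def test_definition_and_exclusions(self):
        panel = _panel([100, 200, 300, 400])
        father = _sample(panel, ["AB", "AB", "NC", "AB"], "F", "father")
        mother = _sample(panel, ["AA", "AB", "AB", "BB"], "M", "mother")
        from alphapgt import GenomeInterval

        inf = find_informative_snps(
            father, mother, regions=[GenomeInterval("16", 1, 500)]
        )
        # rs0: father AB / mother AA -> father-informative, hom allele A
        # rs1: both AB -> excluded; rs2: father NC -> excluded
        # rs3: father AB / mother BB -> father-informative, hom allele B
        assert list(inf["snp_id"]) == ["rs0", "rs3"]
        assert set(inf["informative_for"]) == {"father"}
        assert list(inf["hom_parent_allele"]) == ["A", "B"]

    def test_mismatched_panels_rejected(self):
        p1, p2 = _panel([100]), _panel([200])
        with pytest.raises(IntegrityError):
            find_informative_snps(
                _sample(p1, ["AB"], role="father"),
                _sample(p2, ["AA"], role="mother"),
            )


class TestInformativeStats:
    def test_single_family_sd_is_missing(self):
        counts = pd.DataFrame({"x": [5]})
        out = summarize_informative_counts(counts)
        assert out.loc["x", "mean"] == 5
        assert np.isnan(out.loc["x", "sd"])

    def test_stats_from_simulated_families(self, small_panel):
        fams = {}
        for seed in range(3):
            sim = simulate_family(
                n_embryos=0, noise=NOISELESS, seed=seed, panel=small_panel
            )
            fams[f"fam{seed}"] = find_informative_snps(
                sim.father_array, sim.mother_array, config=sim.config
            )
        counts, summary = informative_snp_stats(fams)
        assert counts.shape == (3, 6)
        # sample SD uses the n-1 denominator
        col = counts[("mother", "downstream_3p")]
        assert summary.loc[("mother", "downstream_3p"), "sd"] == pytest.approx(
            col.std(ddof=1)
        )


class TestPhaseFromReference:
    def test_affected_and_normal_reference_logic(self):
        panel = _panel([100, 200])
        inf = pd.DataFrame(
            {
                "snp_id": ["rs0", "rs1"],
                "chrom": "16",
                "pos": [100, 200],
                "informative_for": "father",
                "hom_parent_allele": ["A", "A"],
                "flank": "downstream_3p",
            }
        )
        cfg = FamilyConfig("f", "F", "M")
        # affected reference AB: father transmitted B on a risk chromatid
        affected = _sample(panel, ["AB", "AA"], "ref")
        phases = phase_from_reference(affected, PcrGenotype.AFFECTED, inf, cfg)
        assert phases["father"].risk_allele == {"rs0": "B", "rs1": "A"}
        # normal reference AA: transmitted A is non-risk, so risk is B
        normal = _sample(panel, ["AA", "AA"], "ref")
        phases = phase_from_reference(normal, PcrGenotype.NORMAL, inf, cfg)
        assert phases["father"].risk_allele == {"rs0": "B", "rs1": "B"}

    def test_heterozygous_reference_rejected(self):
        panel = _panel([100])
        inf = pd.DataFrame(
            {
                "snp_id": ["rs0"],
                "chrom": "16",
                "pos": [100],
                "informative_for": "father",
                "hom_parent_allele": ["A"],
                "flank": "",
            }
        )
        with pytest.raises(Exception):
            phase_from_reference(
                _sample(panel, ["AB"]), PcrGenotype.CARRIER, inf,
                FamilyConfig("f", "F", "M"),
            )

    def test_mendelian_inconsistency_aborts(self):
        panel = _panel(list(range(100, 2100, 100)))
        inf = pd.DataFrame(
            {
                "snp_id": panel.snp_ids,
                "chrom": "16",
                "pos": panel.positions,
                "informative_for": "father",
                "hom_parent_allele": "A",
                "flank": "",
            }
        )
        # BB calls with an obligate maternal A at >5% of SNPs
        gt = ["AB"] * 17 + ["BB"] * 3
        with pytest.raises(IntegrityError, match="Mendelian"):
            phase_from_reference(
                _sample(panel, gt), PcrGenotype.AFFECTED, inf,
                FamilyConfig("f", "F", "M"),
            )

    def test_truth_recovery_on_simulated_family(self, zero_recomb_family):
        """Noiseless phasing from a homozygous reference equals the
        simulator's true risk haplotypes at 100% of informative SNPs."""
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        ref = next(
            (e, t)
            for e, t in zip(sim.embryos, sim.truths)
            if t.pcr_level in ("AFFECTED", "NORMAL")
        )
        pcr = call_pcr_genotype(simulate_gap_pcr(ref[1], NOISELESS, 0))
        phases = phase_from_reference(ref[0], pcr, inf, sim.config)
        for parent in ("father", "mother"):
            truth = _truth_risk_map(sim, parent, inf)
            got = phases[parent].risk_allele
            assert got and all(truth[s] == a for s, a in got.items())

    def test_phasing_idempotent_across_references(self, zero_recomb_family):
        """Any noise-free homozygous sibling yields the identical phase."""
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        refs = [
            (e, t)
            for e, t in zip(sim.embryos, sim.truths)
            if t.pcr_level in ("AFFECTED", "NORMAL")
        ]
        assert len(refs) >= 2
        maps = []
        for e, t in refs:
            pcr = call_pcr_genotype(simulate_gap_pcr(t, NOISELESS, 0))
            phases = phase_from_reference(e, pcr, inf, sim.config)
            maps.append(
                {p: phases[p].risk_allele for p in ("father", "mother")}
            )
        for other in maps[1:]:
            assert other == maps[0]


class TestCarrierPairPhasing:
    def test_truth_recovery_from_opposite_carriers(self, zero_recomb_family):
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        carriers = [
            (e, t)
            for e, t in zip(sim.embryos, sim.truths)
            if t.pcr_level == "CARRIER"
        ]
        pair = None
        for i in range(len(carriers)):
            for j in range(i + 1, len(carriers)):
                r1 = carriers[i][1].inherited_risk
                r2 = carriers[j][1].inherited_risk
                if r1["father"] != r2["father"]:  # opposite risk parents
                    pair = (carriers[i], carriers[j])
                    break
            if pair:
                break
        assert pair is not None, "no opposite-assignment carrier pair drawn"
        (e1, t1), (e2, t2) = pair
        result = phase_from_carrier_pair(
            e1, e2, sim.father_array, sim.mother_array, inf, sim.config
        )
        assert result.ok, result.reason
        expected_a1 = "father" if t1.inherited_risk["father"][0] else "mother"
        assert result.assignment[0] == expected_a1
        for parent in ("father", "mother"):
            truth = _truth_risk_map(sim, parent, inf)
            got = result.phases[parent].risk_allele
            assert got and all(truth[s] == a for s, a in got.items())

    def test_identical_pair_resolved_by_deletion_anchor(self, zero_recomb_family):
        """Two carriers with the same risk parent are still phasable when the
        in-gene hemizygous alleles identify the intact chromosome's donor."""
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        carrier, truth = next(
            (e, t)
            for e, t in zip(sim.embryos, sim.truths)
            if t.pcr_level == "CARRIER"
        )
        result = phase_from_carrier_pair(
            carrier, carrier, sim.father_array, sim.mother_array, inf, sim.config
        )
        assert result.ok
        expected = "father" if truth.inherited_risk["father"][0] else "mother"
        assert result.assignment == (expected, expected)

    def test_identical_pair_without_anchor_is_ambiguous(self, zero_recomb_family):
        """With the deletion-interval evidence blinded, the global risk /
        non-risk labelling symmetry cannot be broken: no-call."""
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        carrier = next(
            e for e, t in zip(sim.embryos, sim.truths) if t.pcr_level == "CARRIER"
        )
        gene = sim.panel.interval_mask(sim.config.deletion)
        blinded = []
        for parent in (sim.father_array, sim.mother_array):
            data = parent.data.copy()
            data.loc[gene, "gtype"] = "NC"
            blinded.append(
                SampleArray(parent.sample_id, parent.role, sim.panel, data)
            )
        result = phase_from_carrier_pair(
            carrier, carrier, blinded[0], blinded[1], inf, sim.config
        )
        assert not result.ok
        assert "ambiguous" in result.reason

    def test_low_call_rate_guard(self, zero_recomb_family):
        sim = zero_recomb_family
        inf = find_informative_snps(
            sim.father_array, sim.mother_array, config=sim.config
        )
        e = sim.embryos[0]
        degraded = SampleArray(
            "bad", "embryo", e.panel,
            e.data.assign(gtype=np.where(np.arange(len(e.data)) % 2 == 0, "NC", e.gtypes)),
        )
        result = phase_from_carrier_pair(
            degraded, sim.embryos[1], sim.father_array, sim.mother_array,
            inf, sim.config,
        )
        assert not result.ok and "call-rate" in result.reason


def _inf_table(positions, flanks, hom="A"):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(positions))],
            "chrom": "16",
            "pos": positions,
            "informative_for": "father",
            "hom_parent_allele": hom,
            "flank": flanks,
        }
    )


class TestCallEmbryoHaplotype:
    def _phase(self, inf, allele="B"):
        return ParentalPhase(
            "father", {s: allele for s in inf["snp_id"]}, "ref", "affected"
        )

    def test_majority_with_scattered_conflicts(self):
        """30/32 matches with 2 scattered conflicts is a confident RISK."""
        pos = list(range(300_000, 300_000 + 32_000, 1000))
        inf = _inf_table(pos, ["downstream_3p"] * 32)
        gt = ["AB"] * 32          # transmitted B = risk everywhere
        gt[7] = "AA"              # two isolated conflicts (transmitted A)
        gt[21] = "AA"
        panel = _panel(pos)
        call = call_embryo_haplotype(_sample(panel, gt), self._phase(inf), inf)
        assert call.verdict == Verdict.RISK
        assert (call.support, call.conflict) == (30, 2)

    def test_clean_switch_is_recombinant_with_breakpoint(self):
        """Perfect match in one downstream block, perfect mismatch in the
        next: RECOMBINANT with the breakpoint in the gap."""
        pos = [300_000 + i * 1000 for i in range(6)] + [
            900_000 + i * 1000 for i in range(6)
        ]
        inf = _inf_table(pos, ["downstream_3p"] * 12)
        gt = ["AB"] * 6 + ["AA"] * 6
        panel = _panel(pos)
        call = call_embryo_haplotype(_sample(panel, gt), self._phase(inf), inf)
        assert call.verdict == Verdict.RECOMBINANT
        assert call.breakpoint_interval == (305_000, 900_000)

    def test_cross_flank_switch_spans_locus(self):
        """Match in the 5' flank, mismatch in the 3' flank: the breakpoint
        interval brackets the genes, so the joint genotype is undetermined."""
        pos = [100_000, 110_000, 120_000] + [300_000 + i * 1000 for i in range(6)]
        inf = _inf_table(pos, ["upstream_5p"] * 3 + ["downstream_3p"] * 6)
        gt = ["AB"] * 3 + ["AA"] * 6
        panel = _panel(pos)
        call = call_embryo_haplotype(_sample(panel, gt), self._phase(inf), inf)
        assert call.verdict == Verdict.RECOMBINANT
        assert call.breakpoint_interval == (120_000, 300_000)
        other = HaplotypeCall("e", "mother", Verdict.NONRISK, support=10)
        result = haplotype_genotype(call, other)
        assert result.value == "UNDETERMINED"

    def test_too_few_usable_snps_is_nocall(self):
        pos = [100_000, 110_000]
        inf = _inf_table(pos, ["upstream_5p"] * 2)
        panel = _panel(pos)
        call = call_embryo_haplotype(
            _sample(panel, ["NC", "AB"]), self._phase(inf), inf
        )
        assert call.verdict == Verdict.NOCALL

    def test_scattered_half_pattern_is_nocall_not_recombinant(self):
        """The alternating ~50% pattern of a confused (trisomic) region must
        not be mistaken for a crossover."""
        rng = np.random.default_rng(0)
        pos = [300_000 + i * 1000 for i in range(60)]
        inf = _inf_table(pos, ["downstream_3p"] * 60)
        gt = list(np.where(rng.random(60) < 0.5, "AB", "AA"))
        panel = _panel(pos)
        call = call_embryo_haplotype(_sample(panel, gt), self._phase(inf), inf)
        assert call.verdict == Verdict.NOCALL

    def test_single_dropout_never_flips_with_five_snps(self):
        """ADO robustness: with >=5 usable SNPs and majority 0.8, corrupting
        any single SNP cannot flip a unanimous verdict."""
        pos = [300_000 + i * 1000 for i in range(5)]
        inf = _inf_table(pos, ["downstream_3p"] * 5)
        panel = _panel(pos)
        for flip in range(5):
            gt = ["AB"] * 5
            gt[flip] = "AA"
            call = call_embryo_haplotype(
                _sample(panel, gt), self._phase(inf), inf
            )
            assert call.verdict == Verdict.RISK

    def test_conservation_support_conflict_skipped(self):
        pos = [300_000 + i * 1000 for i in range(8)]
        inf = _inf_table(pos, ["downstream_3p"] * 8)
        gt = ["AB"] * 5 + ["NC", "AA", "AB"]
        panel = _panel(pos)
        call = call_embryo_haplotype(_sample(panel, gt), self._phase(inf), inf)
        assert call.support + call.conflict + call.skipped == 8


class TestHaplotypeGenotype:
    def _call(self, parent, verdict):
        return HaplotypeCall("e", parent, verdict, support=10)

    @pytest.mark.parametrize(
        "pv,mv,value,annotation",
        [
            (Verdict.NONRISK, Verdict.RISK, "CARRIER", "maternal heterozygous"),
            (Verdict.RISK, Verdict.NONRISK, "CARRIER", "paternal heterozygous"),
            (Verdict.RISK, Verdict.RISK, "AFFECTED", "abnormal homozygous"),
            (Verdict.NONRISK, Verdict.NONRISK, "NORMAL", "normal homozygous"),
        ],
    )
    def test_mapping(self, pv, mv, value, annotation):
        result = haplotype_genotype(self._call("father", pv), self._call("mother", mv))
        assert (result.value, result.annotation) == (value, annotation)
        assert not result.low_confidence

    def test_nocall_propagates_undetermined(self):
        result = haplotype_genotype(
            self._call("father", Verdict.NOCALL), self._call("mother", Verdict.RISK)
        )
        assert result.value == "UNDETERMINED" and result.low_confidence
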