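"""Simulator properties: Mendelian consistency, recombination statistics,
aneuploidy rendering, determinism and truth retention."""

from __future__ import annotations

import numpy as np
import pytest

from alphapgt import (
    AneuploidySpec,
    DomainError,
    FamilyConfig,
    NoiseModel,
    default_recomb_map,
    find_informative_snps,
    simulate_embryo,
    simulate_family,
    simulate_meiosis,
    simulate_parents,
)
from alphapgt.sim import NOISELESS, RecombinationMap


@pytest.fixture(scope="module")
def config():
    return FamilyConfig("fam", "F", "M")


class TestPanelAndParents:
    def test_default_panel_flank_composition(self, default_panel):
        ids = default_panel.snp_ids
        assert sum(s.startswith("hba_up_") for s in ids) == 42
        assert sum(s.startswith("hba_gene_") for s in ids) == 10
        assert sum(s.startswith("hba_dn_") for s in ids) == 355

    def test_heterozygosity_at_balanced_maf(self, small_panel):
        father, mother = simulate_parents(small_panel, maf=0.5, rng=0)
        dose = father.haplotypes.sum(axis=0)
        het = (dose == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)  # 2p(1-p) at p=1/2

    def test_zero_maf_gives_no_informative_snps(self, small_panel, config):
        father, mother = simulate_parents(small_panel, maf=0.0, rng=0)
        inf = find_informative_snps(
            father.to_sample_array(config), mother.to_sample_array(config),
            config=config,
        )
        assert inf.empty

    def test_expected_informative_count_downstream(self, default_panel, config):
        """At maf 1/2, P(one named parent AB, the other homozygous)
        = 2p(1-p)(p^2+(1-p)^2) = 1/4, so the 355-SNP 3' flank carries
        ~88.75 informative SNPs per parent."""
        counts = []
        for seed in range(20):
            father, mother = simulate_parents(default_panel, maf=0.5, rng=seed)
            inf = find_informative_snps(
                father.to_sample_array(config),
                mother.to_sample_array(config),
                config=config,
            )
            counts.append(
                (
                    (inf["informative_for"] == "mother")
                    & (inf["flank"] == "downstream_3p")
                ).sum()
            )
        # binomial sd per family ~ sqrt(355*0.25*0.75) ~ 8.2; mean of 20 ~ 1.8
        assert np.mean(counts) == pytest.approx(88.75, abs=6.0)

    def test_no_informative_snps_inside_genes(self, clean_family):
        """Carrier parents are hemizygous across the deletion, so in-gene
        SNPs can never satisfy the het/hom informativeness pattern."""
        inf = find_informative_snps(
            clean_family.father_array,
            clean_family.mother_array,
            config=clean_family.config,
        )
        assert (inf["flank"] == "in_gene").sum() == 0


class TestMeiosis:
    def test_zero_intensity_transmits_one_haplotype_intact(self, small_panel, config):
        father, _ = simulate_parents(small_panel, rng=1)
        zero_map = RecombinationMap(
            {c: [(1, 2, 0.0)] for c in ("16", "1")}
        )
        ev = simulate_meiosis(father, zero_map, rng=2)
        for chrom in ("16", "1"):
            assert len(ev.crossovers[chrom]) == 0
            src = ev.source_at(chrom, small_panel.positions[small_panel.chromosome_mask(chrom)])
            assert len(np.unique(src)) == 1

    def test_crossover_counts_are_poisson(self, small_panel):
        """Crossover counts over many meioses follow Poisson(lambda)."""
        father, _ = simulate_parents(small_panel, rng=3)
        lam = 1.5
        rmap = RecombinationMap({"5": [(1, 180_000_000, lam)]})
        rng = np.random.default_rng(4)
        counts = np.array(
            [len(simulate_meiosis(father, rmap, rng).crossovers["5"]) for _ in range(2000)]
        )
        assert counts.mean() == pytest.approx(lam, abs=0.1)
        assert counts.var() == pytest.approx(lam, abs=0.2)  # Poisson: var = mean

    def test_no_crossover_telomeric_of_hba(self, small_panel, config):
        """The default map puts zero intensity between the 16p terminus and
        the locus, so no crossover ever falls in [1, 222845]."""
        father, _ = simulate_parents(small_panel, rng=5)
        rmap = default_recomb_map(config=config)
        rng = np.random.default_rng(6)
        for _ in range(500):
            ev = simulate_meiosis(father, rmap, rng)
            xs = ev.crossovers["16"]
            assert (xs >= config.locus.start).all()


class TestEmbryoRendering:
    def test_double_risk_transmission_renders_nullizygous_locus(
        self, small_panel, config
    ):
        """Find a --/-- embryo: its deletion-interval SNPs carry no allele."""
        father, mother = simulate_parents(small_panel, rng=7)
        for seed in range(40):
            sample, truth = simulate_embryo(
                "e", father, mother, config, noise=NOISELESS, rng=seed
            )
            if truth.true_genotype == "--/--":
                break
        else:
            pytest.fail("no homozygous affected embryo in 40 draws")
        gene = small_panel.interval_mask(config.deletion)
        assert (sample.gtypes[gene] == "NC").all()
        assert np.isnan(sample.baf[gene]).all()

    def test_maternal_mi_trisomy_baf_third(self, small_panel, config):
        """Maternal MI trisomy: at mother-AB / father-AA SNPs the embryo is
        AAB, so the ideal BAF is exactly 1/3."""
        father, mother = simulate_parents(small_panel, rng=8)
        sample, truth = simulate_embryo(
            "e",
            father,
            mother,
            config,
            aneuploidy=AneuploidySpec("trisomy", "16", "mother", "MI"),
            noise=NOISELESS,
            rng=9,
        )
        m16 = small_panel.chromosome_mask("16")
        mo_het = mother.haplotypes[0] != mother.haplotypes[1]
        fa_aa = father.haplotypes.sum(axis=0) == 0
        sel = m16 & mo_het & fa_aa & ~small_panel.interval_mask(config.deletion)
        assert sel.sum() > 10
        np.testing.assert_allclose(sample.baf[sel], 1 / 3)

    def test_maternal_mii_trisomy_baf_never_third(self, small_panel, config):
        """MII duplicates a single chromatid: at the same SNP class the BAF is
        0 or 2/3, never 1/3."""
        father, mother = simulate_parents(small_panel, rng=8)
        sample, _ = simulate_embryo(
            "e",
            father,
            mother,
            config,
            aneuploidy=AneuploidySpec("trisomy", "16", "mother", "MII"),
            noise=NOISELESS,
            recomb_map=RecombinationMap({"16": [(1, 2, 0.0)]}),
            rng=10,
        )
        m16 = small_panel.chromosome_mask("16")
        mo_het = mother.haplotypes[0] != mother.haplotypes[1]
        fa_aa = father.haplotypes.sum(axis=0) == 0
        sel = m16 & mo_het & fa_aa & ~small_panel.interval_mask(config.deletion)
        baf = sample.baf[sel]
        assert set(np.round(baf, 6)) <= {0.0, round(2 / 3, 6)}

    def test_monosomy_lrr_and_baf(self, small_panel, config):
        father, mother = simulate_parents(small_panel, rng=11)
        sample, truth = simulate_embryo(
            "e",
            father,
            mother,
            config,
            aneuploidy=AneuploidySpec("monosomy", "16", "mother"),
            noise=NOISELESS,
            rng=12,
        )
        m16 = small_panel.chromosome_mask("16") & ~small_panel.interval_mask(
            config.deletion
        )
        np.testing.assert_allclose(sample.lrr[m16], -1.0)
        assert set(np.round(sample.baf[m16], 6)) <= {0.0, 1.0}
        assert truth.true_genotype in ("αα", "--")

    def test_trisomy_without_stage_rejected(self):
        with pytest.raises(DomainError):
            AneuploidySpec("trisomy", "16", "mother")


class TestFamilyLevelProperties:
    def test_mendelian_consistency_noise_free(self, clean_family):
        """Every noiseless euploid embryo genotype is compatible with the
        parents at every SNP outside the deletion interval."""
        sim = clean_family
        fa = sim.father_array.b_dose
        mo = sim.mother_array.b_dose
        outside = ~sim.panel.interval_mask(sim.config.deletion)
        for e in sim.embryos:
            eb = e.b_dose
            called = (eb >= 0) & outside & (fa >= 0) & (mo >= 0)
            # embryo B dose must be achievable as one allele from each parent
            fa_can = {0: [0], 1: [0, 1], 2: [1]}
            ok = np.zeros(len(eb), dtype=bool)
            for fd in (0, 1, 2):
                for md in (0, 1, 2):
                    m = called & (fa == fd) & (mo == md)
                    if not m.any():
                        continue
                    achievable = {a + b for a in fa_can[fd] for b in fa_can[md]}
                    ok[m] = np.isin(eb[m], list(achievable))
            assert ok[called].all()

    def test_genotype_ratio_one_two_one(self, small_panel):
        """Carrier x carrier embryos segregate --/-- : --/αα : αα/αα at
        1:2:1 (binomial check at n=400 here; the acceptance suite runs
        n=2,000)."""
        n = 400
        sim = simulate_family(
            n_embryos=n, noise=NOISELESS, seed=21, panel=small_panel
        )
        counts = {"--/--": 0, "--/αα": 0, "αα/αα": 0}
        for t in sim.truths:
            counts[t.true_genotype] += 1
        for geno, p in (("--/--", 0.25), ("--/αα", 0.5), ("αα/αα", 0.25)):
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(counts[geno] - n * p) < 3 * sd

    def test_determinism_same_seed_identical(self, small_panel):
        a = simulate_family(n_embryos=3, seed=33, panel=small_panel)
        b = simulate_family(n_embryos=3, seed=33, panel=small_panel)
        for ea, eb in zip(a.embryos, b.embryos):
            assert ea.data.equals(eb.data)
        for ta, tb in zip(a.truths, b.truths):
            assert ta.true_genotype == tb.true_genotype
        assert {k: [(p.size_bp, p.height) for p in v] for k, v in a.peaks.items()} == {
            k: [(p.size_bp, p.height) for p in v] for k, v in b.peaks.items()
        }

    def test_truth_retention_recomputable(self, clean_family):
        """With noise off, the rendered PCR peak set is recomputable from the
        truth record's copy composition."""
        from alphapgt import simulate_gap_pcr

        for t in clean_family.truths:
            peaks = simulate_gap_pcr(t, NOISELESS, rng=0)
            sizes = {p.size_bp for p in peaks}
            expected = set()
            if t.n_normal_copies:
                expected.add(280)
            if t.n_deletion_copies:
                expected.add(178)
            assert sizes == expected

    def test_noise_model_validation(self):
        with pytest.raises(DomainError):
            NoiseModel(ado_rate=1.5)
        with pytest.raises(DomainError):
            NoiseModel(baf_sd=-0.1)
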