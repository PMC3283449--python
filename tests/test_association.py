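"""Dosage-based multi-allelic association, allele-ratio odds ratios,
codon translation and synonymous collapsing."""

import math

import numpy as np
import pandas as pd
import pytest

from diploseq.association import (
    CdsModel,
    allele_ratio_or,
    collapse_dosages,
    collapse_synonymous,
    expected_dosages,
    multiallelic_test,
    translate_allele,
)
from diploseq.core import Diplotype, GeneAllele, SnpLocus
from diploseq.simulate import SimulationConfig, simulate_case_control, simulate_pool

A1 = GeneAllele("A*1", (0,))
A2 = GeneAllele("A*2", (1,))


class TestExpectedDosages:
    def test_hard_call_point_mass(self):
        d = expected_dosages([Diplotype(A1, A2)], ["A*1", "A*2"])
        assert d.iloc[0].tolist() == [1.0, 1.0]

    def test_uncertain_call_mixes(self):
        dist = {("A*1", "A*1"): 0.5, ("A*1", "A*2"): 0.5}
        d = expected_dosages([dist], ["A*1", "A*2"])
        assert d.iloc[0]["A*1"] == pytest.approx(1.5)
        assert d.iloc[0]["A*2"] == pytest.approx(0.5)

    def test_dosages_sum_to_two(self, rng):
        dists = []
        for _ in range(20):
            w = rng.dirichlet(np.ones(3))
            dists.append(
                {
                    ("A*1", "A*1"): w[0],
                    ("A*1", "A*2"): w[1],
                    ("A*2", "A*2"): w[2],
                }
            )
        d = expected_dosages(dists, ["A*1", "A*2"])
        assert np.allclose(d.sum(axis=1), 2.0)


class TestMultiallelicTest:
    def _null_data(self, rng, n=400):
        counts = rng.multinomial(2, [0.5, 0.3, 0.2], size=n)
        dosages = pd.DataFrame(counts, columns=["G*1", "G*2", "G*3"])
        y = np.repeat([0, 1], n // 2)
        return dosages, y

    def test_null_has_small_coefficients(self, rng):
        dosages, y = self._null_data(rng)
        results = multiallelic_test(dosages, y)
        tested = [r for r in results if r.tested and not r.reference]
        assert tested
        for r in tested:
            assert abs(r.coef) < 3 * r.se
            assert r.or_ == pytest.approx(math.exp(r.coef))
            assert r.ci[0] < r.or_ < r.ci[1]

    def test_reference_defaults_to_most_frequent(self, rng):
        dosages, y = self._null_data(rng)
        results = multiallelic_test(dosages, y)
        assert results[0].reference and results[0].allele == "G*1"
        assert results[0].or_ == 1.0

    def test_rare_allele_untested(self):
        n = 1000
        rng = np.random.default_rng(0)
        counts = rng.multinomial(2, [0.6, 0.395, 0.005], size=n)
        dosages = pd.DataFrame(counts, columns=["G*1", "G*2", "G*3"])
        y = np.repeat([0, 1], n // 2)
        results = multiallelic_test(dosages, y, floor=0.01)
        rare = [r for r in results if r.allele == "G*3"][0]
        assert rare.tested is False
        assert rare.coef is None and rare.p is None

    def test_recovers_simulated_effect(self):
        cfg = SimulationConfig(
            n_alleles=4, n_gene_snps=3, n_flank_snps=3,
            allele_freqs=[0.4, 0.3, 0.2, 0.1], seed=11,
        )
        pool = simulate_pool(cfg)
        cc = simulate_case_control(pool, {"GENE1*2": 0.3}, 2000, 3000, 99)
        dosages = expected_dosages(
            cc.diplotypes, [a.label for a in pool.alleles]
        )
        results = multiallelic_test(dosages, cc.phenotypes)
        hit = [r for r in results if r.allele == "GENE1*2"][0]
        assert hit.ci[0] < math.exp(0.3) < hit.ci[1]
        assert hit.p < 0.05


class TestAlleleRatioOr:
    def test_printed_frequency_worked_examples(self):
        # amino-acid allele vs reference from case/control frequencies
        assert allele_ratio_or(0.365, 0.616, 0.336, 0.647) == pytest.approx(
            1.14, abs=0.005
        )
        # genomic allele *5 vs reference *3
        assert allele_ratio_or(0.018, 0.364, 0.015, 0.336) == pytest.approx(
            1.1, abs=0.05
        )

    def test_equal_frequencies_give_unity(self):
        assert allele_ratio_or(0.3, 0.5, 0.3, 0.5) == pytest.approx(1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            allele_ratio_or(0.3, 0.0, 0.3, 0.5)


TOY_REF = "ATGGAAAAA"  # M E K
TOY_CDS = CdsModel(chrom="1", strand="+", exons=((1, 9),))


def _locus(pos, ref, alt):
    return SnpLocus(f"rs{pos}", "1", pos, ref, alt)


class TestTranslateAllele:
    def test_reference_allele_gives_reference_protein(self):
        loci = [_locus(4, "G", "A")]
        assert translate_allele(GeneAllele("G*1", (0,)), loci, TOY_CDS, TOY_REF) == "MEK"

    def test_missense_substitution(self):
        loci = [_locus(4, "G", "A")]
        # GAA -> AAA is an E2K substitution
        assert translate_allele(GeneAllele("G*2", (1,)), loci, TOY_CDS, TOY_REF) == "MKK"

    def test_synonymous_variants_share_protein(self):
        loci = [_locus(6, "A", "G")]  # GAA -> GAG, both glutamate
        p_ref = translate_allele(GeneAllele("G*1", (0,)), loci, TOY_CDS, TOY_REF)
        p_syn = translate_allele(GeneAllele("G*2", (1,)), loci, TOY_CDS, TOY_REF)
        assert p_ref == p_syn == "MEK"

    def test_minus_strand(self):
        # reverse complement of ATGGAAAAA is TTTTTCCAT; put it on the
        # genome so the minus-strand CDS reads ATGGAAAAA
        ref = "TTTTTCCAT"
        cds = CdsModel(chrom="1", strand="-", exons=((1, 9),))
        assert translate_allele(GeneAllele("G*1", ()), [], cds, ref) == "MEK"
        # genomic C>T at pos 6 complements to G>A at CDS position 4 (E2K)
        loci = [_locus(6, "C", "T")]
        assert translate_allele(GeneAllele("G*2", (1,)), loci, cds, ref) == "MKK"

    def test_variant_outside_cds_ignored(self, caplog):
        loci = [_locus(50, "G", "A")]
        with caplog.at_level("WARNING"):
            protein = translate_allele(
                GeneAllele("G*2", (1,)), loci, TOY_CDS, TOY_REF
            )
        assert protein == "MEK"
        assert "outside the CDS" in caplog.text

    def test_frame_violation_raises(self):
        cds = CdsModel(chrom="1", strand="+", exons=((1, 8),))
        with pytest.raises(ValueError, match="frame"):
            translate_allele(GeneAllele("G*1", (0,)), [_locus(4, "G", "A")], cds, TOY_REF)

    def test_stop_codon_retained(self):
        ref = "ATGTAAAAA"
        assert translate_allele(GeneAllele("G*1", ()), [], TOY_CDS, ref) == "M*K"


class TestCollapseSynonymous:
    FREQS = {
        "control": {"G*1": 0.5, "G*2": 0.3, "G*3": 0.2},
        "case": {"G*1": 0.45, "G*2": 0.35, "G*3": 0.2},
    }

    def test_grouping_and_frequency_sums(self):
        translations = {"G*1": "MEK", "G*2": "MKK", "G*3": "MKK"}
        aa = collapse_synonymous("G", self.FREQS, translations)
        assert len(aa) == 2
        by_protein = {a.protein: a for a in aa}
        assert by_protein["MKK"].frequencies["control"] == pytest.approx(0.5)
        assert by_protein["MKK"].frequencies["case"] == pytest.approx(0.55)
        # ranked by control frequency: both groups at 0.5, tie on protein
        assert {a.label for a in aa} == {"G*aa*1", "G*aa*2"}
        for group in ("control", "case"):
            assert sum(a.frequencies[group] for a in aa) == pytest.approx(1.0)

    def test_all_distinct_is_identity(self):
        translations = {"G*1": "MEK", "G*2": "MKK", "G*3": "MNK"}
        aa = collapse_synonymous("G", self.FREQS, translations)
        assert len(aa) == 3
        assert aa[0].members == ("G*1",)  # most frequent in controls

    def test_collapsed_dosages_sum_to_two(self, rng):
        translations = {"G*1": "MEK", "G*2": "MKK", "G*3": "MKK"}
        aa = collapse_synonymous("G", self.FREQS, translations)
        counts = rng.multinomial(2, [0.5, 0.3, 0.2], size=25)
        dosages = pd.DataFrame(counts, columns=["G*1", "G*2", "G*3"])
        collapsed = collapse_dosages(dosages, aa)
        assert np.allclose(collapsed.sum(axis=1), 2.0)


class TestPowerIncrease:
    def test_collapsing_shared_causal_protein_increases_z(self):
        """When two DNA alleles encode one causal protein, testing the
        collapsed amino-acid allele concentrates the signal: its |Z| should
        beat the best single-allele |Z| in most replicates."""
        cfg = SimulationConfig(
            n_alleles=3, n_gene_snps=3, n_flank_snps=3,
            allele_freqs=[0.5, 0.25, 0.25], seed=21,
        )
        pool = simulate_pool(cfg)
        labels = [a.label for a in pool.alleles]
        effects = {"GENE1*2": 0.3, "GENE1*3": 0.3}  # shared causal protein
        translations = {"GENE1*1": "MEK", "GENE1*2": "MKK", "GENE1*3": "MKK"}
        wins = 0
        n_reps = 25
        for rep in range(n_reps):
            cc = simulate_case_control(pool, effects, 600, 900, 1000 + rep)
            dosages = expected_dosages(cc.diplotypes, labels)
            single = multiallelic_test(dosages, cc.phenotypes, reference="GENE1*1")
            z_single = max(
                abs(r.z) for r in single if r.z is not None and not r.reference
            )
            freqs = {
                "control": {l: 1 / 3 for l in labels},
                "case": {l: 1 / 3 for l in labels},
            }
            aa = collapse_synonymous("GENE1", freqs, translations)
            collapsed = collapse_dosages(dosages, aa)
            ref_label = [a.label for a in aa if a.protein == "MEK"][0]
            merged = multiallelic_test(
                collapsed, cc.phenotypes, reference=ref_label
            )
            z_merged = max(
                abs(r.z) for r in merged if r.z is not None and not r.reference
            )
            wins += z_merged >= z_single
        assert wins >= 0.8 * n_reps
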