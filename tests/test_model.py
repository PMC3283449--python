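"""Joint model building: objective Q, candidate windows, forward-backward
tag-SNP selection, flank scan rescaling and train/validation splitting."""

import itertools
import math

import numpy as np
import pytest
from sklearn.base import clone

from diploseq.core import (
    Diplotype,
    FrequencyTable,
    GeneAllele,
    GeneSnpHaplotype,
    GenotypeMatrix,
    SnpLocus,
)
from diploseq.model import (
    BuildConfig,
    GeneAllelePredictor,
    PredictionModel,
    _diplotypes_to_idx,
    _fit_joint,
    _q_value,
    candidate_window,
    flank_scan,
    forward_backward_select,
    objective_q,
    rescale_objectives,
    split_train_validation,
)

from conftest import make_loci

A1 = GeneAllele("G*1", (0,))
A2 = GeneAllele("G*2", (1,))


def perfect_model(snp_loci=None):
    """1-SNP model where the tag SNP deterministically encodes the allele."""
    entries = {
        GeneSnpHaplotype(A1, (0,)): 0.5,
        GeneSnpHaplotype(A2, (1,)): 0.5,
    }
    return PredictionModel(
        gene_name="G",
        selected_snps=tuple(snp_loci or make_loci(1)),
        joint_freqs=FrequencyTable(entries),
        allele_dictionary={"G*1": (0,), "G*2": (1,)},
    )


class TestObjectiveQ:
    def test_perfect_prediction_no_extra_parameters(self):
        model = perfect_model()
        diplotypes = [Diplotype(A1, A2), Diplotype(A1, A1)]
        G = np.array([[1], [0]])
        # f(h|g) = 1 for both subjects and m = k = 2
        assert objective_q(model, diplotypes, G) == pytest.approx(0.0, abs=1e-12)

    def test_half_posterior_with_two_extra_parameters(self):
        # gene and SNP independent: m = 4 joint haplotypes, k = 2 alleles
        entries = {
            GeneSnpHaplotype(A1, (0,)): 0.25,
            GeneSnpHaplotype(A1, (1,)): 0.25,
            GeneSnpHaplotype(A2, (0,)): 0.25,
            GeneSnpHaplotype(A2, (1,)): 0.25,
        }
        model = PredictionModel(
            gene_name="G",
            selected_snps=tuple(make_loci(1)),
            joint_freqs=FrequencyTable(entries),
            allele_dictionary={"G*1": (0,), "G*2": (1,)},
        )
        diplotypes = [Diplotype(A1, A2), Diplotype(A1, A2)]
        G = np.array([[1], [1]])
        assert objective_q(model, diplotypes, G) == pytest.approx(
            2 * math.log(2) + 2
        )

    def test_inconsistent_training_subject_raises(self):
        model = perfect_model()
        with pytest.raises(ValueError, match="inconsistent"):
            # hom-alt SNP genotype with a hom-G*1 diplotype has no support
            objective_q(model, [Diplotype(A1, A1)], np.array([[2]]))


class TestCandidateWindow:
    def test_window_and_ordering(self):
        catalog = [
            SnpLocus(f"rs{p}", "1", p, "A", "G") for p in (60, 150, 240, 260)
        ]
        window = candidate_window(("1", 100, 200), 50, catalog)
        assert [l.pos for l in window] == [150, 60, 240]

    def test_zero_flank_is_intragenic_only(self):
        catalog = [
            SnpLocus(f"rs{p}", "1", p, "A", "G") for p in (60, 150, 240)
        ]
        window = candidate_window(("1", 100, 200), 0, catalog)
        assert [l.pos for l in window] == [150]

    def test_large_flank_covers_catalog(self):
        catalog = [
            SnpLocus(f"rs{p}", "1", p, "A", "G") for p in (60, 150, 240)
        ]
        window = candidate_window(("1", 100, 200), 10_000, catalog)
        assert len(window) == 3

    def test_other_chromosome_excluded(self):
        catalog = [SnpLocus("rsX", "2", 150, "A", "G")]
        assert candidate_window(("1", 100, 200), 500, catalog) == []


def _tagging_cohort(n=80, seed=0):
    """2-allele gene; SNP 0 tags the allele deterministically, SNP 1 is
    independent noise."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2, size=(n, 2))  # allele indices per chromosome
    noise = rng.integers(0, 2, size=(n, 2))
    alleles = [A1, A2]
    diplotypes = [Diplotype(alleles[a], alleles[b]) for a, b in draws]
    codes = np.column_stack([draws.sum(axis=1), noise.sum(axis=1)])
    loci = make_loci(2)
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], list(loci), codes)
    return diplotypes, gm


class TestForwardBackwardSelect:
    def test_selects_only_the_tagging_snp(self):
        diplotypes, gm = _tagging_cohort()
        model = forward_backward_select(diplotypes, gm, gm.loci)
        assert [l.id for l in model.selected_snps] == ["rs1"]

    def test_greedy_matches_exhaustive_subset_search(self):
        """With <= 4 candidates the greedy Q can be compared against every
        subset; on the perfect-tagging fixture they agree."""
        diplotypes, gm = _tagging_cohort()
        cfg = BuildConfig()
        model = forward_backward_select(diplotypes, gm, gm.loci, cfg)
        greedy_q = model.training_meta["q"]

        labels = ["G*1", "G*2"]
        y_idx = _diplotypes_to_idx(diplotypes, labels)
        best = math.inf
        for r in range(len(gm.loci) + 1):
            for subset in itertools.combinations(range(gm.n_loci), r):
                Gs = gm.codes[:, list(subset)].astype(np.int64)
                fit = _fit_joint(y_idx, Gs, 2, cfg)
                best = min(best, _q_value(fit, y_idx, Gs, 2))
        assert greedy_q >= best - 1e-9
        assert greedy_q == pytest.approx(best, abs=1e-6)

    def test_zero_information_candidates_select_nothing(self):
        rng = np.random.default_rng(1)
        n = 60
        draws = rng.integers(0, 2, size=(n, 2))
        alleles = [A1, A2]
        diplotypes = [Diplotype(alleles[a], alleles[b]) for a, b in draws]
        codes = rng.integers(0, 2, size=(n, 2, 3)).sum(axis=1)  # independent
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], list(make_loci(3)), codes
        )
        model = forward_backward_select(diplotypes, gm, gm.loci)
        assert model.selected_snps == ()

    def test_no_candidates_gives_prior_only_model(self):
        diplotypes, gm = _tagging_cohort()
        model = forward_backward_select(diplotypes, gm, [])
        assert model.selected_snps == ()
        assert set(model.allele_dictionary) == {"G*1", "G*2"}

    def test_q_trace_strictly_decreasing(self):
        diplotypes, gm = _tagging_cohort()
        model = forward_backward_select(diplotypes, gm, gm.loci)
        trace = model.training_meta["q_trace"]
        assert all(b < a for a, b in zip(trace, trace[1:]))


class TestFlankScan:
    @pytest.mark.parametrize(
        "objectives, expected",
        [
            ((10, 5, 0), [1.0, 0.5, 0.0]),
            ((3, 3, 3), [0.0, 0.0, 0.0]),  # constant series convention
            ((9, 6, 3, 0), [1.0, 2 / 3, 1 / 3, 0.0]),
        ],
    )
    def test_rescaling(self, objectives, expected):
        assert rescale_objectives(objectives) == pytest.approx(expected)

    def test_scan_runs_one_selection_per_size(self):
        diplotypes, gm = _tagging_cohort(n=40)
        # loci at pos 1,2; gene interval covering pos 1 only at flank 0
        result = flank_scan(
            ("1", 1, 1), diplotypes, gm, sizes=[0, 1], gene_name="G"
        )
        assert len(result.objectives) == 2
        assert min(result.rescaled) == 0.0
        # more candidates can only improve (or match) the objective
        assert result.objectives[1] <= result.objectives[0] + 1e-9


class TestSplitTrainValidation:
    def test_even_split(self):
        train, val = split_train_validation(["p"] * 10, seed=1)
        assert len(train) == len(val) == 5
        assert sorted(list(train) + list(val)) == list(range(10))

    def test_odd_count_extra_goes_to_training(self):
        train, val = split_train_validation(["p"] * 11, seed=1)
        assert len(train) == 6 and len(val) == 5

    def test_reproducible_and_stratified(self):
        pops = ["a"] * 6 + ["b"] * 7
        t1, v1 = split_train_validation(pops, seed=42)
        t2, v2 = split_train_validation(pops, seed=42)
        assert t1.tolist() == t2.tolist() and v1.tolist() == v2.tolist()
        assert sum(1 for i in t1 if i < 6) == 3  # half of population a
        assert sum(1 for i in t1 if i >= 6) == 4  # ceil half of population b
        t3, _ = split_train_validation(pops, seed=43)
        assert t1.tolist() != t3.tolist()


class TestGeneAllelePredictor:
    def test_fit_predict_score(self):
        diplotypes, gm = _tagging_cohort(n=100)
        est = GeneAllelePredictor(gene_name="G")
        est.fit(gm.codes, diplotypes)
        assert est.selected_indices_ == [0]
        assert est.q_trace_ == sorted(est.q_trace_, reverse=True)
        assert est.score(gm.codes, diplotypes) == pytest.approx(1.0)

    def test_clone_preserves_params(self):
        est = GeneAllelePredictor(call_threshold=0.5, max_snps=7)
        params = clone(est).get_params()
        assert params["call_threshold"] == 0.5 and params["max_snps"] == 7
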