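"""Counting, log-enrichment scores, permutation tests, q-values, classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from immunopep import (
    AACounts,
    AA_CLASSES,
    PeptideRecord,
    PeptideSet,
    RecordError,
    SourceProtein,
    background_frequencies,
    class_analysis,
    compute_enrichment,
    count_nonanchor_aa,
    permutation_test,
    property_correlation,
    qvalues,
)
from immunopep.alphabet import AMINO_ACIDS
from immunopep.enrichment import class_count

counts_strategy = st.lists(st.integers(1, 50), min_size=20, max_size=20)


def _set(*seq_allele):
    return PeptideSet(tuple(PeptideRecord(s, a) for s, a in seq_allele))


class TestCounting:
    def test_single_homopolymer_default_mask(self, masks):
        counts = count_nonanchor_aa(_set(("AAAAAAAAA", "HLA-A*02:01")), masks)
        assert counts["A"] == 6
        assert counts.total == 6

    def test_empty_set_gives_zero_counts(self, masks):
        counts = count_nonanchor_aa(PeptideSet(()), masks)
        assert counts.total == 0

    def test_each_peptide_contributes_six_residues(self, masks):
        pset = _set(
            ("SLFNTVATL", "HLA-A*02:01"),
            ("GILGFVFTL", "HLA-A*02:01"),
            ("AAKARAAAA", "HLA-B*08:01"),
        )
        assert count_nonanchor_aa(pset, masks).total == 6 * 3

    def test_b0801_masks_p2_p5_p9(self, masks):
        # P2 = W, P5 = W, P9 = W are anchors for B*08:01 and must not count
        counts = count_nonanchor_aa(_set(("AWAAWAAAW", "HLA-B*0801")), masks)
        assert counts["W"] == 0
        assert counts["A"] == 6

    def test_non_9mers_rejected(self, masks):
        with pytest.raises(RecordError, match="9mer"):
            count_nonanchor_aa(_set(("AAAAAAAAAA", "HLA-A*02:01")), masks)


class TestBackground:
    def test_two_letter_protein(self):
        bg = background_frequencies([SourceProtein("p", "AC")])
        assert bg[0] == 0.5 and bg[1] == 0.5

    def test_x_excluded_from_both_sides(self):
        bg = background_frequencies([SourceProtein("p", "AXA")])
        assert bg[0] == 1.0

    def test_concatenation_invariance(self):
        p1, p2 = "MKVLAWY", "GGGPQR"
        split = background_frequencies(
            [SourceProtein("a", p1), SourceProtein("b", p2)]
        )
        joined = background_frequencies([SourceProtein("ab", p1 + p2)])
        assert np.allclose(split, joined)

    def test_no_countable_residues_rejected(self):
        with pytest.raises(RecordError):
            background_frequencies([SourceProtein("p", "XXX")])


class TestComputeEnrichment:
    def test_direct_formula_log2(self):
        # A: 4/100 vs 2/100 with no pseudocount -> E(A) = ln 2
        other = {aa: 5 for aa in AMINO_ACIDS if aa != "A"}
        imm = AACounts.from_dict({**other, "A": 4, "C": 6})  # total 100
        non = AACounts.from_dict({**other, "A": 2, "C": 8})  # total 100
        table = compute_enrichment(imm, non, pseudocount=0)
        assert math.isclose(table["A"], math.log(2), rel_tol=1e-12)

    def test_tyrosine_like_worked_example(self):
        # frequencies 2.5% vs 1.5% -> about 1.7-fold, log enrichment ~ 0.51
        assert math.isclose(math.log(2.5 / 1.5), 0.5108, abs_tol=5e-4)
        assert round(math.log(1.7), 2) == 0.53

    def test_identical_counts_give_zero_scores(self):
        c = AACounts.from_dict({aa: 3 for aa in AMINO_ACIDS})
        table = compute_enrichment(c, c)
        assert np.allclose(table.as_array(), 0.0)

    def test_zero_count_without_pseudocount_names_residue(self):
        imm = AACounts.from_dict({aa: 5 for aa in AMINO_ACIDS})
        non = AACounts.from_dict({**{aa: 5 for aa in AMINO_ACIDS}, "W": 0})
        with pytest.raises(RecordError, match="W"):
            compute_enrichment(imm, non, pseudocount=0)

    def test_auto_pseudocount_keeps_scores_finite(self):
        imm = AACounts.from_dict({**{aa: 5 for aa in AMINO_ACIDS}, "W": 0})
        non = AACounts.from_dict({aa: 5 for aa in AMINO_ACIDS})
        table = compute_enrichment(imm, non)
        assert table.pseudocount == 0.5
        assert np.all(np.isfinite(table.as_array()))

    @settings(deadline=None, max_examples=30)
    @given(imm=counts_strategy, non=counts_strategy)
    def test_antisymmetry(self, imm, non):
        """Swapping the classes negates every log-enrichment score."""
        a, b = AACounts(tuple(imm)), AACounts(tuple(non))
        fwd = compute_enrichment(a, b, pseudocount=0.5).as_array()
        rev = compute_enrichment(b, a, pseudocount=0.5).as_array()
        assert np.allclose(fwd, -rev, atol=1e-12)


class TestPermutationTest:
    def test_zero_observed_difference_gives_p_one(self):
        c = AACounts.from_dict({aa: 10 for aa in AMINO_ACIDS})
        bg = np.full(20, 1 / 20)
        p = permutation_test("A", c, c, bg, n_perm=500, seed=0)
        assert p == 1.0

    def test_reproducible_given_seed(self):
        imm = AACounts.from_dict({**{aa: 10 for aa in AMINO_ACIDS}, "F": 40})
        non = AACounts.from_dict({aa: 10 for aa in AMINO_ACIDS})
        bg = np.full(20, 1 / 20)
        p1 = permutation_test("F", imm, non, bg, n_perm=2000, seed=7)
        p2 = permutation_test("F", imm, non, bg, n_perm=2000, seed=7)
        assert p1 == p2

    def test_matches_exhaustive_enumeration_on_tiny_case(self):
        """Totals 2 and 2 on a two-letter alphabet: the Monte-Carlo p must
        agree with the exact enumeration over all multinomial draws."""
        imm = AACounts.from_dict({"A": 2})
        non = AACounts.from_dict({"C": 2})
        q = 0.3  # background probability of A
        bg = np.zeros(20)
        bg[0], bg[1] = q, 1 - q
        observed = abs(2 / 2 - 0 / 2)
        exact = 0.0
        for k_imm in range(3):
            for k_non in range(3):
                if abs(k_imm / 2 - k_non / 2) >= observed:
                    exact += (
                        stats.binom.pmf(k_imm, 2, q) * stats.binom.pmf(k_non, 2, q)
                    )
        p = permutation_test("A", imm, non, bg, n_perm=100_000, seed=3)
        assert math.isclose(p, exact, abs_tol=5e-3)

    def test_uniform_under_null(self):
        """p-values are ~uniform when both classes are background draws.

        Totals are coprime (study-scale 1847/809): with commensurable
        totals the folded |difference| statistic collapses onto a coarse
        lattice whose atoms make the discrete p conservative enough to
        fail a KS check even though the test is valid."""
        rng = np.random.default_rng(11)
        bg = np.full(20, 1 / 20)
        pvals = []
        for rep in range(200):
            imm = AACounts(tuple(rng.multinomial(1847, bg)))
            non = AACounts(tuple(rng.multinomial(809, bg)))
            pvals.append(
                permutation_test("F", imm, non, bg, n_perm=2000, seed=1000 + rep)
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestQValues:
    def test_all_ones_stay_ones(self):
        assert np.all(qvalues([1.0, 1.0, 1.0], "storey") == 1.0)

    def test_single_p(self):
        assert qvalues([0.03], "bh")[0] == pytest.approx(0.03)
        assert qvalues([0.03], "storey")[0] <= 0.03

    def test_bh_hand_computation(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_p(self):
        p = [0.001, 0.2, 0.5, 0.9]
        q = qvalues(p, "bh")
        assert np.all(np.diff(q) >= 0)

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(RecordError):
            qvalues(bad)


class TestClassAnalysis:
    def test_identical_sets_give_unit_enrichment(self):
        c = AACounts.from_dict({aa: 7 for aa in AMINO_ACIDS})
        for result in class_analysis(c, c):
            assert result.enrichment == pytest.approx(1.0)
            assert result.p_value == pytest.approx(1.0)

    def test_class_counts_are_member_sums(self):
        rng = np.random.default_rng(5)
        counts = AACounts(tuple(rng.integers(0, 30, size=20)))
        for cdef in AA_CLASSES.values():
            assert class_count(counts, cdef.members) == sum(
                counts[aa] for aa in cdef.members
            )

    def test_zero_class_count_in_non_set_reported_undefined(self):
        imm = AACounts.from_dict({aa: 5 for aa in AMINO_ACIDS})
        non = AACounts.from_dict(
            {aa: (0 if aa in "DE" else 5) for aa in AMINO_ACIDS}
        )
        acidic = next(
            r for r in class_analysis(imm, non) if r.name == "acidic"
        )
        assert acidic.enrichment is None


class TestPropertyCorrelation:
    def _table(self):
        imm = AACounts.from_dict({aa: 5 + i for i, aa in enumerate(AMINO_ACIDS)})
        non = AACounts.from_dict({aa: 25 - i for i, aa in enumerate(AMINO_ACIDS)})
        return compute_enrichment(imm, non, pseudocount=0)

    def test_self_correlation_is_one(self):
        table = self._table()
        rho, _ = property_correlation(table, table.as_array())
        assert rho == pytest.approx(1.0)
        rho_neg, _ = property_correlation(table, -table.as_array())
        assert rho_neg == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        """Tie-free case must match 1 - 6*sum(d^2)/(n(n^2-1)) exactly."""
        table = self._table()
        rng = np.random.default_rng(9)
        prop = rng.permutation(np.arange(20, dtype=float))
        rho, _ = property_correlation(table, prop)
        rank_e = stats.rankdata(table.as_array())
        rank_p = stats.rankdata(prop)
        d2 = np.sum((rank_e - rank_p) ** 2)
        assert rho == pytest.approx(1 - 6 * d2 / (20 * (400 - 1)))

    def test_constant_property_rejected(self):
        with pytest.raises(RecordError):
            property_correlation(self._table(), np.ones(20))

    def test_accepts_mapping_input(self):
        table = self._table()
        rho, _ = property_correlation(
            table, {aa: float(i) for i, aa in enumerate(AMINO_ACIDS)}
        )
        assert -1 <= rho <= 1
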