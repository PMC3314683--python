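"""Independence testing, coding-SNP classification, summary arithmetic."""

import numpy as np
import pytest

from ploidykit.haplotypes import HaplotypeResolution
from ploidykit.io import Assembly, Contig, OrfModel, PloidykitError, revcomp
from ploidykit.pileup import SnpSite
from ploidykit.stats import (STANDARD_CODE, CegAccounting, ContingencyTable,
                             VerdictParams, annotation_fractions,
                             ceg_completeness, classify_coding_snps,
                             collapse_low_density, contingency_table,
                             pearson_independence, ploidy_verdict)


def _resolution(cls, n, orf_id="o", sister=99.0, div=95.0):
    idents = {}
    if n == 2:
        idents = {"h1-h2": sister}
    elif n == 3:
        idents = {"h1-h2": sister, "h1-h3": div, "h2-h3": div}
    return HaplotypeResolution(orf_id, cls, n, {}, idents,
                               {f"h{i+1}": 5 for i in range(min(n, 3))})


class TestContingencyTable:
    def test_counts_and_conservation(self):
        res = ([_resolution(0.02, 2, f"a{i}") for i in range(15)]
               + [_resolution(0.02, 3, f"b{i}") for i in range(5)]
               + [_resolution(0.06, 3, f"c{i}") for i in range(18)]
               + [_resolution(0.06, 1, "weird")]
               + [_resolution(0.06, 4, "multi")])
        table = contingency_table(res, [0.02, 0.06])
        assert table.counts.tolist() == [[15, 5], [0, 18]]
        assert table.total == 38                       # 1 and >=4 excluded
        assert table.excluded == {"n=1": 1, "n=4": 1}

    def test_empty_input_rejected(self):
        with pytest.raises(PloidykitError):
            contingency_table([], [0.02, 0.06])

    def test_collapse_pools_higher_classes(self):
        t = ContingencyTable([0.02, 0.04, 0.06], ["2", "3"],
                             np.array([[10, 2], [3, 17], [1, 19]]))
        c = collapse_low_density(t)
        assert c.counts.tolist() == [[10, 2], [4, 36]]


class TestPearsonIndependence:
    def test_no_association_gives_zero(self):
        t = ContingencyTable(["a", "b"], ["x", "y"],
                             np.array([[10, 10], [10, 10]]))
        out = pearson_independence(t)
        assert out.statistic == 0.0
        assert out.p_value == 1.0

    def test_balanced_association_exact_value(self):
        t = ContingencyTable(["a", "b"], ["x", "y"],
                             np.array([[15, 5], [5, 15]]))
        out = pearson_independence(t)
        assert out.statistic == pytest.approx(10.0, abs=1e-12)
        assert out.df == 1
        assert out.p_value == pytest.approx(0.001565, abs=2e-6)
        assert (out.expected == 10.0).all()

    def test_invariance_under_permutation(self, rng):
        counts = rng.integers(1, 30, size=(3, 2))
        t1 = ContingencyTable(list("abc"), list("xy"), counts)
        t2 = ContingencyTable(list("cab"), list("yx"),
                              counts[[2, 0, 1]][:, [1, 0]])
        assert pearson_independence(t1).statistic == pytest.approx(
            pearson_independence(t2).statistic)

    def test_statistic_scales_linearly_with_counts(self, rng):
        counts = rng.integers(1, 20, size=(2, 2))
        x1 = pearson_independence(
            ContingencyTable(list("ab"), list("xy"), counts)).statistic
        x3 = pearson_independence(
            ContingencyTable(list("ab"), list("xy"), counts * 3)).statistic
        assert x3 == pytest.approx(3 * x1)

    def test_zero_row_dropped_with_warning(self):
        t = ContingencyTable(list("abc"), list("xy"),
                             np.array([[8, 9], [0, 0], [9, 8]]))
        out = pearson_independence(t)
        assert out.dropped_rows == ["b"]
        assert out.df == 1

    def test_yates_reduces_statistic(self):
        t = ContingencyTable(list("ab"), list("xy"),
                             np.array([[15, 5], [5, 15]]))
        assert pearson_independence(t, yates=True).statistic < 10.0

    @pytest.mark.parametrize("table_seed", [11, 12, 13])
    def test_p_agrees_with_permutation_null(self, table_seed):
        """Chi-square upper-tail p within +/-0.01 of a 20,000-draw
        permutation null on random 3x2 tables with N = 60 and adequate
        expected counts (>= 5, the classical validity condition the result
        object itself flags via low_expected_warning)."""
        rng = np.random.default_rng(table_seed)
        while True:
            rows = rng.dirichlet([5.0, 5.0, 5.0])
            cols = rng.dirichlet([5.0, 5.0])
            probs = np.outer(rows, cols)
            # induce mild association so p spans a useful range
            probs[0, 0] *= 1.6
            probs /= probs.sum()
            counts = rng.multinomial(60, probs.ravel()).reshape(3, 2)
            expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
            if counts.min() >= 1 and expected.min() >= 5.0:
                break
        table = ContingencyTable(list("abc"), list("xy"), counts)
        out = pearson_independence(table)

        row_labels = np.repeat(np.arange(3), counts.sum(axis=1))
        col_labels = np.repeat(np.arange(2), counts.sum(axis=0).astype(int))
        n_draws, hits = 20_000, 0
        for _ in range(n_draws):
            rng.shuffle(col_labels)
            perm = np.zeros((3, 2))
            np.add.at(perm, (row_labels, col_labels), 1)
            expected = np.outer(perm.sum(1), perm.sum(0)) / perm.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                cells = np.where(expected > 0,
                                 (perm - expected) ** 2 / expected, 0.0)
            hits += cells.sum() >= out.statistic - 1e-9
        assert abs(hits / n_draws - out.p_value) <= 0.01


class TestCodingSnpClassification:
    def _setup(self, orf_seq, strand="+"):
        seq = orf_seq if strand == "+" else revcomp(orf_seq)
        asm = Assembly([Contig("c0", seq, "c0")])
        orf = OrfModel("o1", "c0", 0, len(seq), strand)
        return asm, orf

    def _site(self, pos, ref, alt, cid="c0"):
        return SnpSite(cid, pos, ref, [(alt, 0.33)], 30)

    def test_third_position_lysine_synonymous(self):
        asm, orf = self._setup("AAA" * 3)
        out = classify_coding_snps(orf, asm, [self._site(2, "A", "G")])
        assert (out.n_syn, out.n_nonsyn) == (1, 0)

    def test_first_position_lysine_to_glutamate_nonsynonymous(self):
        asm, orf = self._setup("AAA" * 3)
        out = classify_coding_snps(orf, asm, [self._site(3, "A", "G")])
        assert (out.n_syn, out.n_nonsyn) == (0, 1)

    def test_stop_gained_flagged_nonsynonymous(self):
        asm, orf = self._setup("TACAAA")        # TAC -> TAA is stop
        out = classify_coding_snps(orf, asm, [self._site(2, "C", "A")])
        assert out.n_nonsyn == 1
        assert out.n_stop_gained == 1

    def test_multiallelic_counts_once(self):
        asm, orf = self._setup("AAAAAA")
        site = SnpSite("c0", 0, "A", [("G", 0.3), ("C", 0.3)], 30)
        out = classify_coding_snps(orf, asm, [site])
        assert out.n_coding_sites == 1
        assert out.n_nonsyn == 1
        assert out.n_multiallelic == 1

    def test_minus_strand_equals_revcomp_plus(self, rng):
        """Metamorphic: classifying a minus-strand ORF must match
        classifying its reverse complement as a plus-strand ORF."""
        bases = "ACGT"
        for _ in range(25):
            codons = rng.integers(0, 4, size=(6, 3))
            orf_seq = "".join(bases[b] for row in codons for b in row)
            pos = int(rng.integers(0, 18))
            ref = orf_seq[pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            plus_asm, plus_orf = self._setup(orf_seq, "+")
            plus = classify_coding_snps(plus_orf, plus_asm,
                                        [self._site(pos, ref, alt)])
            minus_asm = Assembly([Contig("c0", revcomp(orf_seq), "c0")])
            minus_orf = OrfModel("o1", "c0", 0, 18, "-")
            mpos = 18 - 1 - pos
            msite = self._site(mpos, revcomp(ref), revcomp(alt))
            minus = classify_coding_snps(minus_orf, minus_asm, [msite])
            assert (plus.n_syn, plus.n_nonsyn) == (minus.n_syn, minus.n_nonsyn)

    def test_counts_match_translate_both_oracle(self, rng):
        """Brute-force oracle: translate the whole ORF with the reference and
        with the minor allele substituted; compare full protein strings."""
        from Bio.Seq import Seq
        bases = "ACGT"
        for _ in range(200):
            n_codons = int(rng.integers(2, 8))
            orf_seq = "".join(bases[b] for b in rng.integers(0, 4, 3 * n_codons))
            pos = int(rng.integers(0, len(orf_seq)))
            ref = orf_seq[pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            asm, orf = self._setup(orf_seq)
            out = classify_coding_snps(orf, asm, [self._site(pos, ref, alt)])
            mutated = orf_seq[:pos] + alt + orf_seq[pos + 1:]
            expected_nonsyn = (Seq(orf_seq).translate() !=
                               Seq(mutated).translate())
            assert out.n_nonsyn == int(expected_nonsyn)
            assert out.n_syn == int(not expected_nonsyn)


class TestSummaryArithmetic:
    def test_ceg_completeness_reference_accounting(self):
        acc = CegAccounting(n_total=248, n_orf_hits=213, n_scaffold_hits=20,
                            n_ortholog_confirmed=11, n_partial=4)
        assert ceg_completeness(acc) == 98

    def test_ceg_extremes(self):
        assert ceg_completeness(CegAccounting(10, 10, 0, 0)) == 100
        assert ceg_completeness(CegAccounting(10, 0, 0, 0)) == 0

    def test_ceg_over_accounting_rejected(self):
        with pytest.raises(PloidykitError):
            CegAccounting(10, 9, 2, 0)

    @pytest.mark.parametrize("orphan,total,expected", [
        (588, 4969, 11.8), (0, 4969, 0.0), (4969, 4969, 100.0),
    ])
    def test_orphan_fraction(self, orphan, total, expected):
        assert annotation_fractions(orphan, total) == expected

    def test_orphan_bounds_checked(self):
        with pytest.raises(PloidykitError):
            annotation_fractions(10, 5)


class TestVerdict:
    def test_triploid_pattern_detected(self):
        res = ([_resolution(0.06, 3, f"t{i}") for i in range(12)]
               + [_resolution(0.02, 2, f"d{i}") for i in range(8)])
        out = ploidy_verdict(res)
        assert out["triploid_hybrid_pattern"] == "yes"
        assert out["three_haplotype_fraction"] == pytest.approx(0.6)

    def test_two_haplotype_only_pattern_rejected(self):
        res = [_resolution(0.02, 2, f"d{i}") for i in range(20)]
        assert ploidy_verdict(res)["triploid_hybrid_pattern"] == "no"

    def test_high_divergent_identity_rejected(self):
        res = [_resolution(0.06, 3, f"t{i}", sister=99.5, div=98.5)
               for i in range(20)]
        assert ploidy_verdict(res)["triploid_hybrid_pattern"] == "no"

    def test_thresholds_echoed(self):
        out = ploidy_verdict([_resolution(0.06, 3)], VerdictParams())
        assert out["thresholds"]["max_divergent_identity"] == 97.0
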