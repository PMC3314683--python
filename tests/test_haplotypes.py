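"""ORF sampling, read phasing, consensus, identity and labelling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ploidykit.haplotypes import (PhaseParams, SamplingParams,
                                  haplotype_consensus, label_haplotypes,
                                  orf_snp_density, pairwise_identity,
                                  phase_orf_reads, resolve_orf,
                                  sample_orfs_by_density)
from ploidykit.io import AlignedRead, Assembly, Contig, OrfModel, PloidykitError
from ploidykit.pileup import SnpSite


def _orf(length=30, cid="c0"):
    return OrfModel("o1", cid, 0, length, "+")


def _reads_from(haplotype: str, n: int, cid="c0", prefix="r", length=None,
                stagger=0):
    length = length or len(haplotype)
    return [AlignedRead(f"{prefix}{i}", cid, (i * stagger) % max(
        1, len(haplotype) - length + 1), "+",
        haplotype[(i * stagger) % max(1, len(haplotype) - length + 1):]
        [:length]) for i in range(n)]


class TestOrfDensity:
    def test_density_is_site_count_over_length(self):
        orf = OrfModel("o", "c0", 0, 999, "+")
        snps = [SnpSite("c0", p, "A", [("G", 0.3)], 20)
                for p in range(0, 999, 50)]  # 20 sites inside
        assert orf_snp_density(orf, snps) == pytest.approx(20 / 999)

    def test_no_sites_zero(self):
        assert orf_snp_density(_orf(), []) == 0.0

    def test_sites_outside_interval_ignored(self):
        orf = OrfModel("o", "c0", 100, 199, "+")
        snps = [SnpSite("c0", 50, "A", [("G", 0.3)], 20),
                SnpSite("c0", 150, "A", [("G", 0.3)], 20),
                SnpSite("c1", 150, "A", [("G", 0.3)], 20)]
        assert orf_snp_density(orf, snps) == pytest.approx(1 / 99)


class TestSampling:
    def _orfs(self, densities):
        orfs = [OrfModel(f"o{i:03d}", "c0", i * 1000, i * 1000 + 999, "+")
                for i in range(len(densities))]
        return orfs, {o.id: d for o, d in zip(orfs, densities)}

    def test_exact_supply_selects_all(self):
        orfs, dens = self._orfs([0.02] * 20)
        params = SamplingParams(density_classes=(0.02,), n_per_class=20)
        sel = sample_orfs_by_density(orfs, dens, params)
        assert len(sel[0.02]) == 20

    def test_seed_determinism(self):
        orfs, dens = self._orfs([0.02] * 40)
        params = SamplingParams(density_classes=(0.02,), n_per_class=10, seed=5)
        s1 = sample_orfs_by_density(orfs, dens, params)
        s2 = sample_orfs_by_density(orfs, dens, params)
        assert [o.id for o in s1[0.02]] == [o.id for o in s2[0.02]]
        params2 = SamplingParams(density_classes=(0.02,), n_per_class=10, seed=6)
        s3 = sample_orfs_by_density(orfs, dens, params2)
        assert [o.id for o in s1[0.02]] != [o.id for o in s3[0.02]]

    def test_selected_densities_within_class_bounds(self):
        orfs, dens = self._orfs([0.017, 0.02, 0.023, 0.03, 0.06, 0.021])
        params = SamplingParams(density_classes=(0.02,), n_per_class=4)
        sel = sample_orfs_by_density(orfs, dens, params)
        assert all(abs(dens[o.id] - 0.02) <= 0.005 for o in sel[0.02])

    def test_underpopulated_class_errors_with_counts(self):
        orfs, dens = self._orfs([0.02] * 5)
        params = SamplingParams(density_classes=(0.02,), n_per_class=20)
        with pytest.raises(PloidykitError, match="only 5"):
            sample_orfs_by_density(orfs, dens, params)


# three 30 bp haplotypes differing at sites 3, 9, 15, 21, 27
H_A = "AAAGAAAAAGAAAAAGAAAAAGAAAAAGAA"
H_B = "AAACAAAAACAAAAACAAAAACAAAAACAA"
H_C = "AAATAAAAATAAAAATAAAAATAAAAATAA"
SITES = [3, 9, 15, 21, 27]


def _site_objs(cid="c0"):
    return [SnpSite(cid, p, "A", [("G", 0.3), ("C", 0.3), ("T", 0.3)], 30)
            for p in SITES]


class TestPhasing:
    def test_three_clean_haplotypes_recovered(self):
        reads = (_reads_from(H_A, 5, prefix="a", length=20, stagger=3)
                 + _reads_from(H_B, 5, prefix="b", length=20, stagger=3)
                 + _reads_from(H_C, 5, prefix="c", length=20, stagger=3))
        clusters, flag = phase_orf_reads(_orf(), reads, SITES, PhaseParams())
        assert not flag
        assert len(clusters) == 3
        vectors = sorted("".join(c.alleles[i] for i in range(5))
                         for c in clusters)
        assert vectors == ["CCCCC", "GGGGG", "TTTTT"]

    def test_single_copy_gives_one_cluster(self):
        reads = _reads_from(H_A, 8, length=20, stagger=2)
        clusters, _ = phase_orf_reads(_orf(), reads, SITES, PhaseParams())
        assert len(clusters) == 1
        assert clusters[0].n_reads == 8

    def test_support_threshold_discards_with_flag(self):
        reads = _reads_from(H_A, 2, prefix="a") + _reads_from(H_B, 2, prefix="b")
        clusters, flag = phase_orf_reads(
            _orf(), reads, SITES, PhaseParams(min_reads_per_haplotype=3))
        assert clusters == []
        assert flag

    def test_no_het_sites_is_single_haplotype_not_error(self):
        reads = _reads_from(H_A, 5)
        clusters, flag = phase_orf_reads(_orf(), reads, [], PhaseParams())
        assert clusters == [] and not flag

    def test_reads_with_too_few_sites_unused(self):
        reads = [AlignedRead("r0", "c0", 0, "+", H_A[:5])]   # covers 1 site
        clusters, _ = phase_orf_reads(_orf(), reads, SITES,
                                      PhaseParams(min_reads_per_haplotype=1))
        assert clusters == []

    def test_permutation_invariance(self):
        reads = (_reads_from(H_A, 5, prefix="a", length=20, stagger=3)
                 + _reads_from(H_B, 5, prefix="b", length=20, stagger=3)
                 + _reads_from(H_C, 4, prefix="c", length=20, stagger=3))
        base, _ = phase_orf_reads(_orf(), reads, SITES, PhaseParams())
        rng = np.random.default_rng(0)
        for _ in range(3):
            shuffled = list(reads)
            rng.shuffle(shuffled)
            out, _ = phase_orf_reads(_orf(), shuffled, SITES, PhaseParams())
            assert [c.read_ids for c in out] == [c.read_ids for c in base]

    def test_error_read_absorbed_by_majority(self):
        # one 'a' read carries a C (a real allele) at site 9
        bad = H_A[:20].replace("G", "C", 2)[:20]
        bad = H_A[:9] + "C" + H_A[10:20]
        reads = (_reads_from(H_A, 6, prefix="a", length=20, stagger=3)
                 + _reads_from(H_B, 6, prefix="b", length=20, stagger=3)
                 + [AlignedRead("bad", "c0", 0, "+", bad)])
        clusters, _ = phase_orf_reads(_orf(), reads, _site_objs(),
                                      PhaseParams())
        assert len(clusters) == 2
        assert any("bad" in c.read_ids for c in clusters)

    def test_unlinked_blocks_of_same_copy_are_linked(self):
        # left block covers sites 3,9; right block covers 21,27; nothing
        # spans site 15, so the two A2-like blocks share no site
        left = [AlignedRead(f"l{i}", "c0", 0, "+", H_B[:12]) for i in range(3)]
        right = [AlignedRead(f"r{i}", "c0", 18, "+", H_B[18:]) for i in range(3)]
        other = _reads_from(H_A, 6, length=30)
        clusters, _ = phase_orf_reads(
            _orf(), other + left + right, [3, 9, 21, 27], PhaseParams())
        assert len(clusters) == 2

    def test_clusters_internally_consistent_on_simulation(self, small_model):
        """Re-scan: within a cluster, read disagreement with the cluster
        consensus at any site never exceeds the stray-read tolerance, and
        every retained read belongs to exactly one cluster."""
        from ploidykit.haplotypes import _read_profile, _site_entries
        import ploidykit.pileup as pp
        pile = pp.build_pileup(small_model.assembly, small_model.reads)
        snps = pp.call_het_sites(pile, small_model.config.snp)
        params = small_model.config.phase
        for planted in small_model.truth.orfs[:6]:
            orf = planted.orf
            reads = [r for r in small_model.reads
                     if r.contig_id == orf.contig_id and r.end > orf.start
                     and r.start < orf.end]
            sites = [s for s in snps if s.contig_id == orf.contig_id]
            clusters, _ = phase_orf_reads(orf, reads, sites, params)
            entries = _site_entries(orf, sites)
            read_by_id = {r.read_id: r for r in reads}
            seen = set()
            for cluster in clusters:
                assert not (set(cluster.read_ids) & seen)
                seen |= set(cluster.read_ids)
                votes = {}
                for rid in cluster.read_ids:
                    for idx, base in _read_profile(read_by_id[rid],
                                                   entries).items():
                        votes.setdefault(idx, []).append(base)
                for idx, bases in votes.items():
                    dissent = sum(1 for b in bases
                                  if b != cluster.alleles.get(idx))
                    assert dissent <= max(params.max_conflict_reads,
                                          len(bases) // 2)


class TestConsensusAndIdentity:
    def test_cluster_covering_all_sites_reconstructs_copy(self):
        asm = Assembly([Contig("c0", H_A, "c0")])
        reads = _reads_from(H_B, 6, length=30)
        clusters, _ = phase_orf_reads(_orf(), reads, SITES, PhaseParams())
        ((seq, uncovered),) = haplotype_consensus(clusters, _orf(), asm, SITES)
        assert seq == H_B
        assert uncovered == []

    def test_no_sites_consensus_equals_reference(self):
        asm = Assembly([Contig("c0", H_A, "c0")])
        out = haplotype_consensus([], _orf(), asm, [])
        assert out == []

    def test_uncovered_sites_flagged_and_take_reference(self):
        asm = Assembly([Contig("c0", H_A, "c0")])
        reads = [AlignedRead(f"x{i}", "c0", 0, "+", H_B[:12])
                 for i in range(3)]             # covers sites 3 and 9 only
        clusters, _ = phase_orf_reads(_orf(), reads, SITES, PhaseParams())
        ((seq, uncovered),) = haplotype_consensus(clusters, _orf(), asm, SITES)
        assert uncovered == [2, 3, 4]
        assert seq[3] == "C" and seq[9] == "C"
        assert seq[15] == "G"                   # reference base retained

    def test_identity_examples(self):
        assert pairwise_identity("A" * 999, "A" * 999) == 100.0
        a = "A" * 1000
        b = "C" * 50 + "A" * 950
        assert pairwise_identity(a, b) == 95.0

    def test_identity_requires_equal_length(self):
        with pytest.raises(PloidykitError):
            pairwise_identity("AAA", "AA")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_identity_bounds_and_symmetry(self, seq):
        other = seq[::-1]
        ab = pairwise_identity(seq, other)
        assert 0.0 <= ab <= 100.0
        assert ab == pairwise_identity(other, seq)
        assert pairwise_identity(seq, seq) == 100.0


class TestLabelling:
    def test_most_similar_pair_becomes_h1_h2(self):
        seqs = ["AAAA", "AAAT", "GGGG"]          # identity(0,1)=75 highest
        labels = label_haplotypes(seqs, [5, 4, 6])
        assert {labels["h1"], labels["h2"]} == {0, 1}
        assert labels["h3"] == 2
        assert seqs[labels["h1"]] <= seqs[labels["h2"]]

    def test_all_equal_identities_resolved_by_tie_chain(self):
        seqs = ["AC", "CA", "GG"]                # all pairwise identity 0
        labels = label_haplotypes(seqs, [3, 5, 4])
        assert {labels["h1"], labels["h2"]} == {1, 2}   # largest summed support

    def test_two_haplotypes_by_support(self):
        labels = label_haplotypes(["TTTT", "AAAA"], [2, 9])
        assert labels == {"h1": 1, "h2": 0}

    def test_labelling_invariant_on_resolutions(self, default_results):
        for r in default_results.resolutions:
            if r.n_haplotypes == 3:
                assert r.sister_identity == max(r.identities.values())
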