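"""Stratified ORF sampling, read-backed phasing, consensus haplotypes,
pairwise identity, and h1/h2/h3 labelling.

Phasing is a deterministic greedy agglomeration of reads over the het
sites inside an ORF, in three stages.  First, strict merging: every
retained read starts as its own cluster and the pair of clusters whose
majority-vote consensus vectors share the most agreeing sites (and disagree
at none) is merged, to a fixed point.  Second, tolerant merging: the same
ordering, but a disagreeing site is excused when it is explainable as a
stray read — pooled minority support within a small tolerance against a
clear majority — which soaks up sequencing errors that landed on a real
allele once genuine haplotype boundaries are backed by broad coverage.
Third, linking: clusters
with no shared covered site (unlinked phase blocks of the same genome copy,
e.g. across a gap between het sites longer than a read) are joined so the
haplotype count reflects distinct local sequences, not phase blocks.  The
procedure replaces a manual read-separation step with an auditable
algorithm; all thresholds are exposed in PhaseParams.

For a three-haplotype ORF the pair of consensus sequences with the highest
nucleotide identity is labelled {h1, h2} (the putative sister subgenome
pair) and the remaining haplotype h3 (the divergent subgenome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AlignedRead, Assembly, OrfModel, PloidykitError
from .pileup import SnpSite

_PROFILE_BASES = "ACGT"
_PROFILE_CODE = {b: i for i, b in enumerate(_PROFILE_BASES)}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SamplingParams:
    density_classes: tuple[float, ...] = (0.02, 0.04, 0.06)
    class_tolerance: float = 0.005
    n_per_class: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.density_classes) != sorted(self.density_classes):
            raise PloidykitError("density classes must be ascending")
        if self.n_per_class < 1:
            raise PloidykitError("n_per_class must be >= 1")


@dataclass
class PhaseParams:
    """Thresholds for the greedy read agglomeration.

    A merge between two clusters is blocked by a shared site whose pooled
    minority allele has more than ``max_conflict_reads`` supporting reads,
    or whose majority has fewer than ``min_majority_reads`` — i.e. a single
    stray read (a sequencing error landing on a real allele) cannot hold a
    cluster apart once the majority evidence is clear, while genuine
    haplotype differences, supported by several reads on each side, always
    conflict.  ``max_conflict_reads=0`` recovers the strict all-reads-agree
    rule.
    """

    min_sites_per_read: int = 2
    min_reads_per_haplotype: int = 3
    max_haplotypes_reported: int = 4
    max_conflict_reads: int = 1
    min_majority_reads: int = 3

    def __post_init__(self) -> None:
        if min(self.min_sites_per_read, self.min_reads_per_haplotype,
               self.max_haplotypes_reported, self.min_majority_reads) < 1:
            raise PloidykitError("phase parameters must be >= 1")
        if self.max_conflict_reads < 0:
            raise PloidykitError("max_conflict_reads must be >= 0")


# ---------------------------------------------------------------------------
# densities and sampling
# ---------------------------------------------------------------------------

def orf_snp_density(orf: OrfModel, snps: Sequence[SnpSite]) -> float:
    """Called het sites inside [start, end) divided by ORF length."""
    n = sum(1 for s in snps
            if s.contig_id == orf.contig_id and orf.start <= s.pos < orf.end)
    return n / len(orf)


def orf_densities(orfs: Sequence[OrfModel],
                  snps: Sequence[SnpSite]) -> dict[str, float]:
    by_contig: dict[str, np.ndarray] = {}
    for s in snps:
        by_contig.setdefault(s.contig_id, [])
    for s in snps:
        by_contig[s.contig_id].append(s.pos)
    by_contig = {c: np.array(sorted(v)) for c, v in by_contig.items()}
    out = {}
    for o in orfs:
        pos = by_contig.get(o.contig_id, np.array([], dtype=int))
        n = int(np.searchsorted(pos, o.end) - np.searchsorted(pos, o.start))
        out[o.id] = n / len(o)
    return out


def sample_orfs_by_density(orfs: Sequence[OrfModel],
                           densities: Mapping[str, float],
                           params: SamplingParams) -> dict[float, list[OrfModel]]:
    """Draw n_per_class ORFs per density class (within tolerance), without
    replacement, deterministically under the sampling seed."""
    rng = np.random.default_rng(params.seed)
    selection: dict[float, list[OrfModel]] = {}
    for cls in params.density_classes:
        eligible = sorted(
            (o for o in orfs
             if abs(densities[o.id] - cls) <= params.class_tolerance),
            key=lambda o: o.id)
        if len(eligible) < params.n_per_class:
            raise PloidykitError(
                f"density class {cls}: only {len(eligible)} eligible ORFs, "
                f"{params.n_per_class} requested")
        picks = rng.choice(len(eligible), size=params.n_per_class, replace=False)
        selection[cls] = [eligible[i] for i in sorted(picks)]
    return selection


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------

@dataclass
class ReadCluster:
    read_ids: tuple[str, ...]
    alleles: dict[int, str]       # het-site index -> base

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def _site_entries(orf: OrfModel, het_sites) -> list[tuple[int, set | None]]:
    """(position, allowed allele set) per het site inside the ORF.

    ``het_sites`` may be SnpSite objects (allowed alleles = the called set,
    so error bases at a site stay undefined rather than faking conflicts)
    or bare positions (no allele restriction).
    """
    entries: dict[int, set | None] = {}
    for s in het_sites:
        if isinstance(s, SnpSite):
            if s.contig_id != orf.contig_id:
                continue
            pos, allowed = s.pos, set(s.alleles)
        else:
            pos, allowed = int(s), None
        if orf.start <= pos < orf.end:
            entries[pos] = allowed
    return sorted(entries.items())


def _read_profile(read: AlignedRead,
                  entries: list[tuple[int, set | None]]) -> dict[int, str]:
    alleles = {}
    for idx, (pos, allowed) in enumerate(entries):
        if read.start <= pos < read.end:
            base = read.aligned_seq[pos - read.start]
            if base in _PROFILE_CODE and (allowed is None or base in allowed):
                alleles[idx] = base
    return alleles


def _profile_key(profile: np.ndarray) -> str:
    return "".join("." if c < 0 else _PROFILE_BASES[c] for c in profile)


def _consensus(counts: np.ndarray) -> np.ndarray:
    """Majority base per site (argmax ties break alphabetically),
    -1 where the cluster has no coverage."""
    cons = counts.argmax(axis=1).astype(np.int8)
    cons[counts.sum(axis=1) == 0] = -1
    return cons


def _merge_stage(counts_list: list[np.ndarray], members: list[tuple[str, ...]],
                 params: PhaseParams, stage: str) -> None:
    """One greedy merge stage, applied to a fixed point (in place).

    strict   — merge the pair sharing the most agreeing consensus sites,
               any consensus disagreement at a shared site blocks;
    tolerant — same ordering, but a disagreeing site no longer blocks when
               the pooled minority is within max_conflict_reads against a
               majority of at least min_majority_reads (a stray sequencing
               error on a real allele); run after strict so that genuine
               haplotype boundaries are already backed by broad coverage;
    link     — join clusters with no shared covered site into one haplotype
               (unlinked phase blocks of the same copy), established
               clusters only.
    """
    while len(counts_list) > 1:
        k = len(counts_list)
        C = np.stack(counts_list)                      # (k, S, 4)
        cons = np.stack([_consensus(c) for c in counts_list])
        defined = cons >= 0
        both = defined[:, None, :] & defined[None, :, :]
        equal = (cons[:, None, :] == cons[None, :, :]) & both
        agree = equal.sum(axis=2)
        differ = both & ~equal
        sizes = np.array([len(m) for m in members])
        small = sizes < params.min_reads_per_haplotype
        if stage == "strict":
            conflict = differ.any(axis=2)
            eligible = (~conflict) & (agree >= 1)
        elif stage == "tolerant":
            pooled = C[:, None] + C[None, :]           # (k, k, S, 4)
            winner_n = pooled.max(axis=3)
            minority_n = pooled.sum(axis=3) - winner_n
            tolerable = ((minority_n <= params.max_conflict_reads)
                         & (winner_n >= params.min_majority_reads))
            conflict = (differ & ~tolerable).any(axis=2)
            eligible = (~conflict) & (agree >= 1)
        elif stage == "link":
            disjoint = ~both.any(axis=2)
            neither_small = ~(small[:, None] | small[None, :])
            eligible = disjoint & neither_small
        else:                                          # pragma: no cover
            raise PloidykitError(f"unknown merge stage {stage!r}")
        iu = np.triu_indices(k, 1)
        ok = eligible[iu]
        if not ok.any():
            return
        best_agree = agree[iu][ok].max()
        cand = [(i, j) for i, j, a, good in
                zip(iu[0], iu[1], agree[iu], ok)
                if good and a == best_agree]

        # ties: larger combined read count, then order-free lexicographic key
        def _pair_key(pair):
            i, j = pair
            keys = sorted([(_profile_key(cons[i]), members[i]),
                           (_profile_key(cons[j]), members[j])])
            return (-(len(members[i]) + len(members[j])), keys[0], keys[1])

        i, j = min(cand, key=_pair_key)
        merged = counts_list[i] + counts_list[j]
        merged_members = tuple(sorted(members[i] + members[j]))
        for idx in sorted((i, j), reverse=True):
            del counts_list[idx]
            del members[idx]
        counts_list.append(merged)
        members.append(merged_members)


def phase_orf_reads(orf: OrfModel, reads: Sequence[AlignedRead],
                    het_sites, params: PhaseParams) -> tuple[list[ReadCluster], bool]:
    """Greedy conflict-free agglomeration of reads over ORF het sites.

    ``het_sites`` is a sequence of SnpSite objects or bare positions.
    Returns the surviving clusters (read support >= min_reads_per_haplotype,
    largest first) and a flag set when candidate clusters existed but all
    fell below the support threshold.  An ORF with no het sites returns no
    clusters and no flag (a single haplotype by definition).
    """
    entries = _site_entries(orf, het_sites)
    if not entries:
        return [], False
    n_sites = len(entries)

    counts_list: list[np.ndarray] = []    # per cluster: (n_sites, 4) read counts
    members: list[tuple[str, ...]] = []
    for read in reads:
        if read.contig_id != orf.contig_id or read.end <= orf.start \
                or read.start >= orf.end:
            continue
        alleles = _read_profile(read, entries)
        if len(alleles) < params.min_sites_per_read:
            continue
        counts = np.zeros((n_sites, 4), dtype=np.int16)
        for idx, base in alleles.items():
            counts[idx, _PROFILE_CODE[base]] = 1
        counts_list.append(counts)
        members.append((read.read_id,))
    if not counts_list:
        return [], False

    _merge_stage(counts_list, members, params, stage="strict")
    _merge_stage(counts_list, members, params, stage="tolerant")
    _merge_stage(counts_list, members, params, stage="link")

    clusters = [
        ReadCluster(m, {idx: _PROFILE_BASES[c]
                        for idx, c in enumerate(_consensus(counts)) if c >= 0})
        for counts, m in zip(counts_list, members)
    ]
    survivors = [c for c in clusters
                 if c.n_reads >= params.min_reads_per_haplotype]
    survivors.sort(key=lambda c: (-c.n_reads, c.read_ids))
    all_discarded = bool(clusters) and not survivors
    return survivors, all_discarded


def cluster_site_positions(orf: OrfModel, het_sites) -> np.ndarray:
    return np.array([pos for pos, _ in _site_entries(orf, het_sites)],
                    dtype=int)


def haplotype_consensus(clusters: Sequence[ReadCluster], orf: OrfModel,
                        assembly: Assembly,
                        het_sites) -> list[tuple[str, list[int]]]:
    """Per cluster: the reference ORF sequence with the cluster allele
    substituted at each covered het site; uncovered sites keep the reference
    base and are returned as flags (site indices)."""
    sites = cluster_site_positions(orf, het_sites)
    ref = assembly[orf.contig_id].sequence[orf.start:orf.end]
    out = []
    for cluster in clusters:
        seq = list(ref)
        uncovered = []
        for idx, pos in enumerate(sites):
            base = cluster.alleles.get(idx)
            if base is None:
                uncovered.append(idx)
            else:
                seq[pos - orf.start] = base
        out.append(("".join(seq), uncovered))
    return out


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent of matching positions between equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise PloidykitError("sequences must have equal length")
    if not seq_a:
        raise PloidykitError("empty sequences")
    matches = sum(a == b for a, b in zip(seq_a, seq_b))
    return 100.0 * matches / len(seq_a)


# ---------------------------------------------------------------------------
# resolution and labelling
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeResolution:
    orf_id: str
    density_class: float | None
    n_haplotypes: int
    consensus: dict[str, str]                # label -> sequence
    identities: dict[str, float]             # "h1-h2" -> percent
    read_counts: dict[str, int]
    flags: list[str] = field(default_factory=list)

    @property
    def sister_identity(self) -> float | None:
        return self.identities.get("h1-h2")

    @property
    def divergent_identities(self) -> list[float]:
        return [v for k, v in sorted(self.identities.items()) if "h3" in k]


def label_haplotypes(sequences: Sequence[str],
                     read_counts: Sequence[int]) -> dict[str, int]:
    """Assign h1..hn: for three haplotypes the most similar pair is {h1, h2}
    (h1 the lexicographically smaller sequence) and the remainder h3; for two,
    labels follow read support (descending).  Ties break by larger summed
    read support, then lexicographic sequence order."""
    n = len(sequences)
    if n == 1:
        return {"h1": 0}
    if n == 2:
        order = sorted(range(2), key=lambda i: (-read_counts[i], sequences[i]))
        return {"h1": order[0], "h2": order[1]}
    if n != 3:
        raise PloidykitError("labelling applies to 1-3 haplotypes")
    pairs = list(combinations(range(3), 2))
    def _pair_rank(pair):
        i, j = pair
        ident = pairwise_identity(sequences[i], sequences[j])
        support = read_counts[i] + read_counts[j]
        seqs = sorted([sequences[i], sequences[j]])
        return (-ident, -support, seqs[0], seqs[1])
    i, j = min(pairs, key=_pair_rank)
    h1, h2 = sorted((i, j), key=lambda x: sequences[x])
    (h3,) = set(range(3)) - {i, j}
    return {"h1": h1, "h2": h2, "h3": h3}


def resolve_orf(orf: OrfModel, reads: Sequence[AlignedRead],
                het_sites, assembly: Assembly, params: PhaseParams,
                density_class: float | None = None) -> HaplotypeResolution:
    """Phase one ORF and package consensus sequences, identities and labels."""
    clusters, all_discarded = phase_orf_reads(orf, reads, het_sites, params)
    sites = cluster_site_positions(orf, het_sites)
    flags = []
    if len(sites) == 0:
        ref = assembly[orf.contig_id].sequence[orf.start:orf.end]
        return HaplotypeResolution(orf.id, density_class, 1, {"h1": ref}, {},
                                   {"h1": 0}, ["no_het_sites"])
    if all_discarded:
        return HaplotypeResolution(orf.id, density_class, 0, {}, {}, {},
                                   ["all_clusters_below_support"])
    if not clusters:
        return HaplotypeResolution(orf.id, density_class, 0, {}, {}, {},
                                   ["no_informative_reads"])
    n_observed = len(clusters)
    reported = clusters
    if len(reported) > 3:
        flags.append(f"haplotypes_observed={n_observed}")
        reported = reported[:3]
    consensus = haplotype_consensus(reported, orf, assembly, het_sites)
    uncovered_total = sum(len(u) for _, u in consensus)
    if uncovered_total:
        flags.append(f"uncovered_sites={uncovered_total}")
    seqs = [s for s, _ in consensus]
    counts = [c.n_reads for c in reported]
    labels = label_haplotypes(seqs, counts)
    consensus_by_label = {lab: seqs[i] for lab, i in labels.items()}
    read_counts = {lab: counts[i] for lab, i in labels.items()}
    identities = {
        f"{a}-{b}": pairwise_identity(consensus_by_label[a], consensus_by_label[b])
        for a, b in combinations(sorted(labels), 2)
    }
    return HaplotypeResolution(orf.id, density_class, n_observed,
                               consensus_by_label, identities, read_counts,
                               flags)


def resolve_sampled_orfs(selection: Mapping[float, Sequence[OrfModel]],
                         reads: Sequence[AlignedRead],
                         snps: Sequence[SnpSite], assembly: Assembly,
                         params: PhaseParams) -> list[HaplotypeResolution]:
    """Phase every sampled ORF; reads are pre-bucketed per contig for speed."""
    by_contig: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_contig.setdefault(r.contig_id, []).append(r)
    for contig_reads in by_contig.values():
        contig_reads.sort(key=lambda r: r.start)
    snp_by_contig: dict[str, list[SnpSite]] = {}
    for s in snps:
        snp_by_contig.setdefault(s.contig_id, []).append(s)
    resolutions = []
    for cls in sorted(selection):
        for orf in selection[cls]:
            contig_reads = by_contig.get(orf.contig_id, [])
            starts = [r.start for r in contig_reads]
            import bisect
            lo = bisect.bisect_left(starts, orf.start - 10_000)
            hi = bisect.bisect_right(starts, orf.end)
            local = [r for r in contig_reads[lo:hi] if r.end > orf.start]
            resolutions.append(resolve_orf(
                orf, local, snp_by_contig.get(orf.contig_id, []), assembly,
                params, density_class=cls))
    return resolutions
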