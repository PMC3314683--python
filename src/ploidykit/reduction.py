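"""Iterative reciprocal-best-hit merging of small contigs into large ones.

Heterozygous assemblies strand small allelic contigs alongside the large
contig carrying the other haplotype of the same locus.  This module pairs
each small contig with its reciprocal best-hit large contig using an
internal seed-and-extend overlap search (exact k-mer seeds chained on a
diagonal band, then a banded gapped extension) and reassembles the small
contig into the large one: the large contig's base wins at every
disagreeing column and the small contig only contributes overhanging
sequence.  A second pass retries unmerged small contigs in reverse
complement; passes repeat until a fixed point.

The classic E-value gate of an external search engine is replaced by a raw
score gate (unit match, -1 mismatch, configurable gap costs); E-values are
database-size dependent and not reproducible inside a self-contained tool.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping

import edlib

from .io import Assembly, Contig, PloidykitError, revcomp


@dataclass
class ReductionParams:
    """Overlap-search and merge thresholds.

    The defaults mirror a conservative assembly-finishing profile:
    12-mer seeds, 80% minimum identity, 100 bp minimum aligned length,
    at most 70 added gaps per kb, no gap-open cost, and 0.7 per gap base.
    ``size_cutoff`` separating small from large contigs is a required,
    logged choice with no canonical value.
    """

    size_cutoff: int = 5000
    seed_k: int = 12
    min_identity: float = 80.0
    min_seq_length: int = 100
    max_gaps_per_kb: float = 70.0
    gap_open_penalty: float = 0.0
    gap_extend_penalty: float = 0.7
    min_score: float = 50.0

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise PloidykitError("seed_k must be >= 8")
        if not 0 < self.min_identity <= 100:
            raise PloidykitError("min_identity must be in (0, 100]")
        if self.size_cutoff < self.min_seq_length:
            raise PloidykitError("size_cutoff below min_seq_length")


@dataclass
class OverlapHit:
    small_id: str
    large_id: str
    orientation: str          # fwd | rc
    small_span: tuple[int, int]
    large_span: tuple[int, int]
    identity: float
    score: float
    gaps_per_kb: float
    n_matches: int
    proj_start: int           # projected placement of small on large (may be <0)
    proj_end: int


def _parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, gap_columns, gap_runs)."""
    matches = mismatches = gap_cols = gap_runs = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        elif ch in "ID":
            gap_cols += n
            gap_runs += 1
        else:
            raise PloidykitError(f"unexpected CIGAR op {ch!r}")
    return matches, mismatches, gap_cols, gap_runs


def seed_and_extend(small: str, large: str,
                    params: ReductionParams) -> OverlapHit | None:
    """Best banded overlap of ``small`` against ``large``, or None.

    Exact ``seed_k``-mers shared by both sequences vote for a diagonal
    band; the best band is extended with a gapped alignment and the hit is
    kept only if it clears the identity, length, gap-density and score
    filters.  Identifiers and orientation are filled in by the caller.
    """
    k = params.seed_k
    if len(small) < params.min_seq_length or len(large) < params.min_seq_length:
        return None
    if len(small) < k or len(large) < k:
        return None
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(large) - k + 1):
        index[large[i:i + k]].append(i)
    band_width = max(16, int(params.max_gaps_per_kb * len(small) / 1000.0))
    votes: dict[int, list[int]] = defaultdict(list)
    for j in range(len(small) - k + 1):
        for i in index.get(small[j:j + k], ()):
            votes[(i - j) // band_width].append(i - j)
    if not votes:
        return None
    # merge each band with its right neighbour so seeds straddling a band
    # boundary still chain together
    best_bucket, best_n = None, 0
    for b in votes:
        n = len(votes[b]) + len(votes.get(b + 1, ()))
        if n > best_n or (n == best_n and (best_bucket is None or b < best_bucket)):
            best_bucket, best_n = b, n
    diagonals = sorted(votes[best_bucket] + votes.get(best_bucket + 1, []))
    diag = diagonals[len(diagonals) // 2]

    proj_start, proj_end = diag, diag + len(small)
    ss = max(0, -proj_start)
    se = len(small) - max(0, proj_end - len(large))
    if se - ss < params.min_seq_length:
        return None
    pad = band_width
    ls = max(0, proj_start + ss - pad)
    le = min(len(large), proj_start + se + pad)
    query = small[ss:se]
    target = large[ls:le]
    result = edlib.align(query, target, mode="HW", task="path")
    if result["editDistance"] < 0 or not result.get("locations"):
        return None
    loc_start, loc_end = result["locations"][0]
    matches, mismatches, gap_cols, gap_runs = _parse_cigar(result["cigar"])
    columns = matches + mismatches + gap_cols
    if columns == 0:
        return None
    identity = 100.0 * matches / columns
    gaps_per_kb = 1000.0 * gap_cols / columns
    score = (matches - mismatches
             - params.gap_open_penalty * gap_runs
             - params.gap_extend_penalty * gap_cols)
    if identity < params.min_identity or gaps_per_kb > params.max_gaps_per_kb \
            or score < params.min_score:
        return None
    return OverlapHit(
        small_id="", large_id="", orientation="fwd",
        small_span=(ss, se),
        large_span=(ls + loc_start, ls + loc_end + 1),
        identity=identity, score=score, gaps_per_kb=gaps_per_kb,
        n_matches=matches, proj_start=proj_start, proj_end=proj_end)


def reciprocal_best_hits(smalls: Mapping[str, str], larges: Mapping[str, str],
                         params: ReductionParams,
                         orientation: str = "fwd") -> list[OverlapHit]:
    """Pairs where each sequence is the other's best hit by score.

    Ties break by identity, then lexicographic id.  ``orientation='rc'``
    searches the reverse complement of each small contig.
    """
    hits: dict[tuple[str, str], OverlapHit] = {}
    for sid in sorted(smalls):
        query = smalls[sid] if orientation == "fwd" else revcomp(smalls[sid])
        for lid in sorted(larges):
            hit = seed_and_extend(query, larges[lid], params)
            if hit is not None:
                hit.small_id, hit.large_id = sid, lid
                hit.orientation = orientation
                hits[(sid, lid)] = hit

    def _best(candidates: list[OverlapHit], key_attr: str) -> OverlapHit:
        return min(candidates,
                   key=lambda h: (-h.score, -h.identity, getattr(h, key_attr)))

    best_large: dict[str, OverlapHit] = {}
    best_small: dict[str, OverlapHit] = {}
    for sid in smalls:
        cands = [h for (s, _), h in hits.items() if s == sid]
        if cands:
            best_large[sid] = _best(cands, "large_id")
    for lid in larges:
        cands = [h for (_, l), h in hits.items() if l == lid]
        if cands:
            best_small[lid] = _best(cands, "small_id")
    pairs = []
    for sid, hit in sorted(best_large.items()):
        back = best_small.get(hit.large_id)
        if back is not None and back.small_id == sid:
            pairs.append(hit)
    return pairs


def _merge_sequences(small: str, large: str, hit: OverlapHit) -> tuple[str, dict]:
    """Large-priority consensus: the large sequence is kept verbatim and the
    small contig contributes only overhangs beyond the large's ends."""
    ss, se = hit.small_span
    left = small[:ss] if hit.proj_start < 0 else ""
    right = small[se:] if hit.proj_end > len(large) else ""
    merged = left + large + right
    detail = {
        "left_overhang": len(left),
        "right_overhang": len(right),
        "large_span": list(hit.large_span),
        "identity": round(hit.identity, 3),
        "score": round(hit.score, 3),
    }
    return merged, detail


def merge_pass(assembly: Assembly,
               params: ReductionParams) -> tuple[Assembly, list[dict]]:
    """Iterate forward then reverse-complement RBH merge passes to a fixed
    point; returns the reduced assembly and a log of every merge."""
    seqs = {c.id: c.sequence for c in assembly}
    meta = {c.id: (c.scaffold_id, c.index_in_scaffold) for c in assembly}
    order = [c.id for c in assembly]
    log: list[dict] = []
    pass_no = 0
    while True:
        merged_any = False
        for orientation in ("fwd", "rc"):
            smalls = {cid: s for cid, s in seqs.items()
                      if len(s) < params.size_cutoff}
            larges = {cid: s for cid, s in seqs.items()
                      if len(s) >= params.size_cutoff}
            if not smalls or not larges:
                continue
            assert not (set(smalls) & set(larges))
            pass_no += 1
            pairs = reciprocal_best_hits(smalls, larges, params, orientation)
            for hit in pairs:
                small_seq = smalls[hit.small_id] if orientation == "fwd" \
                    else revcomp(smalls[hit.small_id])
                merged, detail = _merge_sequences(
                    small_seq, seqs[hit.large_id], hit)
                new_len, old_len = len(merged), len(seqs[hit.large_id])
                assert new_len - old_len <= len(small_seq)
                seqs[hit.large_id] = merged
                del seqs[hit.small_id]
                order.remove(hit.small_id)
                log.append({
                    "pass": pass_no, "orientation": orientation,
                    "small": hit.small_id, "large": hit.large_id,
                    **detail,
                })
                merged_any = True
        if not merged_any:
            break
    contigs = [Contig(cid, seqs[cid], *meta[cid]) for cid in order]
    organelle = assembly.organelle_ids & set(seqs)
    return Assembly(contigs, organelle_ids=organelle), log


def audit_merges(log: list[dict], original: Assembly, reduced: Assembly,
                 params: ReductionParams) -> bool:
    """Post-hoc check: every merged small contig still aligns to its final
    host contig at >= min_identity."""
    for entry in log:
        small = original[entry["small"]].sequence
        if entry["orientation"] == "rc":
            small = revcomp(small)
        host = reduced[entry["large"]].sequence
        hit = seed_and_extend(small, host, params)
        if hit is None or hit.identity < params.min_identity:
            return False
    return True
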