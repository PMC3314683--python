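"""Per-base pileups, heterozygous-site calling, and SNP-density tracks.

A het site is an assembly position where the second-most-frequent read base
reaches a minimum fraction of the depth — under a triploid model an allele
carried by one of three copies sits near 1/3 frequency.  Density is summarised
in sliding windows (1001 bp, 100 bp step by default) as sites per 10 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignedRead, Assembly, PloidykitError

logger = logging.getLogger("ploidykit")

_BASE_ORDER = "ACGT"
_PILEUP_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _PILEUP_CODE[_b] = _i          # '-' stays 255 and is dropped entirely


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    contig_id: str
    pos: int
    counts: dict[str, int]
    depth: int


class Pileup:
    """Per-contig base-count matrices: rows A, C, G, T, N."""

    def __init__(self, counts: dict[str, np.ndarray]):
        self._counts = counts

    def contigs(self) -> list[str]:
        return list(self._counts)

    def counts(self, contig_id: str) -> np.ndarray:
        return self._counts[contig_id]

    def depth(self, contig_id: str) -> np.ndarray:
        """Read depth per base; N-only reads count, deletion gaps do not."""
        return self._counts[contig_id].sum(axis=0)

    def acgt(self, contig_id: str) -> np.ndarray:
        return self._counts[contig_id][:4]

    def column(self, contig_id: str, pos: int) -> PileupColumn:
        col = self._counts[contig_id][:, pos]
        return PileupColumn(
            contig_id, pos,
            {b: int(col[i]) for i, b in enumerate(_BASE_ORDER)},
            int(col.sum()),
        )


def build_pileup(assembly: Assembly, reads: Iterable[AlignedRead]) -> Pileup:
    """Accumulate base counts; deletions ('-') add to neither counts nor depth."""
    index_lists: dict[str, list[np.ndarray]] = {c.id: [] for c in assembly}
    lengths = {c.id: len(c) for c in assembly}
    for read in reads:
        L = lengths.get(read.contig_id)
        if L is None:
            raise PloidykitError(f"read {read.read_id!r}: unknown contig")
        if read.start < 0 or read.end > L:
            raise PloidykitError(
                f"read {read.read_id!r}: outside contig {read.contig_id!r}")
        codes = _PILEUP_CODE[np.frombuffer(read.aligned_seq.encode(), np.uint8)]
        keep = codes != 255
        pos = read.start + np.nonzero(keep)[0]
        index_lists[read.contig_id].append(codes[keep].astype(np.int64) * L + pos)
    counts = {}
    for cid, chunks in index_lists.items():
        L = lengths[cid]
        if chunks:
            flat = np.bincount(np.concatenate(chunks), minlength=5 * L)
        else:
            flat = np.zeros(5 * L, dtype=np.int64)
        counts[cid] = flat.reshape(5, L).astype(np.int32)
    return Pileup(counts)


# ---------------------------------------------------------------------------
# het-site calling
# ---------------------------------------------------------------------------

@dataclass
class SnpCallParams:
    """Depth and minor-fraction thresholds for het-site calling.

    The default minor fraction 0.15 keeps per-site recall of a
    one-of-three-copies allele near 0.98 at 20-30x depth while sequencing
    errors at 0.5% have a ~1e-7 chance of reaching the threshold; 0.25
    (conservative triploid) and 0.50 (diploid-style consensus export,
    ``consensus_export``) are standard presets.
    """

    min_depth: int = 8
    min_minor_fraction: float = 0.15
    consensus_export_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.min_minor_fraction <= 0.5:
            raise PloidykitError("min_minor_fraction must be in (0, 0.5]")
        if self.min_depth < 1:
            raise PloidykitError("min_depth must be >= 1")

    @classmethod
    def consensus_export(cls) -> "SnpCallParams":
        return cls(min_minor_fraction=0.50)


@dataclass
class SnpSite:
    contig_id: str
    pos: int
    major_allele: str
    minor_alleles: list[tuple[str, float]]   # (base, fraction), count-descending
    depth: int
    alleles: list[str] | None = None         # called allele set (major first)

    def __post_init__(self) -> None:
        if self.alleles is None:
            self.alleles = [self.major_allele] + [b for b, _ in self.minor_alleles]

    @property
    def minor_fraction(self) -> float:
        return self.minor_alleles[0][1] if self.minor_alleles else 0.0


def call_het_sites(pileup: Pileup, params: SnpCallParams) -> list[SnpSite]:
    """Call sites where depth and the second-most-frequent base qualify.

    Ties for the major allele break alphabetically; third alleles are
    recorded with their fractions but are not required for the call.
    """
    sites: list[SnpSite] = []
    for cid in pileup.contigs():
        acgt = pileup.acgt(cid)
        depth = pileup.depth(cid)
        ranked = np.sort(acgt, axis=0)
        second = ranked[-2]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, second / np.maximum(depth, 1), 0.0)
        called = ((depth >= params.min_depth)
                  & (second > 0)
                  & (frac >= params.min_minor_fraction))
        for pos in np.nonzero(called)[0]:
            col = acgt[:, pos]
            order = sorted(range(4), key=lambda i: (-col[i], _BASE_ORDER[i]))
            major = _BASE_ORDER[order[0]]
            minors = [(_BASE_ORDER[i], float(col[i] / depth[pos]))
                      for i in order[1:] if col[i] > 0]
            alleles = [major] + [
                b for b, f in minors if f >= params.min_minor_fraction]
            sites.append(SnpSite(cid, int(pos), major, minors, int(depth[pos]),
                                 alleles=alleles))
    sites.sort(key=lambda s: (s.contig_id, s.pos))
    return sites


def snp_positions(snps: Sequence[SnpSite]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for s in snps:
        out.setdefault(s.contig_id, []).append(s.pos)
    return {cid: np.array(sorted(v), dtype=int) for cid, v in out.items()}


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowParams:
    window: int = 1001
    step: int = 100

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise PloidykitError("window must be odd (integer center)")
        if self.window < self.step:
            raise PloidykitError("window must be >= step")
        if self.step < 1:
            raise PloidykitError("step must be >= 1")


@dataclass
class WindowRecord:
    contig_id: str
    start: int
    end: int
    snp_per_10kb: float | None = None
    median_cov: float | None = None
    log2_ratio: float | None = None

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start - 1) // 2


def window_starts(length: int, params: WindowParams) -> np.ndarray:
    if length < params.window:
        return np.array([], dtype=int)
    return np.arange(0, length - params.window + 1, params.step)


def snp_density_track(snps: Sequence[SnpSite], assembly: Assembly,
                      params: WindowParams) -> list[WindowRecord]:
    """Left-anchored sliding windows of called-site density per 10 kb."""
    positions = snp_positions(snps)
    track: list[WindowRecord] = []
    for contig in assembly:
        starts = window_starts(len(contig), params)
        if len(starts) == 0:
            logger.warning("contig %s shorter than one window; skipped", contig.id)
            continue
        pos = positions.get(contig.id, np.array([], dtype=int))
        counts = (np.searchsorted(pos, starts + params.window, side="left")
                  - np.searchsorted(pos, starts, side="left"))
        for s, n in zip(starts, counts):
            track.append(WindowRecord(
                contig.id, int(s), int(s + params.window),
                snp_per_10kb=float(n) / params.window * 10_000))
    return track


def combine_tracks(density: Sequence[WindowRecord],
                   coverage: Sequence[WindowRecord]) -> list[WindowRecord]:
    """Merge SNP-density and coverage records on (contig, start)."""
    cov = {(w.contig_id, w.start): w for w in coverage}
    merged = []
    for w in density:
        c = cov.get((w.contig_id, w.start))
        merged.append(WindowRecord(
            w.contig_id, w.start, w.end, w.snp_per_10kb,
            c.median_cov if c else None,
            c.log2_ratio if c else None))
    return merged


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def implied_site_total(median_per_kb: float, genome_length: int) -> int:
    """Genome-wide site count implied by a per-kb median density."""
    return int(round(median_per_kb / 1000.0 * genome_length))


def density_summary(track: Sequence[WindowRecord], snps: Sequence[SnpSite],
                    assembly: Assembly) -> dict:
    """Median window density (per kb), per-scaffold and per-contig medians,
    the called-site total, and the genome-wide total implied by the median.
    """
    organelle = assembly.organelle_ids
    genomic = [w for w in track if w.contig_id not in organelle]
    values = np.array([w.snp_per_10kb for w in genomic], dtype=float)
    median_per_kb = float(np.median(values) / 10.0) if len(values) else 0.0
    scaffold_of = {c.id: c.scaffold_id for c in assembly}
    per_scaffold: dict[str, list[float]] = {}
    for w in genomic:
        per_scaffold.setdefault(scaffold_of[w.contig_id], []).append(w.snp_per_10kb)
    positions = snp_positions([s for s in snps if s.contig_id not in organelle])
    per_contig = {
        c.id: len(positions.get(c.id, ())) / len(c) * 1000.0
        for c in assembly.genomic_contigs()
    }
    contig_median = float(np.median(list(per_contig.values()))) if per_contig else 0.0
    total_genomic = assembly.total_length(include_organelle=False)
    total_sites = sum(1 for s in snps if s.contig_id not in organelle)
    return {
        "median_per_kb": median_per_kb,
        "median_per_kb_whole_contigs": contig_median,
        "total_sites": total_sites,
        "implied_total": implied_site_total(median_per_kb, total_genomic),
        "per_scaffold_medians": {
            sc: float(np.median(v) / 10.0) for sc, v in sorted(per_scaffold.items())
        },
        "genome_length": total_genomic,
    }


@dataclass
class LowDensityRegion:
    contig_id: str
    start: int
    end: int
    n_windows: int
    mean_snp_per_10kb: float


def flag_low_density_regions(track: Sequence[WindowRecord],
                             rel_threshold: float = 1 / 3,
                             min_windows: int = 50,
                             organelle_ids: Iterable[str] = ()) -> list[LowDensityRegion]:
    """Maximal runs of >= min_windows consecutive windows below
    rel_threshold x genome-median density (candidate LOH regions)."""
    organelle = set(organelle_ids)
    genomic = [w for w in track if w.contig_id not in organelle]
    if not genomic:
        return []
    genome_median = float(np.median([w.snp_per_10kb for w in genomic]))
    cut = rel_threshold * genome_median
    regions: list[LowDensityRegion] = []
    by_contig: dict[str, list[WindowRecord]] = {}
    for w in genomic:
        by_contig.setdefault(w.contig_id, []).append(w)
    for cid, windows in by_contig.items():
        windows.sort(key=lambda w: w.start)
        run: list[WindowRecord] = []
        for w in windows + [None]:
            if w is not None and w.snp_per_10kb < cut:
                run.append(w)
                continue
            if len(run) >= min_windows:
                regions.append(LowDensityRegion(
                    cid, run[0].start, run[-1].end, len(run),
                    float(np.mean([r.snp_per_10kb for r in run]))))
            run = []
    regions.sort(key=lambda r: (r.contig_id, r.start))
    return regions
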