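"""Truth-tracked synthetic triploid hybrid genome and read simulator.

The generative model mirrors the ploidy structure inferred for a hybrid
yeast genome: a moderately heterozygous sister pair of subgenome copies
(``A`` and ``A2``, ~99% nucleotide identity) plus a divergent haploid copy
(``B``, ~95% identity to the sisters), co-assembled onto a single reference
(copy ``A`` plays the role of the assembly consensus).  On top of that
background the simulator plants:

* LOH regions where the divergent copy has been replaced by the sister
  subgenome (position-wise ``B == A``), collapsing local heterozygosity;
* CNV segments realised in read space (extra template copies of a segment,
  so the pipeline sees elevated coverage over an unchanged reference);
* ORFs at targeted heterozygosity classes.  In classes above twice the
  sister rate the ORF carries the sister rate plus enough divergent-copy
  substitutions to hit the class exactly (three distinct haplotypes); at or
  below twice the sister rate the locus is modelled as an LOH-type locus —
  the divergent copy locally equals copy ``A`` and the sister pair drifts at
  the class rate, so only two haplotypes genuinely exist there.  This is the
  mechanism by which low-density loci yield fewer three-haplotype
  resolutions;
* a single AT-rich organelle contig sequenced at high depth.

Reads are substitution-error only (no indels), drawn uniformly from every
template copy, and each read's copy of origin is recorded in the truth
object but never exposed through the pipeline-facing artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (AlignedRead, Assembly, Contig, OrfModel, PloidykitError,
                 params_to_dict, write_alignment_tsv, write_fasta,
                 write_orfs_gff3, write_report, write_sam, write_scaffold_map)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# parameters and truth record
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study conditions for the synthetic triploid genome.

    Defaults emulate the sequencing design the analysis was built for:
    three genome copies at 8.7-fold each (~26-fold total), 345 bp
    substitution-error reads, sister-pair divergence 1%, divergent-copy
    divergence 5%, and a high-copy organelle contig at 225-fold.
    """

    n_contigs: int = 12
    contig_length: int = 100_000
    gc_fraction: float = 0.40
    d_sister: float = 0.01
    d_divergent: float = 0.05
    loh_regions: list[tuple[int, int, int]] | None = None   # (contig idx, start, end)
    cnv_segments: list[tuple[int, int, int, float]] | None = None  # (+ extra copies)
    orf_density_targets: tuple[tuple[float, int], ...] = (
        (0.02, 24), (0.04, 24), (0.06, 24))
    orf_length: int = 999
    per_copy_depth: float = 8.7
    read_len: int = 345
    err_rate: float = 0.005
    organelle_length: int = 20_000
    organelle_gc: float = 0.25
    organelle_depth: float = 225.0
    triploid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_sister", "d_divergent", "err_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 0.25:
                raise PloidykitError(f"{name}={rate} outside [0, 0.25]")
        if self.n_contigs < 1 or self.contig_length < self.read_len:
            raise PloidykitError("contigs must be at least one read long")
        if not 0.0 < self.gc_fraction < 1.0:
            raise PloidykitError("gc_fraction must be in (0, 1)")
        if self.orf_length % 3:
            raise PloidykitError("orf_length must be divisible by 3")

    def resolved_loh_regions(self) -> list[tuple[int, int, int]]:
        if self.loh_regions is not None:
            return list(self.loh_regions)
        L = self.contig_length
        idx = min(1, self.n_contigs - 1)
        return [(idx, int(0.40 * L), int(0.60 * L))]

    def resolved_cnv_segments(self) -> list[tuple[int, int, int, float]]:
        if self.cnv_segments is not None:
            return list(self.cnv_segments)
        if self.n_contigs < 4:
            return []
        L = self.contig_length
        # one 4/3-fold gain and one clear 1.5-class gain, on separate contigs
        return [(2, int(0.20 * L), int(0.36 * L), 1.0),
                (3, int(0.50 * L), int(0.66 * L), 1.65)]

    def contig_id(self, idx: int) -> str:
        return f"ctg_{idx:02d}"


@dataclass
class PlantedOrf:
    orf: OrfModel
    density_class: float
    loh_type: bool
    haplotypes: dict[str, str]      # copy name -> true sequence over the ORF
    n_het_sites: int


@dataclass
class SimTruth:
    """Ground truth of one simulation; never read by the pipeline."""

    params: SimParams
    contig_ids: list[str]
    copies: dict[str, dict[str, np.ndarray]]      # copy -> contig -> codes
    het_sites: dict[str, list[tuple[int, dict[str, str]]]] = field(default_factory=dict)
    loh_regions: list[tuple[str, int, int]] = field(default_factory=list)
    cnv_segments: list[tuple[str, int, int, float, float]] = field(default_factory=list)
    orfs: list[PlantedOrf] = field(default_factory=list)
    organelle_id: str | None = None
    organelle_codes: np.ndarray | None = None
    read_origins: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return self.params.seed

    def copy_names(self) -> list[str]:
        return sorted(self.copies)

    def sequence(self, copy: str, contig_id: str) -> str:
        return codes_to_seq(self.copies[copy][contig_id])

    def recompute_het_sites(self) -> None:
        """Het sites = position-wise differences among the genome copies."""
        names = self.copy_names()
        self.het_sites = {}
        for cid in self.contig_ids:
            stacks = np.stack([self.copies[n][cid] for n in names])
            differing = np.where((stacks != stacks[0]).any(axis=0))[0]
            self.het_sites[cid] = [
                (int(pos), {n: codes_to_seq(stacks[i, pos:pos + 1])
                            for i, n in enumerate(names)})
                for pos in differing
            ]

    def het_positions(self, contig_id: str) -> np.ndarray:
        return np.array([p for p, _ in self.het_sites.get(contig_id, [])], dtype=int)

    def n_het_sites(self) -> int:
        return sum(len(v) for v in self.het_sites.values())


# ---------------------------------------------------------------------------
# generative steps
# ---------------------------------------------------------------------------

def simulate_ancestor(length: int, gc_fraction: float,
                      seed: int | np.random.Generator) -> str:
    """I.i.d. ancestral sequence with the requested GC content."""
    if length <= 0:
        raise PloidykitError("length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise PloidykitError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return codes_to_seq(codes.astype(np.uint8))


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hits = np.where(rng.random(len(codes)) < rate)[0]
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def _mutate_at(codes: np.ndarray, positions: np.ndarray,
               rng: np.random.Generator) -> None:
    codes[positions] = (codes[positions]
                        + rng.integers(1, 4, size=len(positions))) % 4


def _check_disjoint(regions: Sequence[tuple[int, int]], what: str) -> None:
    ordered = sorted(regions)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise PloidykitError(f"overlapping {what}: ({s1},{e1}) and ({s2},{e2})")


def derive_subgenomes(ancestor: str, params: SimParams,
                      rng: np.random.Generator,
                      loh_regions: Sequence[tuple[int, int]] = ()):
    """One contig's three genome copies plus its het-site list.

    copy A equals the ancestor (and plays the assembly consensus); A2 is
    substituted at ``d_sister``; B at ``d_divergent`` and then overwritten by
    A inside LOH regions.
    """
    _check_disjoint(loh_regions, "LOH regions")
    anc = seq_to_codes(ancestor)
    for s, e in loh_regions:
        if not (0 <= s < e <= len(anc)):
            raise PloidykitError(f"LOH region ({s},{e}) outside contig bounds")
    copy_a = anc.copy()
    copy_a2 = _mutate(anc, params.d_sister, rng)
    copies = {"A": copy_a, "A2": copy_a2}
    if params.triploid:
        copy_b = _mutate(anc, params.d_divergent, rng)
        for s, e in loh_regions:
            copy_b[s:e] = copy_a[s:e]
        copies["B"] = copy_b
    names = sorted(copies)
    stacks = np.stack([copies[n] for n in names])
    differing = np.where((stacks != stacks[0]).any(axis=0))[0]
    het = [(int(p), {n: codes_to_seq(stacks[i, p:p + 1])
                     for i, n in enumerate(names)})
           for p in differing]
    return copies, het


def _reserve(reserved: dict[str, list[tuple[int, int]]], cid: str,
             start: int, end: int, pad: int, length: int) -> None:
    reserved.setdefault(cid, []).append(
        (max(0, start - pad), min(length, end + pad)))


def _free_slot(rng: np.random.Generator, length: int, span: int,
               reserved: list[tuple[int, int]], margin: int,
               max_tries: int = 400) -> int | None:
    for _ in range(max_tries):
        start = int(rng.integers(margin, length - span - margin))
        if all(start + span <= s or start >= e for s, e in reserved):
            return start
    return None


def plant_features(truth: SimTruth, params: SimParams,
                   rng: np.random.Generator) -> SimTruth:
    """Plant ORFs at target het densities; register CNV segments; append organelle."""
    L = params.contig_length
    reserved: dict[str, list[tuple[int, int]]] = {}
    for idx, s, e in params.resolved_loh_regions():
        cid = params.contig_id(idx)
        if not (0 <= s < e <= L):
            raise PloidykitError(f"LOH region ({s},{e}) outside contig")
        truth.loh_regions.append((cid, s, e))
        _reserve(reserved, cid, s, e, 1500, L)
    ploidy = 3 if params.triploid else 2
    for idx, s, e, extra in params.resolved_cnv_segments():
        cid = params.contig_id(idx)
        if not (0 <= s < e <= L):
            raise PloidykitError(f"CNV segment ({s},{e}) outside contig")
        fold = (ploidy + extra) / ploidy
        fold_class = 1.5 if fold >= 1.5 else 1.25
        truth.cnv_segments.append((cid, s, e, extra, fold_class))
        _reserve(reserved, cid, s, e, 1500, L)
    _check_disjoint(
        [(s, e) for _, s, e, _, _ in truth.cnv_segments], "CNV segments")

    orf_len = params.orf_length
    n_orf = 0
    contig_cycle = 0
    for density_class, count in params.orf_density_targets:
        for _ in range(count):
            # spread ORFs across contigs round-robin, skipping full contigs
            start = None
            for attempt in range(params.n_contigs):
                cid = params.contig_id((contig_cycle + attempt) % params.n_contigs)
                start = _free_slot(rng, L, orf_len, reserved.get(cid, []),
                                   margin=1500)
                if start is not None:
                    break
            contig_cycle += 1
            if start is None:
                raise PloidykitError(
                    f"cannot place an ORF of class {density_class}; "
                    "use longer or more contigs")
            _reserve(reserved, cid, start, start + orf_len, 300, L)
            n_orf += 1
            orf = OrfModel(f"orf_{n_orf:04d}", cid, start, start + orf_len,
                           "+" if rng.random() < 0.5 else "-")
            planted = _plant_orf(truth, params, orf, density_class, rng)
            truth.orfs.append(planted)

    if params.organelle_length:
        mito_codes = seq_to_codes(simulate_ancestor(
            params.organelle_length, params.organelle_gc, rng))
        truth.organelle_id = "mito"
        truth.organelle_codes = mito_codes
    truth.recompute_het_sites()
    for planted in truth.orfs:
        o = planted.orf
        planted.n_het_sites = int(np.sum(
            (truth.het_positions(o.contig_id) >= o.start)
            & (truth.het_positions(o.contig_id) < o.end)))
        realized = planted.n_het_sites / len(o)
        if abs(realized - planted.density_class) > 0.005:
            raise PloidykitError(
                f"ORF {o.id}: realized density {realized:.4f} misses class "
                f"{planted.density_class}; use longer contigs")
    return truth


def _plant_orf(truth: SimTruth, params: SimParams, orf: OrfModel,
               density_class: float, rng: np.random.Generator) -> PlantedOrf:
    """Overwrite the ORF footprint with an exact-count variant pattern."""
    s, e = orf.start, orf.end
    n_target = int(round(density_class * len(orf)))
    anc = truth.copies["A"][orf.contig_id][s:e]
    a2 = truth.copies["A2"][orf.contig_id]
    a2[s:e] = anc                                 # clear background variants
    loh_type = (not params.triploid) or (density_class <= 2 * params.d_sister)
    if params.triploid:
        b = truth.copies["B"][orf.contig_id]
        b[s:e] = anc
    if loh_type:
        # two genuine haplotypes: divergent copy locally equals copy A,
        # sister pair drifted at the class rate
        pos = rng.choice(len(orf), size=n_target, replace=False) + s
        _mutate_at(a2, pos, rng)
    else:
        n_sis = int(round(params.d_sister * len(orf)))
        pos = rng.choice(len(orf), size=n_target, replace=False) + s
        _mutate_at(a2, pos[:n_sis], rng)
        _mutate_at(truth.copies["B"][orf.contig_id], pos[n_sis:], rng)
    haplotypes = {
        name: codes_to_seq(truth.copies[name][orf.contig_id][s:e])
        for name in truth.copy_names()
    }
    return PlantedOrf(orf, density_class, loh_type, haplotypes, n_target)


def simulate_reads(truth: SimTruth, params: SimParams,
                   rng: np.random.Generator) -> list[AlignedRead]:
    """Uniform substitution-error reads from every template copy.

    Copy of origin per read lands in ``truth.read_origins`` only.
    """
    read_len = params.read_len
    templates: list[tuple[str, str, np.ndarray, float, int]] = []
    for cid in truth.contig_ids:
        for name in truth.copy_names():
            templates.append((cid, name, truth.copies[name][cid],
                              params.per_copy_depth, 0))
    for cid, s, e, extra, _fold in truth.cnv_segments:
        templates.append((cid, "A", truth.copies["A"][cid][s:e],
                          extra * params.per_copy_depth, s))
    if truth.organelle_id is not None:
        templates.append((truth.organelle_id, "M", truth.organelle_codes,
                          params.organelle_depth, 0))

    reads: list[AlignedRead] = []
    counter = 0
    for cid, copy_name, codes, depth, offset in templates:
        span = len(codes)
        if read_len > span:
            raise PloidykitError(
                f"read_len {read_len} exceeds template length {span} on {cid}")
        n_starts = span - read_len + 1
        n_reads = int(round(depth * n_starts / read_len))
        starts = rng.integers(0, n_starts, size=n_reads)
        n_err = rng.binomial(read_len, params.err_rate, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            start = int(starts[i])
            seq_codes = codes[start:start + read_len]
            if n_err[i]:
                seq_codes = seq_codes.copy()
                err_pos = rng.choice(read_len, size=n_err[i], replace=False)
                _mutate_at(seq_codes, err_pos, rng)
            counter += 1
            read_id = f"read_{counter:06d}"
            reads.append(AlignedRead(
                read_id, cid, offset + start,
                "-" if strands[i] else "+", codes_to_seq(seq_codes)))
            truth.read_origins[read_id] = (copy_name, cid, offset + start)
    return reads


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def simulate(params: SimParams):
    """Full simulation: returns (assembly, reads, orfs, truth).

    The pipeline-facing assembly consensus is genome copy A plus the
    organelle contig; everything else lives only in the truth object.
    """
    rng = np.random.default_rng(params.seed)
    contig_ids = [params.contig_id(i) for i in range(params.n_contigs)]
    loh_by_contig: dict[str, list[tuple[int, int]]] = {}
    for idx, s, e in params.resolved_loh_regions():
        loh_by_contig.setdefault(params.contig_id(idx), []).append((s, e))

    copies: dict[str, dict[str, np.ndarray]] = {}
    for cid in contig_ids:
        ancestor = simulate_ancestor(params.contig_length, params.gc_fraction, rng)
        contig_copies, _ = derive_subgenomes(
            ancestor, params, rng, loh_by_contig.get(cid, []))
        for name, codes in contig_copies.items():
            copies.setdefault(name, {})[cid] = codes

    truth = SimTruth(params=params, contig_ids=contig_ids, copies=copies)
    truth = plant_features(truth, params, rng)
    reads = simulate_reads(truth, params, rng)

    contigs = [
        Contig(cid, truth.sequence("A", cid), f"scf_{i // 3:02d}", i % 3)
        for i, cid in enumerate(contig_ids)
    ]
    organelle_ids = []
    if truth.organelle_id is not None:
        contigs.append(Contig(truth.organelle_id,
                              codes_to_seq(truth.organelle_codes),
                              "scf_mito", 0))
        organelle_ids.append(truth.organelle_id)
    assembly = Assembly(contigs, organelle_ids=organelle_ids)
    orfs = [p.orf for p in truth.orfs]
    return assembly, reads, orfs, truth


def truth_to_report(truth: SimTruth) -> dict:
    """JSON-safe dump of the full ground truth (copies, variants, origins)."""
    return {
        "seed": truth.seed,
        "params": params_to_dict(truth.params),
        "copies": {
            name: {cid: truth.sequence(name, cid) for cid in truth.contig_ids}
            for name in truth.copy_names()
        },
        "het_sites": {
            cid: [[pos, alleles] for pos, alleles in sites]
            for cid, sites in truth.het_sites.items()
        },
        "loh_regions": [list(r) for r in truth.loh_regions],
        "cnv_segments": [list(r) for r in truth.cnv_segments],
        "orfs": [
            {
                "id": p.orf.id, "contig": p.orf.contig_id,
                "start": p.orf.start, "end": p.orf.end,
                "strand": p.orf.strand,
                "density_class": p.density_class,
                "loh_type": p.loh_type,
                "n_het_sites": p.n_het_sites,
                "haplotypes": p.haplotypes,
            }
            for p in truth.orfs
        ],
        "organelle": truth.organelle_id,
        "read_origins": {
            rid: list(origin) for rid, origin in truth.read_origins.items()
        },
    }


def write_simulation(outdir: str | Path, assembly: Assembly,
                     reads: list[AlignedRead], orfs: list[OrfModel],
                     truth: SimTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"seed={truth.seed}", f"params={params_to_dict(truth.params)}"]
    write_fasta(assembly, outdir / "genome.fasta")
    write_scaffold_map(assembly, outdir / "scaffolds.tsv")
    write_sam(reads, assembly, outdir / "reads.sam")
    write_alignment_tsv(reads, outdir / "alignments.tsv", header_lines=header)
    write_orfs_gff3(orfs, outdir / "orfs.gff3", header_lines=header)
    write_report(truth_to_report(truth), outdir / "truth.json")
    write_report({"params": params_to_dict(truth.params),
                  "seed": truth.seed}, outdir / "params.json")
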