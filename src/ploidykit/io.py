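"""Readers, writers and domain containers for the on-disk formats.

Internal coordinates are 0-based half-open everywhere.  Conversions happen
only at format boundaries: SAM positions are 1-based, GFF3 intervals are
1-based inclusive, BED output is 0-based half-open.  All writers emit a
commented (``#``) header echoing the parameters and seed of the producing
run so every artifact is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
ALIGNED_ALPHABET = DNA_ALPHABET | {"-"}

SCHEMA_VERSION = "1.0"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PloidykitError(ValueError):
    """Base class for input-validation failures."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A named assembly sequence with its scaffold placement."""

    id: str
    sequence: str
    scaffold_id: str
    index_in_scaffold: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PloidykitError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise PloidykitError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.index_in_scaffold < 0:
            raise PloidykitError(f"contig {self.id!r}: negative scaffold index")

    def __len__(self) -> int:
        return len(self.sequence)


class Assembly:
    """Ordered contigs plus the genomic/organelle partition."""

    def __init__(self, contigs: Sequence[Contig],
                 organelle_ids: Iterable[str] = ()) -> None:
        self.contigs = list(contigs)
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PloidykitError(f"duplicate contig ids: {dupes}")
        placements = [(c.scaffold_id, c.index_in_scaffold) for c in self.contigs]
        if len(set(placements)) != len(placements):
            raise PloidykitError("duplicate (scaffold_id, index_in_scaffold)")
        self.organelle_ids = set(organelle_ids)
        unknown = self.organelle_ids - set(ids)
        if unknown:
            raise PloidykitError(f"organelle ids not in assembly: {sorted(unknown)}")
        self._by_id = {c.id: c for c in self.contigs}

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def genomic_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.id not in self.organelle_ids]

    def total_length(self, include_organelle: bool = False) -> int:
        contigs = self.contigs if include_organelle else self.genomic_contigs()
        return sum(len(c) for c in contigs)

    def n50(self) -> int:
        """N50 of the genomic contigs (bp)."""
        lengths = sorted((len(c) for c in self.genomic_contigs()), reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for n in lengths:
            acc += n
            if acc >= half:
                return n
        return 0


@dataclass
class AlignedRead:
    """A read placed on the assembly, projected onto reference coordinates.

    ``aligned_seq`` has insertions dropped and deletions rendered as ``-``,
    so ``len(aligned_seq)`` is the reference span of the alignment.
    """

    read_id: str
    contig_id: str
    start: int
    strand: str
    aligned_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.aligned_seq)


@dataclass
class OrfModel:
    """An open reading frame on a contig; [start, end) 0-based half-open."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        length = self.end - self.start
        if length <= 0:
            raise PloidykitError(f"ORF {self.id!r}: empty interval")
        if length % 3:
            raise PloidykitError(
                f"ORF {self.id!r}: length {length} not divisible by 3"
            )
        if self.strand not in "+-":
            raise PloidykitError(f"ORF {self.id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_scaffold_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """TSV with columns contig_id, scaffold_id, index_in_scaffold."""
    frame = pd.read_csv(path, sep="\t", comment="#",
                        names=["contig_id", "scaffold_id", "index_in_scaffold"],
                        dtype={"contig_id": str, "scaffold_id": str})
    return {
        r.contig_id: (r.scaffold_id, int(r.index_in_scaffold))
        for r in frame.itertuples()
    }


def read_fasta(path: str | Path, scaffold_map: str | Path | dict | None = None,
               organelle_ids: Iterable[str] = ()) -> Assembly:
    """Load an assembly FASTA.

    Scaffold membership comes from ``scaffold_map`` (TSV path or dict) when
    given; otherwise a ``scaffold=NAME`` token in the record description is
    honoured, and failing that each contig is its own scaffold.
    """
    if scaffold_map is not None and not isinstance(scaffold_map, dict):
        scaffold_map = read_scaffold_map(scaffold_map)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PloidykitError(f"{path}: empty or not FASTA")
    contigs = []
    per_scaffold_counter: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise PloidykitError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)!r}"
            )
        if scaffold_map is not None:
            if rec.id not in scaffold_map:
                raise PloidykitError(f"scaffold map missing contig {rec.id!r}")
            scaffold_id, idx = scaffold_map[rec.id]
        else:
            scaffold_id = rec.id
            for token in rec.description.split():
                if token.startswith("scaffold="):
                    scaffold_id = token.split("=", 1)[1]
            idx = per_scaffold_counter.get(scaffold_id, 0)
            per_scaffold_counter[scaffold_id] = idx + 1
        contigs.append(Contig(rec.id, seq, scaffold_id, idx))
    return Assembly(contigs, organelle_ids=organelle_ids)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id,
                  description=f"scaffold={c.scaffold_id}")
        for c in assembly
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def write_scaffold_map(assembly: Assembly, path: str | Path) -> None:
    with open(path, "w") as handle:
        for c in assembly:
            handle.write(f"{c.id}\t{c.scaffold_id}\t{c.index_in_scaffold}\n")


# ---------------------------------------------------------------------------
# alignments: minimal SAM subset + simulator-native TSV
# ---------------------------------------------------------------------------

_SUPPORTED_CIGAR = {0, 1, 2, 4, 7, 8}  # M, I, D, S, =, X (pysam op codes)
_CIGAR_NAMES = {3: "N", 5: "H", 6: "P"}

TSV_ALIGNMENT_COLUMNS = ["read_id", "contig_id", "start", "strand", "aligned_seq"]


def project_alignment(query: str, cigartuples: Sequence[tuple[int, int]],
                      read_id: str = "?") -> str:
    """Project a query sequence onto reference coordinates.

    M/=/X consume both; I and S consume query only (dropped); D consumes
    reference only (gap characters).  N, H and P are refused.
    """
    out = []
    qpos = 0
    for op, n in cigartuples:
        if op in (0, 7, 8):          # M, =, X
            out.append(query[qpos:qpos + n])
            qpos += n
        elif op in (1, 4):           # I, S
            qpos += n
        elif op == 2:                # D
            out.append("-" * n)
        else:
            raise PloidykitError(
                f"read {read_id!r}: unsupported CIGAR op "
                f"{_CIGAR_NAMES.get(op, op)!r}"
            )
    return "".join(out)


def _read_sam(path: str | Path, assembly: Assembly) -> list[AlignedRead]:
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            contig_id = rec.reference_name
            if contig_id not in assembly:
                raise PloidykitError(
                    f"read {rec.query_name!r}: unknown contig {contig_id!r}"
                )
            aligned = project_alignment(
                rec.query_sequence or "", rec.cigartuples or [], rec.query_name
            ).upper()
            read = AlignedRead(
                read_id=rec.query_name,
                contig_id=contig_id,
                start=rec.reference_start,       # pysam is already 0-based
                strand="-" if rec.is_reverse else "+",
                aligned_seq=aligned,
            )
            if read.end > len(assembly[contig_id]):
                raise PloidykitError(
                    f"read {rec.query_name!r}: alignment exceeds contig "
                    f"{contig_id!r} length"
                )
            reads.append(read)
    return reads


def _read_alignment_tsv(path: str | Path, assembly: Assembly) -> list[AlignedRead]:
    frame = pd.read_csv(path, sep="\t", comment="#",
                        names=TSV_ALIGNMENT_COLUMNS,
                        dtype={"read_id": str, "contig_id": str, "start": int,
                               "strand": str, "aligned_seq": str})
    reads = []
    for r in frame.itertuples():
        if r.contig_id not in assembly:
            raise PloidykitError(
                f"read {r.read_id!r}: unknown contig {r.contig_id!r}"
            )
        read = AlignedRead(r.read_id, r.contig_id, int(r.start), r.strand,
                           r.aligned_seq.upper())
        bad = set(read.aligned_seq) - ALIGNED_ALPHABET
        if bad:
            raise PloidykitError(
                f"read {r.read_id!r}: bad characters {sorted(bad)!r}"
            )
        if read.end > len(assembly[r.contig_id]):
            raise PloidykitError(
                f"read {r.read_id!r}: alignment exceeds contig bounds"
            )
        reads.append(read)
    return reads


def read_alignments(path: str | Path, assembly: Assembly) -> list[AlignedRead]:
    """Read placed reads from a SAM file or the simulator's alignment TSV.

    Format is sniffed: a leading ``@`` or a ``.sam`` suffix means SAM.
    """
    path = Path(path)
    if path.suffix == ".sam":
        return _read_sam(path, assembly)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("@"):
        return _read_sam(path, assembly)
    return _read_alignment_tsv(path, assembly)


def write_alignment_tsv(reads: Iterable[AlignedRead], path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        for r in reads:
            handle.write(
                f"{r.read_id}\t{r.contig_id}\t{r.start}\t{r.strand}\t{r.aligned_seq}\n"
            )


def write_sam(reads: Iterable[AlignedRead], assembly: Assembly,
              path: str | Path) -> None:
    """Write reads as minimal SAM (substitution-only reads: CIGAR is all M)."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in assembly:
            handle.write(f"@SQ\tSN:{c.id}\tLN:{len(c)}\n")
        for r in reads:
            flag = 16 if r.strand == "-" else 0
            seq = r.aligned_seq.replace("-", "")
            cigar = f"{len(r.aligned_seq)}M" if "-" not in r.aligned_seq else \
                _gapped_cigar(r.aligned_seq)
            handle.write(
                f"{r.read_id}\t{flag}\t{r.contig_id}\t{r.start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def _gapped_cigar(aligned_seq: str) -> str:
    parts = []
    run_op, run_len = None, 0
    for ch in aligned_seq:
        op = "D" if ch == "-" else "M"
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                parts.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    parts.append(f"{run_len}{run_op}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# GFF3 (ORF models)
# ---------------------------------------------------------------------------

def read_orfs_gff3(path: str | Path, assembly: Assembly | None = None) -> list[OrfModel]:
    """Read ORF models from GFF3 (1-based inclusive -> 0-based half-open)."""
    orfs = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise PloidykitError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "CDS", "ORF", "open_reading_frame"):
                continue
            orf_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    orf_id = kv[3:]
            if orf_id is None:
                raise PloidykitError(f"{path}:{lineno}: feature without ID")
            start = int(start1) - 1
            end = int(end1)
            if assembly is not None:
                if seqid not in assembly:
                    raise PloidykitError(
                        f"{path}:{lineno}: unknown contig {seqid!r}"
                    )
                if end > len(assembly[seqid]):
                    raise PloidykitError(
                        f"{path}:{lineno}: ORF {orf_id!r} exceeds contig bounds"
                    )
            orfs.append(OrfModel(orf_id, seqid, start, end, strand))
    return orfs


def write_orfs_gff3(orfs: Iterable[OrfModel], path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for line in header_lines:
            handle.write(f"# {line}\n")
        for o in orfs:
            handle.write(
                f"{o.contig_id}\tploidykit\tORF\t{o.start + 1}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.id}\n"
            )


# ---------------------------------------------------------------------------
# tracks, CNV calls, reports
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["contig", "window_start", "window_end", "center",
                 "snp_per_10kb", "median_cov", "log2_ratio"]


def write_tracks(windows, path: str | Path,
                 header_lines: Sequence[str] = ()) -> None:
    """Windowed track TSV; ``windows`` is a sequence of WindowRecord."""
    rows = [
        (w.contig_id, w.start, w.end, w.center,
         _fmt(w.snp_per_10kb), _fmt(w.median_cov), _fmt(w.log2_ratio))
        for w in windows
    ]
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write("\t".join(TRACK_COLUMNS) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def _fmt(value) -> str:
    if value is None:
        return "NA"
    return f"{value:.6g}"


def read_tracks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_cnv_bed(calls, path: str | Path,
                  header_lines: Sequence[str] = ()) -> None:
    """BED (0-based half-open): name = direction_foldclass, score ~ |log2 ratio|."""
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        for call in calls:
            import math
            score = min(1000, int(round(abs(math.log2(call.median_ratio)) * 500)))
            name = f"{call.direction}_{call.fold_class}x"
            handle.write(
                f"{call.contig_id}\t{call.start}\t{call.end}\t{name}\t{score}\n"
            )


def write_report(report: dict, path: str | Path) -> None:
    report = dict(report)
    report.setdefault("schema_version", SCHEMA_VERSION)
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def params_to_dict(params) -> dict:
    """Dataclass -> JSON-safe dict (tuples become lists)."""
    if dataclasses.is_dataclass(params):
        return json.loads(json.dumps(dataclasses.asdict(params)))
    return dict(params)
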