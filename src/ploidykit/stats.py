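"""Ploidy statistics: the Pearson independence test on haplotype counts,
synonymous/non-synonymous SNP classification, completeness and annotation
arithmetic, and the final ploidy-model report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats as sps

from .io import Assembly, OrfModel, PloidykitError, revcomp
from .pileup import SnpSite
from .haplotypes import HaplotypeResolution

logger = logging.getLogger("ploidykit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = "*"
    return code


STANDARD_CODE = _standard_code()


# ---------------------------------------------------------------------------
# contingency table and chi-square
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    row_labels: list          # density classes, ascending
    col_labels: list          # haplotype bins
    counts: np.ndarray        # shape (rows, cols), non-negative ints
    excluded: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise PloidykitError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise PloidykitError("negative counts")
        if self.counts.sum() <= 0:
            raise PloidykitError("empty contingency table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency_table(resolutions: Sequence[HaplotypeResolution],
                      classes: Sequence[float]) -> ContingencyTable:
    """Counts of two- vs three-haplotype resolutions per density class.

    Resolutions with one haplotype or more than three are excluded from the
    table; their counts are retained on the result for reporting.
    """
    if not resolutions:
        raise PloidykitError("no haplotype resolutions supplied")
    classes = sorted(classes)
    counts = np.zeros((len(classes), 2), dtype=int)
    excluded: dict[str, int] = {}
    for r in resolutions:
        if r.density_class not in classes:
            excluded["unclassed"] = excluded.get("unclassed", 0) + 1
            continue
        row = classes.index(r.density_class)
        if r.n_haplotypes == 2:
            counts[row, 0] += 1
        elif r.n_haplotypes == 3:
            counts[row, 1] += 1
        else:
            key = f"n={r.n_haplotypes}"
            excluded[key] = excluded.get(key, 0) + 1
    if excluded:
        logger.info("contingency table exclusions: %s", excluded)
    return ContingencyTable(list(classes), ["2_haplotypes", "3_haplotypes"],
                            counts, excluded)


def collapse_low_density(table: ContingencyTable,
                         low_class=None) -> ContingencyTable:
    """2x2 collapse: the lowest density class against all others pooled."""
    low = table.row_labels[0] if low_class is None else low_class
    idx = table.row_labels.index(low)
    other = np.delete(table.counts, idx, axis=0).sum(axis=0)
    counts = np.stack([table.counts[idx], other])
    return ContingencyTable([low, "other"], list(table.col_labels), counts)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)


def pearson_independence(table: ContingencyTable,
                         yates: bool = False) -> ChiSquareResult:
    """Uncorrected Pearson chi-square test of independence.

    E_ij = row_i * col_j / N; X^2 = sum (O-E)^2/E over cells with E > 0;
    the p-value is the upper tail of the chi-square distribution with
    (r-1)(c-1) degrees of freedom.  Zero rows/columns are dropped with a
    warning; an optional Yates continuity correction is available for 2x2.
    """
    counts = table.counts.astype(float)
    row_labels, col_labels = list(table.row_labels), list(table.col_labels)
    dropped_rows = [row_labels[i] for i in np.nonzero(counts.sum(1) == 0)[0]]
    dropped_cols = [col_labels[j] for j in np.nonzero(counts.sum(0) == 0)[0]]
    if dropped_rows or dropped_cols:
        logger.warning("dropping empty rows/cols: %s %s",
                       dropped_rows, dropped_cols)
        counts = counts[counts.sum(1) > 0][:, counts.sum(0) > 0]
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise PloidykitError("table degenerate after dropping empty margins")
    n = counts.sum()
    expected = np.outer(counts.sum(1), counts.sum(0)) / n
    diff = np.abs(counts - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, diff ** 2 / expected, 0.0)
    statistic = float(cells.sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p_value = float(sps.chi2.sf(statistic, df))
    return ChiSquareResult(statistic, df, p_value, expected,
                           bool((expected < 5).any()), dropped_rows,
                           dropped_cols)


# ---------------------------------------------------------------------------
# synonymous / non-synonymous classification
# ---------------------------------------------------------------------------

@dataclass
class SynNonsynCounts:
    orf_id: str
    n_syn: int
    n_nonsyn: int
    n_coding_sites: int
    fraction_nonsyn_of_orf_nt: float
    n_stop_gained: int = 0
    n_multiallelic: int = 0


def classify_coding_snps(orf: OrfModel, assembly: Assembly,
                         het_sites: Sequence[SnpSite],
                         genetic_code: Mapping[str, str] = STANDARD_CODE,
                         min_minor_fraction: float = 0.15) -> SynNonsynCounts:
    """Classify each het site inside an ORF as synonymous or non-synonymous.

    The site's minor allele is substituted into its reference codon in the
    strand-resolved reading frame; a site is synonymous iff the translations
    are equal.  Stop-gained changes count as non-synonymous and are flagged;
    a site with more than one qualifying minor allele counts once, as
    non-synonymous if any substitution is non-synonymous.
    """
    seq = assembly[orf.contig_id].sequence[orf.start:orf.end]
    if orf.strand == "-":
        seq = revcomp(seq)
    n_syn = n_nonsyn = n_stop = n_multi = 0
    for site in het_sites:
        if site.contig_id != orf.contig_id or not \
                (orf.start <= site.pos < orf.end):
            continue
        minors = [b for b, f in site.minor_alleles if f >= min_minor_fraction]
        if not minors:
            continue
        if len(minors) > 1:
            n_multi += 1
        off = site.pos - orf.start
        if orf.strand == "-":
            off = len(orf) - 1 - off
            minors = [b.translate(_COMPLEMENT) for b in minors]
        codon_start = (off // 3) * 3
        within = off - codon_start
        ref_codon = seq[codon_start:codon_start + 3]
        ref_aa = genetic_code[ref_codon]
        any_nonsyn = any_stop = False
        for minor in minors:
            alt_codon = ref_codon[:within] + minor + ref_codon[within + 1:]
            if alt_codon == ref_codon:
                continue
            alt_aa = genetic_code[alt_codon]
            if alt_aa != ref_aa:
                any_nonsyn = True
                if alt_aa == "*":
                    any_stop = True
        if any_nonsyn:
            n_nonsyn += 1
            n_stop += int(any_stop)
        else:
            n_syn += 1
    n_sites = n_syn + n_nonsyn
    return SynNonsynCounts(orf.id, n_syn, n_nonsyn, n_sites,
                           n_nonsyn / len(orf), n_stop, n_multi)


def classify_all_orfs(orfs: Sequence[OrfModel], assembly: Assembly,
                      snps: Sequence[SnpSite],
                      **kwargs) -> tuple[list[SynNonsynCounts], dict]:
    by_contig: dict[str, list[SnpSite]] = {}
    for s in snps:
        by_contig.setdefault(s.contig_id, []).append(s)
    per_orf = [classify_coding_snps(o, assembly, by_contig.get(o.contig_id, []),
                                    **kwargs) for o in orfs]
    total_nt = sum(len(o) for o in orfs)
    total_nonsyn = sum(c.n_nonsyn for c in per_orf)
    total_syn = sum(c.n_syn for c in per_orf)
    summary = {
        "n_orfs": len(orfs),
        "n_syn": total_syn,
        "n_nonsyn": total_nonsyn,
        "pct_nonsyn_of_orf_nt": round(100.0 * total_nonsyn / total_nt, 2)
        if total_nt else 0.0,
        "pct_syn_of_classified": round(
            100.0 * total_syn / max(total_syn + total_nonsyn, 1), 1),
    }
    return per_orf, summary


# ---------------------------------------------------------------------------
# completeness and annotation arithmetic
# ---------------------------------------------------------------------------

@dataclass
class CegAccounting:
    """Core-gene completeness bookkeeping against a reference set of
    widely conserved proteins (248 by convention)."""

    n_total: int = 248
    n_orf_hits: int = 0
    n_scaffold_hits: int = 0
    n_ortholog_confirmed: int = 0
    n_partial: int = 0

    def __post_init__(self) -> None:
        accounted = (self.n_orf_hits + self.n_scaffold_hits
                     + self.n_ortholog_confirmed + self.n_partial)
        if accounted > self.n_total:
            raise PloidykitError("accounted CEGs exceed the reference total")
        if min(self.n_total, self.n_orf_hits, self.n_scaffold_hits,
               self.n_ortholog_confirmed, self.n_partial) < 0:
            raise PloidykitError("negative CEG counts")


def ceg_completeness(accounting: CegAccounting) -> int:
    """Percent of the core set accounted for (ORF hits + scaffold hits +
    ortholog-confirmed), rounded to the nearest integer."""
    found = (accounting.n_orf_hits + accounting.n_scaffold_hits
             + accounting.n_ortholog_confirmed)
    return int(round(100.0 * found / accounting.n_total))


def annotation_fractions(n_orphan: int, n_models: int) -> float:
    """Orphan-model percentage, rounded to one decimal."""
    if not 0 <= n_orphan <= n_models:
        raise PloidykitError("need 0 <= n_orphan <= n_models")
    return round(100.0 * n_orphan / n_models, 1)


# ---------------------------------------------------------------------------
# ploidy verdict and report
# ---------------------------------------------------------------------------

@dataclass
class VerdictParams:
    """Decision thresholds for the hybrid-triploid pattern."""

    min_sister_identity: float = 98.0
    max_divergent_identity: float = 97.0
    min_three_haplotype_fraction: float = 0.5


def ploidy_verdict(resolutions: Sequence[HaplotypeResolution],
                   params: VerdictParams = VerdictParams()) -> dict:
    """Decide whether the sister-pair/divergent identity pattern and the
    three-haplotype prevalence support a hybrid-triploid genome model."""
    three = [r for r in resolutions if r.n_haplotypes == 3]
    two = [r for r in resolutions if r.n_haplotypes == 2]
    binned = len(three) + len(two)
    frac3 = len(three) / binned if binned else 0.0
    sister = [r.sister_identity for r in three if r.sister_identity is not None]
    divergent = [v for r in three for v in r.divergent_identities]
    median_sister = float(np.median(sister)) if sister else None
    median_divergent = float(np.median(divergent)) if divergent else None
    supported = (
        median_sister is not None and median_divergent is not None
        and median_sister >= params.min_sister_identity
        and median_divergent <= params.max_divergent_identity
        and frac3 >= params.min_three_haplotype_fraction
    )
    return {
        "triploid_hybrid_pattern": "yes" if supported else "no",
        "median_sister_identity": median_sister,
        "median_divergent_identity": median_divergent,
        "three_haplotype_fraction": frac3,
        "n_three_haplotype": len(three),
        "n_two_haplotype": len(two),
        "n_binned": binned,
        "thresholds": {
            "min_sister_identity": params.min_sister_identity,
            "max_divergent_identity": params.max_divergent_identity,
            "min_three_haplotype_fraction": params.min_three_haplotype_fraction,
        },
    }


def resolution_summary(r: HaplotypeResolution) -> dict:
    return {
        "orf_id": r.orf_id,
        "density_class": r.density_class,
        "n_haplotypes": r.n_haplotypes,
        "identities": {k: round(v, 3) for k, v in sorted(r.identities.items())},
        "read_counts": dict(sorted(r.read_counts.items())),
        "flags": list(r.flags),
    }


def chi_square_summary(result: ChiSquareResult, table: ContingencyTable) -> dict:
    return {
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
        "counts": table.counts.astype(int).tolist(),
        "row_labels": [str(x) for x in table.row_labels],
        "col_labels": [str(x) for x in table.col_labels],
        "expected": np.round(result.expected, 3).tolist(),
        "low_expected_warning": result.low_expected_warning,
        "excluded": dict(table.excluded),
    }
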