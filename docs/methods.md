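# Methods

## The inference problem

A de-novo assembly of a heterozygous genome collapses homologous genome
copies onto a single consensus.  When the copies are unequally diverged —
a sister pair at ~99% identity plus a third copy at ~95% — the collapsed
assembly shows (i) a high and spatially structured density of heterozygous
sites, (ii) loci where reads separate into three distinct local sequences,
two similar and one divergent, and (iii) regions of collapsed density
where the divergent copy has been replaced by the sister subgenome (loss
of heterozygosity, LOH).  `ploidykit` formalises the chain of evidence for
that triploid-hybrid interpretation: windowed SNP-density and coverage
tracks, a run-based CNV/aneuploidy screen, ORF-level read-backed phasing
with sister/divergent labelling, an independence test of density class
versus haplotype count, and summary accounting (organelle copy number,
core-gene completeness, orphan fraction).

Assumptions: reads are already placed on the assembly (no alignment is
performed); substitution variation dominates (indels are not called);
copies are sampled evenly by sequencing, so copy number is proportional to
depth; the assembly consensus is close to one genome copy at every locus.

## Synthetic data: what the generator emulates

`simulate.SimParams` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_contigs` x `contig_length` | 12 x 100 kb | genomic contigs (1.2 Mb total), 4 scaffolds of 3 |
| `d_sister` | 0.01 | substitutions/bp between sister copies A and A2 |
| `d_divergent` | 0.05 | substitutions/bp of the haploid copy B vs the ancestor |
| `gc_fraction` | 0.40 | i.i.d. ancestor composition |
| `loh_regions` | one 20 kb region | copy B overwritten by copy A position-wise |
| `cnv_segments` | 16 kb at +1.0 copy; 16 kb at +1.65 copies | realised in read space only (4/3- and ~1.55-fold) |
| `orf_density_targets` | 24 ORFs each at 2%, 4%, 6% | 999 bp ORFs planted at exact het-site counts |
| `per_copy_depth` | 8.7 | per genome copy; 3 x 8.7 ≈ 26x total |
| `read_len`, `err_rate` | 345 bp, 0.005 | uniform substitution-error reads |
| `organelle_length`, `organelle_depth` | 20 kb, 225x | single AT-rich (GC 0.25) organelle contig |

The pipeline-facing assembly consensus is copy A plus the organelle
contig; every read's copy of origin is recorded in the truth object only.

ORF density classes are realised mechanistically, not by rescaling both
divergences: the 6% class carries the genome-wide rates (sister 1% +
divergent 5%), the 4% class sister 1% + divergent 3% (a locally conserved
divergent copy), and the 2% class is an LOH-type locus — the divergent
copy equals copy A over the ORF and the sister pair drifts at 2%, so only
two distinct haplotypes genuinely exist there.  This choice keeps the
sister pair at 99% identity in every class, puts the divergent identity at
95% exactly where the genome-wide rates apply, and makes low-density loci
intrinsically two-haplotype — the mechanism behind the observation that
three haplotypes are less often resolvable at 2% density.  A fraction of
total length in LOH (the default single region is ~1.7%) is a free
parameter with no published value.

CNV segments are realised as extra read-space copies of a copy-A segment
(fractional `extra_copies` allowed), so the screen sees elevated coverage
over an unchanged reference.  The 1.5-fold-class default plants +1.65
copies (fold 1.55) so the planted segment sits inside the 1.5 class
rather than exactly on its decision boundary.

Not emulated: indels and homopolymer errors, paired-end structure,
GC-coverage bias, chimeric reads, repeat families.  Passing tests
therefore demonstrate correct recovery of substitution-dominated ploidy
signals at ~26x, not robustness to alignment artefacts or systematic
coverage bias in real sequencing data.

## Het-site calling

A site is called when depth ≥ `min_depth` (8) and the second-most-frequent
base is at least `min_minor_fraction` of the depth.  The default fraction
is 0.15: a one-of-three-copies allele has count ~ Binomial(D, 1/3), and at
D ≈ 20–30 the probability of clearing 0.15 is 0.98–0.99, while a 0.5%
per-base error rate needs four identical errors at one site to reach it
(probability ~1e-7 per site), so recall ≥ 0.95 at ≥ 20x coexists with
precision ≈ 1.  Thresholds of 0.25 (conservative triploid) and 0.50
(diploid-style consensus export) are presets; 0.25 costs ~18% of singleton
alleles at 26x, which is why it is not the default.  Ties for the major
allele break alphabetically; multi-allelic sites count once toward
density.

## Windows, LOH and CNV screens

Windows are left-anchored at multiples of the step (1001 bp window, 100 bp
step; odd window so the centre base is integral); sequence shorter than
one window is unwindowed, and windows never span contig boundaries.
Density is called sites per 10 kb; coverage is the within-window median of
per-base depth; log2 ratios are taken to the median per-base depth over
all non-organelle contigs.  Zero-coverage windows carry a sentinel and are
excluded from runs.

The LOH screen flags maximal runs of ≥ `min_windows` (50) consecutive
windows below `rel_threshold` (1/3) of the genome-median density.

The CNV screen classifies a window as elevated/depressed at the
symmetric fold `entry_fold` (1.125) relative to the genomic median, forms
maximal same-direction runs allowing interior interruptions of at most
`max_gap` (10) windows — never extending the ends and never crossing an
opposite-direction window — and calls a run when it has ≥ `min_run` (101)
qualifying windows *and* its median ratio clears the lowest fold class
(1.25); the class is upgraded to 1.5 when the run median clears it.  The
entry/gap softening exists because window medians of integer depth are
coarse: at 26x a genuine 4/3-fold segment (median ≈ 34.7 vs a 32.5
threshold) throws ~9% of windows and occasional ~700 bp stretches under a
strict per-window 1.25 test, fragmenting runs below the 101-window
minimum.  `entry_fold=1.25, max_gap=0` restores the strict per-window
screen.  Organelle contigs are excluded from the genomic median and from
run calling; their copy number is reported as the depth ratio rounded to
the nearest integer (ties half up).  Organelle contigs are taken from a
user flag when given, else flagged heuristically (depth ratio > 4 and AT
fraction > 0.65).

## ORF sampling and phasing

ORF SNP density is the count of called sites in [start, end) divided by
ORF length.  Sampling draws `n_per_class` (20) ORFs per density class
within ± 0.005, without replacement, deterministically under the sampling
seed; an underpopulated class is an error naming the class and the count.

Phasing is a deterministic greedy agglomeration over the called het sites
inside one ORF.  A read participates if it covers ≥ `min_sites_per_read`
(2) sites with alleles among the called allele set of each site (a read
base that is not a called allele — almost always a sequencing error —
leaves that site undefined for the read rather than fabricating a
conflict).  Clusters carry per-site allele counts; their consensus is the
per-site majority with alphabetical tie-break.  Three stages, each greedy
on the pair with the most shared agreeing consensus sites (ties: larger
combined read count, then an order-free lexicographic key, which makes the
result invariant to read input order):

1. **strict** — any consensus disagreement at a shared site blocks a merge;
2. **tolerant** — a disagreeing site is excused when the pooled minority
   support is ≤ `max_conflict_reads` (1) against a majority of ≥
   `min_majority_reads` (3): one stray read (an error landing on a real
   allele) cannot hold clusters apart once the evidence is clear, while
   genuine haplotype differences — several reads on each side — always
   conflict.  Running strict first matters: established clusters already
   cover their span broadly, so sister-discriminating sites are backed by
   multiple reads before any tolerance applies;
3. **link** — clusters sharing no covered site (unlinked phase blocks of
   one copy, e.g. across a between-site gap longer than a read) are
   joined, established clusters only, so the haplotype count reflects
   distinct local sequences rather than phase blocks.

Clusters with fewer than `min_reads_per_haplotype` (3) reads are
discarded; an ORF with no het sites is a single haplotype by definition.
`max_conflict_reads=0` recovers the fully strict rule.

Consensus sequences substitute cluster alleles into the reference over the
ORF; uncovered het sites keep the reference base and are flagged.
Pairwise identity is percent matching positions.  For three haplotypes the
most similar pair is labelled {h1, h2} (h1 the lexicographically smaller
sequence) and the remainder h3; ties break by summed read support, then
sequence order.  Observed counts above three are reported as observed and
binned out of the 2-vs-3 contingency table.

## Statistics

The independence test is the uncorrected Pearson chi-square on the
class x {2,3} table (E = row x col / N; p from the upper tail of the
chi-square distribution with (r−1)(c−1) df), with zero margins dropped
with a warning, a low-expected-count flag below 5, an optional Yates
correction, and a 2x2 collapse of the lowest class against the rest
reported alongside the full table.  Coding het sites are classified by
substituting the minor allele into its strand-resolved reference codon
under the standard genetic code (injectable); stop-gained changes count
as non-synonymous and are flagged; multi-allelic sites count once, as
non-synonymous if any substitution is.  Completeness is
100 x (ORF hits + scaffold hits + ortholog-confirmed)/total rounded to an
integer; the orphan fraction is rounded to one decimal — fixed rounding
so the worked examples are exact.

The verdict declares the triploid-hybrid pattern when, over resolved
ORFs, median sister identity ≥ 98%, median divergent identity ≤ 97%, and
≥ 50% of 2-or-3-resolved ORFs give three haplotypes; thresholds are
echoed in every report.

## Contig reduction

Small contigs (< `size_cutoff`, default 5000 bp — deliberately a required,
logged choice with no canonical value) are paired with large contigs by
reciprocal best hit under an internal seed-and-extend search: exact
12-mers vote for a diagonal band (width from `max_gaps_per_kb`), the best
band is extended with a gapped alignment, and the hit is scored with unit
match, −1 mismatch, gap open 0.0 and gap extend 0.7 per base, filtered at
≥ 80% identity, ≥ 100 bp aligned, ≤ 70 gaps/kb and score ≥ `min_score`
(50) — the score gate standing in for an external E-value cutoff.  The
gapped extension reuses the edlib alignment path; scoring, seeding,
banding, reciprocity and merging are native.  Merging is large-priority:
the large contig's bases win everywhere, the small contig contributes only
overhangs beyond the large's ends; unmerged smalls retry in reverse
complement; passes repeat to a fixed point, which makes `merge_pass`
idempotent and total length non-increasing.

## Numerical and reproducibility choices

All internal coordinates are 0-based half-open; SAM (1-based) and GFF3
(1-based inclusive) convert at the format boundary; BED output is 0-based
half-open.  One run seed threads the simulator and the ORF sampler; no
output embeds a timestamp, so a config + seed pair reproduces every
artifact byte-for-byte.  Reads with N contribute to depth but never to
allele counts; deletion gaps contribute to neither.

Problem sizes: the test suite and the acceptance script exercise the full
default simulation (1.2 Mb, ~104k reads) once, plus 30–60 kb instances
for brute-force oracle comparisons — sizes chosen so every planted
feature (20 kb LOH, 16 kb CNVs, 101-window runs, 60 sampled ORFs) is
comfortably represented while a complete run stays under a minute.

## Known limitations

Phasing counts haplotypes per ORF; it does not phase across ORFs or
scaffolds (the collapsed assembly does not support it).  At 2% density a
locus occasionally splits into unlinkable blocks when no read spans a
between-site gap; the linking stage joins disjoint blocks but cannot
reorder genuinely conflicting fragments, so a small residue (~2-5%) of
ORFs off-by-one in haplotype count remains at 26x.  The CNV screen has no
GC correction and no segmentation model; folds between 1x and 1.25x are
not callable by design.  The syn/nonsyn classifier evaluates one site at a
time against the reference codon; co-occurring substitutions in one codon
are not phased into joint codons.  The reduction consensus never edits
large-contig bases, so small-contig-specific variants are dropped rather
than reconciled.
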