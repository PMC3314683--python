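"""Median-smoothed coverage track, log2 ratios, the contiguous-run CNV and
aneuploidy screen, and organelle copy-number estimation.

The screen follows the smoothed-segment rule: a window is elevated (or
depressed) at a fold threshold when its median coverage differs from the
overall genomic median by at least that fold; a maximal same-direction run
of at least ``min_run`` consecutive windows becomes a call, labelled with
the highest fold class its run-median ratio clears.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import Assembly, PloidykitError
from .pileup import Pileup, WindowParams, WindowRecord, window_starts

logger = logging.getLogger("ploidykit")


@dataclass
class CnvParams:
    """Run length, fold classes, and the run-membership entry fold.

    Window medians of integer read depth are coarse: at ~26x a genuine
    4/3-fold segment produces occasional windows — and short window runs,
    where read starts thin out locally — just under 1.25x, which would
    fragment a strict per-window run.  Windows therefore join a run at the
    softer ``entry_fold`` (midway between 1x and the first class), interior
    sub-entry interruptions of at most ``max_gap`` windows do not break a
    run (they never extend its ends and never span an opposite-direction
    window), and the run is only called — and classified — by the median
    ratio of its qualifying windows against ``fold_thresholds``.
    ``entry_fold = fold_thresholds[0]`` with ``max_gap = 0`` recovers the
    strict per-window screen.
    """

    min_run: int = 101
    fold_thresholds: tuple[float, ...] = (1.25, 1.5)
    entry_fold: float = 1.125
    max_gap: int = 10

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise PloidykitError("min_run must be >= 2")
        if self.max_gap < 0:
            raise PloidykitError("max_gap must be >= 0")
        thresholds = tuple(self.fold_thresholds)
        if any(t <= 1 for t in thresholds) or list(thresholds) != sorted(thresholds):
            raise PloidykitError("fold_thresholds must be > 1 and ascending")
        if not 1.0 < self.entry_fold <= thresholds[0]:
            raise PloidykitError("entry_fold must be in (1, first threshold]")
        self.fold_thresholds = thresholds


@dataclass
class CnvCall:
    contig_id: str
    start: int
    end: int
    n_windows: int
    direction: str            # gain | loss
    fold_class: float
    median_ratio: float


def coverage_track(pileup: Pileup, assembly: Assembly,
                   params: WindowParams) -> list[WindowRecord]:
    """Median per-base depth in each sliding window."""
    track: list[WindowRecord] = []
    for contig in assembly:
        starts = window_starts(len(contig), params)
        if len(starts) == 0:
            continue
        depth = pileup.depth(contig.id)
        view = np.lib.stride_tricks.sliding_window_view(depth, params.window)
        medians = np.median(view[starts], axis=1)
        for s, m in zip(starts, medians):
            track.append(WindowRecord(contig.id, int(s), int(s + params.window),
                                      median_cov=float(m)))
    return track


def genomic_median_depth(pileup: Pileup, assembly: Assembly) -> float:
    """Median of per-base depth over all non-organelle contigs."""
    depths = [pileup.depth(c.id) for c in assembly.genomic_contigs()]
    if not depths:
        raise PloidykitError("no genomic contigs")
    return float(np.median(np.concatenate(depths)))


def organelle_median_depth(pileup: Pileup, assembly: Assembly) -> float:
    depths = [pileup.depth(c.id) for c in assembly
              if c.id in assembly.organelle_ids]
    if not depths:
        raise PloidykitError("no organelle contigs flagged")
    return float(np.median(np.concatenate(depths)))


def log2_ratio_track(track: Sequence[WindowRecord],
                     genomic_median: float) -> list[WindowRecord]:
    """Fill log2(median_cov / genomic median); zero-coverage windows keep a
    None sentinel and are excluded from CNV runs."""
    if genomic_median <= 0:
        raise PloidykitError("genomic median coverage must be positive")
    out = []
    for w in track:
        ratio = None
        if w.median_cov is not None and w.median_cov > 0:
            ratio = math.log2(w.median_cov / genomic_median)
        out.append(WindowRecord(w.contig_id, w.start, w.end, w.snp_per_10kb,
                                w.median_cov, ratio))
    return out


def _window_direction(median_cov: float | None, genomic_median: float,
                      t: float) -> str | None:
    if median_cov is None or median_cov <= 0:
        return None
    if median_cov >= t * genomic_median:
        return "gain"
    if median_cov <= genomic_median / t:
        return "loss"
    return None


def screen_copy_number(track: Sequence[WindowRecord], params: CnvParams,
                       genomic_median: float,
                       organelle_ids: Iterable[str] = ()) -> list[CnvCall]:
    """Maximal same-direction runs of >= min_run windows beyond the lowest
    fold threshold; the fold class is upgraded to the highest threshold the
    run's median ratio clears.  Runs never cross contig boundaries; organelle
    contigs are screened separately via their copy-number estimate."""
    organelle = set(organelle_ids)
    by_contig: dict[str, list[WindowRecord]] = {}
    for w in track:
        if w.contig_id not in organelle:
            by_contig.setdefault(w.contig_id, []).append(w)
    calls: list[CnvCall] = []
    for cid, windows in sorted(by_contig.items()):
        windows.sort(key=lambda w: w.start)
        directions = [_window_direction(w.median_cov, genomic_median,
                                        params.entry_fold) for w in windows]
        for direction in ("gain", "loss"):
            run: list[WindowRecord] = []
            gap = 0
            for w, d in zip(windows, directions):
                if d == direction:
                    run.append(w)
                    gap = 0
                    continue
                opposite = d is not None
                gap += 1
                if run and (opposite or gap > params.max_gap):
                    call = _make_call(cid, run, direction, params,
                                      genomic_median)
                    if call is not None:
                        calls.append(call)
                    run = []
            if run:
                call = _make_call(cid, run, direction, params, genomic_median)
                if call is not None:
                    calls.append(call)
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def _make_call(cid: str, run: list[WindowRecord], direction: str,
               params: CnvParams, genomic_median: float) -> CnvCall | None:
    """A run becomes a call when it is long enough and its median ratio
    clears the first fold class; sub-threshold runs are logged only."""
    ratios = np.array([w.median_cov / genomic_median for w in run])
    median_ratio = float(np.median(ratios))
    fold_class = None
    for t in params.fold_thresholds:
        if (direction == "gain" and median_ratio >= t) or \
           (direction == "loss" and median_ratio <= 1 / t):
            fold_class = t
    if len(run) < params.min_run or fold_class is None:
        logger.debug("sub-threshold %s run of %d windows on %s "
                     "(median ratio %.3f)", direction, len(run), cid,
                     median_ratio)
        return None
    return CnvCall(cid, run[0].start, run[-1].end, len(run), direction,
                   fold_class, median_ratio)


def estimate_organelle_copies(organelle_median_cov: float,
                              genomic_median_cov: float) -> dict:
    """Copy number = organelle/genomic depth ratio, rounded (ties half up)."""
    if organelle_median_cov <= 0 or genomic_median_cov <= 0:
        raise PloidykitError("median coverages must be positive")
    ratio = organelle_median_cov / genomic_median_cov
    return {"ratio": ratio, "copies": int(math.floor(ratio + 0.5))}


def identify_organelle_contigs(assembly: Assembly, pileup: Pileup,
                               ratio_threshold: float = 4.0,
                               at_threshold: float = 0.65) -> list[str]:
    """Heuristic organelle flagging: AT-rich contigs at high depth ratio.

    A user-provided organelle flag always takes precedence; this is the
    fallback when none is given.
    """
    all_depth = np.concatenate([pileup.depth(c.id) for c in assembly])
    overall = float(np.median(all_depth))
    flagged = []
    for c in assembly:
        med = float(np.median(pileup.depth(c.id)))
        at = (c.sequence.count("A") + c.sequence.count("T")) / len(c)
        if overall > 0 and med / overall > ratio_threshold and at > at_threshold:
            flagged.append(c.id)
    return flagged
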