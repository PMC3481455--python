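"""Correlation-driven refinement of a weight matrix.

The refinement loop alternates three levels, each maximising the
Matthews correlation coefficient (CC):

1. *Cutoff*: with the matrix built from the previous cycle's site set,
   sweep a cutoff grid (default -4.0 .. -0.5, step 0.1, stringent
   first).  At each cutoff the matrix extracts putative sites from the
   functional window; TP is the number identical — by (promoter, start,
   strand) — to the previous cycle's set, FP the surplus extractions,
   FN the previous sites missed, and TN completes the window population
   ``l_w * N_s``.
2. *Motif length*: holding the optimal cutoff, the site set is extended
   or trimmed by one column at either end (flanking bases taken from
   the source promoters, in binding orientation), the matrix rebuilt,
   and a length kept only when it strictly improves CC.
3. *Functional window*: each candidate window is refined to convergence
   (CC = 1, i.e. the extraction reproduces the previous site set
   exactly) and the window boundaries are hill-climbed by +/-1 bp
   moves (extend-left, extend-right, shrink-left, shrink-right),
   restarting from the initial matrix per variant.

The winner across windows maximises sensitivity on the experimental
sites subject to a shuffled-background occurrence frequency OF_r no
worse than the initial matrix's, ties resolved toward lower OF_r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import reverse_complement
from .evaluate import occurrence_frequency_random, sensitivity
from .matrix import (
    AlignedSites,
    BackgroundModel,
    WeightMatrix,
    background_from_promoters,
    build_weights,
    count_sites,
    score_sites,
)
from .promoters import PromoterSet
from .scan import FunctionalWindow, n_start_positions, sliding_scores, strand_scores


# ---------------------------------------------------------------------------
# confusion counts and the correlation coefficient
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def correlation_coefficient(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 when any marginal of the denominator is 0."""
    num = c.tp * c.tn - c.fn * c.fp
    den = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def cycle_confusion(
    n_new: int, n_original: int, tp: int, l_w: int, n_s: int
) -> ConfusionCounts:
    """The refinement-loop accounting: FP/FN/TN derived from TP.

    ``FP = N_new - TP``, ``FN = N_original - TP`` and
    ``TN = l_w * N_s - TP - FP - FN``, so the four counts always
    partition the ``l_w * N_s`` candidate windows.
    """
    fp = n_new - tp
    fn = n_original - tp
    tn = l_w * n_s - tp - fp - fn
    counts = ConfusionCounts(tp, fp, tn, fn)
    assert counts.total == l_w * n_s
    return counts


# ---------------------------------------------------------------------------
# configuration and extractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizationConfig:
    cutoff_min: float = -4.0
    cutoff_max: float = -0.5
    cutoff_step: float = 0.1
    length_bounds: tuple[int, int] = (4, 12)
    max_cycles: int = 50
    max_window_moves: int = 25
    vary_length: bool = True

    def __post_init__(self):
        if self.cutoff_step <= 0:
            raise ValueError("cutoff_step must be positive")
        if self.length_bounds[0] < 2:
            raise ValueError("minimum motif length is 2")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    def cutoff_grid(self) -> np.ndarray:
        """Ascending grid: most stringent (most negative) first."""
        n = int(round((self.cutoff_max - self.cutoff_min) / self.cutoff_step))
        return np.round(self.cutoff_min + self.cutoff_step * np.arange(n + 1), 6)


@dataclass(frozen=True)
class SiteOrigin:
    promoter_index: int
    start: int  # TSS-relative forward-strand start of the matrix window
    strand: str


@dataclass(frozen=True)
class Extraction:
    """Window sites in binding orientation with positional identities."""

    sequences: tuple[str, ...]
    origins: tuple[SiteOrigin, ...]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def keys(self) -> frozenset[tuple[int, int, str]]:
        return frozenset((o.promoter_index, o.start, o.strand) for o in self.origins)

    def to_aligned_sites(self) -> AlignedSites:
        if not self.sequences:
            raise ValueError("empty extraction cannot become an aligned site set")
        return AlignedSites(self.sequences)


def _window_index_range(
    promoters: PromoterSet, window: FunctionalWindow, motif_length: int
) -> tuple[int, int]:
    n_starts = n_start_positions(promoters.length, motif_length)
    lo = window.start + promoters.tss_offset
    hi = window.end + promoters.tss_offset
    if lo < 0 or hi >= n_starts:
        raise ValueError(
            f"window {window.start}..{window.end} outside the scannable span"
        )
    return lo, hi


def _window_scan(
    wm: WeightMatrix,
    promoters: PromoterSet,
    window: FunctionalWindow,
    dplus: int = 0,
    dminus: int = 0,
):
    """Strand scores restricted to columns whose *reference-frame* start
    lies in the window.

    ``dplus``/``dminus`` translate a scanned start into the reference
    frame for each strand (non-zero only while trying length variants,
    where the two strands shift differently).
    """
    fwd, rev = strand_scores(wm, promoters.encoded)
    n_cols = fwd.shape[1]
    lo = window.start + promoters.tss_offset
    hi = window.end + promoters.tss_offset
    if dplus == 0 and dminus == 0:
        _window_index_range(promoters, window, wm.motif_length)
    # columns whose strand-adjusted reference start falls inside the window
    cols = np.arange(n_cols)
    plus_ok = (cols + dplus >= lo) & (cols + dplus <= hi)
    minus_ok = (cols + dminus >= lo) & (cols + dminus <= hi)
    fwd = np.where(plus_ok, fwd, -np.inf)
    rev = np.where(minus_ok, rev, -np.inf)
    return fwd, rev


def extract_window_sites(
    wm: WeightMatrix,
    promoters: PromoterSet,
    window: FunctionalWindow,
    cutoff: float,
    dplus: int = 0,
    dminus: int = 0,
) -> Extraction:
    """Sites whose start lies inside the window and whose score (on
    either strand) reaches the cutoff, in binding orientation.

    At a position where both strands pass, the better-scoring strand
    provides the orientation.  The recorded start is always the
    forward-strand start of the matched window, shifted to the
    reference frame by the strand-specific deltas.
    """
    if cutoff > 0:
        return Extraction((), ())
    fwd, rev = _window_scan(wm, promoters, window, dplus, dminus)
    best = np.maximum(fwd, rev)
    hit = best >= cutoff
    lm = wm.motif_length
    seqs: list[str] = []
    origins: list[SiteOrigin] = []
    for p, i in zip(*np.nonzero(hit)):
        minus = rev[p, i] > fwd[p, i]
        word = promoters.sequences[p][i : i + lm]
        delta = dminus if minus else dplus
        seqs.append(reverse_complement(word) if minus else word)
        origins.append(
            SiteOrigin(
                int(p),
                promoters.position_of(int(i)) + delta,
                "-" if minus else "+",
            )
        )
    return Extraction(tuple(seqs), tuple(origins))


# ---------------------------------------------------------------------------
# initial cutoff
# ---------------------------------------------------------------------------


def initial_cutoff(
    wm: WeightMatrix,
    experimental_sites: AlignedSites,
    shuffled: PromoterSet,
    config: OptimizationConfig | None = None,
) -> float:
    """Cutoff maximising CC of experimental sites against shuffled windows.

    Positives are the experimental sites; the negative population is
    every candidate window of the shuffled database (``(L - L_m) * N_s``
    windows, hit when either strand reaches the cutoff).  Grid ties go
    to the more stringent cutoff.
    """
    config = config or OptimizationConfig()
    site_scores = score_sites(wm, experimental_sites)
    n_starts = n_start_positions(shuffled.length, wm.motif_length)
    fwd, rev = strand_scores(wm, shuffled.encoded)
    neg_scores = np.maximum(fwd[:, :n_starts], rev[:, :n_starts]).ravel()
    total_pos = site_scores.size
    total_neg = neg_scores.size
    best_cutoff, best_cc = None, -np.inf
    for c in config.cutoff_grid():
        tp = int((site_scores >= c).sum())
        fp = int((neg_scores >= c).sum())
        cc = correlation_coefficient(
            ConfusionCounts(tp, fp, total_neg - fp, total_pos - tp)
        )
        if cc > best_cc:
            best_cutoff, best_cc = float(c), cc
    return best_cutoff


# ---------------------------------------------------------------------------
# one refinement cycle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleResult:
    matrix: WeightMatrix
    cutoff: float
    confusion: ConfusionCounts
    cc: float
    extraction: Extraction  # the accepted matrix's window sites, own frame
    length_move: str | None = None

    @property
    def converged(self) -> bool:
        return self.confusion.fp == 0 and self.confusion.fn == 0 and self.confusion.tp > 0


_MASK_PAD = 2  # room for +/-1 frame shifts during length variants


def _keys_mask_padded(
    keys: frozenset, promoters: PromoterSet, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean key grids; reference start index ``i`` sits at column
    ``i + _MASK_PAD`` so shifted views never wrap."""
    plus = np.zeros((promoters.n_s, width + 2 * _MASK_PAD), bool)
    minus = np.zeros_like(plus)
    for p, start, strand in keys:
        i = start + promoters.tss_offset + _MASK_PAD
        if 0 <= i < plus.shape[1]:
            (plus if strand == "+" else minus)[p, i] = True
    return plus, minus


def _shifted_view(mask_padded: np.ndarray, d: int, n_cols: int) -> np.ndarray:
    """View whose column ``i`` is the key flag at reference start ``i + d``."""
    return mask_padded[:, _MASK_PAD + d : _MASK_PAD + d + n_cols]


def _cc_at_cutoff(
    fwd: np.ndarray,
    rev: np.ndarray,
    cutoff: float,
    keys_plus_shifted: np.ndarray,
    keys_minus_shifted: np.ndarray,
    n_original: int,
    l_w: int,
    n_s: int,
) -> tuple[ConfusionCounts, float] | None:
    """Confusion of an extraction at one cutoff against reference keys.

    A position is a TP when any passing strand matches a reference key
    at the strand-adjusted reference start.  Returns ``None`` when the
    accounting degenerates (a cutoff so relaxed that the four counts
    cannot partition the window population).
    """
    fwd_hit = fwd >= cutoff
    rev_hit = rev >= cutoff
    n_new = int((fwd_hit | rev_hit).sum())
    tp_cells = (fwd_hit & keys_plus_shifted) | (rev_hit & keys_minus_shifted)
    tp = int(tp_cells.sum())
    try:
        counts = cycle_confusion(n_new, n_original, tp, l_w, n_s)
    except ValueError:
        return None
    return counts, correlation_coefficient(counts)


_LENGTH_MOVES = {
    # move -> (left columns added, right columns added); -1 trims
    "extend-left": (1, 0),
    "extend-right": (0, 1),
    "shrink-left": (-1, 0),
    "shrink-right": (0, -1),
}

# translation of a scanned start into the previous frame, per strand:
# key = move, value = (dplus, dminus)
_FRAME_DELTAS = {
    "extend-left": (1, 0),
    "extend-right": (0, 1),
    "shrink-left": (-1, 0),
    "shrink-right": (0, -1),
}


def _vary_sites(
    extraction: Extraction,
    promoters: PromoterSet,
    move: str,
) -> Extraction | None:
    """Rebuild a site set one column longer/shorter in binding orientation.

    Flanking bases come from the source promoters; if any site lacks
    the required flank the move is infeasible and ``None`` is returned.
    """
    add_left, add_right = _LENGTH_MOVES[move]
    lm = len(extraction.sequences[0])
    if lm + add_left + add_right < 2:
        return None
    seqs, origins = [], []
    for seq, origin in zip(extraction.sequences, extraction.origins):
        idx = origin.start + promoters.tss_offset
        prom = promoters.sequences[origin.promoter_index]
        if origin.strand == "+":
            a = idx - add_left
            b = idx + lm + add_right
        else:
            a = idx - add_right
            b = idx + lm + add_left
        if a < 0 or b > len(prom):
            return None
        word = prom[a:b]
        seqs.append(word if origin.strand == "+" else reverse_complement(word))
        origins.append(SiteOrigin(origin.promoter_index, promoters.position_of(a), origin.strand))
    return Extraction(tuple(seqs), tuple(origins))


def optimization_cycle(
    current: WeightMatrix,
    original_extraction: Extraction,
    promoters: PromoterSet,
    window: FunctionalWindow,
    config: OptimizationConfig,
    background: BackgroundModel,
) -> CycleResult:
    """One cutoff-then-length refinement step.

    ``current`` is the matrix built from ``original_extraction``; the
    cycle sweeps the cutoff grid, optionally tries one-column length
    variants at the optimal cutoff, and returns the accepted matrix
    together with its window extraction (the next cycle's reference).
    """
    if original_extraction.n == 0:
        raise ValueError("reference extraction is empty")
    n_s = promoters.n_s
    l_w = window.l_w
    keys = original_extraction.keys
    n_original = original_extraction.n
    width = promoters.length  # covers any motif length's start grid
    keys_plus, keys_minus = _keys_mask_padded(keys, promoters, width)

    fwd, rev = _window_scan(current, promoters, window)
    kp = _shifted_view(keys_plus, 0, fwd.shape[1])
    km = _shifted_view(keys_minus, 0, fwd.shape[1])
    best_cutoff, best_counts, best_cc = None, None, -np.inf
    for c in config.cutoff_grid():
        result = _cc_at_cutoff(fwd, rev, c, kp, km, n_original, l_w, n_s)
        if result is None:
            continue
        counts, cc = result
        if cc > best_cc:
            best_cutoff, best_counts, best_cc = float(c), counts, cc
    if best_cutoff is None:
        raise ValueError("no cutoff on the grid yields a valid confusion table")

    accepted_matrix = current
    accepted_move = None
    dplus = dminus = 0

    if config.vary_length:
        lo_len, hi_len = config.length_bounds
        for move in _LENGTH_MOVES:
            add_left, add_right = _LENGTH_MOVES[move]
            new_len = accepted_matrix.motif_length + add_left + add_right
            if not lo_len <= new_len <= hi_len:
                continue
            varied_sites = _vary_sites(original_extraction, promoters, move)
            if varied_sites is None:
                continue
            try:
                varied_wm = build_weights(
                    count_sites(varied_sites.to_aligned_sites(), current.order),
                    background,
                )
                dp, dm = _FRAME_DELTAS[move]
                vfwd, vrev = _window_scan(varied_wm, promoters, window, dp, dm)
                vkp = _shifted_view(keys_plus, dp, vfwd.shape[1])
                vkm = _shifted_view(keys_minus, dm, vfwd.shape[1])
                result = _cc_at_cutoff(
                    vfwd, vrev, best_cutoff, vkp, vkm, n_original, l_w, n_s
                )
            except ValueError:
                continue
            if result is None:
                continue
            counts, cc = result
            if cc > best_cc:
                accepted_matrix, accepted_move = varied_wm, move
                best_counts, best_cc = counts, cc
                dplus, dminus = dp, dm
                break  # one length change per cycle

    extraction = extract_window_sites(
        accepted_matrix, promoters, window, best_cutoff, 0, 0
    )
    return CycleResult(
        accepted_matrix, best_cutoff, best_counts, best_cc, extraction, accepted_move
    )


# ---------------------------------------------------------------------------
# the full optimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    matrix: WeightMatrix
    window: FunctionalWindow
    cc: float
    converged: bool
    sensitivity: float
    of_r: float
    cycles: int

    @property
    def cutoff(self) -> float:
        return self.matrix.cutoff


@dataclass
class OptimizationResult:
    final_matrix: WeightMatrix
    final_window: FunctionalWindow
    converged: bool
    sensitivity: float
    of_r: float
    initial_cutoff: float
    initial_of_r: float
    initial_sensitivity: float
    candidates: list[Candidate]
    trajectory: list[dict] = field(default_factory=list)

    @property
    def final_cutoff(self) -> float:
        return self.final_matrix.cutoff

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory)


def _recognition_rate(wm: WeightMatrix, cutoff: float, sites: AlignedSites) -> float:
    """Sensitivity tolerant of a motif-length change during refinement.

    Sites longer than the matrix are recognised through their best
    sub-window; sites shorter than the matrix cannot be scored and
    count as missed.
    """
    if sites.length == wm.motif_length:
        return sensitivity(wm, cutoff, sites)
    if sites.length < wm.motif_length:
        return 0.0
    scores = sliding_scores(wm, sites.encoded()).max(axis=1)
    return float((scores >= cutoff).mean())


def _selection_key(cand: Candidate, of_r_ceiling: float) -> tuple:
    return (cand.of_r <= of_r_ceiling + 1e-12, cand.sensitivity, -cand.of_r)


def optimize(
    initial: WeightMatrix,
    experimental_sites: AlignedSites,
    promoters: PromoterSet,
    shuffled: PromoterSet,
    initial_windows: Sequence[FunctionalWindow],
    config: OptimizationConfig | None = None,
    background: BackgroundModel | None = None,
) -> OptimizationResult:
    """Run the three-level refinement from one or more starting windows."""
    config = config or OptimizationConfig()
    if background is None:
        background = background_from_promoters(promoters.sequences, initial.order)

    cutoff0 = initial.cutoff
    if cutoff0 is None:
        cutoff0 = initial_cutoff(initial, experimental_sites, shuffled, config)
    of_r0 = occurrence_frequency_random(initial, cutoff0, shuffled)
    sens0 = _recognition_rate(initial, cutoff0, experimental_sites)

    trajectory: list[dict] = []
    candidates: list[Candidate] = []
    run_counter = [0]

    def run_window(window: FunctionalWindow, label: str) -> Candidate | None:
        run_counter[0] += 1
        variant = f"run{run_counter[0]}:{label}"
        extraction = extract_window_sites(initial, promoters, window, cutoff0)
        if extraction.n == 0:
            return None
        res = None
        converged = False
        cycles = 0
        for cycle_index in range(config.max_cycles):
            matrix = build_weights(
                count_sites(extraction.to_aligned_sites(), initial.order), background
            )
            res = optimization_cycle(
                matrix, extraction, promoters, window, config, background
            )
            cycles = cycle_index + 1
            trajectory.append(
                {
                    "window_variant": variant,
                    "window_start": window.start,
                    "window_end": window.end,
                    "cycle": cycles,
                    "cutoff": res.cutoff,
                    "motif_length": res.matrix.motif_length,
                    "cc": res.cc,
                    "n_new": res.confusion.tp + res.confusion.fp,
                    "n_original": res.confusion.tp + res.confusion.fn,
                    "length_move": res.length_move,
                }
            )
            if res.converged:
                converged = True
                break
            if res.extraction.n == 0:
                break
            extraction = res.extraction
        final = res.matrix.with_cutoff(res.cutoff)
        return Candidate(
            matrix=final,
            window=window,
            cc=res.cc,
            converged=converged,
            sensitivity=_recognition_rate(final, res.cutoff, experimental_sites),
            of_r=occurrence_frequency_random(final, res.cutoff, shuffled),
            cycles=cycles,
        )

    n_starts = n_start_positions(promoters.length, initial.motif_length)

    def window_feasible(w: FunctionalWindow) -> bool:
        lo = w.start + promoters.tss_offset
        hi = w.end + promoters.tss_offset
        return 0 <= lo <= hi < n_starts

    moves = (
        ("extend-left", (-1, 0)),
        ("extend-right", (0, 1)),
        ("shrink-left", (1, 0)),
        ("shrink-right", (0, -1)),
    )

    for w_index, window in enumerate(initial_windows):
        best = run_window(window, f"w{w_index}")
        if best is None:
            continue
        candidates.append(best)
        for _ in range(config.max_window_moves):
            improved = False
            for name, (dstart, dend) in moves:
                new_start = best.window.start + dstart
                new_end = best.window.end + dend
                if new_start > new_end:
                    continue
                trial = FunctionalWindow(new_start, new_end, best.window.peak_z)
                if not window_feasible(trial):
                    continue
                cand = run_window(trial, f"w{w_index}:{name}")
                if cand is None:
                    continue
                candidates.append(cand)
                if _selection_key(cand, of_r0) > _selection_key(best, of_r0):
                    best = cand
                    improved = True
                    break
            if not improved:
                break

    if not candidates:
        raise ValueError("no window produced a non-empty initial extraction")

    winner = max(candidates, key=lambda c: _selection_key(c, of_r0))
    return OptimizationResult(
        final_matrix=winner.matrix,
        final_window=winner.window,
        converged=winner.converged,
        sensitivity=winner.sensitivity,
        of_r=winner.of_r,
        initial_cutoff=cutoff0,
        initial_of_r=of_r0,
        initial_sensitivity=sens0,
        candidates=candidates,
        trajectory=trajectory,
    )
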