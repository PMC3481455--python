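"""Double-strand promoter scanning and positional over-representation.

A window starting at array index ``i`` is a hit when its forward score
or its reverse-complement score reaches the cutoff; the hit indicator is
binary per promoter position regardless of strand multiplicity, and a
minus-strand match is reported at the forward-strand start coordinate of
the matched window.

By convention ``L - L_m`` start positions are scanned per sequence (the
window flush with the 3' end is excluded), so a 600-bp promoter offers
594 candidate starts to a 6-base matrix; pass ``include_last_start=True``
for the ``L - L_m + 1`` convention.

The per-position z-score standardises observed hit counts against the
mean count in shuffled replicates of the database::

    z_i = (n_obs_i - n_exp_i) / sqrt(n_exp_i)

which grows with the square root of the database size at fixed observed
and expected occurrence frequencies.  Maximal runs of positions with
z above a threshold (~3) form "functional windows".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .alphabet import dinucleotide_codes, reverse_complement
from .matrix import ScoredSite, WeightMatrix
from .promoters import PromoterSet

Strands = Literal["both", "forward"]


def n_start_positions(
    length: int, motif_length: int, include_last_start: bool = False
) -> int:
    """Candidate window starts per sequence (default ``L - L_m``)."""
    n = length - motif_length
    if include_last_start:
        n += 1
    if n < 1:
        raise ValueError(
            f"motif length {motif_length} too long for sequences of {length} bp"
        )
    return n


def sliding_scores(wm: WeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Forward-strand scores of every window (all ``L - L_m + 1`` starts)."""
    sym = dinucleotide_codes(codes) if wm.order == "di" else codes
    w = wm.weights
    m = w.shape[1]
    n_starts = sym.shape[-1] - m + 1
    if n_starts < 1:
        raise ValueError("sequences shorter than the motif")
    sym = np.atleast_2d(sym)
    out = np.zeros((sym.shape[0], n_starts))
    for k in range(m):
        out += w[sym[:, k : k + n_starts], k]
    return out


def strand_scores(
    wm: WeightMatrix, codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse-complement) scores indexed by forward-strand start."""
    codes = np.atleast_2d(codes)
    fwd = sliding_scores(wm, codes)
    rc_codes = (3 - codes)[:, ::-1]
    rev = sliding_scores(wm, rc_codes)[:, ::-1]
    return fwd, rev


@dataclass(frozen=True)
class ScanResult:
    """Per-promoter, per-start hit indicators with best-strand scores."""

    hits: np.ndarray  # bool (N_s, n_starts)
    scores: np.ndarray  # best-of-strand score, float (N_s, n_starts)
    strands: np.ndarray  # '+'/'-' of the better strand
    cutoff: float
    motif_length: int
    strand_policy: Strands

    @property
    def n_starts(self) -> int:
        return self.hits.shape[1]

    def hit_count_by_position(self) -> np.ndarray:
        """Number of promoters with a hit starting at each position."""
        return self.hits.sum(axis=0)

    def scored_sites(self, promoters: PromoterSet) -> list[ScoredSite]:
        sites = []
        lm = self.motif_length
        for p, i in zip(*np.nonzero(self.hits)):
            window = promoters.sequences[p][i : i + lm]
            strand = str(self.strands[p, i])
            sites.append(
                ScoredSite(
                    sequence=window if strand == "+" else reverse_complement(window),
                    score=float(self.scores[p, i]),
                    strand=strand,
                    promoter_id=promoters.ids[p],
                    start=promoters.position_of(int(i)),
                )
            )
        return sites


def scan_hits(
    wm: WeightMatrix,
    promoters: PromoterSet,
    cutoff: float | None = None,
    strands: Strands = "both",
    include_last_start: bool = False,
) -> ScanResult:
    """Scan every window of every promoter on the requested strands."""
    if cutoff is None:
        cutoff = wm.cutoff
    if cutoff is None:
        raise ValueError("no cutoff given and the matrix carries none")
    n_starts = n_start_positions(promoters.length, wm.motif_length, include_last_start)
    if cutoff > 0:
        warnings.warn("cutoff > 0 can never be reached; returning no hits")
        shape = (promoters.n_s, n_starts)
        return ScanResult(
            np.zeros(shape, bool),
            np.full(shape, -np.inf),
            np.full(shape, "+"),
            cutoff,
            wm.motif_length,
            strands,
        )
    fwd, rev = strand_scores(wm, promoters.encoded)
    fwd = fwd[:, :n_starts]
    rev = rev[:, :n_starts]
    if strands == "forward":
        best, strand = fwd, np.full(fwd.shape, "+")
    else:
        best = np.maximum(fwd, rev)
        strand = np.where(rev > fwd, "-", "+")
    return ScanResult(best >= cutoff, best, strand, cutoff, wm.motif_length, strands)


@dataclass(frozen=True)
class PositionalProfile:
    """Observed vs expected hit counts per TSS-relative start position."""

    positions: np.ndarray  # TSS-relative starts
    n_obs: np.ndarray
    n_s: int
    n_exp: np.ndarray | None = None
    n_exp_std: np.ndarray | None = None  # replicate spread, diagnostic
    z: np.ndarray | None = None

    @property
    def of_obs(self) -> np.ndarray:
        return self.n_obs / self.n_s

    @property
    def of_exp(self) -> np.ndarray:
        if self.n_exp is None:
            raise ValueError("profile has no expectation filled in")
        return self.n_exp / self.n_s


def occurrence_profile(hits: ScanResult, promoters: PromoterSet) -> PositionalProfile:
    """Observed occurrence profile: OF_i = n_i / N_s per start position."""
    n_obs = hits.hit_count_by_position()
    positions = np.arange(hits.n_starts) - promoters.tss_offset
    return PositionalProfile(positions, n_obs, promoters.n_s)


def zscore_profile(
    obs: PositionalProfile, replicate_counts: Sequence[np.ndarray]
) -> PositionalProfile:
    """Fill the expectation and z-score from shuffled-replicate hit counts.

    ``replicate_counts`` holds one per-position hit-count array per
    shuffled replicate (same matrix, cutoff and strand policy as the
    observed scan).  Positions with zero expectation get ``z = 0`` when
    nothing was observed and ``+inf`` otherwise.
    """
    replicate_counts = [np.asarray(c) for c in replicate_counts]
    if not replicate_counts:
        raise ValueError("no shuffled replicates supplied")
    stack = np.vstack(replicate_counts)
    n_exp = stack.mean(axis=0)
    n_exp_std = stack.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs.n_obs - n_exp) / np.sqrt(n_exp)
    zero = n_exp == 0
    z[zero & (obs.n_obs == 0)] = 0.0
    z[zero & (obs.n_obs > 0)] = np.inf
    return PositionalProfile(obs.positions, obs.n_obs, obs.n_s, n_exp, n_exp_std, z)


def profile_promoters(
    wm: WeightMatrix,
    promoters: PromoterSet,
    shuffled_replicates: Iterable[PromoterSet],
    cutoff: float | None = None,
    strands: Strands = "both",
    include_last_start: bool = False,
) -> PositionalProfile:
    """Observed-vs-shuffled z-score profile in one call."""
    observed = scan_hits(wm, promoters, cutoff, strands, include_last_start)
    counts = [
        scan_hits(wm, rep, cutoff, strands, include_last_start).hit_count_by_position()
        for rep in shuffled_replicates
    ]
    return zscore_profile(occurrence_profile(observed, promoters), counts)


@dataclass(frozen=True)
class FunctionalWindow:
    """A TSS-relative interval of over-represented motif starts."""

    start: int
    end: int  # inclusive
    peak_z: float = np.inf

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("window start must not exceed end")

    @property
    def l_w(self) -> int:
        return self.end - self.start + 1

    def moved(self, dstart: int = 0, dend: int = 0) -> "FunctionalWindow":
        return FunctionalWindow(self.start + dstart, self.end + dend, self.peak_z)

    def overlaps(self, other: "FunctionalWindow") -> bool:
        return self.start <= other.end and other.start <= self.end


def find_functional_windows(
    profile: PositionalProfile,
    z_threshold: float = 3.0,
    merge_gap: int = 0,
) -> list[FunctionalWindow]:
    """Maximal runs of positions with z >= threshold, sorted by peak z.

    Runs separated by at most ``merge_gap`` sub-threshold positions are
    merged into one window.
    """
    if profile.z is None:
        raise ValueError("profile has no z-scores; run zscore_profile first")
    above = profile.z >= z_threshold
    runs: list[list[int]] = []
    for i in np.nonzero(above)[0]:
        if runs and i - runs[-1][-1] <= merge_gap + 1:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    windows = [
        FunctionalWindow(
            int(profile.positions[r[0]]),
            int(profile.positions[r[-1]]),
            float(np.max(profile.z[r[0] : r[-1] + 1])),
        )
        for r in runs
    ]
    return sorted(windows, key=lambda w: -w.peak_z)
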