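"""Construction, representation and scoring of position weight matrices.

Two matrix orders are supported: *mono* (4 symbol rows, one column per
motif base) and *di* (16 overlapping di-nucleotide rows, one column per
adjacent base pair, i.e. ``motif_length - 1`` columns).

A weight is a smoothed log-odds::

    w_b(i) = ln( (n_b(i) / n) / e_b + s_b(i) ) + c(i)

where ``n_b(i)`` is the count of symbol ``b`` in column ``i`` of the
aligned sites, ``n`` the number of sites, ``e_b`` the background
probability of ``b`` averaged over a promoter database, ``s_b(i)`` a
smoothing term that is non-zero only for rare or absent symbols
(``s_b = 0.01 * (1/K) / e_b`` with ``K`` the alphabet size, applied
whenever the odds do not exceed that value), and ``c(i)`` the constant
that makes the maximum weight of each column exactly zero.  Scores of
any word are therefore sums of non-positive column weights, with the
per-column argmax word scoring 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .alphabet import (
    BASES,
    DINUCS,
    dinucleotide_codes,
    encode,
    encode_many,
    validate_sequence,
)

Order = Literal["mono", "di"]

#: smoothing scale of the rare-symbol pseudo-term, as a fraction of the
#: uniform symbol probability
SMOOTHING_FRACTION = 0.01

#: floor applied to background frequencies of zero before renormalisation
BACKGROUND_FLOOR = 1e-4


def _alphabet_size(order: Order) -> int:
    return 4 if order == "mono" else 16


def symbols_for(order: Order) -> tuple[str, ...]:
    """Row labels of a matrix of the given order."""
    return tuple(BASES) if order == "mono" else DINUCS


@dataclass(frozen=True)
class AlignedSites:
    """A non-empty collection of equal-length, pre-aligned binding sites."""

    sequences: tuple[str, ...]

    def __init__(self, sequences: Iterable[str]):
        seqs = tuple(validate_sequence(s) for s in sequences)
        if not seqs:
            raise ValueError("aligned site set is empty")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sites have unequal lengths: {sorted(lengths)}")
        if len(seqs[0]) < 2:
            raise ValueError("aligned sites must be at least 2 bp long")
        object.__setattr__(self, "sequences", seqs)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        return encode_many(self.sequences)


@dataclass(frozen=True)
class CountMatrix:
    """Per-position symbol counts tallied from aligned sites."""

    order: Order
    counts: np.ndarray
    site_count: int
    motif_length: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != _alphabet_size(self.order):
            raise ValueError(
                f"{self.order} counts must have {_alphabet_size(self.order)} rows"
            )
        expected_cols = (
            self.motif_length if self.order == "mono" else self.motif_length - 1
        )
        if counts.shape[1] != expected_cols:
            raise ValueError(
                f"expected {expected_cols} columns for motif_length="
                f"{self.motif_length}, got {counts.shape[1]}"
            )
        if (counts < 0).any():
            raise ValueError("negative counts")
        if not (counts.sum(axis=0) == self.site_count).all():
            raise ValueError("column sums do not equal site_count")
        object.__setattr__(self, "counts", counts)

    @property
    def n_columns(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        """Column-normalised symbol frequencies."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class BackgroundModel:
    """Position-averaged expected symbol frequencies of a promoter database."""

    order: Order
    frequencies: np.ndarray
    source_length: int | None = None

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (_alphabet_size(self.order),):
            raise ValueError(
                f"{self.order} background needs {_alphabet_size(self.order)} frequencies"
            )
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if (freqs <= 0).any():
            raise ValueError(
                "background contains non-positive frequencies; apply flooring"
            )
        object.__setattr__(self, "frequencies", freqs)

    @classmethod
    def uniform(cls, order: Order = "mono") -> "BackgroundModel":
        k = _alphabet_size(order)
        return cls(order, np.full(k, 1.0 / k))


@dataclass(frozen=True)
class WeightMatrix:
    """Smoothed log-odds matrix with every column maximum normalised to 0."""

    order: Order
    weights: np.ndarray
    motif_length: int
    cutoff: float | None = None
    provenance: str = ""

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        expected_cols = (
            self.motif_length if self.order == "mono" else self.motif_length - 1
        )
        if weights.shape != (_alphabet_size(self.order), expected_cols):
            raise ValueError(
                f"weights shape {weights.shape} inconsistent with order="
                f"{self.order}, motif_length={self.motif_length}"
            )
        colmax = weights.max(axis=0)
        if (np.abs(colmax) > 1e-9).any():
            raise ValueError("every weight column must have maximum 0")
        if (weights > 1e-9).any():
            raise ValueError("weights must be non-positive")
        object.__setattr__(self, "weights", weights)

    @property
    def n_columns(self) -> int:
        return self.weights.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def with_cutoff(self, cutoff: float) -> "WeightMatrix":
        return WeightMatrix(
            self.order, self.weights, self.motif_length, cutoff, self.provenance
        )

    def argmax_word(self) -> str:
        """The word assembled from per-column argmax symbols (score 0).

        For di matrices consecutive argmax di-nucleotides may disagree on
        the shared base; in that case the word is built greedily from the
        first column's di-nucleotide and subsequent best-compatible rows.
        """
        syms = symbols_for(self.order)
        if self.order == "mono":
            return "".join(syms[int(i)] for i in self.weights.argmax(axis=0))
        word = syms[int(self.weights[:, 0].argmax())]
        for col in range(1, self.n_columns):
            prev = word[-1]
            rows = [i for i, d in enumerate(syms) if d[0] == prev]
            best = max(rows, key=lambda i: self.weights[i, col])
            word += syms[best][1]
        return word


@dataclass(frozen=True)
class ScoredSite:
    """A scored motif occurrence, optionally anchored in a promoter."""

    sequence: str
    score: float
    strand: str = "+"
    promoter_id: str | None = None
    start: int | None = None  # TSS-relative start of the forward-strand window

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.score > 1e-9:
            raise ValueError("scores are non-positive by construction")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def count_sites(sites: AlignedSites, order: Order = "mono") -> CountMatrix:
    """Tally per-position symbol counts from aligned sites.

    Mono counts are direct base tallies; di counts tally the overlapping
    di-nucleotide starting at each position (one fewer column).
    """
    codes = sites.encoded()
    if order == "di":
        if sites.length < 2:
            raise ValueError("di counting needs sites of length >= 2")
        codes = dinucleotide_codes(codes)
    k = _alphabet_size(order)
    counts = np.vstack([(codes == s).sum(axis=0) for s in range(k)])
    return CountMatrix(order, counts, sites.n, sites.length)


def background_from_promoters(
    promoters: Sequence[str],
    order: Order = "mono",
    floor: float = BACKGROUND_FLOOR,
) -> BackgroundModel:
    """Position-averaged symbol frequencies over a promoter database.

    Frequencies of zero are floored at ``floor`` and the vector is
    renormalised, so the model can always serve as a log-odds denominator.
    """
    promoters = list(promoters)
    if not promoters:
        raise ValueError("empty promoter set")
    k = _alphabet_size(order)
    totals = np.zeros(k)
    for seq in promoters:
        codes = encode(validate_sequence(seq))
        if order == "di":
            codes = dinucleotide_codes(codes)
        totals += np.bincount(codes, minlength=k)
    freqs = totals / totals.sum()
    if (freqs <= 0).any():
        freqs = np.maximum(freqs, floor)
        freqs = freqs / freqs.sum()
    length = len(promoters[0]) if len({len(s) for s in promoters}) == 1 else None
    return BackgroundModel(order, freqs, source_length=length)


def build_weights(
    counts: CountMatrix,
    background: BackgroundModel,
    cutoff: float | None = None,
    provenance: str = "",
) -> WeightMatrix:
    """Convert counts into a smoothed log-odds weight matrix.

    Per column, ``odds_b = (n_b / n) / e_b``; rare symbols whose odds do
    not exceed ``0.01 * (1/K) / e_b`` receive that value as an additive
    smoothing term before the logarithm, and the column is shifted so its
    maximum is exactly zero.
    """
    if counts.order != background.order:
        raise ValueError(
            f"counts order {counts.order!r} does not match background order "
            f"{background.order!r}"
        )
    k = _alphabet_size(counts.order)
    e = background.frequencies[:, None]
    odds = (counts.counts / counts.site_count) / e
    sigma = SMOOTHING_FRACTION * (1.0 / k) / e
    smoothing = np.where(odds > sigma, 0.0, sigma)
    w = np.log(odds + smoothing)
    w = w - w.max(axis=0, keepdims=True)
    return WeightMatrix(counts.order, w, counts.motif_length, cutoff, provenance)


def score_sequence(wm: WeightMatrix, seq: str) -> float:
    """Additive weight score of one word of the matrix's motif length."""
    seq = validate_sequence(seq)
    if len(seq) != wm.motif_length:
        raise ValueError(
            f"sequence length {len(seq)} != motif length {wm.motif_length}"
        )
    codes = encode(seq)
    if wm.order == "di":
        codes = dinucleotide_codes(codes)
    return float(wm.weights[codes, np.arange(wm.n_columns)].sum())


def score_sites(wm: WeightMatrix, sites: AlignedSites) -> np.ndarray:
    """Vectorised :func:`score_sequence` over an aligned site set."""
    if sites.length != wm.motif_length:
        raise ValueError("site length does not match motif length")
    codes = sites.encoded()
    if wm.order == "di":
        codes = dinucleotide_codes(codes)
    return wm.weights[codes, np.arange(wm.n_columns)].sum(axis=1)


def expected_dinucleotide_counts(
    mono_counts: CountMatrix, di_site_count: int
) -> np.ndarray:
    """Expected di-nucleotide counts under column independence.

    ``expected[b1b2, i] = N * f(b1, i) * f(b2, i+1)`` with ``f`` the
    column-normalised mono frequencies and ``N = di_site_count``; each
    column of the result sums to ``N``.  Used to contrast a di-nucleotide
    count table with what the mono matrix alone would predict.
    """
    if mono_counts.order != "mono":
        raise ValueError("expected counts are derived from a mono matrix")
    if di_site_count <= 0:
        raise ValueError("di_site_count must be positive")
    colsums = mono_counts.counts.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("zero mono column total")
    f = mono_counts.counts / colsums
    ncols = mono_counts.motif_length - 1
    expected = np.empty((16, ncols))
    for i in range(ncols):
        expected[:, i] = di_site_count * np.outer(f[:, i], f[:, i + 1]).ravel()
    return expected


def consensus(counts: CountMatrix, inclusion_threshold: float = 0.5) -> str:
    """Degenerate consensus: per position, bases at or above the threshold.

    Bases are ordered by descending frequency and bracketed when more
    than one qualifies; when none qualifies the single most frequent
    base is emitted.
    """
    if not 0 < inclusion_threshold <= 1:
        raise ValueError("inclusion_threshold must be in (0, 1]")
    if counts.order != "mono":
        raise ValueError("consensus is defined on mono counts")
    freqs = counts.frequencies()
    out = []
    for i in range(freqs.shape[1]):
        order = np.argsort(-freqs[:, i], kind="stable")
        chosen = [BASES[b] for b in order if freqs[b, i] >= inclusion_threshold]
        if not chosen:
            chosen = [BASES[order[0]]]
        out.append(chosen[0] if len(chosen) == 1 else "[" + "/".join(chosen) + "]")
    return "".join(out)
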