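"""Seeded synthetic promoter, site and bound/unbound set generators.

Every generator is a pure function of its specification and seed, and
returns ground truth sufficient to compute exact expected values for
downstream checks.  The promoter model emulates the statistical shape of
TSS-aligned human promoter databases: GC-rich background composition, an
optional first-order chain that modulates the CpG rate, motif plants
concentrated in a near-TSS window, and strand-symmetric planting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import BASES, decode
from .matrix import AlignedSites
from .promoters import PromoterSet, default_tss_offset

#: GC-rich promoter-like base composition, ACGT order
PROMOTER_COMPOSITION = (0.20, 0.32, 0.30, 0.18)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic promoter database.

    ``cpg_boost`` multiplies the C->G transition probability of a
    first-order background chain (1.0 keeps the background zeroth
    order); ``plant_window`` bounds the TSS-relative start of planted
    motifs; ``occupancy`` is the probability that a promoter receives
    one plant; a plant is reverse-complemented with probability
    ``minus_strand_prob``.
    """

    n_sequences: int = 1000
    length: int = 600
    base_composition: tuple[float, float, float, float] = PROMOTER_COMPOSITION
    cpg_boost: float = 1.0
    motif_pfm: np.ndarray | None = None  # (4, L_m) column probabilities
    plant_window: tuple[int, int] = (-7, 0)
    occupancy: float = 0.0
    minus_strand_prob: float = 0.5
    tss_offset: int | None = None
    seed: int = 0

    def __post_init__(self):
        comp = np.asarray(self.base_composition, dtype=float)
        if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be a probability vector")
        if not 0 <= self.occupancy <= 1 or not 0 <= self.minus_strand_prob <= 1:
            raise ValueError("occupancy and minus_strand_prob must be in [0, 1]")
        if self.cpg_boost <= 0:
            raise ValueError("cpg_boost must be positive")
        if self.motif_pfm is not None:
            pfm = np.asarray(self.motif_pfm, dtype=float)
            if pfm.ndim != 2 or pfm.shape[0] != 4:
                raise ValueError("motif_pfm must be a 4-row column-probability grid")
            if not np.allclose(pfm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("motif_pfm columns must sum to 1")
            object.__setattr__(self, "motif_pfm", pfm)

    @property
    def resolved_tss_offset(self) -> int:
        return (
            self.tss_offset
            if self.tss_offset is not None
            else default_tss_offset(self.length)
        )

    def plant_index_range(self) -> tuple[int, int]:
        """Inclusive array-index range of allowed plant starts."""
        if self.motif_pfm is None:
            raise ValueError("spec has no motif_pfm to plant")
        lo = self.plant_window[0] + self.resolved_tss_offset
        hi = self.plant_window[1] + self.resolved_tss_offset
        lm = self.motif_pfm.shape[1]
        if lo < 0 or hi + lm > self.length or lo > hi:
            raise ValueError("plant_window does not fit inside the sequences")
        return lo, hi


def _transition_matrix(composition: np.ndarray, cpg_boost: float) -> np.ndarray:
    """First-order background chain; row = current base, column = next."""
    trans = np.tile(composition, (4, 1))
    c = BASES.index("C")
    g = BASES.index("G")
    trans[c, g] *= cpg_boost
    trans[c] /= trans[c].sum()
    return trans


def _background_codes(
    n: int, length: int, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    comp = np.asarray(spec.base_composition)
    if spec.cpg_boost == 1.0:
        u = rng.random((n, length))
        return np.searchsorted(np.cumsum(comp), u, side="right").astype(np.int8)
    trans_cum = np.cumsum(_transition_matrix(comp, spec.cpg_boost), axis=1)
    codes = np.empty((n, length), dtype=np.int8)
    codes[:, 0] = np.searchsorted(np.cumsum(comp), rng.random(n), side="right")
    for j in range(1, length):
        u = rng.random(n)
        rows = trans_cum[codes[:, j - 1]]
        codes[:, j] = (u[:, None] < rows).argmax(axis=1)
    return codes


def _sample_words(pfm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent draws from per-column base probabilities, as codes."""
    cum = np.cumsum(pfm, axis=0)
    u = rng.random((n, pfm.shape[1]))
    return (u[:, None, :] < cum[None, :, :]).argmax(axis=1).astype(np.int8)


def generate_promoters(spec: GeneratorSpec) -> tuple[PromoterSet, pd.DataFrame]:
    """Promoter database plus the ground-truth plant table.

    The truth table has one row per planted site: promoter id,
    TSS-relative start of the forward-strand window, strand and the
    planted word in binding orientation.  At most one plant per
    promoter; a plant overwrites the background.
    """
    rng = np.random.default_rng(spec.seed)
    codes = _background_codes(spec.n_sequences, spec.length, spec, rng)
    rows = []
    ids = [f"prom{i + 1}" for i in range(spec.n_sequences)]
    if spec.occupancy > 0 and spec.motif_pfm is not None:
        lo, hi = spec.plant_index_range()
        lm = spec.motif_pfm.shape[1]
        planted = rng.random(spec.n_sequences) < spec.occupancy
        starts = rng.integers(lo, hi + 1, spec.n_sequences)
        minus = rng.random(spec.n_sequences) < spec.minus_strand_prob
        words = _sample_words(spec.motif_pfm, spec.n_sequences, rng)
        for i in np.nonzero(planted)[0]:
            word = words[i]
            written = (3 - word)[::-1] if minus[i] else word
            codes[i, starts[i] : starts[i] + lm] = written
            rows.append(
                {
                    "promoter_id": ids[i],
                    "start": int(starts[i]) - spec.resolved_tss_offset,
                    "strand": "-" if minus[i] else "+",
                    "word": decode(word),
                }
            )
    promoters = PromoterSet(
        [decode(c) for c in codes], ids, spec.resolved_tss_offset
    )
    truth = pd.DataFrame(rows, columns=["promoter_id", "start", "strand", "word"])
    return promoters, truth


def generate_site_set(pfm: np.ndarray, n: int, seed: int = 0) -> AlignedSites:
    """Aligned sites drawn independently per column from a PFM."""
    pfm = np.asarray(pfm, dtype=float)
    if not np.allclose(pfm.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("pfm columns must sum to 1")
    rng = np.random.default_rng(seed)
    return AlignedSites([decode(w) for w in _sample_words(pfm, n, rng)])


def generate_site_set_correlated(
    start_probs: np.ndarray,
    transitions: list[np.ndarray],
    n: int,
    seed: int = 0,
) -> AlignedSites:
    """Sites from an explicit first-order chain over motif columns.

    ``start_probs`` gives the base distribution of column 1 and
    ``transitions[i]`` the 4x4 row-stochastic matrix from column ``i+1``
    to ``i+2``; adjacent-column correlation makes di-nucleotide counts
    informative beyond the mono marginals.
    """
    rng = np.random.default_rng(seed)
    start_probs = np.asarray(start_probs, dtype=float)
    codes = np.empty((n, len(transitions) + 1), dtype=np.int8)
    codes[:, 0] = np.searchsorted(np.cumsum(start_probs), rng.random(n), "right")
    for j, trans in enumerate(transitions, start=1):
        cum = np.cumsum(np.asarray(trans, dtype=float), axis=1)
        codes[:, j] = (rng.random(n)[:, None] < cum[codes[:, j - 1]]).argmax(axis=1)
    return AlignedSites([decode(w) for w in codes])


def generate_bound_unbound(
    spec: GeneratorSpec,
    p_bound: float,
    p_unbound: float,
    n_each: int,
    seed: int = 0,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Bound/unbound evaluation sets with per-sequence plant probabilities.

    A "bound" sequence receives one plant with probability ``p_bound``
    (uniform position, strand-symmetric); "unbound" sequences likewise
    with ``p_unbound`` (typically 0, i.e. pure background).
    """
    if not 0 <= p_bound <= 1 or not 0 <= p_unbound <= 1:
        raise ValueError("plant probabilities must be in [0, 1]")
    if spec.motif_pfm is None:
        raise ValueError("spec has no motif_pfm to plant")
    rng = np.random.default_rng(seed)
    lm = spec.motif_pfm.shape[1]
    rows = []

    def make(label: str, p: float) -> list[str]:
        codes = _background_codes(n_each, spec.length, spec, rng)
        planted = rng.random(n_each) < p
        starts = rng.integers(0, spec.length - lm + 1, n_each)
        minus = rng.random(n_each) < spec.minus_strand_prob
        words = _sample_words(spec.motif_pfm, n_each, rng)
        for i in np.nonzero(planted)[0]:
            written = (3 - words[i])[::-1] if minus[i] else words[i]
            codes[i, starts[i] : starts[i] + lm] = written
        for i in range(n_each):
            rows.append(
                {
                    "set": label,
                    "index": i,
                    "planted": bool(planted[i]),
                    "start": int(starts[i]) if planted[i] else -1,
                    "strand": ("-" if minus[i] else "+") if planted[i] else ".",
                }
            )
        return [decode(c) for c in codes]

    bound = make("bound", p_bound)
    unbound = make("unbound", p_unbound)
    return bound, unbound, pd.DataFrame(rows)
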