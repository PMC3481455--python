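"""Sensitivity, shuffled-background false-positive rates and set-level
classification for weight matrices.

Sensitivity is the fraction of experimentally confirmed sites scoring at
or above the cutoff (sites are scored in their given binding
orientation).  The false-positive level is the occurrence frequency in
shuffled sequences::

    OF_r = total predictions / (N * (L - L_m))

counting both strands at every start position, so each prediction (not
each position) contributes and the saturation value is 2.0.  Bound vs
unbound sequence sets are classified per sequence: a sequence is
positive when it contains at least one hit anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import encode
from .matrix import AlignedSites, WeightMatrix, score_sites
from .promoters import PromoterSet
from .scan import n_start_positions, strand_scores


def sensitivity(wm: WeightMatrix, cutoff: float, sites: AlignedSites) -> float:
    """Fraction of aligned sites recognised at the cutoff."""
    return float((score_sites(wm, sites) >= cutoff).mean())


def occurrence_frequency_random(
    wm: WeightMatrix,
    cutoff: float,
    shuffled: PromoterSet,
    include_last_start: bool = False,
) -> float:
    """Predictions per candidate window in a shuffled database (OF_r)."""
    n_starts = n_start_positions(shuffled.length, wm.motif_length, include_last_start)
    fwd, rev = strand_scores(wm, shuffled.encoded)
    fwd, rev = fwd[:, :n_starts], rev[:, :n_starts]
    predictions = int((fwd >= cutoff).sum() + (rev >= cutoff).sum())
    return predictions / (shuffled.n_s * n_starts)


def sensitivity_ofr_curve(
    wm: WeightMatrix,
    cutoffs,
    sites: AlignedSites,
    shuffled: PromoterSet,
) -> pd.DataFrame:
    """(cutoff, sensitivity, of_r) per grid point; both columns are
    non-decreasing as the cutoff relaxes."""
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    site_scores = score_sites(wm, sites)
    n_starts = n_start_positions(shuffled.length, wm.motif_length)
    fwd, rev = strand_scores(wm, shuffled.encoded)
    window_scores = np.concatenate(
        [fwd[:, :n_starts].ravel(), rev[:, :n_starts].ravel()]
    )
    rows = [
        {
            "cutoff": c,
            "sensitivity": float((site_scores >= c).mean()),
            "of_r": float((window_scores >= c).sum())
            / (shuffled.n_s * n_starts),
        }
        for c in cutoffs
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SetReport:
    """Per-set totals of the bound/unbound evaluation."""

    total_hits: int
    sequences_with_hits: int
    sequences_without_hits: int

    @property
    def n_sequences(self) -> int:
        return self.sequences_with_hits + self.sequences_without_hits

    @property
    def hit_fraction(self) -> float:
        return self.sequences_with_hits / self.n_sequences


@dataclass(frozen=True)
class BoundUnboundReport:
    bound: SetReport
    unbound: SetReport

    @property
    def sensitivity(self) -> float:
        """Bound sequences containing at least one hit / total bound."""
        return self.bound.hit_fraction


def _count_set(wm: WeightMatrix, cutoff: float, seqs) -> SetReport:
    total_hits = 0
    with_hits = 0
    without = 0
    for seq in seqs:
        if len(seq) < wm.motif_length:
            warnings.warn(
                f"sequence of {len(seq)} bp shorter than the motif; counted as no-hit"
            )
            without += 1
            continue
        codes = encode(seq.upper())
        fwd, rev = strand_scores(wm, codes)
        hits = int((fwd >= cutoff).sum() + (rev >= cutoff).sum())
        total_hits += hits
        if hits:
            with_hits += 1
        else:
            without += 1
    return SetReport(total_hits, with_hits, without)


def evaluate_bound_unbound(
    wm: WeightMatrix, cutoff: float, bound, unbound
) -> BoundUnboundReport:
    """Per-sequence classification of bound and unbound sequence sets.

    Sequences may vary in length; every window of every sequence is
    scored on both strands (all ``L_i - L_m + 1`` starts).
    """
    bound, unbound = list(bound), list(unbound)
    if not bound or not unbound:
        raise ValueError("bound and unbound sets must be non-empty")
    return BoundUnboundReport(
        _count_set(wm, cutoff, bound), _count_set(wm, cutoff, unbound)
    )
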