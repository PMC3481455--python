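"""Composition-preserving fragment shuffling of promoter databases.

Each shuffling pass cuts a sequence left-to-right into fragments whose
lengths are drawn uniformly from ``[min_fragment, max_fragment]`` (the
final fragment may be shorter) and rearranges the fragments by a uniform
random permutation.  A pass preserves the per-sequence base multiset
exactly; repeated passes progressively randomise higher-order structure,
so di-nucleotide content (e.g. CpG counts) drifts toward the product of
the marginal base frequencies as ``rounds_per_sequence`` grows.
:func:`composition_report` quantifies that drift.

Shuffled databases serve as the expectation ensemble for positional
z-scores and for the false-positive rate OF_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import validate_sequence
from .promoters import PromoterSet


@dataclass(frozen=True)
class ShuffleConfig:
    """Fragmentation and replication parameters of the shuffling scheme.

    ``rounds_per_sequence`` successive cut-and-rearrange passes are
    applied to each sequence (mixing); ``replicates`` independent
    shuffled copies of the whole database are produced for expectation
    averaging.
    """

    min_fragment: int = 1
    max_fragment: int = 10
    rounds_per_sequence: int = 100
    replicates: int = 100
    seed: int | None = None

    def __post_init__(self):
        if not 1 <= self.min_fragment <= self.max_fragment:
            raise ValueError("need 1 <= min_fragment <= max_fragment")
        if self.rounds_per_sequence < 1 or self.replicates < 1:
            raise ValueError("rounds_per_sequence and replicates must be >= 1")


def _fragment_bounds(
    length: int, config: ShuffleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative fragment end positions covering [0, length)."""
    # oversample fragment lengths, then truncate at the sequence end
    n_draw = length // config.min_fragment + 1
    lengths = rng.integers(config.min_fragment, config.max_fragment + 1, n_draw)
    ends = np.cumsum(lengths)
    cut = int(np.searchsorted(ends, length))
    ends = ends[: cut + 1]
    ends[-1] = length
    # all but the final fragment respect the configured granularity
    assert len(ends) == 1 or (np.diff(ends, prepend=0)[:-1] >= config.min_fragment).all()
    return ends


def shuffle_sequence(
    seq: str, config: ShuffleConfig, rng: np.random.Generator
) -> str:
    """One sequence through ``rounds_per_sequence`` cut-and-rearrange passes."""
    for _ in range(config.rounds_per_sequence):
        ends = _fragment_bounds(len(seq), config, rng)
        if len(ends) < 2:
            continue
        starts = np.concatenate(([0], ends[:-1]))
        order = rng.permutation(len(ends))
        seq = "".join(seq[starts[i] : ends[i]] for i in order)
    return seq


def shuffle_database(
    promoters: PromoterSet, config: ShuffleConfig
) -> list[PromoterSet]:
    """Independent shuffled replicates of a promoter database.

    Each replicate has the same number of sequences, the same length and
    the same per-sequence base multiset as the input; record ids carry a
    ``/rep{k}`` suffix identifying the replicate.
    """
    rng = np.random.default_rng(config.seed)
    replicates = []
    for k in range(config.replicates):
        shuffled = [
            shuffle_sequence(validate_sequence(s), config, rng)
            for s in promoters.sequences
        ]
        ids = [f"{i}/rep{k}" for i in promoters.ids]
        replicates.append(PromoterSet(shuffled, ids, promoters.tss_offset))
    return replicates


def composition_report(seqs) -> pd.Series:
    """Base frequencies, mean CpG per sequence and CpG observed/expected.

    CpG is counted as overlapping ``CG`` occurrences.  The ``cpg_oe``
    entry divides the pooled CpG rate by the product of the pooled C and
    G frequencies — the diagnostic used to judge how much first-order
    structure a shuffle preserved.
    """
    seqs = [validate_sequence(s) for s in seqs]
    if not seqs:
        raise ValueError("empty sequence set")
    total = sum(len(s) for s in seqs)
    counts = {b: sum(s.count(b) for s in seqs) for b in "ACGT"}
    cpg_per_seq = [s.count("CG") for s in seqs]
    pairs = sum(len(s) - 1 for s in seqs)
    p_c = counts["C"] / total
    p_g = counts["G"] / total
    cpg_rate = sum(cpg_per_seq) / pairs if pairs else 0.0
    report = {f"freq_{b}": counts[b] / total for b in "ACGT"}
    report["cpg_mean"] = float(np.mean(cpg_per_seq))
    report["cpg_oe"] = cpg_rate / (p_c * p_g) if p_c * p_g > 0 else np.nan
    report["n_sequences"] = float(len(seqs))
    return pd.Series(report)
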