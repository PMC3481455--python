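"""TSS-aligned promoter containers.

A :class:`PromoterSet` holds equal-length DNA sequences aligned so that a
single array index corresponds to the transcription start site in every
record.  The conventional window in this toolkit is -499..+100 with the
TSS at 0, i.e. ``tss_offset = length - 101`` for a 600-bp record.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from .alphabet import encode_many, validate_sequence


def default_tss_offset(length: int) -> int:
    """Array index of TSS-relative 0 for a -(L-101)..+100 window.

    Records shorter than 101 bp cannot honour the +100 downstream
    convention; their TSS defaults to the first position.
    """
    return max(length - 101, 0)


@dataclass(frozen=True)
class PromoterSet:
    """Equal-length, TSS-aligned promoter sequences with identifiers."""

    sequences: tuple[str, ...]
    ids: tuple[str, ...]
    tss_offset: int

    def __init__(
        self,
        sequences: Iterable[str],
        ids: Sequence[str] | None = None,
        tss_offset: int | None = None,
    ):
        seqs = tuple(validate_sequence(s) for s in sequences)
        if not seqs:
            raise ValueError("promoter set is empty")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"promoters must share one length, got {sorted(lengths)}"
            )
        length = len(seqs[0])
        if tss_offset is None:
            tss_offset = default_tss_offset(length)
        if not 0 <= tss_offset < length:
            raise ValueError(
                f"tss_offset {tss_offset} outside sequence length {length}"
            )
        if ids is None:
            ids = tuple(f"seq{i + 1}" for i in range(len(seqs)))
        else:
            ids = tuple(str(i) for i in ids)
            if len(ids) != len(seqs):
                raise ValueError("ids and sequences differ in number")
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate promoter ids")
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "tss_offset", int(tss_offset))

    @property
    def n_s(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @cached_property
    def encoded(self) -> np.ndarray:
        return encode_many(self.sequences)

    def index_of(self, tss_relative: int) -> int:
        """Array index of a TSS-relative position."""
        idx = tss_relative + self.tss_offset
        if not 0 <= idx < self.length:
            raise ValueError(
                f"TSS-relative position {tss_relative} outside promoter span"
            )
        return idx

    def position_of(self, index: int) -> int:
        """TSS-relative position of an array index."""
        return index - self.tss_offset

    def subset(self, indices: Sequence[int]) -> "PromoterSet":
        return PromoterSet(
            [self.sequences[i] for i in indices],
            [self.ids[i] for i in indices],
            self.tss_offset,
        )
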