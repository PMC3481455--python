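"""DNA alphabet encoding shared by every matrix and scanning routine.

Bases are encoded as integers in ``ACGT`` order; the 16 overlapping
di-nucleotides are encoded lexicographically (``AA=0 .. TT=15``) so that
the code of a di-nucleotide is ``4 * first + second``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DINUCS = tuple(a + b for a in BASES for b in BASES)
DINUC_INDEX = {d: i for i, d in enumerate(DINUCS)}

_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")

# lookup table mapping ASCII codes of A/C/G/T to 0..3, everything else to -1
_CODE_LUT = np.full(128, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string to an int8 array of base codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw & 0x7F]
    codes[raw >= 128] = -1
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise AlphabetError(
            f"non-ACGT character {bad!r} in sequence {seq[:40]!r}"
        )
    return codes


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length sequences to an (n, L) int8 matrix."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.vstack([encode(s) for s in seqs])


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in np.asarray(codes).ravel())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def dinucleotide_codes(codes: np.ndarray) -> np.ndarray:
    """Overlapping di-nucleotide codes along the last axis (length L-1)."""
    codes = np.asarray(codes)
    return 4 * codes[..., :-1] + codes[..., 1:]


def validate_sequence(seq: str) -> str:
    """Return ``seq`` uppercased, raising :class:`AlphabetError` otherwise."""
    seq = seq.upper()
    encode(seq)
    return seq
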