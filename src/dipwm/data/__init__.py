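"""Published GATA-3 matrices shipped with the package.

These are small public reference tables: the JASPAR-derived aligned-site
counts for human GATA-3 (63 sites), the refined mono-nucleotide count
matrix built from promoter-extracted sites (68 sites), and the refined
di-nucleotide matrix (observed counts over 79 sites and its weight
block, published with an optimized cutoff of -3.5).
"""

from importlib import resources

from ..io import read_matrix
from ..matrix import CountMatrix, WeightMatrix

__all__ = [
    "gata3_jaspar_counts",
    "gata3_refined_mono_counts",
    "gata3_refined_di_counts",
    "gata3_refined_di_weights",
]


def _load(name: str, dialect: str):
    with resources.as_file(resources.files(__package__) / name) as path:
        return read_matrix(path, dialect)


def gata3_jaspar_counts() -> CountMatrix:
    """JASPAR aligned-site counts for human GATA-3 (63 sites, 6 bp)."""
    return _load("gata3_jaspar_counts.pfm", "jaspar_pfm")


def gata3_refined_mono_counts() -> CountMatrix:
    """Refined GATA-3 mono-nucleotide counts (68 sites, 6 bp)."""
    return _load("gata3_refined_mono_counts.pfm", "jaspar_pfm")


def gata3_refined_di_counts() -> CountMatrix:
    """Observed di-nucleotide counts of the refined GATA-3 matrix (79 sites)."""
    return _load("gata3_refined_di_counts.tsv", "native_tsv")


def gata3_refined_di_weights() -> WeightMatrix:
    """Refined GATA-3 di-nucleotide weight matrix (cutoff -3.5)."""
    return _load("gata3_refined_di_weights.tsv", "native_tsv")
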