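import numpy as np
import pytest

from dipwm.data import (
    gata3_jaspar_counts,
    gata3_refined_di_counts,
    gata3_refined_di_weights,
    gata3_refined_mono_counts,
)
from dipwm.matrix import BackgroundModel


@pytest.fixture(scope="session")
def jaspar_counts():
    return gata3_jaspar_counts()


@pytest.fixture(scope="session")
def refined_mono_counts():
    return gata3_refined_mono_counts()


@pytest.fixture(scope="session")
def di_observed_counts():
    return gata3_refined_di_counts()


@pytest.fixture(scope="session")
def di_weights():
    return gata3_refined_di_weights()


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform("mono")


@pytest.fixture(scope="session")
def promoter_bg():
    # GC-rich promoter-like background, ACGT order
    return BackgroundModel("mono", np.array([0.20, 0.32, 0.30, 0.18]))


@pytest.fixture(scope="session")
def recovery_pfm():
    """8-bp GATA-like PFM with bounded column degeneracy.

    One dominant base (0.9) per column and equal minor probabilities,
    so every one-mismatch word stays above the refinement sweep floor
    while two-mismatch words fall below it — the planted model is then
    identifiable by cutoff-thresholded site extraction.
    """
    consensus = "ATGATAAG"
    idx = {b: i for i, b in enumerate("ACGT")}
    pfm = np.full((4, 8), 0.1 / 3)
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = 0.9
    return pfm


def random_aligned_sites(rng, n, length):
    from dipwm.alphabet import BASES
    from dipwm.matrix import AlignedSites

    codes = rng.integers(0, 4, (n, length))
    return AlignedSites(["".join(BASES[c] for c in row) for row in codes])
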