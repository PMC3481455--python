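"""The Matthews-correlation machinery and the refinement loop."""

import math

import numpy as np
import pytest

import dipwm
from dipwm.matrix import AlignedSites, build_weights, count_sites
from dipwm.optimize import (
    ConfusionCounts,
    OptimizationConfig,
    correlation_coefficient,
    cycle_confusion,
    extract_window_sites,
    initial_cutoff,
    optimization_cycle,
    optimize,
)
from dipwm.promoters import PromoterSet
from dipwm.scan import FunctionalWindow
from dipwm.shuffle import ShuffleConfig, shuffle_database
from tests.test_scan import consensus_matrix

from dipwm.alphabet import reverse_complement


# ---------------------------------------------------------------------------
# correlation coefficient
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tp, fp, tn, fn, expected",
    [
        (10, 0, 100, 0, 1.0),
        (50, 10, 930, 10, 46400 / math.sqrt(60 * 940 * 60 * 940)),
        (0, 0, 100, 10, 0.0),  # zero-denominator convention
        (0, 100, 0, 10, -1.0),  # perfect anti-correlation
    ],
)
def test_correlation_coefficient_values(tp, fp, tn, fn, expected):
    assert correlation_coefficient(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
        expected, abs=1e-12
    )


def test_correlation_matches_sklearn_on_random_tables():
    """Cross-check against scikit-learn's MCC on label vectors."""
    from sklearn.metrics import matthews_corrcoef

    rng = np.random.default_rng(2)
    for _ in range(200):
        tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, 4))
        if tp + fp + tn + fn == 0:
            continue
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        ours = correlation_coefficient(ConfusionCounts(tp, fp, tn, fn))
        assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)


def test_correlation_bounds_and_perfect_condition():
    rng = np.random.default_rng(3)
    for _ in range(2000):
        c = ConfusionCounts(*(int(x) for x in rng.integers(0, 1000, 4)))
        cc = correlation_coefficient(c)
        assert -1.0 <= cc <= 1.0
        if cc == 1.0:
            assert c.fp == 0 and c.fn == 0 and c.tp > 0 and c.tn > 0


def test_cycle_confusion_partitions_window_population():
    counts = cycle_confusion(n_new=12, n_original=10, tp=9, l_w=8, n_s=100)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (9, 3, 1, 787)
    assert counts.total == 800
    # direct evaluation of the Matthews formula on these counts
    expected = (9 * 787 - 1 * 3) / math.sqrt(10 * 790 * 12 * 788)
    assert correlation_coefficient(counts) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# initial cutoff
# ---------------------------------------------------------------------------


def _background_promoters(n, length, seed, tss_offset=None):
    spec = dipwm.GeneratorSpec(n_sequences=n, length=length, seed=seed)
    promoters, _ = dipwm.generate_promoters(spec)
    if tss_offset is not None:
        promoters = PromoterSet(promoters.sequences, promoters.ids, tss_offset)
    return promoters


def test_initial_cutoff_perfect_separation_prefers_stringent():
    """Sites all scoring 0 with a clean background: CC = 1 across the grid,
    so the most stringent grid point is returned."""
    word = "GATTAGAT"  # one-hot 8-mer: any mismatch scores below -4
    wm = build_weights(
        count_sites(AlignedSites([word] * 10), "mono"),
        dipwm.BackgroundModel.uniform("mono"),
    )
    sites = AlignedSites([word] * 10)
    shuffled = _background_promoters(30, 60, 4, tss_offset=30)
    config = OptimizationConfig()
    cut = initial_cutoff(wm, sites, shuffled, config)
    # no shuffled window may outscore the grid floor for this to hold
    from dipwm.scan import strand_scores

    fwd, rev = strand_scores(wm, shuffled.encoded)
    assert max(fwd.max(), rev.max()) < config.cutoff_min
    assert cut == config.cutoff_min


def test_initial_cutoff_matches_brute_force_grid_search():
    rng = np.random.default_rng(6)
    wm = consensus_matrix("GATAAG")
    site_seqs = ["GATAAG"] * 8 + ["GATAAC"] * 4 + ["CCTAAC"] * 2
    sites = AlignedSites(site_seqs)
    shuffled = _background_promoters(40, 80, 7, tss_offset=40)
    config = OptimizationConfig()
    cut = initial_cutoff(wm, sites, shuffled, config)

    from dipwm.matrix import score_sites
    from dipwm.scan import n_start_positions, strand_scores

    scores = score_sites(wm, sites)
    n_starts = n_start_positions(shuffled.length, wm.motif_length)
    fwd, rev = strand_scores(wm, shuffled.encoded)
    neg = np.maximum(fwd[:, :n_starts], rev[:, :n_starts]).ravel()
    best, best_cc = None, -np.inf
    for c in config.cutoff_grid():
        tp = int((scores >= c).sum())
        fp = int((neg >= c).sum())
        cc = correlation_coefficient(
            ConfusionCounts(tp, fp, neg.size - fp, scores.size - tp)
        )
        if cc > best_cc:
            best, best_cc = float(c), cc
    assert cut == best


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def _planted_promoters(word, n_with, n_without, start_rel, length=40, tss_offset=20, minus=False):
    planted = reverse_complement(word) if minus else word
    idx = start_rel + tss_offset
    rng = np.random.default_rng(12)
    seqs = []
    for k in range(n_with + n_without):
        base = "".join("ACGT"[c] for c in rng.integers(0, 4, length))
        # scrub accidental near-matches by forcing a neutral backbone
        base = ("AC" * length)[:length]
        if k < n_with:
            base = base[:idx] + planted + base[idx + len(word):]
        seqs.append(base)
    return PromoterSet(seqs, tss_offset=tss_offset)


def test_extract_planted_sites_from_window():
    word = "GATAAG"
    wm = consensus_matrix(word)
    promoters = _planted_promoters(word, 5, 5, start_rel=-3)
    extraction = extract_window_sites(
        wm, promoters, FunctionalWindow(-3, -1), cutoff=-0.01
    )
    assert extraction.n == 5
    assert set(extraction.sequences) == {word}
    assert {o.start for o in extraction.origins} == {-3}
    assert all(o.strand == "+" for o in extraction.origins)


def test_extract_with_positive_cutoff_is_empty():
    wm = consensus_matrix("GATAAG")
    promoters = _planted_promoters("GATAAG", 3, 0, start_rel=-2)
    extraction = extract_window_sites(wm, promoters, FunctionalWindow(-3, -1), 0.5)
    assert extraction.n == 0
    with pytest.raises(ValueError):
        extraction.to_aligned_sites()


def test_extract_minus_strand_site_is_reverse_complemented():
    word = "GATAAG"
    wm = consensus_matrix(word)
    promoters = _planted_promoters(word, 4, 0, start_rel=-2, minus=True)
    extraction = extract_window_sites(wm, promoters, FunctionalWindow(-3, -1), -0.01)
    assert extraction.n == 4
    assert set(extraction.sequences) == {word}
    assert all(o.strand == "-" for o in extraction.origins)


def test_extract_rejects_window_outside_span():
    wm = consensus_matrix("GATAAG")
    promoters = _planted_promoters("GATAAG", 2, 0, start_rel=-2)
    with pytest.raises(ValueError):
        extract_window_sites(wm, promoters, FunctionalWindow(-100, -90), -1.0)


# ---------------------------------------------------------------------------
# cycles and full optimization
# ---------------------------------------------------------------------------


def _benchmark(seed, n_sequences=400, occupancy=0.4, n_sites=120):
    consensus = "ATGATAAG"
    idx = {b: i for i, b in enumerate("ACGT")}
    pfm = np.full((4, 8), 0.1 / 3)
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = 0.9
    spec = dipwm.GeneratorSpec(
        n_sequences=n_sequences, length=200, motif_pfm=pfm,
        plant_window=(-7, 0), occupancy=occupancy, seed=seed,
    )
    promoters, truth = dipwm.generate_promoters(spec)
    bg = dipwm.background_from_promoters(promoters.sequences, "mono")
    sites = dipwm.generate_site_set(pfm, n_sites, seed=seed + 1)
    wm = build_weights(count_sites(sites, "mono"), bg)
    shuffled = shuffle_database(
        promoters, ShuffleConfig(rounds_per_sequence=2, replicates=1, seed=seed + 2)
    )[0]
    return pfm, promoters, bg, sites, wm, shuffled


def test_cycle_at_fixed_point_reports_cc_one():
    """A matrix whose extraction reproduces the reference converges in one
    cycle with FP = FN = 0."""
    pfm, promoters, bg, sites, wm, shuffled = _benchmark(50)
    window = FunctionalWindow(-7, 0)
    cutoff = initial_cutoff(wm, sites, shuffled, OptimizationConfig(cutoff_min=-6.0))
    extraction = extract_window_sites(wm, promoters, window, cutoff)
    assert extraction.n > 0
    matrix = build_weights(count_sites(extraction.to_aligned_sites(), "mono"), bg)
    config = OptimizationConfig(cutoff_min=-6.0, vary_length=False)
    res = optimization_cycle(matrix, extraction, promoters, window, config, bg)
    # run a second cycle from the returned state: the accounting identity
    # holds and CC cannot decrease at the accepted state
    res2 = optimization_cycle(
        build_weights(count_sites(res.extraction.to_aligned_sites(), "mono"), bg),
        res.extraction, promoters, window, config, bg,
    )
    for r in (res, res2):
        assert r.confusion.total == window.l_w * promoters.n_s
        assert -1 <= r.cc <= 1
    if res.converged:
        assert res.cc == 1.0


def test_identical_extraction_gives_cc_one_regardless_of_tn():
    counts = cycle_confusion(n_new=10, n_original=10, tp=10, l_w=5, n_s=50)
    assert counts.fp == 0 and counts.fn == 0
    assert correlation_coefficient(counts) == 1.0


def test_optimize_recovers_planted_model_and_is_deterministic():
    """End-to-end refinement on a planted benchmark: CC trajectories are
    non-decreasing to 1, the result is reproducible, and re-optimizing the
    converged output is a fixed point."""
    pfm, promoters, bg, sites, wm, shuffled = _benchmark(60)
    config = OptimizationConfig(cutoff_min=-6.0, max_cycles=30)
    res = optimize(wm, sites, promoters, shuffled, [FunctionalWindow(-3, -1)], config, bg)
    assert res.converged
    tf = res.trajectory_frame()
    for _, group in tf.groupby("window_variant"):
        ccs = group.cc.to_numpy()
        assert (np.diff(ccs) >= -1e-12).all()
        assert ccs[-1] <= 1.0
    assert res.final_window.overlaps(FunctionalWindow(-7, 0))

    # determinism: identical inputs give an identical trajectory
    res_again = optimize(
        wm, sites, promoters, shuffled, [FunctionalWindow(-3, -1)], config, bg
    )
    assert res.trajectory == res_again.trajectory
    assert np.array_equal(res.final_matrix.weights, res_again.final_matrix.weights)

    # idempotence: optimizing the converged matrix changes nothing
    res_fixed = optimize(
        res.final_matrix, sites, promoters, shuffled, [res.final_window], config, bg
    )
    assert np.allclose(res_fixed.final_matrix.weights, res.final_matrix.weights)
    assert (res_fixed.final_window.start, res_fixed.final_window.end) == (
        res.final_window.start, res.final_window.end,
    )


def test_optimize_requires_nonempty_extraction():
    pfm, promoters, bg, sites, wm, shuffled = _benchmark(70, n_sequences=50, occupancy=0.0)
    impossible = wm.with_cutoff(1.0)  # scores are never positive
    with pytest.raises(ValueError):
        optimize(
            impossible, sites, promoters, shuffled,
            [FunctionalWindow(-3, -1)], OptimizationConfig(), bg,
        )
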