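import numpy as np
import pytest

from dcescan.correlation import MaskedCorrelation, permutation_mask
from dcescan.detection import (
    BinSignal, DCESet, bin_signal, call_dces, detect_minima,
    evaluate_boundaries, fuse_dces, read_bed, tune_window, write_bed,
)
from conftest import make_binned


def mc_from_matrix(masked: np.ndarray) -> MaskedCorrelation:
    n = masked.shape[0]
    return MaskedCorrelation(
        chrom="chrT", group="g", bin_index=np.arange(n),
        rho=masked.copy(), pval=np.zeros((n, n)), masked_rho=masked,
        n_perm=0, alpha=0.05, seed=None, constant_bins=np.array([], dtype=int),
    )


def block_matrix(n, blocks, value=1.0, base=0.0):
    m = np.full((n, n), base)
    for lo, hi in blocks:
        m[lo : hi + 1, lo : hi + 1] = value
    np.fill_diagonal(m, 1.0)
    return m


def brute_force_signal(m, w):
    """Oracle: explicit double loop over the cross-window pairs."""
    n = m.shape[0]
    sig = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        total = 0.0
        for a in range(i - w + 1, i + 1):
            for b in range(i + 1, i + w + 1):
                total += m[a, b]
        sig[i] = total / (w * w)
    sig[: w - 1] = sig[w - 1]
    sig[n - w :] = sig[n - w - 1]
    return sig


class TestBinSignal:
    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(15):
            n = int(rng.integers(8, 50))
            w = int(rng.integers(2, 5))
            m = rng.uniform(-1, 1, size=(n, n))
            m = (m + m.T) / 2
            sig = bin_signal(mc_from_matrix(m), w=w)
            np.testing.assert_allclose(sig.values, brute_force_signal(m, w), atol=1e-12)

    def test_zero_matrix_gives_zero_signal(self):
        m = np.zeros((12, 12)); np.fill_diagonal(m, 1.0)
        sig = bin_signal(mc_from_matrix(m), w=3)
        np.testing.assert_allclose(sig.values, 0.0)

    def test_block_interior_high_and_drops_at_edge(self):
        m = block_matrix(20, [(0, 9)])
        sig = bin_signal(mc_from_matrix(m), w=3)
        assert sig.values[4] == pytest.approx(1.0)
        assert sig.values[9] < sig.values[4]  # crossing the block edge
        assert sig.values[13] == pytest.approx(0.0)

    def test_junction_of_two_blocks_is_a_local_minimum(self):
        m = block_matrix(24, [(0, 11), (12, 23)])
        sig = bin_signal(mc_from_matrix(m), w=3)
        assert sig.values[11] < sig.values[8]
        assert sig.values[11] < sig.values[14]

    def test_short_chromosome_is_an_error(self):
        m = np.eye(5)
        with pytest.raises(ValueError, match="surviving bins"):
            bin_signal(mc_from_matrix(m), w=3)


def make_signal(values, w=3):
    values = np.asarray(values, dtype=float)
    return BinSignal(
        chrom="chrT", group="g", w=w, values=values,
        smoothed=values.copy(), bin_index=np.arange(len(values)),
    )


class TestDetectMinima:
    def test_single_basin_gives_boundary_and_two_domains(self):
        values = np.r_[np.full(10, 0.8), [0.05], np.full(10, 0.8)]
        sig = make_signal(values)
        minima, domains = detect_minima(sig)
        assert minima == [10]
        assert domains == [(2, 10), (11, 17)]

    def test_all_below_threshold_gives_no_domains(self):
        sig = make_signal(np.full(15, 0.1))
        minima, domains = detect_minima(sig)
        assert domains == []

    def test_two_basins_give_three_domains(self):
        values = np.r_[np.full(6, 0.8), [0.0], np.full(6, 0.8), [0.0], np.full(6, 0.8)]
        _, domains = detect_minima(make_signal(values))
        assert len(domains) == 3

    def test_high_valued_minimum_does_not_split(self):
        values = np.r_[np.full(6, 0.9), [0.5], np.full(6, 0.9)]
        minima, domains = detect_minima(make_signal(values))
        assert minima == []
        assert len(domains) == 1

    def test_domains_break_at_long_missing_runs(self):
        values = np.full(14, 0.8)
        sig = make_signal(values)
        sig.bin_index = np.r_[np.arange(7), np.arange(12, 19)]  # 5 missing bins
        _, domains = detect_minima(sig, max_missing_gap=2)
        assert domains == [(2, 6), (7, 10)]  # admissible range is 2..10 for w=3


class TestEvaluateBoundaries:
    def test_perfect_block_keeps_both_boundaries(self):
        m = block_matrix(24, [(8, 15)], value=0.9)
        out = evaluate_boundaries([(8, 15)], mc_from_matrix(m), w=3)
        assert len(out) == 1
        s, e, lp, rp = out[0]
        assert (s, e) == (8, 15)
        assert lp <= 0.05 and rp <= 0.05

    def test_one_bin_overhang_chopped_exactly_once(self):
        m = block_matrix(24, [(9, 15)], value=0.9)
        out = evaluate_boundaries([(8, 15)], mc_from_matrix(m), w=3)
        assert [(s, e) for s, e, *_ in out] == [(9, 15)]

    def test_noise_domain_discarded(self, rng):
        m = np.zeros((30, 30))
        np.fill_diagonal(m, 1.0)
        out = evaluate_boundaries([(10, 20)], mc_from_matrix(m), w=3)
        assert out == []


class TestFusion:
    def test_one_low_gap_bin_fuses(self):
        signal = np.full(20, 0.1)
        signal[3:8] = 0.9
        signal[9:14] = 0.9
        out = fuse_dces([(3, 7, 0.01, 0.01), (9, 13, 0.01, 0.01)], signal)
        assert [(s, e) for s, e, *_ in out] == [(3, 13)]

    def test_three_domains_with_two_low_bins_fuse_into_one(self):
        signal = np.full(24, 0.1)
        doms = [(2, 5, 0.01, 0.01), (7, 10, 0.01, 0.01), (12, 15, 0.01, 0.01)]
        for s, e, *_ in doms:
            signal[s : e + 1] = 0.9
        out = fuse_dces(doms, signal)
        assert [(s, e) for s, e, *_ in out] == [(2, 15)]

    def test_fourth_domain_starts_a_new_chain(self):
        signal = np.full(30, 0.1)
        doms = [(2, 5), (7, 10), (12, 15), (17, 20)]
        for s, e in doms:
            signal[s : e + 1] = 0.9
        out = fuse_dces([(s, e, 0.01, 0.01) for s, e in doms], signal)
        assert [(s, e) for s, e, *_ in out] == [(2, 15), (17, 20)]

    def test_high_signal_gap_blocks_fusion(self):
        signal = np.full(20, 0.9)
        out = fuse_dces([(3, 7, 0.01, 0.01), (9, 13, 0.01, 0.01)], signal)
        assert len(out) == 2


class TestCallDces:
    def test_planted_blocks_recovered_and_invariants_hold(self, rng):
        # two latent blocks, independent background
        n_bins, n_samp = 60, 40
        latents = rng.normal(size=(2, n_samp))
        values = np.exp(rng.normal(0, 0.3, size=(n_bins, n_samp)) + 4.0)
        for k, (lo, hi) in enumerate([(10, 22), (35, 50)]):
            values[lo : hi + 1] *= np.exp(latents[k])[None, :]
        be, samples = make_binned(values)
        dceset = call_dces(be, samples, group="healthy", n_perm=100, seed=7)
        ranges = [(d.start_bin, d.end_bin) for d in dceset.dces]
        assert len(ranges) == 2
        for (lo, hi), (s, e) in zip([(10, 22), (35, 50)], ranges):
            assert abs(s - lo) <= 1 and abs(e - hi) <= 1
        for d in dceset.dces:
            assert d.left_p <= 0.05 and d.right_p <= 0.05
            assert d.end > d.start
            assert d.genes  # bin->gene map propagated
        starts = [d.start for d in dceset.dces]
        ends = [d.end for d in dceset.dces]
        assert all(e <= s for e, s in zip(ends, starts[1:]))  # non-overlap

    def test_same_seed_reproduces_identical_set(self, rng):
        values = rng.lognormal(size=(25, 20))
        values[5:15] *= np.exp(rng.normal(size=20))[None, :]
        be, samples = make_binned(values)
        a = call_dces(be, samples, n_perm=60, seed=9)
        b = call_dces(be, samples, n_perm=60, seed=9)
        assert [(d.start, d.end, d.left_p, d.right_p) for d in a.dces] == \
               [(d.start, d.end, d.left_p, d.right_p) for d in b.dces]

    def test_tiny_chromosome_skipped_with_warning(self, rng):
        be, samples = make_binned(rng.lognormal(size=(4, 10)))
        with pytest.warns(UserWarning, match="skipped"):
            out = call_dces(be, samples, w=3, n_perm=20, seed=0)
        assert len(out) == 0


class TestTuneWindow:
    def test_single_candidate_returned(self, rng):
        values = rng.lognormal(size=(30, 25))
        values[8:20] *= np.exp(rng.normal(size=25))[None, :]
        be, samples = make_binned(values)
        assert tune_window(be, samples, [3], n_perm=60, seed=1) == 3

    def test_planted_blocks_select_small_window(self, rng):
        values = np.exp(rng.normal(0, 0.3, size=(50, 40)) + 4.0)
        for lo, hi in [(8, 17), (28, 39)]:
            values[lo : hi + 1] *= np.exp(rng.normal(size=40))[None, :]
        be, samples = make_binned(values)
        w = tune_window(be, samples, [2, 3, 4], n_perm=80, seed=2)
        assert w in (2, 3, 4)
        # deterministic under the same seed
        assert w == tune_window(be, samples, [2, 3, 4], n_perm=80, seed=2)


def test_bed_roundtrip(tmp_path, rng):
    values = rng.lognormal(size=(30, 25))
    values[5:15] *= np.exp(rng.normal(size=25))[None, :]
    be, samples = make_binned(values)
    dceset = call_dces(be, samples, group="healthy", n_perm=60, seed=3)
    assert len(dceset) >= 1
    path = tmp_path / "dce.bed"
    write_bed(dceset, str(path))
    back = read_bed(str(path), group="healthy")
    assert [(d.chrom, d.start, d.end) for d in back.dces] == \
           [(d.chrom, d.start, d.end) for d in dceset.dces]


def test_overlapping_dces_rejected():
    from dcescan.detection import DCE

    mk = lambda s, e: DCE(chrom="chr1", start_bin=0, end_bin=0, start=s, end=e,
                          mean_signal=0.5, left_p=0.01, right_p=0.01)
    with pytest.raises(ValueError, match="overlapping"):
        DCESet(group="g", dces=[mk(0, 100), mk(50, 150)])
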