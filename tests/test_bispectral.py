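"""Bispectrum estimation, bootstrap class CIs, gap band/box detection."""

import numpy as np
import pytest

from tbs.bispectral import (ClassBandCI, bootstrap_class_ci,
                            detect_gap_bands_1d, detect_gap_boxes_2d,
                            estimate_bispectrum)

FS = 10240.0
NPER = 256
DF = FS / NPER  # 40 Hz bins


def _qpc_signal(fa, fb, n_segments=64, seed=0):
    """Quadratically coupled triad with randomized per-segment phases: the
    classic construction with a bispectral peak at (fa, fb)."""
    rng = np.random.default_rng(seed)
    t = np.arange(NPER) / FS
    parts = []
    for _ in range(n_segments):
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        parts.append(np.cos(2 * np.pi * fa * t + p1) +
                     np.cos(2 * np.pi * fb * t + p2) +
                     0.5 * np.cos(2 * np.pi * (fa + fb) * t + p1 + p2))
    return np.concatenate(parts)


class TestBispectrum:
    def test_qpc_peak_dominates_background(self):
        fa, fb = 400.0, 600.0
        bm = estimate_bispectrum(_qpc_signal(fa, fb), FS, nperseg=NPER)
        peak = bm.magnitude[int(fb / DF), int(fa / DF)]
        background = np.median(bm.magnitude[bm.magnitude > 0])
        assert peak > 10 * background

    def test_gaussian_noise_has_no_structure(self):
        rng = np.random.default_rng(1)
        fa, fb = 400.0, 600.0
        qpc = estimate_bispectrum(_qpc_signal(fa, fb), FS, nperseg=NPER)
        noise = estimate_bispectrum(rng.standard_normal(64 * NPER), FS,
                                    nperseg=NPER)
        assert noise.magnitude.max() < 0.05 * \
            qpc.magnitude[int(fb / DF), int(fa / DF)]

    def test_exact_symmetry(self):
        rng = np.random.default_rng(2)
        bm = estimate_bispectrum(rng.standard_normal(8 * NPER), FS,
                                 nperseg=NPER)
        assert np.array_equal(bm.magnitude, bm.magnitude.T)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            estimate_bispectrum(np.zeros(NPER), FS, nperseg=NPER)


class TestBootstrapCI:
    def test_identical_subjects_collapse(self):
        spec = np.linspace(1, 2, 20)
        ci = bootstrap_class_ci(np.tile(spec, (5, 1)), n_boot=200, seed=0)
        assert np.allclose(ci.lower, spec)
        assert np.allclose(ci.upper, spec)

    def test_bounds_bracket_mean_and_order(self):
        rng = np.random.default_rng(3)
        spectra = rng.random((12, 30)) + 1
        ci = bootstrap_class_ci(spectra, n_boot=300, seed=1)
        assert np.all(ci.lower <= ci.mean + 1e-12)
        assert np.all(ci.mean <= ci.upper + 1e-12)

    def test_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((160, 25))

        def mean_width(n):
            ci = bootstrap_class_ci(base[:n], n_boot=600, seed=2)
            return np.mean(ci.upper - ci.lower)

        ratio = mean_width(40) / mean_width(160)
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        spectra = rng.random((8, 10))
        a = bootstrap_class_ci(spectra, n_boot=100, seed=9)
        b = bootstrap_class_ci(spectra, n_boot=100, seed=9)
        assert np.array_equal(a.lower, b.lower)
        assert np.array_equal(a.upper, b.upper)

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            bootstrap_class_ci(np.ones((2, 5)))


def _ci(lower, upper, label, grid=None):
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    return ClassBandCI(grid=grid, lower=lower, mean=(lower + upper) / 2,
                       upper=upper, class_label=label, n_boot=0)


class TestGapBands:
    def test_identical_classes_no_gap(self):
        a = _ci(np.zeros(30), np.ones(30), "A", np.arange(30.0))
        assert detect_gap_bands_1d(a, a) == []

    def test_offset_region_gives_one_exact_band(self):
        """Brute-force oracle: bins 10..20 separated, everything else
        overlapping."""
        n = 40
        lo_a, up_a = np.zeros(n), np.ones(n)
        lo_b, up_b = np.zeros(n), np.ones(n)
        lo_b[10:21] += 5.0
        up_b[10:21] += 5.0
        bands = detect_gap_bands_1d(_ci(lo_a, up_a, "A", np.arange(float(n))),
                                    _ci(lo_b, up_b, "B", np.arange(float(n))),
                                    min_bins=2)
        assert len(bands) == 1
        assert (bands[0].bin_lo, bands[0].bin_hi) == (10, 20)
        assert bands[0].direction == "B"

    def test_bridge_below_min_bins_splits_runs(self):
        n = 30
        lo_b, up_b = np.zeros(n), np.ones(n)
        lo_b[5:8] += 5; up_b[5:8] += 5
        lo_b[9:12] += 5; up_b[9:12] += 5  # bin 8 overlaps: 1-bin bridge
        bands = detect_gap_bands_1d(_ci(np.zeros(n), np.ones(n), "A"),
                                    _ci(lo_b, up_b, "B"),
                                    min_bins=2, freqs=np.arange(float(n)))
        assert [(b.bin_lo, b.bin_hi) for b in bands] == [(5, 7), (9, 11)]

    def test_symmetric_in_class_order(self):
        n = 25
        lo_b, up_b = np.zeros(n), np.ones(n)
        lo_b[4:9] += 3; up_b[4:9] += 3
        a = _ci(np.zeros(n), np.ones(n), "A", np.arange(float(n)))
        b = _ci(lo_b, up_b, "B", np.arange(float(n)))
        ab = detect_gap_bands_1d(a, b)
        ba = detect_gap_bands_1d(b, a)
        assert [(x.bin_lo, x.bin_hi) for x in ab] == \
            [(x.bin_lo, x.bin_hi) for x in ba]
        assert ab[0].direction == ba[0].direction == "B"

    def test_wider_intervals_never_create_gaps(self):
        """Monotonicity: inflating both CIs symmetrically can only lose
        gap bins."""
        rng = np.random.default_rng(6)
        n = 50
        mid_a = rng.random(n)
        mid_b = rng.random(n) + 0.3
        for widen in (0.0, 0.2, 0.5):
            def bands_at(w):
                a = _ci(mid_a - 0.1 - w, mid_a + 0.1 + w, "A", np.arange(float(n)))
                b = _ci(mid_b - 0.1 - w, mid_b + 0.1 + w, "B", np.arange(float(n)))
                return detect_gap_bands_1d(a, b, min_bins=1)

            narrow_bins = {i for b in bands_at(0.0)
                           for i in range(b.bin_lo, b.bin_hi + 1)}
            wide_bins = {i for b in bands_at(widen)
                         for i in range(b.bin_lo, b.bin_hi + 1)}
            assert wide_bins <= narrow_bins


class TestGapBoxes:
    def test_no_disjoint_bins_empty(self):
        a = _ci(np.zeros((10, 10)), np.ones((10, 10)), "A")
        assert detect_gap_boxes_2d(a, a) == []

    def test_injected_block_exact_bounds(self):
        """Flood-fill oracle: a single 5x3 separated block yields one box
        with exactly those index bounds."""
        lo_b = np.zeros((20, 20)); up_b = np.ones((20, 20))
        lo_b[4:9, 10:13] += 9; up_b[4:9, 10:13] += 9
        boxes = detect_gap_boxes_2d(
            _ci(np.zeros((20, 20)), np.ones((20, 20)), "A"),
            _ci(lo_b, up_b, "B"), min_area=4,
            f1=np.arange(20.0), f2=np.arange(20.0))
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.row_lo, b.row_hi, b.col_lo, b.col_hi) == (4, 8, 10, 12)
        assert b.component_size == 15

    def test_diagonal_touching_blocks_are_one_component(self):
        lo_b = np.zeros((12, 12)); up_b = np.ones((12, 12))
        lo_b[2:4, 2:4] += 9; up_b[2:4, 2:4] += 9
        lo_b[4:6, 4:6] += 9; up_b[4:6, 4:6] += 9
        boxes = detect_gap_boxes_2d(
            _ci(np.zeros((12, 12)), np.ones((12, 12)), "A"),
            _ci(lo_b, up_b, "B"), min_area=4,
            f1=np.arange(12.0), f2=np.arange(12.0))
        assert len(boxes) == 1
        assert boxes[0].component_size == 8

    def test_min_area_and_ordering(self):
        lo_b = np.zeros((30, 30)); up_b = np.ones((30, 30))
        lo_b[1:3, 1:3] += 9; up_b[1:3, 1:3] += 9      # area 4
        lo_b[10:15, 10:15] += 9; up_b[10:15, 10:15] += 9  # area 25
        lo_b[20:21, 20:21] += 9; up_b[20:21, 20:21] += 9  # area 1, dropped
        boxes = detect_gap_boxes_2d(
            _ci(np.zeros((30, 30)), np.ones((30, 30)), "A"),
            _ci(lo_b, up_b, "B"), min_area=4,
            f1=np.arange(30.0), f2=np.arange(30.0))
        assert [b.component_size for b in boxes] == [25, 4]

    def test_every_disjoint_bin_covered_unless_small(self):
        rng = np.random.default_rng(7)
        mask_src = rng.random((25, 25)) < 0.12
        lo_b = np.zeros((25, 25)); up_b = np.ones((25, 25))
        lo_b[mask_src] += 9; up_b[mask_src] += 9
        boxes = detect_gap_boxes_2d(
            _ci(np.zeros((25, 25)), np.ones((25, 25)), "A"),
            _ci(lo_b, up_b, "B"), min_area=1,
            f1=np.arange(25.0), f2=np.arange(25.0))
        covered = np.zeros((25, 25), dtype=bool)
        for b in boxes:
            covered[b.row_lo:b.row_hi + 1, b.col_lo:b.col_hi + 1] = True
        assert np.all(covered[mask_src])
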