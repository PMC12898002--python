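"""Bispectrum estimation and class-pair gap-region detection.

The bispectrum B(f1, f2) = E[X(f1) X(f2) X*(f1+f2)] is a third-order spectrum
that vanishes for Gaussian processes and peaks where quadratic phase coupling
links frequency triads (f1, f2, f1+f2) — a signature of nonlinear airflow
interaction in breathing sounds.  Class contrasts are localized by bootstrap
confidence intervals of the class-mean spectra: frequency bands (1D, on the
PSD) or bifrequency boxes (2D, on the bispectrum) where the two classes' 95%
CIs do not overlap become the "gap regions" from which Range/BBox features
are extracted downstream.  Gap regions must be learned on training subjects
only and frozen before they touch held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BispectrumMatrix",
    "ClassBandCI",
    "GapBand1D",
    "BispecGapBox",
    "estimate_bispectrum",
    "bootstrap_class_ci",
    "detect_gap_bands_1d",
    "detect_gap_boxes_2d",
]


@dataclass
class BispectrumMatrix:
    f1: np.ndarray
    f2: np.ndarray
    magnitude: np.ndarray  # (len(f2), len(f1)), symmetric, zero outside f1+f2 <= fs/2
    n_segments: int


@dataclass
class ClassBandCI:
    """Per-bin 95% bootstrap percentile CI of a class's mean spectrum.

    ``grid`` is the 1D frequency axis or the (f1, f2) axes tuple; lower/mean/
    upper share the spectrum's shape.
    """

    grid: object
    lower: np.ndarray
    mean: np.ndarray
    upper: np.ndarray
    class_label: str
    n_boot: int


@dataclass
class GapBand1D:
    f_lo: float
    f_hi: float
    bin_lo: int
    bin_hi: int  # inclusive
    direction: str  # class label whose CI lies above


@dataclass
class BispecGapBox:
    row_lo: int
    row_hi: int  # inclusive index bounds on the bifrequency grid
    col_lo: int
    col_hi: int
    f1_extent: tuple[float, float]
    f2_extent: tuple[float, float]
    component_id: int
    component_size: int


def estimate_bispectrum(x: np.ndarray, fs: float, nperseg: int = 256,
                        overlap: float = 0.5) -> BispectrumMatrix:
    """Direct (FFT) bispectrum estimate: per Hann-windowed segment accumulate
    X(f1) X(f2) X*(f1+f2), average over segments, return the magnitude.

    The matrix is computed on the full rfft grid and is exactly symmetric in
    (f1, f2); entries with f1+f2 > fs/2 are zero.
    """
    x = np.asarray(x, dtype=float)
    hop = int(nperseg * (1 - overlap))
    if x.size < nperseg + hop:
        raise ValueError("input too short for two segments")
    win = np.hanning(nperseg)
    nf = nperseg // 2 + 1
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    sum_idx = np.add.outer(np.arange(nf), np.arange(nf))
    valid = sum_idx < nf
    sum_idx_c = np.where(valid, sum_idx, 0)
    acc = np.zeros((nf, nf), dtype=complex)
    n_seg = 0
    for start in range(0, x.size - nperseg + 1, hop):
        seg = x[start:start + nperseg]
        X = np.fft.rfft((seg - seg.mean()) * win)
        acc += np.outer(X, X) * np.conj(X[sum_idx_c]) * valid
        n_seg += 1
    mag = np.abs(acc) / n_seg
    mag = 0.5 * (mag + mag.T)  # symmetric up to float roundoff; enforce exactly
    return BispectrumMatrix(f1=freqs, f2=freqs, magnitude=mag, n_segments=n_seg)


def bootstrap_class_ci(spectra: np.ndarray, class_label: str = "",
                       alpha: float = 0.05, n_boot: int = 1000,
                       seed: int = 0, grid=None) -> ClassBandCI:
    """Percentile bootstrap CI for the class-mean spectrum.

    ``spectra`` stacks one spectrum per subject along axis 0 (subjects are
    the exchangeable resampling unit); any spectrum shape (1D band or 2D
    bifrequency matrix) is supported.
    """
    spectra = np.asarray(spectra, dtype=float)
    n = spectra.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects for a bootstrap CI")
    rng = np.random.default_rng(seed)
    flat = spectra.reshape(n, -1)
    idx = rng.integers(0, n, size=(n_boot, n))
    # bootstrap means via a weight matrix: counts (n_boot, n) @ flat (n, bins)
    counts = np.zeros((n_boot, n))
    for b in range(n_boot):
        np.add.at(counts[b], idx[b], 1.0)
    boots = (counts / n) @ flat
    lo = np.quantile(boots, alpha / 2, axis=0).reshape(spectra.shape[1:])
    hi = np.quantile(boots, 1 - alpha / 2, axis=0).reshape(spectra.shape[1:])
    mean = spectra.mean(axis=0)
    lo = np.minimum(lo, mean)  # percentile bounds bracket the sample mean
    hi = np.maximum(hi, mean)
    return ClassBandCI(grid=grid, lower=lo, mean=mean, upper=hi,
                       class_label=class_label, n_boot=n_boot)


def _disjoint_mask(ci_a: ClassBandCI, ci_b: ClassBandCI) -> np.ndarray:
    if ci_a.lower.shape != ci_b.lower.shape:
        raise ValueError("class CIs on mismatched grids")
    return np.maximum(ci_a.lower, ci_b.lower) > np.minimum(ci_a.upper, ci_b.upper)


def detect_gap_bands_1d(ci_a: ClassBandCI, ci_b: ClassBandCI,
                        min_bins: int = 2,
                        freqs: np.ndarray | None = None) -> list[GapBand1D]:
    """Maximal runs of bins where the two classes' CIs are disjoint; runs
    shorter than ``min_bins`` are dropped.  ``direction`` names the class
    whose interval lies above within the run."""
    mask = _disjoint_mask(ci_a, ci_b)
    f = np.asarray(freqs if freqs is not None else ci_a.grid, dtype=float)
    bands = []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges, [mask.size - 1]))
    for s, e in zip(starts, ends):
        if not mask[s] or (e - s + 1) < min_bins:
            continue
        above = ci_a if ci_a.lower[s] > ci_b.upper[s] else ci_b
        bands.append(GapBand1D(f_lo=float(f[s]), f_hi=float(f[e]),
                               bin_lo=int(s), bin_hi=int(e),
                               direction=above.class_label))
    return bands


def detect_gap_boxes_2d(ci_a: ClassBandCI, ci_b: ClassBandCI,
                        min_area: int = 4,
                        f1: np.ndarray | None = None,
                        f2: np.ndarray | None = None) -> list[BispecGapBox]:
    """Tight bounding boxes of 8-connected components of the disjoint-CI
    mask on the bifrequency grid, ordered by descending component size with
    ties broken by the top-left corner."""
    mask = _disjoint_mask(ci_a, ci_b)
    if f1 is None or f2 is None:
        if ci_a.grid is not None:
            f1, f2 = ci_a.grid
        else:
            f1 = np.arange(mask.shape[1], dtype=float)
            f2 = np.arange(mask.shape[0], dtype=float)
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    boxes = []
    for comp_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        size = int(np.count_nonzero(labels == comp_id))
        if size < min_area:
            continue
        r0, r1 = sl[0].start, sl[0].stop - 1
        c0, c1 = sl[1].start, sl[1].stop - 1
        boxes.append(BispecGapBox(
            row_lo=int(r0), row_hi=int(r1), col_lo=int(c0), col_hi=int(c1),
            f1_extent=(float(f1[c0]), float(f1[c1])),
            f2_extent=(float(f2[r0]), float(f2[r1])),
            component_id=comp_id, component_size=size))
    boxes.sort(key=lambda b: (-b.component_size, b.row_lo, b.col_lo))
    return boxes
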