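"""Image-style descriptors of spectrogram / bispectrum sub-regions.

A gap bounding box cuts a non-negative sub-matrix (a :class:`RegionMatrix`)
out of a time-frequency or bifrequency magnitude image.  Three descriptor
families are computed on it: value statistics (moments, entropy, energy,
intensity-weighted centroids), binary shape/topology metrics after Otsu
thresholding (components, holes, Euler number, perimeter, compactness,
box-counting fractal dimension), and gray-level co-occurrence (GLCM) texture
(contrast, homogeneity, correlation, energy).  All are invariant to global
positive scaling of the region values: thresholds and quantization are
relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu

from .spectral import DescriptorMap

__all__ = [
    "RegionMatrix",
    "BinaryMask",
    "region_statistics",
    "binarize_region",
    "region_morphology",
    "glcm_texture",
    "box_counting_dimension",
]


@dataclass
class RegionMatrix:
    """Non-negative sub-matrix with axis calibration.

    ``row_axis``/``col_axis`` carry physical coordinates per row/column
    (Hz for bispectrum rows/cols; Hz rows and seconds columns for
    spectrograms).  ``freq_axis`` names which axis is frequency ("row" or
    "col") for the frequency-weighted statistics.
    """

    values: np.ndarray
    row_axis: np.ndarray | None = None
    col_axis: np.ndarray | None = None
    freq_axis: str = "row"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty region")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("region values must be finite and non-negative")
        self.values = v


@dataclass
class BinaryMask:
    mask: np.ndarray
    threshold_method: str
    threshold_value: float
    flagged: bool = False


def region_statistics(region: RegionMatrix) -> DescriptorMap:
    """Value statistics of the region: moments, quantiles, entropy of the
    L1-normalized cells, energy, peak, intensity-weighted centroids, and
    frequency-axis weighted centroid/bandwidth."""
    v = region.values
    flat = v.ravel()
    out = DescriptorMap()
    out["MeanValue"] = flat.mean()
    out["MedianValue"] = np.median(flat)
    out["StdValue"] = flat.std(ddof=0)
    q1, q3 = np.quantile(flat, [0.25, 0.75])  # linear-interpolation quantiles
    out["IQRValue"] = q3 - q1
    sd = flat.std(ddof=0)
    if flat.size >= 4 and sd > 0:
        z = (flat - flat.mean()) / sd
        out["SkewnessValue"] = np.mean(z ** 3)
        out["KurtosisValue"] = np.mean(z ** 4) - 3.0
    else:
        out.flag("SkewnessValue")
        out.flag("KurtosisValue")
    out["EnergyValue"] = np.sum(flat ** 2)
    out["PeakValue"] = flat.max()
    total = flat.sum()
    if total > 0:
        p = flat / total
        nz = p[p > 0]
        out["EntropyValue"] = -np.sum(nz * np.log(nz))
        rows, cols = np.indices(v.shape)
        w = v / total
        cy = float(np.sum(w * rows))
        cx = float(np.sum(w * cols))
        out["CentroidX"] = cx
        out["CentroidY"] = cy
        # frequency-calibrated centroid/bandwidth along the frequency axis
        if region.freq_axis == "row":
            axis_vals, axis_w = region.row_axis, w.sum(axis=1)
        else:
            axis_vals, axis_w = region.col_axis, w.sum(axis=0)
        if axis_vals is not None:
            axis_vals = np.asarray(axis_vals, dtype=float)
            fc = float(np.sum(axis_w * axis_vals))
            out["FrequencyCentroidX"] = fc
            out["FrequencyBandwidth"] = float(
                np.sqrt(np.sum(axis_w * (axis_vals - fc) ** 2)))
    else:
        for k in ("EntropyValue", "CentroidX", "CentroidY",
                  "FrequencyCentroidX", "FrequencyBandwidth"):
            out.flag(k)
    return out


def binarize_region(region: RegionMatrix) -> BinaryMask:
    """Otsu threshold (256-bin histogram) on the region values; degenerate
    single-valued regions fall back to max/2 and yield an all-false mask."""
    v = region.values
    if np.unique(v).size < 2:
        thr = float(v.max() / 2)
        return BinaryMask(mask=np.zeros_like(v, dtype=bool),
                          threshold_method="max/2", threshold_value=thr,
                          flagged=True)
    thr = float(threshold_otsu(v, nbins=256))
    return BinaryMask(mask=v > thr, threshold_method="otsu",
                      threshold_value=thr)


_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _count_holes(mask: np.ndarray) -> int:
    """4-connected background components not touching the border."""
    bg, n = ndimage.label(~mask, structure=_FOUR)
    if n == 0:
        return 0
    border = np.unique(np.concatenate([bg[0], bg[-1], bg[:, 0], bg[:, -1]]))
    return int(n - np.count_nonzero(border))


def _perimeter(mask: np.ndarray) -> int:
    """Exposed-edge count: 4*area minus twice the 4-neighbour adjacencies."""
    area = int(mask.sum())
    adj = int(np.count_nonzero(mask[:, :-1] & mask[:, 1:]) +
              np.count_nonzero(mask[:-1, :] & mask[1:, :]))
    return 4 * area - 2 * adj


def box_counting_dimension(mask: np.ndarray) -> float:
    """Least-squares slope of log N(s) vs log(1/s) over box sizes 1,2,4,..."""
    if not mask.any():
        return 0.0
    n = max(mask.shape)
    sizes = []
    s = 1
    while s <= n:
        sizes.append(s)
        s *= 2
    counts = []
    for s in sizes:
        h = -(-mask.shape[0] // s)
        w = -(-mask.shape[1] // s)
        padded = np.zeros((h * s, w * s), dtype=bool)
        padded[:mask.shape[0], :mask.shape[1]] = mask
        blocks = padded.reshape(h, s, w, s).any(axis=(1, 3))
        counts.append(max(1, int(blocks.sum())))
    if len(sizes) < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(np.asarray(counts, dtype=float)), 1)[0]
    return float(slope)


def region_morphology(mask: BinaryMask | np.ndarray) -> DescriptorMap:
    """Shape/topology metrics of a binary mask: area, tight bounding-box
    geometry, exposed-edge perimeter, compactness, 8-connected components,
    4-connected holes, Euler number = components - holes, and box-counting
    fractal dimension."""
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("empty mask")
    out = DescriptorMap()
    area = int(m.sum())
    out["Area"] = area
    if area == 0:
        for k in ("BoundingBoxWidth", "BoundingBoxHeight", "BoundingBoxDiagonal",
                  "AspectRatio", "Perimeter", "Compactness",
                  "ConnectedComponents", "Holes", "EulerNumber",
                  "FractalDimension"):
            out[k] = 0.0
        out.flags.update(out.values.keys())
        return out
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    h = int(rows[-1] - rows[0] + 1)
    w = int(cols[-1] - cols[0] + 1)
    out["BoundingBoxWidth"] = w
    out["BoundingBoxHeight"] = h
    # Euclidean distance between opposite corner cell centres
    out["BoundingBoxDiagonal"] = float(np.hypot(w - 1, h - 1))
    out["AspectRatio"] = w / h
    per = _perimeter(m)
    out["Perimeter"] = per
    out["Compactness"] = 4 * np.pi * area / per ** 2 if per > 0 else 0.0
    _, n_comp = ndimage.label(m, structure=_EIGHT)
    holes = _count_holes(m)
    out["ConnectedComponents"] = n_comp
    out["Holes"] = holes
    out["EulerNumber"] = n_comp - holes
    out["FractalDimension"] = box_counting_dimension(m)
    return out


def glcm_texture(region: RegionMatrix, levels: int = 8,
                 offsets=((0, 1), (1, 0))) -> DescriptorMap:
    """GLCM texture scalars from the symmetric, normalized co-occurrence
    matrix averaged over the given distance-1 offsets.

    Values are quantized to ``levels`` equal-width gray levels.  Energy is
    the sum of squared co-occurrence probabilities (angular second moment).
    Correlation is undefined for single-level regions and flagged.
    """
    v = region.values
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("region must be at least 2x2")
    rng = v.max() - v.min()
    if rng == 0:
        q = np.zeros(v.shape, dtype=np.uint8)
    else:
        q = np.minimum((levels * (v - v.min()) / rng).astype(int),
                       levels - 1).astype(np.uint8)
    # skimage encodes an offset as (distance, angle); (0,1)->0, (1,0)->pi/2
    angle_of = {(0, 1): 0.0, (1, 0): np.pi / 2, (1, 1): np.pi / 4,
                (1, -1): 3 * np.pi / 4}
    angles = [angle_of[tuple(o)] for o in offsets]
    glcm = graycomatrix(q, distances=[1], angles=angles, levels=levels,
                        symmetric=True, normed=True)
    p = glcm[:, :, 0, :].mean(axis=2)
    p = p / p.sum()
    i, j = np.indices(p.shape)
    out = DescriptorMap()
    out["TextureContrast"] = float(np.sum(p * (i - j) ** 2))
    out["TextureHomogeneity"] = float(np.sum(p / (1.0 + (i - j) ** 2)))
    out["TextureEnergy"] = float(np.sum(p ** 2))
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)
    sd_i = np.sqrt(np.sum(p * (i - mu_i) ** 2))
    sd_j = np.sqrt(np.sum(p * (j - mu_j) ** 2))
    if sd_i > 0 and sd_j > 0:
        out["TextureCorrelation"] = float(
            np.sum(p * (i - mu_i) * (j - mu_j)) / (sd_i * sd_j))
    else:
        out.flag("TextureCorrelation")
    return out
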