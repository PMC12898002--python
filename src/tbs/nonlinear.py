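"""Fractal, chaos, recurrence and time-frequency descriptor families.

All estimators are deterministic given input and configuration.  The fractal
and recurrence estimators operate on short (<= a few thousand sample) series;
callers are expected to downsample mid-flow segments first to bound the
O(n^2) phase-space computations.

Known asymptotics used as test oracles: a straight line has Katz and Higuchi
dimension 1; uncorrelated noise has Higuchi dimension ~2 and Hurst exponent
~0.5; the r=4 logistic map has largest Lyapunov exponent ln 2; periodic
orbits have near-zero Lyapunov exponent and near-unity RQA determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from scipy.fft import dct
from scipy.spatial.distance import pdist, squareform

from .spectral import DescriptorMap

__all__ = [
    "EmbeddingConfig",
    "katz_fd",
    "higuchi_fd",
    "hurst_exponent",
    "largest_lyapunov",
    "rqa_metrics",
    "wavelet_stats",
    "mfcc_stats",
    "cqt_stats",
]


@dataclass
class EmbeddingConfig:
    """Phase-space embedding for the Lyapunov and RQA estimators.

    delay=None selects the first zero crossing of the autocorrelation;
    radius is a fraction of the embedded cloud's diameter; theiler excludes
    temporally adjacent points from neighbour searches.
    """

    dimension: int = 3
    delay: int | None = None
    radius: float = 0.1
    theiler: int | None = None

    def __post_init__(self):
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if not (0 < self.radius < 1):
            raise ValueError("radius must be in (0, 1)")


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension log10(n) / (log10(n) + log10(d/L))."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    steps = np.hypot(1.0, np.diff(x))
    L = steps.sum()
    if L == 0:
        raise ValueError("zero path length")
    d = np.max(np.hypot(np.arange(1, x.size), x[1:] - x[0]))
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension: -slope of log L(k) vs log k."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 * kmax:
        raise ValueError(f"need >= {10 * kmax} samples for kmax={kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1, dtype=float)
    slope = np.polyfit(np.log(k_arr), np.log(lk), 1)[0]
    return float(-slope)


def hurst_exponent(x: np.ndarray, min_window: int = 8,
                   n_scales: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent over log-spaced window sizes."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 256:
        raise ValueError("need >= 256 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant series")
    n_scales = max(6, n_scales)
    windows = np.unique(np.floor(np.logspace(
        np.log10(min_window), np.log10(n // 2), n_scales)).astype(int))
    rs = []
    for w in windows:
        m = n // w
        seg = x[:m * w].reshape(m, w)
        mean = seg.mean(axis=1, keepdims=True)
        dev = np.cumsum(seg - mean, axis=1)
        r = dev.max(axis=1) - dev.min(axis=1)
        s = seg.std(axis=1, ddof=0)
        ok = s > 0
        if np.any(ok):
            rs.append(np.mean(r[ok] / s[ok]))
        else:
            rs.append(np.nan)
    rs = np.asarray(rs)
    ok = np.isfinite(rs) & (rs > 0)
    slope = np.polyfit(np.log(windows[ok].astype(float)), np.log(rs[ok]), 1)[0]
    return float(slope)


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n <= 0:
        raise ValueError("series too short for embedding")
    return np.column_stack([x[i * tau:i * tau + n] for i in range(m)])


def _default_delay(x: np.ndarray) -> int:
    x = x - x.mean()
    ac = signal.correlate(x, x, mode="full")[x.size - 1:]
    below = np.flatnonzero(ac <= 0)
    return int(below[0]) if below.size else max(1, x.size // 10)


def largest_lyapunov(x: np.ndarray, cfg: EmbeddingConfig | None = None,
                     fit_len: int | None = None, fs: float = 1.0) -> float:
    """Largest Lyapunov exponent by the Rosenstein method.

    Nearest neighbours outside the Theiler window are tracked forward; the
    exponent is the least-squares slope of the mean log divergence over the
    initial linear region (``fit_len`` steps, default n/10).  Returned per
    sample step scaled by ``fs`` (per second when fs is the sampling rate).
    """
    cfg = cfg or EmbeddingConfig()
    x = np.asarray(x, dtype=float)
    tau = cfg.delay or _default_delay(x)
    emb = _embed(x, cfg.dimension, tau)
    n = emb.shape[0]
    if n < 100:
        raise ValueError("need >= 100 embedded points")
    theiler = cfg.theiler if cfg.theiler is not None else tau
    d = squareform(pdist(emb))
    ii, jj = np.indices(d.shape)
    d[np.abs(ii - jj) <= theiler] = np.inf
    nn = np.argmin(d, axis=1)
    valid = np.isfinite(d[np.arange(n), nn])
    if not np.any(valid):
        raise ValueError("no valid neighbour pairs")
    fit_len = fit_len or max(5, n // 10)
    max_t = min(fit_len, n - 1)
    mean_log = np.full(max_t, np.nan)
    for t in range(1, max_t + 1):
        i = np.arange(n - t)
        j = nn[i] + t
        ok = valid[i] & (j < n)
        if not np.any(ok):
            break
        sep = np.linalg.norm(emb[i[ok] + t] - emb[j[ok]], axis=1)
        sep = sep[sep > 0]
        if sep.size == 0:
            continue
        mean_log[t - 1] = np.mean(np.log(sep))
    t_arr = np.arange(1, max_t + 1, dtype=float)
    ok = np.isfinite(mean_log)
    if ok.sum() < 2:
        raise ValueError("insufficient divergence data")
    slope = np.polyfit(t_arr[ok], mean_log[ok], 1)[0]
    return float(slope * fs)


def rqa_metrics(x: np.ndarray, cfg: EmbeddingConfig | None = None) -> DescriptorMap:
    """Recurrence quantification: recurrence rate, determinism, laminarity,
    longest off-diagonal line, and diagonal-length Shannon entropy.

    The recurrence matrix thresholds pairwise distances at ``radius`` times
    the phase-space diameter; the main diagonal is excluded throughout.
    """
    cfg = cfg or EmbeddingConfig()
    x = np.asarray(x, dtype=float)
    tau = cfg.delay or _default_delay(x)
    emb = _embed(x, cfg.dimension, tau)
    n = emb.shape[0]
    if n < 50:
        raise ValueError("need >= 50 embedded points")
    d = squareform(pdist(emb))
    eps = cfg.radius * d.max()
    rec = d <= eps
    np.fill_diagonal(rec, False)
    n_rec = int(rec.sum())
    out = DescriptorMap()
    out["RecurrenceRate"] = n_rec / (n * (n - 1))
    if n_rec == 0:
        for k in ("Determinism", "Laminarity", "LongestDiagonal",
                  "DiagonalEntropy"):
            out.flag(k)
        return out
    # diagonal line lengths (main diagonal excluded)
    diag_lengths = []
    for off in range(1, n):
        line = np.diagonal(rec, offset=off)
        diag_lengths.extend(_line_lengths(line))
    diag_lengths = np.asarray(diag_lengths)
    on_diag = 2 * diag_lengths[diag_lengths >= 2].sum()  # both triangles
    out["Determinism"] = float(on_diag / n_rec)
    out["LongestDiagonal"] = float(diag_lengths.max()) if diag_lengths.size else 0.0
    # vertical line lengths for laminarity
    vert = []
    for col in range(n):
        vert.extend(_line_lengths(rec[:, col]))
    vert = np.asarray(vert)
    out["Laminarity"] = float(vert[vert >= 2].sum() / n_rec) if vert.size else 0.0
    dl = diag_lengths[diag_lengths >= 2]
    if dl.size:
        _, counts = np.unique(dl, return_counts=True)
        p = counts / counts.sum()
        out["DiagonalEntropy"] = float(-np.sum(p * np.log(p)))
    else:
        out["DiagonalEntropy"] = 0.0
    return out


def _line_lengths(binary_line: np.ndarray) -> list[int]:
    lengths = []
    run = 0
    for b in binary_line:
        if b:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def wavelet_stats(x: np.ndarray, wavelet: str = "db4",
                  levels: int = 5) -> DescriptorMap:
    """Discrete wavelet decomposition: per-level relative energies (summing
    to 1) and the log-energy entropy across levels."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError("series too short for requested depth")
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    energies = np.array([np.sum(c ** 2) for c in coeffs])
    total = energies.sum()
    out = DescriptorMap()
    rel = energies / total if total > 0 else np.zeros_like(energies)
    # coeffs[0] is the coarse approximation; detail levels follow fine->coarse
    out["WaveletApproxRelEnergy"] = float(rel[0])
    for i, r in enumerate(rel[1:], start=1):
        level_no = levels - i + 1  # detail level, coarse (levels) .. fine (1)
        out[f"WaveletD{level_no}RelEnergy"] = float(r)
    nz = rel[rel > 0]
    out["WaveletEntropy"] = float(-np.sum(nz * np.log(nz)))
    return out


def _mel(f):
    return 2595.0 * np.log10(1.0 + f / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mfcc_stats(x: np.ndarray, fs: float, n_coeff: int = 13,
               n_filters: int = 26, nperseg: int = 512,
               band: tuple[float, float] = (75.0, 3000.0)) -> DescriptorMap:
    """Frame-wise MFCCs (triangular mel filterbank on the analysis band, log,
    DCT-II) summarized as per-coefficient mean and SD: 2*n_coeff keys."""
    x = np.asarray(x, dtype=float)
    hop = nperseg // 2
    if x.size < nperseg + 4 * hop:
        raise ValueError("need >= 5 frames")
    _, _, Z = signal.stft(x, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg - hop, boundary=None, padded=False)
    power = np.abs(Z) ** 2
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    mel_pts = _mel_inv(np.linspace(_mel(band[0]), _mel(band[1]), n_filters + 2))
    fb = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, mid, hi = mel_pts[i], mel_pts[i + 1], mel_pts[i + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        fb[i] = np.clip(np.minimum(up, down), 0, None)
    mel_energy = fb @ power
    floor = 1e-12 * max(mel_energy.max(), 1e-30)
    log_mel = np.log(np.maximum(mel_energy, floor))
    cep = dct(log_mel, type=2, axis=0, norm="ortho")[:n_coeff]
    out = DescriptorMap()
    silent = mel_energy.max() <= 1e-30
    for c in range(n_coeff):
        out[f"MFCC{c}Mean"] = float(cep[c].mean())
        out[f"MFCC{c}Std"] = float(cep[c].std(ddof=0))
        if silent:
            out.flags.update({f"MFCC{c}Mean", f"MFCC{c}Std"})
    return out


def cqt_stats(x: np.ndarray, fs: float, bins_per_octave: int = 24,
              f_min: float = 75.0, f_max: float | None = None,
              ) -> DescriptorMap:
    """Constant-Q magnitudes from ``f_min`` upward, summarized per octave
    band (mean, SD, energy ratio): 3 keys per octave band.

    Direct evaluation: per bin, a Hann-windowed complex exponential kernel of
    Q-dependent length is correlated with the signal at a coarse hop and the
    magnitudes averaged.
    """
    x = np.asarray(x, dtype=float)
    f_max = f_max or min(3000.0, 0.45 * fs)
    Q = 1.0 / (2 ** (1.0 / bins_per_octave) - 1.0)
    n0 = int(np.ceil(Q * fs / f_min))
    if x.size < n0:
        raise ValueError("record shorter than the lowest-bin kernel")
    n_bins = int(np.floor(bins_per_octave * np.log2(f_max / f_min))) + 1
    mags = np.empty(n_bins)
    for k in range(n_bins):
        fk = f_min * 2 ** (k / bins_per_octave)
        nk = int(np.ceil(Q * fs / fk))
        win = np.hanning(nk)
        kernel = win * np.exp(-2j * np.pi * fk * np.arange(nk) / fs) / win.sum()
        hop = max(1, nk // 2)
        vals = [np.abs(np.dot(x[s:s + nk], kernel))
                for s in range(0, x.size - nk + 1, hop)]
        mags[k] = np.mean(vals)
    octave = np.arange(n_bins) // bins_per_octave
    n_oct = int(octave.max()) + 1
    energy = mags ** 2
    total = energy.sum()
    out = DescriptorMap()
    for o in range(n_oct):
        sel = octave == o
        out[f"CQTOct{o}Mean"] = float(mags[sel].mean())
        out[f"CQTOct{o}Std"] = float(mags[sel].std(ddof=0))
        out[f"CQTOct{o}EnergyRatio"] = float(energy[sel].sum() / total) \
            if total > 0 else 0.0
    return out
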