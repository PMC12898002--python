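"""Welch power spectral density and spectral / time-domain descriptors.

Spectral moments treat the (band-limited, L1-normalized) PSD as a probability
distribution over frequency; centroid and bandwidth are its mean and SD,
skewness/kurtosis its standardized moments, entropy its normalized Shannon
entropy.  Time-domain voice-style metrics (jitter, shimmer, NHR) rely on an
autocorrelation pitch estimate and are flagged undefined when the segment has
no detectable periodicity — breath noise frequently has none, which is itself
informative and must not be fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PSDEstimate",
    "DescriptorMap",
    "welch_psd",
    "spectral_descriptors",
    "spectral_flux",
    "time_domain_descriptors",
]


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    nperseg: int
    overlap: float
    window: str
    fs: float


@dataclass
class DescriptorMap:
    """Named scalar features plus the set of undefined-flagged keys."""

    values: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __getitem__(self, k):
        return self.values[k]

    def __setitem__(self, k, v):
        if k in self.values:
            raise KeyError(f"duplicate descriptor key {k!r}")
        self.values[k] = float(v)

    def flag(self, k):
        self.values[k] = float("nan")
        self.flags.add(k)

    def items(self):
        return self.values.items()

    def prefixed(self, prefix: str) -> "DescriptorMap":
        out = DescriptorMap()
        out.values = {f"{prefix}{k}": v for k, v in self.values.items()}
        out.flags = {f"{prefix}{k}" for k in self.flags}
        return out

    def update(self, other: "DescriptorMap"):
        for k in other.values:
            if k in self.values:
                raise KeyError(f"duplicate descriptor key {k!r}")
        self.values.update(other.values)
        self.flags.update(other.flags)


def welch_psd(x: np.ndarray, fs: float, nperseg: int = 1024,
              overlap: float = 0.5, window: str = "hann") -> PSDEstimate:
    """Hann-windowed averaged periodogram with density scaling, so the PSD
    integrates to the signal variance."""
    x = np.asarray(x, dtype=float)
    if x.size < nperseg:
        raise ValueError(f"need >= {nperseg} samples, got {x.size}")
    freqs, power = signal.welch(x, fs=fs, window=window, nperseg=nperseg,
                                noverlap=int(nperseg * overlap),
                                detrend="constant", scaling="density")
    return PSDEstimate(freqs=freqs, power=power, nperseg=nperseg,
                       overlap=overlap, window=window, fs=fs)


def _band_mask(freqs, band):
    return (freqs >= band[0]) & (freqs <= band[1])


def spectral_descriptors(psd: PSDEstimate,
                         band: tuple[float, float] = (75.0, 3000.0),
                         ratio_bands=((150.0, 450.0), (450.0, 3000.0)),
                         mask: np.ndarray | None = None) -> DescriptorMap:
    """Moment/shape descriptors of a PSD restricted to ``band`` (or to an
    arbitrary boolean ``mask`` over bins, used for gap-band "Range" features).
    """
    f, p = psd.freqs, psd.power
    sel = mask if mask is not None else _band_mask(f, band)
    f, p = f[sel], p[sel]
    out = DescriptorMap()
    total = p.sum()
    if f.size == 0 or total <= 0:
        raise ValueError("zero total power in band")
    w = p / total
    centroid = float(np.sum(w * f))
    bw = float(np.sqrt(np.sum(w * (f - centroid) ** 2)))
    out["FreqCentroid"] = centroid
    out["FreqBandwidth"] = bw
    # normalized Shannon entropy over bins
    nz = w[w > 0]
    ent = -np.sum(nz * np.log(nz))
    out["SpectralEntropy"] = ent / np.log(w.size) if w.size > 1 else 0.0
    if bw > 0:
        out["FreqSkewness"] = float(np.sum(w * (f - centroid) ** 3) / bw ** 3)
        out["FreqKurtosis"] = float(np.sum(w * (f - centroid) ** 4) / bw ** 4)
    else:
        out.flag("FreqSkewness")
        out.flag("FreqKurtosis")
    out["Crest"] = float(p.max() / p.mean())
    out["MeanPower"] = float(p.mean())
    out["PeakPower"] = float(p.max())
    out["Maximum"] = float(f[np.argmax(p)])  # frequency of peak power
    lo_sel = _band_mask(psd.freqs, ratio_bands[0])
    hi_sel = _band_mask(psd.freqs, ratio_bands[1])
    hi_pow = psd.power[hi_sel].sum()
    if hi_pow > 0:
        out["FreqRatio"] = float(psd.power[lo_sel].sum() / hi_pow)
    else:
        out.flag("FreqRatio")
    return out


def spectral_flux(x: np.ndarray, fs: float, nperseg: int = 256,
                  overlap: float = 0.5) -> float:
    """Mean Euclidean norm of successive differences of per-frame
    L1-normalized magnitude spectra (gain invariant by construction)."""
    x = np.asarray(x, dtype=float)
    hop = int(nperseg * (1 - overlap))
    if x.size < nperseg + hop:
        raise ValueError("need at least 2 frames")
    _, _, Z = signal.stft(x, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg - hop, boundary=None, padded=False)
    mag = np.abs(Z)
    norms = mag.sum(axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    mag = mag / norms
    d = np.diff(mag, axis=1)
    return float(np.mean(np.linalg.norm(d, axis=0)))


def _autocorr_pitch(x, fs, fmin=60.0, fmax=400.0):
    """Fundamental period (samples) from the autocorrelation peak in
    [fmin, fmax]; returns None when periodicity is weak."""
    x = x - x.mean()
    n = x.size
    ac = signal.correlate(x, x, mode="full")[n - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lo = int(fs / fmax)
    hi = min(int(fs / fmin), n - 1)
    if hi <= lo + 1:
        return None
    k = lo + int(np.argmax(ac[lo:hi]))
    if ac[k] < 0.5:  # weak periodicity
        return None
    return k


def _cycle_peaks(x, period):
    """Per-cycle peak positions (parabolic-interpolated) and amplitudes."""
    n = x.size
    peaks, amps = [], []
    start = 0
    while start + period <= n:
        seg = x[start:start + period]
        i = int(np.argmax(seg))
        j = start + i
        if 0 < j < n - 1:
            y0, y1, y2 = x[j - 1], x[j], x[j + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            peaks.append(j + delta)
            amps.append(y1 - 0.25 * (y0 - y2) * delta)
        else:
            peaks.append(float(j))
            amps.append(x[j])
        start += period
    return np.array(peaks), np.array(amps)


def time_domain_descriptors(x: np.ndarray, fs: float) -> DescriptorMap:
    """ZCR, RMS, coefficient of variation, and (when periodic) jitter,
    shimmer and noise-to-harmonics ratio."""
    x = np.asarray(x, dtype=float)
    out = DescriptorMap()
    crossings = np.count_nonzero(np.diff(np.signbit(x - 0.0)))
    out["ZCR"] = crossings / (x.size / fs)
    rms = float(np.sqrt(np.mean(x ** 2)))
    out["RMS"] = rms
    env = np.abs(signal.hilbert(x)) if x.size < 200000 else np.abs(x)
    out["CoefVariation"] = float(env.std() / env.mean()) if env.mean() > 0 else 0.0

    period = _autocorr_pitch(x, fs)
    if period is None or x.size < 3 * period:
        for k in ("Jitter", "Shimmer", "NHR"):
            out.flag(k)
        return out
    peaks, amps = _cycle_peaks(x, period)
    if peaks.size < 3:
        for k in ("Jitter", "Shimmer", "NHR"):
            out.flag(k)
        return out
    periods = np.diff(peaks)
    out["Jitter"] = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))
    out["Shimmer"] = float(np.mean(np.abs(np.diff(amps))) / np.mean(np.abs(amps)))

    # comb decomposition at the detected fundamental
    f0 = fs / period
    nfft = int(2 ** np.ceil(np.log2(x.size)))
    spec = np.abs(np.fft.rfft((x - x.mean()) * np.hanning(x.size), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    df = freqs[1]
    harm = np.zeros(spec.size, dtype=bool)
    # harmonic lobe width: Hann mainlobe spans ~2 bins of the pre-padding
    # resolution on each side
    half = int(np.ceil(2 * nfft / x.size)) + 1
    k = 1
    while k * f0 < fs / 2:
        c = int(round(k * f0 / df))
        harm[max(0, c - half):c + half + 1] = True
        k += 1
    p_h = spec[harm].sum()
    p_n = spec[~harm].sum()
    if p_h > 0:
        out["NHR"] = float(p_n / p_h)
    else:
        out.flag("NHR")
    return out
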