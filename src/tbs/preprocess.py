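"""Preprocessing of tracheal breathing sound recordings.

Pipeline: zero-phase 75–3000 Hz Butterworth bandpass, adaptive segmentation of
the log-variance envelope into inspiratory/expiratory phases with per-segment
SNR gating, mid-flow extraction, and mutual-information-driven selection of
the feature normalization method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.metrics import mutual_info_score

__all__ = [
    "BAND_HZ",
    "SegmentationConfig",
    "BreathPhaseSegment",
    "NormalizationChoice",
    "bandpass_filter",
    "segment_breath_phases",
    "compute_snr",
    "extract_midflow",
    "select_normalization",
    "apply_normalization",
]

#: Analysis band isolating tracheal-breathing components (Hz).
BAND_HZ = (75.0, 3000.0)


def bandpass_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """4th-order Butterworth bandpass 75–3000 Hz, applied forward-backward
    (zero phase, so segment timing is preserved; effective order doubles)."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * BAND_HZ[1]:
        raise ValueError(f"fs={fs} too low for the {BAND_HZ[1]} Hz band edge")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    if x.size <= 12:  # 3x filter order
        raise ValueError("input too short to filter")
    sos = signal.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


@dataclass
class SegmentationConfig:
    frame_s: float = 0.05          # envelope frame length
    overlap: float = 0.5           # frame overlap fraction
    min_phase_s: float = 0.2       # discard shorter supra-threshold runs
    merge_gap_s: float = 0.1       # fuse shorter sub-threshold gaps
    low_pct: float = 5.0           # noise-floor percentile of log-variance
    high_pct: float = 95.0         # activity percentile
    min_snr_db: float = 5.0        # gate for retained segments
    first_phase: str = "inspiration"  # protocol starts with an inspiration


@dataclass
class BreathPhaseSegment:
    """One filtered breath phase cut from a recording."""

    samples: np.ndarray
    fs: float
    route: str
    phase: str
    breath_index: int
    snr_db: float
    subject_id: str = ""
    start: int = 0  # sample offset in the source recording


@dataclass
class NormalizationChoice:
    method: str
    mi_scores: dict[str, float]
    params: dict = field(default_factory=dict)
    flagged_columns: list[str] = field(default_factory=list)


def _log_variance_envelope(x, fs, cfg):
    frame = max(4, int(cfg.frame_s * fs))
    hop = max(1, int(frame * (1 - cfg.overlap)))
    n_frames = 1 + max(0, (x.size - frame) // hop)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    v = frames.var(axis=1)
    env = np.log10(v + 1e-20)
    centers = idx[:, 0] + frame // 2
    return env, centers, hop, frame


def segment_breath_phases(x: np.ndarray, fs: float,
                          cfg: SegmentationConfig | None = None,
                          route: str = "nose", subject_id: str = "",
                          prefilter: bool = True) -> list[BreathPhaseSegment]:
    """Adaptive segmentation of a recording into breath phases.

    The log-variance envelope is thresholded at the midpoint between its
    low-percentile noise floor and high-percentile activity level.  Short
    supra-threshold runs are discarded, short sub-threshold gaps merged, and
    retained runs are labelled alternately inspiration/expiration starting
    from the protocol's known first phase.  Per-segment SNR against the
    sub-threshold noise floor is attached; segments below the SNR gate are
    dropped (their count is recoverable by passing ``min_snr_db=-inf``).
    """
    cfg = cfg or SegmentationConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if prefilter:
        x = bandpass_filter(x, fs)
    env, centers, hop, frame = _log_variance_envelope(x, fs, cfg)
    if env.size < 3:
        return []
    lo = np.percentile(env, cfg.low_pct)
    hi = np.percentile(env, cfg.high_pct)
    if hi - lo < 0.5:  # < ~5 dB dynamic range: no breath activity present
        return []
    thr = 0.5 * (lo + hi)
    active = env > thr

    # merge sub-threshold gaps shorter than merge_gap_s
    min_gap = max(1, int(round(cfg.merge_gap_s * fs / hop)))
    runs = _runs(active)
    for s, e, val in runs:
        if not val and s > 0 and e < active.size and (e - s) < min_gap:
            active[s:e] = True
    # drop supra-threshold runs shorter than min_phase_s
    min_run = max(1, int(round(cfg.min_phase_s * fs / hop)))
    segments_idx = [(s, e) for s, e, val in _runs(active) if val and (e - s) >= min_run]

    noise_mask = ~active
    noise_samples = _mask_to_samples(noise_mask, centers, frame, x.size)
    noise = x[noise_samples] if noise_samples.size else x[:frame]

    phases = ("inspiration", "expiration")
    start_idx = phases.index(cfg.first_phase)
    out = []
    for k, (s, e) in enumerate(segments_idx):
        a = max(0, centers[s] - frame // 2)
        b = min(x.size, centers[e - 1] + frame // 2)
        seg = x[a:b]
        snr = compute_snr(seg, noise)
        if snr < cfg.min_snr_db:
            continue
        out.append(BreathPhaseSegment(
            samples=seg, fs=fs, route=route,
            phase=phases[(start_idx + k) % 2],
            breath_index=k // 2 + 1, snr_db=snr,
            subject_id=subject_id, start=int(a)))
    return out


def _runs(mask):
    """(start, end, value) runs of a boolean array; end exclusive."""
    out = []
    if mask.size == 0:
        return out
    edges = np.flatnonzero(np.diff(mask.astype(int))) + 1
    bounds = np.concatenate(([0], edges, [mask.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        out.append((int(s), int(e), bool(mask[s])))
    return out


def _mask_to_samples(frame_mask, centers, frame, n):
    sel = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(frame_mask):
        a = max(0, centers[i] - frame // 2)
        sel[a:min(n, a + frame)] = True
    return np.flatnonzero(sel)


def compute_snr(segment: np.ndarray, noise_floor: np.ndarray) -> float:
    """10 log10(segment power / noise-floor power), in dB."""
    segment = np.asarray(segment, dtype=float)
    noise_floor = np.asarray(noise_floor, dtype=float)
    if segment.size == 0 or noise_floor.size == 0:
        raise ValueError("empty input")
    p_n = np.mean(noise_floor ** 2)
    if p_n == 0:
        raise ValueError("zero noise-floor power")
    return float(10 * np.log10(np.mean(segment ** 2) / p_n))


def extract_midflow(segment: BreathPhaseSegment, fraction: float = 0.5,
                    min_len: int = 256) -> np.ndarray:
    """Central ``fraction`` of the segment, centred on the envelope peak
    (the high-flow portion of the phase carries the informative turbulence)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    x = segment.samples
    n = x.size
    m = int(round(fraction * n))
    if m < min_len:
        raise ValueError(f"mid-flow window of {m} samples below minimum {min_len}")
    if m >= n:
        return x.copy()
    frame = max(4, int(0.05 * segment.fs))
    env = np.convolve(x ** 2, np.ones(frame) / frame, mode="same")
    peak = int(np.argmax(env))
    a = int(np.clip(peak - m // 2, 0, n - m))
    return x[a:a + m]


# ---------------------------------------------------------------------------
# normalization selection

_METHOD_ORDER = ["mean-range", "z-score", "min-max", "robust"]


def _norm_params(col: np.ndarray, method: str):
    if method == "mean-range":
        return dict(center=col.mean(), scale=np.ptp(col))
    if method == "z-score":
        return dict(center=col.mean(), scale=col.std(ddof=0))
    if method == "min-max":
        return dict(center=col.min(), scale=np.ptp(col))
    if method == "robust":
        q1, q3 = np.percentile(col, [25, 75])
        return dict(center=np.median(col), scale=q3 - q1)
    raise ValueError(method)


def _mi_binned(col: np.ndarray, labels: np.ndarray) -> float:
    """MI (nats) between an equal-frequency-binned column and the label."""
    n = col.size
    n_bins = max(2, int(np.ceil(np.sqrt(n))))
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1))
    binned = np.searchsorted(edges[1:-1], col, side="right")
    return float(mutual_info_score(labels, binned))


def select_normalization(features: pd.DataFrame, labels,
                         ) -> tuple[NormalizationChoice, pd.DataFrame]:
    """Pick the column-wise normalization maximizing mean feature-label MI.

    Each candidate (mean-range, z-score, min-max, robust scaling) is applied
    column-wise with statistics learned from ``features`` (call this on the
    training partition only), MI is estimated per column by equal-frequency
    binning with ceil(sqrt(n)) bins, and the method with maximal mean MI wins;
    ties break by the fixed order mean-range > z-score > min-max > robust.
    Zero-scale columns pass through unscaled and are flagged.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 subjects each")
    mi_scores: dict[str, float] = {}
    all_params: dict[str, dict] = {}
    flagged: dict[str, list[str]] = {}
    for method in _METHOD_ORDER:
        params, flags = {}, []
        mis = []
        for name in features.columns:
            col = features[name].to_numpy(dtype=float)
            p = _norm_params(col, method)
            if p["scale"] <= 0 or not np.isfinite(p["scale"]):
                p = dict(center=0.0, scale=1.0)
                flags.append(name)
            params[name] = p
            z = (col - p["center"]) / p["scale"]
            mis.append(_mi_binned(z, labels))
        mi_scores[method] = float(np.mean(mis)) if mis else 0.0
        all_params[method] = params
        flagged[method] = flags
    best = max(_METHOD_ORDER, key=lambda m: (mi_scores[m], -_METHOD_ORDER.index(m)))
    choice = NormalizationChoice(method=best, mi_scores=mi_scores,
                                 params=all_params[best],
                                 flagged_columns=flagged[best])
    return choice, apply_normalization(features, choice)


def apply_normalization(features: pd.DataFrame,
                        choice: NormalizationChoice) -> pd.DataFrame:
    """Apply a learned normalization to a (train or held-out) feature table."""
    out = {}
    for name in features.columns:
        p = choice.params.get(name, dict(center=0.0, scale=1.0))
        out[name] = (features[name].to_numpy(dtype=float) - p["center"]) / p["scale"]
    return pd.DataFrame(out, index=features.index)
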