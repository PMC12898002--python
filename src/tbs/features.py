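"""Feature extraction orchestration: from recordings to named feature tables.

Two layers:

* :func:`extract_subject_acoustics` is pair-independent.  It segments each
  subject's nose/mouth recordings into breath phases, and per route-phase
  condition caches the condition-average Welch PSD, the condition-average
  bispectrum magnitude, and the full-signal descriptor families (spectral,
  flux, time-domain, fractal/nonlinear/recurrence, wavelet, MFCC, CQT)
  averaged over the condition's mid-flow segments.

* :func:`gap_region_features` is pair- and fold-specific.  Given frozen gap
  regions (1D spectral bands and the largest 2D bispectral box, learned from
  training subjects only), it evaluates "Range" spectral descriptors on the
  gap-band bins of each subject's PSD and "BBox" region/morphology/texture
  descriptors on the box cut from each subject's bispectrum.

The ``Average`` condition is the mean of a descriptor across the four
route-phase conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import naming
from .bispectral import (BispectrumMatrix, bootstrap_class_ci,
                         detect_gap_bands_1d, detect_gap_boxes_2d,
                         estimate_bispectrum)
from .morphology import (RegionMatrix, binarize_region, glcm_texture,
                         region_morphology, region_statistics)
from .nonlinear import (EmbeddingConfig, cqt_stats, higuchi_fd, hurst_exponent,
                        katz_fd, largest_lyapunov, mfcc_stats, rqa_metrics,
                        wavelet_stats)
from .preprocess import (SegmentationConfig, extract_midflow,
                         segment_breath_phases)
from .spectral import (DescriptorMap, PSDEstimate, spectral_descriptors,
                       spectral_flux, time_domain_descriptors, welch_psd)

__all__ = [
    "FeatureConfig",
    "SubjectAcoustics",
    "extract_subject_acoustics",
    "base_feature_table",
    "learn_gap_regions",
    "gap_region_features",
    "compute_spectrogram",
]

CONDITIONS = [("nose", "inspiration"), ("nose", "expiration"),
              ("mouth", "inspiration"), ("mouth", "expiration")]


@dataclass
class FeatureConfig:
    midflow_fraction: float = 0.5
    welch_nperseg: int = 1024
    bispec_nperseg: int = 256
    nonlinear_max_samples: int = 1500  # bound O(n^2) phase-space costs
    band: tuple[float, float] = (75.0, 3000.0)
    ratio_bands: tuple = ((150.0, 450.0), (450.0, 3000.0))
    n_boot: int = 1000
    min_gap_bins: int = 2
    min_box_area: int = 4
    glcm_levels: int = 8
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)


@dataclass
class SubjectAcoustics:
    subject_id: str
    psd: dict  # condition name -> PSDEstimate (condition-average)
    bispec: dict  # condition name -> BispectrumMatrix (condition-average)
    base: DescriptorMap  # pair-independent named features
    n_segments: dict


def _downsample(x: np.ndarray, max_n: int) -> np.ndarray:
    if x.size <= max_n:
        return x
    factor = int(np.ceil(x.size / max_n))
    return sp_signal.decimate(x, factor, ftype="fir", zero_phase=True)


def _nanmean_maps(maps: list[DescriptorMap]) -> DescriptorMap:
    """Average descriptor maps over segments, ignoring flagged values;
    a key flagged in every segment stays flagged."""
    out = DescriptorMap()
    keys = maps[0].values.keys()
    for k in keys:
        vals = np.array([m.values[k] for m in maps])
        if np.all(np.isnan(vals)):
            out.flag(k)
        else:
            out[k] = float(np.nanmean(vals))
    return out


def extract_subject_acoustics(recordings: dict[str, np.ndarray], fs: float,
                              subject_id: str = "",
                              cfg: FeatureConfig | None = None,
                              ) -> SubjectAcoustics:
    """Segment a subject's per-route recordings and compute the cached
    per-condition spectra and the full-signal feature families."""
    cfg = cfg or FeatureConfig()
    psds: dict[str, PSDEstimate] = {}
    bispecs: dict[str, BispectrumMatrix] = {}
    base = DescriptorMap()
    n_segments = {}
    for route, phase in CONDITIONS:
        cond = naming.condition_of(route, phase)
        segs = [s for s in segment_breath_phases(
            recordings[route], fs, cfg.segmentation, route=route,
            subject_id=subject_id) if s.phase == phase]
        n_segments[cond] = len(segs)
        if not segs:
            raise ValueError(f"no {phase} segments found for route {route}")
        mids = [extract_midflow(s, cfg.midflow_fraction) for s in segs]
        # fragments shorter than the PSD analysis window (split phases,
        # spurious bursts) are excluded from the condition averages
        long_enough = [m for m in mids if m.size >= cfg.welch_nperseg]
        if long_enough:
            mids = long_enough
        else:
            raise ValueError(f"all {phase} segments of route {route} shorter "
                             f"than the analysis window")

        # condition-average PSD and bispectrum
        psd_list = [welch_psd(m, fs, nperseg=cfg.welch_nperseg) for m in mids]
        mean_power = np.mean([p.power for p in psd_list], axis=0)
        psds[cond] = PSDEstimate(freqs=psd_list[0].freqs, power=mean_power,
                                 nperseg=cfg.welch_nperseg, overlap=0.5,
                                 window="hann", fs=fs)
        bis_list = [estimate_bispectrum(m, fs, nperseg=cfg.bispec_nperseg)
                    for m in mids]
        mean_mag = np.mean([b.magnitude for b in bis_list], axis=0)
        bispecs[cond] = BispectrumMatrix(f1=bis_list[0].f1, f2=bis_list[0].f2,
                                         magnitude=mean_mag,
                                         n_segments=sum(b.n_segments for b in bis_list))

        fam = DescriptorMap()
        fam.update(spectral_descriptors(psds[cond], band=cfg.band,
                                        ratio_bands=cfg.ratio_bands))
        fam["SpectralFlux"] = float(np.mean([spectral_flux(m, fs) for m in mids]))
        fam.update(_nanmean_maps([time_domain_descriptors(m, fs) for m in mids]))
        fam.update(_per_segment_nonlinear(mids, fs, cfg))
        fam.update(_nanmean_maps([_safe(wavelet_stats, _wavelet_keys(), m)
                                  for m in mids]))
        fam.update(_nanmean_maps([_safe(mfcc_stats, _mfcc_keys(), m, fs)
                                  for m in mids]))
        fam.update(_nanmean_maps([_safe(cqt_stats, _cqt_keys(fs), m, fs)
                                  for m in mids]))
        base.update(fam.prefixed(cond + "_"))

    _add_average(base)
    return SubjectAcoustics(subject_id=subject_id, psd=psds, bispec=bispecs,
                            base=base, n_segments=n_segments)


def _safe(fn, keys, *args, **kwargs) -> DescriptorMap:
    """Run one descriptor family on one segment; a segment too short for the
    family yields the canonical key set flagged undefined instead of failing."""
    try:
        return fn(*args, **kwargs)
    except ValueError:
        d = DescriptorMap()
        for k in keys:
            d.flag(k)
        return d


def _wavelet_keys(levels: int = 5):
    return (["WaveletApproxRelEnergy"] +
            [f"WaveletD{levels - i + 1}RelEnergy" for i in range(1, levels + 1)] +
            ["WaveletEntropy"])


def _mfcc_keys(n_coeff: int = 13):
    return [f"MFCC{c}{s}" for c in range(n_coeff) for s in ("Mean", "Std")]


def _cqt_keys(fs: float, bins_per_octave: int = 24, f_min: float = 75.0):
    f_max = min(3000.0, 0.45 * fs)
    n_bins = int(np.floor(bins_per_octave * np.log2(f_max / f_min))) + 1
    n_oct = (n_bins - 1) // bins_per_octave + 1
    return [f"CQTOct{o}{s}" for o in range(n_oct)
            for s in ("Mean", "Std", "EnergyRatio")]


def _per_segment_nonlinear(mids, fs, cfg) -> DescriptorMap:
    maps = []
    emb = EmbeddingConfig()
    for m in mids:
        x = _downsample(m, cfg.nonlinear_max_samples)
        d = DescriptorMap()
        d["KatzFD"] = katz_fd(x)
        try:
            d["HiguchiFD"] = higuchi_fd(x)
        except ValueError:
            d.flag("HiguchiFD")
        try:
            d["Hurst"] = hurst_exponent(x)
        except ValueError:
            d.flag("Hurst")
        try:
            d["Lyapunov"] = largest_lyapunov(x, emb)
        except ValueError:
            d.flag("Lyapunov")
        try:
            d.update(rqa_metrics(x, emb))
        except ValueError:
            for k in ("RecurrenceRate", "Determinism", "Laminarity",
                      "LongestDiagonal", "DiagonalEntropy"):
                d.flag(k)
        maps.append(d)
    return _nanmean_maps(maps)


def _add_average(base: DescriptorMap):
    """Append Average_* = mean of each descriptor across the 4 conditions."""
    conds = [naming.condition_of(r, p) for r, p in CONDITIONS]
    descs = {}
    for key, val in list(base.items()):
        cond, ctx, desc = naming.parse_name(key)
        descs.setdefault((ctx, desc), []).append(val)
    for (ctx, desc), vals in descs.items():
        if len(vals) == len(conds):
            name = naming.make_name("Average", desc, ctx)
            v = np.array(vals, dtype=float)
            if np.all(np.isnan(v)):
                base.flag(name)
            else:
                base[name] = float(np.nanmean(v))


def base_feature_table(acoustics: dict[str, SubjectAcoustics]) -> pd.DataFrame:
    """Wide table of the pair-independent features, rows indexed by subject."""
    rows = {sid: ac.base.values for sid, ac in acoustics.items()}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# pair/fold-specific gap regions


@dataclass
class GapRegions:
    """Frozen class-pair gap regions per condition (train subjects only)."""

    bands: dict  # condition -> list[GapBand1D] on the band-limited PSD grid
    boxes: dict  # condition -> list[BispecGapBox]
    band_bins: dict  # condition -> indices of the band-limited grid
    pair: tuple[str, str]


def learn_gap_regions(acoustics: dict[str, SubjectAcoustics],
                      class_members: dict[str, list[str]],
                      cfg: FeatureConfig | None = None,
                      seed: int = 0) -> GapRegions:
    """Bootstrap class CIs over *training* subjects and detect 1D gap bands
    (PSD) and 2D gap boxes (bispectrum) per condition."""
    cfg = cfg or FeatureConfig()
    (cls_a, ids_a), (cls_b, ids_b) = sorted(class_members.items())
    bands, boxes, band_bins = {}, {}, {}
    degenerate = len(ids_a) < 3 or len(ids_b) < 3
    if degenerate:
        import warnings
        warnings.warn("fewer than 3 training subjects in a class; "
                      "no gap regions learned (full-band fallback)")
    for ci, (route, phase) in enumerate(CONDITIONS):
        cond = naming.condition_of(route, phase)
        any_psd = acoustics[ids_a[0]].psd[cond]
        sel = np.flatnonzero((any_psd.freqs >= cfg.band[0]) &
                             (any_psd.freqs <= cfg.band[1]))
        band_bins[cond] = sel
        freqs = any_psd.freqs[sel]
        if degenerate:
            bands[cond] = []
            boxes[cond] = []
            continue

        def class_ci_1d(label, ids, off):
            spectra = np.stack([acoustics[s].psd[cond].power[sel] for s in ids])
            return bootstrap_class_ci(spectra, class_label=label,
                                      n_boot=cfg.n_boot,
                                      seed=seed + 13 * ci + off, grid=freqs)

        ci_a = class_ci_1d(cls_a, ids_a, 0)
        ci_b = class_ci_1d(cls_b, ids_b, 1)
        bands[cond] = detect_gap_bands_1d(ci_a, ci_b, min_bins=cfg.min_gap_bins)

        def class_ci_2d(label, ids, off):
            mats = np.stack([acoustics[s].bispec[cond].magnitude for s in ids])
            bm = acoustics[ids[0]].bispec[cond]
            return bootstrap_class_ci(mats, class_label=label,
                                      n_boot=cfg.n_boot,
                                      seed=seed + 13 * ci + off + 7,
                                      grid=(bm.f1, bm.f2))

        ci2_a = class_ci_2d(cls_a, ids_a, 0)
        ci2_b = class_ci_2d(cls_b, ids_b, 1)
        boxes[cond] = detect_gap_boxes_2d(ci2_a, ci2_b,
                                          min_area=cfg.min_box_area)
    return GapRegions(bands=bands, boxes=boxes, band_bins=band_bins,
                      pair=(cls_a, cls_b))


def gap_region_features(ac: SubjectAcoustics, regions: GapRegions,
                        cfg: FeatureConfig | None = None) -> DescriptorMap:
    """Evaluate Range (gap-band spectral) and BBox (bispectral box) features
    of one subject against frozen gap regions."""
    cfg = cfg or FeatureConfig()
    out = DescriptorMap()
    for route, phase in CONDITIONS:
        cond = naming.condition_of(route, phase)
        psd = ac.psd[cond]
        sel = regions.band_bins[cond]
        mask = np.zeros(psd.freqs.size, dtype=bool)
        gap_bands = regions.bands[cond]
        if gap_bands:
            for b in gap_bands:
                mask[sel[b.bin_lo:b.bin_hi + 1]] = True
        else:  # no gap: fall back to the full analysis band
            mask[sel] = True
        rng_feats = spectral_descriptors(psd, mask=mask,
                                         ratio_bands=cfg.ratio_bands)
        out.update(rng_feats.prefixed(cond + "_Range_"))

        bm = ac.bispec[cond]
        box_list = regions.boxes[cond]
        bbox_feats = DescriptorMap()
        if box_list:
            b = box_list[0]  # largest component's bounding box
            sub = bm.magnitude[b.row_lo:b.row_hi + 1, b.col_lo:b.col_hi + 1]
            region = RegionMatrix(values=sub,
                                  row_axis=bm.f2[b.row_lo:b.row_hi + 1],
                                  col_axis=bm.f1[b.col_lo:b.col_hi + 1],
                                  freq_axis="row")
            bbox_feats.update(region_statistics(region))
            bbox_feats.update(region_morphology(binarize_region(region)))
            if sub.shape[0] >= 2 and sub.shape[1] >= 2:
                bbox_feats.update(glcm_texture(region, levels=cfg.glcm_levels))
        else:
            for k in ("MeanValue", "MedianValue", "StdValue", "IQRValue",
                      "EnergyValue", "PeakValue", "EntropyValue"):
                bbox_feats.flag(k)
        out.update(bbox_feats.prefixed(cond + "_BBox_"))
    _add_average(out)
    return out


def save_gap_regions(regions: GapRegions, path: str) -> None:
    """Serialize frozen gap regions to JSON so feature extraction on new
    subjects is replayable without re-learning."""
    import json

    payload = {
        "pair": list(regions.pair),
        "band_bins": {c: np.asarray(v).tolist()
                      for c, v in regions.band_bins.items()},
        "bands": {c: [dict(f_lo=b.f_lo, f_hi=b.f_hi, bin_lo=b.bin_lo,
                           bin_hi=b.bin_hi, direction=b.direction)
                      for b in v] for c, v in regions.bands.items()},
        "boxes": {c: [dict(row_lo=b.row_lo, row_hi=b.row_hi, col_lo=b.col_lo,
                           col_hi=b.col_hi, f1_extent=list(b.f1_extent),
                           f2_extent=list(b.f2_extent),
                           component_id=b.component_id,
                           component_size=b.component_size)
                      for b in v] for c, v in regions.boxes.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_gap_regions(path: str) -> GapRegions:
    """Inverse of :func:`save_gap_regions`."""
    import json

    from .bispectral import BispecGapBox, GapBand1D

    with open(path) as fh:
        payload = json.load(fh)
    bands = {c: [GapBand1D(**b) for b in v]
             for c, v in payload["bands"].items()}
    boxes = {}
    for c, v in payload["boxes"].items():
        boxes[c] = [BispecGapBox(row_lo=b["row_lo"], row_hi=b["row_hi"],
                                 col_lo=b["col_lo"], col_hi=b["col_hi"],
                                 f1_extent=tuple(b["f1_extent"]),
                                 f2_extent=tuple(b["f2_extent"]),
                                 component_id=b["component_id"],
                                 component_size=b["component_size"])
                    for b in v]
    band_bins = {c: np.asarray(v, dtype=int)
                 for c, v in payload["band_bins"].items()}
    return GapRegions(bands=bands, boxes=boxes, band_bins=band_bins,
                      pair=tuple(payload["pair"]))


def compute_spectrogram(x: np.ndarray, fs: float, nperseg: int = 256,
                        ) -> RegionMatrix:
    """Magnitude spectrogram in dB as a calibrated region (rows = frequency),
    for applying the same box machinery to time-frequency images."""
    f, t, Z = sp_signal.stft(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2, boundary=None,
                             padded=False)
    db = 20 * np.log10(np.abs(Z) + 1e-12)
    db -= db.min()  # keep the region non-negative
    return RegionMatrix(values=db, row_axis=f, col_axis=t, freq_axis="row")
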