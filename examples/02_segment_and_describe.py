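"""Segment one recording into breath phases and compute spectral features.

Shows the preprocessing contract: 5 deep breaths -> 10 alternating
inspiration/expiration segments, each with an SNR, and the spectral
descriptor family of one mid-flow window.
"""

from tbs.cohort import generate_cohort
from tbs.preprocess import extract_midflow, segment_breath_phases
from tbs.spectral import spectral_descriptors, welch_psd

FS = 10240.0
recordings, _ = generate_cohort({"Moderate": 1}, seed=3)
wav = recordings[("Moderate0000", "nose")]

segments = segment_breath_phases(wav, FS, route="nose")
print(f"{len(segments)} segments:",
      [f"{s.phase[:3]}{s.breath_index}({s.snr_db:.0f}dB)" for s in segments])

mid = extract_midflow(segments[0], fraction=0.5)
psd = welch_psd(mid, FS)
d = spectral_descriptors(psd)
for key in ("FreqCentroid", "FreqBandwidth", "SpectralEntropy", "FreqRatio"):
    print(f"{key:16s} {d[key]:.3f}")
print("\nCentroid/bandwidth are the power-weighted mean/SD of frequency in "
      "75-3000 Hz; FreqRatio compares 150-450 Hz vs 450-3000 Hz band power.")
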