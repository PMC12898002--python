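"""Synthetic cohort generation: anthropometric records and breath-sound audio.

Real wakefulness tracheal-breathing-sound (TBS) recordings from clinical OSA
cohorts are access-restricted, so every downstream stage of this package is
exercised against a synthetic cohort.  Two generators live here:

* :func:`sample_anthropometrics` draws subject records (AHI, age, sex, BMI,
  neck circumference, Mallampati score) whose class-conditional moments match
  a reference clinical cohort of 199 PSG-referred adults.  Continuous fields
  use truncated normals whose *underlying* parameters are moment-matched by
  numeric root finding, so the truncated distribution reproduces the target
  mean/SD despite hard class bounds on AHI.

* :func:`synth_breath_cycle` / :func:`generate_cohort` synthesise breath-phase
  audio with a severity-dependent acoustic profile: band-shaped noise under a
  raised-cosine envelope, with spectral centroid shift, bandwidth growth,
  impulsive bursts and amplitude variability all increasing monotonically with
  severity.  The profiles are engineered fixtures that encode the qualitative
  escalation of turbulence and impulsiveness with OSA severity; they are not a
  physiological airway model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.io import wavfile

__all__ = [
    "SEVERITY_ORDER",
    "AHI_BOUNDS",
    "SubjectRecord",
    "AcousticSeverityProfile",
    "DEFAULT_PROFILES",
    "COHORT_TEMPLATE",
    "sample_anthropometrics",
    "synth_breath_cycle",
    "generate_cohort",
]

#: Severity labels in increasing clinical order.
SEVERITY_ORDER = ("Non", "Mild", "Moderate", "Severe")

#: Standard AHI (events/hour) intervals defining each class; right-open,
#: partitioning [0, inf).
AHI_BOUNDS = {
    "Non": (0.0, 5.0),
    "Mild": (5.0, 15.0),
    "Moderate": (15.0, 30.0),
    "Severe": (30.0, np.inf),
}


@dataclass
class SubjectRecord:
    """One subject's metadata: severity label, AHI and anthropometrics."""

    subject_id: str
    severity: str
    ahi: float
    age: float
    sex: str  # "M" or "F"
    bmi: float
    nc: float  # neck circumference, cm
    mps: int  # Mallampati score 1-4
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.severity not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity label: {self.severity!r}")
        lo, hi = AHI_BOUNDS[self.severity]
        if not (lo <= self.ahi < hi):
            raise ValueError(
                f"AHI {self.ahi} outside bounds {AHI_BOUNDS[self.severity]} "
                f"for class {self.severity}"
            )
        if self.mps not in (1, 2, 3, 4):
            raise ValueError("Mallampati score must be in 1..4")


# Class-conditional summary statistics of the reference cohort used to
# parameterize the samplers: n, AHI mean/SD, male count, age mean/SD,
# NC mean/SD (cm), BMI mean/SD (kg/m^2), Mallampati counts for scores 1..4.
COHORT_TEMPLATE = {
    "Non": dict(n=74, ahi=(1.2, 1.3), males=29, age=(46.8, 12.9),
                nc=(38.8, 4.0), bmi=(30.6, 6.2), mps=(41, 19, 6, 8)),
    "Mild": dict(n=35, ahi=(8.7, 2.6), males=21, age=(52.3, 11.6),
                 nc=(42.1, 6.5), bmi=(34.3, 8.4), mps=(18, 6, 9, 1)),
    "Moderate": dict(n=50, ahi=(21.5, 4.2), males=36, age=(54.7, 11.3),
                     nc=(43.1, 3.4), bmi=(33.8, 6.4), mps=(17, 17, 8, 8)),
    "Severe": dict(n=40, ahi=(69.5, 33.3), males=30, age=(48.9, 11.1),
                   nc=(45.3, 3.6), bmi=(39.7, 8.7), mps=(5, 13, 14, 8)),
}


def _truncnorm_moments(mu, sigma, lo, hi):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    d = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return d.mean(), d.std()


import functools


@functools.lru_cache(maxsize=None)
def match_truncnorm(target_mean, target_sd, lo, hi):
    """Find (mu, sigma) so the truncated normal on [lo, hi) has the target
    mean/SD.  Falls back to least-squares moment error when the targets are
    infeasible on the given support; returns (mu, sigma, achieved_mean,
    achieved_sd, exact_flag).
    """

    def resid(p):
        mu, log_sigma = p
        m, s = _truncnorm_moments(mu, np.exp(log_sigma), lo, hi)
        return [m - target_mean, s - target_sd]

    best = None
    for mu0, s0 in [(target_mean, target_sd), (target_mean - target_sd, 2 * target_sd),
                    (lo if np.isfinite(lo) else target_mean, 3 * target_sd)]:
        sol = optimize.least_squares(resid, np.array([mu0, np.log(s0)]),
                                     method="lm", xtol=1e-13, ftol=1e-13)
        if best is None or sol.cost < best.cost:
            best = sol
    if best.cost > 1e-10:  # infeasible targets: polish the squared moment error
        sol = optimize.minimize(lambda p: sum(r ** 2 for r in resid(p)), best.x,
                                method="Nelder-Mead",
                                options=dict(xatol=1e-8, fatol=1e-10,
                                             maxiter=300))
        if sol.fun < 2 * best.cost:
            best = sol
        mu, sigma = best.x[0], float(np.exp(best.x[1]))
    else:
        mu, sigma = best.x[0], float(np.exp(best.x[1]))
    m, s = _truncnorm_moments(mu, sigma, lo, hi)
    exact = abs(m - target_mean) < 1e-6 * max(1, abs(target_mean)) and \
        abs(s - target_sd) < 1e-6 * max(1, target_sd)
    return mu, sigma, m, s, exact


def _sample_truncnorm(rng, target_mean, target_sd, lo, hi, n):
    mu, sigma, m, s, exact = match_truncnorm(target_mean, target_sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    x = stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(size=n, random_state=rng)
    return x, dict(mu=mu, sigma=sigma, achieved_mean=m, achieved_sd=s, exact=exact)


def sample_anthropometrics(severity: str, n: int, seed: int) -> list[SubjectRecord]:
    """Draw ``n`` subject records for one severity class.

    Continuous fields come from truncated normals moment-matched to the
    reference cohort's class-conditional mean/SD (AHI truncated to the class
    AHI interval; age/NC/BMI truncated at zero).  Sex and Mallampati score are
    drawn from the reference category proportions.  Deterministic given seed.
    Achieved sampler moments are recorded in each record's ``meta``.
    """
    if severity not in SEVERITY_ORDER:
        raise ValueError(f"unknown severity label: {severity!r}")
    if n <= 0:
        raise ValueError("n must be >= 1")
    tpl = COHORT_TEMPLATE[severity]
    rng = np.random.default_rng(seed)
    lo, hi = AHI_BOUNDS[severity]
    ahi, ahi_info = _sample_truncnorm(rng, *tpl["ahi"], lo, hi, n)
    age, _ = _sample_truncnorm(rng, *tpl["age"], 0.0, np.inf, n)
    nc, _ = _sample_truncnorm(rng, *tpl["nc"], 0.0, np.inf, n)
    bmi, _ = _sample_truncnorm(rng, *tpl["bmi"], 0.0, np.inf, n)
    p_male = tpl["males"] / tpl["n"]
    sex = np.where(rng.random(n) < p_male, "M", "F")
    mps_p = np.asarray(tpl["mps"], dtype=float)
    mps = rng.choice([1, 2, 3, 4], size=n, p=mps_p / mps_p.sum())
    records = [
        SubjectRecord(
            subject_id=f"{severity}{i:04d}",
            severity=severity,
            ahi=float(ahi[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            nc=float(nc[i]),
            mps=int(mps[i]),
            meta={"ahi_sampler": ahi_info},
        )
        for i in range(n)
    ]
    return records


@dataclass(frozen=True)
class AcousticSeverityProfile:
    """Acoustic parameters of the synthetic breath model for one severity.

    centroid_shift
        Upward shift of the noise band's centre frequency (Hz).
    bandwidth_scale
        Multiplier (>= 1) on the base noise bandwidth — broader, more
        turbulent spectra with severity.
    burst_rate
        Expected number of impulsive bursts per breath phase (Poisson).
    amplitude_cv
        Coefficient of variation of slow multiplicative envelope modulation,
        modelling breath-to-breath effort variability.
    ar_regularity
        In [0, 1): mixing weight of a narrow autoregressive resonator against
        broadband noise; high values give a more regular, tonal spectrum.
    """

    centroid_shift: float
    bandwidth_scale: float
    burst_rate: float
    amplitude_cv: float
    ar_regularity: float

    def __post_init__(self):
        if self.bandwidth_scale < 1:
            raise ValueError("bandwidth_scale must be >= 1")
        if not (0 <= self.ar_regularity < 1):
            raise ValueError("ar_regularity must be in [0, 1)")
        if self.burst_rate < 0 or self.amplitude_cv < 0:
            raise ValueError("burst_rate and amplitude_cv must be >= 0")


#: Monotone severity ladder: turbulence, bandwidth, centroid and
#: impulsiveness escalate from Non to Severe while spectral regularity drops.
DEFAULT_PROFILES = {
    "Non": AcousticSeverityProfile(0.0, 1.0, 0.0, 0.05, 0.90),
    "Mild": AcousticSeverityProfile(60.0, 1.15, 1.0, 0.10, 0.85),
    "Moderate": AcousticSeverityProfile(140.0, 1.35, 3.0, 0.20, 0.78),
    "Severe": AcousticSeverityProfile(250.0, 1.60, 6.0, 0.35, 0.68),
}

#: SD (in class-index steps) of the per-subject severity latent around the
#: class centre; models inter-subject heterogeneity of airway acoustics so
#: adjacent severity classes overlap acoustically as clinical cohorts do.
SUBJECT_PROFILE_JITTER = 0.5


def interpolated_profile(z: float) -> AcousticSeverityProfile:
    """Profile at a continuous severity coordinate z in [0, 3] obtained by
    linear interpolation along the class ladder."""
    z = float(np.clip(z, 0.0, 3.0))
    grid = np.arange(4.0)
    ladder = [DEFAULT_PROFILES[s] for s in SEVERITY_ORDER]

    def interp(attr):
        return float(np.interp(z, grid, [getattr(p, attr) for p in ladder]))

    return AcousticSeverityProfile(
        centroid_shift=interp("centroid_shift"),
        bandwidth_scale=max(1.0, interp("bandwidth_scale")),
        burst_rate=max(0.0, interp("burst_rate")),
        amplitude_cv=max(0.0, interp("amplitude_cv")),
        ar_regularity=float(np.clip(interp("ar_regularity"), 0.0, 0.999)))


BASE_CENTER_HZ = 450.0  # tracheal noise band centre for a healthy airway
BASE_HALFWIDTH_HZ = 250.0
MOUTH_CENTER_OFFSET_HZ = 80.0  # mouth route sits slightly higher in frequency
EXPIRATION_GAIN = 0.8  # expirations are a little quieter than inspirations


def _resonator_noise(rng, n, fs, f_center, bw):
    """AR(2) resonator driven by white noise: pole angle at f_center,
    radius set by bandwidth."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * f_center / fs
    a = [1.0, -2 * r * np.cos(theta), r * r]
    return signal.lfilter([1.0], a, rng.standard_normal(n))


def _band_noise(rng, n, fs, f_lo, f_hi):
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfilt(sos, rng.standard_normal(n))


def synth_breath_cycle(route: str, phase: str, profile: AcousticSeverityProfile,
                       fs: float, duration: float, seed: int) -> np.ndarray:
    """Synthesise one breath-phase waveform (zero mean, unit-scale RMS core).

    Raised-cosine amplitude envelope over band-shaped noise (an AR resonator
    mixed with broadband bandpass noise), slow multiplicative amplitude
    modulation with coefficient of variation ``amplitude_cv``, plus Poisson
    impulsive bursts at ``burst_rate`` per phase.
    """
    if fs < 6000:
        raise ValueError("fs must be >= 6000 Hz (Nyquist above analysis band)")
    if not (0.5 <= duration <= 5.0):
        raise ValueError("duration must be in [0.5, 5] s")
    if route not in ("nose", "mouth") or phase not in ("inspiration", "expiration"):
        raise ValueError("route must be nose/mouth, phase inspiration/expiration")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    center = BASE_CENTER_HZ + profile.centroid_shift
    if route == "mouth":
        center += MOUTH_CENTER_OFFSET_HZ
    half = BASE_HALFWIDTH_HZ * profile.bandwidth_scale
    f_lo = max(80.0, center - half)
    f_hi = min(0.45 * fs, center + half)

    tonal = _resonator_noise(rng, n, fs, center, 0.4 * half)
    broad = _band_noise(rng, n, fs, f_lo, f_hi)
    w = profile.ar_regularity
    x = w * tonal / (np.std(tonal) + 1e-12) + (1 - w) * broad / (np.std(broad) + 1e-12)

    # slow multiplicative amplitude modulation (effort variability)
    if profile.amplitude_cv > 0:
        slow = rng.standard_normal(max(8, int(duration * 8)))
        slow = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, slow.size), slow)
        mod = 1.0 + profile.amplitude_cv * slow / (np.std(slow) + 1e-12)
        x *= np.clip(mod, 0.1, None)

    # impulsive bursts: short damped high-band wavelets
    n_bursts = rng.poisson(profile.burst_rate)
    burst_len = int(0.008 * fs)
    t_b = np.arange(burst_len) / fs
    for _ in range(n_bursts):
        pos = rng.integers(burst_len, max(burst_len + 1, n - burst_len))
        f_b = rng.uniform(800, 2500)
        wavelet = np.exp(-t_b / 0.002) * np.sin(2 * np.pi * f_b * t_b)
        x[pos:pos + burst_len] += 4.0 * rng.uniform(0.5, 1.0) * wavelet

    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))  # raised cosine
    x *= env
    if phase == "expiration":
        x *= EXPIRATION_GAIN
    x -= x.mean()
    rms = np.sqrt(np.mean(x ** 2))
    return x / (rms + 1e-12)


#: Default recording-protocol constants.
DEFAULT_FS = 10240.0
PHASE_DURATION_S = 1.5
SILENCE_GAP_S = 0.3
N_BREATHS = 5
NOISE_FLOOR_DB = -40.0  # microphone noise relative to breath RMS


def _render_recording(records_rng_seed: int, route: str,
                      profile: AcousticSeverityProfile, fs: float) -> np.ndarray:
    """One recording: N_BREATHS cycles of inspiration/expiration separated by
    silence gaps, over an additive microphone noise floor."""
    gap = np.zeros(int(SILENCE_GAP_S * fs))
    parts = [gap]
    for b in range(N_BREATHS):
        for j, phase in enumerate(("inspiration", "expiration")):
            seed = records_rng_seed + 17 * b + 7 * j
            parts.append(synth_breath_cycle(route, phase, profile, fs,
                                            PHASE_DURATION_S, seed))
            parts.append(gap)
    x = np.concatenate(parts)
    floor = 10 ** (NOISE_FLOOR_DB / 20.0)
    rng = np.random.default_rng(records_rng_seed + 999)
    x = x + floor * rng.standard_normal(x.size)
    return x


def generate_cohort(class_sizes: dict[str, int], fs: float = DEFAULT_FS,
                    seed: int = 0, out_dir: str | None = None,
                    profiles: dict[str, AcousticSeverityProfile] | None = None,
                    ) -> tuple[dict[tuple[str, str], np.ndarray], pd.DataFrame]:
    """Generate a full synthetic cohort: per subject one nose and one mouth
    recording of five breath cycles, plus the metadata table.

    Returns ``(recordings, metadata)`` where ``recordings`` maps
    ``(subject_id, route)`` to the waveform.  When ``out_dir`` is given, WAV
    files (PCM 16-bit mono) and ``metadata.csv`` are also written there.
    """
    profiles = profiles or DEFAULT_PROFILES
    for sev, cnt in class_sizes.items():
        if sev not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity label: {sev!r}")
        if cnt < 0:
            raise ValueError("class sizes must be >= 0")
    recordings: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    for si, sev in enumerate(s for s in SEVERITY_ORDER if class_sizes.get(s, 0) > 0):
        n = class_sizes[sev]
        recs = sample_anthropometrics(sev, n, seed=seed + 1000 * si)
        cls_idx = SEVERITY_ORDER.index(sev)
        jit_rng = np.random.default_rng(seed + 7717 * si)
        for ri, rec in enumerate(recs):
            base = seed * 100003 + si * 90001 + ri * 1009
            if profiles is DEFAULT_PROFILES:
                z = cls_idx + SUBJECT_PROFILE_JITTER * jit_rng.standard_normal()
                profile = interpolated_profile(z)
            else:  # custom profiles are used verbatim
                profile = profiles[sev]
            for route_i, route in enumerate(("nose", "mouth")):
                wav = _render_recording(base + 50021 * route_i, route,
                                        profile, fs)
                recordings[(rec.subject_id, route)] = wav
            rows.append(dict(subject_id=rec.subject_id, severity=rec.severity,
                             ahi=rec.ahi, age=rec.age, sex=rec.sex,
                             bmi=rec.bmi, nc=rec.nc, mps=rec.mps))
    metadata = pd.DataFrame(rows, columns=["subject_id", "severity", "ahi",
                                           "age", "sex", "bmi", "nc", "mps"])
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for (sid, route), wav in recordings.items():
            peak = np.max(np.abs(wav)) + 1e-12
            pcm = np.clip(wav / peak * 0.9 * 32767, -32768, 32767).astype(np.int16)
            wavfile.write(os.path.join(out_dir, f"{sid}_{route}.wav"),
                          int(fs), pcm)
        metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    return recordings, metadata
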