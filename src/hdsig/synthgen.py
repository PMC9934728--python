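"""Synthetic cohort generator.

Generates multichannel EEG/ECG/fNIRS recordings with the statistical contrasts
the downstream analysis assumes:

* EEG — a sum of band-limited random-phase oscillations (delta 0.5-3.5,
  theta 3.5-7.5, alpha 7.5-13, beta 13-30, gamma 30-45 Hz), realized as
  narrowband Gaussian noise with a fixed RMS per band, plus white sensor
  noise. HD patients' delta/theta oscillation amplitudes are scaled down by
  ``eeg_lowband_amp_ratio``, emulating the low-voltage slow activity that
  accompanies cortical atrophy.
* ECG — a PQRST-like Gaussian-bump pulse train at ~1.1 Hz whose beat-to-beat
  intervals jitter with a class-dependent standard deviation (HD rhythms are
  less periodic).
* fNIRS — band-limited slow oscillations in 0.2-1.5 Hz per optode; the HbO
  channel and the (sign-inverted) HbR channel of an optode share a common
  component with correlation ``fnirs_coupling_rho`` (tighter coupling in
  controls).

The band oscillations are stochastic with a correlation time (roughly the
reciprocal bandwidth) much shorter than the 4 s epoch step, and every
patient's band RMS is the same class-dependent constant. Consequently, under
a null configuration (amplitude ratio 1, equal jitter and coupling)
epoch-level features carry essentially no patient-level random effect and
the two classes are exchangeable — the property the classifier- and
p-value-calibration checks rely on. A deterministic per-patient waveform
(e.g. fixed sinusoids) would instead stamp a patient-identifying signature
on the features that grouped cross-validation detects as spurious signal.
Real cohorts do have patient-level effects (see docs/methods.md).

Patients are independently reproducible: patient ``i`` is generated from
``numpy.random.default_rng([seed, i])``, so regenerating a cohort with the
same seed is bit-identical regardless of which patients are inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import (
    ECG_CHANNELS,
    EEG_CHANNELS,
    FNIRS_CHANNELS,
    Cohort,
    Diagnosis,
    Modality,
    PatientRecord,
    Recording,
)

__all__ = [
    "EffectConfig",
    "generate_cohort",
    "clinic_scale_config",
    "desk_scale_config",
    "EEG_BANDS",
    "EEG_BAND_AMPLITUDES_V",
]

#: Canonical EEG band bounds, Hz.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (3.5, 7.5),
    "alpha": (7.5, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Per-band oscillation amplitudes in volts (roughly 1/f-shaped, tens of µV).
EEG_BAND_AMPLITUDES_V: dict[str, float] = {
    "delta": 20e-6,
    "theta": 15e-6,
    "alpha": 10e-6,
    "beta": 5e-6,
    "gamma": 2e-6,
}

_FNIRS_BAND = (0.2, 1.5)  # Hz, hemodynamic oscillation band

# ECG wave morphology: (centre as fraction of beat interval, amplitude V, width s)
_ECG_WAVES = (
    (0.15, 0.10e-3, 0.040),   # P
    (0.28, -0.10e-3, 0.012),  # Q
    (0.30, 1.00e-3, 0.020),   # R
    (0.32, -0.15e-3, 0.012),  # S
    (0.55, 0.20e-3, 0.070),   # T
)


@dataclass
class EffectConfig:
    """Cohort structure and class-contrast parameters.

    The defaults reproduce the clinic cohort's structure (69 patients, 1200 s,
    EEG 1 kHz / ECG 1.2 kHz / fNIRS 31.25 Hz). The contrast magnitudes are free
    parameters — the source study reports no effect sizes — chosen so that the
    class differences are visible to the feature set without being degenerate.
    """

    # class-contrast knobs (the HD side; control baselines below)
    eeg_lowband_amp_ratio: float = 0.6    # ×delta/theta amplitude in HD
    ecg_period_jitter_sd: float = 0.06    # s, HD beat-interval jitter
    fnirs_coupling_rho: float = 0.5       # HbO/HbR coupling in HD
    ecg_jitter_sd_control: float = 0.02   # s
    fnirs_rho_control: float = 0.9

    # noise levels
    noise_sd_eeg: float = 5e-6            # V
    noise_sd_ecg: float = 2e-5            # V
    noise_sd_fnirs: float = 0.05          # arbitrary OD units

    # cohort structure
    n_shd: int = 15
    n_phd: int = 12
    n_control: int = 36
    n_unknown: int = 6
    duration_s: float = 1200.0
    eeg_fs: float = 1000.0
    ecg_fs: float = 1200.0
    fnirs_fs: float = 31.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.eeg_lowband_amp_ratio <= 2.0):
            raise ValueError("eeg_lowband_amp_ratio must be in (0, 2]")
        for name in ("n_shd", "n_phd", "n_control", "n_unknown"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.duration_s < 5.0:
            raise ValueError("duration_s must cover at least one epoch (5 s)")

    @property
    def n_patients(self) -> int:
        return self.n_shd + self.n_phd + self.n_control + self.n_unknown

    def replace(self, **changes) -> "EffectConfig":
        return replace(self, **changes)


def clinic_scale_config(seed: int = 0) -> EffectConfig:
    """Configuration matching the clinic cohort's structure (69 patients, 1200 s)."""
    return EffectConfig(seed=seed)


def desk_scale_config(
    seed: int = 0,
    *,
    n_shd: int = 5,
    n_phd: int = 5,
    n_control: int = 10,
    n_unknown: int = 0,
    duration_s: float = 60.0,
) -> EffectConfig:
    """Reduced-scale configuration for tests and examples.

    Same montage (channel counts are what the feature-space structure depends
    on); shorter recordings and lower EEG/ECG sampling rates keep a full
    pipeline run in the tens of seconds on one CPU.
    """
    return EffectConfig(
        seed=seed,
        n_shd=n_shd,
        n_phd=n_phd,
        n_control=n_control,
        n_unknown=n_unknown,
        duration_s=duration_s,
        eeg_fs=250.0,
        ecg_fs=300.0,
        fnirs_fs=31.25,
    )


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float
) -> np.ndarray:
    """Narrowband Gaussian noise with exact RMS, synthesized in the frequency
    domain (random phases on every in-band Fourier mode)."""
    spec = np.fft.rfft(rng.normal(size=n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gen_eeg(rng: np.random.Generator, cfg: EffectConfig, hd: bool) -> Recording:
    n = int(round(cfg.duration_s * cfg.eeg_fs))
    data = np.empty((len(EEG_CHANNELS), n))
    for ci in range(len(EEG_CHANNELS)):
        sig = rng.normal(0.0, cfg.noise_sd_eeg, size=n)
        for band, (lo, hi) in EEG_BANDS.items():
            amp = EEG_BAND_AMPLITUDES_V[band]
            if hd and band in ("delta", "theta"):
                amp *= cfg.eeg_lowband_amp_ratio
            # RMS amp/sqrt(2): same band power as a sinusoid of amplitude amp
            sig += _band_noise(rng, n, cfg.eeg_fs, lo, hi, amp / np.sqrt(2.0))
        data[ci] = sig
    return Recording(Modality.EEG, data, cfg.eeg_fs, EEG_CHANNELS)


def _gen_ecg(rng: np.random.Generator, cfg: EffectConfig, hd: bool) -> Recording:
    n = int(round(cfg.duration_s * cfg.ecg_fs))
    t = np.arange(n) / cfg.ecg_fs
    jitter_sd = cfg.ecg_period_jitter_sd if hd else cfg.ecg_jitter_sd_control
    mean_period = 1.0 / 1.1  # ~66 bpm
    sig = rng.normal(0.0, cfg.noise_sd_ecg, size=n)
    beat_start = -mean_period * rng.uniform()  # random cardiac phase at t=0
    while beat_start < cfg.duration_s:
        period = max(0.4, mean_period + jitter_sd * rng.normal())
        for frac, amp, width in _ECG_WAVES:
            centre = beat_start + frac * period
            lo = np.searchsorted(t, centre - 5 * width)
            hi = np.searchsorted(t, centre + 5 * width)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / width) ** 2)
        beat_start += period
    return Recording(Modality.ECG, sig[None, :], cfg.ecg_fs, ECG_CHANNELS)


def _gen_fnirs(rng: np.random.Generator, cfg: EffectConfig, hd: bool) -> Recording:
    n = int(round(cfg.duration_s * cfg.fnirs_fs))
    rho = cfg.fnirs_coupling_rho if hd else cfg.fnirs_rho_control
    lo, hi = _FNIRS_BAND
    data = np.empty((len(FNIRS_CHANNELS), n))
    for opt in range(len(FNIRS_CHANNELS) // 2):
        shared = _band_noise(rng, n, cfg.fnirs_fs, lo, hi, 1.0)
        indep = _band_noise(rng, n, cfg.fnirs_fs, lo, hi, 1.0)
        hbo = shared + rng.normal(0.0, cfg.noise_sd_fnirs, size=n)
        # HbR mirrors HbO with coupling rho; physiologically anti-correlated
        hbr = -(rho * shared + np.sqrt(1 - rho**2) * indep)
        hbr += rng.normal(0.0, cfg.noise_sd_fnirs, size=n)
        data[2 * opt] = hbo
        data[2 * opt + 1] = hbr
    return Recording(Modality.FNIRS, data, cfg.fnirs_fs, FNIRS_CHANNELS)


def generate_cohort(cfg: EffectConfig) -> Cohort:
    """Generate a synthetic cohort; deterministic given ``cfg.seed``."""
    diagnoses = (
        [Diagnosis.SHD] * cfg.n_shd
        + [Diagnosis.PHD] * cfg.n_phd
        + [Diagnosis.CONTROL] * cfg.n_control
        + [Diagnosis.UNKNOWN] * cfg.n_unknown
    )
    patients = []
    for idx, diagnosis in enumerate(diagnoses):
        rng = np.random.default_rng([cfg.seed, idx])
        hd = diagnosis in (Diagnosis.SHD, Diagnosis.PHD)
        patients.append(
            PatientRecord(
                patient_id=f"P{idx + 1:03d}",
                diagnosis=diagnosis,
                recordings={
                    Modality.EEG: _gen_eeg(rng, cfg, hd),
                    Modality.ECG: _gen_ecg(rng, cfg, hd),
                    Modality.FNIRS: _gen_fnirs(rng, cfg, hd),
                },
            )
        )
    return Cohort(patients=patients)
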