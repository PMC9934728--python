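"""Filtering, segmentation, epoch rejection and normalization.

The pipeline order is: zero-phase band-pass per modality, cut into 5 s epochs
with 1 s overlap (4 s step), drop epochs exceeding a peak-to-peak amplitude
threshold, then subtract the per-epoch per-channel mean.

Epoch emission rule: a window starts at every multiple of the 4 s step whose
start lies at or before ``duration - step`` — i.e. every window contains at
least 4 s of real signal — and a trailing deficit is zero-padded. This is the
one convention under which a 1200 s recording yields exactly 300 epochs
(starts 0, 4, ..., 1196 s; the last window is padded by 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Modality, Recording

__all__ = [
    "BandPassSpec",
    "EpochSet",
    "DEFAULT_BANDS",
    "DEFAULT_PTP_THRESHOLDS",
    "bandpass",
    "epochize",
    "drop_bad_epochs",
    "normalize",
    "preprocess_recording",
]

#: Per-modality pass-bands, Hz: EEG keeps delta-gamma, ECG keeps the machine's
#: full range below high-frequency noise, fNIRS keeps hemodynamics between
#: blood-pressure drift and cardiac pulsation.
DEFAULT_BANDS: dict[Modality, tuple[float, float]] = {
    Modality.EEG: (0.5, 45.0),
    Modality.ECG: (0.05, 100.0),
    Modality.FNIRS: (0.2, 1.5),
}

#: Peak-to-peak rejection thresholds per modality (EEG/ECG in volts);
#: None disables rejection for that modality.
DEFAULT_PTP_THRESHOLDS: dict[Modality, float | None] = {
    Modality.EEG: 500e-6,
    Modality.ECG: 5e-3,
    Modality.FNIRS: None,
}

_FILTER_ORDER = 5


@dataclass(frozen=True)
class BandPassSpec:
    """Pass-band edges in Hz; must sit strictly inside (0, fs/2)."""

    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(f"need 0 < lo < hi, got ({self.lo_hz}, {self.hi_hz})")

    def validate_for(self, fs: float) -> None:
        if self.hi_hz >= fs / 2:
            raise ValueError(
                f"upper edge {self.hi_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


@dataclass
class EpochSet:
    """Segmented windows for one modality of one patient.

    epochs has shape (n_epochs, n_channels, samples_per_epoch).
    """

    epochs: np.ndarray
    fs: float
    modality: Modality
    patient_id: str
    channel_names: tuple[str, ...]
    epoch_length_s: float = 5.0
    overlap_s: float = 1.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, channels, samples)")
        expected = int(round(self.epoch_length_s * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples, expected {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def bandpass(rec: Recording, spec: BandPassSpec) -> Recording:
    """Zero-phase 5th-order Butterworth band-pass (applied forward-backward)."""
    spec.validate_for(rec.fs)
    sos = sps.butter(
        _FILTER_ORDER, (spec.lo_hz, spec.hi_hz), btype="bandpass", fs=rec.fs,
        output="sos",
    )
    # sosfiltfilt needs enough samples for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if rec.n_samples <= padlen:
        raise ValueError(
            f"signal of {rec.n_samples} samples too short for the filter "
            f"(needs > {padlen})"
        )
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(rec.modality, filtered, rec.fs, rec.channel_names)


def epochize(
    rec: Recording, epoch_length_s: float = 5.0, overlap_s: float = 1.0
) -> EpochSet:
    """Cut a recording into overlapping fixed-length windows.

    Consecutive windows share exactly ``overlap_s`` seconds. A window is
    emitted iff its start is at most ``duration - step``; a trailing deficit
    is zero-padded.
    """
    if overlap_s >= epoch_length_s:
        raise ValueError("overlap must be shorter than the epoch length")
    step_s = epoch_length_s - overlap_s
    if rec.duration_s < step_s:
        raise ValueError(
            f"recording of {rec.duration_s} s shorter than one step ({step_s} s)"
        )
    step = int(round(step_s * rec.fs))
    win = int(round(epoch_length_s * rec.fs))
    n_samples = rec.n_samples
    last_start = n_samples - step  # emit while start <= duration - step
    starts = np.arange(0, last_start + 1, step)
    epochs = np.zeros((len(starts), rec.n_channels, win))
    for i, s in enumerate(starts):
        chunk = rec.data[:, s : s + win]
        epochs[i, :, : chunk.shape[1]] = chunk
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        modality=rec.modality,
        patient_id="",
        channel_names=rec.channel_names,
        epoch_length_s=epoch_length_s,
        overlap_s=overlap_s,
    )


def drop_bad_epochs(es: EpochSet, ptp_threshold: float | None) -> EpochSet:
    """Remove epochs whose peak-to-peak amplitude on any channel exceeds the
    threshold; ``None`` disables rejection. Order is preserved."""
    if ptp_threshold is None:
        return es
    if ptp_threshold <= 0:
        raise ValueError("ptp_threshold must be positive (or None to disable)")
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # (n_epochs, channels)
    keep = (ptp <= ptp_threshold).all(axis=1)
    if not keep.any():
        raise ValueError(
            f"all {es.n_epochs} epochs rejected for patient "
            f"{es.patient_id or '<unknown>'!r} ({es.modality.value})"
        )
    return EpochSet(
        epochs=es.epochs[keep],
        fs=es.fs,
        modality=es.modality,
        patient_id=es.patient_id,
        channel_names=es.channel_names,
        epoch_length_s=es.epoch_length_s,
        overlap_s=es.overlap_s,
    )


def normalize(es: EpochSet) -> EpochSet:
    """Subtract each channel's mean within each epoch (variance unchanged)."""
    if es.n_epochs == 0:
        return es
    centred = es.epochs - es.epochs.mean(axis=2, keepdims=True)
    return EpochSet(
        epochs=centred,
        fs=es.fs,
        modality=es.modality,
        patient_id=es.patient_id,
        channel_names=es.channel_names,
        epoch_length_s=es.epoch_length_s,
        overlap_s=es.overlap_s,
    )


def preprocess_recording(
    rec: Recording,
    patient_id: str = "",
    band: tuple[float, float] | None = None,
    ptp_threshold: float | None | str = "default",
    epoch_length_s: float = 5.0,
    overlap_s: float = 1.0,
) -> EpochSet:
    """Full per-recording pipeline: band-pass, epochize, reject, normalize."""
    lo, hi = band if band is not None else DEFAULT_BANDS[rec.modality]
    es = epochize(bandpass(rec, BandPassSpec(lo, hi)), epoch_length_s, overlap_s)
    es.patient_id = patient_id
    thr = (
        DEFAULT_PTP_THRESHOLDS[rec.modality]
        if isinstance(ptp_threshold, str)
        else ptp_threshold
    )
    return normalize(drop_bad_epochs(es, thr))
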