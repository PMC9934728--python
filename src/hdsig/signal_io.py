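"""Data model for multichannel biosignal recordings and cohorts, plus plain-text IO.

A patient in this package carries three simultaneous recordings — EEG (scalp
electrical activity), ECG (cardiac electrical activity) and fNIRS (cortical
hemodynamics via oxy-/deoxy-hemoglobin optical channels) — together with a
clinical diagnosis that collapses to a binary Huntington's-disease label.

On disk a cohort is a directory of per-recording CSV files (header row =
channel names, one column per channel, one row per sample) with a JSON
sidecar holding sampling rate and modality, indexed by a manifest CSV. The
format is deliberately plain text: fixtures stay inspectable and diffs stay
meaningful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Diagnosis",
    "Recording",
    "PatientRecord",
    "Cohort",
    "CohortIOError",
    "read_cohort",
    "write_cohort",
    "EEG_CHANNELS",
    "FNIRS_CHANNELS",
    "ECG_CHANNELS",
]


class Modality(str, Enum):
    EEG = "EEG"
    ECG = "ECG"
    FNIRS = "fNIRS"


class Diagnosis(str, Enum):
    SHD = "SHD"          # symptomatic Huntington's disease
    PHD = "PHD"          # pre-symptomatic mutation carrier
    CONTROL = "Control"
    UNKNOWN = "Unknown"  # unclassified; treated as control for labelling


#: 16-electrode 10-20 montage used for EEG.
EEG_CHANNELS: tuple[str, ...] = (
    "C3", "C4", "Cz", "F3", "F4", "Fp1", "Fp2", "O1",
    "O2", "P3", "P4", "P7", "P8", "Pz", "T7", "T8",
)

#: 11 optodes x {HbO, HbR} = 22 fNIRS channels.
FNIRS_CHANNELS: tuple[str, ...] = tuple(
    f"N{i}_{h}" for i in range(1, 12) for h in ("HbO", "HbR")
)

ECG_CHANNELS: tuple[str, ...] = ("ECG",)

_EXPECTED_CHANNELS = {
    Modality.EEG: set(EEG_CHANNELS),
    Modality.FNIRS: set(FNIRS_CHANNELS),
}


class CohortIOError(RuntimeError):
    """Raised for malformed cohorts on disk (missing files, NaNs, fs mismatch)."""


@dataclass
class Recording:
    """One modality's multichannel signal.

    data is a (channels, samples) float array; EEG/ECG in volts, fNIRS in
    arbitrary optical-density units.
    """

    modality: Modality
    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels, samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = self.channel_names[int(np.argwhere(bad.any(axis=1))[0, 0])]
            raise ValueError(f"non-finite sample in channel {ch!r}")
        if self.modality is Modality.ECG and len(self.channel_names) != 1:
            raise ValueError("ECG must be single-channel")
        expected = _EXPECTED_CHANNELS.get(self.modality)
        if expected is not None and not set(self.channel_names) <= expected:
            extra = sorted(set(self.channel_names) - expected)
            raise ValueError(
                f"unrecognised {self.modality.value} channel names: {extra}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


def _label_for(diagnosis: Diagnosis) -> int:
    # Unclassified participants behaved like controls and are labelled 0.
    return 1 if diagnosis in (Diagnosis.SHD, Diagnosis.PHD) else 0


@dataclass
class PatientRecord:
    """All three recordings of one participant plus diagnosis."""

    patient_id: str
    diagnosis: Diagnosis
    recordings: dict[Modality, Recording]
    #: duration tolerance across modalities, in seconds (one epoch step)
    duration_tol_s: float = 4.0

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        self.recordings = {Modality(k): v for k, v in self.recordings.items()}
        missing = [m.value for m in Modality if m not in self.recordings]
        if missing:
            raise ValueError(
                f"patient {self.patient_id!r} missing modalities: {missing}"
            )
        durations = [r.duration_s for r in self.recordings.values()]
        if max(durations) - min(durations) > self.duration_tol_s:
            raise ValueError(
                f"patient {self.patient_id!r}: modality durations differ by "
                f"{max(durations) - min(durations):.2f} s (> {self.duration_tol_s} s)"
            )

    @property
    def label(self) -> int:
        """Binary target: 1 for HD-positive (SHD or PHD), else 0."""
        return _label_for(self.diagnosis)

    def __getitem__(self, modality: Modality | str) -> Recording:
        return self.recordings[Modality(modality)]


@dataclass
class Cohort:
    """Ordered collection of patients with unique ids."""

    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, idx: int) -> PatientRecord:
        return self.patients[idx]


_MODALITY_STEM = {Modality.EEG: "eeg", Modality.ECG: "ecg", Modality.FNIRS: "fnirs"}
_MANIFEST_COLUMNS = ("patient_id", "diagnosis", "eeg_path", "ecg_path", "fnirs_path")


def write_cohort(cohort: Cohort, root_path: str | Path) -> Path:
    """Write a cohort as per-patient CSV signals + JSON sidecars + a manifest.

    Returns the manifest path. Signal values are serialized with 10
    significant digits, keeping the round trip within 1e-9 relative
    (sub-nanovolt fidelity at EEG scale).
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in cohort:
        pdir = root / patient.patient_id
        pdir.mkdir(exist_ok=True)
        row: dict[str, str] = {
            "patient_id": patient.patient_id,
            "diagnosis": patient.diagnosis.value,
        }
        for modality, stem in _MODALITY_STEM.items():
            rec = patient[modality]
            csv_path = pdir / f"{stem}.csv"
            with open(csv_path, "w") as fh:
                fh.write(",".join(rec.channel_names) + "\n")
                np.savetxt(fh, rec.data.T, fmt="%.10g", delimiter=",")
            sidecar = {
                "modality": rec.modality.value,
                "fs_hz": rec.fs,
                "channel_names": list(rec.channel_names),
                "duration_s": rec.duration_s,
            }
            (pdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
            row[f"{stem}_path"] = str(csv_path.relative_to(root))
        rows.append(row)
    manifest = root / "manifest.csv"
    pd.DataFrame(rows, columns=list(_MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def _read_recording(csv_path: Path, patient_id: str, modality: Modality) -> Recording:
    if not csv_path.exists():
        raise CohortIOError(
            f"patient {patient_id!r}: missing {modality.value} file {csv_path}"
        )
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise CohortIOError(
            f"patient {patient_id!r}: missing {modality.value} sidecar {sidecar_path}"
        )
    meta = json.loads(sidecar_path.read_text())
    if Modality(meta["modality"]) is not modality:
        raise CohortIOError(
            f"patient {patient_id!r}: sidecar modality {meta['modality']!r} "
            f"does not match manifest slot {modality.value}"
        )
    frame = pd.read_csv(csv_path, header=0, dtype=float)
    channel_names = tuple(str(c) for c in frame.columns)
    if tuple(meta["channel_names"]) != channel_names:
        raise CohortIOError(
            f"patient {patient_id!r} {modality.value}: sidecar channel names "
            "disagree with CSV header"
        )
    data = frame.to_numpy().T
    if data.size == 0:
        raise CohortIOError(f"patient {patient_id!r} {modality.value}: empty signal")
    bad = ~np.isfinite(data)
    if bad.any():
        ch = channel_names[int(np.argwhere(bad.any(axis=1))[0, 0])]
        raise CohortIOError(
            f"patient {patient_id!r} {modality.value}: non-finite value in "
            f"channel {ch!r}"
        )
    fs = float(meta["fs_hz"])
    dur = meta.get("duration_s")
    if dur is not None and not math.isclose(dur, data.shape[1] / fs, rel_tol=1e-6):
        raise CohortIOError(
            f"patient {patient_id!r} {modality.value}: sidecar duration "
            f"{dur} s inconsistent with {data.shape[1]} samples at {fs} Hz"
        )
    return Recording(modality=modality, data=data, fs=fs, channel_names=channel_names)


def read_cohort(root_path: str | Path, manifest: str | Path | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Patient order follows the manifest; channel order follows each CSV header.
    """
    root = Path(root_path)
    manifest_path = Path(manifest) if manifest is not None else root / "manifest.csv"
    if not manifest_path.exists():
        raise CohortIOError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path, dtype=str)
    missing_cols = set(_MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise CohortIOError(f"manifest missing columns: {sorted(missing_cols)}")
    patients = []
    for row in table.itertuples(index=False):
        recordings = {
            modality: _read_recording(
                root / getattr(row, f"{stem}_path"), row.patient_id, modality
            )
            for modality, stem in _MODALITY_STEM.items()
        }
        patients.append(
            PatientRecord(
                patient_id=row.patient_id,
                diagnosis=Diagnosis(row.diagnosis),
                recordings=recordings,
            )
        )
    return Cohort(patients=patients)
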