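"""Per-channel quantitative features and cohort feature-matrix assembly.

Each 5 s epoch of each channel yields:

* 3 Hjorth parameters — activity (variance), mobility (RMS frequency in
  rad/sample), complexity (a bandwidth estimate);
* 7 statistical descriptors — excess kurtosis, mean/max of the absolute
  second difference, skewness, coefficient of variation, mean/max of the
  absolute first difference;
* 3 slope descriptors — mean and variance of the first derivative (units/s)
  and the Higuchi fractal dimension;
* 8 single-level DWT summaries — mean, SD, energy and Shannon entropy of the
  approximation and detail coefficient sets (coif1 for EEG/fNIRS, db4 for
  ECG; periodization boundary so the two energies sum to the signal energy);
* Welch band powers — 5 canonical EEG bands, 5 ECG bands, 2 fNIRS bands.

That is 26 features per EEG or ECG channel and 23 per fNIRS channel; with
the 16/1/22-channel montage the epoch feature vector is 948-dimensional.

Feature names encode ``modality.channel.feature`` (e.g.
``EEG.P8.wavelet_detail_energy``) in a deterministic order: modality (EEG,
ECG, fNIRS), then channel, then feature family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import EpochSet
from .signal_io import EEG_CHANNELS, FNIRS_CHANNELS, Modality

__all__ = [
    "FeatureMatrix",
    "statistical_features",
    "higuchi_fd",
    "hjorth",
    "wavelet_features",
    "welch_band_powers",
    "channel_feature_names",
    "assemble",
    "feature_family",
    "feature_signal",
    "feature_channel",
    "PSD_BANDS",
    "WAVELETS",
    "STAT_NAMES",
]

COV_EPS = 1e-12  # guard for coefficient of variation on mean-subtracted signals
HFD_KMAX = 10

#: Per-modality PSD band bounds in Hz. ECG bands follow the peak powers of a
#: typical cardiac spectrum; fNIRS bands bracket respiration and heartbeat.
PSD_BANDS: dict[Modality, dict[str, tuple[float, float]]] = {
    Modality.EEG: {
        "delta": (0.5, 3.5),
        "theta": (3.5, 7.5),
        "alpha": (7.5, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 45.0),
    },
    Modality.ECG: {
        "lf": (0.05, 6.0),
        "lmf": (6.0, 11.0),
        "mf": (11.0, 16.0),
        "hf": (16.0, 20.0),
        "vhf": (20.0, 100.0),
    },
    Modality.FNIRS: {
        "resp": (0.2, 0.6),
        "cardiac": (0.6, 1.5),
    },
}

WAVELETS: dict[Modality, str] = {
    Modality.EEG: "coif1",
    Modality.ECG: "db4",
    Modality.FNIRS: "coif1",
}

HJORTH_NAMES = ("hjorth_activity", "hjorth_mobility", "hjorth_complexity")
STAT_NAMES = (
    "kurtosis",
    "diff2_mean",
    "diff2_max",
    "skewness",
    "coef_variation",
    "diff1_mean",
    "diff1_max",
)
SLOPE_NAMES = ("slope_mean", "slope_var", "higuchi_fd")
WAVELET_NAMES = (
    "wavelet_approx_mean",
    "wavelet_approx_sd",
    "wavelet_approx_energy",
    "wavelet_approx_entropy",
    "wavelet_detail_mean",
    "wavelet_detail_sd",
    "wavelet_detail_energy",
    "wavelet_detail_entropy",
)

_FAMILY_OF = (
    {n: "hjorth" for n in HJORTH_NAMES}
    | {n: "statistical" for n in STAT_NAMES}
    | {n: "slope" for n in SLOPE_NAMES}
    | {n: "wavelet" for n in WAVELET_NAMES}
)


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of one epoch.

    activity = var(x); mobility = sqrt(var(Δx)/var(x)) — the RMS angular
    frequency in rad/sample; complexity = mobility(Δx)/mobility(x). A
    zero-variance signal returns (0, 0, 0) by convention.
    """
    x = np.asarray(x, dtype=float)
    var0 = float(np.var(x))
    if var0 == 0.0:
        return (0.0, 0.0, 0.0)
    d1 = np.diff(x)
    var1 = float(np.var(d1))
    mobility = math.sqrt(var1 / var0)
    if var1 == 0.0:
        return (var0, 0.0, 0.0)
    var2 = float(np.var(np.diff(d1)))
    complexity = math.sqrt(var2 / var1) / mobility
    return (var0, mobility, complexity)


def higuchi_fd(x: np.ndarray, kmax: int = HFD_KMAX) -> float:
    """Higuchi fractal dimension via the curve-length method.

    For each lag k the mean normalized curve length L(k) is averaged over the
    k possible offsets; the dimension is the least-squares slope of
    log L(k) against log(1/k) for k = 1..kmax. Roughly 1 for smooth signals,
    2 for white noise. A constant signal (all curve lengths zero) yields NaN.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * kmax:
        raise ValueError(f"need more than {2 * kmax} samples, got {n}")
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
    if np.any(lk <= 0.0):
        return float("nan")
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lk), 1)[0]
    return float(slope)


def statistical_features(x: np.ndarray, fs: float, kmax: int = HFD_KMAX) -> np.ndarray:
    """Ten statistical/slope descriptors of one epoch.

    Returns, in order: excess kurtosis, coefficient of variation
    (SD/(mean+eps)), skewness, mean|Δx|, mean|Δ²x|, max|Δx|, max|Δ²x|,
    slope mean, slope variance, Higuchi fractal dimension. The slope is the
    first difference scaled by fs (units per second). Kurtosis and skewness
    of a constant signal are defined as 0; its fractal dimension is NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("epoch too short for difference features")
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    sd = float(np.std(x))
    if sd == 0.0:
        kurt = skew = 0.0
    else:
        kurt = float(spstats.kurtosis(x, fisher=True, bias=True))
        skew = float(spstats.skew(x, bias=True))
    slope = d1 * fs
    return np.array(
        [
            kurt,
            sd / (float(np.mean(x)) + COV_EPS),
            skew,
            float(np.mean(np.abs(d1))),
            float(np.mean(np.abs(d2))),
            float(np.max(np.abs(d1))),
            float(np.max(np.abs(d2))),
            float(np.mean(slope)),
            float(np.var(slope)),
            higuchi_fd(x, kmax=kmax),
        ]
    )


def wavelet_features(x: np.ndarray, wavelet: str) -> np.ndarray:
    """Single-level DWT coefficient summaries.

    Returns (approx mean, SD, energy, entropy, detail mean, SD, energy,
    entropy). Energy is the sum of squared coefficients; entropy is the
    Shannon entropy −Σ pᵢ log pᵢ of the normalized squared coefficients
    (0·log 0 := 0, all-zero set → 0). Periodization boundary handling keeps
    the transform orthogonal, so the two energies sum to Σx².
    """
    x = np.asarray(x, dtype=float)
    ca, cd = pywt.dwt(x, wavelet, mode="periodization")
    out = np.empty(8)
    for j, c in enumerate((ca, cd)):
        energy = float(np.sum(c**2))
        if energy > 0.0:
            p = c**2 / energy
            nz = p > 0
            entropy = float(-(p[nz] * np.log(p[nz])).sum())
        else:
            entropy = 0.0
        out[4 * j : 4 * j + 4] = (
            float(np.mean(c)),
            float(np.std(c)),
            energy,
            entropy,
        )
    return out


def welch_band_powers(
    x: np.ndarray,
    fs: float,
    bands: list[tuple[float, float]],
    nperseg: int | None = None,
) -> np.ndarray:
    """Band powers from a Welch PSD (Hann window, 50% overlap).

    ``nperseg`` defaults to one second of signal (capped at the epoch length);
    pass ``len(x)`` for a single full-epoch periodogram. Each band power is
    the trapezoidal integral of the PSD over frequencies in [lo, hi).
    """
    x = np.asarray(x, dtype=float)
    for lo, hi in bands:
        if not (0 <= lo < hi) or hi > fs / 2:
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={fs / 2})")
    if nperseg is None:
        nperseg = min(x.size, int(round(fs)))
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    out = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() >= 2:
            out[i] = np.trapezoid(psd[mask], freqs[mask])
        elif mask.sum() == 1:
            out[i] = float(psd[mask][0]) * (freqs[1] - freqs[0])
        else:
            out[i] = 0.0
    return out


def channel_feature_names(modality: Modality) -> tuple[str, ...]:
    """Per-channel feature keys for one modality, in canonical order."""
    psd = tuple(f"psd_{b}" for b in PSD_BANDS[modality])
    return HJORTH_NAMES + STAT_NAMES + SLOPE_NAMES + WAVELET_NAMES + psd


def feature_family(name: str) -> str:
    """Family of a full feature name: hjorth/statistical/slope/wavelet/psd."""
    key = name.rsplit(".", 1)[-1]
    if key.startswith("psd_"):
        return "psd"
    return _FAMILY_OF[key]


def feature_signal(name: str) -> str:
    """Modality component of a full feature name (EEG/ECG/fNIRS)."""
    return name.split(".", 1)[0]


def feature_channel(name: str) -> str:
    return name.split(".")[1]


@dataclass
class FeatureMatrix:
    """Epochs × named features with per-epoch labels and patient groups."""

    X: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.groups = np.asarray(self.groups)
        self.feature_names = tuple(self.feature_names)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X must be (n_epochs, n_features) matching names")
        if len(self.labels) != self.X.shape[0] or len(self.groups) != self.X.shape[0]:
            raise ValueError("labels/groups must have one entry per epoch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def family_counts(self) -> dict[str, dict[str, int]]:
        """Feature counts per modality per family."""
        counts: dict[str, dict[str, int]] = {}
        for name in self.feature_names:
            sig = feature_signal(name)
            fam = feature_family(name)
            counts.setdefault(sig, {}).setdefault(fam, 0)
            counts[sig][fam] += 1
        return counts

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        """Column subset by feature index."""
        indices = np.asarray(indices)
        return FeatureMatrix(
            X=self.X[:, indices],
            labels=self.labels,
            groups=self.groups,
            feature_names=tuple(self.feature_names[i] for i in indices),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "patient_id", self.groups)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("patient_id", "label"))
        return cls(
            X=df[list(names)].to_numpy(float),
            labels=df["label"].to_numpy(int),
            groups=df["patient_id"].to_numpy(str),
            feature_names=names,
        )


def _epoch_features(es: EpochSet, kmax: int) -> np.ndarray:
    """Feature block (n_epochs, n_channels * features_per_channel) for one
    modality of one patient."""
    modality = es.modality
    bands = list(PSD_BANDS[modality].values())
    wavelet = WAVELETS[modality]
    # full-epoch periodogram for fNIRS: 5 s at 31.25 Hz is too short to split
    # while still resolving the 0.2-0.6 Hz respiration band
    nperseg = es.epochs.shape[2] if modality is Modality.FNIRS else None
    per_chan = len(channel_feature_names(modality))
    out = np.empty((es.n_epochs, es.epochs.shape[1] * per_chan))
    for e in range(es.n_epochs):
        for c in range(es.epochs.shape[1]):
            x = es.epochs[e, c]
            col = c * per_chan
            out[e, col : col + 3] = hjorth(x)
            stat = statistical_features(x, es.fs, kmax=kmax)
            # statistical_features order -> canonical name order
            out[e, col + 3 : col + 13] = stat[[0, 4, 6, 2, 1, 3, 5, 7, 8, 9]]
            out[e, col + 13 : col + 21] = wavelet_features(x, wavelet)
            out[e, col + 21 : col + per_chan] = welch_band_powers(
                x, es.fs, bands, nperseg=nperseg
            )
    return out


_MODALITY_ORDER = (Modality.EEG, Modality.ECG, Modality.FNIRS)


def assemble(
    cohort_epochs: dict[str, dict[Modality, EpochSet]],
    labels: dict[str, int],
    kmax: int = HFD_KMAX,
    nan_to_zero: bool = True,
    max_epoch_mismatch: float = 0.05,
) -> FeatureMatrix:
    """Build the cohort feature matrix from per-patient, per-modality epochs.

    Within a patient, the three modalities' epochs are aligned by index and
    truncated to the shortest modality's count; a mismatch beyond
    ``max_epoch_mismatch`` (fractional) is an error. NaN sentinel features
    (constant-signal fractal dimension) are imputed as 0 when ``nan_to_zero``.

    With no patients, returns an empty matrix whose columns are named for the
    full montage.
    """
    if not cohort_epochs:
        names = _feature_names_for(
            {
                Modality.EEG: EEG_CHANNELS,
                Modality.ECG: ("ECG",),
                Modality.FNIRS: FNIRS_CHANNELS,
            }
        )
        return FeatureMatrix(
            X=np.empty((0, len(names))),
            labels=np.empty(0, int),
            groups=np.empty(0, object),
            feature_names=names,
        )

    blocks, all_labels, all_groups = [], [], []
    names: tuple[str, ...] | None = None
    for pid, per_mod in cohort_epochs.items():
        present = [m for m in _MODALITY_ORDER if m in per_mod]
        counts = [per_mod[m].n_epochs for m in present]
        n_keep = min(counts)
        if n_keep == 0:
            raise ValueError(f"patient {pid!r} has a modality with zero epochs")
        if max(counts) - n_keep > max_epoch_mismatch * max(counts):
            raise ValueError(
                f"patient {pid!r}: modality epoch counts {counts} differ by more "
                f"than {max_epoch_mismatch:.0%}"
            )
        p_names = _feature_names_for(
            {m: per_mod[m].channel_names for m in present}
        )
        if names is None:
            names = p_names
        elif p_names != names:
            raise ValueError(f"patient {pid!r} has a different montage")
        block = np.hstack(
            [_epoch_features(_truncate(per_mod[m], n_keep), kmax) for m in present]
        )
        blocks.append(block)
        all_labels.extend([labels[pid]] * n_keep)
        all_groups.extend([pid] * n_keep)

    X = np.vstack(blocks)
    if nan_to_zero:
        n_bad = int(np.isnan(X).sum())
        if n_bad:
            import logging

            logging.getLogger(__name__).warning(
                "imputed %d missing feature values as 0", n_bad
            )
            X = np.nan_to_num(X, nan=0.0)
    assert names is not None
    return FeatureMatrix(
        X=X,
        labels=np.array(all_labels, int),
        groups=np.array(all_groups, object),
        feature_names=names,
    )


def _truncate(es: EpochSet, n: int) -> EpochSet:
    if es.n_epochs == n:
        return es
    return EpochSet(
        epochs=es.epochs[:n],
        fs=es.fs,
        modality=es.modality,
        patient_id=es.patient_id,
        channel_names=es.channel_names,
        epoch_length_s=es.epoch_length_s,
        overlap_s=es.overlap_s,
    )


def _feature_names_for(
    channels: dict[Modality, tuple[str, ...]]
) -> tuple[str, ...]:
    names = []
    for modality in _MODALITY_ORDER:
        if modality not in channels:
            continue
        keys = channel_feature_names(modality)
        for ch in channels[modality]:
            names.extend(f"{modality.value}.{ch}.{k}" for k in keys)
    return tuple(names)
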