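import numpy as np
import pytest

from hdsig import synthgen
from hdsig.features import FeatureMatrix, channel_feature_names
from hdsig.signal_io import Modality


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-patient cohort with short recordings, for IO and plumbing tests."""
    cfg = synthgen.desk_scale_config(
        seed=7, n_shd=1, n_phd=0, n_control=1, duration_s=10.0
    )
    return synthgen.generate_cohort(cfg)


def make_feature_matrix(
    n_patients=20,
    epochs_per_patient=10,
    n_features=12,
    effect=0.0,
    seed=0,
    feature_names=None,
    informative=(0,),
):
    """Synthetic feature matrix: Gaussian features, optional class shift on
    the informative columns. Half the patients are labelled positive."""
    rng = np.random.default_rng(seed)
    n = n_patients * epochs_per_patient
    if feature_names is None:
        feature_names = tuple(f"EEG.Cz.f{i}" for i in range(n_features))
    X = rng.normal(size=(n, len(feature_names)))
    labels = np.repeat(
        [1 if i < n_patients // 2 else 0 for i in range(n_patients)],
        epochs_per_patient,
    )
    groups = np.repeat([f"P{i:03d}" for i in range(n_patients)], epochs_per_patient)
    for j in informative:
        X[:, j] += effect * labels
    return FeatureMatrix(
        X=X, labels=labels, groups=groups, feature_names=feature_names
    )


@pytest.fixture
def mini_montage_names():
    """Feature names for a reduced montage: 2 EEG + 1 ECG + 2 fNIRS channels."""
    names = []
    for ch in ("C3", "P8"):
        names += [f"EEG.{ch}.{k}" for k in channel_feature_names(Modality.EEG)]
    names += [f"ECG.ECG.{k}" for k in channel_feature_names(Modality.ECG)]
    for ch in ("N1_HbO", "N1_HbR"):
        names += [f"fNIRS.{ch}.{k}" for k in channel_feature_names(Modality.FNIRS)]
    return tuple(names)
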