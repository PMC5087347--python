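import numpy as np
import pytest

from eegselect.features import BAND_NAMES, FeatureTable


def make_table(
    values: np.ndarray,
    labels,
    n_bands: int = 4,
    trial_of_sample=None,
    normalized: bool = True,
) -> FeatureTable:
    """Wrap a raw matrix into a FeatureTable with a channel-major feature map.

    The feature count must divide by *n_bands*; feature ``c*n_bands + b`` is
    band ``b`` of channel ``c``, mirroring the real extraction layout.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n_samples, n_features = values.shape
    assert n_features % n_bands == 0
    n_channels = n_features // n_bands
    if trial_of_sample is None:
        trial_of_sample = np.arange(n_samples)
    return FeatureTable(
        values=values,
        labels=labels,
        feature_channels=np.repeat(np.arange(n_channels), n_bands),
        feature_bands=np.tile(np.array(BAND_NAMES[:n_bands]), n_channels),
        trial_of_sample=np.asarray(trial_of_sample),
        channel_names=[f"CH{i:02d}" for i in range(n_channels)],
        normalized=normalized,
        band_names=BAND_NAMES[:n_bands],
    )


def gaussian_table(
    n_per_class: int,
    n_features: int,
    rng: np.random.Generator,
    class_shift: dict[int, float] | None = None,
    classes=("joy", "fear", "sadness", "relaxation"),
    n_bands: int = 4,
) -> FeatureTable:
    """Balanced Gaussian feature table; *class_shift* plants per-feature mean
    offsets proportional to the class index on the given feature columns."""
    n = n_per_class * len(classes)
    X = rng.standard_normal((n, n_features))
    y = np.repeat(np.array(classes), n_per_class)
    if class_shift:
        for feat, scale in class_shift.items():
            for ci in range(len(classes)):
                rows = slice(ci * n_per_class, (ci + 1) * n_per_class)
                X[rows, feat] += ci * scale
    return make_table(X, y, n_bands=n_bands)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_subject_tables():
    """Selection/validation halves of one DEAP-shaped subject (shortened
    trials) with two planted gamma channels; shared across tests."""
    from eegselect import simstudy

    spec = simstudy.deap_like_spec(
        2024, simstudy.PLANTED_EFFECTS, trial_duration=20.0
    )
    return simstudy.subject_selection_tables(spec, split_seed=77)
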