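"""Band-power feature extraction for trial-structured EEG.

Turns raw trials into the labeled feature table the selection stack operates on:

1. quadrant labeling of valence/arousal ratings (joy / fear / sadness / relaxation),
2. segmentation of each trial into fixed-length windows,
3. band-pass filtering into the four canonical bands (theta, alpha, beta, gamma)
   and FFT band power per segment, channel and band,
4. per-feature z-score normalization,
5. a stratified trial-level split into a channel-selection half and a
   performance-validation half.

Band power of a segment is ``(1/N) * sum_k |X(k)|^2`` over all N FFT bins of the
band-pass-filtered segment, N being the segment length (512 samples for 4 s at
128 Hz). The band filter is a zero-phase 4th-order Butterworth applied
forward-backward; no FFT taper is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import default_channel_names

LABELS: tuple[str, ...] = ("joy", "fear", "sadness", "relaxation")

#: canonical EEG bands (Hz); order fixes the feature layout (channel-major)
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


def default_band_definitions() -> list[BandDefinition]:
    return [BandDefinition(name, lo, hi) for name, lo, hi in DEFAULT_BANDS]


def label_trial(valence: float, arousal: float) -> str:
    """Quadrant label of one trial from its valence and arousal ratings.

    Ratings live on a 1-9 scale; the midpoint 5 belongs to the high side:
    joy (v>=5, a>=5), fear (v<5, a>=5), sadness (v<5, a<5), relaxation (v>=5, a<5).
    """
    if not (1.0 <= valence <= 9.0) or not (1.0 <= arousal <= 9.0):
        raise ValueError(f"ratings must lie in [1, 9]; got ({valence}, {arousal})")
    if valence >= 5.0:
        return "joy" if arousal >= 5.0 else "relaxation"
    return "fear" if arousal >= 5.0 else "sadness"


def label_trials(valence: np.ndarray, arousal: np.ndarray) -> np.ndarray:
    """Vectorized :func:`label_trial` over rating arrays."""
    return np.array([label_trial(v, a) for v, a in zip(valence, arousal)])


def segment_trials(
    signals: np.ndarray,
    sampling_rate: float,
    window: float = 4.0,
    overlap: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut trials × channels × time into fixed windows.

    Parameters
    ----------
    signals
        Array (n_trials, n_channels, n_samples).
    window
        Window length in seconds; ``window * sampling_rate`` must be integral.
    overlap
        Fractional overlap between consecutive windows (0 = non-overlapping,
        the default setting used throughout).

    Returns
    -------
    segments : (n_segments_total, n_channels, window_samples)
    trial_of_segment : (n_segments_total,) source trial index

    Segments are in temporal order within a trial; a trailing remainder shorter
    than one window is dropped.
    """
    signals = np.asarray(signals)
    if signals.ndim != 3:
        raise ValueError("signals must be (trials, channels, samples)")
    win = window * sampling_rate
    if abs(win - round(win)) > 1e-9:
        raise ValueError("window × sampling_rate must be an integer sample count")
    win = int(round(win))
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    n_trials, n_channels, n_samples = signals.shape
    if win > n_samples:
        raise ValueError("window longer than trial")
    step = max(1, int(round(win * (1.0 - overlap))))
    starts = range(0, n_samples - win + 1, step)
    segs, owner = [], []
    for t in range(n_trials):
        for s in starts:
            segs.append(signals[t, :, s : s + win])
            owner.append(t)
    return np.stack(segs), np.asarray(owner)


def _butter_bandpass(band: BandDefinition, sampling_rate: float, order: int = 4):
    nyq = sampling_rate / 2.0
    if not (0.0 < band.low < band.high < nyq):
        raise ValueError(f"band {band.name} ({band.low}-{band.high} Hz) outside (0, Nyquist={nyq})")
    return signal.butter(order, [band.low / nyq, band.high / nyq], btype="band")


def _zero_phase_filter(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward IIR filtering along the last axis.

    Standard zero-phase scheme: odd extension of 3×n_taps samples at both
    ends, steady-state initial conditions scaled to the first sample, one
    forward and one reverse pass, then the extension is trimmed.
    """
    x = np.asarray(x, dtype=float)
    ntaps = max(len(a), len(b))
    padlen = 3 * ntaps
    n = x.shape[-1]
    if n <= padlen:
        raise ValueError(f"signal length {n} must exceed pad length {padlen}")
    ext = np.empty(x.shape[:-1] + (n + 2 * padlen,))
    ext[..., padlen:-padlen] = x
    ext[..., :padlen] = 2.0 * x[..., :1] - x[..., padlen:0:-1]
    ext[..., -padlen:] = 2.0 * x[..., -1:] - x[..., -2 : -padlen - 2 : -1]
    zi = signal.lfilter_zi(b, a)
    zi_shape = (1,) * (ext.ndim - 1) + (len(zi),)
    zi = zi.reshape(zi_shape)
    y, _ = signal.lfilter(b, a, ext, axis=-1, zi=zi * ext[..., :1])
    y = y[..., ::-1]
    y, _ = signal.lfilter(b, a, y, axis=-1, zi=zi * np.ascontiguousarray(y[..., :1]))
    return y[..., ::-1][..., padlen:-padlen]


def bandpass(x: np.ndarray, band: BandDefinition, sampling_rate: float, axis: int = -1) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along *axis*."""
    b, a = _butter_bandpass(band, sampling_rate)
    x = np.asarray(x, dtype=float)
    moved = np.moveaxis(x, axis, -1)
    return np.moveaxis(_zero_phase_filter(b, a, moved), -1, axis)


def band_power(
    segment: np.ndarray,
    band: BandDefinition,
    sampling_rate: float,
    n_fft: int | None = None,
) -> float:
    """Band power of a single-channel segment.

    The segment is band-pass filtered, then power is taken as
    ``(1/N) * sum over all N FFT bins of |X(k)|^2`` with N the segment length.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    n = segment.shape[0]
    if n_fft is not None and n_fft != n:
        raise ValueError(f"configured FFT length {n_fft} does not match segment length {n}")
    filtered = bandpass(segment, band, sampling_rate)
    return float(_full_spectrum_power(filtered) / n)


def _full_spectrum_power(x: np.ndarray) -> np.ndarray:
    """Sum of |X(k)|² over all N FFT bins, computed from the real-input FFT.

    For real signals the spectrum is conjugate-symmetric, so the full-bin sum
    is |X_0|² + 2·Σ_mid |X_k|² (+ |X_{N/2}|² when N is even).
    """
    n = x.shape[-1]
    spectrum = np.abs(np.fft.rfft(x, n=n, axis=-1)) ** 2
    total = 2.0 * spectrum.sum(axis=-1) - spectrum[..., 0]
    if n % 2 == 0:
        total -= spectrum[..., -1]
    return total


def band_power_matrix(
    segments: np.ndarray,
    bands: list[BandDefinition],
    sampling_rate: float,
) -> np.ndarray:
    """Vectorized band power: (n_segments, n_channels, n_bands)."""
    segments = np.asarray(segments, dtype=float)
    n = segments.shape[-1]
    out = np.empty(segments.shape[:-1] + (len(bands),))
    # chunk the segment axis so intermediates stay cache-friendly
    chunk = max(1, int(2e6 // max(1, np.prod(segments.shape[1:]))))
    for start in range(0, segments.shape[0], chunk):
        block = segments[start : start + chunk]
        for j, band in enumerate(bands):
            filtered = bandpass(block, band, sampling_rate, axis=-1)
            out[start : start + chunk, ..., j] = _full_spectrum_power(filtered) / n
    return out


@dataclass
class FeatureTable:
    """Samples × features band-power table with labels and feature provenance.

    Features are channel-major: feature ``c * n_bands + b`` is band ``b`` of
    channel ``c``, named ``<channel>_<band>`` (e.g. ``Fp1_gamma``).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_channels: np.ndarray
    feature_bands: np.ndarray  # band names, parallel to feature_channels
    trial_of_sample: np.ndarray
    channel_names: list[str]
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    normalized: bool = False
    band_names: tuple[str, ...] = BAND_NAMES

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def feature_names(self) -> list[str]:
        return [
            f"{self.channel_names[c]}_{b}"
            for c, b in zip(self.feature_channels, self.feature_bands)
        ]

    def features_of_channels(self, channels) -> np.ndarray:
        """Column indices of all features owned by the given channels, in order."""
        channels = list(channels)
        cols = [
            i
            for ch in channels
            for i in np.flatnonzero(self.feature_channels == ch)
        ]
        return np.asarray(cols, dtype=int)

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        return replace(
            self,
            values=self.values[mask],
            labels=self.labels[mask],
            trial_of_sample=self.trial_of_sample[mask],
        )


def extract_features(
    trials,
    bands: list[BandDefinition] | None = None,
    window: float = 4.0,
    overlap: float = 0.0,
) -> FeatureTable:
    """Full raw-signal → unnormalized band-power table pipeline for one subject."""
    bands = bands if bands is not None else default_band_definitions()
    segments, owner = segment_trials(trials.signals, trials.sampling_rate, window, overlap)
    powers = band_power_matrix(segments, bands, trials.sampling_rate)  # (S, C, B)
    n_seg, n_ch, n_bands = powers.shape
    values = powers.reshape(n_seg, n_ch * n_bands)  # channel-major
    trial_labels = label_trials(trials.valence, trials.arousal)
    names = list(getattr(trials, "channel_names", None) or default_channel_names(n_ch))
    return FeatureTable(
        values=values,
        labels=trial_labels[owner],
        feature_channels=np.repeat(np.arange(n_ch), n_bands),
        feature_bands=np.tile(np.array([b.name for b in bands]), n_ch),
        trial_of_sample=owner,
        channel_names=names,
        band_names=tuple(b.name for b in bands),
    )


def zscore(
    table: FeatureTable,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureTable:
    """Z-score each feature column: (x - mean) / sd.

    The sd uses the population (divide-by-n) convention. When *stats* is given,
    those (mean, sd) are applied instead of refitting — use this to transform a
    held-out set with statistics fitted elsewhere. Constant columns (sd = 0)
    are set to zero with a warning.
    """
    if table.n_samples < 2 and stats is None:
        raise ValueError("need at least 2 samples to fit normalization statistics")
    if stats is None:
        mu = table.values.mean(axis=0)
        sd = table.values.std(axis=0)  # ddof=0
    else:
        mu, sd = (np.asarray(s, dtype=float) for s in stats)
    constant = sd == 0.0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) set to zero during z-scoring",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    values = (table.values - mu) / safe_sd
    values[:, constant] = 0.0
    return replace(table, values=values, mean=mu, std=sd, normalized=True)


def split_dataset(
    table: FeatureTable, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified ≈50/50 trial-level split into (channel-selection, validation).

    All segments of a trial land on the same side — the leakage guard the whole
    selection-then-validation protocol rests on. Within each class, trials are
    shuffled with *seed* and the first half goes to the selection side.
    """
    rng = np.random.default_rng(seed)
    trial_ids = np.unique(table.trial_of_sample)
    trial_label = {
        t: table.labels[table.trial_of_sample == t][0] for t in trial_ids
    }
    sel_trials: list[int] = []
    for cls in sorted(set(trial_label.values())):
        cls_trials = np.array([t for t in trial_ids if trial_label[t] == cls])
        if len(cls_trials) < 2:
            raise ValueError(
                f"category {cls!r} has {len(cls_trials)} trial(s); need at least 2 to split"
            )
        perm = rng.permutation(len(cls_trials))
        n_sel = len(cls_trials) // 2
        sel_trials.extend(cls_trials[perm[:n_sel]])
    sel_mask = np.isin(table.trial_of_sample, sel_trials)
    return table.subset_samples(sel_mask), table.subset_samples(~sel_mask)


def class_trial_counts(table: FeatureTable) -> dict[str, int]:
    """Trials per class, used by the minimum-trials subject filter."""
    trial_ids = np.unique(table.trial_of_sample)
    counts: dict[str, int] = {}
    for t in trial_ids:
        cls = str(table.labels[table.trial_of_sample == t][0])
        counts[cls] = counts.get(cls, 0) + 1
    return counts


def subject_passes_filter(table: FeatureTable, min_trials: int = 5) -> bool:
    """True when every class has at least *min_trials* trials (subject filter)."""
    counts = class_trial_counts(table)
    return all(counts.get(cls, 0) >= min_trials for cls in LABELS)
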