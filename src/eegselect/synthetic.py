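"""Synthetic trial-structured EEG with planted class-dependent band-power effects.

Emulates the layout of a preprocessed DEAP-style recording — 32 channels at
128 Hz, 40 one-minute trials per subject, each rated 1-9 for valence and
arousal — so the whole selection stack can be exercised without the gated
dataset. Trials are split evenly over the four quadrant classes (joy, fear,
sadness, relaxation) and ratings are drawn uniformly inside the quadrant the
class implies.

Signals are broadband Gaussian noise plus, for every ``(class, channel, band)``
entry of the effect map, a band-limited Gaussian-noise component (filtered
white noise, so spectra resemble EEG rather than pure tones) added to the
trials of that class. The component's standard deviation is
``multiplier × noise_sd × sqrt(bandwidth / nyquist)`` — i.e. *multiplier*
times the background amplitude in that band — so a multiplier ``m``
multiplies that band's expected power by ``1 + m²`` for the effect class.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import DEFAULT_BANDS, LABELS, BandDefinition, bandpass
from .montage import default_channel_names

_BAND_EDGES = {name: (lo, hi) for name, lo, hi in DEFAULT_BANDS}

#: effect map key: (class label, channel index, band name) → amplitude multiplier
EffectMap = dict[tuple[str, int, str], float]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic subject.

    ``effect_map`` maps ``(class, channel, band)`` to an amplitude multiplier
    ≥ 0 for the narrowband component planted in that class's trials.
    """

    n_channels: int = 32
    sampling_rate: float = 128.0
    trial_duration: float = 60.0
    n_trials: int = 40
    effect_map: EffectMap = field(default_factory=dict)
    noise_sd: float = 1.0
    pink_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % len(LABELS) != 0:
            raise ValueError(
                f"n_trials={self.n_trials} must divide evenly over the {len(LABELS)} classes"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for (cls, ch, band), mult in self.effect_map.items():
            if cls not in LABELS:
                raise ValueError(f"unknown class {cls!r} in effect_map")
            if not 0 <= ch < self.n_channels:
                raise ValueError(
                    f"effect_map references channel {ch}, outside 0..{self.n_channels - 1}"
                )
            if band not in _BAND_EDGES:
                raise ValueError(f"unknown band {band!r} in effect_map")
            if not np.isfinite(mult) or mult < 0:
                raise ValueError("amplitude multipliers must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        n = self.sampling_rate * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration × sampling_rate must be integral")
        return int(round(n))

    @property
    def informative_channels(self) -> set[int]:
        return {ch for (_, ch, _) in self.effect_map}


@dataclass
class TrialSet:
    """One subject's trial-structured signals plus ratings and metadata."""

    signals: np.ndarray  # (n_trials, n_channels, n_samples)
    valence: np.ndarray
    arousal: np.ndarray
    sampling_rate: float
    channel_names: list[str]

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


_QUADRANTS = {
    # class → ((valence low, high), (arousal low, high)); midpoint 5 is on the high side
    "joy": ((5.0, 9.0), (5.0, 9.0)),
    "fear": ((1.0, 5.0), (5.0, 9.0)),
    "sadness": ((1.0, 5.0), (1.0, 5.0)),
    "relaxation": ((5.0, 9.0), (1.0, 5.0)),
}


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise along the last axis, scaled to sd."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(freqs)
    scale[freqs > 0] = 1.0 / np.sqrt(freqs[freqs > 0])
    out = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    out *= sd / out.std()
    return out


def generate_subject(spec: GeneratorSpec) -> TrialSet:
    """Generate one synthetic subject per *spec*; bit-exact given its seed."""
    rng = np.random.default_rng(spec.seed)
    n_per_class = spec.n_trials // len(LABELS)
    trial_classes = np.repeat(np.array(LABELS), n_per_class)

    n_samples = spec.n_samples
    shape = (spec.n_trials, spec.n_channels, n_samples)
    if spec.pink_background:
        signals = _pink_noise(rng, shape, spec.noise_sd)
    else:
        signals = rng.normal(0.0, spec.noise_sd, size=shape)

    nyquist = spec.sampling_rate / 2.0
    # fixed iteration order so the rng stream is reproducible
    for (cls, ch, band_name), mult in sorted(spec.effect_map.items()):
        if mult == 0.0:
            continue
        lo, hi = _BAND_EDGES[band_name]
        band = BandDefinition(band_name, lo, hi)
        rows = np.flatnonzero(trial_classes == cls)
        raw = rng.standard_normal((len(rows), n_samples))
        narrow = bandpass(raw, band, spec.sampling_rate, axis=-1)
        narrow /= narrow.std(axis=-1, keepdims=True)
        target_sd = mult * spec.noise_sd * np.sqrt((hi - lo) / nyquist)
        signals[rows, ch, :] += target_sd * narrow

    valence = np.empty(spec.n_trials)
    arousal = np.empty(spec.n_trials)
    for i, cls in enumerate(trial_classes):
        (vlo, vhi), (alo, ahi) = _QUADRANTS[cls]
        valence[i] = rng.uniform(vlo, vhi)
        arousal[i] = rng.uniform(alo, ahi)

    return TrialSet(
        signals=signals,
        valence=valence,
        arousal=arousal,
        sampling_rate=spec.sampling_rate,
        channel_names=default_channel_names(spec.n_channels),
    )


#: container format version written by save_trialset
FORMAT_VERSION = 1


def save_trialset(path, trials: TrialSet) -> None:
    """Write one subject to an .npz container (versioned)."""
    np.savez(
        path,
        format_version=FORMAT_VERSION,
        signals=trials.signals,
        valence=trials.valence,
        arousal=trials.arousal,
        sampling_rate=trials.sampling_rate,
        channel_names=np.array(trials.channel_names),
    )


def load_deap_style(path, n_eeg_channels: int = 32, baseline_seconds: float = 3.0,
                    sampling_rate: float = 128.0) -> TrialSet:
    """Optional reader for preprocessed-DEAP-style MATLAB files.

    Expects a .mat file with ``data`` shaped (trials, channels, samples) —
    e.g. 40 × 40 × 8064 at 128 Hz — and ``labels`` shaped (trials, ≥2) whose
    first two columns are valence and arousal ratings. Only the first
    *n_eeg_channels* channels are kept (the rest are peripheral signals) and
    the *baseline_seconds* pre-trial baseline is trimmed so trials are
    exactly 60 s. Not exercised by the synthetic pipeline; provided for
    working with real recordings of that layout.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    data = np.asarray(mat["data"], dtype=float)
    ratings = np.asarray(mat["labels"], dtype=float)
    skip = int(round(baseline_seconds * sampling_rate))
    return TrialSet(
        signals=data[:, :n_eeg_channels, skip:],
        valence=ratings[:, 0],
        arousal=ratings[:, 1],
        sampling_rate=sampling_rate,
        channel_names=default_channel_names(n_eeg_channels),
    )


def load_trialset(path) -> TrialSet:
    """Read a subject container written by :func:`save_trialset`."""
    with np.load(path, allow_pickle=False) as data:
        version = int(data["format_version"]) if "format_version" in data else None
        if version is not None and version > FORMAT_VERSION:
            raise ValueError(f"container format version {version} is newer than supported")
        return TrialSet(
            signals=np.asarray(data["signals"], dtype=float),
            valence=np.asarray(data["valence"], dtype=float),
            arousal=np.asarray(data["arousal"], dtype=float),
            sampling_rate=float(data["sampling_rate"]),
            channel_names=[str(c) for c in data["channel_names"]],
        )
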