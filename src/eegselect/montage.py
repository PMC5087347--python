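"""32-channel 10-20 montage used by the synthetic generator and artifact writers.

The channel order is the Geneva ordering of the 32 EEG electrodes found in the
preprocessed DEAP arrays, so feature names line up with that layout.
"""

from __future__ import annotations

DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: lobe annotation, following the usual coarse grouping of 10-20 labels
_LOBE_PREFIXES = (
    ("Fp", "Frontal"),
    ("AF", "Frontal"),
    ("FC", "Frontal"),
    ("F", "Frontal"),
    ("CP", "Central"),
    ("C", "Central"),
    ("T", "Temporal"),
    ("PO", "Parietal"),
    ("P", "Parietal"),
    ("O", "Occipital"),
)


def lobe_of(channel: str) -> str:
    """Coarse brain-lobe annotation for a 10-20 electrode label."""
    for prefix, lobe in _LOBE_PREFIXES:
        if channel.startswith(prefix):
            return lobe
    return "Unknown"


def default_channel_names(n_channels: int) -> list[str]:
    """Electrode labels for *n_channels*: the 32-channel montage, or generic CHxx."""
    if n_channels == len(DEAP_CHANNELS):
        return list(DEAP_CHANNELS)
    return [f"CH{i:02d}" for i in range(n_channels)]
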