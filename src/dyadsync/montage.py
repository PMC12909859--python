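"""The 12-channel analysis montage shared by both members of a dyad.

Cross-brain synchrony is computed on a fixed subset of the 10-20 system:
mid-frontal (F3, F4), frontal (F7, F8), central (C3, C4), temporal (T7, T8),
parietal (P3, P4) and occipital-temporal (P7, P8) electrodes, in a fixed
canonical order so that channel-pair matrices are comparable across dyads.
"""

from __future__ import annotations

#: Canonical order of the analysis channels (anterior to posterior).
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "F7", "F8", "C3", "C4", "T7", "T8", "P3", "P4", "P7", "P8",
)

#: Immediate spatial neighbours within the analysis montage, used for
#: neighbour-mean interpolation of bad channels.  Symmetric by construction.
NEIGHBORS: dict[str, tuple[str, ...]] = {
    "F7": ("F3", "T7"),
    "F3": ("F7", "F4", "C3"),
    "F4": ("F3", "F8", "C4"),
    "F8": ("F4", "T8"),
    "T7": ("F7", "C3", "P7"),
    "C3": ("F3", "T7", "P3"),
    "C4": ("F4", "T8", "P4"),
    "T8": ("F8", "C4", "P8"),
    "P7": ("T7", "P3"),
    "P3": ("C3", "P7", "P4"),
    "P4": ("C4", "P3", "P8"),
    "P8": ("T8", "P4"),
}


def canonical_index(labels: list[str] | tuple[str, ...]) -> list[int]:
    """Indices that reorder `labels` into the canonical analysis order.

    Raises ``ValueError`` listing any analysis channel missing from `labels`.
    """
    missing = [ch for ch in ANALYSIS_CHANNELS if ch not in labels]
    if missing:
        raise ValueError(
            f"analysis channels missing from recording: {', '.join(missing)}"
        )
    return [list(labels).index(ch) for ch in ANALYSIS_CHANNELS]
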