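"""In-memory containers for time-locked dual recordings and hyper-epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class Annotation:
    """One condition block: onset and duration in seconds, condition label."""

    onset: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(
                f"annotation {self.label!r}: duration must be > 0, "
                f"got {self.duration}"
            )


@dataclass
class DyadRecording:
    """Synchronized mother + infant multichannel EEG.

    Both members are recorded time-locked on interconnected amplifiers, so
    they share the sampling rate, the sample count and the channel montage.
    Signals are channel x sample arrays in microvolts.
    """

    mother: np.ndarray
    infant: np.ndarray
    srate: float
    channel_labels: tuple[str, ...]
    annotations: list[Annotation] = field(default_factory=list)
    dyad_id: str = "dyad-000"
    infant_age_months: float = float("nan")
    infant_sex: str = "F"

    def __post_init__(self) -> None:
        self.mother = np.asarray(self.mother, dtype=float)
        self.infant = np.asarray(self.infant, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.mother.ndim != 2 or self.infant.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.mother.shape != self.infant.shape:
            raise ValueError(
                "time-locking broken: mother and infant sample counts differ "
                f"({self.mother.shape} vs {self.infant.shape})"
            )
        if self.mother.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.mother.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        dur = self.n_samples / self.srate
        prev_end = -np.inf
        for ann in sorted(self.annotations, key=lambda a: a.onset):
            if ann.onset < prev_end - 1e-9:
                raise ValueError("annotation intervals overlap")
            if ann.onset + ann.duration > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} extends past the recording "
                    f"({ann.onset + ann.duration:.3f} s > {dur:.3f} s)"
                )
            prev_end = ann.onset + ann.duration

    @property
    def n_channels(self) -> int:
        return self.mother.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mother.shape[1]

    def copy_with(self, **kw) -> "DyadRecording":
        return replace(self, **kw)


@dataclass
class HyperEpoch:
    """One time-locked 2-s segment pair with its bookkeeping."""

    mother: np.ndarray  # channels x samples
    infant: np.ndarray
    condition: str
    epoch_index: int    # index within its condition block
    start_s: float      # seconds from block onset, half-open [start, start+L)
    block_offset: int = 0   # sample offset of the epoch within its block


@dataclass
class HyperEpochSet:
    """Time-locked mother/infant segment pairs cut from condition blocks.

    ``n_samples`` is the number of time samples per epoch — the N over which
    the per-epoch wPLI numerator and denominator sums run.
    """

    epochs: list[HyperEpoch]
    srate: float
    channel_labels: tuple[str, ...]
    n_samples: int
    overlap: float
    dyad_id: str = "dyad-000"
    infant_age_months: float = float("nan")
    infant_sex: str = "F"
    #: optional continuous per-condition block signals (mother, infant);
    #: when present, band-limited phases are computed on the whole block and
    #: sliced, avoiding narrow-band filter transients on short epochs
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        for ep in self.epochs:
            if ep.mother.shape != ep.infant.shape:
                raise ValueError("epoch members differ in shape")
            if ep.mother.shape[1] != self.n_samples:
                raise ValueError("epoch sample count inconsistent with set")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for ep in self.epochs:
            if ep.condition not in seen:
                seen.append(ep.condition)
        return seen

    def subset(self, condition: str) -> "HyperEpochSet":
        eps = [ep for ep in self.epochs if ep.condition == condition]
        return replace(self, epochs=eps)

    def manifest(self) -> pd.DataFrame:
        """Epoch bookkeeping table (one row per epoch)."""
        return pd.DataFrame(
            {
                "dyad": self.dyad_id,
                "condition": [ep.condition for ep in self.epochs],
                "epoch_index": [ep.epoch_index for ep in self.epochs],
                "start_s": [ep.start_s for ep in self.epochs],
            }
        )
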