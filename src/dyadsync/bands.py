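"""Developmental frequency bands of interest."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz.

    The analysis targets infant developmental bands: theta spans 3-5 Hz and
    alpha 6-9 Hz (infant alpha sits lower than the adult 8-12 Hz band).
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    def validate_for(self, srate: float) -> None:
        if self.high >= srate / 2:
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) exceeds the "
                f"Nyquist frequency at {srate} Hz"
            )


THETA = BandSpec("theta", 3.0, 5.0)
ALPHA = BandSpec("alpha", 6.0, 9.0)
DEFAULT_BANDS: tuple[BandSpec, ...] = (THETA, ALPHA)
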