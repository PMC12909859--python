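"""Synthetic dyad generator with known ground-truth cross-brain coupling.

The raw dual-EEG behind the study design this package implements is not
shareable, so every stage of the pipeline is exercised on simulated dyads
whose coupling structure is known by construction.  Each member's EEG is
independent 1/f background noise; within each condition block a shared
narrow-band oscillator is mixed into designated channels of both members at
strength kappa with a constant cross-brain phase offset delta.  Because the
offset is away from 0 (mod pi), the injected coupling produces a nonzero
imaginary cross-phasor component, which is exactly what the weighted Phase
Lag Index detects; zero-lag (volume-conduction-like) coupling would be
invisible to it by design.

The still-face effect is built in: coupling strength drops by a fixed amount
during the still-face phases, so condition contrasts downstream are
recoverable against the generator's ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .bands import BandSpec, DEFAULT_BANDS
from .montage import ANALYSIS_CHANNELS
from .recording import Annotation, DyadRecording

#: Condition labels of the smartphone-adapted Still-Face Paradigm, in order:
#: free play, still-face, free play, still-face, reunion -- 2 min each.
SFP_CONDITIONS: tuple[str, ...] = ("FP1", "SF1", "FP2", "SF2", "RU")
SFP_BLOCK_S: float = 120.0

#: Reduction of coupling strength during the still-face phases (both bands).
STILL_FACE_KAPPA_DROP: float = 0.15


def default_kappa() -> dict[tuple[str, str], float]:
    """Default (condition, band) -> coupling strength map.

    Baselines are calibrated so that the simulated global wPLI magnitudes
    land where infant hyperscanning studies report them (theta ~0.41, alpha
    ~0.36 at 2-s epochs); the still-face phases drop kappa by 0.15.
    """
    base = {"theta": 0.30, "alpha": 0.30}
    kap: dict[tuple[str, str], float] = {}
    for cond in SFP_CONDITIONS:
        for band, b in base.items():
            drop = STILL_FACE_KAPPA_DROP if cond.startswith("SF") else 0.0
            kap[(cond, band)] = max(0.0, b - drop)
    return kap


@dataclass
class SynthConfig:
    """Parameters of the simulated cohort.

    Defaults mirror the study conditions: 33 dyads, 512 Hz, 12 channels per
    person, five 120-s condition blocks.  ``kappa`` maps (condition label,
    band name) to coupling strength in [0, 1]; ``lag_phase`` is the constant
    cross-brain phase offset delta in radians and must stay away from
    0 (mod pi) whenever coupling is present, because zero-lag coupling is
    invisible to wPLI.  ``kappa_sd`` adds a per-dyad, per-band baseline
    offset (constant across conditions) emulating between-dyad heterogeneity
    in synchrony; ``lag_drift`` (rad/sqrt(s)) lets delta wander as a Brownian
    path, emulating nonstationary lead/lag relations.
    """

    n_dyads: int = 33
    srate: float = 512.0
    channels: tuple[str, ...] = ANALYSIS_CHANNELS
    schedule: tuple[tuple[str, float], ...] = tuple(
        (c, SFP_BLOCK_S) for c in SFP_CONDITIONS
    )
    kappa: dict[tuple[str, str], float] = field(default_factory=default_kappa)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    lag_phase: float = math.pi / 4
    lag_drift: float = 0.0
    lag_wobble_amp: float = 0.0   # rad; slow bounded wander of the offset
    lag_wobble_hz: float = 0.7
    coupling_gain: float = 1.5
    coupled_channels: dict[str, tuple[str, ...]] | None = None
    noise_exponent: float = 1.0
    amp_mother_uv: float = 8.0
    amp_infant_uv: float = 15.0
    artifact_rate: float = 2.0       # bursts per minute, infant channels
    artifact_amp_uv: float = 400.0
    artifact_duration_s: float = 0.5
    kappa_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        known = {c for c, _ in self.schedule} | set(SFP_CONDITIONS)
        for (cond, band), k in self.kappa.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa[{cond},{band}]={k} outside [0, 1]")
            if cond not in known:
                raise ValueError(
                    f"kappa map refers to unknown condition label {cond!r}"
                )
            if band not in {b.name for b in self.bands}:
                raise ValueError(f"kappa map refers to unknown band {band!r}")
        for cond, dur in self.schedule:
            if dur <= 0:
                raise ValueError(
                    f"schedule block {cond!r} has non-positive duration {dur}"
                )
        if any(k > 0 for k in self.kappa.values()):
            if abs(math.sin(self.lag_phase)) < 1e-9:
                raise ValueError(
                    "lag_phase is 0 (mod pi): zero-lag coupling is invisible "
                    "to wPLI, choose a nonzero-lag offset"
                )

    def band_channels(self, band: str) -> tuple[str, ...]:
        if self.coupled_channels is None:
            return self.channels
        return self.coupled_channels.get(band, ())


@dataclass
class GroundTruth:
    """Injected coupling per (dyad, condition, band, channel pair).

    ``table`` is a long DataFrame with columns dyad, condition, band,
    mother_channel, infant_channel, kappa -- the same index structure as the
    pipeline's synchrony table, so recovery experiments can join on it.
    """

    table: pd.DataFrame

    def kappa_matrix(self, condition: str, band: str,
                     labels: tuple[str, ...]) -> np.ndarray:
        sub = self.table[(self.table.condition == condition)
                         & (self.table.band == band)]
        lut = {(r.mother_channel, r.infant_channel): r.kappa
               for r in sub.itertuples()}
        n = len(labels)
        out = np.zeros((n, n))
        for i, m in enumerate(labels):
            for j, c in enumerate(labels):
                out[i, j] = lut.get((m, c), 0.0)
        return out


def make_condition_schedule(config: SynthConfig) -> list[Annotation]:
    """Contiguous condition annotations from the configured schedule."""
    anns: list[Annotation] = []
    onset = 0.0
    for label, dur in config.schedule:
        anns.append(Annotation(onset=onset, duration=dur, label=label))
        onset += dur
    return anns


def pink_noise(n_channels: int, n_samples: int, srate: float,
               rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent background noise, unit variance per channel."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((n_channels, freqs.size))
                  + 1j * rng.standard_normal((n_channels, freqs.size)))
    x = np.fft.irfft(spec, n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def inband_fraction(band: BandSpec, srate: float, n_samples: int,
                    exponent: float) -> float:
    """RMS fraction of the generated 1/f noise that falls inside `band`.

    Computed from the generator's own discrete spectrum so the oscillator
    can be scaled relative to the in-band background level.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    power = np.zeros_like(freqs)
    power[1:] = freqs[1:] ** (-exponent)
    sel = (freqs >= band.low) & (freqs <= band.high)
    return float(np.sqrt(power[sel].sum() / power.sum()))


def narrowband_oscillator(n_samples: int, srate: float, band: BandSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """Complex analytic narrow-band Gaussian oscillator, unit-RMS real part."""
    b, a = butter(4, [band.low / (srate / 2), band.high / (srate / 2)],
                  btype="band")
    x = filtfilt(b, a, rng.standard_normal(n_samples))
    z = hilbert(x)
    return z / np.real(z).std()


def _artifact_burst(n: int, srate: float, rng: np.random.Generator) -> np.ndarray:
    """High-amplitude low-frequency burst (unit peak), Hann-windowed."""
    t = np.arange(n) / srate
    f = rng.uniform(1.0, 3.0)
    w = np.hanning(n)
    return w * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def generate_dyad(config: SynthConfig, dyad_index: int
                  ) -> tuple[DyadRecording, GroundTruth]:
    """Simulate one dyad.  Deterministic given (config.seed, dyad_index)."""
    rng = np.random.default_rng(config.seed + dyad_index)
    anns = make_condition_schedule(config)
    srate = config.srate
    n_total = int(round(sum(d for _, d in config.schedule) * srate))
    n_ch = len(config.channels)

    mother = config.amp_mother_uv * pink_noise(
        n_ch, n_total, srate, rng, config.noise_exponent)
    infant = config.amp_infant_uv * pink_noise(
        n_ch, n_total, srate, rng, config.noise_exponent)

    # per-dyad baseline kappa offset, constant across conditions
    band_offsets = {b.name: rng.normal(0.0, config.kappa_sd)
                    for b in config.bands}

    gt_rows: list[dict] = []
    dyad_id = f"dyad-{dyad_index:03d}"
    for ann in anns:
        i0 = int(round(ann.onset * srate))
        i1 = int(round((ann.onset + ann.duration) * srate))
        nblk = i1 - i0
        # accumulate oscillator terms per channel; the background noise is
        # shrunk once by sqrt(1 - sum kappa^2) so that kappa = 1 in a band
        # leaves a pure oscillator there
        add_m = np.zeros((n_ch, nblk))
        add_i = np.zeros((n_ch, nblk))
        ksq = np.zeros(n_ch)
        for band in config.bands:
            k_nom = config.kappa.get((ann.label, band.name), 0.0)
            k = float(np.clip(k_nom + band_offsets[band.name], 0.0, 1.0)) \
                if k_nom > 0 else 0.0
            coupled = config.band_channels(band.name)
            idx = [i for i, ch in enumerate(config.channels) if ch in coupled]
            if k > 0 and idx:
                z = narrowband_oscillator(nblk, srate, band, rng)
                frac = inband_fraction(band, srate, nblk,
                                       config.noise_exponent)
                delta = config.lag_phase
                if config.lag_drift > 0:
                    walk = np.cumsum(rng.standard_normal(nblk)) / math.sqrt(srate)
                    delta = delta + config.lag_drift * walk
                if config.lag_wobble_amp > 0:
                    t = np.arange(nblk) / srate
                    delta = delta + config.lag_wobble_amp * np.sin(
                        2 * math.pi * config.lag_wobble_hz * t
                        + rng.uniform(0, 2 * math.pi))
                osc_i = np.real(z)
                osc_m = np.real(z * np.exp(1j * delta))
                g = k * config.coupling_gain * frac
                add_i[idx] += g * config.amp_infant_uv * osc_i
                add_m[idx] += g * config.amp_mother_uv * osc_m
                ksq[idx] += k ** 2
            for mch in config.channels:
                for ich in config.channels:
                    gt_rows.append({
                        "dyad": dyad_id, "condition": ann.label,
                        "band": band.name, "mother_channel": mch,
                        "infant_channel": ich,
                        "kappa": k if (mch in coupled and ich in coupled)
                        else 0.0,
                    })
        shrink = np.sqrt(np.clip(1.0 - ksq, 0.0, None))[:, None]
        infant[:, i0:i1] = shrink * infant[:, i0:i1] + add_i
        mother[:, i0:i1] = shrink * mother[:, i0:i1] + add_m

    # movement-artifact bursts on the infant's channels
    minutes = n_total / srate / 60.0
    n_bursts = rng.poisson(config.artifact_rate * minutes)
    blen = int(round(config.artifact_duration_s * srate))
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n_total - blen))
        burst = config.artifact_amp_uv * _artifact_burst(blen, srate, rng)
        infant[:, start:start + blen] += burst

    age = float(np.clip(rng.normal(9.29, 1.38), 5.7, 12.2))
    sex = "F" if rng.random() < 18 / 33 else "M"
    rec = DyadRecording(
        mother=mother, infant=infant, srate=srate,
        channel_labels=config.channels, annotations=anns,
        dyad_id=dyad_id, infant_age_months=age, infant_sex=sex,
    )
    return rec, GroundTruth(pd.DataFrame(gt_rows))


def generate_cohort(config: SynthConfig):
    """Yield (DyadRecording, GroundTruth) for each dyad in the cohort."""
    for d in range(config.n_dyads):
        yield generate_dyad(config, d)
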