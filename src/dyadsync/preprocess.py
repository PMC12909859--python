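"""Filtering, channel repair, epoching and artifact screening.

All filters are zero-phase (forward-backward application), which matters
here more than in single-brain work: any group delay applied unevenly would
shift one member's phases against the other's and corrupt the cross-brain
phase differences that the synchrony measures are built on.  Both members
are always processed identically.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, iirnotch

from .io import read_recording  # noqa: F401  (re-exported surface)
from .montage import NEIGHBORS, canonical_index
from .recording import DyadRecording, HyperEpoch, HyperEpochSet


def filter_raw(rec: DyadRecording, l_freq: float = 1.0, h_freq: float = 30.0,
               notch_hz: float | None = 50.0, order: int = 4,
               notch_q: float = 30.0) -> DyadRecording:
    """Band-pass 1-30 Hz and notch out 50 Hz line noise, zero-phase.

    Butterworth of the given order applied forward-backward (so the
    effective attenuation is the squared magnitude response and the net
    phase response is zero), followed by a narrow zero-phase notch.
    """
    nyq = rec.srate / 2.0
    if notch_hz is not None and rec.srate <= 60.0:
        raise ValueError(
            f"srate {rec.srate} Hz too low for a {notch_hz} Hz notch"
        )
    if h_freq >= nyq:
        raise ValueError(f"low-pass edge {h_freq} Hz at/above Nyquist {nyq}")
    b, a = butter(order, [l_freq / nyq, h_freq / nyq], btype="band")
    out = []
    for sig in (rec.mother, rec.infant):
        y = filtfilt(b, a, sig, axis=-1)
        if notch_hz is not None:
            bn, an = iirnotch(notch_hz, notch_q, fs=rec.srate)
            y = filtfilt(bn, an, y, axis=-1)
        out.append(y)
    return rec.copy_with(mother=out[0], infant=out[1])


def interpolate_bad_channels(rec: DyadRecording,
                             bad_mother: list[str] | None = None,
                             bad_infant: list[str] | None = None,
                             neighbors: dict[str, tuple[str, ...]] | None = None,
                             max_fraction: float = 0.10) -> DyadRecording:
    """Replace bad channels by the mean of their montage neighbours.

    At most ``max_fraction`` (10%) of a member's channels may be repaired;
    beyond that the dyad should be excluded rather than patched, and a
    ``ValueError`` says so.  All other channels are left untouched.
    """
    neighbors = NEIGHBORS if neighbors is None else neighbors
    bad_mother = list(bad_mother or [])
    bad_infant = list(bad_infant or [])
    cap = math.floor(max_fraction * rec.n_channels)
    for who, bads in (("mother", bad_mother), ("infant", bad_infant)):
        if len(bads) > cap:
            raise ValueError(
                f"{len(bads)} bad {who} channels exceeds the repair cap of "
                f"{cap} (10% of {rec.n_channels}); exclude this dyad instead"
            )
        unknown = [ch for ch in bads if ch not in rec.channel_labels]
        if unknown:
            raise ValueError(f"unknown {who} channels: {unknown}")

    labels = list(rec.channel_labels)

    def _repair(sig: np.ndarray, bads: list[str]) -> np.ndarray:
        if not bads:
            return sig
        out = sig.copy()
        for ch in bads:
            nbrs = [n for n in neighbors.get(ch, ()) if n in labels
                    and n not in bads]
            if not nbrs:
                raise ValueError(
                    f"channel {ch} has no good neighbours to interpolate from"
                )
            out[labels.index(ch)] = sig[[labels.index(n) for n in nbrs]].mean(axis=0)
        return out

    return rec.copy_with(mother=_repair(rec.mother, bad_mother),
                         infant=_repair(rec.infant, bad_infant))


def select_channels(rec: DyadRecording) -> DyadRecording:
    """Restrict both members to the 12 analysis channels, canonical order."""
    idx = canonical_index(list(rec.channel_labels))
    return rec.copy_with(
        mother=rec.mother[idx], infant=rec.infant[idx],
        channel_labels=tuple(rec.channel_labels[i] for i in idx),
    )


def n_epochs_in_block(duration_s: float, epoch_s: float,
                      overlap: float) -> int:
    """Closed form for the number of epochs fitting in one block.

    Epochs of length ``epoch_s`` start every ``epoch_s * (1 - overlap)``
    seconds; a partial trailing epoch is discarded.  A 120-s block at 2 s /
    50% overlap yields 119 epochs.
    """
    step = epoch_s * (1.0 - overlap)
    if duration_s < epoch_s:
        return 0
    return int(math.floor((duration_s - epoch_s) / step + 1e-9)) + 1


def make_hyper_epochs(rec: DyadRecording, epoch_s: float = 2.0,
                      overlap: float = 0.5) -> HyperEpochSet:
    """Cut each condition block into time-locked 2-s hyper-epochs.

    Epoch start times are half-open [start, start + epoch_s) in seconds from
    block onset.  At 50% overlap consecutive epochs within a block start
    exactly half an epoch apart.  The 2-s default keeps at least three
    cycles of the lowest analysis frequency (3 Hz) in every epoch.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n_samp = int(round(epoch_s * rec.srate))
    step = int(round(epoch_s * (1.0 - overlap) * rec.srate))
    epochs: list[HyperEpoch] = []
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ann in rec.annotations:
        if ann.duration + 1e-9 < epoch_s:
            raise ValueError(
                f"block {ann.label!r} ({ann.duration} s) shorter than the "
                f"epoch length {epoch_s} s"
            )
        blk0 = int(round(ann.onset * rec.srate))
        blk1 = int(round((ann.onset + ann.duration) * rec.srate))
        blocks[ann.label] = (rec.mother[:, blk0:blk1],
                             rec.infant[:, blk0:blk1])
        n_ep = n_epochs_in_block(ann.duration, epoch_s, overlap)
        for k in range(n_ep):
            s = blk0 + k * step
            epochs.append(HyperEpoch(
                mother=rec.mother[:, s:s + n_samp],
                infant=rec.infant[:, s:s + n_samp],
                condition=ann.label, epoch_index=k,
                start_s=k * step / rec.srate,
                block_offset=k * step,
            ))
    return HyperEpochSet(
        epochs=epochs, srate=rec.srate, channel_labels=rec.channel_labels,
        n_samples=n_samp, overlap=overlap, dyad_id=rec.dyad_id,
        infant_age_months=rec.infant_age_months, infant_sex=rec.infant_sex,
        blocks=blocks,
    )


def reject_artifacts(epochs: HyperEpochSet, mother_pp_uv: float = 100.0,
                     infant_pp_uv: float = 200.0
                     ) -> tuple[HyperEpochSet, pd.DataFrame]:
    """Drop epochs whose peak-to-peak amplitude exceeds a member's threshold.

    An epoch is rejected if *either* member exceeds its threshold on *any*
    analysis channel.  Returns the screened set plus a per-condition
    retention log (condition, n_total, n_retained, retention).
    """
    if mother_pp_uv <= 0 or infant_pp_uv <= 0:
        raise ValueError("peak-to-peak thresholds must be positive")
    kept = []
    rows: dict[str, list[int]] = {}
    for ep in epochs:
        ok = (np.ptp(ep.mother, axis=-1).max() <= mother_pp_uv
              and np.ptp(ep.infant, axis=-1).max() <= infant_pp_uv)
        tot, ret = rows.setdefault(ep.condition, [0, 0])
        rows[ep.condition][0] = tot + 1
        rows[ep.condition][1] = ret + int(ok)
        if ok:
            kept.append(ep)
    log = pd.DataFrame(
        [{"condition": c, "n_total": t, "n_retained": r,
          "retention": r / t if t else float("nan")}
         for c, (t, r) in rows.items()]
    )
    out = HyperEpochSet(
        epochs=kept, srate=epochs.srate, channel_labels=epochs.channel_labels,
        n_samples=epochs.n_samples, overlap=epochs.overlap,
        dyad_id=epochs.dyad_id, infant_age_months=epochs.infant_age_months,
        infant_sex=epochs.infant_sex, blocks=epochs.blocks,
    )
    return out, log
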