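"""Cross-brain phase synchrony: wPLI, PLV, surrogate validation, aggregation.

For every hyper-epoch and every cross-brain channel pair (mother channel j,
infant channel k) the instantaneous phase difference series

    dphi_i = phi_mother,j(t_i) - phi_infant,k(t_i),   i = 1..N

is formed from band-passed Hilbert phases, N being the number of time
samples in the epoch.  The weighted Phase Lag Index of one epoch is

    wPLI = | mean_i ( |sin dphi_i| * sign(sin dphi_i) ) | / mean_i |sin dphi_i|
         = | mean_i sin dphi_i | / mean_i |sin dphi_i|,

since |x|*sign(x) = x.  The outer absolute value makes the index live in
[0, 1]: 0 means no consistent lead/lag, 1 means one signal consistently
leads or lags the other throughout the epoch.  A phase difference locked at
exactly 0 (or pi) gives sin dphi = 0 everywhere and the index is 0 by
convention -- zero-lag coupling, the signature of volume conduction, is
deliberately invisible.  The Phase Locking Value, by contrast, is the
modulus of the mean unit phasor of dphi and happily counts zero-lag
coupling; it is carried along for comparison.

Each observed pair-epoch value is validated against an empirical surrogate
null (one member's phase series replaced so that the cross-brain relation is
destroyed while each marginal phase distribution is preserved); values that
do not beat the null quantile are excluded from the trial averages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert


@lru_cache(maxsize=64)
def _butter_band(order: int, low: float, high: float,
                 srate: float) -> tuple[np.ndarray, np.ndarray]:
    nyq = srate / 2.0
    return butter(order, [low / nyq, high / nyq], btype="band")

from .bands import DEFAULT_BANDS, BandSpec
from .recording import HyperEpochSet


@dataclass
class PhasePair:
    """Per-band instantaneous phases of one hyper-epoch, both members.

    ``phi_mother`` and ``phi_infant`` are channel x sample arrays of phase
    angles in (-pi, pi].  ``delta_phi`` materializes the full
    (mother channel x infant channel x sample) phase-difference array.
    """

    phi_mother: np.ndarray
    phi_infant: np.ndarray
    band: BandSpec
    condition: str
    epoch_index: int

    @property
    def delta_phi(self) -> np.ndarray:
        return self.phi_mother[:, None, :] - self.phi_infant[None, :, :]


@dataclass
class EpochConnectivity:
    """Connectivity matrices of one hyper-epoch (mother x infant channels)."""

    wpli: np.ndarray
    plv: np.ndarray | None
    valid_mask: np.ndarray
    condition: str
    band: str
    epoch_index: int


@dataclass
class SynchronyTable:
    """Trial-averaged synchrony per dyad, condition and band.

    ``pair_df``: long table (dyad, band, condition, mother_channel,
    infant_channel, trial_averaged_wpli, n_retained, n_epochs).
    ``global_df``: one row per (dyad, band, condition) with the scalar
    global wPLI (mean over all channel pairs of the trial-averaged values)
    and the pair-epoch retention fraction from the surrogate test.
    """

    pair_df: pd.DataFrame
    global_df: pd.DataFrame
    channel_labels: tuple[str, ...]

    def pair_matrix(self, dyad: str, condition: str, band: str) -> np.ndarray:
        sub = self.pair_df[(self.pair_df.dyad == dyad)
                           & (self.pair_df.condition == condition)
                           & (self.pair_df.band == band)]
        n = len(self.channel_labels)
        out = np.full((n, n), np.nan)
        li = {ch: i for i, ch in enumerate(self.channel_labels)}
        for r in sub.itertuples():
            out[li[r.mother_channel], li[r.infant_channel]] = \
                r.trial_averaged_wpli
        return out

    @staticmethod
    def concat(tables: list["SynchronyTable"]) -> "SynchronyTable":
        return SynchronyTable(
            pair_df=pd.concat([t.pair_df for t in tables], ignore_index=True),
            global_df=pd.concat([t.global_df for t in tables],
                                ignore_index=True),
            channel_labels=tables[0].channel_labels,
        )


# ---------------------------------------------------------------------------
# scalar / array metrics

def wpli_pair(delta_phi: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Weighted Phase Lag Index of a phase-difference series.

    Returns 0 when the denominator vanishes (all sin dphi = 0, i.e. pure
    zero-lag locking).  Works on any array, reducing over ``axis``.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if delta_phi.size == 0:
        raise ValueError("empty phase-difference series")
    s = np.sin(delta_phi)
    num = np.abs(np.mean(s, axis=axis))
    den = np.mean(np.abs(s), axis=axis)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(out) if out.ndim == 0 else out


def plv_pair(delta_phi: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Phase Locking Value: modulus of the mean unit phasor of dphi."""
    delta_phi = np.asarray(delta_phi, dtype=float)
    if delta_phi.size == 0:
        raise ValueError("empty phase-difference series")
    out = np.abs(np.mean(np.exp(1j * delta_phi), axis=axis))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# band-limited phases

def bandpass_and_phase(epochs: HyperEpochSet, band: BandSpec,
                       order: int = 4) -> list[PhasePair]:
    """Zero-phase band-pass, then analytic-signal phases, per hyper-epoch.

    When the epoch set carries its continuous condition blocks (the normal
    pipeline path), the band-pass and Hilbert transform run once per block
    and the phase series are sliced into epochs afterwards.  A narrow
    low-frequency band-pass cannot settle on an isolated 2-s segment -- its
    impulse response is longer than the segment -- so filtering the
    continuous block is the only way to get trustworthy epoch phases.
    Hand-built epoch sets without blocks fall back to per-epoch filtering
    with generous reflect padding.
    """
    if len(epochs) == 0:
        raise ValueError("no epochs to process")
    band.validate_for(epochs.srate)
    b, a = _butter_band(order, band.low, band.high, epochs.srate)
    n = epochs.n_samples
    out: list[PhasePair] = []
    blocks = epochs.blocks or {}
    cached: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_epoch_phases = None
    for e, ep in enumerate(epochs.epochs):
        if ep.condition in blocks:
            if ep.condition not in cached:
                mom_b, inf_b = blocks[ep.condition]
                cached[ep.condition] = tuple(
                    np.angle(hilbert(filtfilt(b, a, sig, axis=-1), axis=-1))
                    for sig in (mom_b, inf_b))
            pm_b, pi_b = cached[ep.condition]
            o = ep.block_offset
            pm, pi = pm_b[:, o:o + n], pi_b[:, o:o + n]
        else:
            if by_epoch_phases is None:
                mom = np.stack([x.mother for x in epochs.epochs])
                inf = np.stack([x.infant for x in epochs.epochs])
                padlen = min(n - 1, int(3 * epochs.srate / band.low))
                by_epoch_phases = tuple(
                    np.angle(hilbert(filtfilt(b, a, sig, axis=-1,
                                              padlen=padlen), axis=-1))
                    for sig in (mom, inf))
            pm, pi = by_epoch_phases[0][e], by_epoch_phases[1][e]
        out.append(PhasePair(phi_mother=pm, phi_infant=pi, band=band,
                             condition=ep.condition,
                             epoch_index=ep.epoch_index))
    return out


# ---------------------------------------------------------------------------
# fast pair-matrix kernels

def _trig(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.sin(phi), np.cos(phi)


def _wpli_matrix(sm, cm, si, ci) -> np.ndarray:
    """wPLI for all channel pairs from precomputed sin/cos of phases."""
    n = sm.shape[-1]
    num = np.abs(sm @ ci.T - cm @ si.T) / n
    den = np.abs(sm[:, None, :] * ci[None, :, :]
                 - cm[:, None, :] * si[None, :, :]).mean(axis=-1)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def _plv_matrix(sm, cm, si, ci) -> np.ndarray:
    n = sm.shape[-1]
    ms = (sm @ ci.T - cm @ si.T) / n
    mc = (cm @ ci.T + sm @ si.T) / n
    return np.hypot(ms, mc)


def epoch_connectivity_matrix(pp: PhasePair, metric: str = "wpli"
                              ) -> np.ndarray:
    """Connectivity of one epoch for all cross-brain channel pairs."""
    sm, cm = _trig(pp.phi_mother)
    si, ci = _trig(pp.phi_infant)
    if metric == "wpli":
        return _wpli_matrix(sm, cm, si, ci)
    if metric == "plv":
        return _plv_matrix(sm, cm, si, ci)
    raise ValueError(f"unknown metric {metric!r}")


def _stack_wpli(phi_m: np.ndarray, phi_i: np.ndarray) -> np.ndarray:
    """Per-epoch wPLI matrices for a whole epoch stack, (E, C_m, C_i)."""
    sm, cm = _trig(phi_m)                     # (E, C, N)
    si, ci = _trig(phi_i)
    n = phi_m.shape[-1]
    num = np.abs(np.einsum("ecn,edn->ecd", sm, ci)
                 - np.einsum("ecn,edn->ecd", cm, si)) / n
    den = np.abs(sm[:, :, None, :] * ci[:, None, :, :]
                 - cm[:, :, None, :] * si[:, None, :, :]).mean(axis=-1)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


# ---------------------------------------------------------------------------
# surrogate validation

def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def surrogate_validate(phase_pairs: "PhasePair | list[PhasePair]",
                       n_surrogates: int = 200, level: float = 0.05,
                       rng=None, method: str = "time_shuffle",
                       metric: str = "wpli",
                       min_separation: int = 2) -> np.ndarray:
    """Per-pair surrogate test of observed synchrony against an empirical null.

    For every channel pair of every epoch, the observed value is retained iff
    it is strictly greater than at least ceil((1 - level) * n_surrogates) of
    the surrogate values (ties count against retention).  Deterministic for a
    given ``rng`` seed.

    Methods
    -------
    ``time_shuffle`` (default): independent uniform permutation of the time
    index of the mother's phase series within the epoch, fresh permutations
    per surrogate (drawn per mother channel).  This is the classic
    phase-shuffling recipe.  Note that for band-limited phase series it is
    anti-conservative: permutation whitens the smooth phase trajectory, the
    surrogate wPLI distribution collapses toward zero, and nearly every
    epoch of real band-limited data is retained (which is also why this
    validation step barely affects trial averages in practice).  It is
    exactly calibrated only when the phase samples are serially independent.

    ``epoch_shuffle``: the mother's phase series is replaced by her phases
    from another epoch of the same set (donors more than ``min_separation``
    epochs away, clearing epoch overlap and the coherence time of genuine
    coupling).  This preserves the autocorrelation of band-limited phases
    and is calibrated (about ``level`` retention) for independent members
    -- use it for null-calibration work.

    Returns a boolean array (n_epochs, n_mother, n_infant); a single
    ``PhasePair`` input yields shape (n_mother, n_infant).
    """
    single = isinstance(phase_pairs, PhasePair)
    pairs = [phase_pairs] if single else list(phase_pairs)
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates for a 5% test")
    gen = _as_rng(rng)
    need = math.ceil((1.0 - level) * n_surrogates)
    trig = [(_trig(pp.phi_mother), _trig(pp.phi_infant)) for pp in pairs]
    mat = _wpli_matrix if metric == "wpli" else _plv_matrix
    observed = [mat(sm, cm, si, ci) for (sm, cm), (si, ci) in trig]

    masks = np.zeros((len(pairs),) + observed[0].shape, dtype=bool)
    if method == "epoch_shuffle":
        n_ep = len(pairs)
        for e in range(n_ep):
            donors = np.array([r for r in range(n_ep)
                               if abs(r - e) > min_separation])
            if donors.size == 0:
                raise ValueError(
                    "epoch_shuffle needs epochs farther apart than "
                    f"min_separation={min_separation}; got {n_ep} epochs"
                )
            # stratified draw: each donor appears floor/ceil(S/D) times --
            # plain with-replacement sampling adds multinomial noise to the
            # quantile estimate, which only ever inflates retention
            reps = -(-n_surrogates // donors.size)
            draw = gen.permuted(np.tile(donors, reps))[:n_surrogates]
            uniq, counts = np.unique(draw, return_counts=True)
            (_, _), (si, ci) = trig[e]
            exceed = np.zeros(observed[e].shape)
            for r, c in zip(uniq, counts):
                (sm_r, cm_r), _ = trig[r]
                exceed += c * (observed[e] > mat(sm_r, cm_r, si, ci))
            masks[e] = exceed >= need
    elif method == "time_shuffle":
        for e, pp in enumerate(pairs):
            (sm, cm), (si, ci) = trig[e]
            n = pp.phi_mother.shape[-1]
            for j in range(pp.phi_mother.shape[0]):
                # fresh permutations per surrogate, drawn per mother
                # channel and shared across that channel's infant pairings
                perm = np.argsort(gen.random((n_surrogates, n)), axis=-1)
                s_s = np.take(sm[j], perm)                # (S, N)
                c_s = np.take(cm[j], perm)
                sd = s_s[None] * ci[:, None, :] - c_s[None] * si[:, None, :]
                num = np.abs(sd.mean(axis=-1))            # (C_i, S)
                if metric == "wpli":
                    den = np.abs(sd).mean(axis=-1)
                    sur = np.divide(num, den, out=np.zeros_like(num),
                                    where=den > 0)
                else:
                    cd = (c_s[None] * ci[:, None, :]
                          + s_s[None] * si[:, None, :])
                    sur = np.hypot(sd.mean(axis=-1), cd.mean(axis=-1))
                exceed = (observed[e][j][:, None] > sur).sum(axis=-1)
                masks[e, j, :] = exceed >= need
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    return masks[0] if single else masks


# ---------------------------------------------------------------------------
# aggregation

def aggregate(epoch_conns: list[EpochConnectivity],
              channel_labels: tuple[str, ...],
              dyad_id: str = "dyad-000") -> SynchronyTable:
    """Trial-average retained pair-epoch values and form global synchrony.

    Per (condition, band): the pair matrix is the mean over epochs of the
    retained (surrogate-validated) values per channel pair; pairs with no
    retained epoch are recorded as missing.  The global wPLI is the mean of
    the pair matrix entries, and the retention fraction is the share of
    retained pair-epochs.  A condition with zero epochs yields no rows and a
    warning.
    """
    pair_rows, global_rows = [], []
    keys: list[tuple[str, str]] = []
    for ec in epoch_conns:
        if (ec.condition, ec.band) not in keys:
            keys.append((ec.condition, ec.band))
    for cond, band in keys:
        group = [ec for ec in epoch_conns
                 if ec.condition == cond and ec.band == band]
        if not group:
            warnings.warn(f"condition {cond!r} band {band!r}: no epochs")
            continue
        w = np.stack([ec.wpli for ec in group])           # (E, C, C)
        m = np.stack([ec.valid_mask for ec in group])
        n_ret = m.sum(axis=0)
        with np.errstate(invalid="ignore"):
            pair_matrix = np.where(
                n_ret > 0, (w * m).sum(axis=0) / np.maximum(n_ret, 1), np.nan)
        for i, mch in enumerate(channel_labels):
            for j, ich in enumerate(channel_labels):
                pair_rows.append({
                    "dyad": dyad_id, "band": band, "condition": cond,
                    "mother_channel": mch, "infant_channel": ich,
                    "trial_averaged_wpli": pair_matrix[i, j],
                    "n_retained": int(n_ret[i, j]), "n_epochs": len(group),
                })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmean = float(np.nanmean(pair_matrix))
        global_rows.append({
            "dyad": dyad_id, "band": band, "condition": cond,
            "global_wpli": gmean,
            "retention_fraction": float(m.mean()),
            "n_epochs": len(group),
        })
    return SynchronyTable(pd.DataFrame(pair_rows), pd.DataFrame(global_rows),
                          channel_labels)


# ---------------------------------------------------------------------------
# per-dyad driver

def dyad_synchrony(epochs: HyperEpochSet,
                   bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                   n_surrogates: int = 200, level: float = 0.05,
                   surrogate_method: str = "time_shuffle",
                   exclusion: str = "pair_epoch",
                   seed: int = 0, compute_plv: bool = False
                   ) -> SynchronyTable:
    """Full connectivity stage for one dyad's screened hyper-epochs.

    Per band and condition: band-pass + Hilbert phases, per-epoch wPLI for
    all cross-brain channel pairs, surrogate validation (skipped when
    ``n_surrogates`` is 0), then trial averaging of the retained values.

    ``exclusion`` selects the granularity at which non-significant values
    are dropped: ``pair_epoch`` (default) drops individual pair-epoch
    values; ``epoch`` drops a whole epoch (all pairs) when fewer than half
    of its channel-pair values pass the surrogate test.
    """
    if exclusion not in ("pair_epoch", "epoch"):
        raise ValueError(f"unknown exclusion policy {exclusion!r}")
    gen = np.random.default_rng(seed)
    conns: list[EpochConnectivity] = []
    for band in bands:
        for cond in epochs.conditions():
            sub = epochs.subset(cond)
            pps = bandpass_and_phase(sub, band)
            wm = _stack_wpli(np.stack([pp.phi_mother for pp in pps]),
                             np.stack([pp.phi_infant for pp in pps]))
            if n_surrogates > 0:
                masks = surrogate_validate(
                    pps, n_surrogates=n_surrogates, level=level, rng=gen,
                    method=surrogate_method)
                if exclusion == "epoch":
                    ep_ok = masks.mean(axis=(1, 2)) >= 0.5
                    masks = np.broadcast_to(
                        ep_ok[:, None, None], masks.shape).copy()
            else:
                masks = np.ones((len(pps),) + wm[0].shape, dtype=bool)
            for e, pp in enumerate(pps):
                plv = (epoch_connectivity_matrix(pp, "plv")
                       if compute_plv else None)
                conns.append(EpochConnectivity(
                    wpli=wm[e], plv=plv, valid_mask=masks[e],
                    condition=cond, band=band.name,
                    epoch_index=pp.epoch_index))
    return aggregate(conns, epochs.channel_labels, epochs.dyad_id)
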