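"""Reading and writing dual recordings.

Two interchange formats are supported:

* **EDF** (European Data Format): both members in one file, mother channels
  prefixed ``M_`` and infant channels ``I_``, condition blocks stored as
  EDF+ annotations.  Reading goes through mne; writing uses a small
  self-contained 16-bit EDF+ writer (values are quantized to the stored
  physical range, so round trips are exact only to that resolution).
  ``.bdf`` files can be read the same way.
* **packaged numeric**: a directory with one CSV matrix per person
  (samples x channels), a sidecar annotation table and a JSON metadata
  file -- lossless and trivially inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Annotation, DyadRecording

_PKG_FILES = ("mother.csv", "infant.csv", "annotations.csv", "meta.json")


# ---------------------------------------------------------------------------
# packaged numeric format

def write_packaged(rec: DyadRecording, path: str | Path) -> Path:
    """Write a recording as the packaged numeric (CSV + JSON) format."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    for name, sig in (("mother.csv", rec.mother), ("infant.csv", rec.infant)):
        pd.DataFrame(sig.T, columns=list(rec.channel_labels)).to_csv(
            d / name, index=False, float_format="%.6f")
    pd.DataFrame(
        [{"onset": a.onset, "duration": a.duration, "label": a.label}
         for a in rec.annotations]
    ).to_csv(d / "annotations.csv", index=False)
    (d / "meta.json").write_text(json.dumps({
        "dyad_id": rec.dyad_id, "srate": rec.srate,
        "infant_age_months": rec.infant_age_months,
        "infant_sex": rec.infant_sex,
        "channel_labels": list(rec.channel_labels),
    }, indent=1))
    return d


def _read_packaged(path: Path) -> DyadRecording:
    for f in _PKG_FILES:
        if not (path / f).exists():
            raise FileNotFoundError(f"packaged recording missing {f} in {path}")
    meta = json.loads((path / "meta.json").read_text())
    mother = pd.read_csv(path / "mother.csv")
    infant = pd.read_csv(path / "infant.csv")
    if len(mother) != len(infant):
        raise ValueError(
            "time-locking broken: mother and infant sample counts differ "
            f"({len(mother)} vs {len(infant)})"
        )
    if list(mother.columns) != list(infant.columns):
        raise ValueError("mother and infant channel labels differ")
    anns_df = pd.read_csv(path / "annotations.csv")
    anns = [Annotation(r.onset, r.duration, r.label)
            for r in anns_df.itertuples()] if len(anns_df) else []
    return DyadRecording(
        mother=mother.to_numpy().T, infant=infant.to_numpy().T,
        srate=float(meta["srate"]),
        channel_labels=tuple(mother.columns),
        annotations=anns, dyad_id=meta.get("dyad_id", "dyad-000"),
        infant_age_months=float(meta.get("infant_age_months", "nan")),
        infant_sex=meta.get("infant_sex", "F"),
    )


# ---------------------------------------------------------------------------
# minimal EDF+ writer

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _num(x, width: int) -> bytes:
    s = f"{x:.10g}"[:width]
    return _pad(s, width)


def write_edf(rec: DyadRecording, path: str | Path) -> Path:
    """Write a dual recording as a 16-bit EDF+C file.

    Mother channels are labelled ``M_<name>``, infant channels ``I_<name>``;
    condition annotations are stored in an EDF Annotations signal.  The
    recording length must be a whole number of seconds and the sampling rate
    an integer (1-s data records).
    """
    path = Path(path)
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(srate))
    n_records = rec.n_samples // spr
    if n_records * spr != rec.n_samples:
        raise ValueError("EDF writer requires a whole number of seconds")

    sigs = np.vstack([rec.mother, rec.infant])
    labels = [f"M_{ch}" for ch in rec.channel_labels] + \
             [f"I_{ch}" for ch in rec.channel_labels]
    pmax = max(1.0, float(np.abs(sigs).max()) * 1.001)
    dmax = 32767
    digital = np.clip(np.round(sigs / pmax * dmax), -dmax - 1, dmax
                      ).astype("<i2")

    # annotation TALs, all placed in the first record
    tals = b""
    for a in rec.annotations:
        tals += (f"+{a.onset:.6g}\x15{a.duration:.6g}\x14{a.label}\x14\x00"
                 .encode("ascii"))
    ann_spr = max(64, (len(tals) + 32) // 2 + 1)   # int16 slots per record

    ns = len(labels) + 1
    header = b""
    header += _pad("0", 8)
    # single token so EDF+ patient-field parsers keep it intact as the id
    header += _pad(f"{rec.dyad_id}|{rec.infant_sex}|"
                   f"{rec.infant_age_months:.2f}", 80)
    header += _pad("Startdate 01-JAN-2000 dual-EEG dyad recording", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _num(256 * (ns + 1), 8)
    header += _pad("EDF+C", 44)
    header += _num(n_records, 8)
    header += _num(1, 8)
    header += _num(ns, 4)

    def field(values, width):
        return b"".join(_pad(v, width) if isinstance(v, str) else _num(v, width)
                        for v in values)

    ann_label = "EDF Annotations"
    header += field(labels + [ann_label], 16)
    header += field([""] * ns, 80)                       # transducer
    header += field(["uV"] * (ns - 1) + [""], 8)          # physical dim
    header += field([-pmax] * (ns - 1) + [-1], 8)         # phys min
    header += field([pmax] * (ns - 1) + [1], 8)           # phys max
    header += field([-dmax - 1] * ns, 8)                  # dig min
    header += field([dmax] * ns, 8)                       # dig max
    header += field(["HP:1Hz LP:30Hz N:50Hz"] * (ns - 1) + [""], 80)
    header += field([spr] * (ns - 1) + [ann_spr], 8)
    header += field([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
            ann = f"+{r}\x14\x14\x00".encode("ascii")
            if r == 0:
                ann += tals
            ann += b"\x00" * (2 * ann_spr - len(ann))
            fh.write(ann)
    return path


def _read_edf(path: Path) -> DyadRecording:
    import mne

    reader = (mne.io.read_raw_bdf if path.suffix.lower() == ".bdf"
              else mne.io.read_raw_edf)
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    names = raw.ch_names
    mother_idx = [i for i, n in enumerate(names) if n.startswith("M_")]
    infant_idx = [i for i, n in enumerate(names) if n.startswith("I_")]
    m_labels = [names[i][2:] for i in mother_idx]
    i_labels = [names[i][2:] for i in infant_idx]
    if m_labels != i_labels:
        raise ValueError("mother/infant channel sets differ in the EDF file")
    anns = [Annotation(float(on), float(du), str(de))
            for on, du, de in zip(raw.annotations.onset,
                                  raw.annotations.duration,
                                  raw.annotations.description)
            if du > 0]
    dyad_id, age, sex = "dyad-000", float("nan"), "F"
    info = raw.info.get("subject_info") or {}
    his = (info.get("his_id", "") or "").split("|")
    if his and his[0]:
        dyad_id = his[0]
    if len(his) >= 3:
        sex = his[1]
        try:
            age = float(his[2])
        except ValueError:
            pass
    return DyadRecording(
        mother=data[mother_idx], infant=data[infant_idx],
        srate=float(raw.info["sfreq"]), channel_labels=tuple(m_labels),
        annotations=anns, dyad_id=dyad_id, infant_age_months=age,
        infant_sex=sex,
    )


def read_recording(path: str | Path, fmt: str | None = None) -> DyadRecording:
    """Read a dual recording (EDF/BDF file or packaged-numeric directory)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "packaged" if path.is_dir() else path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt in ("edf", "bdf"):
        return _read_edf(path)
    if fmt in ("packaged", "packaged-numeric", "csv"):
        return _read_packaged(path)
    raise ValueError(f"unknown recording format {fmt!r}")
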