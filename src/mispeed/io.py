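"""Session persistence: EDF+ raw signals, BIDS-style events.tsv, JSON sidecar.

The EDF+ writer is self-contained (EDF+C, 16-bit samples, per-channel
physical scaling, an annotations signal carrying the record-keeping time
stamps EDF+ requires).  Reading goes through ``mne.io.read_raw_edf``, so the
round trip is also an independent check of the writer.  Trial events are
stored in a tab-separated ``events.tsv`` (onset seconds at MI onset,
duration, trial_type, run); the session design and ground-truth condition
specs, which EDF cannot carry, round-trip through ``session.json``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ConditionSpec, Event, NoiseSpec, RawSession, SessionDesign

EDF_DIG_MIN, EDF_DIG_MAX = -32768, 32767
_ANNOT_SAMPLES_PER_RECORD = 30  # 60 bytes per record for the timestamp TAL


def _ascii(value, width) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, data: np.ndarray, fs: float, channel_names) -> None:
    n_ch, n_samples = data.shape
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = max(1, int(np.ceil(n_samples / fs_int)))
    padded = np.zeros((n_ch, n_records * fs_int))
    padded[:, :n_samples] = data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (EDF_DIG_MAX - EDF_DIG_MIN) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + EDF_DIG_MIN)
    digital = digital.astype("<i2")

    n_sig = n_ch + 1  # + annotations
    header_bytes = 256 * (1 + n_sig)
    hdr = b""
    hdr += _ascii("0", 8)
    hdr += _ascii("X X X X", 80)  # local patient id (anonymous)
    hdr += _ascii("Startdate 01-JAN-2000 X X X", 80)
    hdr += _ascii("01.01.00", 8)
    hdr += _ascii("00.00.00", 8)
    hdr += _ascii(header_bytes, 8)
    hdr += _ascii("EDF+C", 44)
    hdr += _ascii(n_records, 8)
    hdr += _ascii(1, 8)  # record duration, seconds
    hdr += _ascii(n_sig, 4)

    labels = [str(ch) for ch in channel_names] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        (["" for _ in range(n_sig)], 80),  # transducer
        (["uV"] * n_ch + [""], 8),
        ([f"{v:.6g}"[:8] for v in pmin] + ["-1"], 8),
        ([f"{v:.6g}"[:8] for v in pmax] + ["1"], 8),
        ([str(EDF_DIG_MIN)] * n_sig, 8),
        ([str(EDF_DIG_MAX)] * n_sig, 8),
        (["" for _ in range(n_sig)], 80),  # prefiltering
        ([str(fs_int)] * n_ch + [str(_ANNOT_SAMPLES_PER_RECORD)], 8),
        (["" for _ in range(n_sig)], 32),  # reserved
    ]
    for values, width in fields:
        for v in values:
            hdr += _ascii(v, width)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            fh.write(digital[:, rec * fs_int : (rec + 1) * fs_int].tobytes())
            tal = f"+{rec}\x14\x14\x00".encode("ascii")
            fh.write(tal.ljust(2 * _ANNOT_SAMPLES_PER_RECORD, b"\x00"))


def _cond_to_json(cond: ConditionSpec) -> dict:
    d = asdict(cond)
    for key in ("ssmrp_topography", "ssvep_topography"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["harmonic_amps"] = list(d["harmonic_amps"])
    return d


def _cond_from_json(d: dict) -> ConditionSpec:
    kw = dict(d)
    for key in ("ssmrp_topography", "ssvep_topography"):
        if kw[key] is not None:
            kw[key] = np.asarray(kw[key], dtype=float)
    kw["harmonic_amps"] = tuple(kw["harmonic_amps"])
    return ConditionSpec(**kw)


def write_session(session: RawSession, directory) -> Path:
    """Write session.edf + events.tsv + session.json into ``directory``."""
    session.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_edf(d / "session.edf", session.data, session.fs, session.channel_names)
    events = pd.DataFrame(
        {
            "onset": [ev.onset_sample / session.fs for ev in session.events],
            "duration": [session.design.mi_s] * len(session.events),
            "trial_type": [ev.label for ev in session.events],
            "run": [ev.run for ev in session.events],
        }
    )
    events.to_csv(d / "events.tsv", sep="\t", index=False)
    design = asdict(session.design)
    design["class_labels"] = list(design["class_labels"])
    design["channel_names"] = list(design["channel_names"])
    meta = {
        "n_samples": int(session.data.shape[1]),
        "design": design,
        "ground_truth": None
        if session.ground_truth is None
        else {lab: _cond_to_json(c) for lab, c in session.ground_truth.items()},
    }
    (d / "session.json").write_text(json.dumps(meta, indent=2))
    return d


def read_session(directory) -> RawSession:
    """Read a session written by :func:`write_session`."""
    import mne

    d = Path(directory)
    for name in ("session.edf", "events.tsv", "session.json"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing session file: {d / name}")
    meta = json.loads((d / "session.json").read_text())
    design_kw = dict(meta["design"])
    design_kw["class_labels"] = tuple(design_kw["class_labels"])
    design_kw["channel_names"] = tuple(design_kw["channel_names"])
    design = SessionDesign(**design_kw)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(d / "session.edf", preload=True, verbose="error")
    picks = [ch for ch in raw.ch_names if ch in design.channel_names]
    data = raw.get_data(picks=picks, units="uV")[:, : meta["n_samples"]]

    events_df = pd.read_csv(d / "events.tsv", sep="\t")
    valid = set(design.class_labels)
    bad = sorted(set(events_df["trial_type"].astype(str)) - valid)
    if bad:
        raise ValueError(
            f"unknown trial_type values {bad}; valid labels are {sorted(valid)}"
        )
    events = [
        Event(
            onset_sample=int(round(row.onset * design.fs)),
            label=str(row.trial_type),
            run=int(row.run),
        )
        for row in events_df.itertuples()
    ]
    gt = meta["ground_truth"]
    session = RawSession(
        data=data,
        fs=design.fs,
        channel_names=tuple(picks),
        events=events,
        design=design,
        ground_truth=None if gt is None else {lab: _cond_from_json(c) for lab, c in gt.items()},
    )
    session.validate()
    return session


def quantization_step(session: RawSession) -> np.ndarray:
    """Per-channel EDF 16-bit quantization step for round-trip tolerances."""
    pmin = session.data.min(axis=1)
    pmax = session.data.max(axis=1)
    rng = np.where(pmax - pmin > 0, pmax - pmin, 2.0)
    return rng / (EDF_DIG_MAX - EDF_DIG_MIN)


def noise_to_json(noise: NoiseSpec) -> dict:
    return asdict(noise)
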