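"""Filtering, epoching, normalization, and train/test splitting."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import RawSession


@dataclass
class EpochSet:
    """Trials x channels x samples, time axis relative to MI onset (seconds)."""

    data: np.ndarray
    labels: np.ndarray  # class indices 0..3
    time_axis: np.ndarray
    fs: float
    channel_names: tuple
    runs: np.ndarray | None = None  # per-trial run index (for run-wise CV)
    class_labels: tuple = ("rest", "slow", "medium", "fast")

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            time_axis=self.time_axis.copy(),
            fs=self.fs,
            channel_names=self.channel_names,
            runs=None if self.runs is None else self.runs[idx],
            class_labels=self.class_labels,
        )

    def save(self, path) -> None:
        header = {
            "fs": self.fs,
            "channel_names": list(self.channel_names),
            "class_labels": list(self.class_labels),
        }
        np.savez(
            path,
            data=self.data,
            labels=self.labels,
            time_axis=self.time_axis,
            runs=np.array([]) if self.runs is None else self.runs,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "EpochSet":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"].tobytes()).decode())
            runs = z["runs"]
            return cls(
                data=z["data"],
                labels=z["labels"],
                time_axis=z["time_axis"],
                fs=header["fs"],
                channel_names=tuple(header["channel_names"]),
                runs=None if runs.size == 0 else runs.astype(int),
                class_labels=tuple(header["class_labels"]),
            )


def bandpass(session: RawSession, low: float, high: float, order: int = 4) -> RawSession:
    """Zero-phase Butterworth band-pass (forward-backward), per channel."""
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= session.fs / 2:
        raise ValueError(f"high edge {high} Hz violates Nyquist ({session.fs / 2} Hz)")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=session.fs, output="sos")
    return RawSession(
        data=signal.sosfiltfilt(sos, session.data, axis=-1),
        fs=session.fs,
        channel_names=session.channel_names,
        events=list(session.events),
        design=session.design,
        ground_truth=session.ground_truth,
    )


def epoch(session: RawSession, t_min: float = -1.0, t_max: float = 5.0) -> EpochSet:
    """Cut trials around each event; t = 0 is MI onset (the beep)."""
    if t_min >= t_max:
        raise ValueError(f"need t_min < t_max, got ({t_min}, {t_max})")
    fs = session.fs
    n = int(round((t_max - t_min) * fs))
    off = int(round(t_min * fs))
    n_samples = session.data.shape[1]
    trials, labels, runs = [], [], []
    label_to_idx = {lab: i for i, lab in enumerate(session.design.class_labels)}
    for ev in session.events:
        start = ev.onset_sample + off
        if start < 0 or start + n > n_samples:
            raise ValueError(
                f"epoch window [{t_min}, {t_max}] s around event at sample "
                f"{ev.onset_sample} (run {ev.run}, {ev.label!r}) leaves the recording"
            )
        trials.append(session.data[:, start : start + n])
        labels.append(label_to_idx[ev.label])
        runs.append(ev.run)
    data = np.stack(trials) if trials else np.empty((0, len(session.channel_names), n))
    return EpochSet(
        data=data,
        labels=np.asarray(labels, int),
        time_axis=t_min + np.arange(n) / fs,
        fs=fs,
        channel_names=tuple(session.channel_names),
        runs=np.asarray(runs, int),
        class_labels=tuple(session.design.class_labels),
    )


def normalize(epochs: EpochSet) -> EpochSet:
    """Z-score each channel of each trial over the epoch; constant channels -> 0."""
    if epochs.n_trials == 0:
        raise ValueError("cannot normalize an empty EpochSet")
    mu = epochs.data.mean(axis=-1, keepdims=True)
    sd = epochs.data.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (epochs.data - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return EpochSet(
        data=out,
        labels=epochs.labels.copy(),
        time_axis=epochs.time_axis.copy(),
        fs=epochs.fs,
        channel_names=epochs.channel_names,
        runs=None if epochs.runs is None else epochs.runs.copy(),
        class_labels=epochs.class_labels,
    )


def iter_folds(epochs: EpochSet, scheme: str = "leave-one-run-out", seed: int = 0, n_folds: int = 5):
    """Yield (train, test) EpochSet pairs.

    ``leave-one-run-out`` folds by recording run (needs per-trial run info);
    ``stratified`` is a seeded stratified K-fold preserving class ratios.
    """
    if scheme == "leave-one-run-out":
        if epochs.runs is None:
            raise ValueError("leave-one-run-out requires per-trial run indices")
        for run in np.unique(epochs.runs):
            test = epochs.runs == run
            yield epochs.subset(~test), epochs.subset(test)
    elif scheme == "stratified":
        from sklearn.model_selection import StratifiedKFold

        counts = np.bincount(epochs.labels)
        if (counts[counts > 0] < 2).any():
            raise ValueError("every class needs >= 2 trials for a stratified split")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(np.zeros(epochs.n_trials), epochs.labels):
            yield epochs.subset(tr), epochs.subset(te)
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")


def split(epochs: EpochSet, scheme: str = "stratified", seed: int = 0, n_folds: int = 5):
    """First (train, test) fold of :func:`iter_folds` — a plain holdout split."""
    return next(iter_folds(epochs, scheme=scheme, seed=seed, n_folds=n_folds))
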