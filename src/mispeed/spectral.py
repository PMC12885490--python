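"""Steady-state response analysis: CSD, Welch PSD in dB, neighbor-bin SNR.

The SNR of a frequency bin is its power divided by the mean power of the
``n_neighbors`` bins on each side (the bin itself excluded); bins closer
than ``n_neighbors`` to either edge are flagged undefined.  Steady-state
peaks then stand out as local ratios independent of the 1/f background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import SSMRP_CHANNELS, SSVEP_CHANNELS

DB_FLOOR = -300.0

CHANNEL_SETS = {
    "ssvep": SSVEP_CHANNELS,
    "ssmrp": SSMRP_CHANNELS,
}


@dataclass(frozen=True)
class ChannelSet:
    name: str
    channels: tuple

    @classmethod
    def named(cls, name: str) -> "ChannelSet":
        if name not in CHANNEL_SETS:
            raise KeyError(f"unknown channel set {name!r}; known: {sorted(CHANNEL_SETS)}")
        return cls(name=name, channels=CHANNEL_SETS[name])


@dataclass
class SNRSpectrum:
    freq_grid: np.ndarray  # Hz, uniform
    psd_db: np.ndarray  # 10*log10(power)
    psd_linear: np.ndarray
    snr: np.ndarray  # linear ratio; NaN on the excluded edges
    n_neighbors: int

    @property
    def excluded_edges(self) -> tuple:
        k, f = self.n_neighbors, self.freq_grid
        return ((f[0], f[k - 1]), (f[-k], f[-1]))

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.snr)


def csd_transform(epochs, stiffness: int = 4, lambda2: float = 1e-5):
    """Spherical-spline surface-Laplacian (current source density) transform.

    Sharpened spatial resolution for steady-state analysis; output units are
    µV/m² when the input is in µV.  Delegates to MNE's implementation with
    the standard 10-10 montage; raises if any channel lacks a position.
    """
    import mne

    from .montage import standard_montage
    from .preprocess import EpochSet

    montage = standard_montage()
    known = set(montage.get_positions()["ch_pos"])
    missing = [ch for ch in epochs.channel_names if ch not in known]
    if missing:
        raise ValueError(f"channels without scalp positions: {missing}")
    if len(epochs.channel_names) < 4:
        raise ValueError("CSD needs at least 4 channels")

    info = mne.create_info(list(epochs.channel_names), epochs.fs, ch_types="eeg")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = mne.EpochsArray(
            epochs.data * 1e-6, info, tmin=float(epochs.time_axis[0]), verbose="error"
        )
        arr.set_montage(montage, verbose="error")
        csd = mne.preprocessing.compute_current_source_density(
            arr, stiffness=stiffness, lambda2=lambda2, verbose="error"
        )
    out = csd.get_data() * 1e6  # V/m² -> µV/m²
    return EpochSet(
        data=out,
        labels=epochs.labels.copy(),
        time_axis=epochs.time_axis.copy(),
        fs=epochs.fs,
        channel_names=epochs.channel_names,
        runs=None if epochs.runs is None else epochs.runs.copy(),
    )


def welch_psd(
    epochs,
    channel_set: ChannelSet | str | None = None,
    segment_s: float = 2.5,
    overlap: float = 0.5,
    tmin: float | None = None,
    tmax: float | None = None,
    concat_trials: int = 1,
    window: str = "blackman",
):
    """Trial- and channel-averaged Welch PSD over the MI window, in dB.

    ``concat_trials`` > 1 concatenates that many trials end to end before
    segmenting, so segments longer than one MI period (hence finer than
    1/mi_s frequency resolution) are possible; e.g. two 5-s MI windows give
    10-s segments and a 0.1-Hz grid.

    Returns ``(freq_grid, psd_db, psd_linear)``.
    """
    data = epochs.data
    if isinstance(channel_set, str):
        channel_set = ChannelSet.named(channel_set)
    if channel_set is not None:
        idx = [epochs.channel_names.index(ch) for ch in channel_set.channels]
        data = data[:, idx, :]
    t = epochs.time_axis
    lo = 0.0 if tmin is None else tmin
    hi = t[-1] + 0.5 / epochs.fs if tmax is None else tmax
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    data = data[:, :, mask]

    if concat_trials > 1:
        n_groups = data.shape[0] // concat_trials
        if n_groups == 0:
            raise ValueError("fewer trials than concat_trials")
        data = data[: n_groups * concat_trials]
        # (groups, channels, concat*samples)
        data = np.concatenate(
            np.split(data, n_groups, axis=0), axis=0
        ).reshape(n_groups, concat_trials, data.shape[1], -1)
        data = np.moveaxis(data, 1, 2).reshape(n_groups, data.shape[2], -1)

    nperseg = int(round(segment_s * epochs.fs))
    if nperseg > data.shape[-1]:
        raise ValueError(
            f"segment of {segment_s} s ({nperseg} samples) exceeds the "
            f"analysis span of {data.shape[-1]} samples"
        )
    noverlap = int(round(overlap * nperseg))
    freq, pxx = signal.welch(
        data, fs=epochs.fs, window=window, nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    psd = pxx.mean(axis=(0, 1))  # average trials/groups and channels
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(psd)
    if np.any(np.isneginf(psd_db)):
        warnings.warn("zero-power bins floored at -300 dB", RuntimeWarning, stacklevel=2)
        psd_db = np.maximum(psd_db, DB_FLOOR)
    return freq, psd_db, psd


def steady_state_psd(
    epochs,
    channel_set: ChannelSet | str | None = "ssmrp",
    segment_s: float = 10.0,
    overlap: float = 0.75,
    tmin: float = 0.0,
    tmax: float | None = None,
    n_orderings: int = 4,
    seed: int = 12345,
):
    """High-resolution PSD of the MI period via trial concatenation.

    All trials' MI spans are concatenated into one record and analyzed with
    Welch segments longer than a single trial (10-s segments give a 0.1-Hz
    grid at any fs).  Because the concatenation order is arbitrary and
    segments straddling trial boundaries see random relative phases of the
    steady-state response, the PSD is additionally averaged over
    ``n_orderings`` seeded permutations of trial order, which marginalizes
    out that arbitrary choice and stabilizes harmonic-bin power.

    Returns ``(freq_grid, psd_db, psd_linear)``.
    """
    if tmax is None:
        tmax = float(epochs.time_axis[-1]) + 0.5 / epochs.fs
    rng = np.random.default_rng(seed)
    acc = None
    for k in range(max(1, n_orderings)):
        order = np.arange(epochs.n_trials) if k == 0 else rng.permutation(epochs.n_trials)
        freq, _, lin = welch_psd(
            epochs.subset(order),
            channel_set=channel_set,
            segment_s=segment_s,
            overlap=overlap,
            tmin=tmin,
            tmax=tmax,
            concat_trials=epochs.n_trials,
        )
        acc = lin if acc is None else acc + lin
    psd = acc / max(1, n_orderings)
    with np.errstate(divide="ignore"):
        psd_db = np.maximum(10.0 * np.log10(psd), DB_FLOOR)
    return freq, psd_db, psd


def snr_spectrum(freq_grid, psd_linear, n_neighbors: int = 5) -> SNRSpectrum:
    """Neighbor-bin SNR: power at each bin over the mean of its ±n neighbors."""
    freq_grid = np.asarray(freq_grid, float)
    p = np.asarray(psd_linear, float)
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if p.shape != freq_grid.shape or p.ndim != 1:
        raise ValueError("freq_grid and psd_linear must be matching 1-D arrays")
    if len(p) < 2 * n_neighbors + 1:
        raise ValueError(
            f"spectrum of {len(p)} bins is shorter than 2*{n_neighbors}+1"
        )
    df = np.diff(freq_grid)
    if df.size and not np.allclose(df, df[0], rtol=1e-6, atol=1e-12):
        raise ValueError("frequency grid must be uniform")
    snr = np.full_like(p, np.nan)
    k = n_neighbors
    for i in range(k, len(p) - k):
        neigh = np.concatenate([p[i - k : i], p[i + 1 : i + k + 1]])
        m = neigh.mean()
        snr[i] = p[i] / m if m > 0 else np.inf
    with np.errstate(divide="ignore"):
        psd_db = np.maximum(10.0 * np.log10(p, where=p > 0, out=np.full_like(p, -np.inf)), DB_FLOOR)
    return SNRSpectrum(
        freq_grid=freq_grid, psd_db=psd_db, psd_linear=p, snr=snr, n_neighbors=n_neighbors
    )


def harmonic_readout(snr: SNRSpectrum, f0: float, n_harmonics: int = 4, fmax_peak: float = 8.0):
    """SNR at the nearest bin to each harmonic h*f0, plus the global-max flag.

    ``is_global_max`` marks harmonics whose bin is the argmax of the SNR
    spectrum over 1 Hz..``fmax_peak`` (defined bins only).  Nearest-bin ties
    resolve toward the lower frequency.  Returns a pandas DataFrame with
    columns (harmonic, freq_hz, snr, is_global_max).
    """
    import pandas as pd

    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    f = snr.freq_grid
    defined = snr.defined()
    rows = []
    band = defined & (f >= 1.0) & (f <= fmax_peak)
    if not band.any():
        raise ValueError("no defined SNR bins in the peak-search band")
    peak_bin = np.flatnonzero(band)[np.nanargmax(snr.snr[band])]
    for h in range(1, n_harmonics + 1):
        target = h * f0
        if target > f[-1]:
            break
        d = np.abs(f - target)
        i = int(np.flatnonzero(d <= d.min() + 1e-12)[0])  # tie -> lower freq
        if not defined[i]:
            raise ValueError(f"harmonic {h} at {target:.2f} Hz falls on an excluded edge bin")
        rows.append(
            {
                "harmonic": h,
                "freq_hz": float(f[i]),
                "snr": float(snr.snr[i]),
                "is_global_max": bool(i == peak_bin),
            }
        )
    return pd.DataFrame(rows)


def peak_snr_frequency(snr: SNRSpectrum, fmin: float = 1.0, fmax: float = 8.0) -> float:
    """Frequency of the global SNR maximum within [fmin, fmax] (defined bins)."""
    f = snr.freq_grid
    band = snr.defined() & (f >= fmin) & (f <= fmax)
    if not band.any():
        raise ValueError("no defined SNR bins in the requested band")
    return float(f[np.flatnonzero(band)[np.nanargmax(snr.snr[band])]])
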