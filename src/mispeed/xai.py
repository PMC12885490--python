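"""Model interpretation: kernel spectra, spatial patterns, CAM and CAT.

* Temporal kernels act as FIR frequency filters; their Fourier magnitudes
  show which bands the decoder relies on (mean response smoothed with a
  Savitzky-Golay filter, window 5, order 3).
* The spatial filter matrix W mixes channels into sources, like common
  spatial patterns; columns of W^-1 (pseudo-inverse when W is non-square or
  ill-conditioned) are the corresponding scalp patterns, reported as
  normalized absolute values since the sign of an oscillatory source is
  arbitrary.
* Grad-CAM on the conv-module output tokens gives a signed per-class
  temporal attention map: positive values read as ERS-like evidence,
  negative as ERD-like, so no rectification is applied.  Class activation
  topography (CAT) projects the CAM onto channels by weighting the
  normalized EEG with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .conformer import TrainedModel
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

COND_THRESHOLD = 1e6


@dataclass
class KernelSpectra:
    freq_grid: np.ndarray  # Hz, up to fs/2
    magnitude: np.ndarray  # n_filters x n_freqs
    mean_magnitude: np.ndarray  # smoothed mean over filters


@dataclass
class SpatialPattern:
    pattern_matrix: np.ndarray  # n_channels x n_filters
    normalized_abs: np.ndarray  # column max = 1
    used_pseudo_inverse: bool
    condition_number: float


@dataclass
class CAMResult:
    class_label: str
    time_axis: np.ndarray  # seconds, input resolution
    activation: np.ndarray  # signed, input resolution
    bin_starts: np.ndarray  # seconds
    binned: np.ndarray  # per 0.5-s bin
    bin_s: float = 0.5


@dataclass
class CATopography:
    class_label: str
    channel_names: tuple
    values: np.ndarray  # per channel, signed


def kernel_frequency_response(
    trained: TrainedModel, smooth: tuple = (5, 3), n_freqs: int = 256
) -> KernelSpectra:
    """Discrete Fourier magnitude of each temporal kernel on [0, fs/2].

    The magnitude of the time-reversed kernel equals that of the kernel
    itself, so the response is |FFT(K)| on a zero-padded grid of at least
    ``n_freqs`` points; the filter-bank mean is Savitzky-Golay smoothed.
    """
    window, order = smooth
    if window % 2 == 0 or window <= order:
        raise ValueError(
            f"Savitzky-Golay window must be odd and > order, got ({window}, {order})"
        )
    K = trained.kernels
    nfft = 2 * max(n_freqs, K.shape[1])
    mag = np.abs(np.fft.rfft(K, n=nfft, axis=1))
    freq = np.fft.rfftfreq(nfft, 1.0 / trained.fs)
    mean_mag = savgol_filter(mag.mean(axis=0), window_length=window, polyorder=order)
    return KernelSpectra(freq_grid=freq, magnitude=mag, mean_magnitude=mean_mag)


def spatial_pattern(trained: TrainedModel) -> SpatialPattern:
    """Scalp patterns from the (pseudo-)inverse of the spatial filter matrix."""
    W = trained.spatial_filters  # n_filters x n_channels
    cond = float(np.linalg.cond(W))
    square = W.shape[0] == W.shape[1]
    if square and cond < COND_THRESHOLD:
        pattern = np.linalg.inv(W)
        pseudo = False
    else:
        if square:
            logger.warning(
                "spatial filter matrix ill-conditioned (cond=%.3g); using pseudo-inverse",
                cond,
            )
        pattern = np.linalg.pinv(W)  # n_channels x n_filters
        pseudo = True
    absval = np.abs(pattern)
    colmax = absval.max(axis=0, keepdims=True)
    normalized = np.divide(absval, colmax, out=np.zeros_like(absval), where=colmax > 0)
    return SpatialPattern(
        pattern_matrix=pattern,
        normalized_abs=normalized,
        used_pseudo_inverse=pseudo,
        condition_number=cond,
    )


def _upsample_tokens(values, token_centers, n_samples):
    """Nearest-token assignment of per-token values onto input samples.

    Each token's receptive-field center defines its position; samples go to
    the token with the nearest center, ties to the earlier token.
    """
    edges = (token_centers[:-1] + token_centers[1:]) / 2.0
    idx = np.searchsorted(edges, np.arange(n_samples), side="left")
    return values[..., idx]


def _bin_cam(activation, time_axis, bin_s=0.5):
    t0 = time_axis[0]
    duration = time_axis[-1] - t0 + (time_axis[1] - time_axis[0])
    n_bins = int(np.floor(duration / bin_s + 1e-9))
    starts = t0 + bin_s * np.arange(n_bins)
    binned = np.empty(n_bins)
    for i, s in enumerate(starts):
        m = (time_axis >= s - 1e-9) & (time_axis < s + bin_s - 1e-9)
        binned[i] = activation[m].mean()
    return starts, binned


def gradcam(trained: TrainedModel, epochs: EpochSet, target_class: int | str) -> CAMResult:
    """Signed gradient-weighted class activation map over input time.

    Feature maps are the conv-module output tokens A_k; weights are the
    token-time means of d score(target)/d A_k; the map sum_k alpha_k A_k is
    kept signed (no rectification), upsampled to the input time axis by
    nearest token center, averaged over trials of the target class, and
    binned into non-overlapping 0.5-s bins.
    """
    if isinstance(target_class, str):
        target_idx = trained.class_labels.index(target_class)
    else:
        target_idx = int(target_class)
    mask = epochs.labels == target_idx
    if not mask.any():
        raise ValueError(
            f"no trials of class {trained.class_labels[target_idx]!r} in the epochs"
        )
    X = epochs.data[mask]
    model = trained.model
    logits, cache = model.forward(X, want_cache=True)
    dlogits = np.zeros_like(logits)
    dlogits[:, target_idx] = 1.0  # d score_c / d logits
    _, d_tokens = model.backward(dlogits, cache)  # (B, n_tokens, F)
    tokens = cache["tokens"]
    alpha = d_tokens.mean(axis=1, keepdims=True)  # (B, 1, F): spatial mean of grads
    cam_tokens = (alpha * tokens).sum(axis=-1)  # (B, n_tokens), signed
    cam = _upsample_tokens(cam_tokens, model.token_centers(), model.n_samples)
    activation = cam.mean(axis=0)
    starts, binned = _bin_cam(activation, epochs.time_axis)
    return CAMResult(
        class_label=trained.class_labels[target_idx],
        time_axis=epochs.time_axis.copy(),
        activation=activation,
        bin_starts=starts,
        binned=binned,
    )


def cat(cam: CAMResult, normalized_epochs: EpochSet, target_class: int | str) -> CATopography:
    """Class activation topography: CAM-weighted normalized EEG per channel."""
    if isinstance(target_class, str):
        target_idx = normalized_epochs.class_labels.index(target_class)
    else:
        target_idx = int(target_class)
    if cam.time_axis.shape != normalized_epochs.time_axis.shape or not np.allclose(
        cam.time_axis, normalized_epochs.time_axis
    ):
        raise ValueError("CAM and epoch time axes are misaligned")
    mask = normalized_epochs.labels == target_idx
    if not mask.any():
        raise ValueError("no trials of the target class in the epochs")
    X = normalized_epochs.data[mask]  # (B, C, T)
    values = (X * cam.activation[None, None, :]).mean(axis=(0, 2))
    return CATopography(
        class_label=normalized_epochs.class_labels[target_idx],
        channel_names=normalized_epochs.channel_names,
        values=values,
    )


def channel_group_mass(topo: CATopography, group: tuple) -> float:
    """Fraction of total |CAT| mass carried by the named channel group."""
    absval = np.abs(topo.values)
    total = absval.sum()
    if total == 0:
        return 0.0
    idx = [topo.channel_names.index(ch) for ch in group]
    return float(absval[idx].sum() / total)
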