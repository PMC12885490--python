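"""Electrode geometry helpers.

Channel positions come from the standard 10-10 montage shipped with MNE;
they are used both for spatially smooth ground-truth topographies in the
simulator and for the spherical-spline current source density transform.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Channels named in the steady-state analyses, plus Fz.
SSMRP_CHANNELS = ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4")
SSVEP_CHANNELS = ("Pz", "O1", "O2")
DEFAULT_CHANNELS = SSMRP_CHANNELS + SSVEP_CHANNELS + ("T7", "Fz")


@lru_cache(maxsize=4)
def standard_montage():
    """The 10-10 montage used throughout (cached MNE DigMontage)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return mne.channels.make_standard_montage("standard_1005")


def channel_positions(channel_names: tuple[str, ...] | list[str]) -> np.ndarray:
    """3-D head-frame positions (meters), one row per channel.

    Raises ``KeyError`` listing any channel absent from the montage.
    """
    pos = standard_montage().get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos]
    if missing:
        raise KeyError(f"channels without montage positions: {missing}")
    return np.asarray([pos[ch] for ch in channel_names], dtype=float)


def gaussian_topography(
    channel_names: list[str] | tuple[str, ...],
    centers: tuple[str, ...],
    sigma_m: float = 0.03,
) -> np.ndarray:
    """Smooth per-channel weights: max of Gaussian bumps centered on ``centers``.

    Channels inside the named set get weight ~1; weight decays with the
    Euclidean scalp distance to the nearest center (``sigma_m`` meters).
    """
    xyz = channel_positions(tuple(channel_names))
    cxyz = channel_positions(tuple(centers))
    d = np.linalg.norm(xyz[:, None, :] - cxyz[None, :, :], axis=-1)
    return np.exp(-0.5 * (d.min(axis=1) / sigma_m) ** 2)
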