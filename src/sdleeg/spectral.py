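"""Power spectral density and band-energy features.

The spectral feature used for classification is the PSD integrated over
0.5-25 Hz (the delta-through-low-beta range where scalp EEG carries most of
its power), averaged across the selected strongest channels. Single 4 s
epochs are short, so a single-segment Hann-tapered periodogram is used,
renormalized so that its integral over frequency equals the signal variance
(Parseval), which keeps band energies in µV² regardless of taper.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .io_edf import EEGEpoch

logger = logging.getLogger(__name__)

#: Classification band (Hz).
DEFAULT_BAND = (0.5, 25.0)

#: Conventional clinical EEG bands (Hz); gamma's upper edge is capped at
#: the acquisition bandwidth downstream.
CLINICAL_BANDS = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 70.0),
}


def compute_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a single channel.

    Mean is removed, a Hann taper applied, and the density rescaled so
    ``trapezoid(power, freq) == var(x)`` exactly (zero for a constant
    input).

    Returns
    -------
    freqs, powers : ndarray
        Frequencies in Hz and density in µV²/Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("compute_psd expects a 1-D series")
    if len(x) < 64:
        raise ValueError("series too short for a meaningful PSD (< 64)")
    if fs <= 0:
        raise ValueError("fs must be positive")
    var = float(np.var(x))
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    if var == 0.0:
        logger.info("constant signal: returning all-zero PSD")
        return freqs, np.zeros_like(pxx)
    total = float(np.trapezoid(pxx, freqs))
    if total > 0:
        pxx = pxx * (var / total)
    return freqs, pxx


def band_energy(freqs: np.ndarray, powers: np.ndarray,
                lo: float, hi: float) -> float:
    """Trapezoidal integral of a PSD over ``[lo, hi]`` Hz.

    Band edges falling between grid points are handled by linear
    interpolation so the result is exact for a piecewise-linear density.
    """
    if lo >= hi:
        raise ValueError(f"band ({lo}, {hi}) is empty")
    if lo < 0 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band ({lo}, {hi}) outside PSD support")
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    vals = np.interp(grid, freqs, powers)
    return float(np.trapezoid(vals, grid))


def epoch_psd_feature(epoch: EEGEpoch,
                      band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean band energy over the epoch's channels.

    The epoch is expected to be already restricted to the selected
    strongest channels; the result is invariant to channel order.
    """
    energies = []
    for row in epoch.data:
        freqs, pxx = compute_psd(row, epoch.fs)
        energies.append(band_energy(freqs, pxx, *band))
    return float(np.mean(energies))


def clinical_band_energies(epoch: EEGEpoch) -> dict[str, float]:
    """Energies of the named delta/theta/alpha/beta/gamma bands (µV²)."""
    nyq = epoch.fs / 2
    out: dict[str, float] = {}
    for name, (lo, hi) in CLINICAL_BANDS.items():
        hi = min(hi, nyq - 1e-6)
        if hi <= lo:
            continue
        vals = []
        for row in epoch.data:
            freqs, pxx = compute_psd(row, epoch.fs)
            vals.append(band_energy(freqs, pxx, lo, hi))
        out[name] = float(np.mean(vals))
    return out
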