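"""ROI-averaged, area-normalized power spectra and alpha peak frequency.

The estimator is Bartlett's method on the fixed 4096-sample epochs: a raw
single-taper periodogram per ROI and epoch, averaged over ROIs and epochs,
restricted to the analysis band and divided by its own area so that
``sum(power) * df = 1``.  Frequency resolution is 312.5 / 4096 ≈ 0.0763 Hz.
An optional Hann taper is offered; the default is no taper, since the signals
of interest are already band-limited at this resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

EPOCH_SAMPLES = 4096
TARGET_RATE = 312.5
SPECTRAL_BAND = (0.5, 30.0)
PEAK_SEARCH = (4.0, 13.0)


class SpectralError(ValueError):
    pass


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray  # normalized: sum(power) * df = 1 over the band
    band: tuple[float, float]
    n_epochs: int
    n_rois: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def epoch_spectrum(epoch: np.ndarray, rate: float = TARGET_RATE,
                   taper: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided raw periodogram per ROI of a single 4096-sample epoch.

    Density scaling: the sum of power times the bin width equals the signal
    mean square (Parseval).  Returns (freqs, rois x 2049 power).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-1] != EPOCH_SAMPLES:
        raise SpectralError(f"epoch must be {EPOCH_SAMPLES} samples")
    window = "hann" if taper == "hann" else "boxcar"
    freqs, pxx = sps.periodogram(epoch, fs=rate, window=window,
                                 detrend=False, axis=-1)
    return freqs, pxx


def average_normalized_spectrum(epochs, band: tuple[float, float] =
                                SPECTRAL_BAND, taper: str | None = None
                                ) -> PowerSpectrum:
    """Mean periodogram over ROIs and epochs, restricted to ``band`` (bins with
    lo <= f <= hi) and normalized to unit area (Riemann sum)."""
    data = epochs.data
    if data.shape[0] < 1:
        raise SpectralError("need at least one epoch")
    freqs, pxx = epoch_spectrum(
        data.reshape(-1, data.shape[-1]), rate=epochs.rate, taper=taper)
    mean_power = pxx.mean(axis=0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise SpectralError(f"band {band} contains no frequency bins")
    f = freqs[sel]
    p = mean_power[sel]
    df = freqs[1] - freqs[0]
    area = p.sum() * df
    if area <= 0:
        raise SpectralError("spectrum has zero area")
    return PowerSpectrum(freqs=f, power=p / area, band=band,
                         n_epochs=data.shape[0], n_rois=data.shape[1])


def group_mean_spectrum(specs: list[PowerSpectrum]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group mean and standard error of per-subject normalized spectra on a
    common grid — the usual group power-spectrum figure."""
    if not specs:
        raise SpectralError("need at least one spectrum")
    f0 = specs[0].freqs
    for s in specs[1:]:
        if len(s.freqs) != len(f0) or np.max(np.abs(s.freqs - f0)) > 1e-9:
            raise SpectralError("spectra must share one frequency grid")
    stack = np.stack([s.power for s in specs])
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(specs))
           if len(specs) > 1 else np.zeros_like(f0))
    return f0, stack.mean(axis=0), sem


def peak_frequency(spec: PowerSpectrum,
                   search: tuple[float, float] = PEAK_SEARCH) -> float:
    """Frequency of the maximum bin within the search window (default
    4-13 Hz); ties break toward the lowest frequency."""
    sel = (spec.freqs >= search[0]) & (spec.freqs <= search[1])
    if not sel.any():
        raise SpectralError("search window contains no bins")
    p = spec.power[sel]
    if np.all(p == 0):
        raise SpectralError("flat-zero spectrum has no peak")
    return float(spec.freqs[sel][int(np.argmax(p))])
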