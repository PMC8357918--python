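"""Decimation to the common 312.5 Hz rate, epoching, and automated
bad-channel / artifact-epoch flagging.

Epochs are exactly 4096 samples (13.1072 s at 312.5 Hz, reported as 13.11 s).
Channel and epoch rejection in the original workflow was visual; here both are
deterministic robust-z (median/MAD) rules so the pipeline is reproducible, with
thresholds logged in the run report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

EPOCH_SAMPLES = 4096
TARGET_RATE = 312.5

#: scale factor making MAD a consistent sigma estimate for Gaussian data
MAD_TO_SIGMA = 0.6744897501960817


class PreprocessError(ValueError):
    pass


@dataclass
class EpochSet:
    """n_epochs x channels x 4096 epochs at the common 312.5 Hz rate."""

    data: np.ndarray
    rate: float = TARGET_RATE
    kept_epoch_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != EPOCH_SAMPLES:
            raise PreprocessError(
                f"epochs must be {EPOCH_SAMPLES} samples long")
        if abs(self.rate - TARGET_RATE) > 1e-9:
            raise PreprocessError(f"epoch rate must be {TARGET_RATE} Hz")
        if self.kept_epoch_ids is None:
            self.kept_epoch_ids = np.arange(self.data.shape[0])

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def decimate(x: np.ndarray, rate: float,
             target_rate: float = TARGET_RATE) -> tuple[np.ndarray, float]:
    """Anti-aliased integer-factor downsampling.

    Zero-phase (forward-backward) low-pass at 0.8x the new Nyquist, then every
    k-th sample.  Factor 1 returns an identity copy.
    """
    x = np.asarray(x, dtype=float)
    factor = rate / target_rate
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise PreprocessError(
            f"decimation factor {factor} is not a positive integer")
    if k == 1:
        return x.copy(), target_rate
    cutoff = 0.8 * (target_rate / 2.0)
    sos = signal.butter(8, cutoff, btype="low", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    return y[..., ::k], target_rate


def split_epochs(x: np.ndarray, rate: float) -> EpochSet:
    """Consecutive non-overlapping 4096-sample epochs; remainder discarded."""
    if abs(rate - TARGET_RATE) > 1e-9:
        raise PreprocessError("epoching requires the 312.5 Hz common rate")
    t = x.shape[-1]
    n = t // EPOCH_SAMPLES
    if n < 1:
        raise PreprocessError("no complete epoch: fewer than 4096 samples")
    trimmed = x[..., :n * EPOCH_SAMPLES]
    data = trimmed.reshape(x.shape[0], n, EPOCH_SAMPLES).transpose(1, 0, 2)
    return EpochSet(data=np.ascontiguousarray(data), rate=TARGET_RATE)


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values)
    return MAD_TO_SIGMA * (values - med) / mad


def flag_bad_channels(rec, z_thresh: float = 4.0) -> np.ndarray:
    """Flag channels whose log-variance is a robust outlier among channels of
    the same kind.  Returns a boolean mask, True = bad."""
    data = rec.data
    kinds = rec.array.kind
    if data.shape[0] < 8:
        raise PreprocessError("need at least 8 channels to flag outliers")
    logvar = np.log(np.var(data, axis=1) + np.finfo(float).tiny)
    bad = np.zeros(data.shape[0], dtype=bool)
    for kind in np.unique(kinds):
        sel = kinds == kind
        z = _robust_z(logvar[sel])
        bad[sel] = np.abs(z) > z_thresh
    if bad.all():
        raise PreprocessError("all channels flagged as bad")
    return bad


def reject_artifact_epochs(ep: EpochSet, amp_thresh_mad: float = 6.0
                           ) -> EpochSet:
    """Drop epochs whose peak |amplitude| is a robust outlier of the
    per-channel epoch-peak distribution."""
    if ep.n_epochs < 1:
        raise PreprocessError("need at least one epoch")
    peaks = np.max(np.abs(ep.data), axis=2)  # (n_epochs, C)
    med = np.median(peaks, axis=0)
    sigma = np.median(np.abs(peaks - med), axis=0) / MAD_TO_SIGMA
    # with few epochs the MAD collapses toward zero; floor the scale at 20% of
    # the median peak so only genuinely large excursions flag
    sigma = np.maximum(sigma, 0.2 * np.abs(med))
    sigma[sigma == 0] = np.inf  # constant-zero channels can never flag
    z = (peaks - med) / sigma
    bad_epoch = (z > amp_thresh_mad).any(axis=1)
    if bad_epoch.all():
        raise PreprocessError("no epoch survives artifact rejection")
    keep = ~bad_epoch
    return EpochSet(data=ep.data[keep], rate=ep.rate,
                    kept_epoch_ids=ep.kept_epoch_ids[keep])
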