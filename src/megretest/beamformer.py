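"""Scalar LCMV beamformer: broadband covariance, optimal source orientation by
generalized eigendecomposition, unit-gain minimum-variance weights, and
centroid time-series reconstruction.

For each ROI centroid the spatial filter is

    w = C^-1 l / (l' C^-1 l),        l = L nu,

where ``L`` is the (M x 3) dipole lead-field block, ``C`` the regularized
broadband (0.5-48 Hz) sensor covariance, and ``nu`` the orientation maximizing
the pseudo-Z output SNR — the leading eigenvector of the pencil
``(L' C^-1 L, L' C^-2 L)`` restricted to the tangential subspace (the sphere
model makes the radial direction silent).  Weights are optionally normalized to
unit Euclidean norm; this rescales amplitudes per ROI only and leaves every
correlation-based statistic downstream unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .connectivity import brickwall_bandpass
from .forward import lead_field_block

BROADBAND = (0.5, 48.0)


class BeamformerError(ValueError):
    pass


@dataclass
class CovarianceEstimate:
    c: np.ndarray
    band: tuple[float, float]
    samples_used: int
    regularization: float


@dataclass
class BeamformerWeights:
    w: np.ndarray  # (n_rois, M_good)
    orientation: np.ndarray  # (n_rois, 3)
    normalized: bool


def estimate_covariance(data: np.ndarray, rate: float,
                        band: tuple[float, float] = BROADBAND,
                        reg: float = 0.05,
                        prefiltered: bool = False) -> CovarianceEstimate:
    """Sample covariance of brickwall band-passed data with diagonal loading
    ``reg * mean(eigenvalues) * I``."""
    m, t = data.shape
    if m < 2:
        raise BeamformerError("need at least 2 good channels")
    if t <= m:
        warnings.warn("fewer samples than channels: covariance is rank "
                      "deficient before regularization", stacklevel=2)
    filtered = data if prefiltered else brickwall_bandpass(data, band, rate)
    c = np.cov(filtered)
    mean_eig = np.trace(c) / m
    c = c + reg * mean_eig * np.eye(m)
    if np.linalg.eigvalsh(c).min() <= 0:
        raise BeamformerError("covariance singular after regularization")
    return CovarianceEstimate(c=c, band=band, samples_used=t,
                              regularization=reg)


def _tangential_basis(l_block: np.ndarray) -> np.ndarray:
    """(3, 2) basis of the two leading right singular directions of L —
    excludes the magnetically silent radial direction of the sphere model."""
    _, _, vt = np.linalg.svd(l_block, full_matrices=False)
    return vt[:2].T


def _fix_sign(v: np.ndarray) -> np.ndarray:
    for comp in v:
        if abs(comp) > 1e-12:
            return v if comp > 0 else -v
    return v


def optimal_orientation(l_block: np.ndarray, c: np.ndarray,
                        c_inv: np.ndarray | None = None) -> np.ndarray:
    """Orientation maximizing the beamformer pseudo-Z output SNR.

    Solves (L' C^-1 L) v = lambda (L' C^-2 L) v in the tangential subspace and
    returns the eigenvector of the largest lambda, unit-normalized with the
    first nonzero component positive.  Near-degenerate eigenvalues are broken
    deterministically (lexicographically smallest vector) with a warning.
    """
    if c_inv is None:
        c_inv = np.linalg.inv(c)
    basis = _tangential_basis(l_block)
    lt = l_block @ basis  # (M, 2)
    a = lt.T @ c_inv @ lt
    b = lt.T @ (c_inv @ c_inv) @ lt
    vals, vecs = linalg.eigh(a, b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    candidates = [0]
    if len(vals) > 1 and abs(vals[0] - vals[1]) <= 1e-9 * max(abs(vals[0]), 1e-30):
        warnings.warn("degenerate beamformer orientation eigenvalues; "
                      "deterministic tie-break applied", stacklevel=2)
        candidates = [i for i in range(len(vals))
                      if abs(vals[0] - vals[i]) <= 1e-9 * max(abs(vals[0]), 1e-30)]
    nus = []
    for i in candidates:
        nu = basis @ vecs[:, i]
        nu = nu / np.linalg.norm(nu)
        nus.append(_fix_sign(nu))
    nus.sort(key=lambda v: tuple(v))
    return nus[0]


def compute_weights(l_block: np.ndarray, c: np.ndarray, nu: np.ndarray,
                    normalize: bool = True,
                    c_inv: np.ndarray | None = None) -> np.ndarray:
    """Minimum-variance unit-gain weights w = C^-1 l / (l' C^-1 l) for
    l = L nu; optionally rescaled to unit norm."""
    if c_inv is None:
        c_inv = np.linalg.inv(c)
    l_vec = l_block @ nu if l_block.ndim == 2 else l_block
    denom_scale = (l_vec @ l_vec) / (np.trace(c) / c.shape[0])
    ci_l = c_inv @ l_vec
    denom = l_vec @ ci_l
    if denom <= 1e-15 * max(denom_scale, np.finfo(float).tiny):
        raise BeamformerError("silent source: l' C^-1 l vanishes")
    w = ci_l / denom
    if normalize:
        w = w / np.linalg.norm(w)
    return w


def reconstruct_roi_series(rec, centroids: np.ndarray, head=None,
                           band: tuple[float, float] = BROADBAND,
                           reg: float = 0.05, normalize: bool = True
                           ) -> tuple[np.ndarray, BeamformerWeights]:
    """Scalar-beamformer source series at every centroid.

    Returns the (n_rois, T) reconstructed broadband series (same rate as the
    input recording) and the weights/orientations used.
    """
    head = rec.head if head is None else head
    good = rec.good_channel_mask
    filtered = brickwall_bandpass(rec.data[good], band, rec.rate)
    cov = estimate_covariance(filtered, rec.rate, band=band, reg=reg,
                              prefiltered=True)
    c_inv = np.linalg.inv(cov.c)
    n_rois = len(centroids)
    w_rows = np.empty((n_rois, filtered.shape[0]))
    orientations = np.empty((n_rois, 3))
    for i, pos in enumerate(centroids):
        l_full = lead_field_block(rec.array, head, pos)
        l_block = l_full[good]
        nu = optimal_orientation(l_block, cov.c, c_inv=c_inv)
        w_rows[i] = compute_weights(l_block, cov.c, nu, normalize=normalize,
                                    c_inv=c_inv)
        orientations[i] = nu
    series = w_rows @ filtered
    weights = BeamformerWeights(w=w_rows, orientation=orientations,
                                normalized=normalize)
    return series, weights
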