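"""Synthetic cohort generator.

Stands in for an unreleased clinical dataset: 8 healthy subjects, three
~5-minute eyes-closed resting-state sessions each (BL and FU1 on a 151-channel
axial-gradiometer system at 312.5/625 Hz, FU2 on a 306-channel
magnetometer+planar-gradiometer system at 1250 Hz).

Each subject carries a stable *fingerprint* — an alpha peak frequency, a 1/f
background exponent, relative band amplitudes, and one band-specific target
envelope-coupling matrix per band of interest — that all of that subject's
sessions share.  Sessions differ only in their noise realization, sampling
rate and sensor system, which is exactly the premise whose recoverability the
downstream consistency statistics measure.

Per ROI the generated signal is a sum over frequency bands of
``band-limited carrier x slow envelope`` plus a 1/f background.  Envelope
coupling is imposed on the envelopes (correlated low-pass Gaussian processes,
mixed through a matrix square root of the target coupling matrix), never on
the raw carriers, so that leakage-corrected amplitude-envelope correlation can
in principle detect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import (DEFAULT_HEAD_RADIUS, HeadModel, SensorArray,
                      build_sensor_array, source_layout)

N_ROIS = 90

#: canonical frequency bands, Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}

#: bands that carry a subject-specific coupling matrix
COUPLED_BANDS = ("alpha", "beta")

DEFAULT_BAND_AMP = {"delta": 0.5, "theta": 0.5, "alpha": 1.2,
                    "beta": 0.7, "gamma": 0.2}
ENVELOPE_CUTOFF_HZ = 1.0
BACKGROUND_AMP = 1.0
#: spectral width of the alpha rhythm around the subject's peak frequency
ALPHA_PEAK_SIGMA_HZ = 0.4

EPOCH_SAMPLES = 4096
TARGET_RATE = 312.5


class CohortConfigError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Study-design parameters of the simulated cohort."""

    n_subjects: int = 8
    timepoints: tuple[str, ...] = ("BL", "FU1", "FU2")
    system_per_timepoint: dict[str, str] = field(default_factory=lambda: {
        "BL": "ctf151", "FU1": "ctf151", "FU2": "vectorview306"})
    duration_s: float = 300.0
    native_rate_per_timepoint: dict[str, float] = field(default_factory=lambda: {
        "BL": 312.5, "FU1": 625.0, "FU2": 1250.0})
    #: per channel kind, sensor-noise std as a fraction of that kind's median
    #: signal RMS (amplitude units are arbitrary; all statistics are scale-free)
    noise: dict[str, float] = field(default_factory=lambda: {
        "axial_gradiometer": 0.3, "magnetometer": 0.3,
        "planar_gradiometer": 0.3})
    head_radius: float = DEFAULT_HEAD_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortConfigError("n_subjects must be at least 2")
        rates = [self.native_rate_per_timepoint[t] for t in self.timepoints]
        if self.duration_s * min(rates) < 2 * EPOCH_SAMPLES:
            raise CohortConfigError(
                "duration too short: need at least 2 epochs after decimation")
        for r in rates:
            k = np.log2(r / TARGET_RATE)
            if abs(k - round(k)) > 1e-9 or r < TARGET_RATE:
                raise CohortConfigError(
                    f"native rate {r} is not 312.5 * 2^k for integer k >= 0")
        for t in self.timepoints:
            if t not in self.system_per_timepoint:
                raise CohortConfigError(f"no system for timepoint {t}")


@dataclass
class SubjectFingerprint:
    """Stable per-subject generative parameters."""

    subject: str
    alpha_peak_hz: float
    one_over_f_exponent: float
    band_amp: dict[str, float]
    coupling_target: dict[str, np.ndarray]  # band -> (90, 90)
    roi_amplitude: np.ndarray  # (90,)


@dataclass
class SourceActivity:
    series: np.ndarray  # (90, T)
    rate: float
    roi_labels: list[str]
    ground_truth: SubjectFingerprint | None = None


@dataclass
class SensorRecording:
    data: np.ndarray  # (M, T)
    rate: float
    array: SensorArray
    head: HeadModel
    system: str
    good_channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.array.n_channels:
            raise ValueError("data rows must match the sensor array")
        if self.good_channel_mask is None:
            self.good_channel_mask = np.ones(self.data.shape[0], dtype=bool)


def nearest_psd_correlation(a: np.ndarray, max_offdiag: float = 0.8,
                            n_iter: int = 8) -> np.ndarray:
    """Project a symmetric matrix to a positive-semidefinite correlation-like
    matrix with unit diagonal and off-diagonals in [0, max_offdiag].

    Alternating projections between the clipped box and the PSD cone; at the
    default iteration count the residual box violation is ~1e-13, so the final
    clip leaves the smallest eigenvalue above -1e-8.
    """
    c = 0.5 * (a + a.T)
    for _ in range(n_iter):
        off = c - np.diag(np.diag(c))
        off = np.clip(off, 0.0, max_offdiag)
        c = off + np.eye(len(c))
        w, v = np.linalg.eigh(c)
        c = (v * np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    c = 0.5 * (c + c.T)
    off = np.clip(c - np.diag(np.diag(c)), 0.0, max_offdiag)
    return off + np.eye(len(c))


def _coupling_matrix(rng: np.random.Generator, n_modules: int = 6) -> np.ndarray:
    """Random modular coupling target: high within-module envelope coupling,
    weak background, unit diagonal, PSD-projected."""
    membership = rng.integers(0, n_modules, size=N_ROIS)
    strength = rng.uniform(0.3, 0.7, size=n_modules)
    c = np.full((N_ROIS, N_ROIS), 0.05)
    for m in range(n_modules):
        idx = np.where(membership == m)[0]
        c[np.ix_(idx, idx)] = strength[m]
    c += 0.05 * rng.standard_normal((N_ROIS, N_ROIS))
    np.fill_diagonal(c, 1.0)
    return nearest_psd_correlation(c)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, subject_index)))


def session_rng_seed(seed: int, subject_index: int, timepoint_index: int
                     ) -> np.random.SeedSequence:
    """Deterministic per-session random stream key."""
    return np.random.SeedSequence(
        entropy=seed, spawn_key=(2, subject_index, timepoint_index))


def make_cohort(spec: CohortSpec) -> list[SubjectFingerprint]:
    """Draw one fingerprint per subject, deterministically from ``spec.seed``."""
    fingerprints = []
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i)
        alpha_peak = rng.uniform(8.0, 12.0)
        exponent = rng.uniform(0.8, 1.4)
        band_amp = {b: a * float(rng.lognormal(0.0, 0.25))
                    for b, a in DEFAULT_BAND_AMP.items()}
        coupling = {b: _coupling_matrix(rng) for b in COUPLED_BANDS}
        roi_amp = rng.lognormal(0.0, 0.2, size=N_ROIS)
        fingerprints.append(SubjectFingerprint(
            subject=f"S{i + 1:02d}", alpha_peak_hz=alpha_peak,
            one_over_f_exponent=exponent, band_amp=band_amp,
            coupling_target=coupling, roi_amplitude=roi_amp))
    for i, fa in enumerate(fingerprints):
        for fb in fingerprints[i + 1:]:
            d = np.linalg.norm(fa.coupling_target["alpha"]
                               - fb.coupling_target["alpha"])
            if d <= 0:
                raise RuntimeError("degenerate cohort: identical fingerprints")
    return fingerprints


def _spectrum_to_unit_rows(spec: np.ndarray, t: int) -> np.ndarray:
    """Inverse-transform a one-sided spectrum (DC and Nyquist zero) to
    unit-variance time series; the normalization is the exact Parseval sum."""
    w = 2.0 * np.einsum("ij,ij->i", spec.real, spec.real)
    w += 2.0 * np.einsum("ij,ij->i", spec.imag, spec.imag)
    std = np.sqrt(w) / t
    std[std == 0] = 1.0
    return np.fft.irfft(spec, n=t, axis=1) / std[:, None]


def _bandlimited_noise(rng: np.random.Generator, n: int, t: int, rate: float,
                       band: tuple[float, float], center: float | None = None,
                       sigma: float | None = None) -> np.ndarray:
    """n independent unit-variance Gaussian series with power confined to
    band, drawn directly in the frequency domain (only the in-band bins).

    With ``center``/``sigma`` the in-band amplitude spectrum is shaped by a
    Gaussian profile — used to give the alpha rhythm a genuine spectral peak.
    """
    f = np.fft.rfftfreq(t, d=1.0 / rate)
    idx = np.arange(len(f))
    sel = (f >= band[0]) & (f <= band[1]) & (idx > 0)
    if t % 2 == 0:
        sel &= idx < len(f) - 1  # Nyquist bin stays empty
    keep = np.where(sel)[0]
    spec = np.zeros((n, len(f)), dtype=complex)
    vals = (rng.standard_normal((n, len(keep)))
            + 1j * rng.standard_normal((n, len(keep))))
    if center is not None and sigma is not None:
        vals *= np.exp(-0.5 * ((f[keep] - center) / sigma) ** 2)
    spec[:, keep] = vals
    return _spectrum_to_unit_rows(spec, t)


def _one_over_f_noise(rng: np.random.Generator, n: int, t: int, rate: float,
                      exponent: float) -> np.ndarray:
    f = np.fft.rfftfreq(t, d=1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    if t % 2 == 0:
        shaping[-1] = 0.0
    spec = (rng.standard_normal((n, len(f)))
            + 1j * rng.standard_normal((n, len(f)))) * shaping
    return _spectrum_to_unit_rows(spec, t)


def _lowpass_noise(rng: np.random.Generator, n: int, t: int, rate: float,
                   cutoff: float) -> np.ndarray:
    """Unit-variance Gaussian noise with power confined below ``cutoff``."""
    return _bandlimited_noise(rng, n, t, rate, (0.0, cutoff))


def _fourier_upsample(x: np.ndarray, t_out: int) -> np.ndarray:
    """Exact band-limited upsampling by zero-padding the spectrum."""
    t_in = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    if t_in % 2 == 0:
        spec[..., -1] *= 0.5  # split the Nyquist bin symmetrically
    out = np.zeros(x.shape[:-1] + (t_out // 2 + 1,), dtype=complex)
    out[..., :spec.shape[-1]] = spec
    return np.fft.irfft(out, n=t_out, axis=-1) * (t_out / t_in)


def _matrix_sqrt_psd(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def simulate_source_activity(fp: SubjectFingerprint, rate: float,
                             duration_s: float, session_seed) -> SourceActivity:
    """One session of 90-ROI ground-truth source activity.

    Same fingerprint + different session seed => a new realization with the
    same spectral shape and the same expected envelope-coupling pattern.
    """
    if rate < 100:
        raise ValueError("rate must be at least 100 Hz")
    t = int(round(rate * duration_s))
    rng = np.random.default_rng(session_seed)
    # all signal content lives below 48 Hz + 1 Hz sidebands, far under the
    # 156.25 Hz Nyquist of the base rate: synthesize on the base grid and
    # Fourier-upsample, which reconstructs the band-limited signal exactly
    k = rate / TARGET_RATE
    if rate > TARGET_RATE and abs(k - round(k)) < 1e-9:
        base = simulate_source_activity(fp, TARGET_RATE, duration_s,
                                        session_seed)
        series = _fourier_upsample(base.series, t)
        return SourceActivity(series=series, rate=rate,
                              roi_labels=base.roi_labels, ground_truth=fp)
    series = np.zeros((N_ROIS, t))
    for band, (lo, hi) in BANDS.items():
        center = sigma = None
        if band == "alpha":
            center, sigma = fp.alpha_peak_hz, ALPHA_PEAK_SIGMA_HZ
        carrier = _bandlimited_noise(rng, N_ROIS, t, rate, (lo, hi),
                                     center=center, sigma=sigma)
        env_noise = _lowpass_noise(rng, N_ROIS, t, rate, ENVELOPE_CUTOFF_HZ)
        if band in fp.coupling_target:
            c = fp.coupling_target[band]
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-8:
                raise ValueError("coupling target must be positive semidefinite")
            env_noise = _matrix_sqrt_psd(c) @ env_noise
        # rectified quasi-linear envelope around 1: mostly linear in the
        # Gaussian driver, so realized envelope correlations track the target
        env_noise *= 0.5
        env_noise += 1.0
        np.maximum(env_noise, 0.05, out=env_noise)
        carrier *= env_noise
        carrier *= fp.band_amp[band]
        series += carrier
    series += BACKGROUND_AMP * _one_over_f_noise(rng, N_ROIS, t, rate,
                                                 fp.one_over_f_exponent)
    series *= fp.roi_amplitude[:, None]
    series -= series.mean(axis=1, keepdims=True)
    labels = [f"ROI_{i:02d}" for i in range(N_ROIS)]
    return SourceActivity(series=series, rate=rate, roi_labels=labels,
                          ground_truth=fp)


_FORWARD_CACHE: dict = {}


def _forward_operator(system: str, head_radius: float, positions: np.ndarray,
                      orientations: np.ndarray):
    """Cache (array, head, gain) per geometry: the forward operator depends
    only on the sensor system and the fixed source layout."""
    from .forward import gain_matrix
    key = (system, head_radius, positions.tobytes(), orientations.tobytes())
    if key not in _FORWARD_CACHE:
        array = build_sensor_array(system)
        head = HeadModel(sphere_radius=head_radius)
        gain = gain_matrix(array, head, positions, orientations)
        _FORWARD_CACHE[key] = (array, head, gain)
    return _FORWARD_CACHE[key]


def simulate_session(fp: SubjectFingerprint, spec: CohortSpec, timepoint: str,
                     subject_index: int, positions: np.ndarray | None = None,
                     orientations: np.ndarray | None = None
                     ) -> tuple[SensorRecording, SourceActivity]:
    """Simulate one subject/timepoint: source activity projected onto the
    timepoint's sensor system with per-kind relative sensor noise."""
    if positions is None or orientations is None:
        positions, orientations, _ = source_layout(
            head_radius=spec.head_radius)
    rate = spec.native_rate_per_timepoint[timepoint]
    system = spec.system_per_timepoint[timepoint]
    ti = list(spec.timepoints).index(timepoint)
    seed_seq = session_rng_seed(spec.seed, subject_index, ti)
    src_seed, noise_seed = seed_seq.spawn(2)
    src = simulate_source_activity(fp, rate, spec.duration_s, src_seed)
    array, head, gain = _forward_operator(system, spec.head_radius,
                                          positions, orientations)
    clean = gain @ src.series
    rms = np.sqrt(np.mean(clean ** 2, axis=1))
    noise_std = {}
    for kind, frac in spec.noise.items():
        sel = array.kind == kind
        if sel.any():
            noise_std[kind] = frac * float(np.median(rms[sel]))
        else:
            noise_std[kind] = 0.0
    std = np.array([noise_std[k] for k in array.kind])
    noise_rng = np.random.default_rng(noise_seed)
    data = clean + std[:, None] * noise_rng.standard_normal(clean.shape)
    rec = SensorRecording(data=data, rate=rate, array=array, head=head,
                          system=system)
    return rec, src
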