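"""Forward model: sensor geometries, spherical head model, dipole lead fields.

The magnetic field of a current dipole in a homogeneous conducting sphere is
given by the Sarvas closed form.  Two consequences shape everything downstream:
a radially oriented dipole is magnetically silent, and so is a dipole at the
sphere center — both follow from the field being proportional to ``Q x r0``.

Two helmet layouts are provided: a 151-channel axial-gradiometer system
(CTF-like) and a 306-channel system with 102 magnetometer sites each carrying
two orthogonal planar gradiometers (Vectorview-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7

AXIAL_GRADIOMETER = "axial_gradiometer"
MAGNETOMETER = "magnetometer"
PLANAR_GRADIOMETER = "planar_gradiometer"

CTF_HELMET_RADIUS = 0.105
CTF_BASELINE = 0.05
VECTORVIEW_BASELINE = 0.0168
DEFAULT_HEAD_RADIUS = 0.09


class ForwardDomainError(ValueError):
    """Source position incompatible with the spherical conductor model."""


@dataclass
class HeadModel:
    """Spherical volume conductor; optionally one sphere center per channel."""

    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = DEFAULT_HEAD_RADIUS
    channel_centers: np.ndarray | None = None  # (M, 3) for multi-sphere

    def __post_init__(self) -> None:
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.channel_centers is not None:
            self.channel_centers = np.asarray(self.channel_centers, dtype=float)

    def center_for_channel(self, ch: int) -> np.ndarray:
        if self.channel_centers is None:
            return self.sphere_center
        return self.channel_centers[ch]


@dataclass
class SensorArray:
    """Coil-level description of an MEG helmet.

    ``coil_positions``/``coil_orientations`` have shape (M, 2, 3); channels with
    a single coil (magnetometers) carry NaN in the second slot.  Gradiometer
    channels measure the difference of the field projections on their two coils.
    """

    channel_id: list[str]
    kind: np.ndarray  # (M,) str
    coil_positions: np.ndarray  # (M, 2, 3) meters
    coil_orientations: np.ndarray  # (M, 2, 3) unit vectors
    baseline: np.ndarray  # (M,) meters; 0 for magnetometers

    def __post_init__(self) -> None:
        self.kind = np.asarray(self.kind)
        self.coil_positions = np.asarray(self.coil_positions, dtype=float)
        self.coil_orientations = np.asarray(self.coil_orientations, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        norms = np.linalg.norm(self.coil_orientations, axis=-1)
        two_coil = self.n_coils == 2
        ok = np.abs(norms[:, 0] - 1.0) < 1e-9
        ok &= ~two_coil | (np.abs(norms[:, 1] - 1.0) < 1e-9)
        if not ok.all():
            raise ValueError("coil orientations must be unit vectors")
        is_grad = np.isin(self.kind, [AXIAL_GRADIOMETER, PLANAR_GRADIOMETER])
        if not np.array_equal(is_grad, two_coil):
            raise ValueError("gradiometers must have exactly two coils")

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)

    @property
    def n_coils(self) -> np.ndarray:
        return np.where(np.isnan(self.coil_positions[:, 1, 0]), 1, 2)


def _fibonacci_cap(n: int, theta_max: float, rotate: float = 0.0) -> np.ndarray:
    """n quasi-uniform unit vectors on the spherical cap theta in [0, theta_max]."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    # uniform in solid angle on the cap: z from 1 down to cos(theta_max)
    z = 1.0 - (1.0 - np.cos(theta_max)) * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = golden * i + rotate
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangents at unit radial vector u (deterministic)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def build_sensor_array(kind: str, helmet_radius: float = CTF_HELMET_RADIUS,
                       baseline: float | None = None,
                       theta_max_deg: float = 110.0) -> SensorArray:
    """Construct a helmet-shaped sensor array.

    ``ctf151``: 151 axial gradiometers, radial normals, two coils separated by
    the gradiometer baseline (default 0.05 m) along the normal.

    ``vectorview306``: 102 sites, each with one radial magnetometer and two
    orthogonal planar gradiometers (coil pairs split by the planar baseline,
    default 0.0168 m, along the two tangent directions) — 306 channels.
    """
    theta_max = np.deg2rad(theta_max_deg)
    if kind == "ctf151":
        bl = CTF_BASELINE if baseline is None else baseline
        units = _fibonacci_cap(151, theta_max)
        ids, kinds, pos, ori, bls = [], [], [], [], []
        for j, u in enumerate(units):
            p1 = helmet_radius * u
            p2 = (helmet_radius + bl) * u
            ids.append(f"MZG{j:03d}")
            kinds.append(AXIAL_GRADIOMETER)
            pos.append([p1, p2])
            ori.append([u, u])
            bls.append(bl)
    elif kind == "vectorview306":
        bl = VECTORVIEW_BASELINE if baseline is None else baseline
        units = _fibonacci_cap(102, theta_max, rotate=0.7)
        ids, kinds, pos, ori, bls = [], [], [], [], []
        nan3 = np.full(3, np.nan)
        for j, u in enumerate(units):
            site = helmet_radius * u
            e1, e2 = _tangent_frame(u)
            ids.append(f"MEG{j:03d}1")
            kinds.append(MAGNETOMETER)
            pos.append([site, nan3])
            ori.append([u, u])
            bls.append(0.0)
            for k, e in enumerate((e1, e2), start=2):
                ids.append(f"MEG{j:03d}{k}")
                kinds.append(PLANAR_GRADIOMETER)
                pos.append([site + 0.5 * bl * e, site - 0.5 * bl * e])
                ori.append([u, u])
                bls.append(bl)
    else:
        raise ValueError(f"unknown sensor array kind: {kind!r}")
    return SensorArray(ids, np.array(kinds), np.array(pos), np.array(ori),
                       np.array(bls))


def _sarvas_b(r: np.ndarray, r0: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Sarvas field of a dipole (moment q, position r0) at field points r.

    All positions relative to the sphere center; r and r0 broadcast over
    leading axes (shape (..., 3)).  The field is proportional to ``q x r0``,
    hence exactly zero for a radial or central dipole.
    """
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)
    if np.any(a < 1e-12):
        raise ForwardDomainError("field point coincides with the dipole")
    qxr0 = np.cross(np.broadcast_to(q, r0.shape), r0) if r0.ndim > 1 \
        else np.cross(q, r0)
    if not np.any(qxr0):
        return np.zeros(np.broadcast_shapes(r.shape, r0.shape))
    rn = np.linalg.norm(r, axis=-1)
    ar = np.einsum("...i,...i->...", a_vec, r)
    r0r = np.einsum("...i,...i->...", r, np.broadcast_to(r0, r.shape))
    f = a * (rn * a + rn * rn - r0r)
    grad_f = ((a * a / rn + ar / a + 2.0 * a + 2.0 * rn)[..., None] * r
              - (a + 2.0 * rn + ar / a)[..., None] * np.broadcast_to(r0, r.shape))
    dot = np.einsum("...i,...i->...", r, np.broadcast_to(qxr0, r.shape))
    return MU0_OVER_4PI * (f[..., None] * qxr0 - dot[..., None] * grad_f) \
        / (f * f)[..., None]


def lead_field(array: SensorArray, head: HeadModel, pos: np.ndarray,
               moment_orientation: np.ndarray) -> np.ndarray:
    """Sensor response (M values) to a unit current dipole.

    Per coil: Sarvas field projected on the coil normal; gradiometer channel =
    first-coil projection minus second-coil projection.
    """
    pos = np.asarray(pos, dtype=float)
    q = np.asarray(moment_orientation, dtype=float)
    if np.linalg.norm(pos - head.sphere_center) >= head.sphere_radius:
        raise ForwardDomainError("dipole must lie strictly inside the sphere")
    m = array.n_channels
    two_coil = array.n_coils == 2
    if head.channel_centers is None:
        centers = np.broadcast_to(head.sphere_center, (m, 3))
    else:
        centers = head.channel_centers
    # vectorized over coils: first coils of all channels, then second coils
    out = np.zeros(m)
    b1 = _sarvas_b(array.coil_positions[:, 0] - centers, pos - centers, q)
    out += np.einsum("ij,ij->i", b1, array.coil_orientations[:, 0])
    if two_coil.any():
        idx = np.where(two_coil)[0]
        b2 = _sarvas_b(array.coil_positions[idx, 1] - centers[idx],
                       pos - centers[idx], q)
        out[idx] -= np.einsum("ij,ij->i", b2, array.coil_orientations[idx, 1])
    return out


def lead_field_block(array: SensorArray, head: HeadModel,
                     pos: np.ndarray) -> np.ndarray:
    """(M, 3) lead fields for unit dipoles along x, y, z at ``pos``."""
    return np.column_stack([lead_field(array, head, pos, e)
                            for e in np.eye(3)])


def source_layout(n_cortical: int = 78, n_subcortical: int = 12,
                  head_radius: float = DEFAULT_HEAD_RADIUS
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Default 90-ROI centroid layout (positions, tangential orientations,
    labels): cortical points quasi-uniform at radius 0.06-0.075 m, subcortical
    at 0.02-0.045 m.  A user-supplied coordinate table overrides this layout
    in the pipeline.
    """
    units = _fibonacci_cap(n_cortical, np.deg2rad(130.0))
    radii = 0.06 + 0.015 * ((np.arange(n_cortical) * 0.618034) % 1.0)
    cort = units * radii[:, None]
    sub_units = _fibonacci_cap(n_subcortical, np.deg2rad(150.0), rotate=1.3)
    sub_radii = 0.02 + 0.025 * ((np.arange(n_subcortical) * 0.618034) % 1.0)
    sub = sub_units * sub_radii[:, None]
    positions = np.vstack([cort, sub])
    if np.any(np.linalg.norm(positions, axis=1) >= head_radius):
        raise ValueError("source layout must lie inside the head sphere")
    orientations = np.empty_like(positions)
    for i, p in enumerate(positions):
        u = p / np.linalg.norm(p)
        e1, e2 = _tangent_frame(u)
        phi = 2.0 * np.pi * ((i * 0.618034) % 1.0)
        orientations[i] = np.cos(phi) * e1 + np.sin(phi) * e2
    labels = ([f"CTX_{i:02d}" for i in range(n_cortical)]
              + [f"SUB_{i:02d}" for i in range(n_subcortical)])
    return positions, orientations, labels


def gain_matrix(array: SensorArray, head: HeadModel, positions: np.ndarray,
                orientations: np.ndarray) -> np.ndarray:
    """(M, n_sources) forward gain for fixed-orientation dipoles."""
    cols = [lead_field(array, head, p, o)
            for p, o in zip(positions, orientations)]
    return np.column_stack(cols)


def project_to_sensors(src, positions: np.ndarray, orientations: np.ndarray,
                       array: SensorArray, head: HeadModel,
                       noise_std, seed) -> "np.ndarray":
    """Project source activity onto the sensors and add white Gaussian noise.

    ``noise_std`` is an absolute per-channel-kind standard deviation (scalar or
    mapping kind -> std).  Returns the M x T sensor data array; wrapping into a
    :class:`~megretest.cohort.SensorRecording` happens in the cohort driver.
    """
    series = src.series if hasattr(src, "series") else np.asarray(src)
    if len(positions) != series.shape[0]:
        raise ValueError("number of source positions must match source series")
    g = gain_matrix(array, head, positions, orientations)
    data = g @ series
    rng = np.random.default_rng(seed)
    if np.isscalar(noise_std):
        std = np.full(array.n_channels, float(noise_std))
    else:
        std = np.array([float(noise_std[k]) for k in array.kind])
    if np.any(std > 0):
        data = data + std[:, None] * rng.standard_normal(data.shape)
    return data
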