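"""Vectorial dipole-emission forward model.

A fluorophore is treated as an oscillating electric dipole sitting in the
sample medium (index ``n0``, typically water) at height ``z0`` above the
glass coverslip (index ``n1``), and imaged through the glass by an aplanatic
oil-immersion objective of aperture ``NA_obj``.  The far field collected in
the glass is evaluated with the reciprocity method: the amplitude coupled
into a collection direction equals the dipole moment projected on the local
field that a unit plane wave, sent back along that direction, produces at
the emitter.  This automatically carries the Fresnel transmission factors of
the water/glass interface and the super-critical (evanescent-coupled)
components between ``NA = n0`` and ``NA_obj`` that give the bright rim of
the pupil for tilted dipoles.

Two detection arms are modelled downstream of a 50/50 splitter: a low-NA arm
(circular diaphragm at ``NA_low``) split by a Wollaston prism into 0 deg and
90 deg analyzers, and a high-NA arm (``NA_high``) whose polarization is
rotated 45 deg by a half-wave plate before an identical Wollaston split,
yielding effective 45 deg / 135 deg projections.  Because the polarized
image ``I_c(r)`` is quadratic in the dipole amplitude, it is a *linear*
function of the second-order orientational moments
``m = (m_xx, m_yy, m_zz, m_xy, m_xz, m_yz)``; the per-channel basis images
``B_cj(r)`` realise ``I_c(r) = sum_j B_cj(r) m_j``.  Over centered circular
apertures the integrals of the ``xz``/``yz`` basis images vanish, which is
why only four moment components are measurable from integrated intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.signal import czt

__all__ = [
    "OpticalConfig",
    "PupilField",
    "BasisPSFSet",
    "ConfigError",
    "SubCriticalError",
    "GeometryError",
    "CalibrationDegeneracyError",
    "build_pupil_field",
    "basis_psfs",
    "psf_from_moments",
    "collection_fraction",
]

CHANNELS = ("I0", "I90", "I45", "I135")
MOMENT_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


class ConfigError(ValueError):
    """Invalid optical configuration."""


class SubCriticalError(ConfigError):
    """NA_high exceeds the sample index: super-critical light would enter the channels."""


class GeometryError(ValueError):
    """A position falls outside the usable frame geometry."""


class CalibrationDegeneracyError(RuntimeError):
    """The integrated propagation matrix is singular and cannot be inverted."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the four-channel detection path.

    Lengths are in nanometres.  ``z0`` is the emitter height above the
    coverslip (in the sample medium), ``z1`` a defocus term applied as a
    pupil phase.  ``pupil_samples`` is the grid resolution per axis used for
    pupil quadrature; ``oversample`` the sub-pixel rendering factor of the
    camera grid; ``psf_halfwidth_px`` the half width of rendered PSF patches
    in camera pixels.
    """

    n0: float = 1.33
    n1: float = 1.515
    NA_obj: float = 1.45
    NA_low: float = 1.1
    NA_high: float = 1.3
    wavelength_em: float = 609.0
    pixel_size_obj: float = 130.0
    z0: float = 0.0
    z1: float = 0.0
    pupil_samples: int = 256
    oversample: int = 4
    psf_halfwidth_px: int = 15
    # which analyzer pair sits behind the low-NA diaphragm; the instrument
    # default puts (0, 90) at NA_low and (45, 135) at NA_high
    low_na_channels: tuple[str, str] = ("I0", "I90")

    def __post_init__(self) -> None:
        if self.NA_high > self.n0 + 1e-12:
            raise SubCriticalError(
                f"NA_high={self.NA_high} exceeds the sample index n0={self.n0}; "
                "the channels must stay below the critical angle"
            )
        if not (0 < self.NA_low < self.NA_high <= self.NA_obj < self.n1):
            raise ConfigError(
                "apertures must satisfy 0 < NA_low < NA_high <= NA_obj < n1, got "
                f"NA_low={self.NA_low}, NA_high={self.NA_high}, "
                f"NA_obj={self.NA_obj}, n1={self.n1}"
            )
        if self.pixel_size_obj <= 0:
            raise ConfigError("pixel_size_obj must be positive")
        if self.pupil_samples < 64:
            raise ConfigError("pupil_samples must be at least 64")
        if self.oversample < 1 or self.psf_halfwidth_px < 3:
            raise ConfigError("oversample >= 1 and psf_halfwidth_px >= 3 required")
        if set(self.low_na_channels) not in ({"I0", "I90"}, {"I45", "I135"}):
            raise ConfigError("low_na_channels must be an analyzer pair")

    def with_(self, **kwargs) -> "OpticalConfig":
        return replace(self, **kwargs)


@dataclass
class PupilField:
    """Complex two-component (Ex, Ey) pupil field of one unit dipole axis.

    ``ux``/``uy`` are transverse-wavevector coordinates in NA units
    (``n1 sin(theta1)``); the field is zero outside ``mask`` (NA_obj).
    """

    axis: str
    Ex: np.ndarray
    Ey: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    mask: np.ndarray

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.Ex) ** 2 + np.abs(self.Ey) ** 2


def _fresnel_reciprocal(u: np.ndarray, n0: float, n1: float):
    """Angular factors for collection through the glass at NA coordinate ``u``.

    Returns (s0, c0, c1, t_s, t_p) where c0 may be imaginary above the
    critical aperture (u > n0) and t_s/t_p are the Fresnel transmission
    amplitudes for a plane wave incident *from the glass side* — the factors
    that reciprocity attaches to the emitted far field.
    """
    s1 = u / n1
    c1 = np.sqrt(np.clip(1.0 - s1**2, 1e-12, None))
    s0 = u / n0
    c0 = np.emath.sqrt(1.0 - s0.astype(complex) ** 2)
    t_s = 2.0 * n1 * c1 / (n1 * c1 + n0 * c0)
    t_p = 2.0 * n1 * c1 / (n0 * c1 + n1 * c0)
    return s0, c0, c1, t_s, t_p


def _soft_mask(u: np.ndarray, na_cut: float, du: float) -> np.ndarray:
    """Anti-aliased circular aperture: intensity weight in [0, 1]."""
    return np.clip((na_cut - u) / du + 0.5, 0.0, 1.0)


def build_pupil_field(axis: Literal["x", "y", "z"], config: OpticalConfig,
                      aberration_phase: np.ndarray | None = None) -> PupilField:
    """Far-field angular spectrum of a unit dipole along ``axis``.

    Includes the interface Fresnel factors, the evanescent-coupled
    super-critical band (relevant only above ``n0``, i.e. outside the
    detection diaphragms), the ``z0`` standoff phase/decay, a defocus phase
    for ``z1`` and the aplanatic ``1/sqrt(cos theta1)`` apodization.  An
    optional extra pupil phase (radians, same grid) models aberrations.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
    n = config.pupil_samples
    u1 = np.linspace(-config.NA_obj, config.NA_obj, n)
    ux, uy = np.meshgrid(u1, u1)
    u = np.hypot(ux, uy)
    du = u1[1] - u1[0]
    w_obj = _soft_mask(u, config.NA_obj, du)
    inside = w_obj > 0

    us = np.where(inside, u, 0.0)
    s0, c0, c1, t_s, t_p = _fresnel_reciprocal(us, config.n0, config.n1)
    phi = np.arctan2(uy, ux)
    cph, sph = np.cos(phi), np.sin(phi)

    mu = {"x": (1.0, 0.0, 0.0), "y": (0.0, 1.0, 0.0), "z": (0.0, 0.0, 1.0)}[axis]
    mu_rho = mu[0] * cph + mu[1] * sph
    mu_phi = -mu[0] * sph + mu[1] * cph

    Ep = t_p * (c0 * mu_rho - s0 * mu[2])
    Es = t_s * mu_phi

    k0 = 2.0 * np.pi / config.wavelength_em
    phase = np.exp(1j * k0 * config.n0 * c0 * config.z0)
    if config.z1 != 0.0:
        phase = phase * np.exp(1j * k0 * config.n1 * c1 * config.z1)
    if aberration_phase is not None:
        phase = phase * np.exp(1j * aberration_phase)

    apod = np.sqrt(w_obj) / np.sqrt(c1)
    Ex = (Ep * cph - Es * sph) * apod * phase
    Ey = (Ep * sph + Es * cph) * apod * phase
    Ex[~inside] = 0.0
    Ey[~inside] = 0.0
    return PupilField(axis=axis, Ex=Ex, Ey=Ey, ux=ux, uy=uy, mask=inside)


# ---------------------------------------------------------------------------
# basis PSFs and the integrated propagation matrix
# ---------------------------------------------------------------------------

_MOMENT_PAIRS = {
    "xx": ("x", "x"), "yy": ("y", "y"), "zz": ("z", "z"),
    "xy": ("x", "y"), "xz": ("x", "z"), "yz": ("y", "z"),
}


@dataclass
class BasisPSFSet:
    """Per-channel basis images and the integrated propagation matrix.

    ``basis[c]`` has shape (6, H, W) over moment components
    (xx, yy, zz, xy, xz, yz) on the oversampled camera grid of one PSF
    patch.  ``K`` is the 4x4 integrated matrix over the accessible
    components (xx, yy, zz, xy); ``K6`` keeps all six columns.
    ``collection`` maps a 6-moment vector to the total power collected at
    full NA_obj, used to normalise photon counts that are defined before the
    channel split and NA reduction.
    """

    config: OpticalConfig
    basis: dict[str, np.ndarray]
    K: np.ndarray
    K6: np.ndarray
    collection: np.ndarray
    condition_number: float

    @property
    def oversample(self) -> int:
        return self.config.oversample

    @property
    def patch_px(self) -> int:
        return 2 * self.config.psf_halfwidth_px + 1

    def collection_factor(self, m6: np.ndarray) -> np.ndarray:
        """Fraction of NA_obj-collected power reaching the four channels."""
        m6 = np.asarray(m6, float)
        return (m6 @ self.K6.sum(axis=0)) / (m6 @ self.collection)

    def channel_intensities(self, m6: np.ndarray, photons: float) -> np.ndarray:
        """Integrated channel intensities for ``photons`` collected at NA_obj."""
        m6 = np.asarray(m6, float)
        scale = photons / (m6 @ self.collection)
        return np.moveaxis(self.K6 @ np.moveaxis(m6, -1, 0), 0, -1) * scale[..., None] \
            if m6.ndim > 1 else scale * (self.K6 @ m6)


def _czt_axis(field: np.ndarray, du: float, x0: float, dx: float, m: int,
              wavelength: float, axis: int) -> np.ndarray:
    """Chirp-z evaluation of sum_n E_n exp(-2i pi u_n x_k / lambda)."""
    n = field.shape[axis]
    ns = np.arange(n)
    u0 = -du * (n - 1) / 2.0
    pre = np.exp(-2j * np.pi * (ns * du) * x0 / wavelength)
    shape = [1] * field.ndim
    shape[axis] = n
    fw = field * pre.reshape(shape)
    w = np.exp(-2j * np.pi * du * dx / wavelength)
    out = czt(fw, m=m, w=w, a=1.0 + 0.0j, axis=axis)
    ks = np.arange(m)
    post = np.exp(-2j * np.pi * u0 * (x0 + ks * dx) / wavelength)
    shape = [1] * field.ndim
    shape[axis] = m
    return out * post.reshape(shape)


def _image_amplitudes(config: OpticalConfig,
                      aberration_phase: np.ndarray | None = None):
    """Image-plane amplitudes of the three dipole axes in the four channels.

    Returns dict channel -> (3, M, M) complex array on the oversampled patch
    grid (one extra pixel of margin per side for sub-pixel shifting).
    """
    os_, hw = config.oversample, config.psf_halfwidth_px
    npx = 2 * hw + 1
    m = (npx + 2) * os_
    dx = config.pixel_size_obj / os_
    x0 = -dx * (m - 1) / 2.0

    n = config.pupil_samples
    du = 2 * config.NA_obj / (n - 1)
    u1 = np.linspace(-config.NA_obj, config.NA_obj, n)
    ugrid = np.hypot(*np.meshgrid(u1, u1))
    w_low = np.sqrt(_soft_mask(ugrid, config.NA_low, du))
    w_high = np.sqrt(_soft_mask(ugrid, config.NA_high, du))

    fields = {ax: build_pupil_field(ax, config, aberration_phase) for ax in "xyz"}

    low_pair = set(config.low_na_channels)
    arm_of = {c: ("low" if c in low_pair else "high") for c in CHANNELS}
    s2 = 1.0 / np.sqrt(2.0)
    analyzers = {
        "I0": lambda Ex, Ey: Ex,
        "I90": lambda Ex, Ey: Ey,
        "I45": lambda Ex, Ey: s2 * (Ex + Ey),
        "I135": lambda Ex, Ey: s2 * (Ey - Ex),
    }

    out: dict[str, np.ndarray] = {}
    for c in CHANNELS:
        w_arm = w_low if arm_of[c] == "low" else w_high
        amps = np.empty((3, m, m), complex)
        for i, ax in enumerate("xyz"):
            pupil = analyzers[c](fields[ax].Ex, fields[ax].Ey) * w_arm
            g = _czt_axis(pupil, du, x0, dx, m, config.wavelength_em, axis=1)
            g = _czt_axis(g, du, x0, dx, m, config.wavelength_em, axis=0)
            amps[i] = g
        # 50/50 splitter: half the power per arm (amplitude 1/sqrt(2));
        # czt normalisation: du^2/(lambda * dx_image_norm) — absorbed into a
        # single global factor so that Parseval holds on the fine grid
        amps *= s2 * du / config.wavelength_em * dx
        out[c] = amps
    return out, fields


def _pupil_K(config: OpticalConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integrated propagation matrix by direct pupil quadrature (no truncation)."""
    n = config.pupil_samples
    du = 2 * config.NA_obj / (n - 1)
    u1 = np.linspace(-config.NA_obj, config.NA_obj, n)
    ugrid = np.hypot(*np.meshgrid(u1, u1))
    w_low = _soft_mask(ugrid, config.NA_low, du)
    w_high = _soft_mask(ugrid, config.NA_high, du)

    fields = {ax: build_pupil_field(ax, config) for ax in "xyz"}
    low_pair = set(config.low_na_channels)
    s2 = 1.0 / np.sqrt(2.0)
    analyzers = {
        "I0": lambda Ex, Ey: Ex,
        "I90": lambda Ex, Ey: Ey,
        "I45": lambda Ex, Ey: s2 * (Ex + Ey),
        "I135": lambda Ex, Ey: s2 * (Ey - Ex),
    }
    K6 = np.zeros((4, 6))
    for ci, c in enumerate(CHANNELS):
        w_arm = w_low if c in low_pair else w_high
        E = {ax: analyzers[c](fields[ax].Ex, fields[ax].Ey) for ax in "xyz"}
        for ji, comp in enumerate(MOMENT_COMPONENTS):
            a, b = _MOMENT_PAIRS[comp]
            v = float(np.sum((E[a] * np.conj(E[b])).real * w_arm)) * du**2
            K6[ci, ji] = 0.5 * v * (2.0 if a != b else 1.0)
    collection = np.zeros(6)
    for ji, comp in enumerate(MOMENT_COMPONENTS):
        a, b = _MOMENT_PAIRS[comp]
        v = float(np.sum((fields[a].Ex * np.conj(fields[b].Ex)
                          + fields[a].Ey * np.conj(fields[b].Ey)).real)) * du**2
        collection[ji] = v * (2.0 if a != b else 1.0)
    return K6, collection


def basis_psfs(config: OpticalConfig,
               aberration_phase: np.ndarray | None = None) -> BasisPSFSet:
    """Compute the per-channel basis images and the integrated matrix.

    The integrated matrix is evaluated by pupil quadrature (exact to grid
    resolution, free of image-window truncation); the rendered basis images
    of the four accessible components are flux-normalised so that their
    patch integrals reproduce the corresponding matrix entries exactly,
    keeping image rendering and integrated-intensity bookkeeping consistent.
    """
    if aberration_phase is None:
        return _basis_psfs_cached(config)
    return _build_basis(config, aberration_phase)


@lru_cache(maxsize=8)
def _basis_psfs_cached(config: OpticalConfig) -> BasisPSFSet:
    return _build_basis(config, None)


def _build_basis(config: OpticalConfig,
                 aberration_phase: np.ndarray | None) -> BasisPSFSet:
    amps, _ = _image_amplitudes(config, aberration_phase)
    K6, collection = _pupil_K(config)
    basis: dict[str, np.ndarray] = {}
    axis_idx = {"x": 0, "y": 1, "z": 2}
    for c in CHANNELS:
        G = amps[c]
        B = np.empty((6,) + G.shape[1:])
        for ji, comp in enumerate(MOMENT_COMPONENTS):
            a, b = _MOMENT_PAIRS[comp]
            prod = (G[axis_idx[a]] * np.conj(G[axis_idx[b]])).real
            B[ji] = prod * (2.0 if a != b else 1.0)
        basis[c] = B
    # flux normalisation of the accessible components (xx, yy, zz, xy):
    # sub-pixel integral of B must equal K entry (area element absorbed)
    os_ = config.oversample
    npx = 2 * config.psf_halfwidth_px + 1
    win = slice(os_, os_ + npx * os_)  # centred rendering window
    for ci, c in enumerate(CHANNELS):
        # bring the whole channel to physical scale first (fixes the xz/yz
        # components, which integrate to ~zero and cannot be normalised by
        # their own flux) ...
        g = K6[ci, 0] / (basis[c][0].sum() / os_**2)
        basis[c] *= g
        # ... then pin the accessible components' window integrals to the
        # pupil-quadrature matrix exactly, so rendering and <K> bookkeeping
        # agree to machine precision
        ref = abs(K6[ci, 0])
        for ji in range(4):
            s = basis[c][ji][win, win].sum() / os_**2
            if abs(s) > 1e-9 * ref:  # xy column vanishes in the 0/90 arm
                basis[c][ji] *= K6[ci, ji] / s
    K = K6[:, :4].copy()
    try:
        cond = float(np.linalg.cond(K))
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e8:
        raise CalibrationDegeneracyError(
            f"integrated propagation matrix is degenerate (cond={cond:.3g})")
    return BasisPSFSet(config=config, basis=basis, K=K, K6=K6,
                       collection=collection, condition_number=cond)


def render_patch(bset: BasisPSFSet, m6: np.ndarray, photons: float,
                 phase: tuple[int, int] = (0, 0)) -> dict[str, np.ndarray]:
    """Noise-free polarized PSF patches on the camera grid.

    ``phase = (ry, rx)`` with 0 <= r < oversample shifts the molecule to
    patch-pixel position ``halfwidth + r/oversample`` along each axis.
    """
    os_ = bset.oversample
    hw = bset.config.psf_halfwidth_px
    npx = 2 * hw + 1
    ry, rx = phase
    if not (0 <= ry < os_ and 0 <= rx < os_):
        raise GeometryError(f"sub-pixel phase {phase} outside [0, {os_})")
    m6 = np.asarray(m6, float)
    scale = photons / float(m6 @ bset.collection)
    out = {}
    sy, sx = os_ - ry, os_ - rx
    for c in CHANNELS:
        over = np.tensordot(m6, bset.basis[c], axes=(0, 0))
        sub = over[sy:sy + npx * os_, sx:sx + npx * os_]
        img = sub.reshape(npx, os_, npx, os_).sum(axis=(1, 3)) / os_**2
        out[c] = img * scale
    return out


def psf_from_moments(m: np.ndarray, photons: float, config: OpticalConfig,
                     position: tuple[float, float] = (0.0, 0.0),
                     frame_shape: tuple[int, int] | None = None,
                     bset: BasisPSFSet | None = None):
    """Render the four noise-free polarized PSFs of one molecule.

    ``m`` may have 4 (xx, yy, zz, xy) or 6 components; ``position`` is the
    sub-pixel fraction (fy, fx) in [0, 1): the molecule is rendered at patch
    pixel coordinate ``halfwidth + f`` along each axis, quantised to the
    rendering oversampling.  Returns (images, info) where ``info`` reports
    the collection factor (detected / collected-at-NA_obj) and the actually
    rendered sub-pixel position.
    """
    if photons <= 0:
        raise ValueError("photons must be positive")
    m = np.asarray(m, float)
    m6 = np.concatenate([m, np.zeros(6 - m.size)]) if m.size < 6 else m
    if bset is None:
        bset = basis_psfs(config)
    os_ = config.oversample
    fy, fx = position
    if not (0.0 <= fy < 1.0 and 0.0 <= fx < 1.0):
        raise GeometryError(f"sub-pixel position {position} outside [0, 1)")
    if frame_shape is not None:
        hw = config.psf_halfwidth_px
        npy, npx_ = frame_shape
        if hw + 1 > npy or hw + 1 > npx_:
            raise GeometryError(f"patch centre outside frame {frame_shape}")
    ry = int(round(fy * os_)) % os_
    rx = int(round(fx * os_)) % os_
    imgs = render_patch(bset, m6, photons, (ry, rx))
    info = {
        "collection_factor": float(bset.collection_factor(m6)),
        "rendered_position": (ry / os_, rx / os_),
    }
    return imgs, info


# ---------------------------------------------------------------------------
# collection fraction
# ---------------------------------------------------------------------------

def _radiance(u: np.ndarray, config: OpticalConfig, emitter: str) -> np.ndarray:
    s0, c0, c1, t_s, t_p = _fresnel_reciprocal(np.asarray(u, float), config.n0, config.n1)
    k0 = 2.0 * np.pi / config.wavelength_em
    decay = np.exp(-2.0 * k0 * config.n0 * np.abs(c0.imag) * config.z0)
    p2 = np.abs(t_p) ** 2
    s2 = np.abs(t_s) ** 2
    if emitter == "isotropic":
        val = p2 * (np.abs(c0) ** 2 + np.abs(s0) ** 2) + s2
    elif emitter == "transverse":
        val = (p2 * np.abs(c0) ** 2 + s2) / 2.0 * 2.0  # x+y incoherent sum
    elif emitter == "axial":
        val = p2 * np.abs(s0) ** 2
    else:
        raise ValueError(f"unknown emitter model {emitter!r}")
    return val.real * decay / c1


def _emitted_power(config: OpticalConfig, emitter: str) -> float:
    """Total power radiated into both half spaces by the emitter at z0.

    Downward (glass) power from the collection-side radiance; upward (sample
    medium) power from the direct + interface-reflected far field.  Used for
    the ``normalization='emitted'`` variant of :func:`collection_fraction`.
    """
    n0, n1 = config.n0, config.n1
    k0 = 2.0 * np.pi / config.wavelength_em

    down = quad(lambda u: _radiance(np.array([u]), config, emitter)[0] * u,
                0.0, n1 * (1 - 1e-9), limit=400,
                points=[n0] if n1 > n0 else None)[0] / n1**2

    def up_integrand(th0: float) -> float:
        s0, c0 = np.sin(th0), np.cos(th0)
        s1c = (n0 / n1) * s0
        c1c = np.sqrt(1 - s1c**2)  # always real (n1 > n0)
        r_s = (n0 * c0 - n1 * c1c) / (n0 * c0 + n1 * c1c)
        r_p = (n1 * c0 - n0 * c1c) / (n1 * c0 + n0 * c1c)
        ph = np.exp(2j * k0 * n0 * c0 * config.z0)
        # per phi-averaged dipole mixtures
        a_s_x = 0.5 * abs(1 + r_s * ph) ** 2          # s-pol, in-plane dipole
        a_p_x = 0.5 * c0**2 * abs(1 - r_p * ph) ** 2  # p-pol, in-plane dipole
        a_p_z = s0**2 * abs(1 + r_p * ph) ** 2        # p-pol, axial dipole
        if emitter == "isotropic":
            val = 2 * (a_s_x + a_p_x) + a_p_z
        elif emitter == "transverse":
            val = 2 * (a_s_x + a_p_x)
        elif emitter == "axial":
            val = a_p_z
        else:  # pragma: no cover
            raise ValueError(emitter)
        return val * s0

    up = quad(up_integrand, 0.0, np.pi / 2, limit=400)[0]
    return down + up


def collection_fraction(config: OpticalConfig, NA_cut: float,
                        emitter: Literal["isotropic", "transverse", "axial"] = "isotropic",
                        normalization: Literal["objective", "emitted"] = "objective") -> float:
    """Fraction of an emitter's signal collected within ``NA_cut``.

    With ``normalization='objective'`` the reference is the power collected
    at the full objective aperture (including its super-critical band);
    with ``'emitted'`` it is the total power radiated into both half spaces.
    ``emitter='isotropic'`` sums the three dipole axes incoherently;
    ``'transverse'`` models an emitter with no longitudinal dipole component
    (an unpolarized source in the optical sense).
    """
    if NA_cut > config.NA_obj + 1e-12:
        raise ValueError(f"NA_cut={NA_cut} exceeds NA_obj={config.NA_obj}")
    if NA_cut < 0:
        raise ValueError("NA_cut must be non-negative")
    if NA_cut == 0:
        return 0.0

    def power(na: float) -> float:
        pts = [config.n0] if na > config.n0 else None
        return quad(lambda u: _radiance(np.array([u]), config, emitter)[0] * u,
                    0.0, na, limit=400, points=pts)[0] / config.n1**2

    num = power(NA_cut)
    if normalization == "objective":
        den = power(config.NA_obj)
    elif normalization == "emitted":
        den = _emitted_power(config, emitter)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(num / den)
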