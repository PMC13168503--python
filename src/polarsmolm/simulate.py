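"""Monte-Carlo generator of ground-truthed four-channel stacks.

Scenes (molecule positions, orientations, photon budgets) are generated with
a counter-based random generator (Philox) so that a seed fully determines
the data across platforms.  Rendering places noise-free vectorial PSF
patches — linear combinations of the cached basis images weighted by each
molecule's second moments — on the camera grid at sub-pixel positions
quantised to the rendering oversampling (the quantised position is what the
ground-truth table records), then adds background and Poisson/read noise.

The default conditions mirror the validation regime of the method: ten
molecules per 64 x 64-pixel frame, 5000 photons per molecule (defined as
the photons collected at the full objective aperture, before the channel
split and NA reduction), ten background photons per pixel per channel, and
a wobble cone of 100 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import (CHANNELS, BasisPSFSet, GeometryError, OpticalConfig,
                     basis_psfs)
from .orientation import moments6_from_orientation

__all__ = [
    "Scene",
    "NoiseModel",
    "AberrationSpec",
    "PackingError",
    "make_scene_random_orientations",
    "make_scene_sphere_membrane",
    "make_scene_filaments",
    "render_stack",
    "SimulatedStack",
]

TRUTH_COLUMNS = ["molecule_id", "frame", "x_px", "y_px", "x_nm", "y_nm",
                 "eta", "xi", "delta", "photons"]


class PackingError(RuntimeError):
    """Molecule density incompatible with the minimum-separation constraint."""


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel camera noise: Poisson shot noise on signal + background,
    optional Gaussian read noise (electrons, sigma) and gain (counts/photon)."""

    background: float = 10.0
    read_noise: float = 0.0
    gain: float = 1.0
    shot_noise: bool = True

    def __post_init__(self):
        if self.background < 0 or self.read_noise < 0 or self.gain <= 0:
            raise ValueError("background, read_noise >= 0 and gain > 0 required")

    @classmethod
    def zeroed(cls) -> "NoiseModel":
        """No background, no shot or read noise: deterministic render."""
        return cls(background=0.0, read_noise=0.0, shot_noise=False)


@dataclass(frozen=True)
class AberrationSpec:
    """Pupil aberration: Noll-indexed Zernike coefficients (radians RMS),
    starting at Noll j=1 (piston), plus a defocus distance z1 in nm."""

    zernike: tuple[float, ...] = ()
    z1_nm: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.zernike):
            raise ValueError("Zernike coefficients must be finite")


def _noll_to_nm(j: int) -> tuple[int, int]:
    """Noll index -> (n, m) with signed azimuthal order."""
    n = 0
    j1 = j - 1
    while j1 >= n + 1:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    ma = abs(m)
    R = np.zeros_like(rho)
    for k in range((n - ma) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k) * math.factorial((n + ma) // 2 - k)
                * math.factorial((n - ma) // 2 - k)))
        R += c * rho ** (n - 2 * k)
    norm = math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1)
    if m > 0:
        return norm * R * np.cos(ma * theta)
    if m < 0:
        return norm * R * np.sin(ma * theta)
    return norm * R


def aberration_phase(spec: AberrationSpec, config: OpticalConfig) -> np.ndarray | None:
    """Pupil phase map (radians) on the quadrature grid, or None if trivial."""
    if not spec.zernike or not any(spec.zernike):
        return None
    n = config.pupil_samples
    u1 = np.linspace(-config.NA_obj, config.NA_obj, n)
    ux, uy = np.meshgrid(u1, u1)
    rho = np.hypot(ux, uy) / config.NA_obj
    theta = np.arctan2(uy, ux)
    phase = np.zeros_like(rho)
    for i, coeff in enumerate(spec.zernike):
        if coeff:
            nn, mm = _noll_to_nm(i + 1)
            phase += coeff * _zernike(nn, mm, np.clip(rho, 0, 1), theta)
    return phase


@dataclass
class Scene:
    """Ground-truth molecule list plus frame geometry."""

    table: pd.DataFrame
    frame_size: int
    n_frames: int
    kind: str = "custom"

    def __post_init__(self):
        t = self.table
        if len(t):
            if ((t.x_px < 0) | (t.x_px >= self.frame_size)
                    | (t.y_px < 0) | (t.y_px >= self.frame_size)).any():
                raise GeometryError("scene positions outside the frame")
            if ((t.eta < 0) | (t.eta > 90) | (t.delta < 0) | (t.delta > 180)).any():
                raise ValueError("invalid orientation angles in scene")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _sample_positions(rng, n: int, frame_size: int, margin: float,
                      min_separation: float, max_tries: int = 200) -> np.ndarray:
    lo, hi = margin, frame_size - margin
    if hi <= lo:
        raise PackingError("frame too small for the requested margin")
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(max_tries):
            p = rng.uniform(lo, hi, size=2)
            if i == 0 or (np.hypot(*(pos[:i] - p).T) >= min_separation).all():
                pos[i] = p
                break
        else:
            raise PackingError(
                f"could not place molecule {i + 1}/{n} with separation "
                f"{min_separation} px in a {frame_size} px frame")
    return pos


def make_scene_random_orientations(n_molecules: int, n_frames: int,
                                   delta_fixed: float = 100.0,
                                   photons: float = 5000.0,
                                   frame_size: int = 64,
                                   seed: int = 0,
                                   min_separation: float = 8.0,
                                   margin: float = 6.0,
                                   pixel_size: float = 130.0) -> Scene:
    """Random mean orientations, uniform over the upper hemisphere.

    ``n_molecules`` molecules per frame at uniform positions with at least
    ``min_separation`` pixels between molecules of one frame; ``cos(eta)``
    uniform on [0, 1] and ``xi`` uniform on [0, 180); wobble fixed.
    """
    if n_molecules <= 0 or n_frames <= 0 or photons <= 0:
        raise ValueError("n_molecules, n_frames and photons must be positive")
    rng = _rng(seed)
    rows = []
    mid = 0
    for f in range(n_frames):
        pos = _sample_positions(rng, n_molecules, frame_size, margin, min_separation)
        eta = np.degrees(np.arccos(rng.uniform(0.0, 1.0, n_molecules)))
        xi = rng.uniform(0.0, 180.0, n_molecules)
        for i in range(n_molecules):
            rows.append((mid, f, pos[i, 1], pos[i, 0], eta[i], xi[i]))
            mid += 1
    t = pd.DataFrame(rows, columns=["molecule_id", "frame", "x_px", "y_px",
                                    "eta", "xi"])
    t["delta"] = float(delta_fixed)
    t["photons"] = float(photons)
    t["x_nm"] = t.x_px * pixel_size
    t["y_nm"] = t.y_px * pixel_size
    return Scene(t, frame_size, n_frames, kind="random_orientations")


def make_scene_sphere_membrane(radius_nm: float, n_planes: int = 5,
                               label_tilt_deg: float = 0.0,
                               wobble: float = 100.0,
                               density: float = 20.0,
                               seed: int = 0,
                               photons: float = 5000.0,
                               frame_size: int = 64,
                               pixel_size: float = 130.0,
                               plane_span_nm: float | None = None,
                               molecules_per_frame: int = 10) -> Scene:
    """Membrane-coated sphere: dipoles along the local outward normal.

    Imaging planes slice the sphere at heights from the bottom contact point
    up to ``plane_span_nm`` (default min(600 nm, radius)); each plane
    contributes a ring of molecules with ``density`` molecules per um of
    circumference (at least 8 per plane).  The label may be tilted away from
    the normal by ``label_tilt_deg`` with uniform random azimuth.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    span = min(600.0, radius_nm) if plane_span_nm is None else plane_span_nm
    if span > radius_nm:
        raise GeometryError("imaging plane above the sphere equator")
    rng = _rng(seed)
    cx = cy = frame_size / 2.0 * pixel_size
    rows = []
    mid = 0
    heights = np.linspace(0.0, span, n_planes)
    for pi, z in enumerate(heights):
        ring_r = math.sqrt(max(radius_nm**2 - (radius_nm - z) ** 2, 0.0))
        n_mol = max(8, int(round(density * 2 * math.pi * ring_r / 1000.0)))
        psi = rng.uniform(0.0, 2 * math.pi, n_mol)
        for p in psi:
            normal = np.array([ring_r * math.cos(p), ring_r * math.sin(p),
                               z - radius_nm]) / radius_nm
            if normal[2] > 0:  # orient outward-down consistently; dipole is a line
                normal = -normal
            u = _tilt_direction(rng, -normal, label_tilt_deg)
            eta, xi = _angles_from_direction(u)
            x = cx + ring_r * math.cos(p)
            y = cy + ring_r * math.sin(p)
            rows.append((mid, x / pixel_size, y / pixel_size, eta, xi, pi, z))
            mid += 1
    t = pd.DataFrame(rows, columns=["molecule_id", "x_px", "y_px", "eta", "xi",
                                    "plane", "plane_z_nm"])
    t = t[(t.x_px > 1) & (t.x_px < frame_size - 1)
          & (t.y_px > 1) & (t.y_px < frame_size - 1)].reset_index(drop=True)
    t["molecule_id"] = np.arange(len(t))
    t["frame"] = np.arange(len(t)) // molecules_per_frame
    t["delta"] = float(wobble)
    t["photons"] = float(photons)
    t["x_nm"] = t.x_px * pixel_size
    t["y_nm"] = t.y_px * pixel_size
    n_frames = int(t.frame.max()) + 1 if len(t) else 1
    return Scene(t, frame_size, n_frames, kind="sphere_membrane")


def make_scene_filaments(segments, label_offset_deg: float = 20.0,
                         wobble: float = 100.0, density: float = 30.0,
                         seed: int = 0, photons: float = 5000.0,
                         frame_size: int = 64, pixel_size: float = 130.0,
                         molecules_per_frame: int = 10) -> Scene:
    """Molecules along 3D line segments, dipole tilted off the filament axis.

    ``segments``: iterable of (x0, y0, z0, x1, y1, z1) in nm (2D four-tuples
    are accepted with z = 0).  ``density``: molecules per um of filament.
    The label dipole sits at ``label_offset_deg`` from the local axis with a
    uniformly random azimuth about it.
    """
    segments = [tuple(s) for s in segments]
    if not segments:
        raise ValueError("empty segment list")
    rng = _rng(seed)
    rows = []
    mid = 0
    for fi, seg in enumerate(segments):
        if len(seg) == 4:
            x0, y0, x1, y1 = seg
            z0 = z1 = 0.0
        else:
            x0, y0, z0, x1, y1, z1 = seg
        a = np.array([x0, y0, z0])
        b = np.array([x1, y1, z1])
        length = float(np.linalg.norm(b - a))
        if length == 0:
            raise ValueError(f"degenerate segment {seg}")
        axis = (b - a) / length
        n_mol = max(2, int(round(density * length / 1000.0)))
        ts = rng.uniform(0.0, 1.0, n_mol)
        for tpar in ts:
            p = a + tpar * (b - a)
            u = _tilt_direction(rng, axis, label_offset_deg)
            eta, xi = _angles_from_direction(u)
            rows.append((mid, p[0] / pixel_size, p[1] / pixel_size, eta, xi, fi))
            mid += 1
    t = pd.DataFrame(rows, columns=["molecule_id", "x_px", "y_px", "eta", "xi",
                                    "filament"])
    if ((t.x_px < 0) | (t.x_px >= frame_size)
            | (t.y_px < 0) | (t.y_px >= frame_size)).any():
        raise GeometryError("filament segments extend outside the frame")
    t["frame"] = np.arange(len(t)) // molecules_per_frame
    t["delta"] = float(wobble)
    t["photons"] = float(photons)
    t["x_nm"] = t.x_px * pixel_size
    t["y_nm"] = t.y_px * pixel_size
    n_frames = int(t.frame.max()) + 1 if len(t) else 1
    return Scene(t, frame_size, n_frames, kind="filaments")


def _tilt_direction(rng, axis: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Unit vector at ``tilt_deg`` from ``axis`` with random azimuth."""
    axis = axis / np.linalg.norm(axis)
    if tilt_deg == 0.0:
        return axis
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = math.radians(tilt_deg)
    phi = rng.uniform(0.0, 2 * math.pi)
    return (math.cos(t) * axis
            + math.sin(t) * (math.cos(phi) * e1 + math.sin(phi) * e2))


def _angles_from_direction(u: np.ndarray) -> tuple[float, float]:
    """(eta, xi) in degrees from a dipole direction (sign-folded)."""
    if u[2] < 0:
        u = -u
    eta = math.degrees(math.acos(np.clip(u[2], -1.0, 1.0)))
    xi = math.degrees(math.atan2(u[1], u[0])) % 180.0
    return eta, xi


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStack:
    """Rendered stack: per-channel image arrays, quadrant frames, and the
    ground-truth table with positions as actually rendered."""

    channels: dict[str, np.ndarray]
    truth: pd.DataFrame
    config: OpticalConfig
    noise: NoiseModel
    seed: int | None
    kind: str = ""

    @property
    def quadrant_frames(self) -> np.ndarray:
        """(n_frames, 2H, 2W) camera-layout frames: I0 | I90 / I45 | I135."""
        c = self.channels
        top = np.concatenate([c["I0"], c["I90"]], axis=2)
        bot = np.concatenate([c["I45"], c["I135"]], axis=2)
        return np.concatenate([top, bot], axis=1)


def _phase_table(bset: BasisPSFSet) -> np.ndarray:
    """Pre-binned basis patches for every sub-pixel phase.

    Shape (os, os, 4, 6, npx, npx): phase (ry, rx) places the molecule at
    patch pixel (hw + ry/os, hw + rx/os).
    """
    os_ = bset.oversample
    hw = bset.config.psf_halfwidth_px
    npx = 2 * hw + 1
    out = np.empty((os_, os_, 4, 6, npx, npx))
    for ry in range(os_):
        for rx in range(os_):
            sy, sx = os_ - ry, os_ - rx
            for ci, c in enumerate(CHANNELS):
                sub = bset.basis[c][:, sy:sy + npx * os_, sx:sx + npx * os_]
                out[ry, rx, ci] = (sub.reshape(6, npx, os_, npx, os_)
                                   .sum(axis=(2, 4)) / os_**2)
    return out


_PHASE_CACHE: dict = {}


def _get_phase_table(bset: BasisPSFSet, key) -> np.ndarray:
    tab = _PHASE_CACHE.get(key)
    if tab is None:
        tab = _phase_table(bset)
        if len(_PHASE_CACHE) >= 2:
            _PHASE_CACHE.clear()
        _PHASE_CACHE[key] = tab
    return tab


def render_stack(scene: Scene, config: OpticalConfig | None = None,
                 noise: NoiseModel | None = None,
                 aberration: AberrationSpec | None = None,
                 seed: int | None = 0) -> SimulatedStack:
    """Render the four-channel stack of a scene.

    Each molecule's sub-pixel position is quantised to the rendering
    oversampling; the truth table of the returned stack records the
    *rendered* positions.  With ``seed=None`` (or a zeroed noise model) the
    noise-free expectation images are returned.
    """
    config = config or OpticalConfig()
    noise = noise or NoiseModel()
    ab_phase = None
    if aberration is not None:
        if aberration.z1_nm:
            config = config.with_(z1=aberration.z1_nm)
        ab_phase = aberration_phase(aberration, config)
    bset = basis_psfs(config, ab_phase)
    table = _get_phase_table(bset, (config, aberration))

    os_ = config.oversample
    hw = config.psf_halfwidth_px
    npx = 2 * hw + 1
    H = W = scene.frame_size
    n_frames = scene.n_frames
    stacks = {c: np.zeros((n_frames, H, W)) for c in CHANNELS}

    t = scene.truth if hasattr(scene, "truth") else scene.table
    t = t.copy()
    m6 = moments6_from_orientation(t.eta.values, t.xi.values, t.delta.values)
    coll = bset.collection
    scales = t.photons.values / (m6 @ coll)

    x_r = np.empty(len(t))
    y_r = np.empty(len(t))
    for i in range(len(t)):
        fr = int(t.frame.values[i])
        for coord, arr in (("x_px", x_r), ("y_px", y_r)):
            v = float(t[coord].values[i])
            px = math.floor(v)
            r = int(round((v - px) * os_))
            if r == os_:
                px, r = px + 1, 0
            arr[i] = px + r / os_
        px_x = int(math.floor(x_r[i]))
        px_y = int(math.floor(y_r[i]))
        rx = int(round((x_r[i] - px_x) * os_))
        ry = int(round((y_r[i] - px_y) * os_))
        patch = np.tensordot(m6[i], table[ry % os_, rx % os_], axes=(0, 1)) * scales[i]
        y0, x0 = px_y - hw, px_x - hw
        ys, xs = max(0, -y0), max(0, -x0)
        ye = npx - max(0, y0 + npx - H)
        xe = npx - max(0, x0 + npx - W)
        if ys >= ye or xs >= xe:
            continue
        for ci, c in enumerate(CHANNELS):
            stacks[c][fr, y0 + ys:y0 + ye, x0 + xs:x0 + xe] += patch[ci, ys:ye, xs:xe]

    t["x_px"] = x_r
    t["y_px"] = y_r
    t["x_nm"] = x_r * config.pixel_size_obj
    t["y_nm"] = y_r * config.pixel_size_obj
    t["collection_factor"] = bset.collection_factor(m6)

    if noise.background:
        for c in CHANNELS:
            stacks[c] += noise.background
    if seed is not None and (noise.shot_noise or noise.read_noise):
        rng = _rng(seed)
        for c in CHANNELS:
            if noise.shot_noise:
                lam = np.clip(stacks[c], 0.0, None)
                stacks[c] = rng.poisson(lam).astype(float)
            if noise.read_noise:
                stacks[c] += rng.normal(0.0, noise.read_noise, stacks[c].shape)
            stacks[c] *= noise.gain
    return SimulatedStack(channels=stacks, truth=t, config=config, noise=noise,
                          seed=seed, kind=scene.kind)
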