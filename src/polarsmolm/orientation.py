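"""Orientation/wobble <-> second-moment mapping and the intensity inversion.

A molecule's emission dipole wobbles uniformly (in solid angle) inside a
cone of full apex angle ``delta`` about a mean direction
``u = (sin eta cos xi, sin eta sin xi, cos eta)``, where ``eta`` is the
polar angle from the optical axis (eta = 0 is vertical/off-plane, 90 is
in-plane) and ``xi`` the in-plane azimuth modulo 180 deg.  Averaging the
dyadic ``mu mu^T`` over the cone gives

    m = gamma(delta) * u u^T + (1 - gamma(delta)) / 3 * I,

with the cone order parameter ``gamma = c (1 + c) / 2``, ``c = cos(delta/2)``
(from the cone-frame axial moment ``(1 + c + c^2)/3``).  The instrument
measures the four integrated intensities ``I = <K> m`` over the accessible
components (xx, yy, zz, xy); inverting and renormalising to unit trace
recovers ``m``, from which (eta, xi, delta) follow in closed form.
Degenerate situations (vertical dipole, isotropic wobble) leave ``xi``
undefined and are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Orientation",
    "SecondMoments",
    "PolarizedIntensities",
    "RatiometricObservables",
    "cone_order_parameter",
    "wobble_from_order_parameter",
    "moments_from_orientation",
    "moments6_from_orientation",
    "invert_intensities",
    "orientation_from_moments",
    "ratiometric_observables",
    "EmptySignalError",
    "CalibrationError",
]

# flag bits used across the pipeline
FLAG_XI_ILL_DEFINED = 1
FLAG_CLIPPED = 2
FLAG_REFINED = 4


class EmptySignalError(ValueError):
    """All four channel intensities are zero (or negative input)."""


class CalibrationError(RuntimeError):
    """Calibration matrix unusable (singular)."""


@dataclass(frozen=True)
class Orientation:
    """Mean-orientation angles in degrees: eta in [0, 90], xi in [0, 180),
    delta in [0, 180]."""

    eta: float
    xi: float
    delta: float

    def __post_init__(self):
        if not (0.0 <= self.eta <= 90.0):
            raise ValueError(f"eta={self.eta} outside [0, 90]")
        if not (0.0 <= self.xi < 180.0):
            raise ValueError(f"xi={self.xi} outside [0, 180)")
        if not (0.0 <= self.delta <= 180.0):
            raise ValueError(f"delta={self.delta} outside [0, 180]")

    @property
    def xi_ill_defined(self) -> bool:
        return self.eta == 0.0 or self.delta == 180.0


@dataclass(frozen=True)
class SecondMoments:
    m_xx: float
    m_yy: float
    m_zz: float
    m_xy: float

    def __post_init__(self):
        if min(self.m_xx, self.m_yy, self.m_zz) < -1e-9:
            raise ValueError("diagonal moments must be non-negative")
        tr = self.m_xx + self.m_yy + self.m_zz
        if abs(tr - 1.0) > 1e-6:
            raise ValueError(f"trace {tr} != 1")
        if self.m_xy**2 > self.m_xx * self.m_yy + 1e-9:
            raise ValueError("m_xy^2 exceeds m_xx * m_yy")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_xx, self.m_yy, self.m_zz, self.m_xy])


@dataclass(frozen=True)
class PolarizedIntensities:
    I0: float
    I90: float
    I45: float
    I135: float

    def __post_init__(self):
        if min(self.I0, self.I90, self.I45, self.I135) < 0:
            raise ValueError("intensities must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.I0, self.I90, self.I45, self.I135])

    @property
    def total(self) -> float:
        return self.I0 + self.I90 + self.I45 + self.I135


@dataclass(frozen=True)
class RatiometricObservables:
    """Stokes-like polarization ratios and the NA-arm ratio."""

    P0: float
    P45: float
    R_NA: float
    valid: bool = True


def cone_order_parameter(delta):
    """Order parameter gamma(delta) of uniform wobble in a cone of full apex
    angle delta (degrees); strictly decreasing from 1 (fixed) to 0 (isotropic)."""
    c = np.cos(np.deg2rad(np.asarray(delta, float)) / 2.0)
    return c * (1.0 + c) / 2.0


def wobble_from_order_parameter(gamma):
    """Inverse of :func:`cone_order_parameter` (degrees)."""
    g = np.clip(np.asarray(gamma, float), 0.0, 1.0)
    c = (-1.0 + np.sqrt(1.0 + 8.0 * g)) / 2.0
    return np.rad2deg(2.0 * np.arccos(np.clip(c, -1.0, 1.0)))


def moments6_from_orientation(eta, xi, delta) -> np.ndarray:
    """All six second moments (xx, yy, zz, xy, xz, yz); angles in degrees.

    Broadcasts; output has shape (..., 6).
    """
    e = np.deg2rad(np.asarray(eta, float))
    x = np.deg2rad(np.asarray(xi, float))
    g = cone_order_parameter(delta)
    e, x, g = np.broadcast_arrays(e, x, g)
    ux = np.sin(e) * np.cos(x)
    uy = np.sin(e) * np.sin(x)
    uz = np.cos(e)
    iso = (1.0 - g) / 3.0
    return np.stack([
        g * ux**2 + iso,
        g * uy**2 + iso,
        g * uz**2 + iso,
        g * ux * uy,
        g * ux * uz,
        g * uy * uz,
    ], axis=-1)


def moments_from_orientation(omega, xi=None, delta=None) -> np.ndarray:
    """Accessible second moments (xx, yy, zz, xy) of one or many molecules.

    Accepts an :class:`Orientation` or (eta, xi, delta) arrays in degrees.
    """
    if isinstance(omega, Orientation):
        eta, xi, delta = omega.eta, omega.xi, omega.delta
    else:
        eta = omega
    return moments6_from_orientation(eta, xi, delta)[..., :4]


def _clip_moments(m4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project raw inverted moments into the physical set.

    Non-negative diagonal, unit trace, |m_xy| <= sqrt(m_xx m_yy).  Returns
    (clipped, was_clipped).  The projection never moves a point that is
    already physical.
    """
    m = np.array(m4, float, copy=True)
    clipped = np.zeros(m.shape[:-1], dtype=bool)

    neg = m[..., :3] < 0
    clipped |= neg.any(axis=-1)
    m[..., :3] = np.clip(m[..., :3], 0.0, None)

    tr = m[..., :3].sum(axis=-1)
    bad = tr <= 0
    # pathological all-zero diagonal: fall back to isotropic
    if np.any(bad):
        m[bad, 0] = m[bad, 1] = m[bad, 2] = 1.0 / 3.0
        m[bad, 3] = 0.0
        clipped |= bad
        tr = m[..., :3].sum(axis=-1)
    m = m / tr[..., None]

    lim = np.sqrt(m[..., 0] * m[..., 1])
    over = np.abs(m[..., 3]) > lim
    clipped |= over
    m[..., 3] = np.clip(m[..., 3], -lim, lim)
    return m, clipped


def invert_intensities(I, Kbar, renormalize: bool = True):
    """Second moments from integrated intensities: ``m = Kbar^-1 I``.

    ``I``: shape (..., 4) photon counts (or a PolarizedIntensities);
    ``Kbar``: the 4x4 integrated calibration matrix.  Returns a dict with
    the trace-normalised, clipped moments ``m`` (..., 4), the raw pre-clip
    solution ``m_raw``, and boolean ``clipped`` flags.  Overall intensity
    scale is irrelevant after trace normalisation, so calibration matrices
    are only needed up to a factor.
    """
    if isinstance(I, PolarizedIntensities):
        I = I.as_array()
    I = np.asarray(I, float)
    if np.any(I < 0):
        raise ValueError("negative channel intensity")
    if I.ndim == 1 and I.sum() == 0:
        raise EmptySignalError("all four intensities are zero")
    Kbar = np.asarray(Kbar, float)
    if Kbar.shape != (4, 4):
        raise CalibrationError(f"calibration matrix must be 4x4, got {Kbar.shape}")
    cond = np.linalg.cond(Kbar)
    if not np.isfinite(cond) or cond > 1e10:
        raise CalibrationError(f"calibration matrix is singular (cond={cond:.3g})")
    Kinv = np.linalg.inv(Kbar)
    m_raw = I @ Kinv.T
    if renormalize:
        tr = m_raw[..., :3].sum(axis=-1)
        safe = np.where(np.abs(tr) > 1e-300, tr, 1.0)
        m_norm = m_raw / safe[..., None]
        m_norm = np.where((tr <= 0)[..., None],
                          np.array([1 / 3, 1 / 3, 1 / 3, 0.0]), m_norm)
    else:
        m_norm = m_raw
    m, clipped = _clip_moments(m_norm)
    empty = I.sum(axis=-1) == 0
    return {"m": m, "m_raw": m_raw, "clipped": clipped | empty, "empty": empty}


def _analytic_inversion(m4: np.ndarray):
    """Closed-form (eta, xi, delta) from physical moments; vectorised."""
    mxx, myy, mzz, mxy = (m4[..., i] for i in range(4))
    xi = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    xi = np.mod(xi, 180.0)
    a_in = np.sqrt((mxx - myy) ** 2 + 4.0 * mxy**2)
    gamma_hat = (3.0 * (a_in + mzz) - 1.0) / 2.0
    iso = (np.abs(gamma_hat) <= 1e-9) & (a_in <= 1e-9)  # exact isotropic limit
    ok = gamma_hat > 1e-12
    ratio = np.where(ok, a_in / np.where(ok, gamma_hat, 1.0), 0.0)
    bad = (~iso) & (~ok | (ratio > 1.0 + 1e-9) | (gamma_hat > 1.0 + 1e-9))
    eta = np.degrees(np.arcsin(np.sqrt(np.clip(ratio, 0.0, 1.0))))
    delta = wobble_from_order_parameter(np.clip(gamma_hat, 0.0, 1.0))
    return eta, xi, delta, gamma_hat, bad


def _refine_one(m4: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Bounded least squares of (eta, xi, delta) against the moment model."""

    def resid(th):
        return moments6_from_orientation(th[0], th[1], th[2])[:4] - m4

    res = least_squares(resid, np.clip(start, [1e-3, 0.0, 1e-3],
                                       [89.999, 179.999, 179.999]),
                        bounds=([0.0, -1.0, 0.0], [90.0, 181.0, 180.0]),
                        xtol=1e-12, ftol=1e-12, max_nfev=200)
    th = res.x
    th[1] = np.mod(th[1], 180.0)
    return th


def orientation_from_moments(m4, refine: bool = False):
    """Retrieve (eta, xi, delta) and quality flags from second moments.

    Closed-form inversion; records whose analytic solution leaves the model
    manifold (order parameter <= 0 or sin^2 eta argument > 1) are refit by
    bounded least squares from the clipped analytic start and flagged
    ``refined``.  With ``refine=True`` every record is re-minimised from the
    analytic start.  Returns dict of arrays eta, xi, delta (degrees) and
    flags (bit mask: 1 = xi ill-defined, 4 = refined).
    """
    m4 = np.asarray(m4, float)
    single = m4.ndim == 1
    m = np.atleast_2d(m4)
    eta, xi, delta, gamma_hat, bad = _analytic_inversion(m)

    flags = np.zeros(m.shape[0], dtype=np.int64)
    # xi undefined: in-plane anisotropy numerically zero
    a_in = np.sqrt((m[:, 0] - m[:, 1]) ** 2 + 4.0 * m[:, 3] ** 2)
    ill = (a_in < 1e-9) | (gamma_hat < 1e-9) | (eta < 1e-6) | (delta > 180.0 - 1e-6)
    flags[ill] |= FLAG_XI_ILL_DEFINED
    xi = np.where(a_in < 1e-9, 0.0, xi)

    todo = np.nonzero(bad | refine)[0]
    for i in todo:
        th = _refine_one(m[i], np.array([eta[i], xi[i], delta[i]]))
        eta[i], xi[i], delta[i] = th
        flags[i] |= FLAG_REFINED

    out = {"eta": eta, "xi": xi, "delta": delta, "flags": flags}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def orientation_from_intensities(I, Kbar, background_total_per_channel: float = 0.0,
                                 start=None):
    """Weighted least-squares retrieval directly in intensity space.

    Minimises ``sum_c (s K m(theta) - I)_c^2 / (I_c + B_c)`` over
    (eta, xi, delta) with the overall scale ``s`` profiled out analytically
    — a Gaussian approximation to the Poisson maximum-likelihood estimator
    on the four integrated intensities.  Starts from the closed-form
    inversion (or ``start``).  Vectorised over rows of ``I``.

    Returns dict of arrays eta, xi, delta, scale, flags.
    """
    I = np.atleast_2d(np.asarray(I, float))
    Kbar = np.asarray(Kbar, float)
    n = I.shape[0]
    Bc = background_total_per_channel
    if start is None:
        inv = invert_intensities(I, Kbar)
        start = orientation_from_moments(inv["m"])
        st = np.column_stack([np.atleast_1d(start["eta"]),
                              np.atleast_1d(start["xi"]),
                              np.atleast_1d(start["delta"])])
        flags0 = np.atleast_1d(start["flags"])
    else:
        st = np.atleast_2d(np.asarray(start, float))
        flags0 = np.zeros(n, dtype=np.int64)

    eta = np.empty(n)
    xi = np.empty(n)
    delta = np.empty(n)
    scale = np.empty(n)
    flags = flags0.copy()

    for i in range(n):
        w = 1.0 / np.sqrt(np.clip(I[i] + Bc, 1.0, None))

        def resid(th):
            m = moments6_from_orientation(th[0], th[1], th[2])[:4]
            f = Kbar @ m
            s = (w**2 * f * I[i]).sum() / max((w**2 * f * f).sum(), 1e-300)
            return (s * f - I[i]) * w

        x0 = np.clip(st[i], [0.5, 0.0, 0.5], [89.5, 179.999, 179.5])
        res = least_squares(resid, x0,
                            bounds=([0.0, -45.0, 0.0], [90.0, 225.0, 180.0]),
                            xtol=1e-10, ftol=1e-10, max_nfev=120)
        eta[i], xi[i], delta[i] = res.x
        xi[i] = np.mod(xi[i], 180.0)
        m = moments6_from_orientation(eta[i], xi[i], delta[i])[:4]
        f = Kbar @ m
        scale[i] = (w**2 * f * I[i]).sum() / max((w**2 * f * f).sum(), 1e-300)
        flags[i] |= FLAG_REFINED
    return {"eta": eta, "xi": xi, "delta": delta, "scale": scale,
            "flags": flags}


def ratiometric_observables(I):
    """Stokes-like ratios P0, P45 and the NA-arm ratio R_NA.

    P0 = (I0 - I90)/(I0 + I90), P45 = (I45 - I135)/(I45 + I135),
    R_NA = (I0 + I90)/(I45 + I135).  Zero denominators mark the record
    invalid (NaN observables) rather than raising, so streams keep flowing.
    """
    if isinstance(I, PolarizedIntensities):
        I = I.as_array()
    I = np.asarray(I, float)
    low = I[..., 0] + I[..., 1]
    high = I[..., 2] + I[..., 3]
    valid = (low > 0) & (high > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        P0 = np.where(low > 0, (I[..., 0] - I[..., 1]) / low, np.nan)
        P45 = np.where(high > 0, (I[..., 2] - I[..., 3]) / high, np.nan)
        R = np.where(high > 0, low / high, np.nan)
    if I.ndim == 1:
        return RatiometricObservables(float(P0), float(P45), float(R), bool(valid))
    return {"P0": P0, "P45": P45, "R_NA": R, "valid": valid}
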