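"""Fisher information and Cramer-Rao lower bounds for (eta, xi, delta).

The estimator operates on the four integrated channel intensities, so the
relevant information is that of a four-point Poisson measurement:

    FIM_ij = sum_c (dI_c/dtheta_i)(dI_c/dtheta_j) / (I_c + B_c),

with B_c the background photons aggregated over the intensity-estimation
footprint of one channel.  The intensity model is the forward chain
``I(theta) = N * K6 m6(theta) / (C . m6(theta))`` where ``C`` normalises the
photon budget N to the power collected at the full objective aperture
(before the channel split and NA reduction), matching how the photon count
of a molecule is defined in the simulations.

Bounds are reported in degrees.  Parameters that are ill-defined at a grid
point (e.g. xi for an isotropic wobble) yield a singular Fisher matrix; the
corresponding bound is returned as infinity with a flag rather than raising.

The default background aggregation uses the effective Gaussian PSF
footprint (4 pi sigma_psf^2 pixels); aggregation over the full search
window is available via ``background_mode='window'``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .optics import BasisPSFSet, OpticalConfig, basis_psfs
from .orientation import cone_order_parameter, moments6_from_orientation

__all__ = [
    "background_per_channel",
    "intensity_jacobian",
    "crlb_orientation",
    "crlb_map",
]


def background_per_channel(bg_per_pixel: float, psf_radius_px: float = 1.3,
                           mode: str = "psf_area", window: int = 11) -> float:
    """Background photons entering one integrated channel intensity.

    ``mode='psf_area'``: the effective Gaussian footprint 4 pi sigma^2
    pixels (the area over which a weighted intensity estimate accumulates
    background); ``mode='window'``: the full ``window x window`` box.
    """
    if mode == "psf_area":
        return float(bg_per_pixel * 4.0 * np.pi * psf_radius_px**2)
    if mode == "window":
        return float(bg_per_pixel * window * window)
    raise ValueError(f"unknown background mode {mode!r}")


def _dm6_domega(eta: float, xi: float, delta: float) -> np.ndarray:
    """Analytic derivative of the six moments w.r.t. (eta, xi, delta) in
    degrees^-1; shape (6, 3)."""
    e, x = np.deg2rad(eta), np.deg2rad(xi)
    g = float(cone_order_parameter(delta))
    c = np.cos(np.deg2rad(delta) / 2.0)
    # dgamma/ddelta in rad^-1 of delta: gamma = c(1+c)/2, dc/ddelta = -sin(delta/2)/2
    dg_ddelta = (1.0 + 2.0 * c) / 2.0 * (-np.sin(np.deg2rad(delta) / 2.0) / 2.0)
    se, ce = np.sin(e), np.cos(e)
    sx, cx = np.sin(x), np.cos(x)
    u = np.array([se * cx, se * sx, ce])
    du_de = np.array([ce * cx, ce * sx, -se])
    du_dx = np.array([-se * sx, se * cx, 0.0])

    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    D = np.zeros((6, 3))
    for r, (i, j) in enumerate(pairs):
        uu = u[i] * u[j]
        duu_de = du_de[i] * u[j] + u[i] * du_de[j]
        duu_dx = du_dx[i] * u[j] + u[i] * du_dx[j]
        D[r, 0] = g * duu_de
        D[r, 1] = g * duu_dx
        D[r, 2] = dg_ddelta * (uu - (1.0 / 3.0 if i == j else 0.0))
    return D * np.pi / 180.0  # per degree


def intensity_jacobian(omega, model, photons: float = 5000.0) -> np.ndarray:
    """4x3 derivative matrix dI_c/d(eta, xi, delta) (photons per degree).

    ``model`` is either a :class:`BasisPSFSet` / :class:`OpticalConfig`
    (full forward model with orientation-dependent collection
    normalisation) or a plain 4x4 calibration matrix (then
    ``I = N * Kbar m4`` and the collection factor is constant).
    """
    eta, xi, delta = (omega.eta, omega.xi, omega.delta) \
        if hasattr(omega, "eta") else omega
    D = _dm6_domega(eta, xi, delta)
    m6 = moments6_from_orientation(eta, xi, delta)
    if isinstance(model, OpticalConfig):
        model = basis_psfs(model)
    if isinstance(model, BasisPSFSet):
        K6, C = model.K6, model.collection
        denom = float(m6 @ C)
        I = K6 @ m6
        # d/dtheta [N K m / (C.m)] = N [K dm (C.m) - (K m)(C.dm)] / (C.m)^2
        J = photons * (K6 @ D * denom - np.outer(I, C @ D)) / denom**2
    else:
        # plain calibration matrix: photons = total detected over the four
        # channels, so a global gain on Kbar cancels exactly
        Kbar = np.asarray(model, float)
        ones = np.ones(4)
        f = Kbar @ m6[:4]
        tot = float(ones @ f)
        df = Kbar @ D[:4]
        J = photons * (df * tot - np.outer(f, ones @ df)) / tot**2
    return J


def _intensities(omega, model, photons: float) -> np.ndarray:
    eta, xi, delta = omega
    m6 = moments6_from_orientation(eta, xi, delta)
    if isinstance(model, BasisPSFSet):
        return model.channel_intensities(m6, photons)
    Kbar = np.asarray(model, float)
    f = Kbar @ m6[:4]
    return photons * f / f.sum()


def crlb_orientation(omega, model, photons: float = 5000.0,
                     background_total_per_channel: float = 0.0,
                     unknown_scale: bool = False):
    """Per-parameter CRLB standard deviations (degrees) at one orientation.

    With ``unknown_scale=True`` the per-molecule photon budget is treated
    as a nuisance parameter (as in the actual retrieval, which estimates
    the intensity scale from the same four numbers) and marginalised out of
    the Fisher matrix; the default bounds assume the scale known.

    Returns dict with ``sd_eta``, ``sd_xi``, ``sd_delta``, the Fisher
    matrix, and ``singular`` flag (ill-defined parameters give infinite
    bounds, no exception).
    """
    omega = (omega.eta, omega.xi, omega.delta) if hasattr(omega, "eta") else tuple(omega)
    if isinstance(model, OpticalConfig):
        model = basis_psfs(model)
    J = intensity_jacobian(omega, model, photons)
    I = _intensities(omega, model, photons)
    if unknown_scale:
        J = np.column_stack([J, I / photons])
    w = 1.0 / np.clip(I + background_total_per_channel, 1e-12, None)
    F = J.T @ (J * w[:, None])
    F = 0.5 * (F + F.T)
    if unknown_scale:
        # marginalise the scale: Schur complement of the nuisance block
        Fss = F[3, 3]
        if Fss > 1e-300:
            F = F[:3, :3] - np.outer(F[:3, 3], F[3, :3]) / Fss
        else:
            F = F[:3, :3]
    sd = np.full(3, np.inf)
    singular = False
    try:
        rank = np.linalg.matrix_rank(F, tol=1e-10 * max(np.abs(F).max(), 1e-30))
        if rank < 3:
            singular = True
            # bound the well-defined parameters by pseudo-inverse; a
            # parameter carrying no information at all has infinite bound
            cov = np.linalg.pinv(F)
            d = np.diag(cov)
            sd = np.sqrt(np.clip(d, 0.0, None))
            no_info = np.diag(F) <= 1e-12 * max(np.abs(F).max(), 1e-30)
            sd[no_info | (d > 1e12)] = np.inf
        else:
            cov = np.linalg.inv(F)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        singular = True
    return {"sd_eta": sd[0], "sd_xi": sd[1], "sd_delta": sd[2],
            "fisher": F, "singular": singular}


def crlb_map(etas, xis, deltas, model=None, photons: float = 5000.0,
             bg_per_pixel: float = 0.0, psf_radius_px: float = 1.3,
             background_mode: str = "psf_area", window: int = 11,
             config: OpticalConfig | None = None,
             unknown_scale: bool = False) -> pd.DataFrame:
    """CRLB standard deviations over a grid of (eta, xi, delta).

    Returns a tidy DataFrame with one row per grid point and columns
    ``eta, xi, delta, sd_eta, sd_xi, sd_delta, singular``; summary minima
    and medians are attached in ``df.attrs['summary']``.
    """
    if model is None:
        model = basis_psfs(config or OpticalConfig())
    Bc = background_per_channel(bg_per_pixel, psf_radius_px,
                                background_mode, window)
    rows = []
    for e in np.atleast_1d(etas):
        for x in np.atleast_1d(xis):
            for d in np.atleast_1d(deltas):
                r = crlb_orientation((e, x, d), model, photons, Bc,
                                     unknown_scale=unknown_scale)
                rows.append((e, x, d, r["sd_eta"], r["sd_xi"], r["sd_delta"],
                             r["singular"]))
    df = pd.DataFrame(rows, columns=["eta", "xi", "delta", "sd_eta", "sd_xi",
                                     "sd_delta", "singular"])
    finite = df.replace(np.inf, np.nan)
    df.attrs["summary"] = {
        p: {"min": float(finite[p].min()), "median": float(finite[p].median())}
        for p in ("sd_eta", "sd_xi", "sd_delta")
    }
    df.attrs["background_total_per_channel"] = Bc
    return df
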