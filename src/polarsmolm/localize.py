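"""Single-molecule detection, intensity estimation and channel pairing.

Detection follows the classic maximum-likelihood scheme for SMLM movies:
inside a sliding window an isotropic Gaussian peak of fixed radius plus a
constant offset (hypothesis H1) is compared against offset-only (H0) under
a Gaussian noise model, and the generalized likelihood ratio statistic
``T = N ln(SSE0 / SSE1)`` is thresholded at the false-alarm quantile
(asymptotically chi-square with one degree of freedom, one-sided on the
peak amplitude).  Candidates are local maxima of the statistic at integer
pixel positions.

Intensity/position estimation offers the three estimators compared in the
method validation: a symmetric Gaussian fit, a rotated elliptical Gaussian
fit (both Gauss-Newton least squares with sub-pixel output), and blind box
integration with an annulus background estimate.  Per-parameter precisions
come from the Fisher matrix of the fitted Gaussian model.

Detections from the four polarized channels are associated by mutual
nearest-neighbour pairing in the reference frame, first within each
Wollaston pair, then across the two NA arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter, uniform_filter
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .optics import CHANNELS, OpticalConfig, basis_psfs
from .orientation import moments6_from_orientation

__all__ = [
    "DetectionCandidate",
    "detect_glrt",
    "fit_psf",
    "fit_candidates",
    "pair_channels",
    "default_detection_radius",
]

FIT_COLUMNS = ["frame", "x_px", "y_px", "intensity", "background", "radius_px",
               "residual", "converged", "sigma_x_px", "sigma_y_px", "method"]


@dataclass(frozen=True)
class DetectionCandidate:
    frame: int
    channel: str
    y: int
    x: int
    statistic: float
    pfa: float


def _gauss_kernel(window: int, radius: float) -> tuple[np.ndarray, float]:
    h = window // 2
    y, x = np.mgrid[-h:h + 1, -h:h + 1]
    g = np.exp(-(x**2 + y**2) / (2.0 * radius**2))
    gc = g - g.mean()
    return gc, float((gc**2).sum())


def glrt_threshold(pfa: float) -> float:
    """GLRT threshold for a one-sided (positive-amplitude) test at ``pfa``."""
    return float(chi2.isf(min(2.0 * pfa, 1.0), df=1))


def detect_glrt(frame_image: np.ndarray, window: int = 11, pfa: float = 1e-3,
                psf_radius_fixed: float = 1.3,
                return_statistic: bool = False):
    """Detect candidate molecules in one channel image.

    Returns an (n, 3) array of (y, x, statistic) at integer pixel positions
    (optionally also the full statistic map).  ``window`` must be odd and
    fit inside the frame; positions closer than ``window//2`` to the border
    are not tested.
    """
    img = np.asarray(frame_image, float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if min(img.shape) < window:
        raise ValueError(f"window {window} larger than frame {img.shape}")
    if not (0.0 < pfa < 1.0):
        raise ValueError("pfa must lie in (0, 1)")

    gc, sgg = _gauss_kernel(window, psf_radius_fixed)
    nw = window * window
    s1 = uniform_filter(img, window, mode="constant") * nw
    s2 = uniform_filter(img**2, window, mode="constant") * nw
    from scipy.ndimage import correlate
    ig = correlate(img, gc, mode="constant")
    amp = ig / sgg
    sse0 = np.clip(s2 - s1**2 / nw, 1e-12, None)
    sse1 = np.clip(sse0 - amp**2 * sgg, 1e-12, None)
    stat = nw * np.log(sse0 / sse1)
    stat[amp <= 0] = 0.0

    h = window // 2
    valid = np.zeros_like(stat, bool)
    valid[h:-h or None, h:-h or None] = True
    thr = glrt_threshold(pfa)
    peaks = (stat == maximum_filter(stat, size=window)) & (stat > thr) & valid
    ys, xs = np.nonzero(peaks)
    cand = np.column_stack([ys, xs, stat[ys, xs]])
    if return_statistic:
        return cand, stat
    return cand


@lru_cache(maxsize=4)
def default_detection_radius(config: OpticalConfig = OpticalConfig()) -> float:
    """Gaussian radius (px) of the PSF of an in-plane wobbling molecule
    (eta=90, delta=100, xi-averaged), used as the fixed detection radius."""
    bset = basis_psfs(config)
    m6 = 0.5 * (moments6_from_orientation(90.0, 0.0, 100.0)
                + moments6_from_orientation(90.0, 90.0, 100.0))
    from .optics import render_patch
    imgs = render_patch(bset, m6, 1.0)
    img = sum(imgs.values())
    fit = _fit_gaussian_batch(img[None, ...], method="gauss_sym")
    return float(fit["radius_px"][0])


# ---------------------------------------------------------------------------
# batched Gaussian fitting
# ---------------------------------------------------------------------------

def _model_sym(params, X, Y):
    x, y, A, s, b = (params[:, i][:, None, None] for i in range(5))
    E = np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2 * s**2))
    M = b + A * E
    J = np.stack([
        A * (X - x) / s**2 * E,
        A * (Y - y) / s**2 * E,
        E,
        A * ((X - x) ** 2 + (Y - y) ** 2) / s**3 * E,
        np.ones_like(E),
    ], axis=-1)
    return M, J


def _model_rot(params, X, Y):
    x, y, A, sx, sy, th, b = (params[:, i][:, None, None] for i in range(7))
    ct, st = np.cos(th), np.sin(th)
    u = ct * (X - x) + st * (Y - y)
    v = -st * (X - x) + ct * (Y - y)
    E = np.exp(-u**2 / (2 * sx**2) - v**2 / (2 * sy**2))
    M = b + A * E
    du_dx, dv_dx = -ct, st
    du_dy, dv_dy = -st, -ct
    dE_du = -u / sx**2 * E
    dE_dv = -v / sy**2 * E
    J = np.stack([
        A * (dE_du * du_dx + dE_dv * dv_dx),
        A * (dE_du * du_dy + dE_dv * dv_dy),
        E,
        A * u**2 / sx**3 * E,
        A * v**2 / sy**3 * E,
        A * (dE_du * v - dE_dv * u) * -1.0,
        np.ones_like(E),
    ], axis=-1)
    return M, J


def _fit_gaussian_batch(patches: np.ndarray, method: str = "gauss_sym",
                        radius_init: float = 1.3, max_iter: int = 50,
                        tol: float = 1e-8) -> dict[str, np.ndarray]:
    """Levenberg-Marquardt fit of a stack of square patches.

    Returns dict of arrays: x, y (patch coords), intensity (integrated
    volume), background, radius_px, residual (RMS), converged,
    sigma_x_px/sigma_y_px (Fisher-based localization precision).
    """
    P = np.asarray(patches, float)
    B, H, W = P.shape
    Y, X = np.mgrid[:H, :W].astype(float)

    border = np.concatenate([P[:, 0, :], P[:, -1, :], P[:, :, 0], P[:, :, -1]],
                            axis=1)
    b0 = np.median(border, axis=1)
    Pc = np.clip(P - b0[:, None, None], 0.0, None)
    tot = np.clip(Pc.sum(axis=(1, 2)), 1e-9, None)
    x0 = (Pc * X).sum(axis=(1, 2)) / tot
    y0 = (Pc * Y).sum(axis=(1, 2)) / tot
    A0 = np.clip(P.max(axis=(1, 2)) - b0, 1e-6, None)

    if method == "gauss_sym":
        n_par = 5
        params = np.column_stack([x0, y0, A0, np.full(B, radius_init), b0])
        model = _model_sym
    elif method == "gauss_rot":
        n_par = 7
        params = np.column_stack([x0, y0, A0, np.full(B, radius_init),
                                  np.full(B, radius_init), np.zeros(B), b0])
        model = _model_rot
    else:
        raise ValueError(f"unknown fit method {method!r}")

    lam = np.full(B, 1e-3)
    M, J = model(params, X, Y)
    resid = P - M
    sse = (resid**2).sum(axis=(1, 2))
    converged = np.zeros(B, bool)
    eye = np.eye(n_par)

    for _ in range(max_iter):
        Jf = J.reshape(B, -1, n_par)
        rf = resid.reshape(B, -1)
        JTJ = np.einsum("bip,biq->bpq", Jf, Jf)
        JTr = np.einsum("bip,bi->bp", Jf, rf)
        diag = np.maximum(np.einsum("bpp->bp", JTJ), 1e-12)
        Aug = JTJ + lam[:, None, None] * (eye[None] * diag[:, None, :])
        try:
            step = np.linalg.solve(Aug, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("bpq,bq->bp", np.linalg.pinv(Aug), JTr)
        trial = params + step
        # keep widths positive and positions inside the patch
        trial[:, 0] = np.clip(trial[:, 0], -1.0, W)
        trial[:, 1] = np.clip(trial[:, 1], -1.0, H)
        trial[:, 3] = np.clip(trial[:, 3], 0.3, max(H, W))
        if n_par == 7:
            trial[:, 4] = np.clip(trial[:, 4], 0.3, max(H, W))
        Mt, Jt = model(trial, X, Y)
        rt = P - Mt
        sset = (rt**2).sum(axis=(1, 2))
        better = sset <= sse
        improve = np.abs(sse - sset) <= tol * np.maximum(sse, 1e-12)
        converged |= better & improve
        params = np.where(better[:, None], trial, params)
        sse_new = np.where(better, sset, sse)
        lam = np.where(better, lam / 3.0, lam * 5.0)
        lam = np.clip(lam, 1e-9, 1e6)
        M = np.where(better[:, None, None], Mt, M)
        J = np.where(better[:, None, None, None], Jt, J)
        resid = np.where(better[:, None, None], rt, resid)
        sse = sse_new
        if converged.all():
            break

    dof = max(H * W - n_par, 1)
    noise_var = sse / dof
    Jf = J.reshape(B, -1, n_par)
    JTJ = np.einsum("bip,biq->bpq", Jf, Jf)
    cov = np.linalg.pinv(JTJ) * noise_var[:, None, None]
    sig = np.sqrt(np.clip(np.einsum("bpp->bp", cov), 0.0, None))

    if method == "gauss_sym":
        A, s, b = params[:, 2], params[:, 3], params[:, 4]
        intensity = 2 * np.pi * A * s**2
        radius = s
    else:
        A, sx, sy, b = params[:, 2], params[:, 3], params[:, 4], params[:, 6]
        intensity = 2 * np.pi * A * sx * sy
        radius = np.sqrt(sx * sy)
    # plausibility guards: a fit whose width fills the window, or whose
    # volume substantially exceeds the background-subtracted window content,
    # is a degenerate solution (typical for a near-empty channel) and is
    # flagged so callers fall back to box integration
    window_content = np.clip(P.sum(axis=(1, 2)) - params[:, -1] * H * W, 0, None)
    converged &= radius < 0.45 * min(H, W)
    converged &= intensity <= 1.5 * window_content + 10.0 * np.sqrt(
        np.clip(params[:, -1], 0.0, None) * H * W + 1.0)
    return {
        "x": params[:, 0], "y": params[:, 1],
        "intensity": np.clip(intensity, 0.0, None),
        "background": params[:, -1],
        "radius_px": radius,
        "residual": np.sqrt(noise_var),
        "converged": converged,
        "sigma_x_px": sig[:, 0], "sigma_y_px": sig[:, 1],
    }


def _fit_box(patches: np.ndarray, annuli: np.ndarray) -> dict[str, np.ndarray]:
    """Box integration: window sum minus annulus-median background."""
    P = np.asarray(patches, float)
    B, H, W = P.shape
    bg = np.median(annuli, axis=1)
    sub = np.clip(P - bg[:, None, None], 0.0, None)
    intensity = P.sum(axis=(1, 2)) - bg * H * W
    tot = np.clip(sub.sum(axis=(1, 2)), 1e-9, None)
    Y, X = np.mgrid[:H, :W].astype(float)
    x = (sub * X).sum(axis=(1, 2)) / tot
    y = (sub * Y).sum(axis=(1, 2)) / tot
    r2 = ((sub * ((X - x[:, None, None]) ** 2 + (Y - y[:, None, None]) ** 2))
          .sum(axis=(1, 2)) / tot)
    radius = np.sqrt(np.clip(r2 / 2.0, 1e-6, None))
    sig = np.sqrt(np.clip(r2, 1e-6, None) / np.clip(intensity, 1.0, None))
    return {
        "x": x, "y": y, "intensity": np.clip(intensity, 0.0, None),
        "background": bg, "radius_px": radius,
        "residual": np.zeros(B), "converged": np.ones(B, bool),
        "sigma_x_px": sig, "sigma_y_px": sig,
    }


def _extract_patches(img: np.ndarray, ys, xs, half: int,
                     annulus: int = 2):
    """Cut fitting windows and background annuli around integer candidates."""
    H, W = img.shape
    n = len(ys)
    w = 2 * half + 1
    patches = np.empty((n, w, w))
    annuli = []
    for i, (y, x) in enumerate(zip(ys, xs)):
        if y - half < 0 or x - half < 0 or y + half >= H or x + half >= W:
            raise ValueError(f"candidate ({y}, {x}) too close to the frame edge")
        patches[i] = img[y - half:y + half + 1, x - half:x + half + 1]
        ylo, yhi = max(0, y - half - annulus), min(H, y + half + annulus + 1)
        xlo, xhi = max(0, x - half - annulus), min(W, x + half + annulus + 1)
        big = img[ylo:yhi, xlo:xhi]
        m = np.ones(big.shape, bool)
        m[(y - half) - ylo:(y + half + 1) - ylo,
          (x - half) - xlo:(x + half + 1) - xlo] = False
        annuli.append(big[m])
    ann = np.stack([np.pad(a, (0, max(0, max(map(len, annuli)) - len(a))),
                           constant_values=np.median(a)) for a in annuli]) \
        if annuli else np.zeros((0, 1))
    return patches, ann


def fit_candidates(img: np.ndarray, candidates: np.ndarray,
                   method: str = "gauss_sym", window: int = 11,
                   radius_init: float = 1.3, frame: int = 0) -> pd.DataFrame:
    """Fit every candidate of one channel image; returns a FitResult table.

    Gaussian fits that fail to converge fall back to box integration and
    are marked ``converged=False``.
    """
    half = window // 2
    if len(candidates) == 0:
        return pd.DataFrame(columns=FIT_COLUMNS)
    ys = candidates[:, 0].astype(int)
    xs = candidates[:, 1].astype(int)
    patches, annuli = _extract_patches(img, ys, xs, half)
    if method == "box":
        fit = _fit_box(patches, annuli)
    else:
        fit = _fit_gaussian_batch(patches, method, radius_init)
        if not fit["converged"].all():
            boxed = _fit_box(patches, annuli)
            badm = ~fit["converged"]
            for k in ("x", "y", "intensity", "background", "radius_px",
                      "sigma_x_px", "sigma_y_px"):
                fit[k] = np.where(badm, boxed[k], fit[k])
    out = pd.DataFrame({
        "frame": frame,
        "x_px": xs - half + fit["x"],
        "y_px": ys - half + fit["y"],
        "intensity": fit["intensity"],
        "background": fit["background"],
        "radius_px": fit["radius_px"],
        "residual": fit["residual"],
        "converged": fit["converged"],
        "sigma_x_px": fit["sigma_x_px"],
        "sigma_y_px": fit["sigma_y_px"],
        "method": method,
    })
    return out


def fit_psf(frame_image: np.ndarray, candidate, method: str = "gauss_sym",
            window: int = 11, radius_init: float = 1.3) -> pd.Series:
    """Fit a single detection candidate (see :func:`fit_candidates`)."""
    if isinstance(candidate, DetectionCandidate):
        arr = np.array([[candidate.y, candidate.x, candidate.statistic]])
        frame = candidate.frame
    else:
        y, x = candidate[:2]
        arr = np.array([[y, x, 0.0]])
        frame = 0
    return fit_candidates(frame_image, arr, method, window, radius_init,
                          frame).iloc[0]


# ---------------------------------------------------------------------------
# channel pairing
# ---------------------------------------------------------------------------

def _mutual_nn(a_xy: np.ndarray, b_xy: np.ndarray, tol: np.ndarray):
    """Mutual nearest-neighbour matches within per-pair tolerance."""
    if len(a_xy) == 0 or len(b_xy) == 0:
        return np.empty((0, 2), int), np.empty(0)
    ta, tb = cKDTree(a_xy), cKDTree(b_xy)
    d_ab, j_ab = tb.query(a_xy)
    d_ba, j_ba = ta.query(b_xy)
    pairs = []
    dists = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if j_ba[j] == i and d <= tol[i]:
            pairs.append((i, j))
            dists.append(d)
    return np.array(pairs, int).reshape(-1, 2), np.array(dists)


def pair_channels(fits_by_channel: dict[str, pd.DataFrame],
                  transforms: dict | None = None,
                  tolerance_mode: float | str = "crlb",
                  tol_k: float = 3.0, tol_min_px: float = 0.75,
                  tol_max_px: float = 3.0,
                  pixel_size: float = 130.0) -> tuple[pd.DataFrame, dict]:
    """Associate detections across the four channels.

    Each channel's coordinates are first mapped to the reference channel
    (I0) with the supplied affine transforms (identity if None); pairing is
    mutual nearest neighbour, first inside each Wollaston pair (I0-I90,
    I45-I135), then between the two arms using intensity-weighted pair
    positions.  The tolerance is ``tol_k`` times the combined fitted
    localization precision (clipped to [tol_min_px, tol_max_px]), or a
    fixed pixel distance when ``tolerance_mode`` is a number.

    Returns (paired table, statistics dict).
    """
    mapped = {}
    for c in CHANNELS:
        df = fits_by_channel.get(c)
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=FIT_COLUMNS)
        df = df.reset_index(drop=True).copy()
        if transforms and transforms.get(c) is not None:
            x, y = transforms[c].apply(df.x_px.values, df.y_px.values)
            df["x_ref"], df["y_ref"] = x, y
        else:
            df["x_ref"], df["y_ref"] = df.x_px, df.y_px
        mapped[c] = df

    stats = {"incomplete": 0, "paired": 0}
    rows = []
    frames = sorted(set().union(*[set(df.frame.unique()) for df in mapped.values()]))
    for f in frames:
        sub = {c: mapped[c][mapped[c].frame == f] for c in CHANNELS}

        def tol_of(da, db):
            if isinstance(tolerance_mode, (int, float)):
                return np.full(len(da), float(tolerance_mode))
            prec_a = np.hypot(da.sigma_x_px.values, da.sigma_y_px.values)
            prec_b = float(np.median(np.hypot(db.sigma_x_px.values,
                                              db.sigma_y_px.values))) \
                if len(db) else 0.0
            return np.clip(tol_k * np.hypot(prec_a, prec_b),
                           tol_min_px, tol_max_px)

        arm_pairs = {}
        for ca, cb, name in (("I0", "I90", "low"), ("I45", "I135", "high")):
            da, db = sub[ca], sub[cb]
            axy = da[["x_ref", "y_ref"]].values
            bxy = db[["x_ref", "y_ref"]].values
            idx, dist = _mutual_nn(axy, bxy, tol_of(da, db))
            arm_pairs[name] = (da, db, idx, dist)

        (d0, d90, i_low, dist_low) = arm_pairs["low"]
        (d45, d135, i_high, dist_high) = arm_pairs["high"]
        if len(i_low) == 0 or len(i_high) == 0:
            stats["incomplete"] += (len(i_low) + len(i_high)
                                    + (len(i_low) == 0) * 0)
            continue

        def fuse(da, db, idx):
            a = da.iloc[idx[:, 0]]
            b = db.iloc[idx[:, 1]]
            wa = np.clip(a.intensity.values, 1e-9, None)
            wb = np.clip(b.intensity.values, 1e-9, None)
            x = (a.x_ref.values * wa + b.x_ref.values * wb) / (wa + wb)
            y = (a.y_ref.values * wa + b.y_ref.values * wb) / (wa + wb)
            return a, b, x, y

        a0, a90, x_lo, y_lo = fuse(d0, d90, i_low)
        a45, a135, x_hi, y_hi = fuse(d45, d135, i_high)
        tol = np.full(len(x_lo), tol_max_px) \
            if not isinstance(tolerance_mode, (int, float)) \
            else np.full(len(x_lo), float(tolerance_mode))
        idx, dist = _mutual_nn(np.column_stack([x_lo, y_lo]),
                               np.column_stack([x_hi, y_hi]), tol)
        n_pair = len(idx)
        stats["incomplete"] += (len(i_low) - n_pair) + (len(i_high) - n_pair)
        for k in range(n_pair):
            il, ih = idx[k]
            parts = (a0.iloc[il], a90.iloc[il], a45.iloc[ih], a135.iloc[ih])
            I = np.array([p.intensity for p in parts])
            w = np.clip(I, 1e-9, None)
            xs = np.array([p.x_ref for p in parts])
            ys_ = np.array([p.y_ref for p in parts])
            x_f = float((xs * w).sum() / w.sum())
            y_f = float((ys_ * w).sum() / w.sum())
            rows.append({
                "frame": f, "x_px": x_f, "y_px": y_f,
                "x_nm": x_f * pixel_size, "y_nm": y_f * pixel_size,
                "I0": I[0], "I90": I[1], "I45": I[2], "I135": I[3],
                "intensity_total": float(I.sum()),
                "background": float(np.mean([p.background for p in parts])),
                "radius_px": float(np.mean([p.radius_px for p in parts])),
                "pair_distance_px": float(dist[k]),
                "sigma_loc_px": float(np.mean([np.hypot(p.sigma_x_px,
                                                        p.sigma_y_px)
                                               for p in parts])),
            })
    stats["paired"] = len(rows)
    cols = ["frame", "x_px", "y_px", "x_nm", "y_nm", "I0", "I90", "I45",
            "I135", "intensity_total", "background", "radius_px",
            "pair_distance_px", "sigma_loc_px"]
    return pd.DataFrame(rows, columns=cols), stats
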