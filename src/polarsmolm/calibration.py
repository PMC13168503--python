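"""Instrument calibration: channel registration, the measured integrated
propagation matrix, and lateral drift correction.

The 4x4 integrated matrix <K> maps accessible second moments to channel
intensities.  It is measured with fluorescent nanobeads: a rotating linear
polarizer placed in the emission path makes the bead emulate a fixed
in-plane dipole of azimuth theta, i.e. moments (cos^2 th, sin^2 th, 0,
sin th cos th), so the intensity of every channel traces a sinusoid
``a + b cos 2th + d sin 2th`` whose coefficients give the xx, yy and xy
columns; the bead without polarizer emulates an isotropic emitter
m = (1/3, 1/3, 1/3, 0) and pins down the zz column.  Without the
unpolarized measurement the zz column is unidentifiable from in-plane
polarizer states alone and calibration must fail loudly.

Channel registration maps each quadrant onto the reference channel (I0 by
default) with an affine transform fitted on matched bead centroids, later
refined on the single-molecule pairs themselves.  Drift correction renders
temporally binned localization histograms and aligns them by phase
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

from .localize import detect_glrt, fit_candidates
from .optics import CHANNELS, CalibrationDegeneracyError

__all__ = [
    "AffineTransform",
    "CalibrationMatrix",
    "InsufficientLandmarksError",
    "CalibrationQualityError",
    "fit_channel_registration",
    "refine_pairing_offset",
    "calibrate_K",
    "polarizer_moments",
    "drift_correct",
]


class InsufficientLandmarksError(RuntimeError):
    """Too few matched beads/molecules to fit a registration."""


class CalibrationQualityError(RuntimeError):
    """Polarizer-sweep fit quality below the acceptance threshold."""


@dataclass
class AffineTransform:
    """2D affine map x' = A x + t (pixel coordinates)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    residual_rms_px: float = 0.0
    warning: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(2, 2)
        self.offset = np.asarray(self.offset, float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        xo = self.matrix[0, 0] * x + self.matrix[0, 1] * y + self.offset[0]
        yo = self.matrix[1, 0] * x + self.matrix[1, 1] * y + self.offset[1]
        return xo, yo

    def shifted(self, dx: float, dy: float) -> "AffineTransform":
        return AffineTransform(self.matrix.copy(),
                               self.offset + np.array([dx, dy]),
                               self.residual_rms_px, self.warning)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()


@dataclass
class CalibrationMatrix:
    """Measured (or theoretical) integrated propagation matrix.

    Rows are channels (I0, I90, I45, I135), columns the moment components
    (xx, yy, zz, xy).  ``stderr`` holds per-entry standard errors where
    available; ``provenance`` is 'theory', 'measured' or 'synthetic'.
    """

    K: np.ndarray
    stderr: np.ndarray | None = None
    provenance: str = "theory"
    r_squared: np.ndarray | None = None

    def __post_init__(self):
        self.K = np.asarray(self.K, float).reshape(4, 4)
        if np.any(self.K[:, :2] < -1e-9 * np.abs(self.K).max()):
            raise ValueError("xx/yy columns of K must be non-negative")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.K))

    def require_invertible(self, max_cond: float = 1e8) -> None:
        c = self.condition_number
        if not np.isfinite(c) or c > max_cond:
            raise CalibrationDegeneracyError(
                f"calibration matrix degenerate (cond={c:.3g})")


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _bead_centroids(image: np.ndarray, pfa: float = 1e-4,
                    psf_radius: float = 1.3) -> np.ndarray:
    cand = detect_glrt(image, window=11, pfa=pfa, psf_radius_fixed=psf_radius)
    if len(cand) == 0:
        return np.zeros((0, 2))
    fits = fit_candidates(image, cand, method="gauss_sym",
                          radius_init=psf_radius)
    return fits[["x_px", "y_px"]].values


def fit_channel_registration(bead_stacks: dict[str, np.ndarray],
                             reference: str = "I0", min_beads: int = 10,
                             match_tol_px: float = 3.0,
                             pfa: float = 1e-4) -> dict[str, AffineTransform]:
    """Affine transforms mapping each channel onto the reference channel.

    ``bead_stacks``: channel -> 2D image (a stack is summed over frames).
    Bead centroids are matched to the reference by nearest neighbour after
    a coarse phase-correlation offset; the affine fit is plain least
    squares on the matched pairs.  Raises InsufficientLandmarksError below
    ``min_beads`` matches; a residual above one pixel only sets a warning.
    """
    imgs = {}
    for c, arr in bead_stacks.items():
        a = np.asarray(arr, float)
        imgs[c] = a.sum(axis=0) if a.ndim == 3 else a
    if reference not in imgs:
        raise ValueError(f"reference channel {reference} missing")
    ref_pts = _bead_centroids(imgs[reference], pfa)
    if len(ref_pts) < min_beads:
        raise InsufficientLandmarksError(
            f"only {len(ref_pts)} beads found in reference channel")
    tree = cKDTree(ref_pts)
    out: dict[str, AffineTransform] = {reference: AffineTransform.identity()}
    for c, img in imgs.items():
        if c == reference:
            continue
        pts = _bead_centroids(img, pfa)
        if len(pts) < min_beads:
            raise InsufficientLandmarksError(
                f"only {len(pts)} beads found in channel {c}")
        shift, *_ = phase_cross_correlation(imgs[reference], img,
                                            upsample_factor=10)
        coarse = pts + shift[::-1]  # (dy, dx) -> (dx, dy)
        d, j = tree.query(coarse)
        keep = d <= match_tol_px
        if keep.sum() < min_beads:
            raise InsufficientLandmarksError(
                f"only {int(keep.sum())} bead matches in channel {c}")
        src = pts[keep]
        dst = ref_pts[j[keep]]
        A = np.column_stack([src, np.ones(len(src))])
        sol, *_ = np.linalg.lstsq(A, dst, rcond=None)
        matrix = sol[:2].T
        offset = sol[2]
        pred = src @ sol[:2] + offset
        rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
        warn = f"registration residual {rms:.2f} px > 1 px" if rms > 1.0 else None
        out[c] = AffineTransform(matrix, offset, rms, warn)
    return out


def refine_pairing_offset(transforms: dict[str, AffineTransform],
                          detections_by_channel: dict[str, pd.DataFrame],
                          reference: str = "I0", min_pairs: int = 100,
                          match_tol_px: float = 1.5):
    """Refine the registration on the single-molecule detections themselves.

    Every channel's detections are mapped into the reference frame with the
    current transforms, matched per frame to the reference-channel
    detections, and the median residual displacement is composed into the
    transform.  With fewer than ``min_pairs`` matches in a channel the
    refinement of that channel is skipped with a warning.

    Returns (updated transforms, info dict).
    """
    ref = detections_by_channel[reference]
    info = {}
    updated = dict(transforms)
    for c, df in detections_by_channel.items():
        if c == reference:
            continue
        tr = transforms.get(c, AffineTransform.identity())
        resid = []
        for f, sub in df.groupby("frame"):
            rsub = ref[ref.frame == f]
            if len(rsub) == 0 or len(sub) == 0:
                continue
            x, y = tr.apply(sub.x_px.values, sub.y_px.values)
            tree = cKDTree(rsub[["x_px", "y_px"]].values)
            d, j = tree.query(np.column_stack([x, y]))
            keep = d <= match_tol_px
            if keep.any():
                target = rsub[["x_px", "y_px"]].values[j[keep]]
                resid.append(target - np.column_stack([x, y])[keep])
        resid = np.concatenate(resid) if resid else np.zeros((0, 2))
        if len(resid) < min_pairs:
            info[c] = {"n_pairs": len(resid), "skipped": True,
                       "warning": f"only {len(resid)} pairs (< {min_pairs}); "
                                  "refinement skipped"}
            continue
        dx, dy = np.median(resid, axis=0)
        updated[c] = tr.shifted(dx, dy)
        info[c] = {"n_pairs": len(resid), "skipped": False,
                   "offset_px": (float(dx), float(dy))}
    return updated, info


# ---------------------------------------------------------------------------
# K calibration from the polarizer sweep
# ---------------------------------------------------------------------------

def polarizer_moments(theta_deg) -> np.ndarray:
    """Accessible moments emulated by a linear polarizer at ``theta``:
    a fixed in-plane dipole (cos^2, sin^2, 0, sin cos)."""
    th = np.deg2rad(np.asarray(theta_deg, float))
    return np.stack([np.cos(th) ** 2, np.sin(th) ** 2, np.zeros_like(th),
                     np.sin(th) * np.cos(th)], axis=-1)


def calibrate_K(polarizer_angles_deg, polarizer_intensities,
                unpolarized_intensities=None,
                min_r_squared: float = 0.9) -> CalibrationMatrix:
    """Measured <K> from a nanobead + rotating-polarizer series.

    ``polarizer_intensities``: (n_angles, 4) bead intensities per channel;
    ``unpolarized_intensities``: (4,) bead intensities without polarizer.
    Per channel the sinusoid ``a + b cos 2th + d sin 2th`` is fitted by
    linear least squares; (xx, yy, xy) columns follow as
    (a + b, a - b, 2 d) and the zz column from the unpolarized frame,
    ``K_zz = 3 I_unpol - K_xx - K_yy``.  Standard errors propagate from the
    fit residuals.
    """
    th = np.asarray(polarizer_angles_deg, float)
    I = np.asarray(polarizer_intensities, float)
    if I.shape != (len(th), 4):
        raise ValueError(f"intensities must be (n_angles, 4), got {I.shape}")
    if len(th) < 8 or (th.max() - th.min()) < 180.0 - 1e-9:
        raise ValueError("need >= 8 polarizer angles spanning >= 180 degrees")
    if unpolarized_intensities is None:
        raise CalibrationDegeneracyError(
            "zz column unidentifiable without an unpolarized measurement: "
            "in-plane polarizer states carry no longitudinal information")
    Iu = np.asarray(unpolarized_intensities, float).reshape(4)

    t2 = np.deg2rad(2.0 * th)
    X = np.column_stack([np.ones_like(t2), np.cos(t2), np.sin(t2)])
    XtXinv = np.linalg.inv(X.T @ X)
    K = np.zeros((4, 4))
    err = np.zeros((4, 4))
    r2 = np.zeros(4)
    for c in range(4):
        beta, *_ = np.linalg.lstsq(X, I[:, c], rcond=None)
        pred = X @ beta
        ss_res = float(np.sum((I[:, c] - pred) ** 2))
        ss_tot = float(np.sum((I[:, c] - I[:, c].mean()) ** 2))
        r2[c] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = max(len(th) - 3, 1)
        sigma2 = ss_res / dof
        se = np.sqrt(np.diag(XtXinv) * sigma2)
        a, b, d = beta
        K[c, 0] = a + b
        K[c, 1] = a - b
        K[c, 3] = 2.0 * d
        err[c, 0] = np.hypot(se[0], se[1])
        err[c, 1] = np.hypot(se[0], se[1])
        err[c, 3] = 2.0 * se[2]
        K[c, 2] = 3.0 * Iu[c] - K[c, 0] - K[c, 1]
        err[c, 2] = np.sqrt(err[c, 0] ** 2 + err[c, 1] ** 2)
    if np.any(r2 < min_r_squared):
        raise CalibrationQualityError(
            f"polarizer sinusoid fit R^2 {r2.round(3).tolist()} below "
            f"{min_r_squared}")
    K[:, :2] = np.clip(K[:, :2], 0.0, None)
    cal = CalibrationMatrix(K, stderr=err, provenance="measured",
                            r_squared=r2)
    cal.require_invertible()
    return cal


def estimator_matched_calibration(config, method: str = "gauss_sym",
                                  window: int = 11,
                                  radius_init: float | None = None,
                                  angles_deg=None) -> CalibrationMatrix:
    """Synthetic bead + rotating-polarizer calibration through the estimator.

    Reproduces the instrument's calibration protocol on the forward model:
    noise-free PSFs of the in-plane dipole states emulated by the polarizer
    (and of the unpolarized bead) are rendered and their intensities
    estimated with the *same* estimator the pipeline uses, so the measured
    <K> absorbs the estimator's per-channel flux response exactly as a real
    bead calibration does.
    """
    from .localize import _fit_box, _fit_gaussian_batch, default_detection_radius
    from .optics import basis_psfs, render_patch

    bset = basis_psfs(config)
    if radius_init is None:
        radius_init = default_detection_radius(config)
    if angles_deg is None:
        angles_deg = np.arange(0.0, 181.0, 15.0)
    hw = config.psf_halfwidth_px
    half = window // 2
    sl = slice(hw - half, hw + half + 1)

    def estimate(m4) -> np.ndarray:
        m6 = np.concatenate([np.asarray(m4, float), [0.0, 0.0]])
        imgs = render_patch(bset, m6, 1e6)
        out = np.empty(4)
        for i, c in enumerate(CHANNELS):
            patch = imgs[c][sl, sl]
            if method == "box":
                big = imgs[c][hw - half - 2:hw + half + 3,
                              hw - half - 2:hw + half + 3]
                mask = np.ones(big.shape, bool)
                mask[2:-2, 2:-2] = False
                fit = _fit_box(patch[None], big[mask][None])
            else:
                fit = _fit_gaussian_batch(patch[None], method, radius_init)
            out[i] = fit["intensity"][0]
        return out

    I = np.stack([estimate(polarizer_moments(a)) for a in angles_deg])
    Iu = estimate(np.array([1 / 3, 1 / 3, 1 / 3, 0.0]))
    cal = calibrate_K(angles_deg, I, Iu)
    return CalibrationMatrix(cal.K, stderr=cal.stderr, provenance="synthetic",
                             r_squared=cal.r_squared)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def drift_correct(table: pd.DataFrame, frames_per_bin: int = 3000,
                  bin_nm: float = 30.0, upsample: int = 20,
                  min_localizations_per_bin: int = 20):
    """Cross-correlation lateral drift correction of a localization table.

    Localizations are rendered as 2D histograms per temporal bin; inter-bin
    shifts relative to the first bin are estimated by sub-pixel phase
    correlation, interpolated linearly over frames and subtracted from
    (x_nm, y_nm).  Bins with too few localizations are skipped and their
    shift interpolated from neighbouring bins.

    Returns (corrected table, drift trace DataFrame).
    """
    if not len(table):
        raise ValueError("empty localization table")
    t = table.copy()
    fmax = int(t.frame.max())
    n_bins = fmax // frames_per_bin + 1
    if n_bins < 2:
        raise ValueError(
            f"table spans {fmax + 1} frames < 2 bins of {frames_per_bin}")
    x0, y0 = t.x_nm.min(), t.y_nm.min()
    nx = int(np.ceil((t.x_nm.max() - x0) / bin_nm)) + 1
    ny = int(np.ceil((t.y_nm.max() - y0) / bin_nm)) + 1

    def hist(sub):
        h, _, _ = np.histogram2d(sub.y_nm, sub.x_nm, bins=(ny, nx),
                                 range=((y0, y0 + ny * bin_nm),
                                        (x0, x0 + nx * bin_nm)))
        return h

    bins = t.frame.values // frames_per_bin
    ref = None
    shifts = np.full((n_bins, 2), np.nan)
    counts = np.zeros(n_bins, int)
    for b in range(n_bins):
        sub = t[bins == b]
        counts[b] = len(sub)
        if len(sub) < min_localizations_per_bin:
            continue
        h = hist(sub)
        if ref is None:
            ref = h
            shifts[b] = 0.0
            continue
        shift, error, _ = phase_cross_correlation(ref, h,
                                                  upsample_factor=upsample,
                                                  normalization=None)
        shifts[b] = shift[::-1] * bin_nm  # (dy, dx) px -> (dx, dy) nm
    good = np.isfinite(shifts[:, 0])
    if good.sum() < 2:
        raise ValueError("not enough populated bins for drift estimation")
    centers = (np.arange(n_bins) + 0.5) * frames_per_bin
    fr = t.frame.values.astype(float)
    cg, sg = centers[good], shifts[good]
    # linear extrapolation beyond the first/last bin centre
    slope0 = (sg[1] - sg[0]) / (cg[1] - cg[0])
    slope1 = (sg[-1] - sg[-2]) / (cg[-1] - cg[-2])
    cg = np.concatenate([[fr.min() - 1], cg, [fr.max() + 1]])
    sg = np.vstack([sg[0] + slope0 * (cg[0] - cg[1]), sg,
                    sg[-1] + slope1 * (cg[-1] - cg[-2])])
    dx = np.interp(fr, cg, sg[:, 0])
    dy = np.interp(fr, cg, sg[:, 1])
    # phase correlation reports how much the bin is displaced relative to
    # the reference; subtracting re-centres every bin on the first
    t["x_nm"] = t.x_nm.values + dx
    t["y_nm"] = t.y_nm.values + dy
    trace = pd.DataFrame({
        "bin": np.arange(n_bins), "frame_center": centers,
        "n_localizations": counts,
        "shift_x_nm": shifts[:, 0], "shift_y_nm": shifts[:, 1],
        "used": good,
    })
    return t, trace
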