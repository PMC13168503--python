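"""Post-retrieval statistics and rendering.

Operates on localization tables (one row per molecule) carrying position,
the retrieved angles (eta, xi, delta), photon counts, PSF radius and
quality flags.  Provides the confidence filter, the population binning of
the off-plane angle with its misclassification bookkeeping, radiality and
orientation-fraction profiles around region centres, PSF-radius focus
classes, and deterministic stick-map rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orientation import FLAG_XI_ILL_DEFINED

__all__ = [
    "ROISpec",
    "filter_confidence",
    "bin_eta",
    "misclassification_rates",
    "radiality",
    "radiality_profile",
    "eta_fraction_profile",
    "focus_classes",
    "render_stick_map",
    "polar_histogram",
    "ETA_SCHEMES",
]

# population limits of the off-plane angle; values exactly at an edge go to
# the lower bin
ETA_SCHEMES = {
    "standard": (30.0, 60.0),   # off-plane < 30, intermediate 30-60, in-plane > 60
    "cell": (40.0, 60.0),   # off-plane < 40 used for cellular data
}
ETA_LABELS = ("off-plane", "intermediate", "in-plane")


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest (nm coordinates)."""

    center_x_nm: float
    center_y_nm: float
    radius_nm: float
    label: str = "in"

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ValueError("ROI radius must be positive")


def filter_confidence(table: pd.DataFrame,
                      eta_range: tuple[float, float] = (5.0, 88.0),
                      delta_range: tuple[float, float] = (5.0, 175.0),
                      min_photons: float = 1000.0):
    """Confidence filter on retrieved parameters.

    Keeps molecules with eta strictly inside ``eta_range``, delta strictly
    inside ``delta_range``, total detected intensity above ``min_photons``
    and no ill-defined-xi flag.  Returns (filtered table, rejection counts
    per reason); a molecule is counted once per reason it violates.
    """
    t = table
    n = len(t)
    if n == 0:
        return t.copy(), {"eta_range": 0, "delta_range": 0,
                          "low_photons": 0, "ill_defined": 0, "kept": 0}
    photons = t["photons"] if "photons" in t else t["intensity_total"]
    bad_eta = ~((t.eta > eta_range[0]) & (t.eta < eta_range[1]))
    bad_delta = ~((t.delta > delta_range[0]) & (t.delta < delta_range[1]))
    bad_phot = ~(photons > min_photons)
    ill = (t["flags"].values.astype(int) & FLAG_XI_ILL_DEFINED).astype(bool) \
        if "flags" in t else np.zeros(n, bool)
    keep = ~(bad_eta | bad_delta | bad_phot | ill)
    counts = {
        "eta_range": int(bad_eta.sum()),
        "delta_range": int(bad_delta.sum()),
        "low_photons": int(bad_phot.sum()),
        "ill_defined": int(np.asarray(ill).sum()),
        "kept": int(keep.sum()),
    }
    return t[keep].reset_index(drop=True), counts


def bin_eta(table: pd.DataFrame, scheme: str = "standard") -> pd.DataFrame:
    """Label each molecule off-plane / intermediate / in-plane.

    Both printed binning schemes are available: 'standard' (30/60) and 'cell'
    (40/60).  Boundary values are assigned to the lower bin.
    """
    if scheme not in ETA_SCHEMES:
        raise ValueError(f"unknown eta binning scheme {scheme!r}; "
                         f"choose from {sorted(ETA_SCHEMES)}")
    lo, hi = ETA_SCHEMES[scheme]
    t = table.copy()
    eta = t.eta.values
    label = np.where(eta <= lo, ETA_LABELS[0],
                     np.where(eta <= hi, ETA_LABELS[1], ETA_LABELS[2]))
    t["eta_class"] = pd.Categorical(label, categories=list(ETA_LABELS))
    return t


def misclassification_rates(retrieved: pd.DataFrame, truth: pd.DataFrame,
                            scheme: str = "standard",
                            per: str = "truth") -> dict[str, float]:
    """Fraction of molecules assigned to the wrong off-plane population.

    Tables are joined on ``molecule_id``.  With ``per='truth'`` (default)
    the rate of each class is computed among molecules whose ground-truth
    eta falls in that class; ``per='retrieved'`` conditions on the
    retrieved class instead.
    """
    if "molecule_id" not in retrieved or "molecule_id" not in truth:
        raise KeyError("both tables need a molecule_id column")
    r = bin_eta(retrieved, scheme)[["molecule_id", "eta_class"]]
    g = bin_eta(truth, scheme)[["molecule_id", "eta_class"]]
    j = r.merge(g, on="molecule_id", suffixes=("_ret", "_true"),
                validate="one_to_one")
    if len(j) == 0:
        raise ValueError("no molecules in common between the tables")
    cond = "eta_class_true" if per == "truth" else "eta_class_ret"
    out = {}
    for cls in ETA_LABELS:
        sub = j[j[cond] == cls]
        out[cls] = float((sub.eta_class_ret != sub.eta_class_true).mean()) \
            if len(sub) else np.nan
    out["n_matched"] = len(j)
    return out


def radiality(table: pd.DataFrame, roi: ROISpec) -> pd.DataFrame:
    """Radiality D_xi and centre distance of every molecule w.r.t. one ROI.

    D_xi is the difference between the molecule's in-plane angle xi and the
    direction of the vector from the ROI centre to the molecule, folded
    into [-90, 90) by the 180-degree stick symmetry.  Molecules exactly at
    the centre are excluded (direction undefined).
    """
    dx = table.x_nm.values - roi.center_x_nm
    dy = table.y_nm.values - roi.center_y_nm
    d = np.hypot(dx, dy)
    ok = d > 0
    ang = np.degrees(np.arctan2(dy[ok], dx[ok]))
    dxi = (table.xi.values[ok] - ang + 90.0) % 180.0 - 90.0
    out = table.loc[ok, ["xi", "eta"] if "eta" in table else ["xi"]].copy()
    out["distance_nm"] = d[ok]
    out["d_xi"] = dxi
    return out.reset_index(drop=True)


def radiality_profile(table: pd.DataFrame, rois, step_nm: float = 10.0,
                      cutoff_deg: float = 10.0,
                      max_distance_nm: float | None = None) -> pd.DataFrame:
    """Fraction of radially oriented molecules vs distance to ROI centres.

    Pools the localizations of all ROIs; per half-open distance bin
    [k*step, (k+1)*step) reports the fraction with |D_xi| < cutoff.  The
    null expectation for random xi is 2*cutoff/180.
    """
    rois = list(np.atleast_1d(rois))
    if not rois:
        raise ValueError("at least one ROI required")
    parts = []
    for roi in rois:
        r = radiality(table, roi)
        if max_distance_nm is None:
            r = r[r.distance_nm <= roi.radius_nm]
        else:
            r = r[r.distance_nm <= max_distance_nm]
        parts.append(r)
    allr = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if len(allr) == 0:
        import warnings
        warnings.warn("no localizations inside the ROIs; empty profile")
        return pd.DataFrame(columns=["distance_nm", "fraction_radial", "n"])
    b = (allr.distance_nm // step_nm).astype(int)
    grp = allr.groupby(b)
    out = pd.DataFrame({
        "distance_nm": grp.size().index * step_nm + step_nm / 2.0,
        "fraction_radial": grp.apply(
            lambda s: float((np.abs(s.d_xi) < cutoff_deg).mean()),
            include_groups=False),
        "n": grp.size(),
    }).reset_index(drop=True)
    return out


def eta_fraction_profile(table: pd.DataFrame, rois, step_nm: float = 10.0,
                         off_plane_max: float = 40.0,
                         in_plane_min: float = 60.0) -> pd.DataFrame:
    """Per-distance fractions of off-plane and in-plane molecules.

    Off-plane: eta < ``off_plane_max``; in-plane: eta > ``in_plane_min``
    (the cellular-scheme limits).  Distances pooled over all ROIs.
    """
    rois = list(np.atleast_1d(rois))
    parts = []
    for roi in rois:
        r = radiality(table, roi)
        parts.append(r[r.distance_nm <= roi.radius_nm])
    allr = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if len(allr) == 0:
        import warnings
        warnings.warn("no localizations inside the ROIs; empty profile")
        return pd.DataFrame(columns=["distance_nm", "fraction_off_plane",
                                     "fraction_in_plane", "n"])
    b = (allr.distance_nm // step_nm).astype(int)
    grp = allr.groupby(b)
    out = pd.DataFrame({
        "distance_nm": grp.size().index * step_nm + step_nm / 2.0,
        "fraction_off_plane": grp.apply(
            lambda s: float((s.eta < off_plane_max).mean()),
            include_groups=False),
        "fraction_in_plane": grp.apply(
            lambda s: float((s.eta > in_plane_min).mean()),
            include_groups=False),
        "n": grp.size(),
    }).reset_index(drop=True)
    return out


def focus_classes(table: pd.DataFrame,
                  in_plane_eta: float = 60.0, in_focus_radius: float = 1.4,
                  off_plane_eta: float = 40.0, off_focus_radius: float = 2.0
                  ) -> pd.DataFrame:
    """Classify molecules by off-plane angle and PSF radius.

    'in-plane/in-focus': eta > 60 and radius < 1.4 px;
    'off-plane/off-focus': eta < 40 and radius > 2 px; otherwise 'other'.
    """
    if "radius_px" not in table:
        raise KeyError("table has no radius_px column")
    t = table.copy()
    cls = np.full(len(t), "other", dtype=object)
    cls[(t.eta.values > in_plane_eta)
        & (t.radius_px.values < in_focus_radius)] = "in-plane/in-focus"
    cls[(t.eta.values < off_plane_eta)
        & (t.radius_px.values > off_focus_radius)] = "off-plane/off-focus"
    t["focus_class"] = cls
    return t


def _colormap(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Simple deterministic HSV-like mapping to RGB in [0, 1]."""
    x = np.clip((values - vmin) / max(vmax - vmin, 1e-12), 0.0, 1.0)
    r = np.clip(1.5 - np.abs(4.0 * x - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * x - 2.0), 0.0, 1.0)
    bl = np.clip(1.5 - np.abs(4.0 * x - 1.0), 0.0, 1.0)
    return np.stack([r, g, bl], axis=-1)


def render_stick_map(table: pd.DataFrame, color_by: str = "xi",
                     stick_length_nm: float = 100.0,
                     pixel_nm: float = 20.0,
                     eta_bins: tuple[float, ...] | None = None,
                     shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize one stick per molecule, oriented along xi.

    The stick of each molecule is centred on its position and tilted by its
    in-plane angle xi; colour encodes ``color_by`` (continuous for xi and
    delta; with ``eta_bins`` the eta colouring uses discrete sectors).
    Returns an RGB float image; output is deterministic for fixed input.
    """
    from skimage.draw import line

    if len(table) == 0:
        raise ValueError("empty table")
    x = table.x_nm.values / pixel_nm
    y = table.y_nm.values / pixel_nm
    if shape is None:
        H = int(np.ceil(y.max())) + 3
        W = int(np.ceil(x.max())) + 3
    else:
        H, W = shape
    vals = table[color_by].values.astype(float)
    if color_by == "xi":
        vmin, vmax = 0.0, 180.0
    elif color_by == "delta":
        vmin, vmax = 0.0, 180.0
    else:
        vmin, vmax = 0.0, 90.0
    if eta_bins is not None and color_by == "eta":
        edges = np.asarray(eta_bins, float)
        vals = edges[np.clip(np.searchsorted(edges, vals), 0, len(edges) - 1)]
    colors = _colormap(vals, vmin, vmax)
    img = np.zeros((H, W, 3))
    half = stick_length_nm / 2.0 / pixel_nm
    ang = np.deg2rad(table.xi.values)
    for i in range(len(table)):
        x0 = int(round(x[i] - half * np.cos(ang[i])))
        y0 = int(round(y[i] - half * np.sin(ang[i])))
        x1 = int(round(x[i] + half * np.cos(ang[i])))
        y1 = int(round(y[i] + half * np.sin(ang[i])))
        rr, cc = line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        img[rr[ok], cc[ok]] += colors[i]
    return np.clip(img / max(img.max(), 1e-12), 0.0, 1.0)


def polar_histogram(xi_values, n_bins: int = 36) -> pd.DataFrame:
    """Histogram of the in-plane angle xi over [0, 180)."""
    xi = np.mod(np.asarray(xi_values, float), 180.0)
    counts, edges = np.histogram(xi, bins=n_bins, range=(0.0, 180.0))
    return pd.DataFrame({"xi_center": (edges[:-1] + edges[1:]) / 2.0,
                         "count": counts})
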