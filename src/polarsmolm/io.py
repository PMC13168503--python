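"""File formats, configuration and the quadrant camera layout.

Stacks travel as multi-page TIFF with the four polarized channels laid out
as quadrants of each camera frame; localization tables as CSV (HDF5
optional); calibration and registration as JSON; configuration as YAML.
Table columns follow the common SMLM dialect (frame, x [nm], y [nm],
intensity [photons]) so tables import directly into standard SMLM viewers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import AffineTransform, CalibrationMatrix
from .optics import CHANNELS, OpticalConfig

__all__ = [
    "QuadrantLayout",
    "LayoutError",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "save_calibration",
    "load_calibration",
    "save_transforms",
    "load_transforms",
    "load_config",
    "save_config",
    "config_hash",
]


class LayoutError(ValueError):
    """Quadrant rectangles do not fit the frame or overlap."""


@dataclass(frozen=True)
class QuadrantLayout:
    """Placement of the four channels inside one camera frame.

    ``rects`` maps channel -> (y0, x0, height, width).  The default puts
    I0 top-left, I90 top-right, I45 bottom-left, I135 bottom-right.
    """

    rects: tuple[tuple[str, tuple[int, int, int, int]], ...]

    @classmethod
    def quadrants(cls, channel_size: int) -> "QuadrantLayout":
        s = channel_size
        return cls((("I0", (0, 0, s, s)), ("I90", (0, s, s, s)),
                    ("I45", (s, 0, s, s)), ("I135", (s, s, s, s))))

    def __post_init__(self):
        d = dict(self.rects)
        if set(d) != set(CHANNELS):
            raise LayoutError(f"layout must define {CHANNELS}")
        sizes = {(h, w) for _, (_, _, h, w) in self.rects}
        if len(sizes) != 1:
            raise LayoutError("all channel rectangles must share one size")
        boxes = [(y, x, y + h, x + w) for _, (y, x, h, w) in self.rects]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise LayoutError("channel rectangles overlap")

    def check_frame(self, shape: tuple[int, int]) -> None:
        H, W = shape
        for c, (y, x, h, w) in self.rects:
            if y + h > H or x + w > W:
                raise LayoutError(
                    f"channel {c} rectangle {(y, x, h, w)} exceeds frame {shape}")

    def split(self, frame: np.ndarray) -> dict[str, np.ndarray]:
        self.check_frame(frame.shape[-2:])
        return {c: frame[..., y:y + h, x:x + w]
                for c, (y, x, h, w) in self.rects}


def write_stack(path, frames: np.ndarray, metadata: dict | None = None) -> None:
    """Write quadrant-layout frames as multi-page TIFF."""
    meta = {"axes": "TYX"}
    if metadata:
        meta.update({k: v for k, v in metadata.items()})
    tifffile.imwrite(path, np.asarray(frames, np.float32),
                     metadata=meta, photometric="minisblack")


def read_stack(path, layout: QuadrantLayout, frames: slice | None = None):
    """Stream per-channel frames from a quadrant-layout TIFF.

    Yields (frame_index, dict channel -> 2D array) without loading the
    whole stack; surface metadata is available via ``tifffile`` directly.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        idx = range(len(pages))
        if frames is not None:
            idx = idx[frames]
        for i in idx:
            try:
                frame = pages[i].asarray()
            except Exception as exc:  # corrupt page
                raise IOError(f"failed to read frame {i} of {path}: {exc}") from exc
            yield i, layout.split(frame)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    """Write a localization table; format chosen by extension (.csv / .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("localizations")
            for col in table.columns:
                data = table[col].values
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)
    else:
        table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            g = f["localizations"]
            cols = {k: np.asarray(g[k]) for k in g}
        df = pd.DataFrame(cols)
        for c in df.columns:
            if df[c].dtype.kind == "S":
                df[c] = df[c].str.decode("utf-8")
        return df
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# calibration / registration / config serialization
# ---------------------------------------------------------------------------

def save_calibration(cal: CalibrationMatrix, path,
                     config: OpticalConfig | None = None) -> None:
    payload = {
        "K": cal.K.tolist(),
        "stderr": None if cal.stderr is None else np.asarray(cal.stderr).tolist(),
        "provenance": cal.provenance,
        "r_squared": None if cal.r_squared is None
        else np.asarray(cal.r_squared).tolist(),
        "condition_number": cal.condition_number,
        "optical_config_hash": config_hash(config) if config else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration(path) -> CalibrationMatrix:
    d = json.loads(Path(path).read_text())
    return CalibrationMatrix(
        K=np.array(d["K"]),
        stderr=None if d.get("stderr") is None else np.array(d["stderr"]),
        provenance=d.get("provenance", "measured"),
        r_squared=None if d.get("r_squared") is None else np.array(d["r_squared"]),
    )


def save_transforms(transforms: dict[str, AffineTransform], path) -> None:
    payload = {c: {"matrix": t.matrix.tolist(), "offset": t.offset.tolist(),
                   "residual_rms_px": t.residual_rms_px, "warning": t.warning}
               for c, t in transforms.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_transforms(path) -> dict[str, AffineTransform]:
    d = json.loads(Path(path).read_text())
    return {c: AffineTransform(np.array(v["matrix"]), np.array(v["offset"]),
                               v.get("residual_rms_px", 0.0), v.get("warning"))
            for c, v in d.items()}


def save_config(config: OpticalConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(config)))


def load_config(path) -> OpticalConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "low_na_channels" in d:
        d["low_na_channels"] = tuple(d["low_na_channels"])
    return OpticalConfig(**d)


def _config_dict(config: OpticalConfig) -> dict:
    d = dataclasses.asdict(config)
    d["low_na_channels"] = list(d["low_na_channels"])
    return d


def config_hash(config: OpticalConfig | None) -> str | None:
    if config is None:
        return None
    blob = yaml.safe_dump(_config_dict(config), sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]
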