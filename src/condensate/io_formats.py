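"""Shared containers and file formats: timelapse stacks, ROIs, tables.

Conventions used throughout the package:

* pixel coordinates are 0-based, ``x`` rightward, ``y`` downward;
* physical quantities carry their unit in the field name (``*_um``, ``*_s``);
* stacks are 4-D ``T x C x Y x X`` arrays with a JSON calibration sidecar;
* tables are UTF-8 TSV with a header row and ``.`` decimal separator;
* genomic intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .exceptions import UncalibratedStackError

__all__ = [
    "ImagingMeta",
    "TimelapseStack",
    "CircleRoi",
    "LineRoi",
    "load_timelapse",
    "save_timelapse",
    "load_rois",
    "save_rois",
    "read_tsv",
    "write_tsv",
]


@dataclass(frozen=True)
class ImagingMeta:
    """Physical calibration of a timelapse acquisition."""

    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("ch0",)
    height_px: int = 64
    width_px: int = 64

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if len(self.channel_names) < 1:
            raise ValueError("at least one channel name is required")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("frame dimensions must be positive")
        object.__setattr__(self, "channel_names", tuple(self.channel_names))


@dataclass
class TimelapseStack:
    """A ``T x C x Y x X`` intensity grid with physical calibration."""

    data: np.ndarray
    meta: ImagingMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack must be 4-D (T,C,Y,X), got ndim={self.data.ndim}")
        t, c, h, w = self.data.shape
        if c != len(self.meta.channel_names):
            raise ValueError(
                f"stack has {c} channels but meta names {len(self.meta.channel_names)}"
            )
        if (h, w) != (self.meta.height_px, self.meta.width_px):
            raise ValueError(
                f"stack frame {h}x{w} does not match meta "
                f"{self.meta.height_px}x{self.meta.width_px}"
            )
        if np.min(self.data) < 0:
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def times_s(self, origin_frame: int = 0) -> np.ndarray:
        """Frame times in seconds with ``t = 0`` at ``origin_frame``."""
        return (np.arange(self.n_frames) - origin_frame) * self.meta.frame_interval_s


@dataclass(frozen=True)
class CircleRoi:
    """A circular region: pixel center, physical diameter."""

    center_px: tuple[float, float]  # (x, y)
    diameter_um: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be > 0")

    def radius_px(self, pixel_size_um: float) -> float:
        return self.diameter_um / (2.0 * pixel_size_um)

    def mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean raster of the circle on a (Y, X) grid."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = self.center_px
        r = self.radius_px(pixel_size_um)
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


@dataclass(frozen=True)
class LineRoi:
    """A line segment with an averaging width perpendicular to it."""

    p0_px: tuple[float, float]
    p1_px: tuple[float, float]
    width_px: int = 1

    def __post_init__(self) -> None:
        if tuple(self.p0_px) == tuple(self.p1_px):
            raise ValueError("line endpoints must differ")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1_px[0] - self.p0_px[0], self.p1_px[1] - self.p0_px[1]))


Roi = Union[CircleRoi, LineRoi]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_timelapse(stack: TimelapseStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar.

    Returns the sidecar path. Pixel values round-trip bit-exactly.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    sidecar = _sidecar_path(path)
    payload = {
        "pixel_size_um": stack.meta.pixel_size_um,
        "frame_interval_s": stack.meta.frame_interval_s,
        "channel_names": list(stack.meta.channel_names),
        "axes": "TCYX",
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def load_timelapse(
    path: str | Path,
    *,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> TimelapseStack:
    """Read a TIFF stack, normalizing axes to ``T x C x Y x X``.

    Calibration comes from the JSON sidecar written by :func:`save_timelapse`;
    explicit keyword arguments override it. A stack without any calibration
    raises :class:`UncalibratedStackError` — there is no silent default.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]  # interpret the leading axis as time
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret a {arr.ndim}-D TIFF as T,C,Y,X")

    sidecar = _sidecar_path(path)
    meta_json: dict = {}
    if sidecar.exists():
        meta_json = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta_json.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta_json.get("frame_interval_s")
    if px is None or dt is None:
        raise UncalibratedStackError(
            f"no calibration for {path}: sidecar {sidecar.name} is missing or "
            "incomplete and no pixel_size_um/frame_interval_s were supplied"
        )
    names = channel_names if channel_names is not None else meta_json.get("channel_names")
    if names is None:
        names = tuple(f"ch{i}" for i in range(arr.shape[1]))
    meta = ImagingMeta(
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
        channel_names=tuple(names),
        height_px=arr.shape[2],
        width_px=arr.shape[3],
    )
    return TimelapseStack(arr, meta)


def save_rois(rois: Sequence[Roi], path: str | Path) -> None:
    entries = []
    for roi in rois:
        if isinstance(roi, CircleRoi):
            entries.append(
                {
                    "type": "circle",
                    "center_px": list(roi.center_px),
                    "diameter_um": roi.diameter_um,
                    "label": roi.label,
                }
            )
        elif isinstance(roi, LineRoi):
            entries.append(
                {
                    "type": "line",
                    "p0_px": list(roi.p0_px),
                    "p1_px": list(roi.p1_px),
                    "width_px": roi.width_px,
                }
            )
        else:  # pragma: no cover - guarded by typing
            raise TypeError(f"unsupported ROI type {type(roi)!r}")
    Path(path).write_text(json.dumps(entries, indent=2))


def load_rois(path: str | Path) -> list[Roi]:
    """Read a JSON ROI list; each entry must declare a known ``type``."""
    entries = json.loads(Path(path).read_text())
    rois: list[Roi] = []
    for i, entry in enumerate(entries):
        kind = entry.get("type")
        if kind == "circle":
            rois.append(
                CircleRoi(
                    center_px=tuple(entry["center_px"]),
                    diameter_um=float(entry["diameter_um"]),
                    label=entry.get("label", ""),
                )
            )
        elif kind == "line":
            rois.append(
                LineRoi(
                    p0_px=tuple(entry["p0_px"]),
                    p1_px=tuple(entry["p1_px"]),
                    width_px=int(entry.get("width_px", 1)),
                )
            )
        else:
            raise ValueError(f"ROI entry {i}: unknown type {kind!r}")
    return rois


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
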