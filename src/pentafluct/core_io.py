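"""Domain types, image/trace I/O, configuration and result serialization.

The containers here are shared by every analysis stage:

* :class:`AcquisitionGeometry` — the microscope timing/scale metadata that
  every correlation fit needs (pixel size, pixel dwell, line time, frame
  time, focal waist).
* :class:`ImageSeries` — a time-ordered stack of 2D intensity frames, one
  stack per detection channel.
* :class:`IntensityTrace` / :class:`CurrentTrace` — 1D time series for
  photobleaching step counting and patch-clamp current analysis.

Image series are persisted as plain multi-page TIFF (channel-interleaved,
geometry recorded as JSON in the image-description tag); traces as one- or
two-column CSV. Acquisition metadata is always supplied explicitly —
vendor TIFF dialects are not parsed, and when embedded tags disagree with
the supplied geometry the discrepancy is logged and the supplied geometry
wins.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger("pentafluct")

__all__ = [
    "AcquisitionGeometry",
    "ImageSeries",
    "IntensityTrace",
    "CurrentTrace",
    "read_image_series",
    "write_image_series",
    "read_trace",
    "write_trace",
    "write_json_result",
    "setup_logging",
]


def setup_logging(verbose: bool = False) -> None:
    """Configure structured logging for CLI and scripts."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Microscope acquisition metadata.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size δr in µm/px.
    focal_waist : float
        Lateral 1/e² radius ω_r of the effective Gaussian detection
        profile, in µm (calibration input).
    modality : str
        ``"raster"`` (point-scanning confocal) or ``"camera"`` (widefield /
        TIRF). Raster requires ``pixel_dwell`` and ``line_time``; camera
        requires ``frame_time``.
    pixel_dwell, line_time, frame_time : float, optional
        τ_p, τ_l and Δt_f in seconds.
    n_channels : int
        Number of detection channels (1 or 2).
    """

    pixel_size: float
    focal_waist: float
    modality: str = "raster"
    pixel_dwell: float | None = None
    line_time: float | None = None
    frame_time: float | None = None
    n_channels: int = 1

    def __post_init__(self) -> None:
        if self.modality not in ("raster", "camera"):
            raise ValueError(f"modality must be 'raster' or 'camera', got {self.modality!r}")
        for name in ("pixel_size", "focal_waist"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("pixel_dwell", "line_time", "frame_time"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.modality == "raster":
            if self.pixel_dwell is None or self.line_time is None:
                raise ValueError("raster modality requires pixel_dwell and line_time")
            if not self.pixel_dwell < self.line_time:
                raise ValueError("pixel_dwell must be smaller than line_time")
        else:
            if self.frame_time is None:
                raise ValueError("camera modality requires frame_time")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "focal_waist": self.focal_waist,
            "modality": self.modality,
            "pixel_dwell": self.pixel_dwell,
            "line_time": self.line_time,
            "frame_time": self.frame_time,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**{k: d[k] for k in (
            "pixel_size", "focal_waist", "modality", "pixel_dwell",
            "line_time", "frame_time", "n_channels") if k in d})


# Paper-grade default geometries (confocal raster scan and TIRF camera).
CONFOCAL_GEOMETRY = AcquisitionGeometry(
    pixel_size=0.05, focal_waist=0.2, modality="raster",
    pixel_dwell=8.19e-6, line_time=4.92e-3, n_channels=1,
)
CAMERA_GEOMETRY = AcquisitionGeometry(
    pixel_size=0.15, focal_waist=0.3, modality="camera",
    frame_time=0.08, n_channels=1,
)


@dataclass
class ImageSeries:
    """Stack(s) of 2D intensity frames, one stack per channel.

    ``data`` is a list with one float array of shape (n_frames, ny, nx) per
    channel. Intensities are non-negative reals: photon-counting inputs are
    integers but detrending corrections produce non-integers, so values are
    never truncated.
    """

    data: list[np.ndarray]
    geometry: AcquisitionGeometry
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("ImageSeries needs at least one channel")
        self.data = [np.asarray(d, dtype=np.float64) for d in self.data]
        shape = self.data[0].shape
        for d in self.data:
            if d.ndim != 3 or d.shape != shape:
                raise ValueError("all channels must share one (frame, row, col) shape")
            if d.shape[0] < 1:
                raise ValueError("ImageSeries needs at least one frame")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(len(self.data))]
        if len(self.channel_names) != len(self.data):
            raise ValueError("one name per channel required")

    @property
    def n_channels(self) -> int:
        return len(self.data)

    @property
    def n_frames(self) -> int:
        return self.data[0].shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data[0].shape[1:]

    def channel(self, i: int) -> np.ndarray:
        return self.data[i]

    def with_data(self, data: list[np.ndarray]) -> "ImageSeries":
        return ImageSeries(data=data, geometry=self.geometry,
                           channel_names=list(self.channel_names))


@dataclass
class IntensityTrace:
    """Per-frame intensity samples for a single diffraction-limited spot."""

    values: np.ndarray
    frame_interval: float
    center: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CurrentTrace:
    """Patch-clamp current samples in pA."""

    values: np.ndarray
    sampling_interval: float
    holding_potential: float = 60.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("current trace must be a non-empty 1D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("current values must be finite")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.sampling_interval


# ---------------------------------------------------------------------------
# Image series I/O
# ---------------------------------------------------------------------------


def write_image_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a series as a channel-interleaved multi-page TIFF.

    Page ``k`` holds frame ``k // n_channels`` of channel ``k % n_channels``
    (page 0 → channel 0 frame 0). The acquisition geometry is stored as
    JSON in the TIFF image description.
    """
    path = Path(path)
    n_ch, n_fr = series.n_channels, series.n_frames
    ny, nx = series.frame_shape
    pages = np.empty((n_fr * n_ch, ny, nx), dtype=np.float32)
    for c in range(n_ch):
        pages[c::n_ch] = series.channel(c)
    meta = {"geometry": series.geometry.to_dict(),
            "channel_names": series.channel_names}
    try:
        tifffile.imwrite(path, pages, description=json.dumps(meta))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot write TIFF to {path}: {exc}") from exc
    return path


def read_image_series(path: str | Path,
                      geometry: AcquisitionGeometry) -> ImageSeries:
    """Read a single- or multi-page TIFF into an :class:`ImageSeries`.

    Pages are de-interleaved according to ``geometry.n_channels``. If the
    file carries embedded geometry metadata that conflicts with the
    supplied geometry, the conflict is logged and the supplied geometry
    wins.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description if tif.pages else ""
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of shape {pages.shape}")

    channel_names: list[str] = []
    if desc:
        try:
            meta = json.loads(desc)
            channel_names = list(meta.get("channel_names", []))
            embedded = meta.get("geometry")
            if embedded is not None and embedded != geometry.to_dict():
                logger.warning(
                    "%s: embedded geometry differs from supplied geometry; "
                    "supplied geometry wins", path)
        except json.JSONDecodeError:
            pass

    n_ch = geometry.n_channels
    if pages.shape[0] % n_ch != 0:
        raise ValueError(
            f"{path}: page count {pages.shape[0]} not divisible by "
            f"channel count {n_ch}")
    data = [pages[c::n_ch].astype(np.float64) for c in range(n_ch)]
    if len(channel_names) != n_ch:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return ImageSeries(data=data, geometry=geometry, channel_names=channel_names)


# ---------------------------------------------------------------------------
# Trace I/O and result writers
# ---------------------------------------------------------------------------


def write_trace(values: np.ndarray, interval: float, path: str | Path,
                times: bool = True) -> Path:
    """Write a 1D trace as CSV: either (time, value) rows or a single column."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if times:
            for i, v in enumerate(values):
                w.writerow([f"{i * interval:.9g}", f"{v:.9g}"])
        else:
            for v in values:
                w.writerow([f"{v:.9g}"])
    return path


def read_trace(path: str | Path, interval: float | None = None
               ) -> tuple[np.ndarray, float]:
    """Read a one- or two-column CSV trace.

    Returns (values, sampling_interval). For two-column files the interval
    is inferred from the time column; for single-column files ``interval``
    must be supplied.
    """
    path = Path(path)
    rows: list[Sequence[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if row and any(cell.strip() for cell in row):
                rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty trace file")
    ncol = len(rows[0])
    arr = np.array([[float(c) for c in row] for row in rows])
    if ncol >= 2:
        t, v = arr[:, 0], arr[:, 1]
        if len(t) > 1:
            dt = float(np.median(np.diff(t)))
        elif interval is not None:
            dt = interval
        else:
            raise ValueError("cannot infer sampling interval from one sample")
        return v, dt
    if interval is None:
        raise ValueError("single-column trace requires an explicit interval")
    return arr[:, 0], interval


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json_result(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyJSONEncoder)
        fh.write("\n")
    return path
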