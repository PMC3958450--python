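"""Calibrated image stacks, ROIs, focus selection, and shared configuration.

A :class:`Movie` is the in-memory currency of the whole pipeline: a
``T x Y x X`` intensity array plus the spatial calibration (micrometres per
pixel) and the temporal calibration (seconds per frame).  Confocal time-lapse
acquisitions of mitochondria in fibroblasts are typically 8-bit, 0.09 um/px,
with one frame every ~109 s; those values are the package defaults.

All pixel coordinates are 0-based ``(row, column)``; rectangles are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi

logger = logging.getLogger("odyn")

DEFAULT_PIXEL_SIZE_UM = 0.09
DEFAULT_TIME_STEP_S = 109.0


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` enables DEBUG."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle in pixel coordinates, half-open, row-major."""

    y0: int
    x0: int
    height: int
    width: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"Roi must have height, width >= 1, got {self}")
        if self.y0 < 0 or self.x0 < 0:
            raise ValueError(f"Roi origin must be non-negative, got {self}")

    def as_slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    def contained_in(self, shape: tuple[int, int]) -> bool:
        return self.y0 + self.height <= shape[0] and self.x0 + self.width <= shape[1]


@dataclass
class Movie:
    """Calibrated intensity time series.

    Parameters
    ----------
    frames
        ``(T, Y, X)`` non-negative intensity array.
    pixel_size_um
        Micrometres per pixel in X and Y.
    time_step_s
        Seconds between consecutive frames.
    z_stacks
        Optional ``(T, Z, Y, X)`` volumetric data from which the analysis
        plane was or can be chosen.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    time_step_s: float = DEFAULT_TIME_STEP_S
    z_stacks: np.ndarray | None = None
    z_spacing_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, Y, X), got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("Movie needs at least one frame")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.time_step_s > 0:
            raise ValueError(f"time_step_s must be > 0, got {self.time_step_s}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_step_s


def read_stack(path: str | Path,
               pixel_size_um: float | None = None,
               time_step_s: float | None = None,
               allow_rgb: bool = False) -> Movie:
    """Read a single- or multi-page grayscale TIFF as a :class:`Movie`.

    Calibration is taken from the arguments; when an argument is ``None`` the
    value stored by :func:`write_stack` (if any) is used, and package defaults
    apply last.  Explicit arguments always win over file metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        stored: dict = {}
        if tif.shaped_metadata:
            stored = dict(tif.shaped_metadata[0])
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        if not allow_rgb:
            raise ValueError(
                f"{path} looks like an RGB image; pass allow_rgb=True to average channels")
        data = data.mean(axis=-1)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D page or a 3-D stack, got shape {data.shape}")
    px = pixel_size_um if pixel_size_um is not None else stored.get(
        "pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
    dt = time_step_s if time_step_s is not None else stored.get(
        "time_step_s", DEFAULT_TIME_STEP_S)
    if not (px > 0 and dt > 0):
        raise ValueError(f"non-positive calibration: pixel_size_um={px}, time_step_s={dt}")
    return Movie(frames=data, pixel_size_um=float(px), time_step_s=float(dt))


def write_stack(path: str | Path, movie: Movie) -> None:
    """Write a movie to a multi-page TIFF, embedding its calibration."""
    tifffile.imwrite(
        Path(path), movie.frames,
        metadata={"pixel_size_um": movie.pixel_size_um,
                  "time_step_s": movie.time_step_s})


def best_focus_plane(z_stack: np.ndarray) -> int:
    """Index of the sharpest plane of a ``(Z, Y, X)`` stack.

    The focus score is the variance of the Laplacian response, a standard
    autofocus criterion; it replaces the manual best-in-focus choice with a
    reproducible one.  Ties resolve to the first index.
    """
    z_stack = np.asarray(z_stack, dtype=float)
    if z_stack.ndim == 2:
        z_stack = z_stack[None]
    if z_stack.ndim != 3 or z_stack.shape[0] < 1:
        raise ValueError("z_stack must be a non-empty (Z, Y, X) array")
    scores = [float(np.var(ndi.laplace(plane))) for plane in z_stack]
    return int(np.argmax(scores))


def crop(movie: Movie, roi: Roi) -> Movie:
    """Spatial sub-movie over ``roi``; calibration preserved."""
    if not roi.contained_in(movie.frame_shape):
        raise ValueError(f"{roi} exceeds frame shape {movie.frame_shape}")
    ys, xs = roi.as_slices()
    return replace(movie, frames=movie.frames[:, ys, xs].copy(), z_stacks=None)


def roi_from_mapping(d: dict) -> Roi:
    return Roi(y0=int(d["y0"]), x0=int(d["x0"]),
               height=int(d["height"]), width=int(d["width"]),
               label=str(d.get("label", "")))


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (paths, calibration, ROIs, stage params)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
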