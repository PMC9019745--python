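"""Movie and mask I/O, per-pixel temporal normalization, and window slicing.

A *movie* is a T x H x W stack of grayscale frames ordered by acquisition
time.  All downstream stages work on per-pixel time series: each of the
P = H*W pixels contributes one row to a feature matrix whose columns are
consecutive frames of a chosen window.

Frame indices are **1-based** in every public signature (frame 1 is the
first frame), matching how window positions are usually quoted for this
kind of data; storage is 0-based internally.  Pixel rows are linearized in
row-major (C) order: row p of a feature matrix is pixel
(p // W, p % W).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, MovieIOError, ValidationError, WindowRangeError

__all__ = [
    "Movie",
    "NormalizedMovie",
    "FeatureMatrix",
    "BinaryMask",
    "read_movie",
    "write_movie",
    "normalize_per_pixel",
    "extract_window",
    "write_mask",
    "read_mask",
]


@dataclass
class Movie:
    """Raw grayscale movie: T x H x W intensities plus acquisition metadata."""

    data: np.ndarray
    frame_rate_hz: float = 1000.0
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(
                f"movie data must be T x H x W (3-D), got {self.data.ndim}-D "
                f"shape {self.data.shape}; a single 2-D frame cannot support "
                "temporal features"
            )
        if min(self.data.shape) < 1:
            raise ValidationError(f"movie dimensions must all be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("movie contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("movie contains negative intensities")
        if self.frame_rate_hz <= 0:
            raise ValidationError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class NormalizedMovie:
    """Per-pixel min-max normalized movie.

    Every non-constant pixel's series spans [0, 1] exactly; pixels whose raw
    series is constant are filled with 0 and flagged in
    ``constant_pixel_mask``.
    """

    data: np.ndarray
    constant_pixel_mask: np.ndarray
    frame_rate_hz: float = 1000.0

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class FeatureMatrix:
    """P x n matrix of per-pixel time windows.

    Row p is pixel (p // W, p % W) of the frame; column j is normalized
    intensity at frame ``start_frame + j`` (1-based frames).
    """

    values: np.ndarray
    n_frames: int
    start_frame: int
    shape_hw: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.shape_hw
        if self.values.shape != (h * w, self.n_frames):
            raise DimensionError(
                f"feature matrix shape {self.values.shape} inconsistent with "
                f"H*W={h * w}, n={self.n_frames}"
            )

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryMask:
    """H x W {0,1} image; 1 marks object (tissue) pixels."""

    values: np.ndarray
    frame_index: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DimensionError(f"mask must be 2-D, got shape {self.values.shape}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("mask values must be exactly 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def object_ratio(self) -> float:
        """Fraction of pixels labeled object (the heart ratio r)."""
        return float(self.values.mean())


def read_movie(path, format: str | None = None) -> Movie:
    """Read a movie stack from a multi-page TIFF or a ``.npy`` array file.

    ``format`` may be ``"tiff"`` or ``"npy"``; by default it is inferred
    from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "npy" if path.suffix.lower() == ".npy" else "tiff"
    try:
        if format == "tiff":
            import tifffile

            data = tifffile.imread(path)
        elif format == "npy":
            data = np.load(path)
        else:
            raise MovieIOError(f"unknown movie format {format!r}")
    except MovieIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decode failure
        raise MovieIOError(f"could not read movie from {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        raise DimensionError(
            f"{path} decodes to a single 2-D frame; temporal segmentation needs a stack"
        )
    if data.ndim != 3 or data.size == 0:
        raise MovieIOError(
            f"could not read movie from {path}: decoded to shape {data.shape}"
        )
    return Movie(data=np.asarray(data), source_path=str(path))


def write_movie(movie: Movie, path) -> None:
    """Write a movie as a multi-page TIFF (or ``.npy`` if so suffixed)."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".npy":
            np.save(path, movie.data)
        else:
            import tifffile

            tifffile.imwrite(path, movie.data)
    except Exception as exc:  # noqa: BLE001
        raise MovieIOError(f"could not write movie to {path}: {exc}") from exc


def normalize_per_pixel(movie: Movie) -> NormalizedMovie:
    """Min-max normalize each pixel's time series independently to [0, 1].

    The minimum and maximum are taken over time *per pixel*, not over the
    whole movie, so a dim pixel and a bright pixel both end up spanning the
    full unit interval.  This is what amplifies background noise into
    full-range signals and is the statistical basis of the whole method.
    Constant pixels (raw min == raw max) are filled with 0 and flagged.
    """
    data = movie.data.astype(np.float64)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    out = (data - lo[None]) / safe_span[None]
    out[:, constant] = 0.0
    return NormalizedMovie(
        data=out, constant_pixel_mask=constant, frame_rate_hz=movie.frame_rate_hz
    )


def extract_window(nmovie: NormalizedMovie, start_frame: int, n_frames: int) -> FeatureMatrix:
    """Slice frames [start_frame, start_frame + n_frames - 1] into a P x n matrix.

    ``start_frame`` is 1-based; the window must satisfy
    ``start_frame + n_frames - 1 <= T``.
    """
    t = nmovie.n_frames
    if n_frames < 1:
        raise WindowRangeError(f"n_frames must be >= 1, got {n_frames}")
    if start_frame < 1:
        raise WindowRangeError(f"start_frame is 1-based and must be >= 1, got {start_frame}")
    if start_frame + n_frames - 1 > t:
        raise WindowRangeError(
            f"window [i={start_frame}, i+n-1={start_frame + n_frames - 1}] exceeds "
            f"movie length T={t}"
        )
    h, w = nmovie.shape_hw
    block = nmovie.data[start_frame - 1 : start_frame - 1 + n_frames]
    values = block.reshape(n_frames, h * w).T.copy()
    return FeatureMatrix(
        values=values, n_frames=n_frames, start_frame=start_frame, shape_hw=(h, w)
    )


def write_mask(mask: BinaryMask, path) -> None:
    """Store a mask as an 8-bit image: 0 = background, 255 = object."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(values=np.asarray(mask))
    path = Path(path)
    img = (mask.values * 255).astype(np.uint8)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, img)
        else:
            import imageio.v3 as iio

            iio.imwrite(path, img)
    except Exception as exc:  # noqa: BLE001
        raise MovieIOError(f"could not write mask to {path}: {exc}") from exc


def read_mask(path, frame_index: int = 1) -> BinaryMask:
    """Read a stored mask image back to a {0,1} array (nonzero -> 1)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise MovieIOError(f"could not read mask from {path}: {exc}") from exc
    return BinaryMask(values=(np.asarray(img) > 0).astype(np.uint8), frame_index=frame_index)
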