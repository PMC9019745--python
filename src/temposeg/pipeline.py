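"""End-to-end segmentation pipelines, polygon labeling, mask filtering, metrics.

The combined method runs in three steps per movie:

1. harvest confident pseudo-labels from one frame window with discounted
   k-means (one run per class, discounting the rival centroid);
2. train a linear classifier (SVM by default) on the pseudo-labels;
3. classify every pixel of each requested window into a binary mask and
   clean dotted noise with the mask median filter.

``tracking_segment`` slides the window across the movie with per-window
re-harvest so moving boundaries are followed with fresh labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .classifiers import LabeledDataset, predict_mask, train
from .errors import GeometryError, ParameterError, ValidationError
from .kmeans import fit_discounted_kmeans, harvest_training_set, identify_object_cluster
from .movie_io import (
    BinaryMask,
    Movie,
    NormalizedMovie,
    extract_window,
    normalize_per_pixel,
)

__all__ = [
    "PolygonROI",
    "FilterSpec",
    "SegmentationResult",
    "label_from_polygons",
    "median_filter_mask",
    "combined_segment",
    "kmeans_only_segment",
    "tracking_segment",
    "ratio_consistency",
    "load_polygon_file",
]


@dataclass
class PolygonROI:
    """Simple polygon over (row, col) frame coordinates with a class label."""

    vertices: Sequence[tuple[float, float]]
    label: int

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")
        if self.label not in (0, 1):
            raise ValidationError(f"polygon label must be 0 or 1, got {self.label}")
        from shapely import Polygon

        if not Polygon(self.vertices).is_valid:
            raise GeometryError("polygon is not simple (self-intersecting or degenerate)")


@dataclass
class FilterSpec:
    """Mask median-filter settings.

    A pixel keeps its value when *more than* ``threshold`` of the
    ``neighborhood x neighborhood`` surrounding pixels (center excluded,
    out-of-frame neighbors counted as 0-valued) share that value; otherwise
    it flips.  ``remove_heart``/``remove_background`` gate whether 1-valued
    / 0-valued pixels may flip.
    """

    threshold: int = 3
    neighborhood: int = 3
    remove_heart: bool = True
    remove_background: bool = True
    passes: int = 1

    def __post_init__(self) -> None:
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ParameterError(
                f"neighborhood must be an odd integer >= 3, got {self.neighborhood}"
            )
        if not (0 <= self.threshold <= self.neighborhood**2 - 1):
            raise ParameterError(
                f"threshold must lie in [0, {self.neighborhood ** 2 - 1}], "
                f"got {self.threshold}"
            )
        if self.passes < 1:
            raise ParameterError(f"passes must be >= 1, got {self.passes}")


@dataclass
class SegmentationResult:
    """Per-frame masks, heart ratios r, and the configuration that produced them."""

    masks: list[BinaryMask]
    heart_ratio_per_frame: list[float] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    log: str = ""

    def __post_init__(self) -> None:
        if not self.heart_ratio_per_frame:
            self.heart_ratio_per_frame = [m.object_ratio for m in self.masks]
        for r, m in zip(self.heart_ratio_per_frame, self.masks):
            if abs(r - m.object_ratio) > 1e-12:
                raise ValidationError(
                    f"stored ratio {r} disagrees with mask ratio {m.object_ratio} "
                    f"(frame {m.frame_index})"
                )


def median_filter_mask(mask: BinaryMask, spec: FilterSpec | None = None) -> BinaryMask:
    """Mask-specific median filter removing dotted noise.

    All counts are taken from the input mask of each pass (synchronous
    update), so the result is independent of pixel visiting order.
    """
    if spec is None:
        spec = FilterSpec()
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(values=np.asarray(mask))
    m = mask.values.astype(np.int64)
    k = spec.neighborhood
    kernel = np.ones((k, k), dtype=np.int64)
    kernel[k // 2, k // 2] = 0
    n_neigh = k * k - 1
    for _ in range(spec.passes):
        ones_count = ndimage.convolve(m, kernel, mode="constant", cval=0)
        same_count = np.where(m == 1, ones_count, n_neigh - ones_count)
        keep = same_count > spec.threshold
        new = m.copy()
        if spec.remove_heart:
            new[(m == 1) & ~keep] = 0
        if spec.remove_background:
            new[(m == 0) & ~keep] = 1
        m = new
    return BinaryMask(values=m.astype(np.uint8), frame_index=mask.frame_index)


def label_from_polygons(
    nmovie: NormalizedMovie, rois: Sequence[PolygonROI]
) -> LabeledDataset:
    """Build a labeled dataset from manually drawn polygon ROIs.

    Every pixel whose center lies strictly inside a polygon receives that
    polygon's label; its feature vector is the pixel's full T-frame
    normalized series (dataset shape (m, T)).  Both classes must be
    represented; pixels claimed by polygons of both labels are an error.
    """
    from shapely import Polygon, box, contains_xy

    h, w = nmovie.shape_hw
    labels_present = {r.label for r in rois}
    if labels_present != {0, 1}:
        raise ValidationError(
            f"need both heart (1) and non-heart (0) polygons, got labels {labels_present}"
        )
    frame_rect = box(-0.5, -0.5, h - 0.5, w - 0.5)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    flat_r, flat_c = rr.ravel(), cc.ravel()

    claimed: dict[int, set[int]] = {0: set(), 1: set()}
    for roi in rois:
        poly = Polygon(roi.vertices)
        if not poly.intersects(frame_rect):
            raise GeometryError(f"polygon with label {roi.label} lies outside the frame")
        inside = contains_xy(poly, flat_r, flat_c)
        claimed[roi.label].update(np.flatnonzero(inside).tolist())

    conflict = claimed[0] & claimed[1]
    if conflict:
        sample = sorted(conflict)[:10]
        raise ValidationError(
            f"{len(conflict)} pixels claimed with both labels, e.g. pixel rows {sample}"
        )
    t = nmovie.n_frames
    series = nmovie.data.reshape(t, h * w).T  # (P, T)
    idx1 = np.asarray(sorted(claimed[1]), dtype=np.intp)
    idx0 = np.asarray(sorted(claimed[0]), dtype=np.intp)
    if idx1.size == 0 or idx0.size == 0:
        raise ValidationError("each class polygon set must enclose at least one pixel center")
    idx = np.concatenate([idx1, idx0])
    labels = np.concatenate([np.ones(idx1.size, int), np.zeros(idx0.size, int)])
    return LabeledDataset(
        features=series[idx],
        labels=labels,
        provenance="manual_polygons",
        pixel_indices=idx,
    )


def load_polygon_file(path) -> list[PolygonROI]:
    """Read a JSON list of ``{"label": 0|1, "vertices": [[row, col], ...]}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return [PolygonROI(vertices=[tuple(v) for v in item["vertices"]], label=item["label"]) for item in raw]


def _window_features(movie: Movie, nmovie: NormalizedMovie | None, i: int, n: int,
                     normalization: str):
    """Features for window [i, i+n-1] under either normalization mode.

    ``"movie"`` normalizes each pixel over the full record once;
    ``"window"`` re-normalizes within the window itself, which is required
    when the object moves: pixels a moving object vacates keep the full
    record's dynamic range and would otherwise collapse into a spurious
    low-level cluster of their own.
    """
    if normalization == "movie":
        return extract_window(nmovie, i, n)
    if normalization != "window":
        raise ParameterError(f"normalization must be 'movie' or 'window', got {normalization!r}")
    sub = Movie(
        data=movie.data[i - 1 : i - 1 + n],
        frame_rate_hz=movie.frame_rate_hz,
        source_path=movie.source_path,
    )
    feats = extract_window(normalize_per_pixel(sub), 1, n)
    feats.start_frame = i
    return feats


def _resolve_frames(frames, n: int, t: int) -> list[int]:
    if frames is None:
        frames = [1]
    frames = [int(i) for i in frames]
    for i in frames:
        if i < 1 or i + n - 1 > t:
            raise ParameterError(
                f"frame window [i={i}, i+n-1={i + n - 1}] exceeds movie length T={t}"
            )
    return frames


def combined_segment(
    movie: Movie,
    n: int,
    frames: Sequence[int] | None = None,
    method: str = "svm",
    gammas: tuple[float, float] = (0.8, 0.8),
    seed: int = 0,
    filter_spec: FilterSpec | None = None,
    reharvest_per_window: bool = False,
    object_cluster: int | None = None,
    hyperparams: dict | None = None,
    normalization: str = "movie",
) -> SegmentationResult:
    """Unsupervised-to-supervised segmentation of the requested frames.

    Pseudo-labels are harvested from the first requested window (or from
    every window when ``reharvest_per_window`` is set, as in tracking), a
    ``method`` classifier is trained on them, each frame ``i`` is
    classified from its window [i, i+n-1], and the median filter is
    applied.  ``gammas`` are the (object, background) discount factors.
    ``normalization`` is per-movie by default; tracking uses per-window.
    """
    nmovie = normalize_per_pixel(movie) if normalization == "movie" else None
    frames = _resolve_frames(frames, n, movie.n_frames)
    if filter_spec is None:
        filter_spec = FilterSpec()
    if isinstance(gammas, str):
        if gammas != "auto":
            raise ParameterError(f"gammas must be a pair or 'auto', got {gammas!r}")
        gamma_obj = gamma_bg = None
        target_fraction = 0.5
    else:
        gamma_obj, gamma_bg = gammas
        target_fraction = None

    log_lines = [
        f"combined_segment: method={method} n={n} gammas=({gamma_obj},{gamma_bg}) "
        f"seed={seed} frames={frames} reharvest={reharvest_per_window} "
        f"normalization={normalization}"
    ]
    masks: list[BinaryMask] = []
    model = None
    for i in frames:
        feats = _window_features(movie, nmovie, i, n, normalization)
        if model is None or reharvest_per_window:
            if target_fraction is None:
                ds = harvest_training_set(
                    feats, gamma_obj=gamma_obj, gamma_bg=gamma_bg, seed=seed,
                    object_cluster=object_cluster,
                )
            else:
                ds = harvest_training_set(
                    feats, seed=seed, object_cluster=object_cluster,
                    target_fraction=target_fraction,
                )
            counts = ds.class_counts()
            log_lines.append(
                f"window {i}: harvested {counts[1]} object / {counts[0]} background pixels"
            )
            model = train(ds, kind=method, hyperparams=hyperparams)
        raw = predict_mask(model, feats)
        masks.append(median_filter_mask(raw, filter_spec))

    snapshot = {
        "method": method,
        "n": n,
        "frames": frames,
        "gamma_obj": gamma_obj,
        "gamma_bg": gamma_bg,
        "seed": seed,
        "reharvest_per_window": reharvest_per_window,
        "normalization": normalization,
        "filter": {
            "threshold": filter_spec.threshold,
            "neighborhood": filter_spec.neighborhood,
            "remove_heart": filter_spec.remove_heart,
            "remove_background": filter_spec.remove_background,
            "passes": filter_spec.passes,
        },
    }
    return SegmentationResult(masks=masks, config_snapshot=snapshot, log="\n".join(log_lines))


def kmeans_only_segment(
    movie: Movie,
    n: int,
    frame: int = 1,
    seed: int = 0,
    object_cluster: int | None = None,
    normalization: str = "movie",
) -> BinaryMask:
    """Plain k-means (gamma=1) baseline: cluster the window, reshape to a mask."""
    nmovie = normalize_per_pixel(movie) if normalization == "movie" else None
    (frame,) = _resolve_frames([frame], n, movie.n_frames)
    feats = _window_features(movie, nmovie, frame, n, normalization)
    model = fit_discounted_kmeans(feats, gamma=1.0, discounted_index=1, seed=seed)
    obj = identify_object_cluster(model, override=object_cluster)
    h, w = feats.shape_hw
    values = (model.assignments == obj).astype(np.uint8).reshape(h, w)
    return BinaryMask(values=values, frame_index=frame)


def tracking_segment(
    movie: Movie,
    n: int,
    stride: int = 1,
    method: str = "svm",
    gammas="auto",
    seed: int = 0,
    filter_spec: FilterSpec | None = None,
    hyperparams: dict | None = None,
    normalization: str = "window",
) -> SegmentationResult:
    """Slide the window across the movie with per-window pseudo-label re-harvest.

    Masks are produced for starts 1, 1+stride, ... while the window fits;
    fresh pseudo-labels per window keep up with moving boundaries, and the
    default per-window normalization keeps vacated pixels from retaining
    the record-wide dynamic range.
    """
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")
    t = movie.n_frames
    starts = list(range(1, t - n + 2, stride))
    if not starts:
        raise ParameterError(f"window of n={n} frames does not fit in T={t}")
    return combined_segment(
        movie,
        n=n,
        frames=starts,
        method=method,
        gammas=gammas,
        seed=seed,
        filter_spec=filter_spec,
        reharvest_per_window=True,
        hyperparams=hyperparams,
        normalization=normalization,
    )


def ratio_consistency(results_by_n: Mapping[int, SegmentationResult]):
    """Heart ratio of frame 1 per window size n, and their population STD.

    The STD across window sizes measures how consistent a method's
    segmentation is as n varies (lower = more consistent).
    """
    if not results_by_n:
        raise ValidationError("results_by_n is empty")
    if len(results_by_n) < 2:
        raise ValidationError("need results for at least 2 window sizes")
    ratios = {int(n): float(res.heart_ratio_per_frame[0]) for n, res in results_by_n.items()}
    std = float(np.std(list(ratios.values())))  # population STD
    return ratios, std
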