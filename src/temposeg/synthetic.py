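"""Synthetic optical-mapping movies with per-frame ground-truth masks.

The generator emulates the statistical structure the segmentation method
relies on: pixels inside a tissue-shaped object carry a repeating action
potential (AP)-like waveform — a fast linear upstroke, a plateau decaying
exponentially, then diastole at baseline — while background pixels carry
only noise.  Because every pixel is later min-max normalized over time,
that background noise is amplified to span the full [0, 1] range, which is
exactly the property (and the difficulty) the method exploits in real
fluorescence recordings.

Optional features:

* a per-pixel conduction delay, linear in distance from the pacing corner,
  emulating AP wave propagation across the tissue;
* rigid rotation or isotropic shrinking of the object across frames, for
  moving-boundary tracking experiments;
* slow baseline wander on background pixels (a per-pixel random walk).
  Real fluorescence backgrounds drift with illumination and bleaching;
  pure i.i.d. noise, once normalized, centres every background pixel at
  0.5, which makes even very short windows artificially easy to cluster.
  Wander is off by default.

Default geometry and timing mirror a typical 1 kHz, 1,024-frame,
100 x 100 px recording of a paced whole heart: a centred disk occupying
roughly a quarter of the frame, 4 Hz pacing (250-frame cycle length), and
an AP duration of 150 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, ParameterError, ValidationError
from .movie_io import BinaryMask, Movie

__all__ = [
    "Waveform",
    "Disk",
    "Ellipse",
    "PolygonShape",
    "Motion",
    "SyntheticSpec",
    "SyntheticMovie",
    "generate",
    "evaluate_masks",
    "sparse_informative_dataset",
]


@dataclass
class Waveform:
    """Repeating AP-like pulse: linear upstroke, exponential plateau decay.

    All times are in frames.  ``phase_frames`` delays the first upstroke so
    a recording can start in diastole.  The pulse occupies
    [0, apd_frames) of each cycle; the rest is diastole at baseline.
    """

    period_frames: int = 250
    upstroke_frames: int = 5
    apd_frames: int = 150
    amplitude: float = 0.5
    baseline: float = 0.2
    phase_frames: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.upstroke_frames < self.apd_frames <= self.period_frames):
            raise ParameterError(
                "waveform must satisfy 0 < upstroke < apd <= period, got "
                f"upstroke={self.upstroke_frames}, apd={self.apd_frames}, "
                f"period={self.period_frames}"
            )
        if self.amplitude < 0:
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")

    def pulse(self, t) -> np.ndarray:
        """Normalized pulse value in [0, 1] at (possibly fractional) frame t."""
        s = np.asarray(t, dtype=np.float64) % self.period_frames
        up, apd = self.upstroke_frames, self.apd_frames
        tau = max((apd - up) / 3.0, 1e-9)
        out = np.zeros_like(s)
        rising = s < up
        out[rising] = s[rising] / up
        decaying = (s >= up) & (s < apd)
        out[decaying] = np.exp(-(s[decaying] - up) / tau)
        return out


@dataclass
class Disk:
    center: tuple[float, float] = (49.5, 49.5)  # (row, col)
    radius: float = 30.0

    def contains(self, rr, cc, frame: int, motion: "Motion | None") -> np.ndarray:
        radius = self.radius
        if motion is not None and motion.kind == "shrink":
            radius = radius * motion.scale_per_frame ** frame
        # rotation leaves a disk invariant
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= radius**2

    def bounds(self) -> tuple[float, float, float, float]:
        r0, c0 = self.center
        return r0 - self.radius, c0 - self.radius, r0 + self.radius, c0 + self.radius


@dataclass
class Ellipse:
    center: tuple[float, float] = (49.5, 49.5)
    semi_major: float = 35.0
    semi_minor: float = 20.0
    angle_deg: float = 0.0

    def contains(self, rr, cc, frame: int, motion: "Motion | None") -> np.ndarray:
        a, b = self.semi_major, self.semi_minor
        angle = self.angle_deg
        if motion is not None:
            if motion.kind == "shrink":
                s = motion.scale_per_frame ** frame
                a, b = a * s, b * s
            elif motion.kind == "rotate":
                angle = angle + motion.deg_per_frame * frame
        th = np.deg2rad(angle)
        dr, dc = rr - self.center[0], cc - self.center[1]
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def bounds(self) -> tuple[float, float, float, float]:
        r0, c0 = self.center
        ext = max(self.semi_major, self.semi_minor)
        return r0 - ext, c0 - ext, r0 + ext, c0 + ext


@dataclass
class PolygonShape:
    vertices: Sequence[tuple[float, float]] = ()  # (row, col) pairs

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError("polygon shape needs >= 3 vertices")

    def _transformed(self, frame: int, motion: "Motion | None") -> np.ndarray:
        v = np.asarray(self.vertices, dtype=np.float64)
        ctr = v.mean(axis=0)
        if motion is not None:
            if motion.kind == "shrink":
                v = ctr + (v - ctr) * motion.scale_per_frame ** frame
            elif motion.kind == "rotate":
                th = np.deg2rad(motion.deg_per_frame * frame)
                rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                v = ctr + (v - ctr) @ rot.T
        return v

    def contains(self, rr, cc, frame: int, motion: "Motion | None") -> np.ndarray:
        from shapely import Polygon, contains_xy

        v = self._transformed(frame, motion)
        poly = Polygon(v)
        return contains_xy(poly, rr.ravel(), cc.ravel()).reshape(rr.shape)

    def bounds(self) -> tuple[float, float, float, float]:
        v = np.asarray(self.vertices, dtype=np.float64)
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()


@dataclass
class Motion:
    """Rigid object motion: 'none', 'rotate' (deg/frame) or 'shrink' (scale/frame)."""

    kind: str = "none"
    deg_per_frame: float = 0.0
    scale_per_frame: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rotate", "shrink"):
            raise ParameterError(f"motion kind must be none|rotate|shrink, got {self.kind!r}")
        if self.kind == "shrink" and not (0 < self.scale_per_frame <= 1):
            raise ParameterError(
                f"shrink scale_per_frame must be in (0, 1], got {self.scale_per_frame}"
            )


@dataclass
class SyntheticSpec:
    """Full description of a synthetic movie; deterministic given ``seed``."""

    height: int = 100
    width: int = 100
    n_frames: int = 1024
    frame_rate_hz: float = 1000.0
    shape: Disk | Ellipse | PolygonShape = field(default_factory=Disk)
    waveform: Waveform = field(default_factory=Waveform)
    conduction_delay_per_px: float = 0.0  # frames per pixel of distance from corner (0,0)
    noise_sigma_object: float = 0.02
    noise_sigma_background: float = 0.02
    background_wander_sigma: float = 0.0  # per-frame random-walk step on background pixels
    motion: Motion | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_object < 0 or self.noise_sigma_background < 0:
            raise ParameterError("noise sigmas must be >= 0")
        if self.background_wander_sigma < 0:
            raise ParameterError("background_wander_sigma must be >= 0")


@dataclass
class SyntheticMovie:
    """Generated movie plus its per-frame ground-truth object masks."""

    movie: Movie
    truth_masks: list[BinaryMask]
    spec: SyntheticSpec

    def truth_stack(self) -> np.ndarray:
        return np.stack([m.values for m in self.truth_masks])


def _truth_for_frame(spec: SyntheticSpec, frame: int, rr, cc) -> np.ndarray:
    motion = spec.motion if (spec.motion and spec.motion.kind != "none") else None
    return spec.shape.contains(rr, cc, frame, motion)


def generate(spec: SyntheticSpec) -> SyntheticMovie:
    """Render the movie described by ``spec``.

    Object pixels receive ``baseline + amplitude * pulse(t - delay) +
    N(0, sigma_obj)``; background pixels receive ``baseline +
    N(0, sigma_bg)`` plus optional baseline wander.  Truth masks are
    rasterized per frame by pixel-center inclusion.
    """
    h, w, t = spec.height, spec.width, spec.n_frames
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")

    rmin, cmin, rmax, cmax = spec.shape.bounds()
    if rmin < -0.5 or cmin < -0.5 or rmax > h - 0.5 or cmax > w - 0.5:
        raise GeometryError(
            f"object bounds ({rmin:.1f},{cmin:.1f})-({rmax:.1f},{cmax:.1f}) exceed "
            f"the {h}x{w} frame"
        )

    static = spec.motion is None or spec.motion.kind == "none"
    if static:
        mask0 = _truth_for_frame(spec, 0, rr, cc)
        truth = np.broadcast_to(mask0, (t, h, w))
    else:
        truth = np.stack([_truth_for_frame(spec, f, rr, cc) for f in range(t)])
    if not truth[0].any():
        raise GeometryError("object covers no pixel at frame 1")

    wf = spec.waveform
    times = np.arange(t, dtype=np.float64)
    if spec.conduction_delay_per_px > 0:
        delay = spec.conduction_delay_per_px * np.sqrt(rr**2 + cc**2)
        pulse = wf.pulse(times[:, None, None] - wf.phase_frames - delay[None])
    else:
        pulse = wf.pulse(times - wf.phase_frames)[:, None, None]
    signal = wf.baseline + wf.amplitude * pulse * truth

    rng = np.random.default_rng(spec.seed)
    sigma = np.where(truth, spec.noise_sigma_object, spec.noise_sigma_background)
    data = signal + rng.normal(size=(t, h, w)) * sigma

    if spec.background_wander_sigma > 0:
        # slow per-pixel baseline wander applied wherever a pixel is
        # background in that frame (regions a moving object vacates included)
        steps = rng.normal(scale=spec.background_wander_sigma, size=(t, h, w))
        data = data + np.cumsum(steps, axis=0) * ~truth
        del steps

    data = np.clip(data, 0.0, None).astype(np.float32)
    movie = Movie(data=data, frame_rate_hz=spec.frame_rate_hz, source_path="<synthetic>")
    masks = [
        BinaryMask(values=truth[f].astype(np.uint8), frame_index=f + 1) for f in range(t)
    ]
    return SyntheticMovie(movie=movie, truth_masks=masks, spec=spec)


def _mask_array(m) -> np.ndarray:
    return m.values if isinstance(m, BinaryMask) else np.asarray(m)


def evaluate_masks(pred, truth) -> dict:
    """Confusion-matrix metrics per frame plus their means.

    Returns per-frame ``accuracy``, ``iou``, ``precision`` and ``recall``
    arrays and scalar ``mean_*`` summaries.  Undefined ratios (empty
    denominator) are scored 1.0 (vacuously correct).
    """
    pred = [_mask_array(m) for m in pred]
    truth = [_mask_array(m) for m in truth]
    if len(pred) != len(truth):
        raise ValidationError(f"got {len(pred)} predictions vs {len(truth)} truths")
    acc, iou, prec, rec = [], [], [], []
    for p, g in zip(pred, truth):
        if p.shape != g.shape:
            raise ValidationError(f"mask shape mismatch: {p.shape} vs {g.shape}")
        p = p.astype(bool)
        g = g.astype(bool)
        tp = np.sum(p & g)
        fp = np.sum(p & ~g)
        fn = np.sum(~p & g)
        tn = np.sum(~p & ~g)
        acc.append((tp + tn) / p.size)
        iou.append(tp / (tp + fp + fn) if tp + fp + fn else 1.0)
        prec.append(tp / (tp + fp) if tp + fp else 1.0)
        rec.append(tp / (tp + fn) if tp + fn else 1.0)
    out = {
        "accuracy": np.asarray(acc),
        "iou": np.asarray(iou),
        "precision": np.asarray(prec),
        "recall": np.asarray(rec),
    }
    for k in ("accuracy", "iou", "precision", "recall"):
        out[f"mean_{k}"] = float(out[k].mean())
    return out


def sparse_informative_dataset(
    n_dims: int,
    n_informative: int = 32,
    effect: float = 0.3,
    noise_sigma: float = 0.15,
    flip_fraction: float = 0.15,
    m_train_per_class: int = 500,
    m_val_per_class: int = 1000,
    seed: int = 0,
):
    """Labeled data whose class signal lives in a few of many dimensions.

    Both classes sit at 0.5 in every dimension except the first
    ``n_informative``, where class means are separated by ``effect``;
    i.i.d. Gaussian noise of ``noise_sigma`` is added everywhere and values
    are clipped to [0, 1].  A fraction of *training* labels is flipped
    (annotation noise, as imperfect pseudo-labels would produce).  Growing
    ``n_dims`` while holding ``n_informative`` fixed adds pure nuisance
    dimensions — the regime in which a weakly regularized,
    high-capacity fit starts absorbing the label noise through the
    nuisance dimensions once they outnumber the training rows.

    Returns ``(train, val)`` :class:`~temposeg.classifiers.LabeledDataset`.
    """
    from .classifiers import LabeledDataset

    if n_informative > n_dims:
        raise ParameterError(
            f"n_informative={n_informative} cannot exceed n_dims={n_dims}"
        )
    rng = np.random.default_rng(seed)

    def draw(m_per_class, flip):
        m = 2 * m_per_class
        y = np.repeat([0, 1], m_per_class)
        x = 0.5 + rng.normal(scale=noise_sigma, size=(m, n_dims))
        shift = np.where(y == 1, effect / 2, -effect / 2)
        x[:, :n_informative] += shift[:, None]
        x = np.clip(x, 0.0, 1.0)
        y_out = y.copy()
        if flip > 0:
            flips = rng.random(m) < flip
            y_out[flips] = 1 - y_out[flips]
        perm = rng.permutation(m)
        return x[perm], y_out[perm]

    xt, yt = draw(m_train_per_class, flip_fraction)
    xv, yv = draw(m_val_per_class, 0.0)
    train = LabeledDataset(features=xt, labels=yt, provenance="manual_polygons", split_seed=seed)
    val = LabeledDataset(features=xv, labels=yv, provenance="manual_polygons", split_seed=seed)
    return train, val
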