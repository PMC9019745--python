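"""Two-cluster k-means with a distance discount factor, and confident-point harvest.

The discount factor gamma in (0, 1] multiplies the distance to one
designated centroid during the assignment step, biasing assignment toward
that centroid.  Points that *resist* the bias — still assigned to the rival
centroid even though its distance was left undiscounted — are "stubborn":
they sit so deep inside their cluster that they survive the handicap.
Those stubborn points are high-confidence members of their cluster and are
harvested as pseudo-labels for supervised training, replacing manual
polygon annotation.

With gamma = 1 the assignment rule reduces exactly to plain Lloyd k-means;
as gamma -> 0 every point is pulled into the discounted cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    AmbiguousClusterError,
    EmptySelectionError,
    ParameterError,
    ValidationError,
)
from .movie_io import FeatureMatrix

__all__ = [
    "ClusterModel",
    "ConfidentSelection",
    "assign_discounted",
    "fit_discounted_kmeans",
    "select_confident",
    "identify_object_cluster",
    "harvest_training_set",
    "auto_tune_gamma",
]


@dataclass
class ClusterModel:
    """Converged two-cluster model: centroids, discount setting, assignments."""

    centroids: np.ndarray  # (2, n); row 0 = cluster 1, row 1 = cluster 2
    gamma: float
    discounted_index: int  # {1, 2}
    assignments: np.ndarray  # (P,) over {1, 2}
    iterations_run: int
    converged: bool
    seed: int
    inertia: float = float("nan")  # undiscounted within-cluster sum of squares

    def cluster_size(self, cluster: int) -> int:
        return int(np.sum(self.assignments == cluster))


@dataclass
class ConfidentSelection:
    """Pixel indices retained as confident members of one semantic class."""

    indices: np.ndarray
    label: int  # 1 = object, 0 = background
    gamma_used: float
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValidationError("confident indices must be unique")
        self.count = int(self.indices.size)


def _as_array(features) -> np.ndarray:
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError(f"features must be 2-D (P x n), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("features contain non-finite values")
    return x


def _check_gamma(gamma: float) -> float:
    if not (0.0 < gamma <= 1.0):
        raise ParameterError(f"discount factor gamma must lie in (0, 1], got {gamma}")
    return float(gamma)


def _check_index(discounted_index: int) -> int:
    if discounted_index not in (1, 2):
        raise ParameterError(f"discounted_index must be 1 or 2, got {discounted_index}")
    return int(discounted_index)


def assign_discounted(points, centroids, gamma: float, discounted_index: int):
    """Assign points to cluster 1 or 2 with one distance discounted.

    With ``discounted_index = 1`` a point goes to cluster 1 iff
    ``gamma * D1 <= D2`` (Euclidean distances); ties go to the discounted
    cluster, which keeps the rival's confident set conservative.  Accepts a
    single n-vector (returns an int) or a P x n matrix (returns a (P,)
    array over {1, 2}).
    """
    gamma = _check_gamma(gamma)
    discounted_index = _check_index(discounted_index)
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    if single:
        pts = pts[None, :]
    cents = np.asarray(centroids, dtype=np.float64)
    if cents.shape != (2, pts.shape[1]):
        raise ValidationError(
            f"centroids must be 2 x n with n={pts.shape[1]}, got {cents.shape}"
        )
    if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(cents))):
        raise ValidationError("assignment inputs must be finite")
    d = cdist(pts, cents)  # (P, 2): columns are D1, D2
    if discounted_index == 1:
        labels = np.where(gamma * d[:, 0] <= d[:, 1], 1, 2)
    else:
        labels = np.where(gamma * d[:, 1] <= d[:, 0], 2, 1)
    return int(labels[0]) if single else labels.astype(np.int8)


def _kmeanspp_init(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding for k=2."""
    first = rng.integers(x.shape[0])
    d2 = ((x - x[first]) ** 2).sum(axis=1)
    total = d2.sum()
    if total == 0:
        second = rng.integers(x.shape[0])
    else:
        second = rng.choice(x.shape[0], p=d2 / total)
    return np.stack([x[first], x[second]])


def _lloyd_discounted(
    x: np.ndarray,
    centroids: np.ndarray,
    gamma: float,
    discounted_index: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    labels = assign_discounted(x, centroids, gamma, discounted_index)
    centroids = centroids.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for k in (1, 2):
            members = labels == k
            if members.any():
                new_centroids[k - 1] = x[members].mean(axis=0)
            else:
                # Empty-cluster repair: reseed from the point farthest from
                # the surviving centroid.
                other = centroids[2 - k]
                far = np.argmax(((x - other) ** 2).sum(axis=1))
                new_centroids[k - 1] = x[far]
                warnings.warn(
                    f"cluster {k} emptied during iteration {it}; reseeded from "
                    "the farthest point",
                    RuntimeWarning,
                    stacklevel=3,
                )
        shift = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        new_labels = assign_discounted(x, new_centroids, gamma, discounted_index)
        moved = bool(np.any(new_labels != labels))
        centroids, labels = new_centroids, new_labels
        if not moved or shift < tol:
            converged = True
            break
    return centroids, labels, it, converged


def fit_discounted_kmeans(
    features,
    gamma: float,
    discounted_index: int = 1,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 5,
    init_centroids=None,
) -> ClusterModel:
    """Fit two clusters by Lloyd iteration with discounted assignment.

    Alternates the discounted assignment rule and centroid-mean updates
    until assignments stabilize, the largest centroid shift drops below
    ``tol``, or ``max_iter`` is reached.  Without ``init_centroids``,
    ``n_restarts`` k-means++ seedings are tried and the run with the lowest
    undiscounted within-cluster sum of squares is kept; everything is
    deterministic given ``seed``.
    """
    gamma = _check_gamma(gamma)
    discounted_index = _check_index(discounted_index)
    x = _as_array(features)
    if x.shape[0] < 2:
        raise ValidationError(f"need at least 2 points to form 2 clusters, got {x.shape[0]}")

    rng = np.random.default_rng(seed)
    if init_centroids is not None:
        inits = [np.asarray(init_centroids, dtype=np.float64).copy()]
    else:
        inits = [_kmeanspp_init(x, rng) for _ in range(n_restarts)]

    best = None
    for init in inits:
        if init.shape != (2, x.shape[1]):
            raise ValidationError(
                f"init centroids must be 2 x {x.shape[1]}, got {init.shape}"
            )
        cents, labels, iters, conv = _lloyd_discounted(
            x, init, gamma, discounted_index, max_iter, tol
        )
        d = cdist(x, cents)
        inertia = float(np.sum(d[np.arange(x.shape[0]), labels - 1] ** 2))
        if best is None or inertia < best[4]:
            best = (cents, labels, iters, conv, inertia)

    cents, labels, iters, conv, inertia = best
    return ClusterModel(
        centroids=cents,
        gamma=gamma,
        discounted_index=discounted_index,
        assignments=labels,
        iterations_run=iters,
        converged=conv,
        seed=seed,
        inertia=inertia,
    )


def select_confident(
    model: ClusterModel,
    features,
    target_cluster: int,
    label: int | None = None,
) -> ConfidentSelection:
    """Extract the stubborn points of ``target_cluster`` as a confident set.

    The model must have been fitted with ``discounted_index`` equal to the
    *rival* of ``target_cluster``: surviving in the target cluster despite
    the rival's discounted pull is what makes a point confident.  ``label``
    is the semantic class (1 object / 0 background) recorded on the
    selection; if omitted it is derived from :func:`identify_object_cluster`.
    """
    target_cluster = _check_index(target_cluster)
    if model.discounted_index == target_cluster:
        raise ParameterError(
            f"model discounts cluster {model.discounted_index}; confident points of "
            f"cluster {target_cluster} require discounting its rival "
            f"{3 - target_cluster}"
        )
    indices = np.flatnonzero(model.assignments == target_cluster)
    if indices.size == 0:
        raise EmptySelectionError(
            f"no confident points for cluster {target_cluster} at gamma="
            f"{model.gamma}; raise gamma"
        )
    if label is None:
        label = 1 if identify_object_cluster(model) == target_cluster else 0
    return ConfidentSelection(indices=indices, label=int(label), gamma_used=model.gamma)


def _lag1_autocorr(series: np.ndarray) -> float:
    """Plain lag-1 autocorrelation; 0 by convention for constant series."""
    s = np.asarray(series, dtype=np.float64)
    if s.size < 3:
        return 0.0
    a, b = s[:-1], s[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _structure_score(series: np.ndarray) -> float:
    """Amplitude of the common temporal structure of a centroid.

    Only object pixels share a waveform, so averaging over a cluster
    preserves the object centroid's amplitude while a background
    centroid's independent noise (or baseline wander) averages toward a
    flat trace.  The amplitude is gated by a positive lag-1
    autocorrelation so a high-variance *white* centroid (e.g. a cluster
    reseeded from a single noisy pixel) does not score as structure.
    """
    s = np.asarray(series, dtype=np.float64)
    return float(s.std()) * max(_lag1_autocorr(s), 0.0)


def identify_object_cluster(model: ClusterModel, override: int | None = None) -> int:
    """Decide which cluster's centroid carries the object (tissue) signal.

    The object centroid is a structured, repeating waveform while the
    background centroid averages out to a flat or slowly wandering noise
    trace, so the cluster whose centroid has the higher temporal-structure
    score (autocorrelation-gated amplitude) is returned.  ``override``
    short-circuits the heuristic for manual control.
    """
    if override is not None:
        return _check_index(override)
    s1 = _structure_score(model.centroids[0])
    s2 = _structure_score(model.centroids[1])
    if abs(s1 - s2) < 1e-6:
        raise AmbiguousClusterError(
            f"centroid structure scores are indistinguishable ({s1:.6g} vs "
            f"{s2:.6g}); pass an explicit object-cluster override"
        )
    return 1 if s1 > s2 else 2


def _identity_intact(model: ClusterModel, expected_object: int) -> bool:
    """True when the refit model's object cluster is still ``expected_object``.

    Aggressive discounting can drag the discounted centroid into the rival
    cloud, silently swapping the semantic identity of the clusters; such a
    fit must not be harvested from.
    """
    try:
        return identify_object_cluster(model) == expected_object
    except AmbiguousClusterError:
        return False


def _tune_gamma_to_fraction(
    x: np.ndarray,
    base: ClusterModel,
    target_cluster: int,
    fraction: float,
    seed: int,
    expected_object: int,
    steps: int = 12,
    rel_tol: float = 0.05,
) -> float:
    """Bisect gamma (discounting the rival, starting from the base centroids)
    so ``target_cluster`` retains about ``fraction`` of its plain members.
    A fit whose cluster identity drifted counts as 0 (over-discounted)."""
    rival = 3 - target_cluster
    target = max(1, int(round(fraction * base.cluster_size(target_cluster))))

    def count_at(gamma: float) -> int:
        if gamma >= 1.0:
            return base.cluster_size(target_cluster)
        model = fit_discounted_kmeans(
            x, gamma=gamma, discounted_index=rival, seed=seed,
            init_centroids=base.centroids,
        )
        if not _identity_intact(model, expected_object):
            return 0
        return model.cluster_size(target_cluster)

    lo, hi = 1e-6, 1.0
    best_gamma, best_err = 1.0, abs(count_at(1.0) - target)
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        c = count_at(mid)
        err = abs(c - target)
        if err < best_err:
            best_gamma, best_err = mid, err
        if err <= rel_tol * target:
            return mid
        if c < target:
            lo = mid
        else:
            hi = mid
    return best_gamma


def harvest_training_set(
    features,
    gamma_obj: float = 0.8,
    gamma_bg: float = 0.8,
    seed: int = 0,
    object_cluster: int | None = None,
    target_fraction: float | None = None,
):
    """Harvest pseudo-labeled training pixels via two discounted fits.

    A plain (gamma=1) fit establishes the two centroids and their semantic
    identity; two discounted fits — one discounting the background centroid
    to isolate confident object pixels, one discounting the object centroid
    to isolate confident background pixels — are then started from those
    centroids.  Pixels selected by both runs (possible because the two fits
    converge independently) are contradictory and dropped from both sides.

    When ``target_fraction`` is given, the two discount factors are instead
    auto-tuned (per class, by bisection) so each confident set retains
    about that fraction of its plain-k-means cluster — the automated
    version of tuning gamma for a target amount of training data.  A fixed
    gamma can over-discount when the clusters are weakly separated (short
    windows), leaving almost no training data for one class.

    Returns a :class:`~temposeg.classifiers.LabeledDataset` with labels
    1 = object, 0 = background.
    """
    from .classifiers import LabeledDataset  # local import to avoid cycle

    x = _as_array(features)

    base = fit_discounted_kmeans(x, gamma=1.0, discounted_index=1, seed=seed)
    obj = identify_object_cluster(base, override=object_cluster)
    bg = 3 - obj

    if target_fraction is not None:
        if not (0.0 < target_fraction <= 1.0):
            raise ParameterError(
                f"target_fraction must lie in (0, 1], got {target_fraction}"
            )
        gamma_obj = _tune_gamma_to_fraction(x, base, obj, target_fraction, seed, obj)
        gamma_bg = _tune_gamma_to_fraction(x, base, bg, target_fraction, seed, obj)
    gamma_obj = _check_gamma(gamma_obj)
    gamma_bg = _check_gamma(gamma_bg)

    model_obj = fit_discounted_kmeans(
        x, gamma=gamma_obj, discounted_index=bg, seed=seed, init_centroids=base.centroids
    )
    model_bg = fit_discounted_kmeans(
        x, gamma=gamma_bg, discounted_index=obj, seed=seed, init_centroids=base.centroids
    )
    if object_cluster is None:
        if not _identity_intact(model_obj, obj):
            raise EmptySelectionError(
                f"cluster identity lost in the object harvest at gamma_obj={gamma_obj}; "
                "use a larger gamma"
            )
        if not _identity_intact(model_bg, obj):
            raise EmptySelectionError(
                f"cluster identity lost in the background harvest at gamma_bg={gamma_bg}; "
                "use a larger gamma"
            )
    try:
        sel_obj = select_confident(model_obj, x, target_cluster=obj, label=1)
    except EmptySelectionError as exc:
        raise EmptySelectionError(
            f"object class empty at gamma_obj={gamma_obj}: {exc}"
        ) from exc
    try:
        sel_bg = select_confident(model_bg, x, target_cluster=bg, label=0)
    except EmptySelectionError as exc:
        raise EmptySelectionError(
            f"background class empty at gamma_bg={gamma_bg}: {exc}"
        ) from exc

    overlap = np.intersect1d(sel_obj.indices, sel_bg.indices)
    obj_idx = np.setdiff1d(sel_obj.indices, overlap)
    bg_idx = np.setdiff1d(sel_bg.indices, overlap)
    if obj_idx.size == 0:
        raise EmptySelectionError(
            f"object class empty after overlap removal at gamma_obj={gamma_obj}"
        )
    if bg_idx.size == 0:
        raise EmptySelectionError(
            f"background class empty after overlap removal at gamma_bg={gamma_bg}"
        )

    idx = np.concatenate([obj_idx, bg_idx])
    labels = np.concatenate([np.ones(obj_idx.size, int), np.zeros(bg_idx.size, int)])
    return LabeledDataset(
        features=x[idx],
        labels=labels,
        provenance="kmeans_confident",
        split_seed=seed,
        pixel_indices=idx,
    )


def auto_tune_gamma(
    features,
    target_count: int,
    target_cluster: int = 1,
    seed: int = 0,
    rel_tol: float = 0.05,
    max_steps: int = 30,
) -> float:
    """Bisect gamma so the confident set of ``target_cluster`` hits a size target.

    Searches gamma in (0, 1] (discounting the rival cluster) until the
    confident count is within ``rel_tol`` of ``target_count`` or
    ``max_steps`` bisections elapse; returns the gamma whose count came
    closest.  Raises if the target exceeds what even gamma=1 yields.
    """
    x = _as_array(features)
    target_cluster = _check_index(target_cluster)
    if not (1 <= target_count <= x.shape[0]):
        raise ParameterError(
            f"target_count must lie in [1, P={x.shape[0]}], got {target_count}"
        )
    rival = 3 - target_cluster
    base = fit_discounted_kmeans(x, gamma=1.0, discounted_index=rival, seed=seed)

    def count_at(gamma: float) -> int:
        if gamma >= 1.0:
            model = base
        else:
            model = fit_discounted_kmeans(
                x, gamma=gamma, discounted_index=rival, seed=seed,
                init_centroids=base.centroids,
            )
        return int(np.sum(model.assignments == target_cluster))

    count_full = count_at(1.0)
    if target_count > count_full:
        raise ParameterError(
            f"target_count={target_count} unreachable: gamma=1 yields at most "
            f"{count_full} points in cluster {target_cluster}"
        )
    if abs(count_full - target_count) <= rel_tol * target_count:
        return 1.0

    lo, hi = 1e-9, 1.0
    best_gamma, best_count = 1.0, count_full
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        c = count_at(mid)
        if abs(c - target_count) < abs(best_count - target_count):
            best_gamma, best_count = mid, c
        if abs(c - target_count) <= rel_tol * target_count:
            return mid
        if c < target_count:
            lo = mid
        else:
            hi = mid
    return best_gamma
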