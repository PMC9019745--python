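"""Canonical synthetic experiments exercising the full method.

Each function freezes one study condition — movie geometry, waveform
timing, noise level, window sizes — and measures the method against the
generator's ground truth.  These are the configurations behind the
package's reported numbers; tests and the reproduction script both call
them, so there is a single source of truth for the conditions.

Problem sizes follow the data the method was designed for: 100 x 100 px,
1,024-frame movies at 1 kHz.
"""

from __future__ import annotations

import numpy as np

from .classifiers import split_train_validation, train, validation_accuracy
from .kmeans import harvest_training_set
from .movie_io import extract_window, normalize_per_pixel
from .pipeline import (
    SegmentationResult,
    combined_segment,
    kmeans_only_segment,
    ratio_consistency,
    tracking_segment,
)
from .synthetic import (
    Disk,
    Ellipse,
    Motion,
    SyntheticSpec,
    SyntheticMovie,
    Waveform,
    evaluate_masks,
    generate,
    sparse_informative_dataset,
)

__all__ = [
    "static_recovery_experiment",
    "frame_count_trend_experiment",
    "highdim_logreg_experiment",
    "tracking_experiment",
    "validation_accuracy_experiment",
    "trend_movie_spec",
    "tracking_movie_spec",
]


def trend_movie_spec(seed: int = 0) -> SyntheticSpec:
    """Movie for the window-size trend experiment.

    Slightly noisier than the default and with baseline wander on the
    background — the realistic regime in which short windows genuinely
    confuse plain k-means (the early stretch of a wandering background
    pixel can sit at any normalized level, including that of quiescent
    tissue).  The first upstroke starts at frame 28 so the n=32 window is
    almost entirely diastolic: the object signature it carries is a few
    upstroke frames, too weak to dominate clustering but enough to anchor
    the semantic identity of the clusters.
    """
    return SyntheticSpec(
        waveform=Waveform(phase_frames=28),
        noise_sigma_object=0.05,
        noise_sigma_background=0.05,
        background_wander_sigma=0.002,
        seed=seed,
    )


def tracking_movie_spec(motion: str, seed: int = 0) -> SyntheticSpec:
    """Movie for moving-boundary tracking.

    Fast pacing (cycle length 100 frames) with continuous repolarization
    (APD = cycle length, as in fast-paced calcium-transient recordings):
    every 32-frame window then contains signal change, which short-window
    tracking fundamentally requires — a window of flat diastole carries no
    information about which pixels are tissue.
    """
    wf = Waveform(period_frames=100, upstroke_frames=5, apd_frames=100)
    if motion == "rotate":
        shape = Ellipse(semi_major=35.0, semi_minor=20.0)
        mo = Motion(kind="rotate", deg_per_frame=0.35)
    elif motion == "shrink":
        shape = Disk(radius=30.0)
        mo = Motion(kind="shrink", scale_per_frame=0.9996)
    else:
        raise ValueError(f"motion must be 'rotate' or 'shrink', got {motion!r}")
    return SyntheticSpec(
        shape=shape, waveform=wf, motion=mo, seed=seed,
        noise_sigma_object=0.01, noise_sigma_background=0.01,
    )


def _harvest_precision(sm: SyntheticMovie, n: int, gammas, seed: int) -> dict:
    nm = normalize_per_pixel(sm.movie)
    feats = extract_window(nm, 1, n)
    ds = harvest_training_set(feats, gamma_obj=gammas[0], gamma_bg=gammas[1], seed=seed)
    truth_flat = sm.truth_masks[0].values.ravel().astype(bool)
    obj_idx = ds.pixel_indices[ds.labels == 1]
    bg_idx = ds.pixel_indices[ds.labels == 0]
    return {
        "object_precision": float(truth_flat[obj_idx].mean()),
        "background_precision": float((~truth_flat[bg_idx]).mean()),
        "n_object": int(obj_idx.size),
        "n_background": int(bg_idx.size),
    }


def static_recovery_experiment(
    seed: int = 0, n: int = 256, method: str = "svm", gammas=(0.8, 0.8)
) -> dict:
    """Default static disk movie: combined-method accuracy and pseudo-label purity."""
    sm = generate(SyntheticSpec(seed=seed))
    res = combined_segment(sm.movie, n=n, frames=[1], method=method, gammas=gammas, seed=seed)
    metrics = evaluate_masks(res.masks, sm.truth_masks[:1])
    out = {
        "accuracy": metrics["mean_accuracy"],
        "iou": metrics["mean_iou"],
        "heart_ratio": res.heart_ratio_per_frame[0],
        "true_ratio": sm.truth_masks[0].object_ratio,
    }
    out.update(_harvest_precision(sm, n, gammas, seed))
    return out


def frame_count_trend_experiment(
    seed: int = 0, ns=(32, 128, 256, 512, 1024)
) -> dict:
    """Window-size trend: plain k-means vs the combined method on one movie.

    Measures frame-1 accuracy per window size for both methods and the
    spread (population STD) of their heart ratios across window sizes.
    """
    sm = generate(trend_movie_spec(seed))
    truth = sm.truth_masks[:1]
    kmeans_acc, combined_acc = {}, {}
    kmeans_res, combined_res = {}, {}
    for n in ns:
        km = kmeans_only_segment(sm.movie, n=n, frame=1, seed=seed)
        kmeans_acc[n] = evaluate_masks([km], truth)["mean_accuracy"]
        kmeans_res[n] = SegmentationResult(masks=[km])
        cb = combined_segment(sm.movie, n=n, frames=[1], method="svm", seed=seed)
        combined_acc[n] = evaluate_masks(cb.masks, truth)["mean_accuracy"]
        combined_res[n] = cb
    _, kmeans_std = ratio_consistency(kmeans_res)
    _, combined_std = ratio_consistency(combined_res)
    return {
        "ns": list(ns),
        "kmeans_accuracy": kmeans_acc,
        "combined_accuracy": combined_acc,
        "kmeans_ratio_std": kmeans_std,
        "combined_ratio_std": combined_std,
    }


def _cv_select_svm_c(tr, grid=(0.01, 0.03, 0.1, 0.3, 1.0), n_folds: int = 5) -> float:
    """Pick the SVM soft-margin C by stratified cross-validation on the
    training set (deterministic; ties go to the smaller, safer C)."""
    from sklearn.model_selection import StratifiedKFold

    from .classifiers import LabeledDataset

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=0)
    best_c, best_acc = grid[0], -1.0
    for c in grid:
        accs = []
        for tr_idx, va_idx in skf.split(tr.features, tr.labels):
            fold_tr = LabeledDataset(features=tr.features[tr_idx], labels=tr.labels[tr_idx])
            fold_va = LabeledDataset(features=tr.features[va_idx], labels=tr.labels[va_idx])
            model = train(fold_tr, kind="svm", hyperparams={"C": c})
            accs.append(validation_accuracy(model, fold_va))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_c, best_acc = c, acc
    return best_c


def highdim_logreg_experiment(seed: int = 0, dims=(128, 1024)) -> dict:
    """Dimension-scaling pathology of weakly regularized logistic regression.

    The informative structure (32 signal dimensions, mild label noise) is
    identical at every total dimension; only nuisance dimensions are
    added.  Logistic regression is trained at the package's deliberately
    weak default regularization (the "unregularized-style" fit); the SVM's
    soft margin is chosen by cross-validation on the training set, as a
    practitioner would.  Logistic regression absorbs the label noise
    through the nuisance dimensions once they outnumber the training rows;
    the max-margin fit does not.
    """
    out = {"dims": list(dims), "logreg": {}, "svm": {}, "svm_C": {}}
    for n_dims in dims:
        tr, va = sparse_informative_dataset(n_dims=n_dims, seed=seed)
        model = train(tr, kind="logreg")
        out["logreg"][n_dims] = validation_accuracy(model, va)
        c = _cv_select_svm_c(tr)
        out["svm_C"][n_dims] = c
        model = train(tr, kind="svm", hyperparams={"C": c})
        out["svm"][n_dims] = validation_accuracy(model, va)
    return out


def tracking_experiment(
    seed: int = 0, motion: str = "rotate", n: int = 32, stride: int | None = None
) -> dict:
    """Moving-boundary tracking with per-window pseudo-label re-harvest.

    Windows are sampled every ``stride`` frames; by default every 32
    (non-overlapping) for rotation and every 64 for shrinking, where the
    readout is the monotone area trend and each sample must shed clearly
    more area than the per-mask prediction jitter.
    """
    if stride is None:
        stride = 64 if motion == "shrink" else 32
    sm = generate(tracking_movie_spec(motion, seed))
    res = tracking_segment(sm.movie, n=n, stride=stride, method="svm", seed=seed)
    truths = [sm.truth_masks[m.frame_index - 1] for m in res.masks]
    metrics = evaluate_masks(res.masks, truths)
    return {
        "motion": motion,
        "starts": [m.frame_index for m in res.masks],
        "mean_accuracy": metrics["mean_accuracy"],
        "min_accuracy": float(metrics["accuracy"].min()),
        "heart_ratios": res.heart_ratio_per_frame,
        "true_ratios": [t.object_ratio for t in truths],
    }


def validation_accuracy_experiment(seed: int = 0, n: int = 256) -> dict:
    """8:1 split validation accuracy of both classifiers on harvested labels
    from the default movie (the headline consistency check for SVM)."""
    sm = generate(SyntheticSpec(seed=seed))
    nm = normalize_per_pixel(sm.movie)
    feats = extract_window(nm, 1, n)
    ds = harvest_training_set(feats, seed=seed)
    tr, va = split_train_validation(ds, ratio=(8, 1))
    out = {}
    for kind in ("logreg", "svm"):
        model = train(tr, kind=kind)
        out[kind] = validation_accuracy(model, va)
    return out
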