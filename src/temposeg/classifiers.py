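"""Supervised pixel classifiers: logistic regression and linear soft-margin SVM.

Both classifiers are linear in the per-pixel time-window features.  The
logistic model is f(x) = sigmoid(w.x + b) thresholded at probability 0.5;
the SVM is a max-margin hyperplane thresholded at decision value 0.
Fitting is delegated to scikit-learn (cross-entropy logistic regression
and primal LinearSVC); the fitted hyperplane is extracted into a plain
:class:`LinearClassifier` so prediction and JSON serialization do not
depend on the fitting backend.

Features arrive already normalized to [0, 1] per pixel, so no further
standardization is applied by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, ParameterError, ValidationError
from .movie_io import BinaryMask, FeatureMatrix

__all__ = [
    "LabeledDataset",
    "LinearClassifier",
    "split_train_validation",
    "train",
    "predict_mask",
    "validation_accuracy",
]

DEFAULT_HYPERPARAMS = {
    "logreg": {"C": 1000.0, "max_iter": 2000, "tol": 1e-6},
    "svm": {"C": 1.0, "max_iter": 10000, "tol": 1e-4},
}


@dataclass
class LabeledDataset:
    """m x n features with binary labels (1 = object/heart, 0 = background)."""

    features: np.ndarray
    labels: np.ndarray
    provenance: str = "manual_polygons"
    split_seed: int = 0
    pixel_indices: np.ndarray | None = None  # original pixel rows, if known

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.features.ndim != 2:
            raise DimensionError(f"features must be m x n, got {self.features.shape}")
        if self.labels.shape != (self.features.shape[0],):
            raise DimensionError(
                f"labels shape {self.labels.shape} does not match m={self.features.shape[0]}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("features contain non-finite values")

    @property
    def m(self) -> int:
        return self.features.shape[0]

    @property
    def n(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {1: int((self.labels == 1).sum()), 0: int((self.labels == 0).sum())}

    def to_csv(self, path) -> None:
        """Tabular export: pixel_index (or row number), label, then features."""
        idx = (
            self.pixel_indices
            if self.pixel_indices is not None
            else np.arange(self.m)
        )
        out = np.column_stack([idx, self.labels, self.features])
        header = "pixel_index,label," + ",".join(f"f{j}" for j in range(self.n))
        np.savetxt(path, out, delimiter=",", header=header, comments="")


@dataclass
class LinearClassifier:
    """Linear decision rule w.x + b, thresholded per classifier kind."""

    weights: np.ndarray
    bias: float
    kind: str  # {"logreg", "svm"}
    trained_on_n: int
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValidationError("classifier weights/bias must be finite")
        if self.kind not in ("logreg", "svm"):
            raise ParameterError(f"kind must be 'logreg' or 'svm', got {self.kind!r}")
        if self.trained_on_n != self.weights.size:
            raise DimensionError(
                f"trained_on_n={self.trained_on_n} != weight dimension {self.weights.size}"
            )

    def decision_function(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.trained_on_n:
            raise DimensionError(
                f"feature dimension {x.shape[-1]} != trained dimension {self.trained_on_n}"
            )
        return x @ self.weights + self.bias

    def predict_proba(self, x) -> np.ndarray:
        """Object probability sigmoid(w.x + b); logistic models only."""
        if self.kind != "logreg":
            raise ParameterError("probabilities are defined only for logreg models")
        z = self.decision_function(x)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, x) -> np.ndarray:
        """Binary labels: logreg thresholds probability at 0.5 (i.e. z >= 0),
        SVM thresholds the decision value at 0."""
        return (self.decision_function(x) >= 0.0).astype(np.int8)

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "trained_on_n": self.trained_on_n,
            "hyperparams": {k: v for k, v in self.hyperparams.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearClassifier":
        try:
            d = json.loads(str(source))
        except (json.JSONDecodeError, TypeError):
            d = json.loads(Path(source).read_text())
        return cls(
            weights=np.asarray(d["weights"]),
            bias=float(d["bias"]),
            kind=d["kind"],
            trained_on_n=int(d["trained_on_n"]),
            hyperparams=d.get("hyperparams", {}),
        )


def split_train_validation(
    ds: LabeledDataset, ratio: tuple[int, int] = (8, 1)
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/validation split at ``ratio`` (train:val) per class.

    Each class contributes ``round(class_size * val/(train+val))`` rows to
    validation (so 8:1 puts round(size/9) in validation) and the remainder
    to training; deterministic under ``ds.split_seed``.
    """
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ParameterError(f"split ratio parts must be positive, got {ratio}")
    rng = np.random.default_rng(ds.split_seed)
    train_rows, val_rows = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(ds.labels == cls)
        if idx.size < 2:
            raise ValidationError(
                f"class {cls} has {idx.size} members; cannot place >=1 in each split"
            )
        n_val = int(round(idx.size * ratio[1] / (ratio[0] + ratio[1])))
        n_val = min(max(n_val, 1), idx.size - 1)
        perm = rng.permutation(idx)
        val_rows.append(perm[:n_val])
        train_rows.append(perm[n_val:])
    tr = np.sort(np.concatenate(train_rows))
    va = np.sort(np.concatenate(val_rows))

    def take(rows):
        return LabeledDataset(
            features=ds.features[rows],
            labels=ds.labels[rows],
            provenance=ds.provenance,
            split_seed=ds.split_seed,
            pixel_indices=None if ds.pixel_indices is None else ds.pixel_indices[rows],
        )

    return take(tr), take(va)


def train(ds: LabeledDataset, kind: str = "svm", hyperparams: dict | None = None) -> LinearClassifier:
    """Fit a linear classifier of the given kind on a labeled dataset.

    ``logreg`` fits an L2-regularized maximum-likelihood logistic model
    (weak regularization by default, C=1000, needed for numerical
    stability in very high dimensions); ``svm`` fits a soft-margin linear
    SVM (C=1).  Both are deterministic given the data order.  If the solver
    exhausts its iteration budget a warning carrying the diagnostics is
    emitted (set hyperparam ``raise_on_nonconvergence`` to make it fatal).
    """
    if kind not in DEFAULT_HYPERPARAMS:
        raise ParameterError(f"kind must be 'logreg' or 'svm', got {kind!r}")
    counts = ds.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValidationError(f"training needs both classes; got counts {counts}")
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    hp.update(hyperparams or {})
    raise_on_nonconv = bool(hp.pop("raise_on_nonconvergence", False))

    x, y = ds.features, ds.labels
    if kind == "logreg":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(
            C=hp["C"], solver="lbfgs", tol=hp["tol"], max_iter=hp["max_iter"]
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(x, y)
        n_iter = int(np.max(est.n_iter_))
        converged = n_iter < hp["max_iter"]
    else:
        from sklearn.svm import LinearSVC

        est = LinearSVC(
            C=hp["C"], loss="hinge", dual=True, tol=hp["tol"],
            max_iter=hp["max_iter"], random_state=0,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(x, y)
        n_iter = int(np.max(est.n_iter_))
        converged = n_iter < hp["max_iter"]

    if not converged:
        msg = (
            f"{kind} solver used its full iteration budget (n_iter={n_iter}, "
            f"max_iter={hp['max_iter']}, m={ds.m}, n={ds.n}); coefficients may "
            "not be fully converged"
        )
        if raise_on_nonconv:
            from .errors import ConvergenceError

            raise ConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    return LinearClassifier(
        weights=est.coef_.ravel(),
        bias=float(est.intercept_[0]),
        kind=kind,
        trained_on_n=ds.n,
        hyperparams=hp,
    )


def predict_mask(model: LinearClassifier, features: FeatureMatrix) -> BinaryMask:
    """Classify every pixel row and reshape the decisions to an H x W mask."""
    if features.values.shape[1] != model.trained_on_n:
        raise DimensionError(
            f"feature window has n={features.values.shape[1]} frames but the model "
            f"was trained on n={model.trained_on_n}"
        )
    preds = model.predict(features.values)
    h, w = features.shape_hw
    return BinaryMask(values=preds.reshape(h, w), frame_index=features.start_frame)


def validation_accuracy(model: LinearClassifier, val: LabeledDataset) -> float:
    """Fraction of validation rows whose prediction matches the label."""
    if val.m == 0:
        raise ValidationError("validation set is empty")
    return float(np.mean(model.predict(val.features) == val.labels))
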