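"""Neural-network prediction of ortho-k decentration from baseline topography.

Two feedforward networks — a 4-class quadrant classifier and a decentration
radius regressor — consume baseline corneal heights re-meshed onto a fixed
polar lattice (radii 0–5 mm, 10 deg angular steps).  Both use the same
training recipe: 10 hidden tanh layers with a linear output, mean
squared error loss (one-hot targets for classification, argmax decode),
a 100-epoch training budget, and a seeded 70/30 train/validation split.
Hidden widths are a free choice (default 16, which a 100-iteration budget
trains reliably).

Optimisation defaults to full-batch quasi-Newton (L-BFGS) minimisation of
the MSE -- the closest available analogue of the batch second-order
training that MATLAB-style ``fitnet``/``train`` pipelines use by default,
for which a learning-rate setting is inert; stochastic ``adam``/``sgd``
solvers (where ``learning_rate`` = 0.01 applies) are available as options.
Deep tanh networks are sensitive to initialisation, so training restarts
from ``n_restarts`` seeded initialisations and keeps the network with the
lowest *training* loss (the validation split is never consulted).

The estimators follow the scikit-learn API (``fit``/``predict``/
``get_params`` and trailing-underscore fitted attributes) and therefore
compose with sklearn model selection; training is delegated to
:class:`sklearn.neural_network.MLPRegressor`, whose squared-error loss and
identity output match the recipe exactly.  Prediction runs through an
explicit forward pass on stored weights, so serialised models need no
refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor

from .surface import CornealSurface, mirror_for_laterality

__all__ = [
    "FEATURE_ANGLE_STEP_DEG",
    "FEATURE_MAX_RADIUS_MM",
    "FEATURE_N_RADII",
    "build_features",
    "QuadrantClassifier",
    "RadiusRegressor",
    "EvaluationReport",
    "train_predictor",
    "predict",
    "evaluate_predictor",
    "model_to_json",
    "model_from_json",
]

FEATURE_ANGLE_STEP_DEG = 10.0
FEATURE_MAX_RADIUS_MM = 5.0
FEATURE_N_RADII = 26  # 0..5 mm at 0.2 mm spacing


def build_features(
    surface: CornealSurface,
    n_radii: int = FEATURE_N_RADII,
    angle_step: float = FEATURE_ANGLE_STEP_DEG,
) -> np.ndarray:
    """Polar height samples of a baseline surface as a flat feature vector.

    Heights are interpolated onto radii 0..5 mm (``n_radii`` samples) at
    ``angle_step`` meridian steps in the nasal-positive frame: OS surfaces
    are mirrored to OD orientation first, so anatomically mirrored fellow
    eyes yield identical features.  Vector length = (360/angle_step) * n_radii.
    """
    if surface.laterality == "OS":
        surface = mirror_for_laterality(surface)
    angles = np.arange(0.0, 360.0, angle_step)
    radii = np.linspace(0.0, FEATURE_MAX_RADIUS_MM, n_radii)
    phi = np.deg2rad(angles)[:, None]
    r = radii[None, :]
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    h = surface.interpolate_at(x, y)
    if not np.all(np.isfinite(h)):
        raise ValueError("coverage hole inside the 5 mm feature zone")
    return h.ravel()


def _tanh_forward(x: np.ndarray, weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    a = x
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w + b)
    return a @ weights[-1] + biases[-1]


class _TanhNetBase(BaseEstimator):
    """Shared fit machinery: z-scored features into a deep tanh MSE network."""

    _task = "base"

    def __init__(
        self,
        hidden_layer_width: int = 16,
        n_hidden_layers: int = 10,
        solver: str = "lbfgs",
        learning_rate: float = 0.01,
        epochs: int = 100,
        n_restarts: int = 20,
        random_state: int = 0,
    ):
        self.hidden_layer_width = hidden_layer_width
        self.n_hidden_layers = n_hidden_layers
        self.solver = solver
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _fit_net(self, x: np.ndarray, targets: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        self.feature_mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.feature_sd_ = np.where(sd > 0, sd, 1.0)  # constant features pass through
        xs = (x - self.feature_mean_) / self.feature_sd_
        kwargs = dict(
            hidden_layer_sizes=(self.hidden_layer_width,) * self.n_hidden_layers,
            activation="tanh",
            solver=self.solver,
            max_iter=self.epochs,
        )
        if self.solver in ("adam", "sgd"):
            kwargs.update(
                learning_rate_init=self.learning_rate,
                n_iter_no_change=self.epochs,  # always run the full epoch budget
                tol=0.0,
                shuffle=True,
            )
        net = None
        restart_seeds = np.random.SeedSequence(self.random_state).generate_state(
            max(1, self.n_restarts)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for rs in restart_seeds:
                cand = MLPRegressor(random_state=int(rs), **kwargs)
                cand.fit(xs, targets)
                if net is None or cand.loss_ < net.loss_:
                    net = cand
        if not np.all([np.all(np.isfinite(c)) for c in net.coefs_]):
            raise RuntimeError("training diverged: non-finite network weights")
        self.weights_ = [c.copy() for c in net.coefs_]
        self.biases_ = [b.copy() for b in net.intercepts_]
        self.n_features_in_ = x.shape[1]
        self.loss_ = float(net.loss_)

    def _forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {x.shape[1]} does not match model ({self.n_features_in_})"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        xs = (x - self.feature_mean_) / self.feature_sd_
        return _tanh_forward(xs, self.weights_, self.biases_)


class QuadrantClassifier(_TanhNetBase):
    """4-class decentration-quadrant network (MSE on one-hot targets, argmax decode)."""

    _task = "quadrant"
    classes_ = np.array([1, 2, 3, 4])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuadrantClassifier":
        y = np.asarray(y, dtype=int)
        if not np.all(np.isin(y, self.classes_)):
            raise ValueError("quadrant labels must be in 1..4")
        present = np.unique(y)
        if present.size < self.classes_.size:
            missing = sorted(set(self.classes_.tolist()) - set(present.tolist()))
            raise ValueError(f"class(es) {missing} absent from the training set")
        onehot = np.eye(4)[y - 1]
        self._fit_net(X, onehot)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw 4-channel network outputs (no softmax; the output layer is linear)."""
        return self._forward(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_scores(X), axis=1) + 1


class RadiusRegressor(_TanhNetBase):
    """Decentration-radius network (mm); predictions are clamped at 0."""

    _task = "radius"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RadiusRegressor":
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("radii must be non-negative")
        self._fit_net(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(self._forward(X).ravel(), 0.0)


@dataclass
class EvaluationReport:
    """Validation metrics of a trained predictor."""

    task: str
    n_train: int
    n_val: int
    accuracy: float | None = None  # quadrant task
    confusion: np.ndarray | None = None  # (true 1..4) x (predicted 1..4) counts
    rms_error: float | None = None  # mm, radius task
    pearson_r: float | None = None  # radius task


def evaluate_predictor(
    model: QuadrantClassifier | RadiusRegressor,
    X: np.ndarray,
    y: np.ndarray,
    n_train: int = 0,
) -> EvaluationReport:
    """Accuracy + confusion matrix (quadrant) or RMS + Pearson R (radius) on a held-out set."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = model.predict(X)
    if model._task == "quadrant":
        y = np.asarray(y, dtype=int)
        conf = np.zeros((4, 4), dtype=int)
        for t, p in zip(y, pred):
            conf[t - 1, p - 1] += 1
        return EvaluationReport(
            task="quadrant",
            n_train=n_train,
            n_val=X.shape[0],
            accuracy=float(np.mean(pred == y)),
            confusion=conf,
        )
    y = np.asarray(y, dtype=float)
    rms = float(np.sqrt(np.mean((pred - y) ** 2)))
    r = float(pearsonr(pred, y).statistic) if np.std(pred) > 0 and np.std(y) > 0 else np.nan
    return EvaluationReport(task="radius", n_train=n_train, n_val=X.shape[0], rms_error=rms, pearson_r=r)


def train_predictor(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    seed: int = 0,
    validation_fraction: float = 0.3,
    hidden_layer_width: int = 16,
) -> tuple[QuadrantClassifier | RadiusRegressor, EvaluationReport]:
    """Train a decentration predictor with the standard recipe and report validation metrics.

    70/30 train/validation split (stratified by quadrant for classification),
    seeded end to end; features are z-scored with training-set statistics
    inside the estimator.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 40:
        raise ValueError(f"need at least 40 examples, got {X.shape[0]}")
    if task == "quadrant":
        y = np.asarray(y, dtype=int)
        strat = y
        model: QuadrantClassifier | RadiusRegressor = QuadrantClassifier(
            hidden_layer_width=hidden_layer_width, random_state=seed
        )
    elif task == "radius":
        y = np.asarray(y, dtype=float)
        strat = None
        model = RadiusRegressor(hidden_layer_width=hidden_layer_width, random_state=seed)
    else:
        raise ValueError("task must be 'quadrant' or 'radius'")
    x_tr, x_va, y_tr, y_va = train_test_split(
        X, y, test_size=validation_fraction, random_state=seed, stratify=strat
    )
    model.fit(x_tr, y_tr)
    report = evaluate_predictor(model, x_va, y_va, n_train=x_tr.shape[0])
    return model, report


def predict(model: QuadrantClassifier | RadiusRegressor, features: np.ndarray) -> np.ndarray:
    """Forward-pass prediction for one feature vector or a batch."""
    return model.predict(np.atleast_2d(features))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def model_to_json(model: QuadrantClassifier | RadiusRegressor, path: str | Path | None = None) -> str:
    """Serialise a trained model (architecture, normalisation, weights) to JSON."""
    payload = {
        "task": model._task,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "feature_mean": model.feature_mean_.tolist(),
        "feature_sd": model.feature_sd_.tolist(),
        "weights": [w.tolist() for w in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def model_from_json(source: str | Path) -> QuadrantClassifier | RadiusRegressor:
    """Reconstruct a serialised model; predictions match the original bit-for-bit."""
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        text = Path(source).read_text(encoding="utf-8")
    payload = json.loads(text)
    cls = QuadrantClassifier if payload["task"] == "quadrant" else RadiusRegressor
    model = cls(**payload["params"])
    model.n_features_in_ = payload["n_features_in"]
    model.feature_mean_ = np.array(payload["feature_mean"])
    model.feature_sd_ = np.array(payload["feature_sd"])
    model.weights_ = [np.array(w) for w in payload["weights"]]
    model.biases_ = [np.array(b) for b in payload["biases"]]
    model.loss_ = payload.get("loss", np.nan)
    return model
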