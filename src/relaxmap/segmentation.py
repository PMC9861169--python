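"""Per-scan MLP classification of pixel intensity-vs-time vectors.

The idea: in a relaxometry series, every pixel traces a curve across the
K acquisitions. Pixels inside a sample follow an exponential recovery or
decay; aerated background pixels trace only the magnitude-noise floor.
A small feed-forward network — K inputs, 10 hidden tanh units, one
sigmoid output — trained on two small square ROIs taken from the very
scan to be segmented (one on the object, labelled 1; one on aerated
background, labelled 0) learns to separate the two behaviours, including
whatever noise character the current scanner session has. Pixels the
network rejects are excluded from curve fitting downstream.

The network is deliberately tiny and trained fresh per scan; it never
transfers across protocols with a different number of acquisitions.
Training is full-batch gradient descent with momentum on binary
cross-entropy, which is ample for a 200-vector training set.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .dicom_io import RelaxationSeries, RoiSquare

__all__ = [
    "ActivationKind",
    "activation",
    "neuron_output",
    "TrainingSet",
    "MLPModel",
    "TrainingReport",
    "extract_training_set",
    "train_classifier",
    "classify_pixels",
]


class ActivationKind(enum.Enum):
    STEP = "step"          # Heaviside: 0 for x <= 0, 1 for x > 0
    UNIPOLAR = "unipolar"  # logistic 1/(1+exp(-beta*x)), range (0, 1)
    BIPOLAR = "bipolar"    # tanh(beta*x), range (-1, 1)


def activation(x, kind: ActivationKind, beta: float = 1.0):
    """Evaluate a neuron activation function elementwise.

    ``beta`` sets the steepness of the continuous kinds; as beta grows
    they approach the step function.
    """
    x_arr = np.asarray(x, dtype=float)
    if kind is ActivationKind.STEP:
        out = (x_arr > 0).astype(float)
    else:
        if beta <= 0:
            raise ValueError("beta must be > 0 for continuous activations")
        if kind is ActivationKind.UNIPOLAR:
            out = expit(beta * x_arr)
        else:
            out = np.tanh(beta * x_arr)
    return out if out.ndim else float(out)


def neuron_output(x, w, b: float, kind: ActivationKind, beta: float = 1.0) -> float:
    """Single-neuron response: activation of the weighted sum ``b + x.w``."""
    x_arr = np.asarray(x, dtype=float)
    w_arr = np.asarray(w, dtype=float)
    if x_arr.shape != w_arr.shape:
        raise ValueError(f"input/weight length mismatch: {x_arr.shape} vs {w_arr.shape}")
    return float(activation(b + float(x_arr @ w_arr), kind, beta))


@dataclass
class TrainingSet:
    """Labelled per-pixel intensity vectors (rows: pixels, cols: times)."""

    vectors: np.ndarray  # (N, K)
    labels: np.ndarray   # (N,), 1 = object, 0 = aerated noise

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be an N x K matrix")
        if self.labels.shape != (self.vectors.shape[0],):
            raise ValueError("one label per vector required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.vectors.shape[1]


def extract_training_set(
    series: RelaxationSeries,
    object_roi: RoiSquare,
    air_roi: RoiSquare,
) -> TrainingSet:
    """Build the training set from two square ROIs of the scan itself.

    One K-vector per ROI pixel, object block first, row-major within each
    ROI; object pixels are labelled 1, aerated pixels 0. Two 10x10 ROIs
    on a 23-frame series therefore yield 200 training vectors of length 23.
    """
    object_roi.validate_within(series.shape)
    air_roi.validate_within(series.shape)
    if object_roi.overlaps(air_roi):
        raise ValueError("object and air ROIs must be disjoint")

    k = series.n_frames
    obj = series.pixels[object_roi.slices()].reshape(-1, k)
    air = series.pixels[air_roi.slices()].reshape(-1, k)
    vectors = np.vstack([obj, air])
    labels = np.concatenate([np.ones(len(obj), dtype=int), np.zeros(len(air), dtype=int)])
    return TrainingSet(vectors=vectors, labels=labels)


@dataclass
class MLPModel:
    """Weights and configuration of the K-hidden-1 pixel classifier.

    ``norm_constant`` is the series-wide intensity maximum recorded at
    training time; inputs are divided by it at both train and predict
    time so raw clinical intensities (~1e3) do not saturate the sigmoids.
    """

    w_in: np.ndarray      # (hidden, K)
    b_hidden: np.ndarray  # (hidden,)
    w_out: np.ndarray     # (hidden,)
    b_out: float
    beta_hidden: float = 1.0
    beta_out: float = 1.0
    norm_constant: float = 1.0

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.ndim != 2 or self.w_in.shape[0] < 1:
            raise ValueError("w_in must be (hidden >= 1) x K")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be > 0")
        for arr in (self.w_in, self.b_hidden, self.w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[0]

    def forward(self, vectors: np.ndarray) -> np.ndarray:
        """Network response in (0, 1) for each row of ``vectors`` (raw units)."""
        x = np.atleast_2d(np.asarray(vectors, dtype=float)) / self.norm_constant
        if x.shape[1] != self.n_inputs:
            raise ValueError(
                f"model expects {self.n_inputs} inputs, got vectors of length {x.shape[1]}"
            )
        h = np.tanh(self.beta_hidden * (x @ self.w_in.T + self.b_hidden))
        u = h @ self.w_out + self.b_out
        return expit(self.beta_out * u)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "architecture": [self.n_inputs, self.n_hidden, 1],
            "hidden_activation": "bipolar",
            "output_activation": "unipolar",
            "beta_hidden": self.beta_hidden,
            "beta_out": self.beta_out,
            "norm_constant": self.norm_constant,
            "w_in": self.w_in.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MLPModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            w_in=np.asarray(doc["w_in"]),
            b_hidden=np.asarray(doc["b_hidden"]),
            w_out=np.asarray(doc["w_out"]),
            b_out=float(doc["b_out"]),
            beta_hidden=float(doc["beta_hidden"]),
            beta_out=float(doc["beta_out"]),
            norm_constant=float(doc["norm_constant"]),
        )


@dataclass
class TrainingReport:
    final_loss: float
    n_epochs: int
    training_accuracy: float


def train_classifier(
    training_set: TrainingSet,
    hidden: int = 10,
    seed: int = 0,
    max_epochs: int = 500,
    tol: float = 1e-6,
    learning_rate: float = 0.5,
    momentum: float = 0.9,
) -> tuple[MLPModel, TrainingReport]:
    """Train the K-hidden-1 classifier on one scan's ROI vectors.

    Full-batch gradient descent with momentum on binary cross-entropy;
    stops when the loss decrease falls below ``tol`` or at ``max_epochs``.
    Reproducible for a fixed seed.
    """
    ts = training_set
    classes = set(np.unique(ts.labels))
    if classes != {0, 1}:
        raise ValueError("training set must contain both classes (0 and 1)")
    if not np.all(np.isfinite(ts.vectors)):
        raise ValueError("training vectors must be finite")

    norm = float(ts.vectors.max())
    if norm <= 0:
        raise ValueError("training vectors are all zero; cannot normalize")
    x = ts.vectors / norm
    t = ts.labels.astype(float)
    n, k = x.shape

    rng = np.random.default_rng(seed)
    w_in = rng.normal(0.0, 1.0 / np.sqrt(k), size=(hidden, k))
    b_h = np.zeros(hidden)
    w_out = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
    b_o = 0.0
    vel = [np.zeros_like(w_in), np.zeros_like(b_h), np.zeros_like(w_out), 0.0]

    def loss_of(y: np.ndarray) -> float:
        eps = 1e-12
        return float(-np.mean(t * np.log(y + eps) + (1 - t) * np.log(1 - y + eps)))

    prev_loss = np.inf
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        h = np.tanh(x @ w_in.T + b_h)          # (n, hidden)
        y = expit(h @ w_out + b_o)
        loss = loss_of(y)

        delta_o = (y - t) / n                   # dL/du_out
        grad_w_out = h.T @ delta_o
        grad_b_out = float(delta_o.sum())
        delta_h = np.outer(delta_o, w_out) * (1.0 - h**2)
        grad_w_in = delta_h.T @ x
        grad_b_h = delta_h.sum(axis=0)

        vel[0] = momentum * vel[0] - learning_rate * grad_w_in
        vel[1] = momentum * vel[1] - learning_rate * grad_b_h
        vel[2] = momentum * vel[2] - learning_rate * grad_w_out
        vel[3] = momentum * vel[3] - learning_rate * grad_b_out
        w_in += vel[0]
        b_h += vel[1]
        w_out += vel[2]
        b_o += vel[3]

        if abs(prev_loss - loss) < tol:
            break
        prev_loss = loss

    model = MLPModel(
        w_in=w_in, b_hidden=b_h, w_out=w_out, b_out=b_o,
        beta_hidden=1.0, beta_out=1.0, norm_constant=norm,
    )
    y_final = model.forward(ts.vectors)
    accuracy = float(np.mean((y_final > 0.5).astype(int) == ts.labels))
    report = TrainingReport(
        final_loss=loss_of(y_final), n_epochs=epoch, training_accuracy=accuracy
    )
    return model, report


def classify_pixels(
    series: RelaxationSeries,
    model: MLPModel,
    threshold: float = 0.5,
) -> np.ndarray:
    """Classify every pixel of a series; 1 = object, 0 = aerated noise.

    The mask is 1 where the network response strictly exceeds
    ``threshold`` (a response of exactly 0.5 is conservatively treated as
    noise). Deterministic, and independent of on-disk frame order because
    the series is time-sorted on read.
    """
    if model.n_inputs != series.n_frames:
        raise ValueError(
            f"model has {model.n_inputs} inputs but series has {series.n_frames} frames"
        )
    responses = model.forward(series.pixel_vectors())
    return (responses > threshold).astype(np.uint8).reshape(series.shape)
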