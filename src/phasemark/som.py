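"""Rectangular self-organizing map trained by competitive learning.

The map is a rows x cols grid of weight vectors (default 3x3, nine
clusters).  Training repeatedly draws a random input vector, finds the
best matching unit (BMU) — the node whose weights are Euclidean-closest —
and pulls every node toward the input:

    w_y  <-  w_y + U(bmu, y, i) * gamma(i) * (x - w_y)

where ``gamma(i)`` is a monotonically decreasing learning coefficient and
``U`` is a neighborhood function of squared grid distance that shrinks
over time (Gaussian by default, ``U(bmu, bmu, i) = 1``).  Training stops
at the step budget or when the weights stop moving over a full epoch.

Node indexing is row-major and 0-based internally; reports and label
matrices use 1-based cluster numbers 1..rows*cols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class SOMTrainParams:
    """Training schedule for a rectangular SOM.

    ``max_iterations`` counts single-sample steps; when None it defaults to
    500 steps per input vector.  ``initial_radius`` defaults to
    max(rows, cols)/2 and decays exponentially to ``final_radius`` at the
    last step.
    """

    rows: int = 3
    cols: int = 3
    max_iterations: int | None = None
    initial_learning_rate: float = 0.5
    learning_decay: str = "exponential"  # or "linear"
    learning_decay_rate: float = 8.0  # gamma(T) = gamma(0) * exp(-rate)
    neighborhood_kind: str = "gaussian"  # or "rectangular"
    initial_radius: float | None = None
    final_radius: float = 0.5
    seed: int = 0
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("grid must have at least 2 nodes")
        if not 0.0 < self.initial_learning_rate <= 1.0:
            raise ValueError("initial_learning_rate must lie in (0, 1]")
        if self.learning_decay not in ("exponential", "linear"):
            raise ValueError(f"unknown learning_decay {self.learning_decay!r}")
        if self.neighborhood_kind not in ("gaussian", "rectangular"):
            raise ValueError(f"unknown neighborhood {self.neighborhood_kind!r}")

    def resolve(self, n_inputs: int) -> "SOMTrainParams":
        """Fill in data-dependent defaults (step budget, initial radius)."""
        out = replace(self)
        if out.max_iterations is None:
            out.max_iterations = 500 * n_inputs
        if out.initial_radius is None:
            out.initial_radius = max(out.rows, out.cols) / 2.0
        return out

    def learning_rate(self, i: int) -> float:
        T = self.max_iterations or 1
        g0 = self.initial_learning_rate
        if self.learning_decay == "linear":
            return g0 * max(0.0, 1.0 - i / T)
        return g0 * float(np.exp(-self.learning_decay_rate * i / T))

    def radius(self, i: int) -> float:
        T = self.max_iterations or 1
        s0 = float(self.initial_radius or 1.0)
        sT = min(self.final_radius, s0)
        return s0 * float((sT / s0) ** (min(i, T) / T))


@dataclass
class SOMModel:
    weights: np.ndarray  # (n_nodes, dim), row-major node order
    grid_coords: np.ndarray  # (n_nodes, 2) integer (row, col)
    params: SOMTrainParams
    training_steps_run: int = 0
    quantization_error: float = 0.0
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "grid_coords": self.grid_coords.tolist(),
                    "params": {
                        k: v for k, v in self.params.__dict__.items()
                    },
                    "training_steps_run": self.training_steps_run,
                    "quantization_error": self.quantization_error,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["weights"], dtype=float),
            np.asarray(d["grid_coords"], dtype=int),
            SOMTrainParams(**d["params"]),
            d["training_steps_run"],
            d["quantization_error"],
        )


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def init_grid(
    rows: int,
    cols: int,
    dim: int,
    data: np.ndarray | None = None,
    seed: int = 0,
    params: SOMTrainParams | None = None,
) -> SOMModel:
    """Random weight initialization, uniform within the per-dimension data range.

    With no data the weights are standard normal.  A constant data
    dimension pins that weight coordinate to the constant.
    """
    if rows <= 0 or cols <= 0 or dim < 1:
        raise ValueError("grid dimensions and input dimension must be positive")
    rng = np.random.default_rng(seed)
    n_nodes = rows * cols
    if data is None:
        weights = rng.standard_normal((n_nodes, dim))
    else:
        data = np.asarray(data, dtype=float)
        lo, hi = data.min(axis=0), data.max(axis=0)
        weights = lo + rng.random((n_nodes, dim)) * (hi - lo)
    params = params or SOMTrainParams(rows=rows, cols=cols, seed=seed)
    return SOMModel(weights, _grid_coords(rows, cols), params)


def find_bmu(model: SOMModel, x: np.ndarray) -> int:
    """Best matching unit: argmin Euclidean distance, lowest index on ties."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValueError(f"input dimension {x.shape} != model dimension {model.dim}")
    d2 = np.einsum("nd,nd->n", model.weights - x, model.weights - x)
    return int(np.argmin(d2))


def neighborhood(model: SOMModel, bmu: int, i: int) -> np.ndarray:
    """U(bmu, y, i) over all nodes y; U at the BMU itself is 1."""
    p = model.params
    d2 = np.sum((model.grid_coords - model.grid_coords[bmu]) ** 2, axis=1).astype(float)
    sigma = p.radius(i)
    if p.neighborhood_kind == "rectangular":
        return (np.sqrt(d2) <= sigma).astype(float)
    return np.exp(-d2 / (2.0 * sigma**2))


def update_weights(model: SOMModel, x: np.ndarray, bmu: int, i: int) -> None:
    """In-place competitive-learning update; only the weights change."""
    if not 0 <= bmu < model.n_nodes:
        raise ValueError(f"invalid BMU index {bmu}")
    x = np.asarray(x, dtype=float)
    U = neighborhood(model, bmu, i)
    gamma = model.params.learning_rate(i)
    model.weights += (U * gamma)[:, None] * (x - model.weights)


def quantization_error(model: SOMModel, data: np.ndarray) -> float:
    """Mean Euclidean distance of inputs to their BMU."""
    data = np.asarray(data, dtype=float)
    d2 = (
        np.sum(data**2, axis=1)[:, None]
        - 2.0 * data @ model.weights.T
        + np.sum(model.weights**2, axis=1)[None, :]
    )
    return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0)).mean())


def train_som(
    data: np.ndarray, params: SOMTrainParams, record_history: bool = False
) -> SOMModel:
    """Train by repeated random draws until the step budget or convergence.

    One epoch is ``n_inputs`` steps; training stops early when the maximum
    absolute weight change over a full epoch falls below
    ``convergence_tol``.  Reproducible: the same data, params and seed give
    bit-identical models.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D array")
    n, dim = data.shape
    params = params.resolve(n)
    rng = np.random.default_rng(params.seed)
    model = init_grid(params.rows, params.cols, dim, data, params.seed, params)
    T = int(params.max_iterations)  # type: ignore[arg-type]
    epoch_start = model.weights.copy()
    for i in range(T):
        q = int(rng.integers(n))
        bmu = find_bmu(model, data[q])
        update_weights(model, data[q], bmu, i)
        if (i + 1) % n == 0:
            delta = float(np.abs(model.weights - epoch_start).max())
            if record_history:  # full-data QE snapshot at the epoch boundary
                model.qe_history.append(quantization_error(model, data))
            if delta < params.convergence_tol:
                model.training_steps_run = i + 1
                break
            epoch_start = model.weights.copy()
    else:
        model.training_steps_run = T
    model.quantization_error = quantization_error(model, data)
    return model


def assign_clusters(model: SOMModel, data: np.ndarray) -> np.ndarray:
    """BMU index per input (0-based, row-major); deterministic given the model."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != model.dim:
        raise ValueError("data dimension does not match model dimension")
    d2 = (
        np.sum(data**2, axis=1)[:, None]
        - 2.0 * data @ model.weights.T
        + np.sum(model.weights**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)
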