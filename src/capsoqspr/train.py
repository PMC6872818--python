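"""Training the feedforward network by CAPSO search over its flat parameters.

The fitness of a particle is the training-set mean squared error of the
network it encodes; the swarm minimizes it inside a box (default
[-10, 10] per weight/bias, which covers the sigmoid saturation range for
normalized inputs).  Validation MSE is monitored at checkpoints for
reporting and architecture selection only — it never drives early
stopping.

The swarm is a global searcher, not a precise local one: on realizable
tasks it reliably finds good basins but stalls around training MSE of a
few 1e-3 (normalized scale).  Training therefore finishes, by default,
with full-batch back-propagation refinement of the swarm's best
parameters — resilient backpropagation (iRprop-), whose sign-based
per-weight steps are robust to the vanishing gradients of deep sigmoid
stacks; plain gradient descent is available as ``method="gd"``.  This
two-stage scheme (population search for initial weights, BP for final
convergence) is the standard construction of the GA-BP/PSO-BP model
family this network belongs to.

Also here: the hidden-node architecture search (same node count in every
hidden layer, candidates tried with identical swarm seeds so candidates
differ only in topology) and a random-parameter baseline evaluated at an
equal objective-evaluation budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .errors import ConfigurationError, ContractError, DataValidationError, OptimizationError
from .network import NetworkArchitecture, decode, parameter_count, predict_batch
from .swarm import OptimizationResult, SwarmConfig, optimize
from . import data as dataio

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "ArchSearchResult",
    "training_objective",
    "make_batch_objective",
    "train",
    "train_from_table",
    "gradient_refine",
    "search_architecture",
    "random_search_baseline",
]

Dataset = Tuple[np.ndarray, np.ndarray]


@dataclass
class TrainingConfig:
    """Everything needed to reproduce one training run."""

    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    arch: NetworkArchitecture = field(default_factory=NetworkArchitecture)
    objective: str = "mse"
    gradient_refinement: bool = True
    refine_method: str = "rprop"
    learning_rate: float = 0.01  # initial per-weight step for rprop, step size for gd
    refine_epochs: int = 2000
    checkpoint_every: int = 100

    def __post_init__(self) -> None:
        if self.objective != "mse":
            raise ConfigurationError(f"unsupported objective {self.objective!r}")
        if self.refine_method not in ("rprop", "gd"):
            raise ConfigurationError(f"unknown refinement method {self.refine_method!r}")
        if self.gradient_refinement and (self.learning_rate <= 0 or self.refine_epochs < 0):
            raise ConfigurationError("refinement needs learning_rate > 0 and epochs >= 0")

    def to_dict(self) -> dict:
        return {
            "swarm": {k: getattr(self.swarm, k) for k in self.swarm.__dataclass_fields__},
            "arch": {
                "layer_sizes": list(self.arch.layer_sizes),
                "output_activation": self.arch.output_activation,
            },
            "objective": self.objective,
            "gradient_refinement": self.gradient_refinement,
            "refine_method": self.refine_method,
            "learning_rate": self.learning_rate,
            "refine_epochs": self.refine_epochs,
        }


@dataclass
class TrainedModel:
    """A trained network with its normalization state and training history."""

    arch: NetworkArchitecture
    best_params: np.ndarray
    training_trace: np.ndarray
    normalization: Optional[dataio.NormalizationParams] = None
    config: Optional[dict] = None
    checkpoints: List[Tuple[int, float, float]] = field(default_factory=list)
    final_train_mse: float = float("nan")
    n_evaluations: int = 0

    def predict_normalized(self, X: np.ndarray) -> np.ndarray:
        """Predictions on the normalized scale from a normalized matrix."""
        return predict_batch(self.arch, self.best_params, X)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        """Predict physical-scale (eV) energies for a raw descriptor table."""
        if self.normalization is None:
            raise ConfigurationError("model carries no normalization state")
        normed = dataio.apply_normalization(self.normalization, table)
        X = normed.loc[:, list(dataio.FEATURE_COLUMNS)].to_numpy(dtype=float)
        yhat = predict_batch(self.arch, self.best_params, X)
        return dataio.denormalize_target(self.normalization, yhat)

    # --- persistence (JSON; load/save round-trips bit-exactly) ----------

    def to_dict(self) -> dict:
        return {
            "format": "capsoqspr-model",
            "version": __version__,
            "architecture": list(self.arch.layer_sizes),
            "output_activation": self.arch.output_activation,
            "parameters": [float(v) for v in self.best_params],
            "normalization": None if self.normalization is None else self.normalization.to_dict(),
            "config": self.config,
            "final_train_mse": self.final_train_mse,
            "n_evaluations": self.n_evaluations,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "capsoqspr-model":
            raise DataValidationError(f"{path} is not a capsoqspr model file")
        arch = NetworkArchitecture(
            tuple(payload["architecture"]), payload["output_activation"]
        )
        norm = payload.get("normalization")
        return cls(
            arch=arch,
            best_params=np.asarray(payload["parameters"], dtype=float),
            training_trace=np.empty(0),
            normalization=None if norm is None else dataio.NormalizationParams.from_dict(norm),
            config=payload.get("config"),
            final_train_mse=payload.get("final_train_mse", float("nan")),
            n_evaluations=payload.get("n_evaluations", 0),
        )


def training_objective(
    params: np.ndarray, arch: NetworkArchitecture, X: np.ndarray, y: np.ndarray
) -> float:
    """Mean squared error of the encoded network on (X, y)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise DataValidationError("cannot evaluate the objective on an empty dataset")
    if X.shape[0] != y.size:
        raise ContractError(f"X has {X.shape[0]} rows but y has {y.size} entries")
    yhat = predict_batch(arch, params, X)
    return float(np.mean((y - yhat) ** 2))


def make_batch_objective(arch: NetworkArchitecture, X: np.ndarray, y: np.ndarray):
    """Vectorized objective: an (m, P) particle matrix -> (m,) MSE vector.

    Evaluates all particles' networks in one einsum pipeline; agrees with
    :func:`training_objective` particle by particle.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise DataValidationError("cannot evaluate the objective on an empty dataset")
    shapes = arch.layer_shapes
    n_layers = len(shapes)
    sigmoid_output = arch.output_activation == "sigmoid"

    offsets = []
    off = 0
    for n_out, n_in in shapes:
        offsets.append((off, off + n_out * n_in, off + n_out * n_in + n_out))
        off += n_out * n_in + n_out

    def batch_objective(P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, dtype=float)
        m = P.shape[0]
        H = np.broadcast_to(X, (m,) + X.shape)
        for i, ((n_out, n_in), (w0, w1, b1)) in enumerate(zip(shapes, offsets)):
            W = P[:, w0:w1].reshape(m, n_out, n_in)
            b = P[:, w1:b1].reshape(m, 1, n_out)
            Z = np.einsum("mni,moi->mno", H, W) + b
            H = expit(Z) if (i < n_layers - 1 or sigmoid_output) else Z
        resid = H[:, :, 0] - y
        return np.mean(resid**2, axis=1)

    return batch_objective


def train(
    train_set: Dataset,
    validation_set: Optional[Dataset],
    config: TrainingConfig,
) -> TrainedModel:
    """Run the CAPSO search over the network's flat parameter space.

    Both sets must already be normalized with the training set's
    statistics.  Seeded determinism: identical configs give identical
    ``best_params``.
    """
    X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != config.arch.n_inputs:
        raise ContractError(
            f"training matrix has shape {X.shape}, architecture {config.arch} "
            f"expects {config.arch.n_inputs} descriptor columns"
        )
    if X.shape[0] != y.size or X.shape[0] == 0:
        raise DataValidationError("empty or inconsistent training set")
    if validation_set is not None:
        Xv = np.asarray(validation_set[0], dtype=float)
        yv = np.asarray(validation_set[1], dtype=float).ravel()
        if Xv.shape[1] != config.arch.n_inputs or Xv.shape[0] != yv.size:
            raise ContractError("validation set inconsistent with the architecture")
    else:
        Xv = yv = None

    dim = parameter_count(config.arch)
    batch_obj = make_batch_objective(config.arch, X, y)
    checkpoints: List[Tuple[int, float, float]] = []

    def callback(state) -> None:
        if Xv is not None and state.iteration % config.checkpoint_every == 0:
            val_mse = training_objective(state.global_best_position, config.arch, Xv, yv)
            checkpoints.append((state.iteration, state.global_best_value, val_mse))

    result = optimize(
        lambda p: training_objective(p, config.arch, X, y),
        dim,
        config.swarm,
        batch_objective=batch_obj,
        callback=callback,
    )

    model = TrainedModel(
        arch=config.arch,
        best_params=result.best_position,
        training_trace=result.best_value_trace,
        config=config.to_dict(),
        checkpoints=checkpoints,
        final_train_mse=result.best_value,
        n_evaluations=result.n_evaluations,
    )
    if config.gradient_refinement and config.refine_epochs > 0:
        model = gradient_refine(
            model, X, y, config.learning_rate, config.refine_epochs, config.refine_method
        )
    return model


def mse_gradient(
    params: np.ndarray, arch: NetworkArchitecture, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Full-batch gradient of the MSE objective, by backpropagation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    layers = decode(params, arch)
    sigmoid_output = arch.output_activation == "sigmoid"
    n = X.shape[0]

    hs = [X]
    h = X
    for i, (w, b) in enumerate(layers):
        z = h @ w.T + b
        h = expit(z) if (i < len(layers) - 1 or sigmoid_output) else z
        hs.append(h)
    delta = (2.0 / n) * (hs[-1][:, 0] - y)[:, None]
    if sigmoid_output:
        delta = delta * hs[-1] * (1.0 - hs[-1])

    parts: List[Optional[np.ndarray]] = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        w, _ = layers[i]
        grad_w = delta.T @ hs[i]
        grad_b = delta.sum(axis=0)
        parts[i] = np.concatenate([grad_w.ravel(), grad_b])
        if i > 0:
            delta = (delta @ w) * hs[i] * (1.0 - hs[i])
    grad = np.concatenate(parts)
    if not np.all(np.isfinite(grad)):
        bad = int(np.flatnonzero(~np.isfinite(grad))[0])
        raise OptimizationError(
            f"non-finite gradient at parameter index {bad} during refinement"
        )
    return grad


def gradient_refine(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    learning_rate: float = 0.01,
    epochs: int = 2000,
    method: str = "rprop",
) -> TrainedModel:
    """Polish a trained model by full-batch backpropagation on MSE.

    ``method="gd"`` takes plain gradient-descent steps of size
    ``learning_rate``; ``method="rprop"`` (default) runs iRprop- with
    ``learning_rate`` as the initial per-weight step, per-weight steps
    growing 1.2x on a stable gradient sign and shrinking 0.5x on a sign
    flip.  The best parameters seen are kept, so the returned model's
    training MSE is never above the input model's; zero epochs returns
    the model unchanged.
    """
    if epochs == 0:
        return model
    if method not in ("rprop", "gd"):
        raise ConfigurationError(f"unknown refinement method {method!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    arch = model.arch

    params = model.best_params.copy()
    best_params = params.copy()
    best_mse = training_objective(params, arch, X, y)
    trace = []

    step = np.full_like(params, learning_rate)
    prev_grad = np.zeros_like(params)

    for _ in range(epochs):
        grad = mse_gradient(params, arch, X, y)
        if method == "gd":
            params = params - learning_rate * grad
        else:
            same = grad * prev_grad
            step = np.where(
                same > 0,
                np.minimum(step * 1.2, 1.0),
                np.where(same < 0, np.maximum(step * 0.5, 1e-10), step),
            )
            grad = np.where(same < 0, 0.0, grad)  # iRprop-: skip after a sign flip
            params = params - np.sign(grad) * step
            prev_grad = grad
        cur = training_objective(params, arch, X, y)
        trace.append(cur)
        if cur < best_mse:
            best_mse = cur
            best_params = params.copy()

    return replace(
        model,
        best_params=best_params,
        final_train_mse=best_mse,
        training_trace=np.concatenate([model.training_trace, np.asarray(trace)]),
    )


@dataclass
class ArchSearchResult:
    """Per-candidate hidden-node counts with their train/validation MSE."""

    records: List[dict] = field(default_factory=list)
    selected_nodes: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def search_architecture(
    train_set: Dataset,
    validation_set: Dataset,
    base_config: TrainingConfig,
    node_candidates: Iterable[int] = range(2, 9),
    hidden_layers: int = 5,
) -> ArchSearchResult:
    """Try one hidden-node count per candidate, same count in every hidden layer.

    All candidates run with identical swarm seeds so they differ only in
    topology.  The selected count minimizes validation MSE; ties break
    toward fewer nodes.  A failing candidate is recorded, not fatal,
    unless every candidate fails.
    """
    candidates = sorted(set(int(c) for c in node_candidates))
    if not candidates:
        raise ConfigurationError("node_candidates must be non-empty")
    n_in = base_config.arch.n_inputs
    n_out = base_config.arch.n_outputs

    result = ArchSearchResult()
    best: Optional[Tuple[float, int]] = None
    Xv, yv = validation_set
    for nodes in candidates:
        arch = NetworkArchitecture(
            (n_in,) + (nodes,) * hidden_layers + (n_out,),
            base_config.arch.output_activation,
        )
        cfg = replace(base_config, arch=arch)
        try:
            model = train(train_set, validation_set, cfg)
            val_mse = training_objective(model.best_params, arch, Xv, yv)
            record = {
                "nodes": nodes,
                "train_mse": model.final_train_mse,
                "validation_mse": val_mse,
                "error": None,
            }
            if best is None or val_mse < best[0]:
                best = (val_mse, nodes)
        except Exception as exc:  # noqa: BLE001 - candidate failures are data
            record = {
                "nodes": nodes,
                "train_mse": float("nan"),
                "validation_mse": float("nan"),
                "error": f"{type(exc).__name__}: {exc}",
            }
        result.records.append(record)
    if best is None:
        raise OptimizationError("every architecture candidate failed to train")
    result.selected_nodes = best[1]
    return result


def random_search_baseline(
    train_set: Dataset,
    arch: NetworkArchitecture,
    n_evaluations: int,
    lower_bound: float = -10.0,
    upper_bound: float = 10.0,
    rng_seed: int = 0,
    chunk: int = 256,
) -> Tuple[np.ndarray, float]:
    """Best of ``n_evaluations`` uniformly random parameter vectors.

    An equal-budget no-optimization comparator: same objective, same box,
    same number of evaluations as a swarm run, but no search dynamics.
    """
    X, y = train_set
    batch_obj = make_batch_objective(arch, np.asarray(X, float), np.asarray(y, float))
    rng = np.random.default_rng(rng_seed)
    dim = parameter_count(arch)
    best_val = np.inf
    best_params = None
    remaining = int(n_evaluations)
    while remaining > 0:
        k = min(chunk, remaining)
        P = rng.uniform(lower_bound, upper_bound, size=(k, dim))
        vals = batch_obj(P)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best_val = float(vals[i])
            best_params = P[i].copy()
        remaining -= k
    return best_params, best_val


def train_from_table(
    table: pd.DataFrame,
    config: Optional[TrainingConfig] = None,
    split_spec: Optional[dataio.SplitSpec] = None,
    normalization_method: str = "minmax_0_1",
) -> TrainedModel:
    """End-to-end pipeline: split (if unlabeled), normalize, train.

    Normalization statistics come from the training rows only; the
    returned model carries them so it can predict raw tables directly.
    """
    table = dataio.validate_table(table)
    if dataio.SPLIT_COLUMN not in table.columns:
        table = dataio.stratified_split(table, split_spec)
    config = config or TrainingConfig()

    train_rows = table[table[dataio.SPLIT_COLUMN] == "training"]
    val_rows = table[table[dataio.SPLIT_COLUMN] == "validation"]
    norm = dataio.fit_normalization(train_rows, normalization_method)

    def prep(rows: pd.DataFrame) -> Optional[Dataset]:
        if len(rows) == 0:
            return None
        normed = dataio.apply_normalization(norm, rows)
        X = normed.loc[:, list(dataio.FEATURE_COLUMNS)].to_numpy(dtype=float)
        y = normed[dataio.TARGET_COLUMN].to_numpy(dtype=float)
        return X, y

    model = train(prep(train_rows), prep(val_rows), config)
    model.normalization = norm
    return model
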