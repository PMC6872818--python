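"""Deep feedforward regression network and the flat-parameter codec.

The model is a fully connected multilayer perceptron: sigmoid hidden
units, a single output node that is linear by default (the target is a
real-valued absorption energy in eV, for which a softmax output would be
degenerate; a sigmoid output for rescaled targets is available).

The swarm optimizer searches over a *flat* parameter vector, so this
module also defines the bijective codec between per-layer weight
matrices/bias vectors and that vector.  Ordering is fixed and documented:

    layer by layer (input->output); within a layer the weight matrix
    first, flattened row-major with one row per *destination* node
    (shape ``(n_out, n_in)``), then the bias vector (length ``n_out``).

For a ``[2, 2, 1]`` network, parameters enumerated 1..9 therefore encode
as ``W0 = [[1, 2], [3, 4]]``, ``b0 = [5, 6]``, ``W1 = [[7, 8]]``,
``b1 = [9]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .errors import ContractError

__all__ = [
    "NetworkArchitecture",
    "LayerActivations",
    "parameter_count",
    "encode",
    "decode",
    "forward",
    "predict_batch",
    "DEFAULT_ARCHITECTURE",
]

#: winning topology of the hidden-node search: 8 descriptors in, five
#: 4-node sigmoid hidden layers, one energy output
DEFAULT_LAYER_SIZES = (8, 4, 4, 4, 4, 4, 1)

OUTPUT_ACTIVATIONS = ("linear", "sigmoid")


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer sizes ``[N0, ..., N_{L+1}]`` plus the output activation."""

    layer_sizes: Tuple[int, ...] = DEFAULT_LAYER_SIZES
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 3:
            raise ContractError(
                f"architecture needs >= 3 layers (input, hidden, output), got {sizes}"
            )
        if any(n < 1 for n in sizes):
            raise ContractError(f"all layer sizes must be >= 1, got {sizes}")
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ContractError(
                f"output_activation must be one of {OUTPUT_ACTIVATIONS}, "
                f"got {self.output_activation!r}"
            )

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def layer_shapes(self) -> List[Tuple[int, int]]:
        """Weight-matrix shapes ``(n_out, n_in)`` per connection layer."""
        s = self.layer_sizes
        return [(s[i + 1], s[i]) for i in range(len(s) - 1)]

    @classmethod
    def from_string(cls, text: str, output_activation: str = "linear") -> "NetworkArchitecture":
        """Parse a dash-separated description such as ``"8-4-4-4-4-4-1"``."""
        try:
            sizes = tuple(int(tok) for tok in text.replace("x", "-").split("-"))
        except ValueError as exc:
            raise ContractError(f"cannot parse architecture {text!r}") from exc
        return cls(sizes, output_activation)

    def __str__(self) -> str:
        return "-".join(str(n) for n in self.layer_sizes)


DEFAULT_ARCHITECTURE = NetworkArchitecture()


@dataclass
class LayerActivations:
    """Per-layer pre-activations ``z^l`` and outputs ``h^l`` of one forward pass."""

    pre_activations: List[np.ndarray] = field(default_factory=list)
    activations: List[np.ndarray] = field(default_factory=list)


def parameter_count(arch) -> int:
    """Total number of weights and biases, ``sum_l (N^l * N^{l+1} + N^{l+1})``.

    Accepts a :class:`NetworkArchitecture` or a bare sequence of layer
    sizes (any length >= 2).
    """
    if isinstance(arch, NetworkArchitecture):
        sizes = arch.layer_sizes
    else:
        sizes = tuple(int(n) for n in arch)
        if len(sizes) < 2 or any(n < 1 for n in sizes):
            raise ContractError(f"need >= 2 positive layer sizes, got {sizes}")
    return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


def encode(layers: Sequence[Tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Flatten per-layer ``(weights, biases)`` pairs into one parameter vector."""
    parts = []
    for weights, biases in layers:
        weights = np.asarray(weights, dtype=float)
        biases = np.asarray(biases, dtype=float)
        if weights.ndim != 2 or biases.ndim != 1 or weights.shape[0] != biases.shape[0]:
            raise ContractError(
                f"inconsistent layer shapes: weights {weights.shape}, biases {biases.shape}"
            )
        parts.append(weights.ravel())
        parts.append(biases)
    return np.concatenate(parts) if parts else np.empty(0)


def decode(
    params: np.ndarray, arch: NetworkArchitecture
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Split a flat parameter vector into per-layer ``(weights, biases)`` pairs."""
    params = np.asarray(params, dtype=float).ravel()
    expected = parameter_count(arch)
    if params.size != expected:
        raise ContractError(
            f"parameter vector has length {params.size}, architecture "
            f"{arch} expects {expected}"
        )
    layers = []
    offset = 0
    for n_out, n_in in arch.layer_shapes:
        w = params[offset : offset + n_out * n_in].reshape(n_out, n_in)
        offset += n_out * n_in
        b = params[offset : offset + n_out]
        offset += n_out
        layers.append((w, b))
    return layers


def forward(
    arch: NetworkArchitecture, params: np.ndarray, x: np.ndarray
) -> Tuple[float, LayerActivations]:
    """Run one input vector through the network.

    Hidden layers apply the sigmoid ``1 / (1 + exp(-z))`` (overflow-safe);
    the output node applies the architecture's output activation.  Returns
    the scalar prediction (or output vector when ``n_outputs > 1``) and
    the per-layer activations.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != arch.n_inputs:
        raise ContractError(
            f"input has length {x.size}, architecture {arch} expects {arch.n_inputs}"
        )
    if not np.all(np.isfinite(x)):
        raise ContractError(f"input contains non-finite values: {x!r}")
    layers = decode(params, arch)
    acts = LayerActivations()
    h = x
    for i, (w, b) in enumerate(layers):
        z = w @ h + b
        acts.pre_activations.append(z)
        if i < len(layers) - 1 or arch.output_activation == "sigmoid":
            h = expit(z)
        else:
            h = z
        acts.activations.append(h)
    prediction = float(h[0]) if arch.n_outputs == 1 else h
    return prediction, acts


def predict_batch(
    arch: NetworkArchitecture, params: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Row-wise forward pass over a descriptor matrix, order preserved.

    Returns an ``(n,)`` vector for single-output networks, ``(n, n_out)``
    otherwise; an empty matrix yields an empty vector.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        X = np.atleast_2d(X)
    if X.shape[0] == 0:
        return np.empty(0) if arch.n_outputs == 1 else np.empty((0, arch.n_outputs))
    if X.shape[1] != arch.n_inputs:
        raise ContractError(
            f"descriptor matrix has {X.shape[1]} columns, architecture "
            f"{arch} expects {arch.n_inputs}"
        )
    layers = decode(params, arch)
    h = X
    for i, (w, b) in enumerate(layers):
        z = h @ w.T + b
        if i < len(layers) - 1 or arch.output_activation == "sigmoid":
            h = expit(z)
        else:
            h = z
    return h[:, 0] if arch.n_outputs == 1 else h
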