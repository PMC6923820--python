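"""Multi-view factorization autoencoder model.

One nonlinear multi-layer encoder per view maps that view's feature matrix
to a shared k-dimensional latent space; one single linear matrix per view
(no bias, no activation) decodes the latent back to the feature space, so
reconstruction is an exact matrix product ``Z = X @ Y`` generalizing matrix
factorization.  Latents are fused by summation and fed to a linear
classification head.

Decoder columns are kept at Euclidean norm ``1/sqrt(p)`` (hence Frobenius
norm 1) by projection, so the graph-Laplacian regularizers of different
views live on a common scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import as_array

logger = logging.getLogger(__name__)

_ACTIVATIONS = ("relu", "tanh", "identity")


@dataclass(frozen=True)
class ViewSpec:
    """Architecture of one view's encoder.

    ``hidden_dims`` lists the encoder layer widths; the last entry is the
    shared latent dimension k and must agree across all views of a model.
    """

    name: str
    input_dim: int
    hidden_dims: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_dims", tuple(int(h) for h in self.hidden_dims))
        if self.input_dim < 1:
            raise ValueError(f"view {self.name!r}: input_dim must be >= 1")
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ValueError(f"view {self.name!r}: hidden_dims must be non-empty, all >= 1")

    @property
    def latent_dim(self) -> int:
        return self.hidden_dims[-1]


@dataclass
class Linear:
    """Dense layer parameters; ``weight`` is (fan_in, fan_out)."""

    weight: np.ndarray
    bias: np.ndarray


@dataclass
class MultiViewModel:
    """Per-view encoders, per-view linear factor decoders, linear classifier."""

    view_specs: tuple[ViewSpec, ...]
    encoders: dict[str, list[Linear]]
    decoders: dict[str, np.ndarray]  # shape (k, p_v)
    classifier: Linear
    class_count: int
    activation: str = "relu"
    fusion: str = "sum"

    @property
    def view_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.view_specs)

    @property
    def latent_dim(self) -> int:
        return self.view_specs[0].latent_dim

    def spec_for(self, view: str) -> ViewSpec:
        for s in self.view_specs:
            if s.name == view:
                return s
        raise KeyError(f"unknown view {view!r}; model has {self.view_names}")


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "tanh":
        return np.tanh(z)
    if activation == "identity":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> Linear:
    # fan-in-scaled uniform init, the PyTorch nn.Linear default
    bound = 1.0 / np.sqrt(fan_in)
    return Linear(
        weight=rng.uniform(-bound, bound, size=(fan_in, fan_out)),
        bias=rng.uniform(-bound, bound, size=fan_out),
    )


def build_model(
    view_specs,
    class_count: int,
    seed: int,
    activation: str = "relu",
    fusion: str = "sum",
) -> MultiViewModel:
    """Construct a model with reproducible seeded initialization.

    All views must share the same latent dimension (the last hidden width).
    Decoder columns are renormalized to ``1/sqrt(p)`` at construction.
    """
    specs = tuple(view_specs)
    if not specs:
        raise ValueError("at least one view spec is required")
    if class_count < 2:
        raise ValueError("class_count must be >= 2")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"activation must be one of {_ACTIVATIONS}")
    if fusion not in ("sum", "concat"):
        raise ValueError("fusion must be 'sum' or 'concat'")
    k = specs[0].latent_dim
    mismatched = [s.name for s in specs if s.latent_dim != k]
    if mismatched:
        raise ValueError(
            f"latent dimension must match across views; views {mismatched} "
            f"differ from {specs[0].name!r} (k={k})"
        )
    if len({s.name for s in specs}) != len(specs):
        raise ValueError("duplicate view names")

    rng = np.random.default_rng(seed)
    encoders: dict[str, list[Linear]] = {}
    decoders: dict[str, np.ndarray] = {}
    for spec in specs:
        dims = (spec.input_dim, *spec.hidden_dims)
        encoders[spec.name] = [
            _init_linear(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)
        ]
        decoders[spec.name] = _init_linear(rng, k, spec.input_dim).weight
    fused_dim = k if fusion == "sum" else k * len(specs)
    classifier = _init_linear(rng, fused_dim, class_count)
    model = MultiViewModel(
        view_specs=specs,
        encoders=encoders,
        decoders=decoders,
        classifier=classifier,
        class_count=class_count,
        activation=activation,
        fusion=fusion,
    )
    renormalize_decoders(model)
    return model


def encoder_forward(
    layers: list[Linear], M: np.ndarray, activation: str
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass returning the latent and per-layer inputs for backprop.

    The cache holds the input activation of every layer (post-nonlinearity
    of the previous layer); the final layer applies no nonlinearity.
    """
    cache = []
    a = M
    for i, layer in enumerate(layers):
        cache.append(a)
        z = a @ layer.weight + layer.bias
        a = z if i == len(layers) - 1 else _activate(z, activation)
    return a, cache


def encoder_backward(
    layers: list[Linear],
    cache: list[np.ndarray],
    d_latent: np.ndarray,
    activation: str,
) -> tuple[list[Linear], np.ndarray]:
    """Backpropagate ``d_latent`` through the encoder.

    Returns per-layer gradients (as Linear holding dW, db) and the gradient
    with respect to the encoder input.
    """
    grads: list[Linear] = [None] * len(layers)  # type: ignore[list-item]
    da = d_latent
    for i in range(len(layers) - 1, -1, -1):
        a_in = cache[i]
        if i < len(layers) - 1:
            # da currently holds gradient wrt post-activation output of layer i
            z_out = a_in @ layers[i].weight + layers[i].bias
            if activation == "relu":
                dz = da * (z_out > 0)
            elif activation == "tanh":
                dz = da * (1.0 - np.tanh(z_out) ** 2)
            else:
                dz = da
        else:
            dz = da
        grads[i] = Linear(weight=a_in.T @ dz, bias=dz.sum(axis=0))
        da = dz @ layers[i].weight.T
    return grads, da


def encode(model: MultiViewModel, view: str, M) -> np.ndarray:
    """Map one view's (n, p) data to its (n, k) latent representation."""
    spec = model.spec_for(view)
    values = as_array(M)
    if values.ndim != 2 or values.shape[1] != spec.input_dim:
        raise ValueError(
            f"view {view!r} expects {spec.input_dim} features, got shape {values.shape}"
        )
    latent, _ = encoder_forward(model.encoders[view], values, model.activation)
    return latent


def decode(model: MultiViewModel, view: str, X: np.ndarray) -> np.ndarray:
    """Exact linear reconstruction ``Z = X @ Y`` (no bias, no nonlinearity)."""
    Y = model.decoders[model.spec_for(view).name]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != Y.shape[0]:
        raise ValueError(f"latent shape {X.shape} incompatible with decoder {Y.shape}")
    return X @ Y


def fuse_views(latents, mode: str = "sum") -> np.ndarray:
    """Combine per-view latents: element-wise sum (default) or concatenation."""
    latents = [np.asarray(x, dtype=float) for x in latents]
    if not latents:
        raise ValueError("no latents to fuse")
    shape = latents[0].shape
    if any(x.shape != shape for x in latents):
        raise ValueError(f"latent shapes differ: {[x.shape for x in latents]}")
    if mode == "sum":
        out = np.zeros(shape)
        for x in latents:
            out += x
        return out
    if mode == "concat":
        return np.concatenate(latents, axis=1)
    raise ValueError("mode must be 'sum' or 'concat'")


def classify(model: MultiViewModel, fused: np.ndarray) -> np.ndarray:
    """Raw (n, class_count) scores from the linear classification head."""
    fused = np.asarray(fused, dtype=float)
    C = model.classifier
    if fused.ndim != 2 or fused.shape[1] != C.weight.shape[0]:
        raise ValueError(
            f"fused latent shape {fused.shape} incompatible with classifier "
            f"{C.weight.shape}"
        )
    return fused @ C.weight + C.bias


def renormalize_decoders(model: MultiViewModel) -> MultiViewModel:
    """Project every decoder column to Euclidean norm ``1/sqrt(p)`` in place.

    Exactly-zero columns cannot be rescaled and are left unchanged with a
    warning.  With no zero columns this pins ``||Y||_F = 1`` per view.
    """
    for name, Y in model.decoders.items():
        p = Y.shape[1]
        norms = np.linalg.norm(Y, axis=0)
        zero = norms == 0
        if zero.any():
            warnings.warn(
                f"view {name!r}: {int(zero.sum())} zero decoder column(s) left unscaled"
            )
            logger.warning("view %r has zero decoder columns", name)
        scale = np.ones(p)
        np.divide(1.0 / np.sqrt(p), norms, out=scale, where=~zero)
        Y *= scale
    return model


def model_state(model: MultiViewModel) -> dict[str, np.ndarray]:
    """Flat name -> parameter-array mapping (live views, not copies)."""
    state: dict[str, np.ndarray] = {}
    for name in model.view_names:
        for i, layer in enumerate(model.encoders[name]):
            state[f"encoder.{name}.{i}.weight"] = layer.weight
            state[f"encoder.{name}.{i}.bias"] = layer.bias
        state[f"decoder.{name}"] = model.decoders[name]
    state["classifier.weight"] = model.classifier.weight
    state["classifier.bias"] = model.classifier.bias
    return state


def save_checkpoint(model: MultiViewModel, path) -> None:
    """Serialize all parameters plus the architecture to one ``.npz`` file."""
    meta = {
        "format_version": 1,
        "class_count": model.class_count,
        "activation": model.activation,
        "fusion": model.fusion,
        "views": [
            {"name": s.name, "input_dim": s.input_dim, "hidden_dims": list(s.hidden_dims)}
            for s in model.view_specs
        ],
    }
    arrays = {k: v for k, v in model_state(model).items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MultiViewModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        specs = tuple(
            ViewSpec(v["name"], v["input_dim"], tuple(v["hidden_dims"]))
            for v in meta["views"]
        )
        model = build_model(
            specs,
            class_count=meta["class_count"],
            seed=0,
            activation=meta["activation"],
            fusion=meta["fusion"],
        )
        for key, arr in model_state(model).items():
            arr[...] = data[key]
    return model
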