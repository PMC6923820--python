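"""Training-objective terms.

The composite objective combines four parts: a classification loss on the
fused latent, per-view squared-Frobenius reconstruction errors weighted by
``eta``, per-view feature-network Laplacian regularizers ``Trace(Y L_G Y^T)``
weighted by ``alpha``, and per-view patient-similarity regularizers
``Trace(X^T L_S X)`` weighted by ``beta``, where ``L_S`` is the Laplacian of
the fused absolute-cosine patient similarity network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model_core
from .data import as_array
from .netprep import GraphLaplacian


@dataclass(frozen=True)
class SimilarityNetwork:
    """Symmetric non-negative sample-by-sample similarity with entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {v.shape}")
        if v.size:
            if np.max(np.abs(v - v.T)) > 1e-8:
                raise ValueError("similarity matrix must be symmetric")
            if np.min(v) < -1e-12 or np.max(v) > 1 + 1e-9:
                raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights (eta, alpha, beta) of the composite objective.

    ``gamma`` (a mutual-information term) is accepted for config completeness
    but must be 0; that term is not part of the implemented objective.
    """

    eta: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta", "alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gamma != 0:
            raise ValueError("gamma must be 0 (mutual-information term unsupported)")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-term values of one objective evaluation (components unweighted)."""

    classification: float
    reconstruction: dict[str, float]
    feature_reg: dict[str, float]
    view_reg: dict[str, float]
    weights: LossWeights

    @property
    def reconstruction_total(self) -> float:
        return float(sum(self.reconstruction.values()))

    @property
    def feature_reg_total(self) -> float:
        return float(sum(self.feature_reg.values()))

    @property
    def view_reg_total(self) -> float:
        return float(sum(self.view_reg.values()))

    @property
    def total(self) -> float:
        w = self.weights
        return float(
            self.classification
            + w.eta * self.reconstruction_total
            + w.alpha * self.feature_reg_total
            + w.beta * self.view_reg_total
        )

    def as_record(self) -> dict[str, float]:
        return {
            "classification": self.classification,
            "reconstruction_total": self.reconstruction_total,
            "feature_reg_total": self.feature_reg_total,
            "view_reg_total": self.view_reg_total,
            "total": self.total,
        }


def reconstruction_loss(M, Z) -> float:
    """Squared Frobenius norm of the reconstruction residual ``||M - Z||_F^2``."""
    M = as_array(M)
    Z = np.asarray(Z, dtype=float)
    if M.shape != Z.shape:
        raise ValueError(f"shape mismatch: data {M.shape} vs reconstruction {Z.shape}")
    diff = M - Z
    return float(np.sum(diff * diff))


def _laplacian_matrix(L) -> np.ndarray:
    if isinstance(L, GraphLaplacian):
        return L.matrix
    return np.asarray(L, dtype=float)


def feature_network_regularizer(Y: np.ndarray, L_G) -> float:
    """``Trace(Y @ L_G @ Y.T)``: inconsistency of feature embeddings with the network.

    Equals ``0.5 * sum_ij G_ij ||Y_:,i - Y_:,j||^2``, so it vanishes when all
    interacting features share an embedding and is non-negative for any
    valid Laplacian.
    """
    Y = np.asarray(Y, dtype=float)
    L = _laplacian_matrix(L_G)
    if Y.ndim != 2 or L.shape != (Y.shape[1], Y.shape[1]):
        raise ValueError(f"decoder {Y.shape} incompatible with Laplacian {L.shape}")
    return float(np.trace(Y @ L @ Y.T))


def cosine_similarity_network(X: np.ndarray) -> SimilarityNetwork:
    """Absolute-cosine sample similarity ``S_ij = |x_i . x_j| / (||x_i|| ||x_j||)``.

    Rows with zero norm get similarity 0 to every sample, including
    themselves (no epsilon inflation of norms).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError(f"latent matrix must be 2-D with >= 1 column, got {X.shape}")
    norms = np.linalg.norm(X, axis=1)
    nonzero = norms > 0
    safe = np.where(nonzero, norms, 1.0)
    S = np.abs(X @ X.T) / np.outer(safe, safe)
    S[~nonzero, :] = 0.0
    S[:, ~nonzero] = 0.0
    np.clip(S, 0.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, np.where(nonzero, 1.0, 0.0))
    return SimilarityNetwork(values=S)


def fuse_similarity(view_networks, fused_latent_network: SimilarityNetwork) -> SimilarityNetwork:
    """Uniform average of the V per-view networks and the fused-latent network."""
    mats = [n.values for n in view_networks] + [fused_latent_network.values]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError(f"similarity shapes differ: {[m.shape for m in mats]}")
    return SimilarityNetwork(values=sum(mats) / len(mats))


def similarity_laplacian(S: SimilarityNetwork) -> GraphLaplacian:
    """Graph Laplacian ``D - S`` of a similarity network."""
    v = S.values
    return GraphLaplacian(matrix=np.diag(v.sum(axis=1)) - v, degree=v.sum(axis=1))


def view_similarity_regularizer(X_v: np.ndarray, L_S) -> float:
    """``Trace(X_v.T @ L_S @ X_v)``: pulls sample latents toward the fused similarity."""
    X_v = np.asarray(X_v, dtype=float)
    L = _laplacian_matrix(L_S)
    if X_v.ndim != 2 or L.shape != (X_v.shape[0], X_v.shape[0]):
        raise ValueError(f"latent {X_v.shape} incompatible with Laplacian {L.shape}")
    return float(np.trace(X_v.T @ L @ X_v))


def cross_entropy(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mean cross-entropy of integer labels under a stable softmax of raw scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n, c = scores.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match {n} score rows")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    shifted = scores - scores.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    return float(np.mean(log_z - shifted[np.arange(n), labels]))


def softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _evaluate_terms(model, views, weights, laplacians):
    names = model.view_names
    if len(views) != len(names):
        raise ValueError(f"{len(views)} views given, model has {len(names)}")
    arrays = [as_array(v) for v in views]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all views must share the sample count")
    if laplacians is not None and len(laplacians) != len(names):
        raise ValueError("one feature-network Laplacian per view is required")
    if laplacians is None and weights.alpha > 0:
        raise ValueError("alpha > 0 requires feature-network Laplacians")

    latents = {v: model_core.encode(model, v, a) for v, a in zip(names, arrays)}
    recon = {
        v: reconstruction_loss(a, model_core.decode(model, v, latents[v]))
        for v, a in zip(names, arrays)
    }
    feature_reg = {
        v: (
            feature_network_regularizer(model.decoders[v], laplacians[i])
            if laplacians is not None
            else 0.0
        )
        for i, v in enumerate(names)
    }
    fused = model_core.fuse_views([latents[v] for v in names], mode=model.fusion)
    view_nets = [cosine_similarity_network(latents[v]) for v in names]
    fused_net = cosine_similarity_network(fused)
    S = fuse_similarity(view_nets, fused_net)
    L_S = similarity_laplacian(S)
    view_reg = {v: view_similarity_regularizer(latents[v], L_S) for v in names}
    return latents, fused, recon, feature_reg, view_reg


def supervised_objective(
    model, views, labels, weights: LossWeights, laplacians=None
) -> LossBreakdown:
    """Full composite objective with the cross-entropy classification term.

    ``laplacians`` supplies one feature-network Laplacian per view (in model
    view order); it may be omitted only when ``weights.alpha == 0``.
    """
    _, fused, recon, feature_reg, view_reg = _evaluate_terms(
        model, views, weights, laplacians
    )
    scores = model_core.classify(model, fused)
    ce = cross_entropy(np.asarray(labels), scores)
    return LossBreakdown(
        classification=ce,
        reconstruction=recon,
        feature_reg=feature_reg,
        view_reg=view_reg,
        weights=weights,
    )


def unsupervised_objective(model, views, weights: LossWeights, laplacians=None) -> LossBreakdown:
    """Composite objective without the classification term."""
    _, _, recon, feature_reg, view_reg = _evaluate_terms(
        model, views, weights, laplacians
    )
    return LossBreakdown(
        classification=0.0,
        reconstruction=recon,
        feature_reg=feature_reg,
        view_reg=view_reg,
        weights=weights,
    )
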