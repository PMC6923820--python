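"""Feature-interaction network construction and normalization.

Networks are symmetric non-negative feature-by-feature weight matrices.
They can be read from edge lists, derived from cross-feature mappings,
densified by a one-step random walk, winsorized, and Frobenius-normalized
before their graph Laplacians enter the training objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

SYMMETRY_ATOL = 1e-8


class NetworkValidationError(ValueError):
    """Raised when a network or mapping violates its structural contract."""


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed; message names the line."""


@dataclass(frozen=True)
class InteractionNetwork:
    """Symmetric non-negative feature-feature weight matrix.

    Parameters
    ----------
    weights
        Square ``(p, p)`` array, symmetric within ``1e-8``, entries >= 0.
    feature_ids
        Ordered feature identifiers of length ``p``, no duplicates.
    normalized
        True when the Frobenius norm of ``weights`` is 1 (within ``1e-6``).
    """

    weights: np.ndarray
    feature_ids: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkValidationError(f"weights must be square, got shape {w.shape}")
        if len(self.feature_ids) != w.shape[0]:
            raise NetworkValidationError(
                f"{len(self.feature_ids)} feature ids for a {w.shape[0]}x{w.shape[1]} matrix"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise NetworkValidationError("duplicate feature ids")
        if w.size and np.min(w) < 0:
            raise NetworkValidationError("network weights must be non-negative")
        if w.size and np.max(np.abs(w - w.T)) > SYMMETRY_ATOL:
            raise NetworkValidationError(
                f"network asymmetric beyond tolerance {SYMMETRY_ATOL}"
            )
        if self.normalized and abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise NetworkValidationError(
                "normalized flag set but Frobenius norm differs from 1"
            )

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GraphLaplacian:
    """Graph Laplacian ``L = D - G`` with ``D_ii = sum_j G_ij``."""

    matrix: np.ndarray
    degree: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if self.degree is None:
            object.__setattr__(self, "degree", np.diag(m).copy())
        row_sums = m.sum(axis=1)
        if m.size and np.max(np.abs(row_sums)) > 1e-6:
            raise NetworkValidationError("Laplacian row sums must be 0")


@dataclass(frozen=True)
class CrossMapping:
    """Non-negative (q source features) x (p target features) mapping weights."""

    weights: np.ndarray
    source_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "source_ids", tuple(str(s) for s in self.source_ids))
        object.__setattr__(self, "target_ids", tuple(str(t) for t in self.target_ids))
        if w.ndim != 2:
            raise NetworkValidationError(f"mapping must be 2-D, got shape {w.shape}")
        if w.shape != (len(self.source_ids), len(self.target_ids)):
            raise NetworkValidationError(
                f"mapping shape {w.shape} does not match id lists "
                f"({len(self.source_ids)}, {len(self.target_ids)})"
            )
        if w.size and np.min(w) < 0:
            raise NetworkValidationError("mapping weights must be non-negative")


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_edge_list(path, id_universe=None) -> InteractionNetwork:
    """Read a 3-column (feature_a, feature_b, weight) edge list.

    Each undirected edge is written into both triangle positions; when both
    directions are present with different weights the maximum wins.  When
    ``id_universe`` is given the matrix is built over exactly those features
    (edges touching unknown features are dropped); otherwise features are
    indexed in first-appearance order.
    """
    edges: list[tuple[str, str, float]] = []
    seen_order: dict[str, None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p for p in line.replace(",", "\t").split("\t") if p != ""]
            if len(parts) != 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, w_str = parts
            try:
                w = float(w_str)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise EdgeListParseError(
                    f"line {lineno}: non-numeric weight {w_str!r}"
                ) from None
            if not np.isfinite(w):
                raise EdgeListParseError(f"line {lineno}: non-finite weight {w_str!r}")
            if w < 0:
                raise NetworkValidationError(
                    f"line {lineno}: negative weight {w}"
                )
            edges.append((a, b, w))
            seen_order.setdefault(a)
            seen_order.setdefault(b)
    if id_universe is not None:
        ids = [str(i) for i in id_universe]
    else:
        ids = list(seen_order)
    index = {f: i for i, f in enumerate(ids)}
    p = len(ids)
    weights = np.zeros((p, p))
    for a, b, w in edges:
        if a not in index or b not in index:
            continue
        i, j = index[a], index[b]
        weights[i, j] = max(weights[i, j], w)
        weights[j, i] = max(weights[j, i], w)
    return InteractionNetwork(weights=weights, feature_ids=tuple(ids))


def filter_by_confidence(
    network: InteractionNetwork, min_conf: float
) -> InteractionNetwork:
    """Zero out entries with weight strictly below ``min_conf``."""
    if min_conf < 0:
        raise NetworkValidationError("min_conf must be >= 0")
    w = network.weights.copy()
    w[w < min_conf] = 0.0
    return replace(network, weights=w, normalized=False)


def random_walk_densify(network: InteractionNetwork) -> InteractionNetwork:
    """One-step random walk: the matrix product of the network with itself."""
    w = network.weights @ network.weights
    w = (w + w.T) / 2.0  # exact for symmetric input; guards rounding drift
    np.maximum(w, 0.0, out=w)
    return replace(network, weights=w, normalized=False)


def clip_outliers(network: InteractionNetwork, quantile: float = 0.99) -> InteractionNetwork:
    """Winsorize: cap entries above the given upper quantile of nonzero weights."""
    if not 0 < quantile <= 1:
        raise NetworkValidationError(f"quantile must be in (0, 1], got {quantile}")
    w = network.weights.copy()
    nonzero = w[w > 0]
    if nonzero.size == 0:
        return replace(network, weights=w, normalized=False)
    cap = float(np.quantile(nonzero, quantile))
    np.minimum(w, cap, out=w)
    return replace(network, weights=w, normalized=False)


def derive_cross_network(
    mapping: CrossMapping, base: InteractionNetwork
) -> InteractionNetwork:
    """Project a base network through a cross-feature mapping: ``A @ G @ A.T``.

    Used to turn e.g. a protein-protein network plus a source-to-protein
    target-score matrix into a source-feature interaction network.
    """
    if mapping.weights.shape[1] != base.n_features:
        raise NetworkValidationError(
            f"mapping target dimension {mapping.weights.shape} does not match "
            f"base network shape {base.weights.shape}"
        )
    w = mapping.weights @ base.weights @ mapping.weights.T
    w = (w + w.T) / 2.0
    np.maximum(w, 0.0, out=w)
    return InteractionNetwork(weights=w, feature_ids=mapping.source_ids)


def normalize_frobenius(network: InteractionNetwork) -> InteractionNetwork:
    """Rescale so the Frobenius norm of the weight matrix equals 1."""
    norm = np.linalg.norm(network.weights)
    if norm == 0:
        raise NetworkValidationError("cannot Frobenius-normalize an all-zero network")
    return replace(network, weights=network.weights / norm, normalized=True)


def graph_laplacian(network: InteractionNetwork) -> GraphLaplacian:
    """Build ``L = D - G`` with ``D_ii = sum_j G_ij``."""
    g = network.weights
    if g.size and np.max(np.abs(g - g.T)) > SYMMETRY_ATOL:
        raise NetworkValidationError("cannot build Laplacian of an asymmetric matrix")
    degree = g.sum(axis=1)
    lap = np.diag(degree) - g
    return GraphLaplacian(matrix=lap, degree=degree)


def prepare_network(
    network: InteractionNetwork,
    min_conf: float = 0.0,
    densify: bool = False,
    clip_quantile: float | None = 0.99,
) -> InteractionNetwork:
    """Standard pipeline: confidence filter -> random walk -> winsorize -> normalize."""
    net = filter_by_confidence(network, min_conf) if min_conf > 0 else network
    if densify:
        net = random_walk_densify(net)
    if clip_quantile is not None:
        net = clip_outliers(net, clip_quantile)
    if np.linalg.norm(net.weights) == 0:
        warnings.warn("network is empty after filtering; skipping normalization")
        return net
    return normalize_frobenius(net)
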