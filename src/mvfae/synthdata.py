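"""Synthetic multi-view benchmark generator and preprocessing transforms.

Each bundle plants a shared low-rank factor matrix, draws binary labels
from a logistic model on those factors, emits one noisy view per requested
feature space, and builds a feature-interaction network per view whose
edges connect features with similar planted loading columns — so the
network regularizer is, by construction, informative about the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, as_array
from .netprep import InteractionNetwork, normalize_frobenius


@dataclass(frozen=True)
class ViewGenSpec:
    p: int
    noise_sd: float = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    N: int = 200
    views: tuple[ViewGenSpec, ...] = (ViewGenSpec(60, 0.05), ViewGenSpec(40, 0.05))
    k_true: int = 6
    label_strength: float = 3.0
    network_density: float = 0.05
    network_noise: float = 0.0
    nonlinearity: str = "identity"  # or "tanh"
    n_clusters: int = 10
    cluster_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        views = tuple(
            v if isinstance(v, ViewGenSpec) else ViewGenSpec(*v) for v in self.views
        )
        object.__setattr__(self, "views", views)
        if self.N < 10:
            raise ValueError(f"N must be >= 10, got {self.N}")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        for v in views:
            if v.p < self.k_true:
                raise ValueError(f"every view needs p >= k_true, got p={v.p}")
            if v.noise_sd < 0:
                raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.network_density <= 1:
            raise ValueError("network_density must be in [0, 1]")
        if not 0 <= self.network_noise <= 1:
            raise ValueError("network_noise must be in [0, 1]")
        if self.nonlinearity not in ("identity", "tanh"):
            raise ValueError("nonlinearity must be 'identity' or 'tanh'")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_jitter < 0:
            raise ValueError("cluster_jitter must be >= 0")


@dataclass(frozen=True)
class SyntheticBundle:
    views: tuple[FeatureMatrix, ...]
    labels: np.ndarray
    networks: tuple[InteractionNetwork, ...]
    factors: np.ndarray  # (N, k_true) planted factor matrix
    loadings: tuple[np.ndarray, ...]  # per view, (k_true, p) with unit columns
    spec: SyntheticSpec = None  # type: ignore[assignment]

    @property
    def n_samples(self) -> int:
        return self.factors.shape[0]


def loading_similarity(B: np.ndarray) -> np.ndarray:
    """Absolute cosine similarity between loading columns, zero diagonal."""
    norms = np.linalg.norm(B, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    sim = np.abs(B.T @ B) / np.outer(safe, safe)
    np.fill_diagonal(sim, 0.0)
    return sim


def _planted_network(
    B: np.ndarray, density: float, noise: float, rng: np.random.Generator
) -> InteractionNetwork:
    p = B.shape[1]
    sim = loading_similarity(B)
    iu = np.triu_indices(p, k=1)
    n_pairs = iu[0].size
    n_edges = int(round(density * n_pairs))
    if n_edges > n_pairs:
        raise ValueError(f"density {density} asks for {n_edges} edges, only {n_pairs} pairs")
    weights = np.zeros((p, p))
    if n_edges > 0:
        pair_sims = sim[iu]
        keep = np.argsort(pair_sims)[::-1][:n_edges]
        edge_set = {(int(iu[0][e]), int(iu[1][e])) for e in keep}
        n_rewire = int(np.floor(noise * n_edges))
        if n_rewire > 0:
            rewire = rng.choice(len(keep), size=n_rewire, replace=False)
            doomed = [tuple(sorted((int(iu[0][keep[e]]), int(iu[1][keep[e]]))))
                      for e in rewire]
            for pair in doomed:
                edge_set.discard(pair)
                while True:
                    i, j = rng.integers(0, p, size=2)
                    if i != j and tuple(sorted((int(i), int(j)))) not in edge_set:
                        edge_set.add(tuple(sorted((int(i), int(j)))))
                        break
        for i, j in edge_set:
            w = max(sim[i, j], 1e-3)  # rewired pairs may have ~0 similarity
            weights[i, j] = w
            weights[j, i] = w
    ids = tuple(f"f{i}" for i in range(p))
    net = InteractionNetwork(weights=weights, feature_ids=ids)
    if np.linalg.norm(weights) > 0:
        net = normalize_frobenius(net)
    return net


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw one fully reproducible multi-view bundle from the spec."""
    rng = np.random.default_rng(spec.seed)
    N, k = spec.N, spec.k_true
    F = rng.standard_normal((N, k))
    direction = np.ones(k) / np.sqrt(k)  # fixed combination linking factors to labels
    logits = spec.label_strength * (F @ direction)
    labels = (rng.random(N) < 1.0 / (1.0 + np.exp(-logits))).astype(int)

    f_of_F = np.tanh(F) if spec.nonlinearity == "tanh" else F
    views, networks, loadings = [], [], []
    for vi, vspec in enumerate(spec.views):
        # Loading columns are drawn around shared cluster directions (feature
        # modules), so the top-similarity pairs that become network edges have
        # near-parallel columns: the planted network is genuinely consistent
        # with the planted loadings.
        directions = rng.standard_normal((k, spec.n_clusters))
        directions /= np.linalg.norm(directions, axis=0, keepdims=True)
        assignment = rng.integers(0, spec.n_clusters, size=vspec.p)
        B = directions[:, assignment] + spec.cluster_jitter * rng.standard_normal(
            (k, vspec.p)
        )
        B /= np.linalg.norm(B, axis=0, keepdims=True)
        M = f_of_F @ B
        if vspec.noise_sd > 0:
            M = M + vspec.noise_sd * rng.standard_normal((N, vspec.p))
        views.append(
            FeatureMatrix(
                values=M,
                sample_ids=tuple(f"s{i}" for i in range(N)),
                feature_ids=tuple(f"f{j}" for j in range(vspec.p)),
            )
        )
        networks.append(_planted_network(B, spec.network_density, spec.network_noise, rng))
        loadings.append(B)
    return SyntheticBundle(
        views=tuple(views),
        labels=labels,
        networks=tuple(networks),
        factors=F,
        loadings=tuple(loadings),
        spec=spec,
    )


def zscore_features(M) -> FeatureMatrix | np.ndarray:
    """Standardize every column to mean 0, standard deviation 1.

    Zero-variance columns cannot be standardized; they are set to all zeros
    with a warning.
    """
    values = as_array(M).copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance column(s) set to zero")
    values -= mean
    values /= np.where(degenerate, 1.0, sd)
    values[:, degenerate] = 0.0
    if isinstance(M, FeatureMatrix):
        return FeatureMatrix(values, M.sample_ids, M.feature_ids)
    return values


def log_transform(M, pseudocount: float = 1.0):
    """Element-wise ``log(value + pseudocount)`` for non-negative data."""
    values = as_array(M)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if values.size and values.min() < 0:
        raise ValueError("log_transform requires non-negative entries")
    out = np.log(values + pseudocount)
    if isinstance(M, FeatureMatrix):
        return FeatureMatrix(out, M.sample_ids, M.feature_ids)
    return out


def winsorize_features(M, quantile: float = 0.99):
    """Cap each column's entries at its upper ``quantile`` value."""
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    values = as_array(M).copy()
    caps = np.quantile(values, quantile, axis=0)
    values = np.minimum(values, caps)
    if isinstance(M, FeatureMatrix):
        return FeatureMatrix(values, M.sample_ids, M.feature_ids)
    return values


def filter_features(M, min_mean: float = 0.0, min_var: float = 0.0):
    """Keep exactly the columns with mean >= min_mean and variance >= min_var."""
    if min_mean < 0 or min_var < 0:
        raise ValueError("thresholds must be >= 0")
    values = as_array(M)
    keep = (values.mean(axis=0) >= min_mean) & (values.var(axis=0) >= min_var)
    if not keep.any():
        raise ValueError("feature filter removed every column")
    if isinstance(M, FeatureMatrix):
        kept_ids = tuple(f for f, k in zip(M.feature_ids, keep) if k)
        return FeatureMatrix(values[:, keep], M.sample_ids, kept_ids)
    return values[:, keep]
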