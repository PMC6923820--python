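"""Shared sample-by-feature data container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FeatureMatrix:
    """One view's samples-by-features numeric data.

    ``values`` has shape ``(n_samples, n_features)``; ``sample_ids`` and
    ``feature_ids`` label the rows and columns.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {v.shape}")
        if v.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match id lists "
                f"({len(self.sample_ids)}, {len(self.feature_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def as_array(m) -> np.ndarray:
    """Accept a FeatureMatrix or a plain array and return a float ndarray."""
    if isinstance(m, FeatureMatrix):
        return m.values
    return np.asarray(m, dtype=float)
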