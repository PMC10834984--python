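"""Class balancing with SMOTE on flattened feature vectors.

SMOTE (synthetic minority over-sampling) grows every minority class to the
majority class size by interpolating between a minority sample ``x`` and one
of its k nearest same-class neighbors ``x_nn``:

    s = x + u * (x_nn - x),   u ~ Uniform(0, 1)

Original rows are preserved verbatim; synthetic rows are flagged and carry a
record of their parent pair, so tests can verify each synthetic point lies
on the segment between its parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class FeatureDataset:
    """An (n, d) feature matrix with labels and per-row provenance flags."""

    features: np.ndarray
    labels: np.ndarray
    synthetic: np.ndarray = None  # bool per row; False = original
    parents: list = field(default_factory=list)  # (base_idx, neighbor_idx) per synthetic row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on n")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def class_counts(self) -> dict:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def smote(
    data: FeatureDataset, k_neighbors: int = 5, seed: int = 0
) -> FeatureDataset:
    """Oversample every minority class up to the majority class count.

    The effective neighbor count is ``min(k_neighbors, class size - 1)``.
    Base rows are drawn uniformly (with replacement) from the class; the
    neighbor is drawn uniformly from the base row's k nearest same-class
    neighbors under Euclidean distance, ties broken by row index.  Output is
    a pure function of ``(data, k_neighbors, seed)``.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = data.class_counts()
    majority = max(counts.values())
    rng = np.random.default_rng(seed)

    x = data.features
    new_rows: list[np.ndarray] = []
    new_labels: list = []
    parents: list[tuple[int, int]] = []
    for label in sorted(counts):  # fixed class order for determinism
        deficit = majority - counts[label]
        if deficit == 0:
            continue
        idx = np.nonzero(data.labels == label)[0]
        if idx.size < 2:
            raise ValueError(
                f"class {label!r} has {idx.size} member(s); SMOTE needs >= 2"
            )
        k = min(k_neighbors, idx.size - 1)
        # k+1 including self; NearestNeighbors sorts ties by index.
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x[idx])
        neighbors = nn.kneighbors(x[idx], return_distance=False)[:, 1:]

        base = rng.integers(0, idx.size, size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.random(deficit)
        for b, p, frac in zip(base, pick, u):
            nb = neighbors[b, p]
            row = x[idx[b]] + frac * (x[idx[nb]] - x[idx[b]])
            new_rows.append(row)
            new_labels.append(label)
            parents.append((int(idx[b]), int(idx[nb])))

    if not new_rows:
        return FeatureDataset(
            x.copy(), data.labels.copy(), data.synthetic.copy(), list(data.parents)
        )
    features = np.vstack([x, np.asarray(new_rows, dtype=x.dtype)])
    labels = np.concatenate([data.labels, np.asarray(new_labels)])
    synthetic = np.concatenate(
        [data.synthetic, np.ones(len(new_rows), dtype=bool)]
    )
    return FeatureDataset(features, labels, synthetic, list(data.parents) + parents)
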