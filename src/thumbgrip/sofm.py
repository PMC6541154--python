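"""Batch Kohonen self-organizing feature map (SOFM) with map-quality errors.

The map is a rectangular 2-D lattice of codebook vectors fitted to the
feature vectors by batch training: every epoch assigns each sample to its
best-matching unit (BMU, nearest codebook vector in Euclidean distance) and
replaces each codebook vector by the neighborhood-weighted mean of the data,
with a Gaussian lattice neighborhood whose radius shrinks over a coarse and a
fine phase.  Batch training plus principal-plane initialization makes the fit
deterministic for fixed data.

Map quality is summarized by three standard errors:

* quantization error — mean distance from each sample to its BMU;
* topographic error — fraction of samples whose first and second BMUs are not
  lattice neighbors (4-neighborhood);
* combined error (Kaski-Lagus) — per sample, the distance to the BMU plus the
  shortest codebook-space path from the BMU to the second BMU stepping only
  between lattice-adjacent units, averaged.

For classification, units are labeled by the majority posture of their
training hits (hitless units inherit the label of the nearest labeled unit on
the lattice) and a sample is assigned the label of its BMU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.decomposition import PCA

__all__ = [
    "SomMap",
    "TrainingSchedule",
    "SomErrors",
    "HitHistogram",
    "LabeledSom",
    "PcaProjection",
    "init_som",
    "train_batch",
    "bmu",
    "map_errors",
    "hit_histogram",
    "label_units",
    "classify",
    "confusion",
    "project_pca",
]


@dataclass(frozen=True)
class SomMap:
    """Codebook plus its rectangular lattice topology."""

    codebook: np.ndarray  # (units, dim)
    rows: int
    cols: int
    trained: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codebook.shape[0] != self.rows * self.cols:
            raise ValueError("codebook row count must equal rows * cols")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook must be finite")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def dim(self) -> int:
        return self.codebook.shape[1]

    @property
    def unit_coords(self) -> np.ndarray:
        """(units, 2) lattice coordinates, unit u at (u // cols, u % cols)."""
        u = np.arange(self.n_units)
        return np.column_stack([u // self.cols, u % self.cols]).astype(float)


@dataclass(frozen=True)
class TrainingSchedule:
    """Piecewise-linear radius decay: tuple of (epochs, start, end) phases.

    Default: coarse ordering phase radius 5 -> 1 over 20 epochs, then fine
    tuning 1 -> 0.5 over 30 epochs.
    """

    phases: tuple[tuple[int, float, float], ...] = ((20, 5.0, 1.0), (30, 1.0, 0.5))

    def __post_init__(self) -> None:
        for epochs, r0, r1 in self.phases:
            if epochs < 1:
                raise ValueError("each phase needs at least one epoch")
            if r0 < r1 or r1 < 0:
                raise ValueError("radii must satisfy start >= end >= 0")

    @property
    def epochs(self) -> int:
        return sum(e for e, _, _ in self.phases)

    def radii(self) -> np.ndarray:
        out = []
        for epochs, r0, r1 in self.phases:
            out.append(np.linspace(r0, r1, epochs))
        return np.concatenate(out)


@dataclass(frozen=True)
class SomErrors:
    quantization: float
    topographic: float
    combined: float


@dataclass(frozen=True)
class HitHistogram:
    """BMU hit counts per unit, broken down by class: (classes, units)."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def total_per_unit(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class LabeledSom:
    som: SomMap
    unit_labels: tuple[str, ...]
    provenance: tuple[str, ...]  # 'majority' or 'inherited' per unit


def init_som(
    rows: int,
    cols: int,
    dim: int,
    method: str = "principal-plane",
    data: np.ndarray | None = None,
    seed: int = 0,
) -> SomMap:
    """Initialize a rows x cols map of ``dim``-dimensional codebook vectors.

    ``principal-plane`` spans the plane of the data's first two principal
    components (deterministic given the data); ``random`` draws i.i.d.
    Gaussian vectors around the data mean (deterministic given the seed).
    """
    if rows < 1 or cols < 1:
        raise ValueError("map dimensions must be positive")
    n_units = rows * cols
    if method == "principal-plane":
        if data is None:
            raise ValueError("principal-plane initialization requires data")
        data = np.asarray(data, float)
        if data.shape[1] != dim:
            raise ValueError(f"data dim {data.shape[1]} != requested dim {dim}")
        mean = data.mean(axis=0)
        n_comp = min(2, data.shape[0], dim)
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(data)
        comps = pca.components_
        sds = np.sqrt(pca.explained_variance_)
        a = np.linspace(-2, 2, rows) if rows > 1 else np.zeros(1)
        b = np.linspace(-2, 2, cols) if cols > 1 else np.zeros(1)
        codebook = np.tile(mean, (n_units, 1))
        grid_a = np.repeat(a, cols)
        grid_b = np.tile(b, rows)
        codebook += np.outer(grid_a, sds[0] * comps[0])
        if n_comp > 1:
            codebook += np.outer(grid_b, sds[1] * comps[1])
    elif method == "random":
        rng = np.random.default_rng(seed)
        if data is not None:
            data = np.asarray(data, float)
            mean, sd = data.mean(axis=0), data.std(axis=0)
        else:
            mean, sd = np.zeros(dim), np.ones(dim)
        codebook = mean + sd * rng.standard_normal((n_units, dim))
    else:
        raise ValueError(f"unknown init method {method!r}")
    return SomMap(codebook=codebook, rows=rows, cols=cols, trained=False, seed=seed)


def _check_data(som: SomMap, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D array")
    if data.shape[1] != som.dim:
        raise ValueError(f"data dim {data.shape[1]} != codebook dim {som.dim}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    return data


def _bmu_pair(codebook: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second BMU index per sample; ties -> lowest unit index."""
    # squared Euclidean distances, (n, units)
    d2 = (
        np.einsum("ij,ij->i", data, data)[:, None]
        - 2.0 * data @ codebook.T
        + np.einsum("ij,ij->i", codebook, codebook)[None, :]
    )
    first = d2.argmin(axis=1)
    d2[np.arange(len(data)), first] = np.inf
    second = d2.argmin(axis=1)
    return first, second


def train_batch(
    som: SomMap, data: np.ndarray, schedule: TrainingSchedule | None = None
) -> SomMap:
    """Batch-train the map; deterministic given the initial codebook.

    Each epoch: find the BMU of every sample, then set every codebook vector
    to the Gaussian-neighborhood-weighted mean of the data (sigma = current
    radius).  A radius of (numerically) zero degenerates to plain centroid
    reassignment; units with no weight keep their previous vector.
    """
    schedule = schedule or TrainingSchedule()
    data = _check_data(som, data)
    codebook = som.codebook.copy()
    coords = som.unit_coords
    # pairwise squared lattice distances between units
    lat2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for radius in schedule.radii():
        first, _ = _bmu_pair(codebook, data)
        if radius < 1e-9:
            h = np.eye(som.n_units)
        else:
            h = np.exp(-lat2 / (2.0 * radius**2))
        w = h[:, first]  # (units, n)
        denom = w.sum(axis=1)
        num = w @ data
        nonzero = denom > 0
        codebook[nonzero] = num[nonzero] / denom[nonzero, None]
    return replace(som, codebook=codebook, trained=True)


def bmu(som: SomMap, x: np.ndarray) -> tuple[int, int]:
    """First and second best-matching unit of one sample."""
    x = np.asarray(x, float)
    if x.shape != (som.dim,):
        raise ValueError(f"expected a vector of length {som.dim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    first, second = _bmu_pair(som.codebook, x[None, :])
    return int(first[0]), int(second[0])


def _lattice_path_lengths(som: SomMap) -> np.ndarray:
    """All-pairs shortest codebook-space path along lattice-adjacent units."""
    rows_i, cols_j, weights = [], [], []
    for u in range(som.n_units):
        r, c = divmod(u, som.cols)
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if rr < som.rows and cc < som.cols:
                v = rr * som.cols + cc
                w = float(np.linalg.norm(som.codebook[u] - som.codebook[v]))
                rows_i += [u, v]
                cols_j += [v, u]
                weights += [w, w]
    graph = coo_matrix(
        (weights, (rows_i, cols_j)), shape=(som.n_units, som.n_units)
    )
    return dijkstra(graph, directed=False)


def map_errors(som: SomMap, data: np.ndarray) -> SomErrors:
    """Quantization, topographic and Kaski-Lagus combined error."""
    data = _check_data(som, data)
    first, second = _bmu_pair(som.codebook, data)
    dist_first = np.linalg.norm(data - som.codebook[first], axis=1)
    quantization = float(dist_first.mean())
    coords = som.unit_coords
    lat = np.abs(coords[first] - coords[second]).sum(axis=1)
    topographic = float((lat != 1).mean())
    if som.n_units == 1:
        # no second unit exists; the path term vanishes
        return SomErrors(quantization, 0.0, quantization)
    paths = _lattice_path_lengths(som)
    combined = float((dist_first + paths[first, second]).mean())
    return SomErrors(quantization, topographic, combined)


def hit_histogram(
    som: SomMap,
    data: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, ...] | None = None,
) -> HitHistogram:
    """Count BMU hits per unit, per class."""
    data = _check_data(som, data)
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels and data length mismatch")
    if classes is None:
        classes = tuple(sorted(set(labels.tolist())))
    first, _ = _bmu_pair(som.codebook, data)
    counts = np.zeros((len(classes), som.n_units), int)
    for k, cls in enumerate(classes):
        np.add.at(counts[k], first[labels == cls], 1)
    return HitHistogram(counts=counts, classes=tuple(classes))


def label_units(som: SomMap, hits: HitHistogram) -> LabeledSom:
    """Label each unit by the majority class of its training hits.

    Hitless units inherit the label of the nearest labeled unit (Euclidean
    lattice distance, ties broken by lowest unit index).  Majority ties break
    toward the lowest class index.
    """
    if hits.counts.sum() == 0:
        raise RuntimeError("cannot label a map with no training hits")
    totals = hits.total_per_unit
    labels: list[str | None] = [None] * som.n_units
    provenance = ["inherited"] * som.n_units
    for u in range(som.n_units):
        if totals[u] > 0:
            labels[u] = hits.classes[int(np.argmax(hits.counts[:, u]))]
            provenance[u] = "majority"
    coords = som.unit_coords
    labeled_idx = np.array([u for u in range(som.n_units) if labels[u] is not None])
    for u in range(som.n_units):
        if labels[u] is None:
            d = np.linalg.norm(coords[labeled_idx] - coords[u], axis=1)
            labels[u] = labels[int(labeled_idx[int(np.argmin(d))])]
    return LabeledSom(
        som=som, unit_labels=tuple(labels), provenance=tuple(provenance)
    )


def classify(labeled: LabeledSom, X: np.ndarray) -> np.ndarray:
    """BMU-label classification of each row of ``X``."""
    X = _check_data(labeled.som, np.atleast_2d(np.asarray(X, float)))
    first, _ = _bmu_pair(labeled.som.codebook, X)
    return np.array([labeled.unit_labels[u] for u in first])


def confusion(
    preds: np.ndarray, truth: np.ndarray, classes: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (rows = truth, cols = predicted) and accuracy."""
    preds = np.asarray(preds)
    truth = np.asarray(truth)
    if len(preds) != len(truth):
        raise ValueError("predictions and truth length mismatch")
    if classes is None:
        classes = tuple(sorted(set(truth.tolist()) | set(preds.tolist())))
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(truth, preds):
        mat.loc[t, p] += 1
    accuracy = float(np.trace(mat.to_numpy())) / len(truth)
    return mat, accuracy


@dataclass(frozen=True)
class PcaProjection:
    scores: np.ndarray
    components: np.ndarray  # (k, dim), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def project_pca(vectors: np.ndarray, k: int) -> PcaProjection:
    """Project vectors onto their first ``k`` principal components."""
    vectors = np.asarray(vectors, float)
    if k > vectors.shape[1]:
        raise ValueError(f"k={k} exceeds dimension {vectors.shape[1]}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(vectors)
    return PcaProjection(
        scores=scores,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )
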