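"""2D stimulus feature space: containers, embedding, grid mask, distances.

A stimulus set lives in a unit-square feature space. Coordinates either come
in directly (``method="none"``, min-max normalized) or are produced by a
pluggable dimensionality reducer (t-SNE / UMAP / PCA) applied to
high-dimensional feature vectors. All downstream statistics (density maps,
tuning regions, category distances) operate on the normalized 2D coordinates
and on a pixel grid covering the square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusSet",
    "FeatureSpace2D",
    "GridMask",
    "embed_features",
    "build_grid_mask",
    "normalized_category_distance",
    "full_feature_distance",
]

_CORNERS = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


@dataclass
class StimulusSet:
    """Stimuli with category labels, 2D coordinates, optional feature vectors.

    ``coords`` is an (n, 2) array in [0, 1]^2 once normalized; ``features`` is
    an optional (n, d) matrix of high-dimensional descriptors.
    """

    stimulus_id: np.ndarray
    category: np.ndarray
    coords: np.ndarray
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stimulus_id = np.asarray(self.stimulus_id)
        self.category = np.asarray(self.category)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.stimulus_id)
        if len(np.unique(self.stimulus_id)) != n:
            raise ValueError("stimulus ids must be unique")
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be (n, 2), got {self.coords.shape}")
        if len(self.category) != n:
            raise ValueError("category length mismatch")
        if any(str(c) == "" for c in self.category):
            raise ValueError("category labels must be non-empty")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != n:
                raise ValueError("features row count mismatch")

    def __len__(self) -> int:
        return len(self.stimulus_id)

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.category)

    def category_centroids(self) -> dict:
        """Mean 2D coordinate per category label."""
        return {
            c: self.coords[self.category == c].mean(axis=0)
            for c in self.categories
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": self.stimulus_id,
                "category": self.category,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, features: np.ndarray | None = None) -> "StimulusSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            stimulus_id=df["stimulus_id"].to_numpy(),
            category=df["category"].astype(str).to_numpy(),
            coords=df[["x", "y"]].to_numpy(float),
            features=features,
        )


@dataclass
class FeatureSpace2D:
    """A normalized unit-square feature space over a stimulus set.

    ``anchors`` holds the four corner pseudo-points when the space was
    corner-anchored; they take part in normalization only and are excluded
    from every downstream statistic (which iterates over ``stimuli``).
    """

    stimuli: StimulusSet
    reducer_method: str = "none"
    reducer_params: dict = field(default_factory=dict)
    corner_anchored: bool = False
    anchors: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = self.stimuli.coords
        if c.min() < -1e-9 or c.max() > 1 + 1e-9:
            raise ValueError("coordinates must lie in the unit square")

    @property
    def coords(self) -> np.ndarray:
        return self.stimuli.coords


def _minmax(coords: np.ndarray) -> np.ndarray:
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    return (coords - lo) / span


def _reduce(features: np.ndarray, method: str, params: dict, seed: int) -> np.ndarray:
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=seed, **params).fit_transform(features)
    if method == "tsne":
        from sklearn.manifold import TSNE

        kw = {"perplexity": 30.0, "init": "pca"}
        kw.update(params)
        return TSNE(n_components=2, random_state=seed, **kw).fit_transform(features)
    if method == "umap":
        from umap import UMAP

        return UMAP(n_components=2, random_state=seed, **params).fit_transform(features)
    raise ValueError(f"unknown reducer method: {method!r}")


def embed_features(
    stimuli: StimulusSet,
    method: str = "none",
    params: dict | None = None,
    seed: int = 0,
    *,
    corner_anchored: bool = False,
) -> FeatureSpace2D:
    """Build a unit-square feature space for a stimulus set.

    With ``method="none"`` the stimulus set's existing 2D coordinates are
    min-max normalized and nothing else happens (the identity on an already
    normalized set). Otherwise the high-dimensional ``features`` matrix is
    reduced to 2D by the named method and then normalized. With
    ``corner_anchored=True`` four pseudo-points at the bounding-box corners
    are carried through normalization (mapping to the corners of the unit
    square) and stored on the space, so that spaces built from different
    stimulus subsets share a common frame; they never enter statistics.
    """
    params = dict(params or {})
    if len(stimuli) < 1:
        raise ValueError("empty stimulus set")
    if method == "none":
        raw = stimuli.coords
    else:
        if stimuli.features is None:
            raise ValueError(f"method {method!r} requires feature vectors")
        if len(stimuli) < 3:
            raise ValueError("need >= 3 stimuli to embed")
        if not np.all(np.isfinite(stimuli.features)):
            raise ValueError("features must be finite")
        raw = _reduce(stimuli.features, method, params, seed)

    anchors = None
    if corner_anchored:
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        box = np.array([[lo[0], lo[1]], [lo[0], hi[1]], [hi[0], lo[1]], [hi[0], hi[1]]])
        norm = _minmax(np.vstack([raw, box]))
        coords, anchors = norm[: len(raw)], norm[len(raw):]
    else:
        coords = _minmax(raw)

    out = replace(stimuli, coords=coords)
    return FeatureSpace2D(
        stimuli=out,
        reducer_method=method,
        reducer_params=params,
        corner_anchored=corner_anchored,
        anchors=anchors,
    )


@dataclass
class GridMask:
    """Valid-pixel mask of the analysis grid.

    Pixel (i, j) covers [i/R, (i+1)/R) x [j/R, (j+1)/R) with center at
    ((i+0.5)/R, (j+0.5)/R); ``valid[i, j]`` is True where the pixel center
    lies within ``mask_radius_factor`` kernel SDs of at least one stimulus.
    """

    resolution: int
    valid: np.ndarray
    mask_radius_factor: float

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.resolution, self.resolution):
            raise ValueError("mask shape must be (resolution, resolution)")
        if not self.valid.any():
            raise ValueError("mask has no valid pixels")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def pixel_centers(resolution: int) -> np.ndarray:
    """(R*R, 2) array of pixel-center coordinates, x-major order."""
    g = (np.arange(resolution) + 0.5) / resolution
    xx, yy = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def coords_to_pixels(coords: np.ndarray, resolution: int) -> np.ndarray:
    """Map unit-square coordinates to (n, 2) integer pixel indices."""
    idx = np.floor(np.asarray(coords) * resolution).astype(int)
    return np.clip(idx, 0, resolution - 1)


def build_grid_mask(
    space: FeatureSpace2D,
    kernel_sd: float,
    mask_radius_factor: float = 2.0,
    resolution: int = 100,
) -> GridMask:
    """Mask off grid pixels far from every stimulus.

    Edge and corner pixels of the smoothed density map that contain no
    stimuli are prone to spurious significance, so a pixel is kept only if
    its center lies within ``mask_radius_factor * kernel_sd`` of at least
    one stimulus coordinate.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if mask_radius_factor <= 0:
        raise ValueError("mask_radius_factor must be positive")
    centers = pixel_centers(resolution)
    tree = cKDTree(space.coords)
    dmin, _ = tree.query(centers, k=1)
    valid = (dmin <= mask_radius_factor * kernel_sd).reshape(resolution, resolution)
    return GridMask(resolution=resolution, valid=valid,
                    mask_radius_factor=mask_radius_factor)


def normalized_category_distance(space: FeatureSpace2D, cat_a, cat_b) -> float:
    """Distance between two category centroids, normalized by the diagonal.

    The unit-square diagonal (sqrt(2)) is the maximum possible distance, so
    the result lies in [0, 1].
    """
    cents = space.stimuli.category_centroids()
    for c in (cat_a, cat_b):
        if c not in cents:
            raise KeyError(f"unknown category: {c!r}")
    return float(np.linalg.norm(cents[cat_a] - cents[cat_b]) / np.sqrt(2.0))


def full_feature_distance(
    stimuli: StimulusSet, selected_sets: dict
) -> pd.DataFrame:
    """Mean normalized high-D feature distance for S-S and S-NS category pairs.

    For each neuron (key of ``selected_sets``, value = its set of selected
    category labels) compute the mean pairwise Euclidean distance between
    category-mean feature vectors over all selected-selected pairs and over
    all selected-nonselected pairs, normalized by the maximum pairwise
    category-mean distance. Neurons with fewer than 2 selected categories are
    excluded (logged).
    """
    if stimuli.features is None:
        raise ValueError("full_feature_distance requires feature vectors")
    cats = list(stimuli.categories)
    means = np.stack([stimuli.features[stimuli.category == c].mean(axis=0)
                      for c in cats])
    dist = squareform(pdist(means))
    dmax = dist.max()
    if dmax > 0:
        dist = dist / dmax
    index = {c: i for i, c in enumerate(cats)}

    rows = []
    for neuron, selected in selected_sets.items():
        sel = [index[c] for c in selected if c in index]
        non = [i for i in range(len(cats)) if i not in sel]
        if len(sel) < 2 or not non:
            logger.info("neuron %s skipped: needs >=2 selected and >=1 "
                        "non-selected categories", neuron)
            continue
        ss = [dist[i, j] for a, i in enumerate(sel) for j in sel[a + 1:]]
        sns = [dist[i, j] for i in sel for j in non]
        rows.append({"neuron": neuron,
                     "s_s": float(np.mean(ss)),
                     "s_ns": float(np.mean(sns))})
    return pd.DataFrame(rows, columns=["neuron", "s_s", "s_ns"])
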