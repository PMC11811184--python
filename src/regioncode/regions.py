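"""Tuning-region detection on smoothed response maps.

The core procedure: a neuron's per-stimulus responses are smoothed into a
continuous density map over the unit-square feature space with an isotropic
2D Gaussian kernel; a per-pixel permutation null is built by shuffling the
responses across stimulus coordinates; significant pixels (inside an
edge/corner mask) are clustered by connectivity, and clusters below a minimum
size (a fraction of the masked pixel count) are discarded. A neuron with at
least one surviving cluster is a "feature neuron" and the surviving pixels
form its tuning region.

The kernel SD is ``sq`` times the unit-square side; the published per-dataset
scaling factors are available as :data:`SQ_PRESETS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .feature_space import (
    FeatureSpace2D,
    GridMask,
    build_grid_mask,
    coords_to_pixels,
    pixel_centers,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SQ_PRESETS",
    "RegionConfig",
    "DensityMap",
    "TuningRegion",
    "GaussianSmoother",
    "response_map",
    "detect_tuning_region",
    "stimuli_in_region",
    "region_overlap",
    "region_coverage",
]

# Published kernel scaling factors per feature space.
SQ_PRESETS = {
    "imagenet": 0.021,
    "coco": 0.05,
    "phased_recognition": 0.11,
    "continuous_recognition": 0.03,
}


@dataclass
class RegionConfig:
    """Parameters of the tuning-region detection procedure.

    sq : kernel scaling factor; kernel SD = sq x unit-square side.
    pixel_alpha : per-pixel permutation significance threshold.
    min_cluster_fraction : minimum cluster size as a fraction of masked pixels.
    connectivity : 4 or 8 pixel neighborhood for clustering.
    """

    resolution: int = 100
    sq: float = SQ_PRESETS["imagenet"]
    n_permutations: int = 1000
    pixel_alpha: float = 0.01
    min_cluster_fraction: float = 0.025
    connectivity: int = 4
    mask_radius_factor: float = 2.0
    cluster_correction: bool = False
    cluster_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pixel_alpha < 1.0):
            raise ValueError("pixel_alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0.0 <= self.min_cluster_fraction < 1.0):
            raise ValueError("min_cluster_fraction must be in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.sq <= 0:
            raise ValueError("sq must be positive")

    @property
    def kernel_sd(self) -> float:
        return self.sq


@dataclass
class DensityMap:
    """Observed smoothed density and per-pixel permutation p-values."""

    observed: np.ndarray
    p_values: np.ndarray | None
    mask: GridMask


@dataclass
class TuningRegion:
    """Set of significant grid pixels forming a neuron's tuning region.

    ``significant`` is an (R, R) boolean grid; ``clusters`` lists the
    surviving connected components as arrays of flat pixel indices
    (x-major, index = i * R + j).
    """

    resolution: int
    significant: np.ndarray
    clusters: list = field(default_factory=list)
    area_fraction: float = 0.0
    member_ids: np.ndarray | None = None
    covered_categories: np.ndarray | None = None
    density: DensityMap | None = None

    @property
    def is_empty(self) -> bool:
        return not bool(self.significant.any())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def pixel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.significant.ravel())


class GaussianSmoother:
    """Precomputed Gaussian kernel operator from stimuli to masked pixels.

    Holds the (n_masked_pixels, n_stimuli) kernel matrix so that maps for
    many neurons (and many permutations) on the same feature space are plain
    matrix products. Reuse one smoother per feature space.
    """

    def __init__(
        self,
        space: FeatureSpace2D,
        kernel_sd: float,
        mask: GridMask | None = None,
        resolution: int = 100,
        mask_radius_factor: float = 2.0,
    ):
        if kernel_sd <= 0:
            raise ValueError("kernel_sd must be positive")
        if mask is None:
            mask = build_grid_mask(space, kernel_sd, mask_radius_factor, resolution)
        self.space = space
        self.mask = mask
        self.kernel_sd = kernel_sd
        self.resolution = mask.resolution
        centers = pixel_centers(self.resolution)
        self._masked_flat = np.flatnonzero(mask.valid.ravel())
        diff = centers[self._masked_flat, None, :] - space.coords[None, :, :]
        d2 = np.einsum("pnk,pnk->pn", diff, diff)
        self.kernel = np.exp(-d2 / (2.0 * kernel_sd**2))

    def smooth(self, responses: np.ndarray) -> np.ndarray:
        """Masked-pixel density values for one response vector."""
        return self.kernel @ responses

    def full_map(self, responses: np.ndarray) -> np.ndarray:
        """(R, R) density map; pixels outside the mask are 0."""
        out = np.zeros(self.resolution * self.resolution)
        out[self._masked_flat] = self.smooth(responses)
        return out.reshape(self.resolution, self.resolution)


def response_map(
    space: FeatureSpace2D,
    responses,
    kernel_sd: float,
    resolution: int = 100,
    mask: GridMask | None = None,
    mask_radius_factor: float = 2.0,
) -> DensityMap:
    """Smooth per-stimulus responses into a continuous density map.

    observed(p) = sum_i r_i * exp(-||p - coord_i||^2 / (2 sd^2)); linear in
    the responses. Only observed values are filled; p-values require
    :func:`detect_tuning_region`.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(space.stimuli),):
        raise ValueError("need one finite response per stimulus")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    sm = GaussianSmoother(space, kernel_sd, mask, resolution, mask_radius_factor)
    return DensityMap(observed=sm.full_map(responses), p_values=None, mask=sm.mask)


def _cluster_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _null_cluster_size_threshold(null: np.ndarray, smoother: GaussianSmoother,
                                 config: RegionConfig) -> float:
    """Cluster-level correction: (1 - cluster_alpha) quantile of the null
    maximum cluster size.

    Each permutation map is thresholded at the per-pixel (1 - pixel_alpha)
    null quantile, its suprathreshold pixels are clustered with the same
    connectivity as the observed map, and the maximum cluster size is
    recorded; an observed cluster is retained only if larger than the
    resulting null quantile.
    """
    R = config.resolution
    thresh = np.quantile(null, 1.0 - config.pixel_alpha, axis=1)
    struct = _cluster_structure(config.connectivity)
    max_sizes = np.zeros(null.shape[1])
    grid = np.zeros(R * R, dtype=bool)
    for j in range(null.shape[1]):
        grid[:] = False
        grid[smoother._masked_flat] = null[:, j] > thresh
        labels, n_lab = ndimage.label(grid.reshape(R, R), structure=struct)
        if n_lab:
            max_sizes[j] = np.bincount(labels.ravel())[1:].max()
    return float(np.quantile(max_sizes, 1.0 - config.cluster_alpha))


def detect_tuning_region(
    space: FeatureSpace2D,
    responses,
    config: RegionConfig,
    smoother: GaussianSmoother | None = None,
    rng: np.random.Generator | None = None,
) -> TuningRegion:
    """Detect a neuron's significant tuning region by permutation testing.

    Responses are shuffled across stimulus coordinates ``n_permutations``
    times; each pixel's p-value is the add-one estimator
    (1 + #{null >= observed}) / (1 + n_permutations), so a permutation-
    invariant (e.g. constant) response map yields p = 1 everywhere. Pixels
    with p < pixel_alpha inside the mask are clustered; clusters smaller
    than ``min_cluster_fraction`` of the masked pixel count are discarded.
    An empty region (no surviving cluster) means the neuron is not a feature
    neuron.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(space.stimuli),):
        raise ValueError("need one response per stimulus")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    if np.ptp(responses) == 0:
        logger.info("constant responses: empty tuning region by the tie rule")
    if smoother is None:
        smoother = GaussianSmoother(
            space, config.kernel_sd, None, config.resolution,
            config.mask_radius_factor,
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    observed = smoother.smooth(responses)
    # a null map equal to the observed one up to summation-order rounding
    # must count as a tie, so compare with a tiny relative tolerance
    obs_cut = (observed - 1e-9 * np.abs(observed))[:, None]
    n_ge = np.zeros(observed.shape, dtype=np.int64)
    null_store = [] if config.cluster_correction else None
    chunk = max(1, min(128, config.n_permutations))
    done = 0
    while done < config.n_permutations:
        b = min(chunk, config.n_permutations - done)
        perms = np.stack([rng.permutation(responses) for _ in range(b)], axis=1)
        null = smoother.kernel @ perms  # (n_masked, b)
        n_ge += (null >= obs_cut).sum(axis=1)
        if null_store is not None:
            null_store.append(null)
        done += b
    p_masked = (1.0 + n_ge) / (1.0 + config.n_permutations)

    R = config.resolution
    p_grid = np.ones((R, R))
    p_grid.ravel()[smoother._masked_flat] = p_masked
    density = DensityMap(
        observed=smoother.full_map(responses), p_values=p_grid, mask=smoother.mask
    )

    sig = (p_grid < config.pixel_alpha) & smoother.mask.valid
    labels, n_lab = ndimage.label(sig, structure=_cluster_structure(config.connectivity))
    min_size = config.min_cluster_fraction * smoother.mask.n_valid
    if null_store is not None:
        min_size = max(min_size, _null_cluster_size_threshold(
            np.concatenate(null_store, axis=1), smoother, config))
    clusters = []
    keep = np.zeros_like(sig)
    for lab in range(1, n_lab + 1):
        member = labels == lab
        if member.sum() > min_size:
            clusters.append(np.flatnonzero(member.ravel()))
            keep |= member

    region = TuningRegion(
        resolution=R,
        significant=keep,
        clusters=clusters,
        area_fraction=float(keep.sum() / smoother.mask.n_valid),
        density=density,
    )
    if not region.is_empty:
        in_ids, _ = stimuli_in_region(region, space)
        region.member_ids = in_ids
        member = np.isin(space.stimuli.stimulus_id, in_ids)
        region.covered_categories = np.unique(space.stimuli.category[member])
    else:
        region.member_ids = np.array([], dtype=space.stimuli.stimulus_id.dtype)
        region.covered_categories = np.array([], dtype=space.stimuli.category.dtype)
    return region


def stimuli_in_region(region: TuningRegion, space: FeatureSpace2D):
    """Partition stimulus ids by whether their pixel is significant."""
    px = coords_to_pixels(space.coords, region.resolution)
    inside = region.significant[px[:, 0], px[:, 1]]
    ids = space.stimuli.stimulus_id
    return ids[inside], ids[~inside]


def region_overlap(a: TuningRegion, b: TuningRegion) -> float:
    """|A n B| / min(|A|, |B|); 0 when either region is empty."""
    if a.resolution != b.resolution:
        raise ValueError("regions are on different grids")
    na, nb = a.significant.sum(), b.significant.sum()
    if na == 0 or nb == 0:
        return 0.0
    inter = (a.significant & b.significant).sum()
    return float(inter / min(na, nb))


def region_coverage(regions, mask: GridMask) -> float:
    """Fraction of masked pixels covered by the union of the regions."""
    union = np.zeros_like(mask.valid)
    for r in regions:
        if r.resolution != mask.resolution:
            raise ValueError("region grid does not match mask")
        union |= r.significant
    return float((union & mask.valid).sum() / mask.n_valid)
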