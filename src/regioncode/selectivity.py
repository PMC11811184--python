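"""Category selectivity and axis-coding analysis.

Classifies neurons as single-category (SC), multi-category (MC; split into
feature-MC when the selected categories cluster inside one connected piece of
the neuron's significant-pixel map, else non-feature-MC), quantifies
selectivity (d-prime between the most- and least-preferred categories, depth
of selectivity, response-ratio curve), and tests axis coding with a
cross-validated partial-least-squares model against a label-shuffled null.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats as sps
from sklearn.cross_decomposition import PLSRegression

from .feature_space import FeatureSpace2D, coords_to_pixels
from .regions import GaussianSmoother, RegionConfig, detect_tuning_region

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisWindows",
    "SelectivityProfile",
    "AxisModel",
    "trial_firing_rate",
    "classify_selectivity",
    "selectivity_dprime",
    "depth_of_selectivity",
    "response_ratio_curve",
    "fit_axis_model",
]


@dataclass(frozen=True)
class AnalysisWindows:
    """Standard analysis windows (seconds relative to onset) and rate floor."""

    response: tuple = (0.25, 1.25)
    baseline: tuple = (-0.5, 0.0)
    fixation: tuple = (0.0, 0.3)
    rate_floor_hz: float = 0.15

    def __post_init__(self) -> None:
        for w in (self.response, self.baseline, self.fixation):
            if w[1] <= w[0]:
                raise ValueError("windows must have positive length")
        if self.rate_floor_hz < 0:
            raise ValueError("rate floor must be non-negative")


def trial_firing_rate(spike_times, window) -> float:
    """Spike count in the half-open window [t0, t1) divided by its length (Hz)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    s = np.asarray(spike_times, dtype=float)
    return float(np.count_nonzero((s >= t0) & (s < t1)) / (t1 - t0))


@dataclass
class SelectivityProfile:
    """Category-selectivity classification of one neuron."""

    anova_p: float
    selected_categories: tuple
    neuron_class: str  # SC | feature-MC | MC | non-feature-MC | none
    dprime: float | None = None
    dos: float | None = None
    response_ratio: np.ndarray | None = None

    @property
    def is_selective(self) -> bool:
        return self.neuron_class != "none"


def selectivity_dprime(rates_by_category: dict) -> float:
    """d-prime between the most- and least-preferred categories.

    (mu_best - mu_least) / sqrt((var_best + var_least) / 2) with per-category
    means and population variances across exemplars. NaN when both variances
    vanish.
    """
    if len(rates_by_category) < 2:
        raise ValueError("need at least 2 categories")
    means = {c: np.mean(r) for c, r in rates_by_category.items()}
    best = max(means, key=means.get)
    least = min(means, key=means.get)
    for c in (best, least):
        if len(np.atleast_1d(rates_by_category[c])) < 2:
            raise ValueError("best/least categories need >= 2 exemplars")
    vb = np.var(rates_by_category[best])
    vl = np.var(rates_by_category[least])
    denom = math.sqrt(0.5 * (vb + vl))
    if denom == 0:
        logger.info("zero variance in both extreme categories: d' undefined")
        return math.nan
    return float((means[best] - means[least]) / denom)


def depth_of_selectivity(mean_rates) -> float:
    """DOS = (n - sum(r_j)/r_max) / (n - 1); 0 = equal response, 1 = one-hot."""
    r = np.asarray(mean_rates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 categories")
    rmax = r.max()
    if rmax <= 0:
        logger.info("all rates zero: DOS undefined")
        return math.nan
    return float((r.size - r.sum() / rmax) / (r.size - 1))


def response_ratio_curve(mean_rates) -> np.ndarray:
    """Rates sorted most- to least-preferred, normalized by the maximum."""
    r = np.sort(np.asarray(mean_rates, dtype=float))[::-1]
    if r.size == 0 or r[0] <= 0:
        raise ValueError("maximum rate must be positive")
    return r / r[0]


def _selected_categories(
    response_rates: np.ndarray,
    baseline_rates: np.ndarray,
    trial_categories: np.ndarray,
    threshold_sd: float = 1.5,
):
    """Categories whose mean response clears baseline mean + threshold_sd * SD."""
    mu_b = baseline_rates.mean()
    sd_b = baseline_rates.std(ddof=1) if len(baseline_rates) > 1 else 0.0
    if sd_b == 0 and mu_b == 0:
        logger.info("degenerate zero baseline: selecting categories with "
                    "positive mean response")
        cut = 0.0
        strict = True
    else:
        cut = mu_b + threshold_sd * sd_b
        strict = False
    selected = []
    for c in np.unique(trial_categories):
        m = response_rates[trial_categories == c].mean()
        if (m > cut) if strict else (m >= cut):
            selected.append(c)
    return tuple(selected)


def classify_selectivity(
    response_rates,
    baseline_rates,
    trial_categories,
    space: FeatureSpace2D | None = None,
    region_config: RegionConfig | None = None,
    smoother: GaussianSmoother | None = None,
    stimulus_rates=None,
    alpha: float = 0.05,
    threshold_sd: float = 1.5,
) -> SelectivityProfile:
    """Classify a neuron's category selectivity.

    A one-way ANOVA across categories on response-window rates must reach
    ``alpha``, and a category counts as selected when its mean response is at
    least ``threshold_sd`` baseline SDs above the mean baseline rate (both
    computed over all trials). One selected category makes an SC neuron;
    several make an MC neuron, subtyped by whether all selected-category
    centroids fall inside one connected component of the neuron's
    significant-pixel map computed WITHOUT the minimum-cluster-size
    threshold (feature-MC) or not (non-feature-MC). Without a feature space
    the subtype is left as plain "MC".

    ``stimulus_rates`` optionally supplies per-stimulus responses (ordered as
    ``space.stimuli``) for the subtype map; otherwise category means are
    spread over each category's stimuli.
    """
    response_rates = np.asarray(response_rates, dtype=float)
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    trial_categories = np.asarray(trial_categories)
    cats = np.unique(trial_categories)
    if len(cats) < 2:
        raise ValueError("need >= 2 categories")

    groups = [response_rates[trial_categories == c] for c in cats]
    if np.ptp(response_rates) == 0:
        anova_p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p = float(sps.f_oneway(*groups).pvalue)
        if math.isnan(anova_p):
            anova_p = 1.0

    selected = ()
    if anova_p < alpha:
        selected = _selected_categories(
            response_rates, baseline_rates, trial_categories, threshold_sd
        )

    if not selected:
        cls = "none"
    elif len(selected) == 1:
        cls = "SC"
    elif space is None or region_config is None:
        cls = "MC"
    else:
        cls = _mc_subtype(response_rates, trial_categories, selected,
                          space, region_config, smoother, stimulus_rates)

    mean_by_cat = np.array([g.mean() for g in groups])
    dp = None
    if all(len(g) >= 2 for g in groups):
        dp = selectivity_dprime({c: g for c, g in zip(cats, groups)})
    dos = depth_of_selectivity(mean_by_cat) if mean_by_cat.max() > 0 else math.nan
    rr = response_ratio_curve(mean_by_cat) if mean_by_cat.max() > 0 else None
    return SelectivityProfile(
        anova_p=anova_p,
        selected_categories=selected,
        neuron_class=cls,
        dprime=dp,
        dos=dos,
        response_ratio=rr,
    )


def _mc_subtype(response_rates, trial_categories, selected, space,
                region_config, smoother, stimulus_rates=None) -> str:
    """feature-MC iff all selected-category centroids share one connected
    component of the unclustered significant-pixel map."""
    if stimulus_rates is not None:
        per_stim = np.asarray(stimulus_rates, dtype=float)
    else:
        per_stim = np.empty(len(space.stimuli))
        stim_cat = space.stimuli.category
        for c in np.unique(stim_cat):
            per_stim[stim_cat == c] = response_rates[trial_categories == c].mean()
    cfg = replace(region_config, min_cluster_fraction=0.0)
    region = detect_tuning_region(space, per_stim, cfg, smoother=smoother)
    if region.is_empty:
        return "non-feature-MC"
    struct = ndimage.generate_binary_structure(2, 1 if cfg.connectivity == 4 else 2)
    labels, _ = ndimage.label(region.significant, structure=struct)
    cents = space.stimuli.category_centroids()
    px = coords_to_pixels(np.array([cents[c] for c in selected]), cfg.resolution)
    comp = labels[px[:, 0], px[:, 1]]
    if np.all(comp > 0) and len(np.unique(comp)) == 1:
        return "feature-MC"
    return "non-feature-MC"


@dataclass
class AxisModel:
    """Cross-validated PLS axis-coding model with a permutation null."""

    observed_r: float
    null_r: np.ndarray
    n_components: int
    split_fraction: float = 0.5
    n_permutations: int = 1000
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(
            self.observed_r > np.percentile(self.null_r, 95.0)
        )


def _pls_split_r(features, responses, n_components, rng) -> float:
    n = len(responses)
    perm = rng.permutation(n)
    half = n // 2
    tr, te = perm[:half], perm[half:]
    k = min(n_components, len(tr) - 1, features.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=k, scale=False)
        model.fit(features[tr], responses[tr])
        pred = model.predict(features[te]).ravel()
    if np.std(pred) == 0 or np.std(responses[te]) == 0:
        return 0.0
    return float(np.corrcoef(pred, responses[te])[0, 1])


def fit_axis_model(
    features,
    responses,
    n_components: int = 10,
    n_permutations: int = 1000,
    split_fraction: float = 0.5,
    n_splits: int = 1,
    seed: int = 0,
) -> AxisModel:
    """Test whether responses follow a linear axis in feature space.

    A PLS regression (default 10 components) is fit on a random 50% of the
    stimuli and evaluated as the Pearson correlation between predicted and
    actual responses on the held-out 50%; the observed correlation
    (optionally averaged over ``n_splits`` random splits) is compared with a
    null distribution from ``n_permutations`` label-shuffled refits. The
    model is significant when the observed correlation exceeds the null's
    95th percentile.
    """
    features = np.asarray(features, dtype=float)
    responses = np.asarray(responses, dtype=float).ravel()
    n = len(responses)
    if features.shape[0] != n:
        raise ValueError("features/responses length mismatch")
    if n <= 2 * n_components:
        raise ValueError("need more than 2 * n_components stimuli")
    k = min(n_components, features.shape[1], n // 2 - 1)
    if k < n_components:
        logger.warning("reducing PLS components from %d to %d", n_components, k)
    rng = np.random.default_rng(seed)

    obs = np.mean(
        [_pls_split_r(features, responses, k, rng) for _ in range(n_splits)]
    )
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _pls_split_r(features, rng.permutation(responses), k, rng)
    return AxisModel(
        observed_r=float(obs),
        null_r=null,
        n_components=k,
        split_fraction=split_fraction,
        n_permutations=n_permutations,
    )
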