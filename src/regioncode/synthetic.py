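"""Synthetic stimulus sets, neurons, and memory sessions with ground truth.

The generator emulates the structure of the recordings the analysis is built
for: ~50 object categories x 10 exemplars clustered in a 2D feature space,
baseline-Poisson neurons with planted Gaussian tuning regions, linear axis
tuning, or single/multi-category selectivity, and learning/recognition
sessions with 1-6 confidence responses whose hit probability follows a
logistic model in image memorability and in-region status. Every output is
fully determined by the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_space import StimulusSet

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "NeuronRecording",
    "GazeTrace",
    "generate_stimulus_set",
    "generate_neuron",
    "generate_memory_session",
    "generate_gaze_trace",
]


@dataclass
class SyntheticConfig:
    """Stated world of the simulations.

    Defaults mirror the recorded setting being emulated: 50 categories x 10
    exemplars, tight category clusters in the unit square, 5 Hz baseline
    Poisson firing with a 20 Hz tuning gain, 1 s stimulus presentations shown
    once each, and a logistic recognition-memory model on a 1-6 confidence
    scale.
    """

    n_categories: int = 50
    n_per_category: int = 10
    cluster_spread: float = 0.03
    n_feature_dims: int = 128
    baseline_rate: float = 5.0
    region_gain: float = 20.0
    region_center: tuple = (0.5, 0.5)
    region_width: float = 0.08
    axis_weights: np.ndarray | None = None
    trial_duration: float = 1.0
    n_trials_per_stimulus: int = 1
    pre_onset: float = 0.5
    response_latency: float = 0.25
    memory_beta0: float = 1.0
    memory_beta_mem: float = 0.0
    memory_beta_region: float = 0.0
    confidence_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.n_per_category < 1:
            raise ValueError("category counts must be positive")
        if self.cluster_spread <= 0:
            raise ValueError("cluster_spread must be positive")
        if self.baseline_rate < 0 or self.region_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


@dataclass
class GroundTruth:
    """Planted structure of one synthetic neuron plus per-stimulus truth.

    ``kind`` is exactly one of null / region / axis / single-category /
    multi-category. Per-stimulus arrays (memorability, in_region) are filled
    by the generators once a stimulus set exists.
    """

    kind: str = "null"
    region_center: tuple | None = None
    region_width: float | None = None
    axis_weights: np.ndarray | None = None
    selected_categories: tuple = ()
    memorability: np.ndarray | None = None
    in_region: np.ndarray | None = None

    _KINDS = ("null", "region", "axis", "single-category", "multi-category")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown neuron kind: {self.kind!r}")
        if self.memorability is not None:
            m = np.asarray(self.memorability, float)
            if np.any((m < 0) | (m > 1)):
                raise ValueError("memorability must lie in [0, 1]")

    @classmethod
    def null(cls) -> "GroundTruth":
        return cls(kind="null")

    @classmethod
    def region(cls, center=(0.5, 0.5), width=0.08) -> "GroundTruth":
        return cls(kind="region", region_center=tuple(center), region_width=width)

    @classmethod
    def axis(cls, weights) -> "GroundTruth":
        return cls(kind="axis", axis_weights=np.asarray(weights, float))

    @classmethod
    def category(cls, selected) -> "GroundTruth":
        selected = tuple(np.atleast_1d(selected).tolist())
        kind = "single-category" if len(selected) == 1 else "multi-category"
        return cls(kind=kind, selected_categories=selected)


@dataclass
class NeuronRecording:
    """Spike trains of one neuron across trials, aligned to stimulus onset.

    Spikes span [-pre_onset, response_latency + trial_duration + pre_onset)
    seconds relative to onset. ``trial_stimulus`` gives the stimulus id shown
    on each trial.
    """

    neuron_id: str
    spike_times: list
    trial_stimulus: np.ndarray
    t_start: float
    t_stop: float
    truth: GroundTruth | None = None

    def rates(self, window: tuple) -> np.ndarray:
        """Per-trial firing rate (Hz) in the half-open window [t0, t1)."""
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window must have positive length")
        return np.array(
            [np.count_nonzero((s >= t0) & (s < t1)) / (t1 - t0)
             for s in self.spike_times]
        )

    def stimulus_rates(self, window: tuple, stimuli: StimulusSet) -> np.ndarray:
        """Mean rate per stimulus (ordered as in ``stimuli``)."""
        r = self.rates(window)
        out = np.empty(len(stimuli))
        for i, sid in enumerate(stimuli.stimulus_id):
            m = self.trial_stimulus == sid
            if not m.any():
                raise ValueError(f"no trials for stimulus {sid!r}")
            out[i] = r[m].mean()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"neuron_id": self.neuron_id, "trial_id": t, "spike_time_s": ts}
            for t, s in enumerate(self.spike_times)
            for ts in s
        ]
        return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_time_s"])


def generate_stimulus_set(config: SyntheticConfig) -> StimulusSet:
    """Draw a clustered stimulus set in the unit square.

    Category centroids are uniform in the interior of the square; exemplars
    are isotropic Gaussian around their centroid with SD ``cluster_spread``;
    coordinates are then min-max normalized into [0, 1]^2. High-dimensional
    feature vectors embed the 2D coordinates in the first two directions of a
    seeded random rotation, so a linear 2D projection of the features matches
    the coordinates up to rotation.
    """
    n = config.n_categories * config.n_per_category
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    rng = config.rng(stream=1)
    centroids = rng.uniform(0.1, 0.9, size=(config.n_categories, 2))
    coords = np.repeat(centroids, config.n_per_category, axis=0)
    coords = coords + rng.normal(0.0, config.cluster_spread, size=(n, 2))
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    coords = (coords - lo) / np.where(hi - lo > 0, hi - lo, 1.0)

    d = config.n_feature_dims
    feats = np.zeros((n, d))
    feats[:, :2] = coords - 0.5
    feats[:, 2:] = rng.normal(0.0, 0.02, size=(n, d - 2))
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    feats = feats @ q.T

    categories = np.repeat(
        [f"cat{c:03d}" for c in range(config.n_categories)], config.n_per_category
    )
    ids = np.array([f"stim{i:04d}" for i in range(n)])
    return StimulusSet(stimulus_id=ids, category=categories, coords=coords,
                       features=feats)


def _stimulus_rates(truth: GroundTruth, stimuli: StimulusSet,
                    config: SyntheticConfig) -> np.ndarray:
    """Deterministic per-stimulus firing rate (Hz) implied by the ground truth."""
    base = np.full(len(stimuli), config.baseline_rate)
    if truth.kind == "null":
        return base
    if truth.kind == "region":
        center = np.asarray(truth.region_center or config.region_center)
        width = truth.region_width or config.region_width
        d2 = ((stimuli.coords - center) ** 2).sum(axis=1)
        return base + config.region_gain * np.exp(-d2 / (2.0 * width**2))
    if truth.kind == "axis":
        if stimuli.features is None:
            raise ValueError("axis neuron requires stimulus features")
        proj = stimuli.features @ truth.axis_weights
        z = (proj - proj.mean()) / (proj.std() if proj.std() > 0 else 1.0)
        rate = base + config.region_gain * z
        if np.any(rate < 0):
            logger.info("axis neuron: %d negative rates clipped to 0",
                        int((rate < 0).sum()))
        return np.clip(rate, 0.0, None)
    # category-selective kinds
    boost = np.isin(stimuli.category, truth.selected_categories)
    return base + config.region_gain * boost


def generate_neuron(
    truth: GroundTruth,
    stimuli: StimulusSet,
    config: SyntheticConfig,
    neuron_id: str = "n0",
    rng: np.random.Generator | None = None,
) -> NeuronRecording:
    """Simulate Poisson spike trains for one neuron over the stimulus set.

    Firing is piecewise-homogeneous Poisson: baseline rate outside the
    response epoch and the truth-implied stimulus rate during
    [response_latency, response_latency + trial_duration) after onset. Each
    stimulus is shown ``n_trials_per_stimulus`` times.
    """
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    if rng is None:
        rng = config.rng(stream=2)
    rate_per_stim = _stimulus_rates(truth, stimuli, config)

    t_start = -config.pre_onset
    resp0 = config.response_latency
    resp1 = config.response_latency + config.trial_duration
    t_stop = resp1 + config.pre_onset

    order = np.repeat(np.arange(len(stimuli)), config.n_trials_per_stimulus)
    rng.shuffle(order)
    spikes, trial_stim = [], []
    for idx in order:
        parts = []
        for a, b, rate in ((t_start, resp0, config.baseline_rate),
                           (resp0, resp1, rate_per_stim[idx]),
                           (resp1, t_stop, config.baseline_rate)):
            k = rng.poisson(rate * (b - a))
            parts.append(rng.uniform(a, b, size=k))
        spikes.append(np.sort(np.concatenate(parts)))
        trial_stim.append(stimuli.stimulus_id[idx])
    truth = replace(truth, in_region=_true_in_region(truth, stimuli))
    return NeuronRecording(
        neuron_id=neuron_id,
        spike_times=spikes,
        trial_stimulus=np.array(trial_stim),
        t_start=t_start,
        t_stop=t_stop,
        truth=truth,
    )


def _true_in_region(truth: GroundTruth, stimuli: StimulusSet) -> np.ndarray | None:
    """Planted in-region flags: within 2 tuning widths of the planted center."""
    if truth.kind != "region":
        return None
    center = np.asarray(truth.region_center)
    d = np.linalg.norm(stimuli.coords - center, axis=1)
    return d <= 2.0 * truth.region_width


def draw_memorability(stimuli: StimulusSet, rng: np.random.Generator,
                      a: float = 4.0, b: float = 4.0) -> np.ndarray:
    """Per-stimulus memorability scores, Beta(4,4) by default (unimodal on [0,1])."""
    return rng.beta(a, b, size=len(stimuli))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_memory_session(
    stimuli: StimulusSet,
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one learning + recognition session as a trial table.

    The first half of the (shuffled) stimulus set is learned, each stimulus
    shown once; recognition mixes the learned ("old") stimuli with the other
    half ("new"). For an old stimulus the probability of an "old" judgment
    (response >= 4) is logistic(beta0 + beta_mem * memorability +
    beta_region * in_region); for a new stimulus the false-alarm probability
    is logistic(-beta0). Confidence within the chosen side tracks the model
    probability with Gaussian noise; RTs are shifted lognormal.

    Columns: trial_id, stimulus_id, phase, old_flag, response, rt_s, onset_s.
    ``truth`` must carry per-stimulus memorability (and in_region flags for
    region neurons); missing memorability is drawn Beta(4,4) from the config
    seed.
    """
    if rng is None:
        rng = config.rng(stream=3)
    n = len(stimuli)
    if n < 2:
        raise ValueError("need at least 2 stimuli for a session")
    mem = truth.memorability
    if mem is None:
        mem = draw_memorability(stimuli, rng)
    in_region = truth.in_region
    if in_region is None:
        in_region = _true_in_region(truth, stimuli)
    if in_region is None:
        in_region = np.zeros(n, dtype=bool)

    perm = rng.permutation(n)
    learn_idx = perm[: n // 2]
    new_idx = perm[n // 2:]
    if len(learn_idx) == 0:
        raise ValueError("empty learning set")

    rows = []
    onset = 0.0

    def rt():
        return 0.3 + rng.lognormal(mean=np.log(0.5), sigma=0.4)

    for t, idx in enumerate(rng.permutation(learn_idx)):
        rows.append(dict(trial_id=t, stimulus_id=stimuli.stimulus_id[idx],
                         phase="learning", old_flag=pd.NA, response=pd.NA,
                         rt_s=rt(), onset_s=onset))
        onset += config.trial_duration + rng.uniform(0.5, 0.75)

    recog = np.concatenate([learn_idx, new_idx])
    is_old = np.concatenate(
        [np.ones(len(learn_idx), bool), np.zeros(len(new_idx), bool)]
    )
    shuffle = rng.permutation(len(recog))
    recog, is_old = recog[shuffle], is_old[shuffle]
    t0 = len(rows)
    for t, (idx, old) in enumerate(zip(recog, is_old)):
        if old:
            logit = (config.memory_beta0
                     + config.memory_beta_mem * mem[idx]
                     + config.memory_beta_region * float(in_region[idx]))
        else:
            logit = -config.memory_beta0
        p_old = _sigmoid(logit)
        says_old = rng.random() < p_old
        center = 4.5 + 2.0 * (p_old - 0.5) if says_old else 2.5 - 2.0 * (p_old - 0.5)
        raw = center + config.confidence_noise * rng.normal()
        response = int(np.clip(np.rint(raw), 4, 6)) if says_old \
            else int(np.clip(np.rint(raw), 1, 3))
        rows.append(dict(trial_id=t0 + t, stimulus_id=stimuli.stimulus_id[idx],
                         phase="recognition", old_flag=bool(old),
                         response=response, rt_s=rt(), onset_s=onset))
        onset += config.trial_duration + rng.uniform(0.5, 0.75)

    return pd.DataFrame(rows)


@dataclass
class GazeTrace:
    """Synthetic gaze samples with planted saccade/fixation intervals."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    planted_saccades: list = field(default_factory=list)
    planted_fixations: list = field(default_factory=list)


def generate_gaze_trace(
    scene_objects,
    durations,
    config: SyntheticConfig | None = None,
    sample_rate: float = 500.0,
    saccade_duration: float = 0.010,
    jitter_deg: float = 0.02,
    rng: np.random.Generator | None = None,
) -> GazeTrace:
    """Piecewise-stationary gaze over object centers with ballistic jumps.

    ``scene_objects`` is a sequence of (x, y) object centers in degrees;
    ``durations`` the fixation dwell time on each (seconds). Consecutive
    fixations are joined by a linear ballistic saccade of
    ``saccade_duration`` seconds. Returns the sampled trace together with
    the planted saccade and fixation intervals.
    """
    if rng is None:
        rng = (config.rng(stream=4) if config is not None
               else np.random.default_rng(0))
    centers = np.asarray(scene_objects, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("need at least one object region")
    if len(durations) != len(centers):
        raise ValueError("one duration per object")
    if np.any(durations <= 0):
        raise ValueError("zero-duration segment")

    dt = 1.0 / sample_rate
    ts, xs, ys = [], [], []
    saccades, fixations = [], []
    t = 0.0
    for i, (c, dur) in enumerate(zip(centers, durations)):
        n = max(2, int(round(dur * sample_rate)))
        seg_t = t + np.arange(n) * dt
        ts.append(seg_t)
        xs.append(c[0] + rng.normal(0, jitter_deg, n))
        ys.append(c[1] + rng.normal(0, jitter_deg, n))
        fixations.append((t, seg_t[-1] + dt))
        t = seg_t[-1] + dt
        if i + 1 < len(centers):
            m = max(2, int(round(saccade_duration * sample_rate)))
            frac = np.linspace(0, 1, m, endpoint=False) + 1.0 / m
            sac_t = t + np.arange(m) * dt
            ts.append(sac_t)
            xs.append(c[0] + frac * (centers[i + 1][0] - c[0]))
            ys.append(c[1] + frac * (centers[i + 1][1] - c[1]))
            saccades.append((t, sac_t[-1] + dt))
            t = sac_t[-1] + dt
    return GazeTrace(
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        sample_rate=sample_rate,
        planted_saccades=saccades,
        planted_fixations=fixations,
    )
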