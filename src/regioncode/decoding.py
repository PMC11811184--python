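"""Pseudo-population decoding of object category.

Neurons recorded in separate sessions are pooled into a pseudo-population
(trial x neuron x time-bin rate tensor). A maximum-correlation-coefficient
classifier (MCC) is trained and tested per sliding time bin under repeated
stratified k-fold cross-validation; per-bin significance against chance is
the fraction of repeats with accuracy below chance, FDR-corrected across
bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingConfig",
    "PseudoPopulation",
    "DecodingResult",
    "mcc_classify",
    "sliding_decoding",
    "compare_decoding",
    "subsample_neurons",
]


@dataclass
class DecodingConfig:
    """Sliding-bin decoding parameters (times in seconds relative to onset)."""

    bin_width: float = 0.5
    step: float = 0.05
    first_bin_start: float = -0.5
    n_bins: int = 31
    folds: int = 8
    repeats: int = 50
    alpha: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def bin_starts(self) -> np.ndarray:
        return self.first_bin_start + self.step * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0


@dataclass
class PseudoPopulation:
    """Trial x neuron x bin firing-rate tensor with a label per trial."""

    rates: np.ndarray
    labels: np.ndarray
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (trials, neurons, bins)")
        if len(self.labels) != self.rates.shape[0]:
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("missing bins in rate tensor")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    @classmethod
    def from_recordings(cls, recordings, labels, config: DecodingConfig
                        ) -> "PseudoPopulation":
        """Bin spike trains of same-trial-structure recordings into a tensor.

        All recordings must share the trial sequence; ``labels`` gives the
        category of each trial.
        """
        n_trials = len(labels)
        starts = config.bin_starts
        tensor = np.empty((n_trials, len(recordings), config.n_bins))
        for j, rec in enumerate(recordings):
            if len(rec.spike_times) != n_trials:
                raise ValueError("recordings must share the trial structure")
            for t, spikes in enumerate(rec.spike_times):
                s = np.asarray(spikes)
                for b, t0 in enumerate(starts):
                    tensor[t, j, b] = (
                        np.count_nonzero((s >= t0) & (s < t0 + config.bin_width))
                        / config.bin_width
                    )
        return cls(rates=tensor, labels=np.asarray(labels),
                   bin_centers=config.bin_centers)


def mcc_classify(train_X, train_y, test_X) -> np.ndarray:
    """Maximum-correlation-coefficient classification.

    A mean template over training trials is computed per class; each test
    trial is assigned the class whose template has the highest Pearson
    correlation with the test vector. Ties (and undefined correlations from
    zero-variance vectors) resolve to the lowest class index, logged.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    templates = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])

    def _center_norm(M):
        M = M - M.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(M, axis=1, keepdims=True)
        bad = norm.ravel() == 0
        norm[norm == 0] = 1.0
        return M / norm, bad

    T, t_bad = _center_norm(templates)
    X, x_bad = _center_norm(test_X)
    corr = X @ T.T
    if t_bad.any() and not t_bad.all():
        corr[:, t_bad] = -np.inf
    if x_bad.any():
        logger.info("%d zero-variance test vectors: tie rule applied",
                    int(x_bad.sum()))
        corr[x_bad] = 0.0
    # argmax takes the first (lowest-index) class on ties
    return classes[np.argmax(corr, axis=1)]


def _stratified_folds(labels, folds, rng):
    """Lists of trial indices per fold, with class-balanced assignment."""
    assign = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        assign[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


@dataclass
class DecodingResult:
    """Accuracy time course with repeat distribution and significance mask."""

    bin_centers: np.ndarray
    mean_accuracy: np.ndarray
    repeat_accuracies: np.ndarray  # (repeats, bins)
    chance: float
    p_below_chance: np.ndarray = field(init=False)
    significant: np.ndarray = field(init=False)
    alpha: float = 0.05
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        self.p_below_chance = (self.repeat_accuracies <= self.chance).mean(axis=0)
        self.significant = bh_fdr(self.p_below_chance, self.fdr_q)


def sliding_decoding(pseudo: PseudoPopulation, config: DecodingConfig
                     ) -> DecodingResult:
    """Repeated stratified k-fold MCC decoding per time bin.

    Firing rates are z-scored per neuron using training-fold statistics and
    the same transform is applied to the test fold. Classes with fewer than
    ``folds`` trials are dropped with a warning. Chance is 1/n_classes.
    """
    labels = pseudo.labels
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    bad = [c for c, n in counts.items() if n < config.folds]
    if bad:
        logger.warning("dropping %d classes with fewer than %d trials",
                       len(bad), config.folds)
        keep = ~np.isin(labels, bad)
        pseudo = PseudoPopulation(pseudo.rates[keep], labels[keep],
                                  pseudo.bin_centers)
        labels = pseudo.labels
    n_classes = pseudo.n_classes
    if n_classes < 2:
        raise ValueError("need at least 2 decodable classes")
    rng = np.random.default_rng(config.seed)
    n_bins = pseudo.rates.shape[2]
    acc = np.zeros((config.repeats, n_bins))
    for rep in range(config.repeats):
        fold_idx = _stratified_folds(labels, config.folds, rng)
        for b in range(n_bins):
            X = pseudo.rates[:, :, b]
            correct = total = 0
            for f in range(config.folds):
                te = fold_idx[f]
                tr = np.concatenate([fold_idx[g] for g in range(config.folds)
                                     if g != f])
                mu = X[tr].mean(axis=0)
                sd = X[tr].std(axis=0)
                sd[sd == 0] = 1.0
                pred = mcc_classify((X[tr] - mu) / sd, labels[tr],
                                    (X[te] - mu) / sd)
                correct += int((pred == labels[te]).sum())
                total += len(te)
            acc[rep, b] = correct / total
    return DecodingResult(
        bin_centers=pseudo.bin_centers,
        mean_accuracy=acc.mean(axis=0),
        repeat_accuracies=acc,
        chance=1.0 / n_classes,
        alpha=config.alpha,
        fdr_q=config.fdr_q,
    )


def subsample_neurons(pseudo: PseudoPopulation, n_neurons: int,
                      seed: int = 0) -> PseudoPopulation:
    """Random neuron subset, for matching neuron counts between compared
    groups before decoding."""
    total = pseudo.rates.shape[1]
    if not (0 < n_neurons <= total):
        raise ValueError(f"n_neurons must be in 1..{total}")
    idx = np.sort(np.random.default_rng(seed).choice(total, n_neurons,
                                                     replace=False))
    return PseudoPopulation(pseudo.rates[:, idx, :], pseudo.labels,
                            pseudo.bin_centers)


def compare_decoding(a: DecodingResult, b: DecodingResult,
                     fdr_q: float = 0.05):
    """Per-bin group comparison: fraction of paired repeats where a <= b.

    Returns (p_per_bin, fdr_significant) where small p means group a beats
    group b in nearly every paired repeat.
    """
    if a.repeat_accuracies.shape != b.repeat_accuracies.shape:
        raise ValueError("results must share repeats and bins")
    p = (a.repeat_accuracies <= b.repeat_accuracies).mean(axis=0)
    return p, bh_fdr(p, fdr_q)
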