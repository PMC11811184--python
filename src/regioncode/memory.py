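"""Recognition-memory behavior, in/out-region memory effects, memorability,
cross-phase region analyses, and saccade/fixation preprocessing.

Trial tables follow the phased recognition-memory layout: a learning phase in
which each stimulus is shown once, then a recognition phase mixing old and
new stimuli with 1-6 confidence responses (1 = new, very sure ... 6 = old,
very sure). A hit is an old stimulus judged old (response >= 4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .feature_space import FeatureSpace2D
from .regions import TuningRegion, region_overlap, stimuli_in_region
from .stats import TestResult, group_comparison

logger = logging.getLogger(__name__)

__all__ = [
    "RecognitionOutcome",
    "SaccadeThresholds",
    "score_recognition",
    "in_out_memory_comparison",
    "memorability_behavior_comparison",
    "select_memorability_neurons",
    "matched_memorability_comparison",
    "cross_phase_analysis",
    "detect_saccades",
]

RT_CEILING_S = 5.0
RT_SD_FACTOR = 3.0
HIT_RESPONSE_MIN = 4
SESSION_HIT_RATE_FLOOR = 0.60
MIN_GROUP_TRIALS = 10


@dataclass
class RecognitionOutcome:
    """Per-stimulus recognition behavior of one session.

    ``table`` has one row per surviving recognition trial with columns
    stimulus_id, old_flag, response, rt_s, hit (old trials only).
    """

    table: pd.DataFrame
    hit_rate: float
    accuracy: float
    mean_confidence: float
    n_excluded_rt: int = 0

    def stimulus_hits(self) -> pd.Series:
        old = self.table[self.table.old_flag.astype(bool)]
        return old.set_index("stimulus_id")["hit"].astype(float)

    def stimulus_confidence(self, judged_old_only: bool = True) -> pd.Series:
        old = self.table[self.table.old_flag.astype(bool)]
        if judged_old_only:
            old = old[old.response >= HIT_RESPONSE_MIN]
        return old.set_index("stimulus_id")["response"].astype(float)


def score_recognition(trials: pd.DataFrame,
                      confidence_judged_old_only: bool = True
                      ) -> RecognitionOutcome:
    """Score one session's recognition phase.

    Trials with outlier reaction times (RT > 5 s, or above the session mean
    plus 3 SD) are excluded first. A hit is an old trial with response >= 4;
    accuracy counts hits and correct rejections over all surviving
    recognition trials; confidence is the mean response over old trials
    judged old (configurable to all old trials).
    """
    rec = trials[trials.phase == "recognition"].copy()
    if len(rec) == 0:
        raise ValueError("no recognition trials")
    rt = rec.rt_s.astype(float)
    cut = min(RT_CEILING_S, rt.mean() + RT_SD_FACTOR * rt.std(ddof=1)) \
        if len(rec) > 1 else RT_CEILING_S
    keep = rt <= cut
    n_excluded = int((~keep).sum())
    rec = rec[keep]
    if len(rec) == 0:
        logger.warning("no trials survive RT filtering")
        return RecognitionOutcome(table=rec, hit_rate=math.nan,
                                  accuracy=math.nan, mean_confidence=math.nan,
                                  n_excluded_rt=n_excluded)
    rec["response"] = rec.response.astype(int)
    rec["old_flag"] = rec.old_flag.astype(bool)
    rec["hit"] = rec.old_flag & (rec.response >= HIT_RESPONSE_MIN)
    old = rec[rec.old_flag]
    new = rec[~rec.old_flag]
    hit_rate = float(old.hit.mean()) if len(old) else math.nan
    correct = int(old.hit.sum()) + int((new.response < HIT_RESPONSE_MIN).sum())
    accuracy = correct / len(rec)
    judged = old[old.response >= HIT_RESPONSE_MIN] \
        if confidence_judged_old_only else old
    conf = float(judged.response.mean()) if len(judged) else math.nan
    return RecognitionOutcome(table=rec, hit_rate=hit_rate, accuracy=accuracy,
                              mean_confidence=conf, n_excluded_rt=n_excluded)


def _paired_frame(pairs, labels=("in", "out")) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=labels)


def _in_out_unit(outcome: RecognitionOutcome, in_ids) -> dict | None:
    """In- vs out-region hit rate and confidence for one unit, or None."""
    hits = outcome.stimulus_hits()
    if len(hits) == 0:
        return None
    inside = hits.index.isin(np.asarray(in_ids))
    if inside.all() or not inside.any():
        logger.info("unit dropped: no in/out partition among old stimuli")
        return None
    conf = outcome.stimulus_confidence()
    c_in = conf[conf.index.isin(np.asarray(in_ids))]
    c_out = conf[~conf.index.isin(np.asarray(in_ids))]
    return {
        "hit_in": float(hits[inside].mean()),
        "hit_out": float(hits[~inside].mean()),
        "conf_in": float(c_in.mean()) if len(c_in) else math.nan,
        "conf_out": float(c_out.mean()) if len(c_out) else math.nan,
    }


def in_out_memory_comparison(units, min_hit_rate: float = SESSION_HIT_RATE_FLOOR
                             ) -> dict:
    """Paired in-region vs out-region memory comparison across units.

    ``units`` is a sequence of (outcome, in_region_stimulus_ids) pairs; a
    unit is one feature neuron (its own region) or one session (union of the
    session's feature-neuron regions). Sessions with hit rate not exceeding
    ``min_hit_rate`` are excluded. Returns the per-unit table plus paired
    two-tailed t-tests on hit rate and confidence.
    """
    rows = []
    for outcome, in_ids in units:
        if not (outcome.hit_rate > min_hit_rate):
            continue
        r = _in_out_unit(outcome, in_ids)
        if r is not None:
            rows.append(r)
    table = pd.DataFrame(rows)
    result = {"per_unit": table, "n_units": len(table)}
    if len(table) >= 2:
        result["hit_test"] = group_comparison(table.hit_in, table.hit_out,
                                              paired=True)
        conf = table.dropna(subset=["conf_in", "conf_out"])
        if len(conf) >= 2:
            result["confidence_test"] = group_comparison(
                conf.conf_in, conf.conf_out, paired=True)
    return result


def memorability_behavior_comparison(outcomes, scores: dict,
                                     top_fraction: float = 0.30) -> dict:
    """High- vs low-memorability behavior across sessions.

    Stimuli in the top 30% of memorability scores form the high group and
    the bottom 30% the low group; sessions need more than 10 surviving
    trials in both groups. Per session the accuracy, confidence, RT and hit
    rate of the two groups are compared with paired two-tailed t-tests
    across sessions.
    """
    vals = np.array(list(scores.values()), dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all memorability scores identical: groups undefined")
    lo_cut = np.quantile(vals, top_fraction)
    hi_cut = np.quantile(vals, 1.0 - top_fraction)
    hi_ids = {s for s, v in scores.items() if v >= hi_cut}
    lo_ids = {s for s, v in scores.items() if v <= lo_cut}

    rows = []
    for outcome in outcomes:
        t = outcome.table
        hi = t[t.stimulus_id.isin(hi_ids)]
        lo = t[t.stimulus_id.isin(lo_ids)]
        if len(hi) <= MIN_GROUP_TRIALS or len(lo) <= MIN_GROUP_TRIALS:
            logger.info("session dropped: <= %d trials in a memorability group",
                        MIN_GROUP_TRIALS)
            continue
        row = {}
        for name, grp in (("high", hi), ("low", lo)):
            old = grp[grp.old_flag.astype(bool)]
            new = grp[~grp.old_flag.astype(bool)]
            correct = int(old.hit.sum()) + int(
                (new.response < HIT_RESPONSE_MIN).sum())
            row[f"accuracy_{name}"] = correct / len(grp)
            judged = old[old.response >= HIT_RESPONSE_MIN]
            row[f"confidence_{name}"] = (float(judged.response.mean())
                                         if len(judged) else math.nan)
            row[f"rt_{name}"] = float(grp.rt_s.mean())
            row[f"hit_{name}"] = float(old.hit.mean()) if len(old) else math.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    result = {"per_session": table, "n_sessions": len(table)}
    for metric in ("accuracy", "confidence", "rt", "hit"):
        sub = table.dropna(subset=[f"{metric}_high", f"{metric}_low"]) \
            if len(table) else table
        if len(sub) >= 2:
            result[f"{metric}_test"] = group_comparison(
                sub[f"{metric}_high"], sub[f"{metric}_low"], paired=True)
    return result


def select_memorability_neurons(stimulus_rates: np.ndarray, scores,
                                alpha: float = 0.05) -> pd.DataFrame:
    """Neurons whose firing rate correlates with image memorability.

    ``stimulus_rates`` is (neurons, stimuli) aligned with ``scores``. A
    neuron is selected when the two-sided Pearson correlation p-value is
    below ``alpha``; both signs count (positive and negative coding both
    carry memorability information).
    """
    scores = np.asarray(scores, dtype=float)
    rates = np.atleast_2d(np.asarray(stimulus_rates, dtype=float))
    if rates.shape[1] != len(scores):
        raise ValueError("rates/scores length mismatch")
    if len(scores) < 10:
        raise ValueError("need >= 10 stimuli with scores")
    rows = []
    for i, r in enumerate(rates):
        if np.ptp(r) == 0:
            logger.info("neuron %d constant rate: not selectable", i)
            rows.append({"neuron": i, "r": math.nan, "p": math.nan,
                         "selected": False, "sign": 0})
            continue
        r_val, p = sps.pearsonr(r, scores)
        rows.append({"neuron": i, "r": float(r_val), "p": float(p),
                     "selected": bool(p < alpha),
                     "sign": int(np.sign(r_val)) if p < alpha else 0})
    return pd.DataFrame(rows)


def matched_memorability_comparison(units, scores: dict,
                                    sd_factor: float = 2.0,
                                    min_hit_rate: float = SESSION_HIT_RATE_FLOOR
                                    ) -> dict:
    """In/out memory comparison after matching out-region memorability.

    For each unit the out-region old stimuli are restricted to those whose
    memorability lies within ``sd_factor`` SD of the in-region stimuli's mean
    score before the paired in/out comparison. With zero in-region score SD
    the matching band collapses to the mean unless all scores are equal.
    """
    matched_units = []
    for outcome, in_ids in units:
        hits = outcome.stimulus_hits()
        in_ids = np.asarray(in_ids)
        in_scores = np.array([scores[s] for s in hits.index if s in set(in_ids)])
        if len(in_scores) == 0:
            logger.info("unit dropped: no in-region old stimuli")
            continue
        mu, sd = in_scores.mean(), in_scores.std()
        lo, hi = mu - sd_factor * sd, mu + sd_factor * sd
        out_keep = [s for s in hits.index
                    if s not in set(in_ids) and lo <= scores[s] <= hi]
        if not out_keep:
            logger.info("unit dropped: empty matched out-region set")
            continue
        keep_ids = set(in_ids) | set(out_keep)
        table = outcome.table[outcome.table.stimulus_id.isin(keep_ids)
                              | ~outcome.table.old_flag.astype(bool)]
        trimmed = RecognitionOutcome(
            table=table, hit_rate=outcome.hit_rate, accuracy=outcome.accuracy,
            mean_confidence=outcome.mean_confidence)
        matched_units.append((trimmed, in_ids))
    return in_out_memory_comparison(matched_units, min_hit_rate=min_hit_rate)


def cross_phase_analysis(
    learning_regions: dict,
    recognition_rates: dict,
    space: FeatureSpace2D,
    recognition_regions: dict | None = None,
    old_ids=None,
    overlap_threshold: float = 0.5,
) -> dict:
    """Do learning-phase tuning regions predict recognition-phase responses?

    For every feature neuron with a non-empty learning region, compare its
    mean recognition-phase response to in-region vs out-region stimuli
    (regions from the learning phase), for all stimuli and for the old/new
    subsets when ``old_ids`` is given. When recognition-phase regions are
    supplied, also report the region-overlap distribution and flag invariant
    neurons (overlap > ``overlap_threshold``).
    """
    rows, overlaps = [], {}
    ids = space.stimuli.stimulus_id
    old_mask = np.isin(ids, np.asarray(list(old_ids))) if old_ids is not None \
        else None
    for neuron, region in learning_regions.items():
        if neuron not in recognition_rates:
            logger.info("neuron %s absent in recognition phase: excluded", neuron)
            continue
        if region is None or region.is_empty:
            continue
        rates = np.asarray(recognition_rates[neuron], dtype=float)
        in_ids, _ = stimuli_in_region(region, space)
        inside = np.isin(ids, in_ids)
        if inside.all() or not inside.any():
            continue
        row = {"neuron": neuron,
               "in_all": float(rates[inside].mean()),
               "out_all": float(rates[~inside].mean())}
        if old_mask is not None:
            for name, m in (("old", old_mask), ("new", ~old_mask)):
                if (inside & m).any() and (~inside & m).any():
                    row[f"in_{name}"] = float(rates[inside & m].mean())
                    row[f"out_{name}"] = float(rates[~inside & m].mean())
        rows.append(row)
        if recognition_regions is not None and neuron in recognition_regions:
            other = recognition_regions[neuron]
            if other is not None and not other.is_empty:
                overlaps[neuron] = region_overlap(region, other)
    table = pd.DataFrame(rows)
    result = {"per_neuron": table, "n_neurons": len(table)}
    for subset in ("all", "old", "new"):
        cols = (f"in_{subset}", f"out_{subset}")
        if len(table) >= 2 and all(c in table for c in cols):
            sub = table.dropna(subset=list(cols))
            if len(sub) >= 2:
                result[f"{subset}_test"] = group_comparison(
                    sub[cols[0]], sub[cols[1]], paired=True)
    if overlaps:
        result["overlaps"] = overlaps
        result["invariant_neurons"] = [n for n, v in overlaps.items()
                                       if v > overlap_threshold]
    return result


@dataclass(frozen=True)
class SaccadeThresholds:
    """EyeLink-style saccade detection thresholds."""

    min_deflection_deg: float = 0.1
    min_velocity_deg_s: float = 30.0
    min_acceleration_deg_s2: float = 8000.0
    min_duration_s: float = 0.004


def detect_saccades(t, x, y, thresholds: SaccadeThresholds | None = None):
    """Detect saccades and complementary fixations in a gaze trace.

    Samples where the instantaneous velocity exceeds the velocity threshold
    or the acceleration exceeds the acceleration threshold are saccade
    candidates; contiguous candidate runs lasting at least the minimum
    duration and with total deflection above the minimum are saccades.
    Fixations are the complementary intervals. Requires uniform sampling.
    """
    th = thresholds or SaccadeThresholds()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 gaze samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3):
        raise ValueError("gaze samples must be uniformly spaced")
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    accel = np.abs(np.gradient(speed, t))
    cand = (speed >= th.min_velocity_deg_s) | (accel >= th.min_acceleration_deg_s2)

    saccades = []
    i = 0
    n = len(t)
    step = dt[0]
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cand[j + 1]:
            j += 1
        dur = (j - i + 1) * step
        deflection = math.hypot(x[j] - x[i], y[j] - y[i])
        if dur >= th.min_duration_s and deflection > th.min_deflection_deg:
            saccades.append((t[i], t[j] + step))
        i = j + 1
    fixations = []
    prev = t[0]
    for s0, s1 in saccades:
        if s0 > prev:
            fixations.append((prev, s0))
        prev = s1
    end = t[-1] + step
    if end > prev:
        fixations.append((prev, end))
    return saccades, fixations
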