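"""Plain-text I/O: TSV tables, JSON region reports, YAML configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .regions import RegionConfig, TuningRegion

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_spikes",
    "read_spikes",
    "region_to_json",
    "region_from_json",
    "load_config",
    "DEFAULT_CONFIG",
]

TRIAL_COLUMNS = ["trial_id", "stimulus_id", "phase", "old_flag", "response",
                 "rt_s", "onset_s"]

DEFAULT_CONFIG = {
    "simulate": {"n_categories": 50, "n_per_category": 10,
                 "cluster_spread": 0.03, "baseline_rate": 5.0,
                 "region_gain": 20.0, "region_width": 0.08},
    "feature_space": {"reducer": {"method": "none", "perplexity": 30.0},
                      "grid": {"resolution": 100, "mask_radius_factor": 2.0}},
    "regions": {"sq": 0.021, "n_permutations": 1000, "pixel_alpha": 0.01,
                "min_cluster_fraction": 0.025, "connectivity": 4},
    "selectivity": {"alpha": 0.05, "threshold_sd": 1.5, "n_components": 10},
    "decoding": {"bin_width": 0.5, "step": 0.05, "first_bin_start": -0.5,
                 "n_bins": 31, "folds": 8, "repeats": 50},
    "memory": {"min_hit_rate": 0.60, "top_fraction": 0.30},
}


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spikes(recordings, path) -> None:
    pd.concat([r.to_frame() for r in recordings], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_spikes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def region_to_json(region: TuningRegion, path=None) -> str:
    payload = {
        "resolution": region.resolution,
        "pixels": region.pixel_indices.tolist(),
        "clusters": [c.tolist() for c in region.clusters],
        "area_fraction": region.area_fraction,
        "member_ids": (region.member_ids.tolist()
                       if region.member_ids is not None else []),
        "covered_categories": (region.covered_categories.tolist()
                               if region.covered_categories is not None else []),
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def region_from_json(path) -> TuningRegion:
    payload = json.loads(Path(path).read_text())
    R = payload["resolution"]
    sig = np.zeros(R * R, dtype=bool)
    sig[np.asarray(payload["pixels"], dtype=int)] = True
    return TuningRegion(
        resolution=R,
        significant=sig.reshape(R, R),
        clusters=[np.asarray(c, dtype=int) for c in payload["clusters"]],
        area_fraction=float(payload["area_fraction"]),
        member_ids=np.asarray(payload["member_ids"]),
        covered_categories=np.asarray(payload["covered_categories"]),
    )


def load_config(path=None) -> dict:
    """Merge a YAML config file over the package defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}

        def merge(base, extra):
            for k, v in extra.items():
                if isinstance(v, dict) and isinstance(base.get(k), dict):
                    merge(base[k], v)
                else:
                    base[k] = v

        merge(cfg, user)
    return cfg


def region_config_from(cfg: dict, seed: int = 0) -> RegionConfig:
    r = cfg.get("regions", {})
    g = cfg.get("feature_space", {}).get("grid", {})
    return RegionConfig(
        resolution=g.get("resolution", 100),
        sq=r.get("sq", 0.021),
        n_permutations=r.get("n_permutations", 1000),
        pixel_alpha=r.get("pixel_alpha", 0.01),
        min_cluster_fraction=r.get("min_cluster_fraction", 0.025),
        connectivity=r.get("connectivity", 4),
        mask_radius_factor=g.get("mask_radius_factor", 2.0),
        seed=seed,
    )
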