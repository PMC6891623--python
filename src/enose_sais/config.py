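"""Flat key-value configuration (YAML) with the package defaults."""

from __future__ import annotations

import warnings

import yaml

#: every tunable exposed by the CLI, with its default.
DEFAULTS: dict = {
    # preprocessing
    "cutoff_hz": 0.1,
    "filter_order": 2,
    "baseline_correct": False,
    "zscore_ddof": 1,
    "zscore_per_sample": False,
    "baseline_seconds": 180,
    "sample_seconds": 180,
    "purge_seconds": 480,
    "sampling_rate_hz": 1.0,
    # alignment
    "subspace_size": 25,
    "n_target_for_subspace": "all",
    # classifier
    "elm_hidden_nodes": 200,
    # selection
    "train_fraction": 0.7,
    # experiment
    "n_sweep": [5, 10, 15, 20, 25, 30],
    "n_repeats": 10,
    # generator
    "n_classes": 5,
    "n_sensors": 31,
    "latent_dim": 8,
    "n_source_per_class": 60,
    "n_target_per_class": 80,
    "gain_low": 0.5,
    "gain_high": 1.5,
    "rotation_strength": 0.3,
    "offset_scale": 1.0,
    "noise_sd": 0.2,
}


def load_config(path=None) -> dict:
    """Merge a YAML file of flat keys over the defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        cfg.update({k: v for k, v in user.items() if k in DEFAULTS})
    return cfg
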