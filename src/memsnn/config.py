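"""Configuration handling: defaults, YAML files, overrides, resolution.

A run is described by one human-readable YAML file with nested sections
(``dataset``, ``device``, ``encoder``, ``lif``, ``plasticity``, ``train``).
Every field has a default; unknown keys are rejected with an error naming
them, and the fully resolved configuration is serialised into the output
directory next to the artifacts it produced.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .device import DeviceParams
from .encoding import (
    EncoderParams,
    ImageSample,
    crop_border,
    generate_synthetic_patterns,
    read_idx,
)
from .errors import ConfigError
from .experiments import TrainConfig
from .network import LIFParams, Topology
from .plasticity import PlasticityParams

__all__ = ["DEFAULTS", "load_config", "resolve", "ResolvedRun", "dump_config"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "runs/latest",
    "dataset": {
        # "synthetic" generates labeled stroke patterns; "idx" reads
        # IDX-format image/label files (28x28 images are border-cropped
        # to 24x24 when crop is true).
        "type": "synthetic",
        "n_classes": 3,
        "grid_size": 12,
        "n_train": 900,
        "n_eval": 150,
        "flip_noise": 0.1,
        "train_images": None,
        "train_labels": None,
        "test_images": None,
        "test_labels": None,
        "crop": True,
    },
    "device": {
        "nu_ltp": 0.0,
        "nu_ltd": 0.0,
        "beta": 4.0,
        "g_min": 0.0,
        "g_max": 1.0,
        "resolution": 256,
    },
    "encoder": {"A": 41.0 / 20.0, "B": 2.004545, "duration": 500.0, "dt": 1.0},
    "lif": {
        "tau": 100.0,
        "v_rest": 0.0,
        "threshold_init": 24.0,
        "t_ref": 5.0,
        "t_inhibit": 10.0,
        "dt": 1.0,
    },
    "plasticity": {
        "ltp_window": 45.0,
        "homeo_gamma": 0.01,
        "homeo_target": 10.0,
        "homeo_interval": 600,
    },
    "train": {
        "n_exc": 300,
        "n_train_presentations": 180_000,
        "eval_interval": 10_000,
        "label_set_size": 1000,
        "eval_set_size": 1000,
    },
}


def _merge(defaults: dict, given: dict, prefix: str = "") -> dict:
    unknown = [f"{prefix}{k}" for k in given if k not in defaults]
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    merged = copy.deepcopy(defaults)
    for k, v in given.items():
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            merged[k] = _merge(defaults[k], v, prefix=f"{prefix}{k}.")
        else:
            merged[k] = v
    return merged


def _parse_override(text: str) -> tuple[list[str], Any]:
    if "=" not in text:
        raise ConfigError(f"override must look like section.key=value, got {text!r}")
    key, raw = text.split("=", 1)
    return key.split("."), yaml.safe_load(raw)


def load_config(
    path: Optional[str] = None, overrides: tuple[str, ...] = ()
) -> dict[str, Any]:
    """Merge defaults, an optional YAML file and ``key=value`` overrides."""
    given: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        given = loaded
    cfg = _merge(DEFAULTS, given)
    for text in overrides:
        keys, value = _parse_override(text)
        node: Any = DEFAULTS
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                raise ConfigError(f"unknown configuration keys: {'.'.join(keys)}")
            node = node[k]
        target = cfg
        for k in keys[:-1]:
            target = target[k]
        target[keys[-1]] = value
    return cfg


@dataclass
class ResolvedRun:
    """A fully constructed run: datasets plus the training configuration."""

    train_samples: list[ImageSample]
    eval_samples: list[ImageSample]
    config: TrainConfig
    raw: dict[str, Any]
    output_dir: Path


def _load_dataset(ds: dict[str, Any], seed: int) -> tuple[list[ImageSample], list[ImageSample]]:
    if ds["type"] == "synthetic":
        import numpy as np

        s_train, s_eval = np.random.SeedSequence(seed).spawn(2)
        train = generate_synthetic_patterns(
            ds["n_classes"], ds["grid_size"], ds["n_train"], ds["flip_noise"], s_train
        )
        evalset = generate_synthetic_patterns(
            ds["n_classes"], ds["grid_size"], ds["n_eval"], ds["flip_noise"], s_eval
        )
        return train, evalset
    if ds["type"] == "idx":
        for key in ("train_images", "train_labels", "test_images", "test_labels"):
            if ds[key] is None:
                raise ConfigError(f"dataset.{key} is required for dataset.type=idx")
        train = read_idx(ds["train_images"], ds["train_labels"])
        evalset = read_idx(ds["test_images"], ds["test_labels"])
        if ds["crop"]:
            train = [crop_border(s) for s in train]
            evalset = [crop_border(s) for s in evalset]
        return train, evalset
    raise ConfigError(f"dataset.type must be 'synthetic' or 'idx', got {ds['type']!r}")


def resolve(cfg: dict[str, Any]) -> ResolvedRun:
    """Build datasets and parameter objects from a merged configuration."""
    train_samples, eval_samples = _load_dataset(cfg["dataset"], cfg["seed"])
    if not train_samples:
        raise ConfigError("training dataset is empty")
    n_inputs = train_samples[0].pixels.size
    tc = TrainConfig(
        device=DeviceParams(**cfg["device"]),
        lif=LIFParams(**cfg["lif"]),
        plasticity=PlasticityParams(**cfg["plasticity"]),
        encoder=EncoderParams(**cfg["encoder"]),
        topology=Topology(n_inputs=n_inputs, n_exc=cfg["train"]["n_exc"]),
        n_train_presentations=cfg["train"]["n_train_presentations"],
        eval_interval=cfg["train"]["eval_interval"],
        label_set_size=cfg["train"]["label_set_size"],
        eval_set_size=cfg["train"]["eval_set_size"],
        master_seed=cfg["seed"],
    )
    return ResolvedRun(
        train_samples=train_samples,
        eval_samples=eval_samples,
        config=tc,
        raw=cfg,
        output_dir=Path(cfg["output_dir"]),
    )


def dump_config(cfg: dict[str, Any], path) -> None:
    """Serialise the resolved configuration (lossless YAML round-trip).

    ``output_dir`` is omitted: the file already lives in that directory, and
    leaving it out keeps artifacts byte-identical across output locations.
    """
    cfg = {k: v for k, v in cfg.items() if k != "output_dir"}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
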