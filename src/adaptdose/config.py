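"""YAML run configuration: defaults, deep-merge, and seed derivation."""

from __future__ import annotations

import copy
import json
import zlib
from pathlib import Path

import yaml

from .networks import DropoutSpec, NetworkConfig
from .phantom import PhantomConfig
from .preprocess import DistanceMapSpec
from .sampling import PatchSpec
from .training import TrainingConfig


def default_config() -> dict:
    return {
        "seed": 0,
        "phantom": {
            "grid_shape": [64, 64, 48],
            "spacing_mm": 5.0,
            "n_ptvs_range": [1, 2],
            "prescription_range_gy": [42.5, 72.0],
            "falloff_scale_mm": 30.0,
            "sparing_strength_range": [0.0, 0.6],
            "noise_amplitude_gy": 0.2,
        },
        "preprocess": {
            "distance_mode": "surface",
            "distance_tau_mm": 50.0,
        },
        "sampling": {
            "patch_shape": [96, 96, 64],
            "translation_sigma": [5.0, 5.0, 5.0],
            "flip_prob": 0.5,
            "rotation_prob": 0.5,
        },
        "network": {
            "base_width": 64,
            "n_levels": 4,
            "norm_groups": 32,
            "dropout_max_rate": 0.05,
            "dropout_power": 0.25,
            "final_relu": True,
        },
        "training": {
            "learning_rate": 1.0e-4,
            "epochs": 3000,
            "patches_per_plan": 1,
            "include_pretreatment_targets": True,
        },
        "evaluation": {
            "dvh_bins": 1000,
            "alpha": 0.05,
        },
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults <- YAML file <- explicit overrides (highest precedence)."""
    cfg = default_config()
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def derive_seed(master_seed: int, component: str) -> int:
    """Stable per-component seed below 2**31."""
    digest = zlib.crc32(f"{master_seed}:{component}".encode())
    return int(digest % (2**31 - 1))


def save_resolved_config(cfg: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.json"
    path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# typed views of the config dict


def phantom_config(cfg: dict) -> PhantomConfig:
    p = cfg["phantom"]
    return PhantomConfig(
        grid_shape=tuple(p["grid_shape"]),
        spacing_mm=float(p["spacing_mm"]),
        n_ptvs_range=tuple(p["n_ptvs_range"]),
        prescription_range_gy=tuple(p["prescription_range_gy"]),
        falloff_scale_mm=float(p["falloff_scale_mm"]),
        sparing_strength_range=tuple(p["sparing_strength_range"]),
        noise_amplitude_gy=float(p["noise_amplitude_gy"]),
    )


def distance_spec(cfg: dict) -> DistanceMapSpec:
    p = cfg["preprocess"]
    return DistanceMapSpec(mode=p["distance_mode"], tau_mm=float(p["distance_tau_mm"]))


def patch_spec(cfg: dict) -> PatchSpec:
    s = cfg["sampling"]
    return PatchSpec(
        patch_shape=tuple(s["patch_shape"]),
        translation_sigma=tuple(s["translation_sigma"]),
        flip_prob=float(s["flip_prob"]),
        rotation_prob=float(s["rotation_prob"]),
    )


def network_config(cfg: dict, seed: int | None = None) -> NetworkConfig:
    n = cfg["network"]
    return NetworkConfig(
        base_width=int(n["base_width"]),
        n_levels=int(n["n_levels"]),
        norm_groups=int(n["norm_groups"]),
        dropout=DropoutSpec(
            max_rate=float(n["dropout_max_rate"]), power=float(n["dropout_power"])
        ),
        final_relu=bool(n["final_relu"]),
        seed=derive_seed(cfg["seed"], "network") if seed is None else seed,
    )


def training_config(cfg: dict) -> TrainingConfig:
    t = cfg["training"]
    return TrainingConfig(
        learning_rate=float(t["learning_rate"]),
        epochs=int(t["epochs"]),
        patches_per_plan=int(t["patches_per_plan"]),
        include_pretreatment_targets=bool(t["include_pretreatment_targets"]),
        seed=derive_seed(cfg["seed"], "training"),
        patch_spec=patch_spec(cfg),
        distance_spec=distance_spec(cfg),
    )
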