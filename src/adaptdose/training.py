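"""Training loop, inference, and checkpointing for the dose predictors.

Protocol: Adam at a constant learning rate, batch size 1, MSE loss on
normalized dose patches, random PTV-centred patches with flip/rotation
augmentation, and best-checkpoint selection by validation loss.  One epoch
visits every training sample ``patches_per_plan`` times in shuffled order
with a fresh random patch each visit.

The dual-head network trains on adaptive sessions (primary = adaptive
anatomy, secondary = pre-treatment plan, target = adaptive dose) and, by
default, additionally on each pre-treatment plan fed to both heads with its
own dose as target (self-conditioning), mirroring a cohort in which
pre-treatment plans are part of the training pool.  The baseline U-Net
trains on the adaptive sessions only.

Validation loss is computed on whole volumes in inference mode, which makes
checkpoint selection deterministic.  Volumes whose dimensions are compatible
with the network's pooling hierarchy are predicted in a single
fully-convolutional forward pass; anything else falls back to sliding-window
tiling with overlap averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn import tensor as F
from .nn.optim import Adam
from .networks import DosePredictor, NetworkConfig
from .preprocess import (
    PRIMARY,
    SECONDARY,
    ChannelAssembly,
    DistanceMapSpec,
    assemble_channels,
)
from .sampling import PatchSpec, draw_transform, extract_patch, _apply_transform, sample_patch_center
from .session import PlanPair


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    epochs: int = 3000
    patches_per_plan: int = 1
    seed: int = 0
    patch_spec: PatchSpec = field(default_factory=PatchSpec)
    include_pretreatment_targets: bool = True
    distance_spec: DistanceMapSpec = field(default_factory=DistanceMapSpec)
    validate_every: int = 1  # epochs between validation passes

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.validate_every < 1:
            raise ValueError("validate_every must be >= 1")


@dataclass
class TrainingHistory:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_val_loss: float
    checkpoint_path: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_losses": self.train_losses,
                "val_losses": self.val_losses,
                "best_epoch": self.best_epoch,
                "best_val_loss": self.best_val_loss,
                "checkpoint_path": self.checkpoint_path,
            },
            indent=2,
        )


def mse_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Sum of squared voxel differences divided by the voxel count."""
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {target.shape}")
    return float(np.mean((predicted - target) ** 2))


@dataclass
class _Sample:
    primary: np.ndarray  # (90, X, Y, Z) normalized channels
    secondary: np.ndarray | None  # (91, X, Y, Z) or None
    target: np.ndarray  # (X, Y, Z) normalized dose
    ptv_map: np.ndarray  # Gy map used to centre patches


def build_samples(
    pairs: list[PlanPair],
    model_kind: str,
    distance_spec: DistanceMapSpec = DistanceMapSpec(),
    include_pretreatment_targets: bool = False,
) -> list[_Sample]:
    """Materialize channel assemblies for each training/validation plan."""
    samples: list[_Sample] = []
    for pair in pairs:
        if pair.adaptive.dose is None:
            raise ValueError(f"{pair.patient_id}: adaptive session lacks a ground-truth dose")
        primary = assemble_channels(pair.adaptive, PRIMARY, spec=distance_spec)
        norm = primary.dose_norm_gy
        secondary = None
        if model_kind == "mhunet":
            secondary = assemble_channels(pair.pre, SECONDARY, spec=distance_spec)
        samples.append(
            _Sample(
                primary=primary.tensor,
                secondary=None if secondary is None else secondary.tensor,
                target=(pair.adaptive.dose / norm).astype(np.float32),
                ptv_map=pair.adaptive.ptv_map,
            )
        )
        if model_kind == "mhunet" and include_pretreatment_targets:
            pre_primary = assemble_channels(pair.pre, PRIMARY, spec=distance_spec)
            pre_secondary = assemble_channels(pair.pre, SECONDARY, spec=distance_spec)
            samples.append(
                _Sample(
                    primary=pre_primary.tensor,
                    secondary=pre_secondary.tensor,
                    target=(pair.pre.dose / norm).astype(np.float32),
                    ptv_map=pair.pre.ptv_map,
                )
            )
    return samples


def _predict_normalized(
    model: DosePredictor,
    primary: np.ndarray,
    secondary: np.ndarray | None,
    patch_shape: tuple[int, int, int],
) -> np.ndarray:
    """Inference on a whole (C, X, Y, Z) stack -> normalized dose (X, Y, Z)."""
    spatial = primary.shape[1:]
    down = 2 ** (model.config.n_levels - 1)
    pooling_ok = all(s % down == 0 for s in spatial)
    small_enough = np.prod(spatial) <= 8 * np.prod(patch_shape)
    if pooling_ok and small_enough:
        # fully convolutional single pass
        return _forward_once(model, primary, secondary)
    return _sliding_window(model, primary, secondary, patch_shape)


def _forward_once(model, primary, secondary):
    with nn.no_grad():
        if model.kind == "mhunet":
            y = model(Tensor(primary), Tensor(secondary))
        else:
            y = model(Tensor(primary))
    return y.data[0]


def _tile_starts(n: int, p: int) -> list[int]:
    if n <= p:
        return [0]
    stride = max(p // 2, 1)
    starts = list(range(0, n - p, stride)) + [n - p]
    return sorted(set(starts))


def _sliding_window(model, primary, secondary, patch_shape):
    spatial = primary.shape[1:]
    pshape = tuple(min(p, ((s + 1) // 2) * 2) for p, s in zip(patch_shape, spatial))
    acc = np.zeros(spatial, dtype=np.float64)
    wsum = np.zeros(spatial, dtype=np.float64)
    for sx in _tile_starts(spatial[0], pshape[0]):
        for sy in _tile_starts(spatial[1], pshape[1]):
            for sz in _tile_starts(spatial[2], pshape[2]):
                sl = (
                    slice(sx, sx + pshape[0]),
                    slice(sy, sy + pshape[1]),
                    slice(sz, sz + pshape[2]),
                )
                ptile = primary[:, sl[0], sl[1], sl[2]]
                stile = None if secondary is None else secondary[:, sl[0], sl[1], sl[2]]
                tile = _forward_once(model, np.ascontiguousarray(ptile),
                                     None if stile is None else np.ascontiguousarray(stile))
                acc[sl] += tile
                wsum[sl] += 1.0
    return (acc / wsum).astype(np.float32)


def predict_dose(
    model: DosePredictor,
    primary: ChannelAssembly,
    secondary: ChannelAssembly | None = None,
    patch_shape: tuple[int, int, int] = (96, 96, 64),
    mode: str = "auto",
) -> np.ndarray:
    """Predict the dose volume in Gy for one session.

    ``mode``: 'auto' (single pass when the grid allows, else sliding window),
    'single', or 'sliding'.
    """
    if model.kind == "mhunet" and secondary is None:
        raise ValueError("MHU-Net prediction requires the pre-treatment assembly")
    sec = None if secondary is None else secondary.tensor
    was_training = model.training
    model.eval()
    try:
        if mode == "single":
            out = _forward_once(model, primary.tensor, sec)
        elif mode == "sliding":
            out = _sliding_window(model, primary.tensor, sec, patch_shape)
        else:
            out = _predict_normalized(model, primary.tensor, sec, patch_shape)
    finally:
        if was_training:
            model.train()
    return out * primary.dose_norm_gy


def _validation_loss(model, val_samples: list[_Sample], patch_shape) -> float:
    """Whole-volume validation MSE, stitched from patch-sized tiles.

    Tiles match the training patch, so normalization statistics at
    validation time match what the network saw during training.
    """
    was_training = model.training
    model.eval()
    try:
        losses = [
            mse_loss(
                _sliding_window(model, s.primary, s.secondary, patch_shape), s.target
            )
            for s in val_samples
        ]
    finally:
        if was_training:
            model.train()
    return float(np.mean(losses))


def train_model(
    model: DosePredictor,
    train_pairs: list[PlanPair],
    val_pairs: list[PlanPair],
    cfg: TrainingConfig,
    checkpoint_dir: str | Path | None = None,
    log=None,
    train_samples: list[_Sample] | None = None,
    val_samples: list[_Sample] | None = None,
) -> TrainingHistory:
    """Train ``model`` and return its history; reproducible under ``cfg.seed``.

    Prebuilt ``train_samples`` / ``val_samples`` (from :func:`build_samples`)
    may be passed to amortize channel assembly across repeated runs on the
    same cohort; otherwise they are built from the plan pairs.
    """
    if not train_pairs and not train_samples:
        raise ValueError("training set is empty")
    if train_samples is None:
        train_samples = build_samples(
            train_pairs, model.kind, cfg.distance_spec, cfg.include_pretreatment_targets
        )
    if val_samples is None:
        val_samples = (
            build_samples(val_pairs, model.kind, cfg.distance_spec) if val_pairs else []
        )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A]).generate_state(2))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    pshape = cfg.patch_spec.patch_shape

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_state = None

    model.train()
    for epoch in range(cfg.epochs):
        order = np.concatenate(
            [rng.permutation(len(train_samples)) for _ in range(cfg.patches_per_plan)]
        )
        epoch_losses = []
        for idx in order:
            s = train_samples[int(idx)]
            center = sample_patch_center(s.ptv_map, cfg.patch_spec, rng)
            p = extract_patch(s.primary, center, pshape)
            t = extract_patch(s.target, center, pshape)
            sec = None if s.secondary is None else extract_patch(s.secondary, center, pshape)
            flip_axis, rot_k = draw_transform(cfg.patch_spec, rng)
            p = _apply_transform(p, flip_axis, rot_k)
            t = _apply_transform(t, flip_axis, rot_k)
            if sec is not None:
                sec = _apply_transform(sec, flip_axis, rot_k)

            if model.kind == "mhunet":
                pred = model(Tensor(p), Tensor(sec))
            else:
                pred = model(Tensor(p))
            loss = F.mse(pred, t[None])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            loss.backward()
            opt.step()
            opt.zero_grad()
            epoch_losses.append(loss.item())
        train_losses.append(float(np.mean(epoch_losses)))

        validate_now = (
            (epoch + 1) % cfg.validate_every == 0 or epoch == cfg.epochs - 1
        )
        if val_samples and validate_now:
            vloss = _validation_loss(model, val_samples, pshape)
        elif val_samples:
            vloss = float("nan")  # not evaluated this epoch
        else:
            vloss = train_losses[-1]
        val_losses.append(vloss)
        if np.isfinite(vloss) and vloss < best_val:
            best_val = vloss
            best_epoch = epoch
            best_state = model.state_dict()
        if log is not None:
            log(f"epoch {epoch}: train={train_losses[-1]:.6f} val={vloss:.6f}")

    if best_state is not None:
        model.load_state_dict(best_state)

    ckpt_path = None
    if checkpoint_dir is not None:
        ckpt_path = str(save_checkpoint(model, Path(checkpoint_dir) / "best.npz"))
    return TrainingHistory(
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        checkpoint_path=ckpt_path,
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: DosePredictor, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = {
        "kind": model.kind,
        "config": {
            "in_channels_primary": cfg.in_channels_primary,
            "in_channels_secondary": cfg.in_channels_secondary,
            "base_width": cfg.base_width,
            "n_levels": cfg.n_levels,
            "norm_groups": cfg.norm_groups,
            "dropout": {"max_rate": cfg.dropout.max_rate, "power": cfg.dropout.power},
            "final_relu": cfg.final_relu,
            "normalize_decoder": cfg.normalize_decoder,
            "bypass_stream": cfg.bypass_stream,
            "seed": cfg.seed,
        },
    }
    arrays = {"param:" + k: v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> DosePredictor:
    from .networks import DropoutSpec, build_mhunet, build_unet

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {
            k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")
        }
    c = meta["config"]
    cfg = NetworkConfig(
        in_channels_primary=c["in_channels_primary"],
        in_channels_secondary=c["in_channels_secondary"],
        base_width=c["base_width"],
        n_levels=c["n_levels"],
        norm_groups=c["norm_groups"],
        dropout=DropoutSpec(**c["dropout"]),
        final_relu=c["final_relu"],
        normalize_decoder=c["normalize_decoder"],
        bypass_stream=c["bypass_stream"],
        seed=c["seed"],
    )
    model = build_mhunet(cfg) if meta["kind"] == "mhunet" else build_unet(cfg)
    model.load_state_dict(state)
    return model
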