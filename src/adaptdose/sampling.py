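"""Training-patch sampling and geometric augmentation.

Patches are drawn around the PTV: the patch centre is sampled from a
Gaussian centred on the PTV centre of mass and clamped so the patch fits in
the volume (volumes smaller than the patch are zero-padded symmetrically).
Augmentation is purely geometric and in-plane (the axial x-y plane of the
patch): with probability ``flip_prob`` one axis flip along x or y, and
independently with probability ``rotation_prob`` one rotation drawn from
{90, 180, 270} degrees.  The identical transform is applied to every input
channel and to the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class PatchSpec:
    patch_shape: tuple[int, int, int] = (96, 96, 64)
    translation_sigma: tuple[float, float, float] = (5.0, 5.0, 5.0)
    flip_prob: float = 0.5
    rotation_prob: float = 0.5
    rotation_angles: tuple[int, ...] = (90, 180, 270)
    include_identity_rotation: bool = False  # alternative reading: uniform over {0,90,180,270}

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.patch_shape):
            raise ValueError("patch_shape must be positive")
        for p in (self.flip_prob, self.rotation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if any(a not in (90, 180, 270) for a in self.rotation_angles):
            raise ValueError("rotation angles restricted to 90/180/270 degrees")


def ptv_center_of_mass(ptv_map: np.ndarray) -> np.ndarray:
    covered = ptv_map > 0
    if not covered.any():
        raise ValueError("PTV map is empty; cannot centre patches")
    return np.asarray(ndimage.center_of_mass(covered), dtype=float)


def sample_patch_center(
    ptv_map: np.ndarray, spec: PatchSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw a patch centre ~ N(PTV centre of mass, translation_sigma), clamped."""
    com = ptv_center_of_mass(ptv_map)
    center = com + rng.normal(0.0, 1.0, size=3) * np.asarray(spec.translation_sigma)
    center = np.rint(center).astype(int)
    for ax, (n, p) in enumerate(zip(ptv_map.shape, spec.patch_shape)):
        if n < p:
            center[ax] = n // 2  # volume smaller than patch: pad later
        else:
            # valid starts are [0, n - p]; centre = start + p // 2
            center[ax] = int(np.clip(center[ax], p // 2, n - p + p // 2))
    return center


def extract_patch(
    volume: np.ndarray, center: np.ndarray, patch_shape: tuple[int, int, int]
) -> np.ndarray:
    """Crop a spatial patch around ``center``; channel axis (if any) leads.

    Out-of-bounds regions are zero-filled (symmetric padding behaviour for
    volumes smaller than the patch).
    """
    spatial = volume.shape[-3:]
    starts = [int(c) - p // 2 for c, p in zip(center, patch_shape)]
    out_shape = volume.shape[:-3] + tuple(patch_shape)
    out = np.zeros(out_shape, dtype=volume.dtype)
    src, dst = [], []
    for s, p, n in zip(starts, patch_shape, spatial):
        s0 = max(s, 0)
        s1 = min(s + p, n)
        if s1 <= s0:
            return out
        src.append(slice(s0, s1))
        dst.append(slice(s0 - s, s1 - s))
    out[..., dst[0], dst[1], dst[2]] = volume[..., src[0], src[1], src[2]]
    return out


def _apply_transform(arr: np.ndarray, flip_axis: int | None, rot_k: int) -> np.ndarray:
    """Apply flip then rotation in the leading two spatial axes (x, y)."""
    x = arr
    nd = x.ndim
    ax_x, ax_y = nd - 3, nd - 2
    if flip_axis is not None:
        x = np.flip(x, axis=ax_x if flip_axis == 0 else ax_y)
    if rot_k:
        if x.shape[ax_x] != x.shape[ax_y]:
            if rot_k % 2:
                raise ValueError("90/270 degree rotation requires a square in-plane patch")
        x = np.rot90(x, k=rot_k, axes=(ax_x, ax_y))
    return np.ascontiguousarray(x)


def draw_transform(spec: PatchSpec, rng: np.random.Generator) -> tuple[int | None, int]:
    """Sample (flip_axis, rotation quarter-turns) per the augmentation policy."""
    flip_axis = None
    if rng.random() < spec.flip_prob:
        flip_axis = int(rng.integers(0, 2))
    rot_k = 0
    if spec.include_identity_rotation:
        angle = int(rng.choice((0,) + tuple(spec.rotation_angles)))
        rot_k = angle // 90
    elif rng.random() < spec.rotation_prob:
        angle = int(rng.choice(spec.rotation_angles))
        rot_k = angle // 90
    return flip_axis, rot_k


def augment_patch(
    patch_in: np.ndarray,
    target: np.ndarray,
    spec: PatchSpec,
    rng: np.random.Generator,
    extra: np.ndarray | None = None,
):
    """Apply one random flip/rotation identically to input, target (and extra).

    ``patch_in`` is (C, x, y, z); ``target`` is (x, y, z).  ``extra`` lets a
    second channel stack (e.g. the pre-treatment assembly patch) share the
    transform.  Returns transformed copies.
    """
    if patch_in.shape[-3:] != target.shape[-3:]:
        raise ValueError("input and target patches must share spatial shape")
    flip_axis, rot_k = draw_transform(spec, rng)
    out_in = _apply_transform(patch_in, flip_axis, rot_k)
    out_t = _apply_transform(target, flip_axis, rot_k)
    if extra is None:
        return out_in, out_t
    return out_in, out_t, _apply_transform(extra, flip_axis, rot_k)
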