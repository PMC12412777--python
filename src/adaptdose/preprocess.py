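"""Channel assembly: from a PlanSession to the tensor stack the networks eat.

The primary head consumes 90 channels — 44 OAR masks in roster order, the
44 matching distance maps, the merged PTV prescription map and the CT.  The
secondary head consumes the same 90 for the pre-treatment session plus the
physician-approved pre-treatment dose, 91 in total.  Structures absent from
a session contribute all-zero mask and distance channels so that the channel
manifest is identical for every patient.

Distance maps are normalized to [0, 1]: 1.0 on voxels inside the structure,
decaying with Euclidean distance outside.  The default (surface mode) decay
is ``exp(-d / tau)`` with ``d`` the distance in mm to the nearest in-structure
voxel; isocenter mode measures distance to the structure's centre of mass
instead, with in-structure voxels clamped to 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .roster import DEFAULT_ROSTER, OarRoster
from .session import PlanSession

PRIMARY = "primary"
SECONDARY = "secondary"

#: CT affine normalization: (HU + shift) / scale, clipped to [0, 1].
CT_SHIFT_HU = 1000.0
CT_SCALE_HU = 2000.0
#: Dose and prescription channels are divided by this (cohort max prescription).
DEFAULT_DOSE_NORM_GY = 72.0


@dataclass(frozen=True)
class DistanceMapSpec:
    """Distance-map construction: mode and exponential decay scale (mm)."""

    mode: str = "surface"  # or "isocenter"
    tau_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("surface", "isocenter"):
            raise ValueError("mode must be 'surface' or 'isocenter'")
        if self.tau_mm <= 0:
            raise ValueError("tau must be positive (mm)")


@dataclass
class ChannelAssembly:
    """Ordered multi-channel tensor plus the manifest naming each slot."""

    tensor: np.ndarray  # (C, X, Y, Z) float32
    manifest: list[str]
    head: str
    spacing: tuple[float, float, float]
    patient_id: str
    dose_norm_gy: float = DEFAULT_DOSE_NORM_GY
    ptv_map_gy: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tensor.shape[0] != len(self.manifest):
            raise ValueError("channel count must equal manifest length")
        expected = 91 if self.head == SECONDARY else 90
        if len(self.manifest) != expected:
            raise ValueError(
                f"{self.head} assembly must have {expected} channels, "
                f"got {len(self.manifest)}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.tensor.shape[1:])


def merge_ptvs(ptv_masks: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Merge PTV masks into one Gy map: per voxel the highest covering prescription.

    Voxels covered by no PTV are zero.
    """
    if not ptv_masks:
        raise ValueError("merge_ptvs requires at least one PTV")
    shape = ptv_masks[0][0].shape
    out = np.zeros(shape, dtype=np.float32)
    for mask, rx in ptv_masks:
        if mask.shape != shape:
            raise ValueError("all PTV masks must share one grid")
        if rx <= 0:
            raise ValueError("prescription doses must be positive")
        np.maximum(out, np.float32(rx) * (mask > 0), out=out)
    return out


def structure_distance_map(
    mask: np.ndarray,
    spec: DistanceMapSpec,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Normalized distance map in [0, 1] for one structure (see module docs)."""
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")
    inside = mask > 0
    if not inside.any():
        if spec.mode == "surface":
            raise ValueError("surface-mode distance map requires a non-empty mask")
        return np.zeros(mask.shape, dtype=np.float32)
    if spec.mode == "surface":
        d = ndimage.distance_transform_edt(~inside, sampling=spacing)
    else:
        com_vox = ndimage.center_of_mass(inside)
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(mask.shape, spacing)], indexing="ij"
        )
        com_mm = [c * s for c, s in zip(com_vox, spacing)]
        d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, com_mm)))
    out = np.exp(-d / spec.tau_mm).astype(np.float32)
    out[inside] = 1.0
    return out


def normalize_ct(ct: np.ndarray) -> np.ndarray:
    return np.clip((ct + CT_SHIFT_HU) / CT_SCALE_HU, 0.0, 1.0).astype(np.float32)


def assemble_channels(
    session: PlanSession,
    head: str = PRIMARY,
    roster: OarRoster | None = None,
    spec: DistanceMapSpec = DistanceMapSpec(),
    dose_norm_gy: float = DEFAULT_DOSE_NORM_GY,
) -> ChannelAssembly:
    """Build the ordered channel stack for one session.

    Channel order: 44 OAR masks (roster order), 44 OAR distance maps (roster
    order), PTV prescription map, CT, and — secondary head only — the dose.
    Missing roster structures yield all-zero mask and distance channels.
    PTV and dose channels are in Gy divided by ``dose_norm_gy``.
    """
    if head not in (PRIMARY, SECONDARY):
        raise ValueError("head must be 'primary' or 'secondary'")
    if head == SECONDARY and session.dose is None:
        raise ValueError("secondary-head assembly requires a dose volume")
    roster = roster if roster is not None else session.roster
    shape = session.shape
    zero = np.zeros(shape, dtype=np.float32)

    channels: list[np.ndarray] = []
    manifest: list[str] = []
    for name in roster:
        mask = session.oar_masks.get(name)
        channels.append(zero if mask is None else mask.astype(np.float32))
        manifest.append(f"oar_mask:{name}")
    for name in roster:
        mask = session.oar_masks.get(name)
        if mask is None or not mask.any():
            channels.append(zero)
        else:
            channels.append(structure_distance_map(mask, spec, session.spacing))
        manifest.append(f"oar_dist:{name}")
    channels.append((session.ptv_map / dose_norm_gy).astype(np.float32))
    manifest.append("ptv")
    channels.append(normalize_ct(session.ct))
    manifest.append("ct")
    if head == SECONDARY:
        channels.append((session.dose / dose_norm_gy).astype(np.float32))
        manifest.append("dose")

    tensor = np.ascontiguousarray(np.stack(channels, axis=0), dtype=np.float32)
    return ChannelAssembly(
        tensor=tensor,
        manifest=manifest,
        head=head,
        spacing=session.spacing,
        patient_id=session.patient_id,
        dose_norm_gy=dose_norm_gy,
        ptv_map_gy=session.ptv_map.astype(np.float32),
    )


def save_assembly(assembly: ChannelAssembly, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "manifest": assembly.manifest,
        "head": assembly.head,
        "spacing_mm": list(assembly.spacing),
        "patient_id": assembly.patient_id,
        "dose_norm_gy": assembly.dose_norm_gy,
        "has_ptv_map": assembly.ptv_map_gy is not None,
    }
    arrays = {
        "tensor": assembly.tensor,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if assembly.ptv_map_gy is not None:
        arrays["ptv_map_gy"] = assembly.ptv_map_gy
    np.savez_compressed(path, **arrays)
    return path


def load_assembly(path: str | Path) -> ChannelAssembly:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        return ChannelAssembly(
            tensor=data["tensor"],
            manifest=list(meta["manifest"]),
            head=meta["head"],
            spacing=tuple(meta["spacing_mm"]),
            patient_id=meta["patient_id"],
            dose_norm_gy=float(meta["dose_norm_gy"]),
            ptv_map_gy=data["ptv_map_gy"] if meta.get("has_ptv_map") else None,
        )
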