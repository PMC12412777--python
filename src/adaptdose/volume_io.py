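"""Session bundle I/O and grid resampling.

Two interchangeable on-disk layouts are supported:

* a directory of NIfTI volumes (``ct.nii.gz``, ``ptv.nii.gz``, optional
  ``dose.nii.gz``, ``masks/<structure>.nii.gz``) plus ``manifest.json``;
* a single compressed ``.npz`` bundle with the same named members and the
  manifest embedded as a JSON string.

Both store voxel spacing in mm.  Axis order is (x, y, z), indices are
0-based, and world coordinates are ``index * spacing + origin``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .roster import DEFAULT_ROSTER, OarRoster
from .session import PlanSession

_MASK_PREFIX = "mask__"


def _manifest(session: PlanSession) -> dict:
    return {
        "format": "adaptdose-session",
        "session_kind": session.session_kind,
        "patient_id": session.patient_id,
        "spacing_mm": list(session.spacing),
        "structures": list(session.present_structures()),
        "has_dose": session.dose is not None,
    }


def save_session(session: PlanSession, path: str | Path) -> Path:
    """Write a session bundle; ``.npz`` suffix selects the array-bundle layout."""
    path = Path(path)
    if path.suffix == ".npz":
        arrays = {
            "ct": session.ct,
            "ptv": session.ptv_map,
            "manifest": np.frombuffer(
                json.dumps(_manifest(session)).encode(), dtype=np.uint8
            ),
        }
        if session.dose is not None:
            arrays["dose"] = session.dose
        for name, mask in session.oar_masks.items():
            arrays[_MASK_PREFIX + name] = mask.astype(np.uint8)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **arrays)
        return path

    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(session.spacing) + [1.0])

    def _write(arr: np.ndarray, fname: str) -> None:
        nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path / fname))

    _write(session.ct.astype(np.float32), "ct.nii.gz")
    _write(session.ptv_map.astype(np.float32), "ptv.nii.gz")
    if session.dose is not None:
        _write(session.dose.astype(np.float32), "dose.nii.gz")
    (path / "masks").mkdir(exist_ok=True)
    for name, mask in session.oar_masks.items():
        _write(mask.astype(np.uint8), f"masks/{name}.nii.gz")
    (path / "manifest.json").write_text(json.dumps(_manifest(session), indent=2))
    return path


def load_session(path: str | Path, roster: OarRoster = DEFAULT_ROSTER) -> PlanSession:
    """Load and validate a session bundle (directory or ``.npz``)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            if "manifest" not in data:
                raise ValueError(f"{path}: not a session bundle (missing manifest)")
            manifest = json.loads(bytes(data["manifest"]).decode())
            ct = data["ct"]
            ptv = data["ptv"]
            dose = data["dose"] if manifest.get("has_dose") else None
            masks = {
                key[len(_MASK_PREFIX):]: data[key].astype(np.uint8)
                for key in data.files
                if key.startswith(_MASK_PREFIX)
            }
    elif path.is_dir():
        mpath = path / "manifest.json"
        if not mpath.exists():
            raise ValueError(f"{path}: not a session bundle (missing manifest.json)")
        manifest = json.loads(mpath.read_text())

        def _read(fname: str) -> np.ndarray:
            return np.asarray(nib.load(str(path / fname)).dataobj)

        ct = _read("ct.nii.gz")
        ptv = _read("ptv.nii.gz")
        dose = _read("dose.nii.gz") if manifest.get("has_dose") else None
        masks = {
            name: _read(f"masks/{name}.nii.gz").astype(np.uint8)
            for name in manifest["structures"]
        }
    else:
        raise ValueError(f"{path}: expected a bundle directory or .npz file")

    roster.validate_names(masks)
    return PlanSession(
        session_kind=manifest["session_kind"],
        ct=ct,
        oar_masks=masks,
        ptv_map=ptv,
        dose=dose,
        spacing=tuple(manifest["spacing_mm"]),
        patient_id=manifest["patient_id"],
        roster=roster,
    )


def resample_volume(
    vol: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float],
    order: int,
) -> np.ndarray:
    """Resample one volume to a new spacing; out shape = ceil(n * s_in / s_out)."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive on all axes")
    if tuple(spacing) == tuple(target_spacing):
        return vol.copy()
    out_shape = tuple(
        int(np.ceil(n * s_in / s_out))
        for n, s_in, s_out in zip(vol.shape, spacing, target_spacing)
    )
    zoom = [o / n for o, n in zip(out_shape, vol.shape)]
    out = ndimage.zoom(vol.astype(np.float32), zoom, order=order, mode="nearest")
    assert out.shape == out_shape
    return out


def resample_session(
    session: PlanSession, target_spacing: tuple[float, float, float]
) -> PlanSession:
    """Resample all session volumes onto the working grid.

    Masks and the prescription map use nearest-neighbour interpolation
    (prescription levels are categorical); CT and dose are trilinear.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive on all axes")
    sp = session.spacing
    ct = resample_volume(session.ct, sp, target_spacing, order=1)
    ptv = resample_volume(session.ptv_map, sp, target_spacing, order=0)
    dose = (
        resample_volume(session.dose, sp, target_spacing, order=1)
        if session.dose is not None
        else None
    )
    masks = {
        name: resample_volume(mask, sp, target_spacing, order=0).astype(np.uint8)
        for name, mask in session.oar_masks.items()
    }
    if dose is not None:
        dose = np.clip(dose, 0.0, None)
    return PlanSession(
        session_kind=session.session_kind,
        ct=ct,
        oar_masks=masks,
        ptv_map=np.clip(ptv, 0.0, None),
        dose=dose,
        spacing=target_spacing,
        patient_id=session.patient_id,
        roster=session.roster,
    )
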