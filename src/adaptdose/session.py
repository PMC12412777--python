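"""Treatment-session containers.

A :class:`PlanSession` holds everything one planning session contributes:
the CT volume (HU), binary OAR masks keyed by canonical structure name, the
merged PTV prescription map (Gy per voxel), an optional planned dose (Gy)
and the voxel spacing in millimetres.  A :class:`PlanPair` links the
pre-treatment session with one adaptive session of the same patient; the
pre-treatment dose is what carries the physician's per-patient sparing
intent into the model's secondary head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roster import DEFAULT_ROSTER, OarRoster

PRETREATMENT = "pretreatment"
ADAPTIVE = "adaptive"
SESSION_KINDS = (PRETREATMENT, ADAPTIVE)


@dataclass
class PlanSession:
    session_kind: str
    ct: np.ndarray
    oar_masks: dict[str, np.ndarray]
    ptv_map: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str
    dose: np.ndarray | None = None
    roster: OarRoster = field(default=DEFAULT_ROSTER, repr=False)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.ct.shape)

    def validate(self) -> None:
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(f"session_kind must be one of {SESSION_KINDS}")
        if self.ct.ndim != 3:
            raise ValueError("ct must be a 3D volume")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        shape = self.ct.shape
        for name, vol in self._named_volumes():
            if vol.shape != shape:
                raise ValueError(
                    f"volume '{name}' shape {vol.shape} differs from CT shape {shape}"
                )
        self.roster.validate_names(self.oar_masks)
        for name, mask in self.oar_masks.items():
            vals = np.unique(mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask '{name}' is not binary (values {vals[:5]}...)")
        if np.any(self.ptv_map < 0):
            raise ValueError("ptv_map contains negative prescription values")
        if self.dose is not None and np.any(self.dose < 0):
            raise ValueError("dose contains negative values")

    def _named_volumes(self):
        yield "ptv_map", self.ptv_map
        if self.dose is not None:
            yield "dose", self.dose
        for name, mask in self.oar_masks.items():
            yield name, mask

    def present_structures(self) -> tuple[str, ...]:
        """Roster structures contoured in this session, in roster order."""
        return tuple(n for n in self.roster if n in self.oar_masks)


@dataclass
class PlanPair:
    """Pre-treatment and adaptive sessions of one patient, co-registered."""

    pre: PlanSession
    adaptive: PlanSession
    patient_id: str

    def __post_init__(self) -> None:
        if self.pre.session_kind != PRETREATMENT:
            raise ValueError("pre session must have session_kind 'pretreatment'")
        if self.adaptive.session_kind != ADAPTIVE:
            raise ValueError("adaptive session must have session_kind 'adaptive'")
        if self.pre.dose is None:
            raise ValueError("pre-treatment session requires a dose volume")
        if self.pre.shape != self.adaptive.shape or self.pre.spacing != self.adaptive.spacing:
            raise ValueError("pair sessions must share one grid (shape and spacing)")
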