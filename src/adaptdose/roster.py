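"""Canonical organ-at-risk roster for head-and-neck adaptive radiotherapy.

The model input layout is fixed: every patient contributes one mask channel
and one distance-map channel per roster structure, in roster order, whether
or not the structure was contoured for that patient.  Keeping the roster as
a single frozen tuple makes channel manifests identical across patients.
"""

from __future__ import annotations

# 44 structures.  The first 43 follow the clinical enumeration (body first,
# superior parotid glands last); ``posterior_neck`` is the planning structure
# used for the posterior neck region and completes the roster.
CANONICAL_OARS: tuple[str, ...] = (
    "body",
    "brachial_plexus_l",
    "brachial_plexus_r",
    "brain",
    "brainstem",
    "cerebellum_l",
    "cerebellum_r",
    "cochlea_l",
    "cochlea_r",
    "constrictor_superior",
    "constrictor_middle",
    "constrictor_inferior",
    "constrictor_combined",
    "esophagus",
    "larynx",
    "mandible",
    "masseter_l",
    "masseter_r",
    "masseter_combined",
    "oral_cavity",
    "postarytenoid_cricoid_space",
    "parotid_l",
    "parotid_r",
    "parotid_combined",
    "submandibular_l",
    "submandibular_r",
    "lacrimal_l",
    "lacrimal_r",
    "optic_nerve_l",
    "optic_nerve_r",
    "optic_chiasm",
    "optic_pathway",
    "eye_l",
    "eye_r",
    "thyroid",
    "spinal_cord",
    "spinal_canal",
    "soft_palate",
    "epiglottis",
    "temporal_lobe_l",
    "temporal_lobe_r",
    "superior_parotid_l",
    "superior_parotid_r",
    "posterior_neck",
)


class OarRoster:
    """Ordered, immutable list of canonical OAR names with index lookup."""

    def __init__(self, names: tuple[str, ...] = CANONICAL_OARS) -> None:
        if len(names) != len(set(names)):
            raise ValueError("roster names must be unique")
        self.names: tuple[str, ...] = tuple(names)
        self.index_of: dict[str, int] = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index_of

    def __iter__(self):
        return iter(self.names)

    def validate_names(self, names) -> None:
        unknown = sorted(set(names) - set(self.names))
        if unknown:
            raise ValueError(f"structure names not in canonical roster: {unknown}")


DEFAULT_ROSTER = OarRoster()
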