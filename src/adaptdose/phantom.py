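"""Synthetic plan-pair simulator for paired pre-treatment/adaptive sessions.

The generator emulates the statistical setting of adaptive head-and-neck
radiotherapy, not beam physics: each synthetic patient has

* an anatomy — a body ellipsoid, 1..n ellipsoidal PTVs with prescriptions,
  and a subset of roster OARs placed as ellipsoids or a cord-like tube near
  the target;
* a latent per-patient :class:`SparingProfile` (one sparing strength per
  OAR) standing in for physician-defined clinical objectives.  It is
  constant across that patient's sessions and observable only through the
  pre-treatment dose — exactly the information a pre-treatment-conditioned
  model can exploit and an anatomy-only model cannot;
* a dose model: prescription inside the PTV, exponential distance falloff
  outside, multiplicatively reduced near spared OARs, plus smooth noise:

  ``D(v) = [P(v) if v in PTV else P_near(v) * exp(-d_PTV(v)/lambda)]
  * prod_o (1 - sigma_o * exp(-d_o(v)/lambda)) + noise``

* a between-session deformation: the PTV shrinks, structures shift, and
  gland-like OARs lose volume.  Masks are re-rasterized from deformed
  analytic shapes, so ground truth stays exact.

The adaptive ground-truth dose is computed from the *same* sparing profile
on the deformed anatomy, making the pre-treatment plan informative about the
adaptive dose beyond anatomy alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import merge_ptvs
from .session import ADAPTIVE, PRETREATMENT, PlanPair, PlanSession
from .volume_io import save_session

#: OARs the default phantom places, with ellipsoid/tube placement priors.
DEFAULT_OAR_SUBSET = (
    "spinal_cord",
    "brainstem",
    "parotid_l",
    "parotid_r",
    "submandibular_l",
    "submandibular_r",
    "oral_cavity",
    "larynx",
)

_GLANDS = {"parotid_l", "parotid_r", "submandibular_l", "submandibular_r"}


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: float = 5.0
    n_ptvs_range: tuple[int, int] = (1, 2)
    prescription_range_gy: tuple[float, float] = (42.5, 72.0)
    oar_subset: tuple[str, ...] = DEFAULT_OAR_SUBSET
    falloff_scale_mm: float = 30.0
    sparing_strength_range: tuple[float, float] = (0.0, 0.6)
    ptv_shrink_range: tuple[float, float] = (0.9, 1.0)
    structure_shift_sigma_mm: float = 2.0
    gland_shrink_range: tuple[float, float] = (0.85, 1.0)
    noise_amplitude_gy: float = 0.2
    max_deform_attempts: int = 10

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small for the requested structures")
        if not 1 <= self.n_ptvs_range[0] <= self.n_ptvs_range[1] <= 5:
            raise ValueError("n_ptvs_range must lie within 1..5")
        if self.prescription_range_gy[0] <= 0:
            raise ValueError("prescriptions must be positive")
        if not 0 < self.ptv_shrink_range[0] <= self.ptv_shrink_range[1] <= 1:
            raise ValueError("PTV shrink factors must lie in (0, 1]")


@dataclass(frozen=True)
class SparingProfile:
    """Latent per-patient sparing intent: strength in [0, 1] per OAR."""

    strengths: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.strengths.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sparing strength for {name} outside [0, 1]")


@dataclass
class _Ellipsoid:
    center_mm: np.ndarray  # (3,)
    radii_mm: np.ndarray  # (3,)

    def scaled(self, volume_factor: float) -> "_Ellipsoid":
        return _Ellipsoid(self.center_mm.copy(), self.radii_mm * volume_factor ** (1 / 3))

    def shifted(self, delta_mm: np.ndarray) -> "_Ellipsoid":
        return _Ellipsoid(self.center_mm + delta_mm, self.radii_mm.copy())


@dataclass
class _Geometry:
    body: _Ellipsoid
    ptvs: list[tuple[_Ellipsoid, float]]  # (shape, prescription Gy)
    oars: dict[str, _Ellipsoid]
    ct_noise_seed: int


def _coords_mm(grid_shape, spacing) -> list[np.ndarray]:
    return np.meshgrid(
        *[np.arange(n) * spacing for n in grid_shape], indexing="ij", sparse=True
    )


def _rasterize(e: _Ellipsoid, coords) -> np.ndarray:
    q = sum(((c - m) / r) ** 2 for c, m, r in zip(coords, e.center_mm, e.radii_mm))
    return (q <= 1.0).astype(np.uint8)


def _sample_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> _Geometry:
    shape = np.asarray(cfg.grid_shape, dtype=float)
    sp = cfg.spacing_mm
    extent = shape * sp
    center = extent / 2

    body = _Ellipsoid(center.copy(), extent * np.array([0.42, 0.42, 0.48]))

    n_ptvs = int(rng.integers(cfg.n_ptvs_range[0], cfg.n_ptvs_range[1] + 1))
    ptvs = []
    ptv_radius = float(np.clip(0.11 * extent.min(), 2.5 * sp, 0.2 * extent.min()))
    for i in range(n_ptvs):
        c = center + rng.normal(0, 0.04, 3) * extent
        radii = ptv_radius * rng.uniform(0.8, 1.2, 3)
        rx = float(rng.uniform(*cfg.prescription_range_gy))
        ptvs.append((_Ellipsoid(c, radii), rx))

    # OARs sit adjacent to the (first) target, in anatomically-inspired
    # directions, so their dose is governed by the falloff/sparing model
    directions = {
        "spinal_cord": np.array([0.0, 1.0, 0.0]),
        "brainstem": np.array([0.0, 0.7, 0.7]),
        "parotid_l": np.array([-1.0, 0.0, 0.2]),
        "parotid_r": np.array([1.0, 0.0, 0.2]),
        "submandibular_l": np.array([-0.7, -0.7, -0.2]),
        "submandibular_r": np.array([0.7, -0.7, -0.2]),
        "oral_cavity": np.array([0.0, -1.0, 0.0]),
        "larynx": np.array([0.0, -0.6, -0.8]),
    }
    ptv_c = ptvs[0][0].center_mm
    ptv_r = float(ptvs[0][0].radii_mm.mean())
    oars = {}
    for i, name in enumerate(cfg.oar_subset):
        u = directions.get(name)
        if u is None:  # spread unknown structures around the axial plane
            ang = 2 * np.pi * (i / max(len(cfg.oar_subset), 1))
            u = np.array([np.cos(ang), np.sin(ang), 0.0])
        u = u / np.linalg.norm(u)
        if name == "spinal_cord":
            radii = np.array([1.5 * sp, 1.5 * sp, 0.45 * extent[2]])
        else:
            radii = np.clip(rng.uniform(0.11, 0.15, 3) * extent.min(), sp, None)
        gap = float(rng.uniform(2.0, 6.0))
        c = ptv_c + u * (ptv_r + gap + float(radii[:2].mean()))
        if name in ("spinal_cord",):
            c[2] = center[2]
        # keep the structure inside the body envelope
        rel = (c - body.center_mm) / (0.9 * body.radii_mm)
        norm = np.linalg.norm(rel)
        if norm > 1.0:
            c = body.center_mm + (c - body.center_mm) / norm
        oars[name] = _Ellipsoid(c, radii * rng.uniform(0.9, 1.1, 3))

    return _Geometry(
        body=body, ptvs=ptvs, oars=oars,
        ct_noise_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _rasterize_session(
    geom: _Geometry, cfg: PhantomConfig, kind: str, patient_id: str
) -> PlanSession:
    coords = _coords_mm(cfg.grid_shape, cfg.spacing_mm)
    body = _rasterize(geom.body, coords)
    if not body.any():
        raise ValueError("grid too small: body ellipsoid rasterized empty")

    ptv_pairs = []
    for e, rx in geom.ptvs:
        mask = _rasterize(e, coords) & body
        if not mask.any():
            raise ValueError("PTV fell outside the body; grid too small")
        ptv_pairs.append((mask, rx))
    ptv_map = merge_ptvs(ptv_pairs)

    masks = {"body": body}
    for name, e in geom.oars.items():
        masks[name] = _rasterize(e, coords) & body

    nrng = np.random.default_rng(geom.ct_noise_seed)
    texture = ndimage.gaussian_filter(nrng.normal(0, 1, cfg.grid_shape), sigma=2.0)
    texture *= 30.0 / max(texture.std(), 1e-9)
    ct = np.where(body > 0, 40.0 + texture, -1000.0).astype(np.float32)

    return PlanSession(
        session_kind=kind,
        ct=ct,
        oar_masks=masks,
        ptv_map=ptv_map,
        spacing=(cfg.spacing_mm,) * 3,
        patient_id=patient_id,
    )


def generate_anatomy(
    cfg: PhantomConfig, rng: np.random.Generator, patient_id: str = "phantom",
    kind: str = PRETREATMENT,
) -> PlanSession:
    """Sample one synthetic anatomy (no dose)."""
    return _rasterize_session(_sample_geometry(cfg, rng), cfg, kind, patient_id)


def synthesize_dose(
    anatomy: PlanSession,
    profile: SparingProfile,
    cfg: PhantomConfig,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Analytic planning dose for an anatomy under a sparing profile (Gy)."""
    ptv_map = anatomy.ptv_map
    in_ptv = ptv_map > 0
    if not in_ptv.any():
        raise ValueError("anatomy has no PTV; cannot synthesize a dose")
    sp = anatomy.spacing
    lam = cfg.falloff_scale_mm

    d_ptv, indices = ndimage.distance_transform_edt(
        ~in_ptv, sampling=sp, return_indices=True
    )
    p_near = ptv_map[tuple(indices)]  # nearest PTV's prescription level
    dose = np.where(in_ptv, ptv_map, p_near * np.exp(-d_ptv / lam))

    for name, sigma in profile.strengths.items():
        if sigma <= 0:
            continue
        mask = anatomy.oar_masks.get(name)
        if mask is None or not mask.any():
            continue
        d_o = ndimage.distance_transform_edt(mask == 0, sampling=sp)
        factor = 1.0 - sigma * np.exp(-d_o / lam)
        # target coverage is preserved: sparing attenuates only outside the PTV
        dose = np.where(in_ptv, dose, dose * factor)

    if noise_rng is not None and cfg.noise_amplitude_gy > 0:
        noise = ndimage.gaussian_filter(noise_rng.normal(0, 1, dose.shape), sigma=2.0)
        noise *= cfg.noise_amplitude_gy / max(noise.std(), 1e-9)
        dose = dose + noise

    return np.clip(dose, 0.0, None).astype(np.float32)


def sample_sparing_profile(
    cfg: PhantomConfig, rng: np.random.Generator
) -> SparingProfile:
    lo, hi = cfg.sparing_strength_range
    strengths = {
        name: float(rng.uniform(lo, hi))
        for name in cfg.oar_subset
        if name != "body"
    }
    return SparingProfile(strengths)


def _deform_geometry(
    geom: _Geometry, cfg: PhantomConfig, rng: np.random.Generator
) -> _Geometry:
    shrink = float(rng.uniform(*cfg.ptv_shrink_range))
    sigma = cfg.structure_shift_sigma_mm
    # targets shrink in place; organs shift (and glands lose volume)
    ptvs = [(e.scaled(shrink), rx) for e, rx in geom.ptvs]
    oars = {}
    for name, e in geom.oars.items():
        d = e.shifted(rng.normal(0, sigma, 3))
        if name in _GLANDS:
            d = d.scaled(float(rng.uniform(*cfg.gland_shrink_range)))
        oars[name] = d
    return _Geometry(
        body=geom.body, ptvs=ptvs, oars=oars,
        ct_noise_seed=geom.ct_noise_seed,
    )


def generate_plan_pair(
    cfg: PhantomConfig, rng: np.random.Generator, patient_id: str = "phantom"
) -> PlanPair:
    """One patient: pre-treatment plan plus a deformed adaptive session,
    both dosed under the same latent sparing profile."""
    geom = _sample_geometry(cfg, rng)
    profile = sample_sparing_profile(cfg, rng)

    pre = _rasterize_session(geom, cfg, PRETREATMENT, patient_id)
    pre.dose = synthesize_dose(pre, profile, cfg, noise_rng=rng)
    pre.validate()

    last_err: Exception | None = None
    for _ in range(cfg.max_deform_attempts):
        try:
            adaptive = _rasterize_session(
                _deform_geometry(geom, cfg, rng), cfg, ADAPTIVE, patient_id
            )
            break
        except ValueError as err:  # deformation pushed a structure out of the body
            last_err = err
    else:
        raise ValueError(
            f"{patient_id}: deformation failed after {cfg.max_deform_attempts} attempts"
        ) from last_err
    adaptive.dose = synthesize_dose(adaptive, profile, cfg, noise_rng=rng)
    adaptive.validate()
    return PlanPair(pre=pre, adaptive=adaptive, patient_id=patient_id)


def generate_cohort(
    n_patients: int,
    cfg: PhantomConfig,
    seed: int,
    out_dir=None,
) -> list[PlanPair]:
    """Independent synthetic patients with per-patient derived seeds.

    With ``out_dir`` set, writes ``<pid>_pre.npz`` / ``<pid>_adaptive.npz``
    session bundles plus a cohort manifest.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    pairs = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_patients)):
        rng = np.random.default_rng(ss)
        pairs.append(generate_plan_pair(cfg, rng, patient_id=f"P{i:03d}"))
    if out_dir is not None:
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pair in pairs:
            save_session(pair.pre, out / f"{pair.patient_id}_pre.npz")
            save_session(pair.adaptive, out / f"{pair.patient_id}_adaptive.npz")
        (out / "cohort.json").write_text(
            json.dumps(
                {"seed": seed, "n_patients": n_patients,
                 "patients": [p.patient_id for p in pairs]},
                indent=2,
            )
        )
    return pairs


def load_cohort(path) -> list[PlanPair]:
    """Reload a cohort written by :func:`generate_cohort`."""
    import json
    from pathlib import Path

    from .volume_io import load_session

    path = Path(path)
    manifest = json.loads((path / "cohort.json").read_text())
    pairs = []
    for pid in manifest["patients"]:
        pre = load_session(path / f"{pid}_pre.npz")
        adaptive = load_session(path / f"{pid}_adaptive.npz")
        pairs.append(PlanPair(pre=pre, adaptive=adaptive, patient_id=pid))
    return pairs
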