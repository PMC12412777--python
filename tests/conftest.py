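"""Shared fixtures: small synthetic sessions built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from adaptdose.session import ADAPTIVE, PRETREATMENT, PlanSession


def make_session(
    shape=(12, 12, 10),
    spacing=(5.0, 5.0, 5.0),
    kind=PRETREATMENT,
    with_dose=True,
    seed=0,
    patient_id="T000",
):
    """A tiny valid session: spherical PTV, two box OARs, noisy CT."""
    rng = np.random.default_rng(seed)
    ct = rng.normal(0.0, 50.0, shape).astype(np.float32)
    zz = np.indices(shape)
    center = [s // 2 for s in shape]
    r2 = sum((z - c) ** 2 for z, c in zip(zz, center))
    ptv_mask = (r2 <= 9).astype(np.uint8)
    ptv_map = (60.0 * ptv_mask).astype(np.float32)
    masks = {
        "body": np.ones(shape, dtype=np.uint8),
        "spinal_cord": np.zeros(shape, dtype=np.uint8),
        "parotid_l": np.zeros(shape, dtype=np.uint8),
    }
    masks["spinal_cord"][center[0], center[1] + 3 :, :] = 1
    masks["parotid_l"][: center[0] - 3, center[1], center[2]] = 1
    dose = None
    if with_dose:
        dose = np.clip(
            60.0 * np.exp(-np.sqrt(r2) / 4.0) + rng.normal(0, 0.5, shape), 0, None
        ).astype(np.float32)
    return PlanSession(
        session_kind=kind,
        ct=ct,
        oar_masks=masks,
        ptv_map=ptv_map,
        dose=dose,
        spacing=spacing,
        patient_id=patient_id,
    )


@pytest.fixture
def session():
    return make_session()


@pytest.fixture
def adaptive_session():
    return make_session(kind=ADAPTIVE, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
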