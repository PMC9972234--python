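"""Shared fixtures: tiny volumes and a streamed full-size synthetic cohort.

The full cohort fixture is session-scoped because the label-recovery
checks and the sampling checks share it; bundles are processed one at a
time and discarded to keep memory flat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chronact.image_core import LabelVolume
from chronact.prl_pipeline import PrlConfig
from chronact.sel_pipeline import SelConfig
from chronact.synthetic_cohort import (
    SimulationConfig,
    clinical_frames,
    ground_truth_frame,
    iter_cohort,
)
from chronact.workbench import process_bundle


def affine_iso(spacing: float = 1.0) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = spacing
    return a


@pytest.fixture
def unit_affine() -> np.ndarray:
    return affine_iso(1.0)


@pytest.fixture
def cube_labels(unit_affine) -> LabelVolume:
    """A 5x5x5 cube lesion (id 1) centred in a 9^3 grid."""
    labels = np.zeros((9, 9, 9), dtype=np.int32)
    labels[2:7, 2:7, 2:7] = 1
    return LabelVolume(labels=labels, affine=unit_affine)


@pytest.fixture(scope="session")
def full_cohort():
    """Default 61-patient cohort: detections merged with ground truth.

    Returns (lesions_with_truth, patients_df, visits_df). This is the
    expensive fixture (~30 s); everything needing the default cohort at
    seed 1 shares it.
    """
    cfg = SimulationConfig()
    sel_cfg, prl_cfg = SelConfig(), PrlConfig()
    frames, truth_frames, clinical_bundles = [], [], []
    for bundle in iter_cohort(cfg, seed=1):
        frames.append(process_bundle(bundle, sel_cfg, prl_cfg))
        truth_frames.append(ground_truth_frame([bundle]))
        clinical_bundles.append(bundle)
        bundle.flair_field = None  # free the big arrays as we go
        bundle.swi = None
        bundle.labels = None
    lesions = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    merged = lesions.merge(
        truth, on=["patient_id", "lesion_id"], suffixes=("", "_true")
    )
    patients, visits = clinical_frames(clinical_bundles)
    return merged, patients, visits
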