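"""Per-lesion expansion summarisation and SEL classification.

A lesion qualifies for analysis when its baseline volume exceeds
10 mm^3 (strict inequality). Expansion is measured as the mean Jacobian
determinant over the lesion's voxels; the mean log-Jacobian divided by the
follow-up time in years gives an annualised expansion rate, which is then
z-scored across the patient's eligible lesions so that patients with
different follow-up intervals remain comparable. Lesions are classified
NON_SEL / POSSIBLE_SEL / DEFINITE_SEL; "combined SEL" means any non-NON_SEL
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from chronact.image_core import LabelVolume, ScalarVolume

#: lesions at or below this baseline volume are never classified
VOLUME_THRESHOLD_MM3 = 10.0


class SelClass(str, Enum):
    NON_SEL = "NON_SEL"
    POSSIBLE_SEL = "POSSIBLE_SEL"
    DEFINITE_SEL = "DEFINITE_SEL"


@dataclass
class SelConfig:
    """Thresholds for SEL classification (all config-exposed).

    tau_abs: minimum annualised mean log-Jacobian (per year) for any SEL.
    z_pos / z_def: z-score cuts for the possible / definite categories.
    zscore_scope: "patient" normalises within each patient's eligible
    lesions (default); "cohort" normalises across all lesions passed in.
    """

    tau_abs: float = 0.002
    z_pos: float = 0.5
    z_def: float = 1.0
    zscore_scope: str = "patient"
    smooth_sigma: float = 0.0


@dataclass
class LesionJacobianStats:
    """Expansion summary for one eligible lesion."""

    lesion_id: int
    volume_mm3: float
    mean_J: float
    annualized_logJ: float
    z_J: Optional[float] = None
    sel_class: Optional[SelClass] = None
    z_fallback: bool = field(default=False)

    @property
    def is_sel(self) -> bool:
        return self.sel_class is not None and self.sel_class != SelClass.NON_SEL


def eligible_lesions(labels: LabelVolume) -> List[int]:
    """Lesion ids whose volume (voxel count x voxel volume) exceeds 10 mm^3."""
    vv = labels.voxel_volume_mm3
    ids = []
    flat = labels.labels.ravel()
    counts = np.bincount(flat[flat > 0])
    for k in np.nonzero(counts)[0]:
        if counts[k] * vv > VOLUME_THRESHOLD_MM3:
            ids.append(int(k))
    return sorted(ids)


def summarize_jacobian(
    labels: LabelVolume,
    J: ScalarVolume,
    follow_up_years: float,
) -> List[LesionJacobianStats]:
    """Per eligible lesion: mean J and annualised mean log J.

    Raises if J is non-positive inside any eligible lesion (a
    non-diffeomorphic field) or if the lattices disagree.
    """
    if follow_up_years <= 0:
        raise ValueError("follow_up_years must be positive")
    if labels.shape != J.shape:
        raise ValueError("labels and Jacobian volume are on different lattices")
    vv = labels.voxel_volume_mm3
    out: List[LesionJacobianStats] = []
    for lesion_id in eligible_lesions(labels):
        mask = labels.labels == lesion_id
        vals = J.data[mask]
        if np.any(vals <= 0):
            raise ValueError(
                f"lesion {lesion_id}: Jacobian <= 0 inside lesion "
                "(non-diffeomorphic field)"
            )
        out.append(
            LesionJacobianStats(
                lesion_id=lesion_id,
                volume_mm3=float(mask.sum() * vv),
                mean_J=float(vals.mean()),
                annualized_logJ=float(np.mean(np.log(vals)) / follow_up_years),
            )
        )
    return out


def zscore_normalize(
    stats: Sequence[LesionJacobianStats],
) -> List[LesionJacobianStats]:
    """Z-score the annualised log-Jacobians across a patient's lesions.

    With fewer than two lesions, or a degenerate (zero) spread, the z-score
    is undefined: classification falls back to the absolute threshold alone
    and the lesions are flagged (``z_fallback``).
    """
    vals = np.array([s.annualized_logJ for s in stats], dtype=float)
    if len(vals) < 2 or np.std(vals, ddof=1) == 0:
        return [replace(s, z_J=None, z_fallback=True) for s in stats]
    mean = vals.mean()
    sd = np.std(vals, ddof=1)
    return [
        replace(s, z_J=float((v - mean) / sd), z_fallback=False)
        for s, v in zip(stats, vals)
    ]


def classify_sel(
    stats: Sequence[LesionJacobianStats],
    config: SelConfig | None = None,
) -> List[LesionJacobianStats]:
    """Assign NON_SEL / POSSIBLE_SEL / DEFINITE_SEL to each lesion.

    DEFINITE requires annualised log J >= tau_abs and z >= z_def; POSSIBLE
    requires annualised log J >= tau_abs and z_def > z >= z_pos. Lesions on
    the z fallback path use the absolute threshold only (classified
    POSSIBLE when it is met). The partition is exhaustive and exclusive.
    """
    cfg = config or SelConfig()
    out: List[LesionJacobianStats] = []
    for s in stats:
        passes_abs = s.annualized_logJ >= cfg.tau_abs
        if s.z_J is None:
            cls = SelClass.POSSIBLE_SEL if passes_abs else SelClass.NON_SEL
        elif passes_abs and s.z_J >= cfg.z_def:
            cls = SelClass.DEFINITE_SEL
        elif passes_abs and s.z_J >= cfg.z_pos:
            cls = SelClass.POSSIBLE_SEL
        else:
            cls = SelClass.NON_SEL
        out.append(replace(s, sel_class=cls))
    return out


def detect_sels(
    labels: LabelVolume,
    J: ScalarVolume,
    follow_up_years: float,
    config: SelConfig | None = None,
) -> List[LesionJacobianStats]:
    """Full per-patient pass: summarise, z-score, classify."""
    stats = summarize_jacobian(labels, J, follow_up_years)
    return classify_sel(zscore_normalize(stats), config)


def stats_to_frame(stats: Sequence[LesionJacobianStats]) -> pd.DataFrame:
    """Tidy one-row-per-lesion table of LesionJacobianStats."""
    return pd.DataFrame(
        {
            "lesion_id": [s.lesion_id for s in stats],
            "volume_mm3": [s.volume_mm3 for s in stats],
            "mean_J": [s.mean_J for s in stats],
            "annualized_logJ": [s.annualized_logJ for s in stats],
            "z_J": [math.nan if s.z_J is None else s.z_J for s in stats],
            "sel_class": [s.sel_class.value if s.sel_class else "" for s in stats],
            "is_sel": [s.is_sel for s in stats],
            "z_fallback": [s.z_fallback for s in stats],
        }
    )
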