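"""Ground-truthed synthetic longitudinal cohort generator.

Each synthetic patient gets:

* a 1 mm isotropic anatomical lattice holding the lesion label volume and
  FLAIR-like / T1-like intensity volumes (lesions are mildly deformed
  ellipsoids with closed-form volumes);
* an analytic displacement field from baseline to the final scan whose
  restriction to every true slowly-expanding lesion is a pure dilation
  (plateau extending two voxels past the lesion boundary, then a C1
  smoothstep taper to identity), so the Jacobian determinant inside the
  lesion is exactly the cube of the total growth factor;
* an anisotropic susceptibility-like volume (0.65 x 0.65 x 3 mm) where a
  known subset of lesions carries a hypointense boundary rim and tubular
  vein confounders cross the white matter;
* a clinical record whose EDSS trajectory slope depends on the patient's
  SEL/rim stratum, with optional rounding onto the 0.5-step EDSS grid.

Everything stochastic is reproducible from the top-level seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from chronact.cohort_stats import Stratum, assign_stratum
from chronact.image_core import (
    Channel,
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    write_volume,
)

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

EDSS_GRID_MAX = 10.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults target the study's marginals."""

    n_patients: int = 61
    # lesion counts: negative binomial, median near 20, clipped to [1, 80]
    lesion_count_mean: float = 24.0
    lesion_count_dispersion: float = 2.2
    lesion_count_max: int = 80
    # lesion-level class fractions
    sel_fraction: float = 0.41
    prl_given_sel: float = 0.07
    prl_given_nonsel: float = 0.04
    # geometry (mm)
    anat_shape: Tuple[int, int, int] = (96, 96, 96)
    anat_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    swi_spacing: Tuple[float, float, float] = (0.65, 0.65, 3.0)
    lesion_radius_range: Tuple[float, float] = (2.0, 4.0)
    prl_radius_range: Tuple[float, float] = (4.5, 6.5)
    axis_jitter: float = 0.12  # relative ellipsoid semi-axis jitter
    gm_slab_mm: float = 10.0  # grey-matter-like slab along axis 0
    # expansion
    growth_rate_range: Tuple[float, float] = (1.03, 1.05)  # per year
    field_plateau_mm: float = 2.0
    field_taper_rho: float = 2.0
    # susceptibility channel
    wm_mean: float = 100.0
    gm_mean: float = 80.0
    lesion_swi_mean: float = 108.0
    noise_sd: float = 5.0
    rim_contrast_sd: float = 3.0
    rim_coverage: float = 0.95
    n_veins: int = 3
    vein_width_mm: float = 0.9
    vein_intensity: float = 82.0
    # anatomical channels
    flair_wm: float = 100.0
    flair_gm: float = 110.0
    flair_lesion: float = 160.0
    t1_wm: float = 120.0
    t1_gm: float = 90.0
    t1_lesion: float = 60.0
    # clinical
    follow_up_range: Tuple[float, float] = (0.7, 8.3)
    edss_slopes: Dict[str, float] = field(
        default_factory=lambda: {
            Stratum.SEL_PRL_BOTH.value: 0.15,
            Stratum.SEL_ONLY.value: -0.02,
            Stratum.SEL_NEG.value: -0.11,
        }
    )
    edss_noise_sd: float = 0.35
    edss_round_to_grid: bool = True
    female_fraction: float = 0.69
    treated_end_fraction: float = 0.84
    relapse_rate_per_year: float = 0.25
    # brain-volume covariates (means/SDs from the cohort's summary table)
    nbv_mean_sd: Tuple[float, float] = (1505.7, 75.1)
    cgm_mean_sd: Tuple[float, float] = (839.9, 47.9)
    dgm_mean_sd: Tuple[float, float] = (49.4, 3.7)
    bpf_mean_sd: Tuple[float, float] = (0.77, 0.02)

    def validate(self) -> None:
        for name in ("sel_fraction", "prl_given_sel", "prl_given_nonsel",
                     "rim_coverage", "female_fraction", "treated_end_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.anat_spacing) <= 0 or min(self.swi_spacing) <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.growth_rate_range[0] < 1.0:
            raise ValueError("growth rates must be >= 1 (expansion)")
        if self.follow_up_range[0] <= 0:
            raise ValueError("follow-up times must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("anat_shape", "anat_spacing", "swi_spacing",
                    "lesion_radius_range", "prl_radius_range",
                    "growth_rate_range", "follow_up_range",
                    "nbv_mean_sd", "cgm_mean_sd", "dgm_mean_sd", "bpf_mean_sd"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class LesionTruth:
    lesion_id: int
    center: np.ndarray  # world mm
    semi_axes: np.ndarray  # world mm
    volume_mm3: float  # analytic 4/3 pi abc
    true_sel: bool
    true_prl: bool
    growth_rate_annual: float  # 1.0 for non-SELs
    growth_total: float  # growth_rate ** follow_up_years
    rim_coverage: float


@dataclass
class PatientBundle:
    """Everything the pipelines need for one synthetic patient."""

    patient_id: int
    labels: LabelVolume
    flair_field: DisplacementField
    swi: ScalarVolume
    lesions: List[LesionTruth]
    follow_up_years: float
    clinical: Dict[str, object]
    visits: List[Tuple[float, float]]
    flair: Optional[ScalarVolume] = None
    t1_baseline: Optional[ScalarVolume] = None
    t1_followups: Optional[List[ScalarVolume]] = None
    vein_mask: Optional[np.ndarray] = None

    @property
    def stratum(self) -> Stratum:
        has_sel = any(l.true_sel for l in self.lesions)
        has_prl = any(l.true_prl for l in self.lesions)
        return assign_stratum(has_sel, has_prl)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = spacing
    return a


def _voxel_centers_box(
    shape: Tuple[int, int, int],
    spacing: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> Tuple[Tuple[slice, slice, slice], np.ndarray]:
    """Index slices and world coordinates for a world-space bounding box."""
    lo_idx = np.maximum(np.floor(lo / spacing).astype(int), 0)
    hi_idx = np.minimum(np.ceil(hi / spacing).astype(int) + 1, np.array(shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
    axes = [np.arange(s.start, s.stop) * sp for s, sp in zip(sl, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return sl, grid


def _rho(grid_world: np.ndarray, center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    d = (grid_world - center) / semi_axes
    return np.sqrt(np.sum(d * d, axis=-1))


def _support_radius(semi_axes: np.ndarray, cfg: SimulationConfig) -> float:
    rho2 = 1.0 + cfg.field_plateau_mm / semi_axes.min() + cfg.field_taper_rho
    return float(semi_axes.max() * rho2)


def _place_lesions(
    rng: np.random.Generator, cfg: SimulationConfig, n_target: int
) -> List[LesionTruth]:
    """Rejection-sample non-interfering ellipsoids with class flags.

    A lesion may not intersect another lesion's displacement-field support,
    so non-expanding lesions keep an exactly-unit Jacobian. Placement
    failures shrink the realised count (recorded in ground truth).
    """
    extent = np.array(cfg.anat_shape) * np.array(cfg.anat_spacing)
    margin = 3.0
    placed: List[LesionTruth] = []
    centers: List[np.ndarray] = []
    for _ in range(n_target):
        true_sel = rng.random() < cfg.sel_fraction
        p_prl = cfg.prl_given_sel if true_sel else cfg.prl_given_nonsel
        true_prl = rng.random() < p_prl
        rad_range = cfg.prl_radius_range if true_prl else cfg.lesion_radius_range
        ok = False
        for _attempt in range(250):
            r = rng.uniform(*rad_range)
            axes = r * (1.0 + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter, size=3))
            support = _support_radius(axes, cfg) if true_sel else axes.max()
            lo = np.array([cfg.gm_slab_mm + margin + support, margin + support,
                           margin + support])
            hi = extent - margin - support
            if np.any(hi <= lo):
                continue
            center = rng.uniform(lo, hi)
            clear = True
            for other, c_other in zip(placed, centers):
                sup_other = (
                    _support_radius(other.semi_axes, cfg)
                    if other.true_sel
                    else other.semi_axes.max()
                )
                need = max(support + other.semi_axes.max(),
                           sup_other + axes.max()) + 2.0
                if np.linalg.norm(center - c_other) < need:
                    clear = False
                    break
            if clear:
                ok = True
                break
        if not ok:
            continue
        placed.append(
            LesionTruth(
                lesion_id=len(placed) + 1,
                center=center,
                semi_axes=axes,
                volume_mm3=float(4.0 / 3.0 * np.pi * np.prod(axes)),
                true_sel=true_sel,
                true_prl=true_prl,
                growth_rate_annual=1.0,
                growth_total=1.0,
                rim_coverage=0.0,
            )
        )
        centers.append(center)
    return placed


def radial_expansion_field(
    grid_world: np.ndarray,
    lesion: LesionTruth,
    scale_total: float,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Analytic compact-support dilation: u = (s-1) w(rho) (x - c).

    w = 1 on the plateau (lesion plus a two-voxel margin along its tightest
    axis), smoothsteps to 0 over ``field_taper_rho`` normalised-radius
    units, and is identically 0 outside — so the field is C1 and the
    Jacobian inside the lesion is exactly s^3.
    """
    rho = _rho(grid_world, lesion.center, lesion.semi_axes)
    rho1 = 1.0 + cfg.field_plateau_mm / lesion.semi_axes.min()
    rho2 = rho1 + cfg.field_taper_rho
    w = np.zeros_like(rho)
    w[rho <= rho1] = 1.0
    taper = (rho > rho1) & (rho < rho2)
    t = (rho[taper] - rho1) / (rho2 - rho1)
    w[taper] = 1.0 - (3.0 * t**2 - 2.0 * t**3)
    return (scale_total - 1.0) * w[..., None] * (grid_world - lesion.center)


# ---------------------------------------------------------------------------
# per-patient synthesis
# ---------------------------------------------------------------------------

def _paint_labels(
    lesions: Sequence[LesionTruth], cfg: SimulationConfig
) -> LabelVolume:
    shape = cfg.anat_shape
    spacing = np.array(cfg.anat_spacing)
    labels = np.zeros(shape, dtype=np.int32)
    for les in lesions:
        pad = les.semi_axes + spacing
        sl, grid = _voxel_centers_box(shape, spacing, les.center - pad, les.center + pad)
        inside = _rho(grid, les.center, les.semi_axes) <= 1.0
        labels[sl][inside] = les.lesion_id
    return LabelVolume(labels=labels, affine=_affine(cfg.anat_spacing))


def _build_field(
    lesions: Sequence[LesionTruth],
    follow_up_years: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> DisplacementField:
    shape = cfg.anat_shape
    spacing = np.array(cfg.anat_spacing)
    u = np.zeros(shape + (3,), dtype=float)
    for les in lesions:
        if not les.true_sel:
            continue
        g = rng.uniform(*cfg.growth_rate_range)
        les.growth_rate_annual = float(g)
        les.growth_total = float(g**follow_up_years)
        support = _support_radius(les.semi_axes, cfg) + spacing.max()
        sl, grid = _voxel_centers_box(
            shape, spacing, les.center - support, les.center + support
        )
        u[sl] += radial_expansion_field(grid, les, les.growth_total, cfg)
    return DisplacementField(vectors=u, affine=_affine(cfg.anat_spacing))


def _swi_lattice(cfg: SimulationConfig) -> Tuple[Tuple[int, int, int], np.ndarray]:
    extent = np.array(cfg.anat_shape) * np.array(cfg.anat_spacing)
    spacing = np.array(cfg.swi_spacing)
    shape = tuple(int(np.floor(e / s)) for e, s in zip(extent, spacing))
    return shape, spacing


def _analytic_mask_on_lattice(
    les: LesionTruth,
    shape: Tuple[int, int, int],
    spacing: np.ndarray,
) -> Tuple[Tuple[slice, slice, slice], np.ndarray]:
    pad = les.semi_axes + spacing
    sl, grid = _voxel_centers_box(shape, spacing, les.center - pad, les.center + pad)
    return sl, _rho(grid, les.center, les.semi_axes) <= 1.0


def _render_swi(
    lesions: Sequence[LesionTruth],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[ScalarVolume, np.ndarray]:
    shape, spacing = _swi_lattice(cfg)
    data = np.full(shape, cfg.wm_mean, dtype=float)
    gm_cols = int(round(cfg.gm_slab_mm / spacing[0]))
    data[:gm_cols] = cfg.gm_mean

    for les in lesions:
        sl, inside = _analytic_mask_on_lattice(les, shape, spacing)
        data[sl][inside] = cfg.lesion_swi_mean
        if les.true_prl:
            core = ndimage.binary_erosion(inside, structure=_STRUCT_6)
            shell = inside & ~core
            keep = rng.random(int(shell.sum())) < cfg.rim_coverage
            shell_idx = np.argwhere(shell)[keep]
            les.rim_coverage = float(keep.mean()) if len(keep) else 0.0
            box = data[sl]
            box[shell_idx[:, 0], shell_idx[:, 1], shell_idx[:, 2]] = (
                cfg.wm_mean - cfg.rim_contrast_sd * cfg.noise_sd
            )

    vein_mask = np.zeros(shape, dtype=bool)
    swi = ScalarVolume(data=data, affine=_affine(cfg.swi_spacing), channel=Channel.SWI)
    extent = np.array(shape) * spacing
    for v in range(cfg.n_veins):
        if lesions and v == 0:
            # route one vein through a random lesion: the designed confounder
            target = lesions[int(rng.integers(len(lesions)))]
            start = target.center + np.array([0.0, 0.0, -extent[2]])
            direction = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), 1.0])
        else:
            start = rng.uniform([cfg.gm_slab_mm, 0, 0], extent)
            direction = rng.normal(size=3)
        swi, mask = implant_vein(
            swi, _vein_path(start, direction, length_mm=2 * extent[2]),
            cfg.vein_width_mm, intensity=cfg.vein_intensity,
        )
        vein_mask |= mask
    noisy = swi.data + rng.normal(0.0, cfg.noise_sd, size=shape)
    return ScalarVolume(data=noisy, affine=swi.affine, channel=Channel.SWI), vein_mask


def _vein_path(
    start: np.ndarray, direction: np.ndarray, length_mm: float
) -> np.ndarray:
    direction = direction / np.linalg.norm(direction)
    ts = np.arange(0.0, length_mm, 0.3)
    return start + ts[:, None] * direction


def implant_vein(
    swi: ScalarVolume,
    path_points: np.ndarray,
    width_mm: float,
    intensity: float = 82.0,
) -> Tuple[ScalarVolume, np.ndarray]:
    """Darken a tube of the given width along a polyline path (world mm).

    Returns the modified volume and the tube's voxel mask. Width 0 leaves
    the volume unchanged.
    """
    mask = np.zeros(swi.shape, dtype=bool)
    if width_mm <= 0 or len(path_points) == 0:
        return swi, mask
    spacing = swi.spacing
    shape = np.array(swi.shape)
    half = width_mm / 2.0
    reach = np.maximum(np.ceil(half / spacing).astype(int), 0)
    offsets = np.stack(
        np.meshgrid(
            *[np.arange(-r, r + 1) for r in reach], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    off_world = offsets * spacing
    keep = np.linalg.norm(off_world, axis=1) <= max(half, float(spacing.min()) / 2)
    offsets = offsets[keep]
    centers = np.round(path_points / spacing).astype(int)
    centers = np.unique(centers, axis=0)
    vox = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    inside = np.all(vox >= 0, axis=1) & np.all(vox < shape, axis=1)
    vox = vox[inside]
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    data = swi.data.copy()
    data[mask] = intensity
    return ScalarVolume(data=data, affine=swi.affine, channel=swi.channel), mask


def _render_anatomy(
    lesions: Sequence[LesionTruth],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    follow_up_years: float,
    visit_times: Sequence[float],
) -> Tuple[ScalarVolume, ScalarVolume, List[ScalarVolume]]:
    shape = cfg.anat_shape
    spacing = np.array(cfg.anat_spacing)
    gm_cols = int(round(cfg.gm_slab_mm / spacing[0]))

    def render(channel: Channel, grow_to: float | None) -> ScalarVolume:
        wm, gm, les_val = {
            Channel.FLAIR: (cfg.flair_wm, cfg.flair_gm, cfg.flair_lesion),
            Channel.T1: (cfg.t1_wm, cfg.t1_gm, cfg.t1_lesion),
        }[channel]
        data = np.full(shape, wm, dtype=float)
        data[:gm_cols] = gm
        for les in lesions:
            axes = les.semi_axes
            if grow_to is not None and les.true_sel:
                axes = axes * les.growth_rate_annual**grow_to
            pad = axes + spacing
            sl, grid = _voxel_centers_box(
                shape, spacing, les.center - pad, les.center + pad
            )
            data[sl][_rho(grid, les.center, axes) <= 1.0] = les_val
        data += rng.normal(0.0, cfg.noise_sd, size=shape)
        return ScalarVolume(data=data, affine=_affine(cfg.anat_spacing),
                            channel=channel)

    flair = render(Channel.FLAIR, None)
    t1_base = render(Channel.T1, 0.0)
    followups = [render(Channel.T1, t) for t in visit_times if t > 0]
    return flair, t1_base, followups


# ---------------------------------------------------------------------------
# clinical trajectories
# ---------------------------------------------------------------------------

def _round_to_edss_grid(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 2.0) / 2.0, 0.0, EDSS_GRID_MAX)


def _draw_baseline_edss(rng: np.random.Generator) -> float:
    # discrete grid 0..4.5 peaked near 1.5 (cohort median), range as reported
    grid = np.arange(0.0, 5.0, 0.5)
    weights = np.exp(-0.5 * ((grid - 1.5) / 1.2) ** 2)
    return float(rng.choice(grid, p=weights / weights.sum()))


def simulate_edss(
    stratum: Stratum,
    slopes: Dict[str, float],
    noise_sd: float,
    visit_times: Sequence[float],
    baseline_edss: float,
    rng: np.random.Generator,
    round_to_grid: bool = True,
) -> List[Tuple[float, float]]:
    """EDSS series: baseline + stratum slope * t + noise, on the 0.5 grid.

    With ``round_to_grid`` off the raw continuous values are returned
    (used by noiseless identifiability checks).
    """
    times = np.asarray(visit_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("visit times must be increasing")
    slope = slopes[stratum.value]
    vals = baseline_edss + slope * times + rng.normal(0.0, noise_sd, size=len(times))
    if round_to_grid:
        vals = _round_to_edss_grid(vals)
    return list(zip(times.tolist(), vals.tolist()))


def _draw_visit_times(rng: np.random.Generator, cfg: SimulationConfig) -> List[float]:
    final = float(rng.uniform(*cfg.follow_up_range))
    mid = float(rng.uniform(0.35, max(0.4, min(1.5, 0.9 * final))))
    times = [0.0, mid, final, final + 0.5]  # last visit confirms progression
    return sorted(times)


def _draw_demographics(rng: np.random.Generator, cfg: SimulationConfig) -> Dict:
    return {
        "age_baseline": float(np.clip(rng.normal(36.0, 10.0), 14.0, 65.0)),
        "sex": "F" if rng.random() < cfg.female_fraction else "M",
        "disease_duration": float(min(rng.lognormal(np.log(0.4), 1.0), 16.6)),
        "treated_end": bool(rng.random() < cfg.treated_end_fraction),
        "nbv": float(rng.normal(*cfg.nbv_mean_sd)),
        "cgm": float(rng.normal(*cfg.cgm_mean_sd)),
        "dgm": float(rng.normal(*cfg.dgm_mean_sd)),
        "bpf": float(rng.normal(*cfg.bpf_mean_sd)),
    }


def _draw_lesion_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    r = cfg.lesion_count_dispersion
    p = r / (r + cfg.lesion_count_mean)
    n = int(rng.negative_binomial(r, p))
    return int(np.clip(n, 1, cfg.lesion_count_max))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_patient(
    cfg: SimulationConfig,
    patient_id: int,
    seed_seq: np.random.SeedSequence,
    render_anatomy: bool = True,
) -> PatientBundle:
    """Synthesize one patient (deterministic given the seed sequence)."""
    rng = np.random.default_rng(seed_seq)
    n_lesions = _draw_lesion_count(rng, cfg)
    lesions = _place_lesions(rng, cfg, n_lesions)
    visit_times = _draw_visit_times(rng, cfg)
    follow_up_years = visit_times[-2]  # final scan; last visit is confirmation

    labels = _paint_labels(lesions, cfg)
    fld = _build_field(lesions, follow_up_years, cfg, rng)
    swi, vein_mask = _render_swi(lesions, cfg, rng)

    has_sel = any(l.true_sel for l in lesions)
    has_prl = any(l.true_prl for l in lesions)
    stratum = assign_stratum(has_sel, has_prl)
    demo = _draw_demographics(rng, cfg)
    baseline_edss = _draw_baseline_edss(rng)
    visits = simulate_edss(
        stratum, cfg.edss_slopes, cfg.edss_noise_sd, visit_times,
        baseline_edss, rng, round_to_grid=cfg.edss_round_to_grid,
    )
    relapse_count = int(rng.poisson(cfg.relapse_rate_per_year * follow_up_years))

    clinical = {
        "patient_id": patient_id,
        **demo,
        "relapse_count": relapse_count,
        "relapse_rate": relapse_count / follow_up_years,
        "follow_up_years": follow_up_years,
        "baseline_edss": baseline_edss,
        "stratum_true": stratum.value,
        "n_lesions": len(lesions),
    }

    flair = t1_base = None
    followups: Optional[List[ScalarVolume]] = None
    if render_anatomy:
        flair, t1_base, followups = _render_anatomy(
            lesions, cfg, rng, follow_up_years, visit_times[1:-1]
        )
    return PatientBundle(
        patient_id=patient_id,
        labels=labels,
        flair_field=fld,
        swi=swi,
        lesions=lesions,
        follow_up_years=follow_up_years,
        clinical=clinical,
        visits=visits,
        flair=flair,
        t1_baseline=t1_base,
        t1_followups=followups,
        vein_mask=vein_mask,
    )


def iter_cohort(
    cfg: SimulationConfig,
    seed: int,
    render_anatomy: bool = False,
) -> Iterator[PatientBundle]:
    """Stream patient bundles without touching disk."""
    cfg.validate()
    children = np.random.SeedSequence(seed).spawn(cfg.n_patients)
    for pid, child in enumerate(children, start=1):
        yield generate_patient(cfg, pid, child, render_anatomy=render_anatomy)


def ground_truth_frame(bundles: Sequence[PatientBundle]) -> pd.DataFrame:
    rows = []
    for b in bundles:
        for l in b.lesions:
            rows.append(
                {
                    "patient_id": b.patient_id,
                    "lesion_id": l.lesion_id,
                    "volume_mm3": l.volume_mm3,
                    "true_sel": l.true_sel,
                    "true_prl": l.true_prl,
                    "growth_rate_annual": l.growth_rate_annual,
                    "growth_total": l.growth_total,
                    "rim_coverage": l.rim_coverage,
                }
            )
    return pd.DataFrame(rows)


def clinical_frames(
    bundles: Sequence[PatientBundle],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level table and long per-visit EDSS table."""
    patients = pd.DataFrame([b.clinical for b in bundles])
    visit_rows = []
    for b in bundles:
        for t, e in b.visits:
            visit_rows.append({"patient_id": b.patient_id, "time": t, "edss": e})
    return patients, pd.DataFrame(visit_rows)


def simulate_clinical_cohort(
    cfg: SimulationConfig, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical-only cohort (no images): lesion class flags are drawn
    per lesion exactly as in the full generator, but no geometry is placed.

    Used for statistics-level recovery studies where rendering volumes for
    hundreds of cohorts would be wasteful.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    patient_rows = []
    visit_rows = []
    for pid in range(1, cfg.n_patients + 1):
        n = _draw_lesion_count(rng, cfg)
        sel_flags = rng.random(n) < cfg.sel_fraction
        p_prl = np.where(sel_flags, cfg.prl_given_sel, cfg.prl_given_nonsel)
        prl_flags = rng.random(n) < p_prl
        stratum = assign_stratum(bool(sel_flags.any()), bool(prl_flags.any()))
        visit_times = _draw_visit_times(rng, cfg)
        demo = _draw_demographics(rng, cfg)
        baseline = _draw_baseline_edss(rng)
        visits = simulate_edss(
            stratum, cfg.edss_slopes, cfg.edss_noise_sd, visit_times,
            baseline, rng, round_to_grid=cfg.edss_round_to_grid,
        )
        follow_up = visit_times[-2]
        relapses = int(rng.poisson(cfg.relapse_rate_per_year * follow_up))
        patient_rows.append(
            {
                "patient_id": pid,
                **demo,
                "relapse_count": relapses,
                "relapse_rate": relapses / follow_up,
                "follow_up_years": follow_up,
                "baseline_edss": baseline,
                "stratum": stratum.value,
                "has_sel": bool(sel_flags.any()),
                "has_prl": bool(prl_flags.any()),
                "sel_count": int(sel_flags.sum()),
                "prl_count": int(prl_flags.sum()),
                "n_lesions": n,
            }
        )
        for t, e in visits:
            visit_rows.append({"patient_id": pid, "time": t, "edss": e})
    return pd.DataFrame(patient_rows), pd.DataFrame(visit_rows)


def generate_cohort(cfg: SimulationConfig, out_dir: Path, seed: int) -> Path:
    """Write per-patient NIfTI bundles, clinical.csv, ground_truth.csv and
    the resolved config; byte-deterministic given the seed."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles = list(iter_cohort(cfg, seed, render_anatomy=True))
    for b in bundles:
        pdir = out_dir / f"patient_{b.patient_id:03d}"
        pdir.mkdir(exist_ok=True)
        write_volume(b.labels, pdir / "labels.nii.gz")
        write_volume(b.flair_field, pdir / "field.nii.gz")
        write_volume(b.swi, pdir / "swi.nii.gz")
        if b.flair is not None:
            write_volume(b.flair, pdir / "flair.nii.gz")
        if b.t1_baseline is not None:
            write_volume(b.t1_baseline, pdir / "t1_baseline.nii.gz")
        for i, t1 in enumerate(b.t1_followups or [], start=1):
            write_volume(t1, pdir / f"t1_followup_{i}.nii.gz")
    patients, visits = clinical_frames(bundles)
    patients.to_csv(out_dir / "clinical.csv", index=False)
    visits.to_csv(out_dir / "visits.csv", index=False)
    ground_truth_frame(bundles).to_csv(out_dir / "ground_truth.csv", index=False)
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({"seed": seed, **cfg.to_dict()}, fh, sort_keys=True)
    return out_dir
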