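"""End-to-end orchestration: simulate -> detect -> analyze, with manifests.

``run_all`` chains the whole pipeline in memory and writes tidy CSV/JSON
artifacts plus a run manifest. Reruns with the same seed reproduce every
CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from chronact import __version__
from chronact.cohort_stats import (
    ModelResult,
    Stratum,
    cdp_flag,
    cohort_summary,
    crosstab_sel_prl,
    fit_cdp_logistic,
    fit_count_and_volume_models,
    fit_edss_mixed,
    spearman_corr,
    stratify_patients,
)
from chronact.image_core import jacobian_determinant, resample_labels_nn
from chronact.prl_pipeline import PrlConfig, classify_prls, scores_to_frame
from chronact.sel_pipeline import SelConfig, detect_sels, stats_to_frame
from chronact.synthetic_cohort import (
    PatientBundle,
    SimulationConfig,
    clinical_frames,
    ground_truth_frame,
    iter_cohort,
)

logger = logging.getLogger("chronact")


@dataclass
class RunManifest:
    """Provenance of one pipeline run (exactly one per output directory)."""

    command: str
    config_hash: str
    seed: Optional[int]
    inputs: List[str]
    outputs: List[str]
    version: str = __version__
    timestamp: str = ""

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def config_hash(*configs) -> str:
    blob = json.dumps(
        [dataclasses.asdict(c) for c in configs], sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_bundle(
    bundle: PatientBundle,
    sel_cfg: SelConfig,
    prl_cfg: PrlConfig,
) -> pd.DataFrame:
    """Run SEL and rim detection for one patient; one row per scored lesion."""
    jac = jacobian_determinant(bundle.flair_field, smooth_sigma=sel_cfg.smooth_sigma)
    sel_stats = detect_sels(
        bundle.labels, jac, bundle.follow_up_years, sel_cfg
    )
    sel_df = stats_to_frame(sel_stats)
    labels_swi = resample_labels_nn(bundle.labels, bundle.swi)
    rim_df = scores_to_frame(
        classify_prls(bundle.swi, labels_swi, bundle.labels, prl_cfg)
    )
    merged = sel_df.merge(rim_df, on="lesion_id", how="outer")
    merged.insert(0, "patient_id", bundle.patient_id)
    # lesions under the volume threshold are never SELs
    merged["is_sel"] = merged["is_sel"].fillna(False).astype(bool)
    merged["is_prl"] = merged["is_prl"].fillna(False).astype(bool)
    for lesion_decision in merged.itertuples(index=False):
        logger.debug("lesion decision: %s", lesion_decision)
    return merged


def derive_patient_columns(
    patients: pd.DataFrame,
    lesions: pd.DataFrame,
    visits: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Fill in per-patient aggregates the statistics layer expects.

    Adds has_sel/has_prl flags, SEL and rim counts, total lesion volume and
    (when visits are given) the confirmed-progression flag — only where the
    columns are not already present.
    """
    patients = patients.copy()
    agg = {
        "has_sel": ("is_sel", "any"),
        "has_prl": ("is_prl", "any"),
        "sel_count": ("is_sel", "sum"),
        "prl_count": ("is_prl", "sum"),
    }
    if "volume_mm3" in lesions:
        agg["tlv_mm3"] = ("volume_mm3", "sum")
    missing = [c for c in agg if c not in patients.columns]
    if missing and len(lesions):
        per = lesions.groupby("patient_id").agg(**{c: agg[c] for c in missing})
        patients = patients.merge(per, on="patient_id", how="left")
    for col in ("has_sel", "has_prl"):
        if col in patients:
            patients[col] = (
                patients[col].astype("boolean").fillna(False).astype(bool)
            )
    for col in ("sel_count", "prl_count", "tlv_mm3"):
        if col in patients:
            patients[col] = patients[col].fillna(0)
    if "tlv_mm3" in patients and "log_tlv" not in patients:
        patients["log_tlv"] = np.log(patients["tlv_mm3"].clip(lower=1.0))
    if "cdp" not in patients and visits is not None and len(visits):
        flags = {
            pid: cdp_flag(list(zip(g["time"], g["edss"])))
            for pid, g in visits.sort_values("time").groupby("patient_id")
        }
        patients["cdp"] = patients["patient_id"].map(flags)
    return patients


def _patient_table(
    bundles: Sequence[PatientBundle], lesions: pd.DataFrame
) -> pd.DataFrame:
    patients, _ = clinical_frames(bundles)
    patients = derive_patient_columns(patients, lesions)
    patients["cdp"] = [cdp_flag(b.visits) for b in bundles]
    return patients


def analyze_cohort(
    lesions: pd.DataFrame,
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> Dict[str, object]:
    """All cohort statistics from tidy tables; flags degenerate fits."""
    results: Dict[str, object] = {}
    table, chi2 = crosstab_sel_prl(lesions)
    results["crosstab"] = table
    results["chi2"] = chi2

    patients, strata_counts = stratify_patients(patients)
    results["patients"] = patients
    results["strata_counts"] = strata_counts
    results["summary"] = cohort_summary(patients, lesions)

    if len(patients) >= 4 and patients["prl_count"].nunique() > 1:
        results["spearman_sel_prl"] = spearman_corr(
            patients["sel_count"], patients["prl_count"]
        )
    else:
        results["spearman_sel_prl"] = None

    visits_long = visits.merge(
        patients[["patient_id", "stratum", *covariates]], on="patient_id"
    )
    try:
        results["edss_mixed"] = fit_edss_mixed(visits_long, "stratum", covariates)
    except (ValueError, KeyError) as exc:
        results["edss_mixed"] = None
        results["edss_mixed_error"] = str(exc)

    patients_ml = patients.copy()
    if "tlv_mm3" in patients_ml:
        patients_ml["sel_volume_ml"] = patients_ml["tlv_mm3"] / 1000.0
    else:
        patients_ml["sel_volume_ml"] = np.nan  # volume model flags degenerate
    results["count_volume_models"] = fit_count_and_volume_models(patients_ml)
    if patients["cdp"].notna().any() and patients["cdp"].dropna().nunique() > 1:
        results["cdp_logistic"] = fit_cdp_logistic(patients, "sel_count")
    else:
        results["cdp_logistic"] = None
        results["cdp_flag"] = "underpowered: no CDP contrast"
    return results


def _model_to_dict(res: Optional[ModelResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "kind": res.kind.value,
        "terms": res.terms.to_dict(orient="records"),
        "flags": {k: str(v) for k, v in res.flags.items()},
    }


def run_all(
    sim_cfg: SimulationConfig,
    sel_cfg: SelConfig,
    prl_cfg: PrlConfig,
    out_dir: Path,
    seed: int,
    write_images: bool = False,
) -> Path:
    """Simulate a cohort, run both detectors and the statistics, write a
    report directory with CSVs, model JSON and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles: List[PatientBundle] = []
    lesion_frames: List[pd.DataFrame] = []
    for bundle in iter_cohort(sim_cfg, seed, render_anatomy=write_images):
        bundles.append(bundle)
        lesion_frames.append(process_bundle(bundle, sel_cfg, prl_cfg))
    lesions = pd.concat(lesion_frames, ignore_index=True)
    patients, visits = clinical_frames(bundles)
    patients = _patient_table(bundles, lesions)
    truth = ground_truth_frame(bundles)

    results = analyze_cohort(lesions, patients, visits)

    lesions.to_csv(out_dir / "lesions.csv", index=False)
    results["patients"].to_csv(out_dir / "patients.csv", index=False)
    visits.to_csv(out_dir / "visits.csv", index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    results["crosstab"].to_csv(out_dir / "crosstab.csv")
    results["strata_counts"].to_csv(out_dir / "strata_counts.csv", header=["n"])

    models = {
        "chi2": _model_to_dict(results["chi2"]),
        "spearman_sel_prl": _model_to_dict(results.get("spearman_sel_prl")),
        "edss_mixed": _model_to_dict(results.get("edss_mixed")),
        "poisson_counts": _model_to_dict(results["count_volume_models"][0]),
        "linear_log_volumes": _model_to_dict(results["count_volume_models"][1]),
        "cdp_logistic": _model_to_dict(results.get("cdp_logistic")),
        "summary": results["summary"],
    }
    with open(out_dir / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    manifest = RunManifest(
        command="run-all",
        config_hash=config_hash(sim_cfg, sel_cfg, prl_cfg),
        seed=seed,
        inputs=[],
        outputs=sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
    )
    manifest.write(out_dir)
    return out_dir
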