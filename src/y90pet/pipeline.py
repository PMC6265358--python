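"""End-to-end orchestration: case → segmentation → dose → metrics → statistics.

For each lesion the gradient segmentation is run twice — once from the
morphologic-mask initialization (PS1) and once with the initialization
jittered by 2 mm (PS2), a proxy for an operator re-drawing the rays — and
absorbed-dose / BED metrics are reported for the morphologic mask (MS) and
both PET segmentations.  Lesions are excluded when the MS volume is below
2 cm³ (PET resolution limit) or the MS mean absorbed dose is below 5 Gy
(no uptake); exclusion always evaluates on MS, never on the PET contour.

Relative differences follow the convention Δ = (PS − MS)/MS × 100%
throughout, and "PS" in correlation analyses is the per-metric average of
the two realizations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import Mask, VoxelImage, volume_cm3
from .dosimetry import PhysicsConstants, activity_to_dose_local
from .metrics import (ConcordanceResult, DoseMetrics, RadiobiologyParams,
                      compute_dvh, concordance, dose_metrics)
from .segmentation import GradientParams, gradient_segment, init_from_mask
from .stats import PairedSample, lin_ccc, paired_mean_difference, pearson
from .synthetic import Case, make_patient_cohort, make_phantom_suite

AD_METRICS = ("mean_gy", "d70_gy", "d90_gy")
BED_METRICS = ("bed_mean_gy", "bed70_gy", "bed90_gy")


@dataclass(frozen=True)
class PipelineConfig:
    gradient: GradientParams = field(default_factory=GradientParams)
    radiobiology: RadiobiologyParams = field(default_factory=RadiobiologyParams)
    physics: PhysicsConstants = field(default_factory=PhysicsConstants)
    jitter_sigma_mm: float = 2.0
    exclude_volume_cm3: float = 2.0
    exclude_mean_dose_gy: float = 5.0
    n_boot: int = 2000

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class LesionResult:
    patient_id: str
    lesion_id: str
    excluded: bool = False
    exclusion_reason: str | None = None
    ms_metrics: DoseMetrics | None = None
    ps1_metrics: DoseMetrics | None = None
    ps2_metrics: DoseMetrics | None = None
    concordance: ConcordanceResult | None = None
    ps_repeat_concordance: ConcordanceResult | None = None
    ps1_mask: Mask | None = None
    ps2_mask: Mask | None = None

    def ps_mean_metric(self, name: str) -> float:
        """Per-metric average of the two PS realizations."""
        return 0.5 * (getattr(self.ps1_metrics, name) + getattr(self.ps2_metrics, name))


def run_lesion(pet: VoxelImage, ms: Mask, config: PipelineConfig, seed,
               dose: VoxelImage | None = None,
               patient_id: str = "p00", lesion_id: str = "l0") -> LesionResult:
    """Dose, two gradient segmentations and all metrics for one lesion."""
    if dose is None:
        dose = activity_to_dose_local(pet, config.physics)
    result = LesionResult(patient_id=patient_id, lesion_id=lesion_id)
    ms_vol = volume_cm3(ms)
    if ms_vol < config.exclude_volume_cm3:
        result.excluded = True
        result.exclusion_reason = "volume_lt_2cm3"
        return result
    result.ms_metrics = dose_metrics(compute_dvh(dose, ms), config.radiobiology)
    if result.ms_metrics.mean_gy < config.exclude_mean_dose_gy:
        result.excluded = True
        result.exclusion_reason = "no_uptake_lt_5Gy"
        return result

    init = init_from_mask(ms)
    rng = np.random.default_rng([_seed_to_int(seed), 0x5E6])
    ps1 = gradient_segment(pet, init, config.gradient, seed=int(rng.integers(2 ** 31)))
    jittered = GradientParams(**{**asdict(config.gradient),
                                 "jitter_sigma": config.jitter_sigma_mm})
    ps2 = gradient_segment(pet, init, jittered, seed=int(rng.integers(2 ** 31)))
    result.ps1_mask, result.ps2_mask = ps1, ps2
    result.ps1_metrics = dose_metrics(compute_dvh(dose, ps1), config.radiobiology)
    result.ps2_metrics = dose_metrics(compute_dvh(dose, ps2), config.radiobiology)
    result.concordance = concordance(ms, ps1)
    result.ps_repeat_concordance = concordance(ps1, ps2)
    return result


def _seed_to_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.default_rng(seed).integers(2 ** 31))


def run_case(case: Case, config: PipelineConfig, seed) -> list[LesionResult]:
    """Run every lesion of a case against a single dose map."""
    dose = activity_to_dose_local(case.pet, config.physics)
    out = []
    for i, (ms, lesion_id) in enumerate(zip(case.ms_masks, case.lesion_ids)):
        out.append(run_lesion(case.pet, ms, config, seed=[_seed_to_int(seed), i],
                              dose=dose, patient_id=case.patient_id,
                              lesion_id=lesion_id))
    return out


def results_table(results: list[LesionResult]) -> pd.DataFrame:
    """Per-lesion table over the non-excluded lesions."""
    rows = []
    for r in results:
        if r.excluded:
            continue
        row = {"patient_id": r.patient_id, "lesion_id": r.lesion_id}
        for name in AD_METRICS + BED_METRICS + ("eud_gy", "eubed_gy", "volume_cm3"):
            row[f"ms_{name}"] = getattr(r.ms_metrics, name)
            row[f"ps1_{name}"] = getattr(r.ps1_metrics, name)
            row[f"ps2_{name}"] = getattr(r.ps2_metrics, name)
            row[f"ps_{name}"] = r.ps_mean_metric(name)
        row["dsc"] = r.concordance.dsc
        row["mda_mm"] = r.concordance.mda_mm
        row["repeat_dsc"] = r.ps_repeat_concordance.dsc
        row["repeat_mda_mm"] = r.ps_repeat_concordance.mda_mm
        rows.append(row)
    return pd.DataFrame(rows)


def _five_number(x: np.ndarray) -> list[float]:
    return [float(v) for v in np.percentile(x, [0, 25, 50, 75, 100])]


def cohort_summary(table: pd.DataFrame, config: PipelineConfig, seed) -> dict:
    """Cohort statistics: summaries, clustered paired differences, r and ccc."""
    if table.empty:
        raise ValueError("empty cohort: all lesions excluded")
    summary: dict = {"n_lesions": int(len(table)),
                     "n_patients": int(table["patient_id"].nunique()),
                     "metrics": {}}
    multi_cluster = table["patient_id"].nunique() >= 2
    for name in AD_METRICS + BED_METRICS + ("volume_cm3",):
        ms = table[f"ms_{name}"].to_numpy()
        ps = table[f"ps_{name}"].to_numpy()
        entry = {
            "ms": {"mean": float(ms.mean()), "sd": float(ms.std(ddof=1)) if len(ms) > 1 else 0.0,
                   "five_number": _five_number(ms)},
            "ps": {"mean": float(ps.mean()), "sd": float(ps.std(ddof=1)) if len(ps) > 1 else 0.0,
                   "five_number": _five_number(ps)},
        }
        if len(table) >= 2 and np.std(ms) > 0 and np.std(ps) > 0:
            entry["pearson_r"] = pearson(ms, ps)
            entry["ccc"] = lin_ccc(ms, ps)
        if multi_cluster and len(table) >= 2:
            sample = PairedSample(x=ms, y=ps, cluster=table["patient_id"].to_numpy())
            metric_tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:2], "big")
            agg = paired_mean_difference(sample, n_boot=config.n_boot,
                                         seed=_seed_to_int([_seed_to_int(seed), metric_tag]))
            entry["ps_minus_ms"] = {"mean_diff": agg.mean_diff, "ci_low": agg.ci_low,
                                    "ci_high": agg.ci_high, "p_value": agg.p_value}
        summary["metrics"][name] = entry
    summary["spatial"] = {
        "dsc_mean": float(table["dsc"].mean()),
        "mda_mean_mm": float(table["mda_mm"].mean()),
        "repeat_dsc_mean": float(table["repeat_dsc"].mean()),
        "repeat_mda_mean_mm": float(table["repeat_mda_mm"].mean()),
    }
    return summary


def run_cohort(cases: list[Case], config: PipelineConfig, seed) -> tuple[pd.DataFrame, dict]:
    """Per-lesion table and cohort summary over a list of cases."""
    if not cases:
        raise ValueError("run_cohort needs at least one case")
    results: list[LesionResult] = []
    for i, case in enumerate(cases):
        results.extend(run_case(case, config, seed=[_seed_to_int(seed), 101 + i]))
    table = results_table(results)
    summary = cohort_summary(table, config, seed=[_seed_to_int(seed), 777])
    summary["n_excluded"] = sum(r.excluded for r in results)
    summary["exclusions"] = [
        {"patient_id": r.patient_id, "lesion_id": r.lesion_id, "reason": r.exclusion_reason}
        for r in results if r.excluded]
    return table, summary


# ---------------------------------------------------------------------------
# Phantom acceptance run
# ---------------------------------------------------------------------------

PHANTOM_BOUNDS = {
    "max_volume_error_pct": 15.0,
    "max_ad_metric_diff_pct": 11.0,
    "min_dsc": 0.86,
    "max_mda_mm": 1.5,
    "min_repeat_dsc": 0.99,
    "max_repeat_metric_diff_pct": 2.0,
}


def run_phantom_acceptance(seed, config: PipelineConfig | None = None) -> dict:
    """Build the phantom suite, run the pipeline, and check the accuracy bounds.

    Reports, per lesion: the gradient-vs-morphologic volume error, AD metric
    differences (Δ = (PS − MS)/MS × 100), DSC and MDA, and the PS1-vs-PS2
    repeatability (DSC, MDA and AD/BED metric differences relative to PS1).
    """
    config = config or PipelineConfig()
    suite = make_phantom_suite(seed=_seed_to_int(seed))
    lesions = []
    for case in suite:
        for r in run_case(case, config, seed=[_seed_to_int(seed), 13]):
            if r.excluded:  # phantom lesions all pass the exclusion rules
                continue
            ad_diffs = {m: 100.0 * (getattr(r.ps1_metrics, m) - getattr(r.ms_metrics, m))
                        / getattr(r.ms_metrics, m) for m in AD_METRICS}
            rep_diffs = {m: 100.0 * (getattr(r.ps1_metrics, m) - getattr(r.ps2_metrics, m))
                         / getattr(r.ps1_metrics, m) for m in AD_METRICS + BED_METRICS}
            lesions.append({
                "case_id": case.case_id,
                "lesion_id": r.lesion_id,
                "ms_volume_cm3": r.ms_metrics.volume_cm3,
                "ps_volume_cm3": r.ps1_metrics.volume_cm3,
                "volume_error_pct": r.concordance.delta_volume_pct,
                "ad_diff_pct": ad_diffs,
                "dsc": r.concordance.dsc,
                "mda_mm": r.concordance.mda_mm,
                "repeat_dsc": r.ps_repeat_concordance.dsc,
                "repeat_mda_mm": r.ps_repeat_concordance.mda_mm,
                "repeat_metric_diff_pct": rep_diffs,
            })
    report = {
        "seed": _seed_to_int(seed),
        "lesions": lesions,
        "aggregate": {
            "max_volume_error_pct": max(abs(l["volume_error_pct"]) for l in lesions),
            "max_ad_metric_diff_pct": max(abs(v) for l in lesions
                                          for v in l["ad_diff_pct"].values()),
            "min_dsc": min(l["dsc"] for l in lesions),
            "max_mda_mm": max(l["mda_mm"] for l in lesions),
            "min_repeat_dsc": min(l["repeat_dsc"] for l in lesions),
            "max_repeat_mda_mm": max(l["repeat_mda_mm"] for l in lesions),
            "max_repeat_metric_diff_pct": max(abs(v) for l in lesions
                                              for v in l["repeat_metric_diff_pct"].values()),
        },
    }
    agg = report["aggregate"]
    report["checks"] = {
        "volume_error_le_15pct": agg["max_volume_error_pct"] <= PHANTOM_BOUNDS["max_volume_error_pct"],
        "ad_metrics_le_11pct": agg["max_ad_metric_diff_pct"] <= PHANTOM_BOUNDS["max_ad_metric_diff_pct"],
        "dsc_ge_0.86": agg["min_dsc"] >= PHANTOM_BOUNDS["min_dsc"],
        "mda_le_1.5mm": agg["max_mda_mm"] <= PHANTOM_BOUNDS["max_mda_mm"],
        "repeat_dsc_ge_0.99": agg["min_repeat_dsc"] >= PHANTOM_BOUNDS["min_repeat_dsc"],
        "repeat_metrics_le_2pct": agg["max_repeat_metric_diff_pct"] <= PHANTOM_BOUNDS["max_repeat_metric_diff_pct"],
    }
    report["passed"] = all(report["checks"].values())
    return report


def write_manifest(out_dir: str | Path, config: PipelineConfig, seed) -> Path:
    """Write a run manifest (config hash, seed, package version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": _seed_to_int(seed),
                "version": __version__}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
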