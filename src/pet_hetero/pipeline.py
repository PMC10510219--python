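"""End-to-end orchestration: phantom -> quantify -> aggregate -> analyze.

A run is fully determined by a :class:`RunConfig` (loadable from YAML): it
either generates a synthetic cohort or consumes external NIfTI volumes plus
annotation and survival tables, quantifies every lesion at the configured
thresholds, applies the inclusion rules, aggregates to the patient level
under the three SUVmax-ranking schemes, and evaluates every
threshold x scheme HI marker against PFS (correlation grid, time-dependent
ROC with optimal cutoff, Kaplan-Meier stratification with log-rank).

All intermediates are persisted as CSV, the statistics as a deterministic
JSON bundle, and a provenance record (config, seed, library versions) is
written next to them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SCHEMES, aggregate_patients, cohort_summary, filter_lesions
from .io import load_suv_nifti, save_suv_nifti
from .phantom import CohortData, PhantomConfig, generate_cohort
from .survstats import progression_by_horizon, spearman_rho, stratify_and_report
from .voi import CLINICAL_THRESHOLDS, SUVolume, ThresholdSpec, metric_grid, segment_voi, lesion_metrics

__all__ = [
    "RunConfig",
    "run_pipeline",
    "quantify_cohort",
    "analyze_cohort",
    "validate_inputs",
]

DEFAULT_THRESHOLDS = tuple(t.label for t in CLINICAL_THRESHOLDS)

#: Threshold used to define the lesion diameter entering the 10 mm filter:
#: the most inclusive relative level, whose VOI tracks the metabolic extent.
DIAMETER_THRESHOLD = "40%"


@dataclass
class RunConfig:
    """Settings of one reproducible pipeline run."""

    phantom: PhantomConfig | None = field(default_factory=PhantomConfig)
    volumes_dir: str | None = None  # external NIfTI inputs (alternative to phantom)
    annotations_csv: str | None = None
    survival_csv: str | None = None
    thresholds: tuple[str, ...] = DEFAULT_THRESHOLDS
    schemes: tuple[str, ...] = SCHEMES
    horizon_months: float = 12.0
    alpha: float = 0.05
    output_dir: str = "pet_hetero_run"
    seed: int = 0
    write_volumes: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("threshold list must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        for t in self.thresholds:
            ThresholdSpec.parse(t)
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown aggregation schemes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom_raw = raw.pop("phantom", {})
        phantom = None
        if phantom_raw is not None:
            for key in ("grid_shape", "lesions_per_patient_range", "diameter_range_mm",
                        "heterogeneity_range", "peak_suv_range"):
                if key in phantom_raw:
                    phantom_raw[key] = tuple(phantom_raw[key])
            phantom = PhantomConfig(**phantom_raw)
        for key in ("thresholds", "schemes"):
            if key in raw:
                raw[key] = tuple(str(v) for v in raw[key])
        cfg = cls(phantom=phantom, **raw)
        if phantom is not None and "seed" not in phantom_raw:
            cfg = dataclasses.replace(cfg, phantom=dataclasses.replace(phantom, seed=cfg.seed))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def quantify_volume(
    volume: SUVolume,
    annotations: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-lesion, per-threshold metric rows for one patient volume.

    The ``diameter_mm`` column is the lesion's 40 %SUVmax-VOI bounding-box
    extent, repeated on every threshold row (it is a lesion property used by
    the inclusion filter, not a per-threshold quantity); each row also keeps
    its own VOI extent as ``extent_mm``.
    """
    specs = [ThresholdSpec.parse(t) for t in thresholds]
    rows, issues = [], []
    for ann in annotations.itertuples(index=False):
        seed = (int(ann.seed_x), int(ann.seed_y), int(ann.seed_z))
        diam_voi = segment_voi(volume, seed, DIAMETER_THRESHOLD)
        lesion_diam = lesion_metrics(diam_voi, volume).diameter_mm
        metrics, failures = metric_grid(volume, seed, specs)
        for label, m in metrics.items():
            rows.append(
                {
                    "patient_id": ann.patient_id,
                    "lesion_id": ann.lesion_id,
                    "threshold": label,
                    "suv_max": m.suv_max,
                    "suv_mean": m.suv_mean,
                    "mtv_ml": m.mtv_ml,
                    "tlg": m.tlg,
                    "hi": m.hi,
                    "diameter_mm": lesion_diam,
                    "extent_mm": m.diameter_mm,
                    "n_voxels": m.n_voxels,
                    "site": ann.site,
                    "ct_confirmed": bool(ann.ct_confirmed),
                }
            )
        for label, msg in failures.items():
            issues.append(
                {"patient_id": ann.patient_id, "lesion_id": ann.lesion_id,
                 "threshold": label, "error": msg}
            )
    return pd.DataFrame(rows), issues


def quantify_cohort(
    volumes: dict[str, SUVolume],
    annotations: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every annotated lesion of every patient volume."""
    frames, issues = [], []
    for pid, vol in volumes.items():
        ann = annotations[annotations["patient_id"] == pid]
        if ann.empty:
            continue
        df, iss = quantify_volume(vol, ann, thresholds)
        frames.append(df)
        issues.extend(iss)
    lesions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["patient_id", "lesion_id", "threshold", "suv_max", "suv_mean",
                     "mtv_ml", "tlg", "hi", "diameter_mm", "extent_mm", "n_voxels",
                     "site", "ct_confirmed"]
        )
    )
    return lesions, issues


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

_GRID_PARAMS = ("suv_max", "tlg", "mtv_ml", "hi")
_PARAM_LABELS = {"suv_max": "SUVmax", "tlg": "TLG", "mtv_ml": "MTV", "hi": "HI"}


def correlation_grid(
    patients: pd.DataFrame,
    thresholds,
    schemes,
    horizon_months: float,
) -> pd.DataFrame:
    """Threshold x parameter x scheme Spearman grid against progression.

    The outcome is the binary progression-by-horizon indicator; patients
    censored before the horizon are excluded pairwise.
    """
    records = []
    for thr in thresholds:
        label = ThresholdSpec.parse(thr).label
        sub = patients[patients["threshold"] == label]
        if sub.empty:
            continue
        prog = progression_by_horizon(
            sub["pfs_months"].to_numpy(), sub["event"].to_numpy(), horizon_months
        )
        known = ~np.isnan(prog)
        for param in _GRID_PARAMS:
            for scheme in schemes:
                col = f"{param}_{scheme}_group"
                rec = {"threshold": label, "parameter": _PARAM_LABELS[param],
                       "scheme": scheme}
                try:
                    rho, p = spearman_rho(
                        sub.loc[known, col].to_numpy(), prog[known]
                    )
                    rec["r"], rec["p_value"] = rho, p
                except ValueError as exc:
                    rec["r"], rec["p_value"] = np.nan, np.nan
                    rec["note"] = str(exc)
                records.append(rec)
    return pd.DataFrame(records)


def analyze_cohort(
    patients: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    schemes=SCHEMES,
    horizon_months: float = 12.0,
) -> dict:
    """Correlation grid plus ROC/KM stratification bundles for the HI marker."""
    grid = correlation_grid(patients, thresholds, schemes, horizon_months)
    bundles: dict = {}
    for thr in thresholds:
        label = ThresholdSpec.parse(thr).label
        sub = patients[patients["threshold"] == label]
        if len(sub) < 4:
            continue
        for scheme in schemes:
            marker = sub[f"hi_{scheme}_group"].to_numpy()
            bundles[f"HI_{label}_{scheme}"] = stratify_and_report(
                marker,
                sub["pfs_months"].to_numpy(),
                sub["event"].to_numpy(),
                horizon_months=horizon_months,
                marker_name=f"HI_{label}_{scheme}",
            )
    return {"correlation_grid": grid, "stratification": bundles}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(
    annotations: pd.DataFrame,
    survival: pd.DataFrame,
    volumes: dict[str, SUVolume] | None = None,
) -> list[dict]:
    """Cross-check tables (and optionally volumes); returns machine-readable
    issues rather than raising."""
    issues: list[dict] = []
    surv_ids = set(survival["patient_id"]) if "patient_id" in survival else set()
    ann_ids = set(annotations["patient_id"]) if "patient_id" in annotations else set()
    for pid in sorted(ann_ids - surv_ids):
        issues.append({"kind": "annotation_without_survival", "patient_id": pid})
    for pid in sorted(surv_ids - ann_ids):
        issues.append({"kind": "survival_without_annotation", "patient_id": pid})
    if "pfs_months" in survival:
        for rec in survival.itertuples(index=False):
            if not rec.pfs_months > 0:
                issues.append(
                    {"kind": "nonpositive_pfs", "patient_id": rec.patient_id,
                     "pfs_months": float(rec.pfs_months)}
                )
    if volumes is not None:
        for pid in sorted(ann_ids - set(volumes)):
            issues.append({"kind": "annotation_without_volume", "patient_id": pid})
        for ann in annotations.itertuples(index=False):
            if ann.patient_id not in volumes:
                continue
            shape = volumes[ann.patient_id].shape
            seed = (ann.seed_x, ann.seed_y, ann.seed_z)
            if any(not 0 <= s < n for s, n in zip(seed, shape)):
                issues.append(
                    {"kind": "seed_out_of_bounds", "patient_id": ann.patient_id,
                     "lesion_id": int(ann.lesion_id), "seed": list(map(int, seed))}
                )
    return issues


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results bundle.

    Deterministic given the configured seed: the same config yields
    byte-identical result JSONs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: inputs -------------------------------------------------
    if config.volumes_dir is not None:
        try:
            annotations = pd.read_csv(config.annotations_csv)
            survival = pd.read_csv(config.survival_csv)
            volumes = {
                p.stem.replace(".nii", ""): load_suv_nifti(p)
                for p in sorted(Path(config.volumes_dir).glob("*.nii*"))
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("load", str(exc)) from exc
    elif config.phantom is not None:
        cohort_data: CohortData = generate_cohort(config.phantom)
        volumes = cohort_data.volumes
        annotations = cohort_data.annotations
        survival = cohort_data.survival
        if config.write_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for pid, vol in volumes.items():
                save_suv_nifti(vol, vol_dir / f"{pid}.nii.gz")
    else:
        raise PipelineError("config", "neither phantom nor external inputs configured")
    annotations.to_csv(out / "annotations.csv", index=False)
    survival.to_csv(out / "survival.csv", index=False)

    issues = validate_inputs(annotations, survival, volumes)
    _write_json({"issues": issues}, out / "validation.json")

    # --- stage 2: quantify ----------------------------------------------
    try:
        lesions, quant_issues = quantify_cohort(volumes, annotations, config.thresholds)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("quantify", str(exc)) from exc
    lesions.to_csv(out / "lesions.csv", index=False)

    # --- stage 3: aggregate ----------------------------------------------
    included, exclusions = filter_lesions(lesions)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    patients, flagged = aggregate_patients(included, survival)
    patients.to_csv(out / "patients.csv", index=False)
    flagged.to_csv(out / "patients_without_lesions.csv", index=False)
    summary = cohort_summary(survival, included)

    # --- stage 4: analyze ------------------------------------------------
    if patients.empty:
        raise PipelineError("analyze", "no evaluable patients after filtering")
    results = analyze_cohort(
        patients, config.thresholds, config.schemes, config.horizon_months
    )
    results["correlation_grid"].to_csv(out / "correlations.csv", index=False)

    bundle = {
        "horizon_months": config.horizon_months,
        "thresholds": list(ThresholdSpec.parse(t).label for t in config.thresholds),
        "schemes": list(config.schemes),
        "n_patients_analyzed": int(patients["patient_id"].nunique()),
        "n_lesions_total": int(lesions[["patient_id", "lesion_id"]]
                               .drop_duplicates().shape[0]) if not lesions.empty else 0,
        "n_lesions_included": int(included[["patient_id", "lesion_id"]]
                                  .drop_duplicates().shape[0]) if not included.empty else 0,
        "cohort_summary": summary,
        "quantification_issues": quant_issues,
        "stratification": results["stratification"],
    }
    _write_json(bundle, out / "results.json")

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=_json_default)
    provenance = {
        "package": "pet-hetero",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    _write_json(provenance, out / "provenance.json")

    if config.make_plots:
        from .plots import plot_km_strata, plot_roc

        for key, strat in bundle["stratification"].items():
            if strat.get("degenerate", True):
                continue
            sub = patients[patients["threshold"] == key.split("_")[1]]
            scheme = key.rsplit("_", 1)[1]
            marker = sub[f"hi_{scheme}_group"].to_numpy()
            t = sub["pfs_months"].to_numpy()
            e = sub["event"].to_numpy()
            stem = key.replace("%", "pct")  # '%' confuses image writers
            plot_roc(marker, t, e, config.horizon_months, out / f"roc_{stem}.png")
            plot_km_strata(
                marker, t, e, strat["roc"]["optimal_cutoff"], out / f"km_{stem}.png"
            )
            break  # one representative pair of figures per run

    return bundle
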