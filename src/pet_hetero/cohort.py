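"""Lesion inclusion rules and per-patient aggregation of lesion metrics.

Two clinical inclusion rules are applied before any statistic is computed:
lesions with diameter below 10 mm are excluded (partial-volume effect and
repeatability), and bone lesions enter only with CT confirmation.  Each
exclusion is logged with the rule that fired.

Multi-lesion patients are then reduced to per-patient values under three
schemes built on the lesion SUVmax ranking:

* maximum group -- the metrics of the single hottest lesion (largest
  SUVmax; ties broken toward the larger HI),
* mean group    -- the arithmetic mean of the per-lesion values,
* median group  -- the median of the per-lesion values.

HI is always computed per lesion first (SUVmax/SUVmean within that lesion's
VOI) and aggregated afterwards.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "MIN_DIAMETER_MM",
    "SCHEMES",
    "filter_lesions",
    "aggregate_patient",
    "aggregate_patients",
    "cohort_summary",
    "percent",
]

#: Diameter inclusion boundary; exactly 10 mm is kept ("less than 10 mm"
#: excluded).
MIN_DIAMETER_MM = 10.0

SCHEMES = ("max", "mean", "median")

#: Per-lesion parameters that are aggregated to the patient level.
_PARAMS = ("suv_max", "mtv_ml", "tlg", "hi")


def filter_lesions(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion rules; return (included rows, exclusion log).

    Rules act at the lesion level: if a lesion fails, all of its threshold
    rows are dropped.  The log has one record per excluded lesion per rule
    (a lesion may violate both).  Idempotent and order-independent.
    """
    required = {"patient_id", "lesion_id", "diameter_mm", "site", "ct_confirmed"}
    missing = required - set(rows.columns)
    if missing:
        raise KeyError(f"lesion table missing columns: {sorted(missing)}")
    if rows.empty:
        return rows.copy(), pd.DataFrame(
            columns=["patient_id", "lesion_id", "rule", "detail"]
        )

    lesions = rows.drop_duplicates(["patient_id", "lesion_id"])
    log_rows = []
    bad = set()
    for rec in lesions.itertuples(index=False):
        key = (rec.patient_id, rec.lesion_id)
        if rec.diameter_mm < MIN_DIAMETER_MM:
            bad.add(key)
            log_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "lesion_id": rec.lesion_id,
                    "rule": "diameter_lt_10mm",
                    "detail": f"diameter {rec.diameter_mm:.2f} mm < {MIN_DIAMETER_MM:g} mm",
                }
            )
        if rec.site == "bone" and not rec.ct_confirmed:
            bad.add(key)
            log_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "lesion_id": rec.lesion_id,
                    "rule": "bone_without_ct_confirmation",
                    "detail": "bone lesion lacking CT confirmation",
                }
            )
    keys = list(zip(rows["patient_id"], rows["lesion_id"]))
    keep = np.array([k not in bad for k in keys])
    log = pd.DataFrame(log_rows, columns=["patient_id", "lesion_id", "rule", "detail"])
    return rows.loc[keep].copy(), log


def aggregate_patient(rows: pd.DataFrame) -> dict[str, float]:
    """Aggregate one patient's included lesion rows at one threshold.

    Returns ``{param}_{scheme}_group`` for param in SUVmax/MTV/TLG/HI and
    scheme in max/mean/median.  The maximum group reports the hottest
    lesion's own metrics (SUVmax ties broken toward the larger HI, the
    conservative choice that flags more heterogeneity); mean and median
    groups aggregate the per-lesion values.
    """
    if rows.empty:
        raise ValueError("no evaluable lesions for this patient")
    suvmax = rows["suv_max"].to_numpy(dtype=float)
    tied = rows.loc[suvmax == suvmax.max()]
    hottest = tied.loc[tied["hi"].idxmax()]
    out: dict[str, float] = {}
    for param in _PARAMS:
        vals = rows[param].to_numpy(dtype=float)
        out[f"{param}_max_group"] = float(hottest[param])
        out[f"{param}_mean_group"] = float(vals.mean())
        out[f"{param}_median_group"] = float(np.median(vals))
    return out


def aggregate_patients(
    lesion_rows: pd.DataFrame, survival: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the patient x threshold table from included lesion rows.

    Returns ``(patients, flagged)``; ``flagged`` lists patients present in
    the survival table but left with zero evaluable lesions (they are
    reported but excluded from statistics).
    """
    records = []
    for (pid, thr), grp in lesion_rows.groupby(["patient_id", "threshold"], sort=True):
        rec = {"patient_id": pid, "threshold": thr, "n_lesions": len(grp)}
        rec.update(aggregate_patient(grp))
        records.append(rec)
    patients = pd.DataFrame(records)

    flagged = pd.DataFrame(columns=["patient_id", "reason"])
    if survival is not None and not survival.empty:
        have = set(patients["patient_id"]) if not patients.empty else set()
        missing = [pid for pid in survival["patient_id"] if pid not in have]
        flagged = pd.DataFrame(
            {"patient_id": missing, "reason": ["no evaluable lesions"] * len(missing)}
        )
        if not patients.empty:
            patients = patients.merge(
                survival[["patient_id", "pfs_months", "event"]],
                on="patient_id",
                how="inner",
            )
    return patients, flagged


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage with half-up rounding (21/32 -> 65.63, not banker's 65.62)."""
    if total == 0:
        return float("nan")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    return float(q.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def cohort_summary(
    patients: pd.DataFrame,
    lesions: pd.DataFrame | None = None,
    characteristics: list[str] | None = None,
) -> dict:
    """Cohort characteristics table plus per-patient lesion-burden report.

    ``patients`` needs a ``patient_id`` column; any listed categorical
    ``characteristics`` columns are tabulated as count and percent of the
    cohort.  If a lesion table with ``site`` is given, per-site patient
    counts (a patient counts once per site, sites are not exclusive) and
    lesion counts per patient are added; if it also carries ``hi`` rows at
    the 50 %SUVmax threshold, the largest HI_50% of every patient is
    reported.
    """
    patients = patients.drop_duplicates("patient_id")
    n = len(patients)
    summary: dict = {"n_patients": n}

    chars = {}
    for col in characteristics or []:
        counts = patients[col].value_counts()
        chars[col] = {
            str(level): {"count": int(c), "percent": percent(int(c), n)}
            for level, c in counts.items()
        }
    summary["characteristics"] = chars

    if lesions is not None and not lesions.empty:
        per_lesion = lesions.drop_duplicates(["patient_id", "lesion_id"])
        site_counts = (
            per_lesion.groupby("site")["patient_id"].nunique().sort_index()
        )
        summary["sites"] = {
            site: {"count": int(c), "percent": percent(int(c), n)}
            for site, c in site_counts.items()
        }
        summary["lesions_per_patient"] = (
            per_lesion.groupby("patient_id").size().to_dict()
        )
        if "hi" in lesions.columns and "threshold" in lesions.columns:
            hi50 = lesions[lesions["threshold"] == "50%"]
            if not hi50.empty:
                summary["largest_hi50_per_patient"] = (
                    hi50.groupby("patient_id")["hi"].max().round(6).to_dict()
                )
    return summary
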