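"""Survival statistics for a baseline imaging biomarker, from first principles.

Implements the full battery used to evaluate a pretreatment marker against
progression-free survival:

* Spearman rank correlation (midranks, t-approximation p-value),
* cumulative/dynamic time-dependent ROC at a fixed horizon with
  Kaplan-Meier-based sensitivity/specificity (Heagerty-Lumley-Pepe form,
  with exact marker-stratified KM in place of nearest-neighbor smoothing),
* Kaplan-Meier product-limit estimation with median survival,
* the two-group log-rank test (hypergeometric variance, 1 df chi-square),
* a one-call stratification report: optimal Youden cutoff, KM per stratum,
  log-rank p, median PFS per stratum.

Everything is deterministic; p-values are two-sided.  Only scipy's chi2 / t
distribution functions are used for tail probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "TdRocResult",
    "RocUndefinedError",
    "spearman_rho",
    "midranks",
    "km_fit",
    "logrank_test",
    "td_roc",
    "stratify_and_report",
]


class RocUndefinedError(ValueError):
    """The time-dependent ROC is undefined (no events, or no survivors)."""


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: marker value, follow-up time (months), event indicator."""

    marker: float
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def as_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpack a sequence of :class:`SurvivalSample` into (marker, time, event)."""
    marker = np.array([s.marker for s in samples], dtype=float)
    time = np.array([s.time for s in samples], dtype=float)
    event = np.array([s.event for s in samples], dtype=int)
    return marker, time, event


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def midranks(x) -> np.ndarray:
    """Ranks 1..n with ties replaced by the average (mid) rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation as the Pearson correlation of midranks.

    The p-value uses the t approximation ``t = rho*sqrt((n-2)/(1-rho^2))``
    on n-2 degrees of freedom, two-sided.  Constant input has no defined
    rank correlation and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(_stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  ``median_months`` is the first event time at which
    S(t) drops to 0.5 or below, or ``None`` if the curve never reaches 0.5
    ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int
    median_months: float | None

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i).

    Subjects censored at an event time are counted at risk for that event
    (deaths-before-censorings convention).  With no censoring the estimate
    equals the empirical survival function exactly.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = time.size

    ts, surv, risks, deaths = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j + 1 < n and time[j + 1] == t:
            j += 1
        d = int(event[i : j + 1].sum())
        n_at_risk = n - i
        if d > 0:
            s *= 1.0 - d / n_at_risk
            ts.append(t)
            surv.append(s)
            risks.append(n_at_risk)
            deaths.append(d)
        i = j + 1

    surv_arr = np.array(surv)
    ts_arr = np.array(ts)
    median = None
    hit = np.flatnonzero(surv_arr <= 0.5 + 1e-12)
    if hit.size:
        median = float(ts_arr[hit[0]])
    return KMCurve(
        times=ts_arr,
        survival=surv_arr,
        n_at_risk=np.array(risks, dtype=int),
        n_events=np.array(deaths, dtype=int),
        n_subjects=n,
        median_months=median,
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, two-sided p).

    At each distinct pooled event time with ``d`` events and ``n`` at risk
    (``n_a`` in group A), the expected group-A events are ``d*n_a/n`` and the
    variance is hypergeometric; the statistic is ``(O_A - E_A)^2 / V`` on one
    degree of freedom.  Symmetric in the group labels.
    """
    ta = np.asarray(time_a, dtype=float)
    ea = np.asarray(event_a, dtype=int)
    tb = np.asarray(time_b, dtype=float)
    eb = np.asarray(event_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(((ta == t) & (ea == 1)).sum())
        db = int(((tb == t) & (eb == 1)).sum())
        d = da + db
        if n == 0 or na == 0 and nb == 0:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var <= 0:
        # Degenerate risk sets (e.g. every subject fails at one time):
        # no information against the null.
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    p = float(_stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

@dataclass
class TdRocResult:
    """Cumulative/dynamic ROC of a baseline marker at one horizon."""

    horizon_months: float
    curve: list  # (cutoff, sensitivity, specificity); cutoff -inf anchors (1,1)
    auc: float
    optimal_cutoff: float
    youden: float
    sensitivity: float
    specificity: float


def _km_surv_at(time, event, horizon) -> float:
    if time.size == 0:
        return 1.0
    return km_fit(time, event).survival_at(horizon)


def td_roc(marker, time, event, horizon_months: float) -> TdRocResult:
    """Cumulative-case / dynamic-control ROC at ``horizon_months``.

    For each observed cutoff ``c`` the marker splits the cohort into
    X > c and X <= c; with stratified Kaplan-Meier survival S_hi, S_lo at the
    horizon and p = P(X > c),

        Se(c) = p (1 - S_hi) / (1 - S(t)),   Sp(c) = (1-p) S_lo / S(t),

    where S(t) = p S_hi + (1-p) S_lo is the mixture of the stratified
    estimates (this keeps Se and Sp in [0, 1] and makes the censoring-free
    case coincide exactly with the binary ROC on the horizon indicator).
    AUC is the trapezoidal area over the (1-Sp, Se) curve; the optimal
    cutoff maximizes Youden's J = Se + Sp - 1, ties broken toward the
    smaller (more sensitive) cutoff.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (marker.size == time.size == event.size):
        raise ValueError("marker, time and event must have equal length")
    if not np.any((event == 1) & (time <= horizon_months)):
        raise RocUndefinedError("ROC undefined: no events by the horizon")
    if not np.any(time > horizon_months):
        raise RocUndefinedError("ROC undefined: no subject event-free past horizon")

    cutoffs = np.unique(marker)
    curve = [(-np.inf, 1.0, 0.0)]  # everyone test-positive
    for c in cutoffs:
        hi = marker > c
        p_hi = float(hi.mean())
        s_hi = _km_surv_at(time[hi], event[hi], horizon_months)
        s_lo = _km_surv_at(time[~hi], event[~hi], horizon_months)
        s_mix = p_hi * s_hi + (1.0 - p_hi) * s_lo
        f_mix = 1.0 - s_mix
        se = p_hi * (1.0 - s_hi) / f_mix if f_mix > 0 else 0.0
        sp = (1.0 - p_hi) * s_lo / s_mix if s_mix > 0 else 1.0
        curve.append((float(c), min(1.0, max(0.0, se)), min(1.0, max(0.0, sp))))

    # Integrate along the cutoff-swept path, from the highest cutoff (0,0)
    # down to the -inf anchor (1,1).  This is deterministic and immune to
    # float jitter among points sharing an FPR; for non-monotone empirical
    # curves it yields the signed trapezoidal area (no enforced concavity).
    path = sorted(curve, key=lambda t: -t[0])
    fpr = np.array([1.0 - sp for _, _, sp in path])
    tpr = np.array([se for _, se, _ in path])
    auc = float(np.trapezoid(tpr, fpr))

    best_j, best_c, best_se, best_sp = -np.inf, None, None, None
    for c, se, sp in curve[1:]:  # optimum must be an observed marker value
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best_c, best_se, best_sp = j, c, se, sp
    return TdRocResult(
        horizon_months=float(horizon_months),
        curve=curve,
        auc=auc,
        optimal_cutoff=float(best_c),
        youden=float(best_j),
        sensitivity=float(best_se),
        specificity=float(best_sp),
    )


# ---------------------------------------------------------------------------
# One-call stratified report
# ---------------------------------------------------------------------------

def progression_by_horizon(time, event, horizon_months: float) -> np.ndarray:
    """Binary progression-by-horizon outcome; NaN where it is unknowable.

    1 if progression observed at or before the horizon, 0 if follow-up
    reaches the horizon event-free, NaN for subjects censored earlier (their
    status at the horizon is unknown and they drop out of the correlation).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = np.full(time.size, np.nan)
    out[(event == 1) & (time <= horizon_months)] = 1.0
    out[time >= horizon_months] = 0.0
    # an event exactly at the horizon counts as progression
    out[(event == 1) & (time <= horizon_months)] = 1.0
    return out


def stratify_and_report(
    marker,
    time,
    event,
    horizon_months: float = 12.0,
    marker_name: str = "HI",
) -> dict:
    """Full marker evaluation: correlation, ROC, cutoff split, KM, log-rank.

    Returns a JSON-serializable bundle.  The high-risk stratum is
    ``marker > cutoff`` (strict).  If either stratum has fewer than two
    patients the survival comparison is flagged degenerate and skipped.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    bundle: dict = {"marker": marker_name, "horizon_months": float(horizon_months),
                    "n_patients": int(marker.size)}

    prog = progression_by_horizon(time, event, horizon_months)
    known = ~np.isnan(prog)
    bundle["n_with_known_horizon_status"] = int(known.sum())
    try:
        rho, p = spearman_rho(marker[known], prog[known])
        bundle["spearman"] = {"rho": rho, "p_value": p}
    except ValueError as exc:
        bundle["spearman"] = {"error": str(exc)}

    try:
        roc = td_roc(marker, time, event, horizon_months)
    except RocUndefinedError as exc:
        bundle["roc"] = {"error": str(exc)}
        bundle["degenerate"] = True
        return bundle
    bundle["roc"] = {
        "auc": roc.auc,
        "optimal_cutoff": roc.optimal_cutoff,
        "youden": roc.youden,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
    }

    high = marker > roc.optimal_cutoff
    bundle["n_high"] = int(high.sum())
    bundle["n_low"] = int((~high).sum())
    if high.sum() < 2 or (~high).sum() < 2:
        bundle["degenerate"] = True
        bundle["note"] = "fewer than 2 patients in a stratum; KM/log-rank skipped"
        return bundle
    bundle["degenerate"] = False

    km_high = km_fit(time[high], event[high])
    km_low = km_fit(time[~high], event[~high])
    chi2, p_lr = logrank_test(time[high], event[high], time[~high], event[~high])
    fmt = lambda m: "not reached" if m is None else m  # noqa: E731
    bundle["km"] = {
        "high": {"n": int(high.sum()), "median_pfs_months": fmt(km_high.median_months)},
        "low": {"n": int((~high).sum()), "median_pfs_months": fmt(km_low.median_months)},
    }
    bundle["logrank"] = {"chi_square": chi2, "p_value": p_lr}
    return bundle
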