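"""Figure helpers: time-dependent ROC curve and stratified KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .survstats import km_fit, logrank_test, td_roc  # noqa: E402

__all__ = ["plot_roc", "plot_km_strata"]


def plot_roc(marker, time, event, horizon_months: float, path: str | Path) -> None:
    """Time-dependent ROC curve with AUC and the optimal Youden cutoff."""
    roc = td_roc(marker, time, event, horizon_months)
    sweep = sorted(roc.curve, key=lambda t: -t[0])
    fpr = np.array([1.0 - sp for _, _, sp in sweep])
    tpr = np.array([se for _, se, _ in sweep])
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.plot(fpr, tpr, drawstyle="steps-post", color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(
        f"t = {horizon_months:g} mo: AUC {roc.auc:.2f}, cutoff {roc.optimal_cutoff:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _steps(km, tmax):
    if km.times.size == 0:
        return np.array([0.0, tmax]), np.array([1.0, 1.0])
    t = np.concatenate([[0.0], km.times, [tmax]])
    s = np.concatenate([[1.0], km.survival, [km.survival[-1]]])
    return t, s


def plot_km_strata(marker, time, event, cutoff: float, path: str | Path) -> None:
    """Kaplan-Meier PFS curves for the marker strata split at ``cutoff``."""
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = marker > cutoff
    fig, ax = plt.subplots(figsize=(4.6, 4.0))
    tmax = float(time.max())
    for mask, label, color in (
        (~high, f"low (≤ {cutoff:.3f})", "tab:blue"),
        (high, f"high (> {cutoff:.3f})", "tab:red"),
    ):
        if mask.sum() == 0:
            continue
        km = km_fit(time[mask], event[mask])
        t, s = _steps(km, tmax)
        ax.plot(t, s, drawstyle="steps-post", label=f"{label}, n={int(mask.sum())}",
                color=color)
    if high.sum() and (~high).sum():
        chi2, p = logrank_test(time[high], event[high], time[~high], event[~high])
        ax.text(0.55, 0.9, f"log-rank p = {p:.3g}", transform=ax.transAxes)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
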