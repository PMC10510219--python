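"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: exhaustive flood
fill for segmentation, the classical rank-difference formula for Spearman,
the empirical binary ROC, the empirical survival function, and a
permutation reference for the log-rank p-value.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np

NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def flood_fill_voi(values: np.ndarray, start: tuple, level: float) -> set:
    """Exhaustive BFS over 26-neighbors of {SUV >= level} from ``start``."""
    if values[start] < level:
        return set()
    shape = values.shape
    seen = {tuple(start)}
    queue = deque([tuple(start)])
    while queue:
        v = queue.popleft()
        for d in NEIGHBORS_26:
            nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if nb in seen:
                continue
            if all(0 <= nb[i] < shape[i] for i in range(3)) and values[nb] >= level:
                seen.add(nb)
                queue.append(nb)
    return seen


def spearman_nodiff_ties(x, y) -> float:
    """Classical 1 - 6 sum d^2 / (n(n^2-1)); valid only without ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = np.empty(n)
    rx[np.argsort(x)] = np.arange(1, n + 1)
    ry = np.empty(n)
    ry[np.argsort(y)] = np.arange(1, n + 1)
    d = rx - ry
    return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))


def binary_roc(marker, positive):
    """Empirical binary ROC: (cutoff, Se, Sp) per observed cutoff, plus AUC."""
    marker = np.asarray(marker, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pts = [(-np.inf, 1.0, 0.0)]
    for c in np.unique(marker):
        se = float((marker[positive] > c).mean())
        sp = float((marker[~positive] <= c).mean())
        pts.append((float(c), se, sp))
    fpr = np.array([1 - sp for _, _, sp in pts])
    tpr = np.array([se for _, se, _ in pts])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return pts, auc


def empirical_survival(times, grid):
    """S(t) = fraction of subjects with time > t (no censoring)."""
    times = np.asarray(times, dtype=float)
    return np.array([(times > t).mean() for t in grid])


def permutation_logrank_p(time, event, group, statistic, n_perm=10_000, seed=0):
    """Permutation reference distribution for a two-group statistic.

    ``statistic(ta, ea, tb, eb)`` is evaluated on the observed labels and on
    ``n_perm`` random relabelings; returns the permutation p-value (fraction
    of permuted statistics >= observed, with the +1 continuity correction).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    obs = statistic(time[group], event[group], time[~group], event[~group])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        stat = statistic(time[perm], event[perm], time[~perm], event[~perm])
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
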