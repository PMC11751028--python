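"""Knee-point cell calling on the barcode-rank curve.

Droplet assays produce a long tail of ambient barcodes carrying a handful
of contacts next to a plateau of true cells carrying orders of magnitude
more.  The cell/ambient threshold is the knee of the log-log
barcode-rank curve, found with the kneedle algorithm; because a single
sensitivity setting tends to underestimate the knee on noisy curves, the
sensitivity is swept (1..10 by default) and the setting whose called
cells retain just over 85% of all contacts is selected.

Kneedle here: min-max normalize both axes, reflect the decreasing convex
curve to concave increasing, form the difference curve d = y_n - x_n,
and accept the first local maximum of d that the curve subsequently
drops below by more than sensitivity x mean(dx_n).  Two robustness
choices (both config-exposed): the curve is first resampled onto a
uniform grid in x — the sensitivity threshold presumes uniform spacing,
and rank curves on log axes are extremely non-uniform — and candidate
maxima are required to have d > 0, since a genuinely convex decreasing
curve satisfies d >= 0 everywhere, so negative-d maxima are local noise,
not knees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KneeResult", "rank_curve", "kneedle_knee", "adaptive_cell_call"]


class DegenerateCurveError(ValueError):
    """Rank curve carries no usable knee (e.g. all counts equal)."""


@dataclass
class KneeResult:
    sensitivity: int
    knee_rank: int              # 1-based rank of the knee point
    threshold_count: float      # contacts at the knee
    retained_fraction: float
    called_barcodes: set
    warning: str | None = None
    sweep: pd.DataFrame | None = field(default=None, repr=False)


def rank_curve(counts: pd.Series):
    """Descending count curve with stable barcode order on ties.

    Returns ``(barcodes, counts)`` arrays sorted by count descending;
    zero-count barcodes are dropped.  Raises
    :class:`DegenerateCurveError` when fewer than two distinct positive
    counts remain (no knee is defined on a flat curve).
    """
    s = pd.Series(counts)
    s = s[s > 0]
    s = s.sort_values(ascending=False, kind="stable")
    if s.nunique() < 2:
        raise DegenerateCurveError(
            "all barcode counts are equal (or fewer than 2 barcodes); "
            "set a manual threshold instead"
        )
    return s.index.to_numpy(), s.to_numpy(dtype=float)


def kneedle_knee(x, y, sensitivity: float = 1.0, resample: int | None = None,
                 positive_only: bool = True):
    """Knee index of a decreasing convex curve, or None.

    ``x`` must be strictly increasing and ``y`` non-increasing.  With
    ``resample`` set, the curve is linearly interpolated onto that many
    uniformly spaced x values first and the returned index refers to the
    resampled grid; use the returned ``(index, x_at_knee)`` pair.
    Returns ``(index, x_value)`` or ``None``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return None
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if resample and resample >= 3:
        xg = np.linspace(x[0], x[-1], int(resample))
        y = np.interp(xg, x, y)
        x = xg
    xr = x[-1] - x[0]
    yr = y.max() - y.min()
    if xr == 0 or yr == 0:
        return None
    xn = (x - x[0]) / xr
    # reflect decreasing-convex to increasing-concave, then difference
    d = (1.0 - (y - y.min()) / yr) - xn
    tstep = sensitivity * np.abs(np.diff(xn)).mean()
    cur_max = None
    cur_max_i = None
    n = len(x)
    for i in range(1, n):
        if i < n - 1 and d[i] > d[i - 1] and d[i] >= d[i + 1]:
            if (not positive_only or d[i] > 0) and (cur_max is None or d[i] > cur_max):
                cur_max = d[i]
                cur_max_i = i
        if cur_max is not None and d[i] < cur_max - tstep:
            return cur_max_i, x[cur_max_i]
    return None


def adaptive_cell_call(counts, s_range=range(1, 11), target_retention: float = 0.85,
                       log_axes: bool = True, resample: int | None = 1000) -> KneeResult:
    """Sweep kneedle sensitivity and pick the knee retaining just over
    ``target_retention`` of all contacts.

    ``counts`` maps barcode -> contact count (dict or Series).  Among
    sensitivities whose knee retains at least the target fraction, the
    one with the smallest retained fraction (closest above the target)
    wins; if none reaches it, the largest retained fraction is returned
    with a warning.  Barcodes tied with the threshold count are called.
    """
    barcodes, sorted_counts = rank_curve(pd.Series(counts))
    total = sorted_counts.sum()
    ranks = np.arange(1, len(sorted_counts) + 1, dtype=float)
    if log_axes:
        x, y = np.log10(ranks), np.log10(sorted_counts)
    else:
        x, y = ranks, sorted_counts
    cum = np.cumsum(sorted_counts)
    results = []
    for S in s_range:
        knee = kneedle_knee(x, y, sensitivity=S, resample=resample)
        if knee is None:
            continue
        _, x_knee = knee
        rank = int(np.clip(np.floor(10 ** x_knee if log_axes else x_knee),
                           1, len(sorted_counts)))
        # the resampled grid blurs the knee by ~1% in rank; snap to the
        # steepest drop of the raw curve within a small window so the
        # threshold sits exactly at the cell/ambient cliff when one exists
        if resample:
            lo = max(1, int(rank / 1.2))
            hi = min(len(sorted_counts) - 1, int(np.ceil(rank * 1.2)))
            if hi > lo:
                gaps = y[lo - 1:hi - 1] - y[lo:hi]   # drop after ranks lo..hi-1
                rank = lo + int(np.argmax(gaps))
        thr = sorted_counts[rank - 1]
        n_called = int(np.searchsorted(-sorted_counts, -thr, side="right"))
        results.append((int(S), rank, thr, cum[n_called - 1] / total, n_called))
    if not results:
        # no knee separates cells from ambient (e.g. a single population):
        # call everything and flag it
        return KneeResult(
            sensitivity=0,
            knee_rank=len(sorted_counts),
            threshold_count=float(sorted_counts[-1]),
            retained_fraction=1.0,
            called_barcodes=set(barcodes),
            warning="no knee detected at any sensitivity; all barcodes called",
            sweep=None,
        )
    sweep = pd.DataFrame(
        results, columns=["sensitivity", "knee_rank", "threshold_count",
                          "retained_fraction", "n_called"],
    )
    above = sweep[sweep["retained_fraction"] >= target_retention]
    if len(above):
        row = above.loc[above["retained_fraction"].idxmin()]
        warning = None
    else:
        row = sweep.loc[sweep["retained_fraction"].idxmax()]
        warning = (
            f"no sensitivity reached target retention {target_retention:.0%}; "
            f"best is {row['retained_fraction']:.1%}"
        )
    n_called = int(row["n_called"])
    return KneeResult(
        sensitivity=int(row["sensitivity"]),
        knee_rank=int(row["knee_rank"]),
        threshold_count=float(row["threshold_count"]),
        retained_fraction=float(row["retained_fraction"]),
        called_barcodes=set(barcodes[:n_called]),
        warning=warning,
        sweep=sweep,
    )
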