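"""Assay quantification formulas and small statistical utilities.

Implements the wet-lab bookkeeping used around the pipeline: LDH-release
cytotoxicity (percent between spontaneous-release low control and full-lysis
high control), phagocytic activity (percent bead-positive cells), Transwell
invasion-count extrapolation from sampled membrane areas, the Smirnoff-Grubbs
single-outlier test, and the two-tailed two-sample t test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


def cytotoxicity(od_test: float, od_low: float, od_high: float) -> float:
    """LDH cytotoxicity percentage from OD490 readings.

    Cytotoxicity (%) = 100 * (OD_test - OD_low) / (OD_high - OD_low).  The
    high control (full lysis) must exceed the low control (spontaneous
    release).  Values outside [0, 100] are returned as-is with a warning —
    biological over/undershoot is information, not an error.
    """
    if od_high <= od_low:
        raise ValueError("high control OD must exceed low control OD")
    pct = 100.0 * (od_test - od_low) / (od_high - od_low)
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"cytotoxicity {pct:.1f}% outside [0, 100]", stacklevel=2)
    return pct


def phagocytic_activity(n_bead_positive: int, n_total: int) -> float:
    """Percent of cells that incorporated fluorescent beads."""
    if n_total <= 0:
        raise ValueError("total cell count must be positive")
    if not 0 <= n_bead_positive <= n_total:
        raise ValueError("bead-positive count must be within [0, total]")
    return 100.0 * n_bead_positive / n_total


def invasion_estimate(area_counts, fraction_sampled: float) -> int:
    """Total cells across the whole membrane extrapolated from sampled areas.

    ``area_counts`` are per-rectangle cell counts (conventionally 20 areas);
    ``fraction_sampled`` is the proportion of membrane area they cover.
    """
    if not 0.0 < fraction_sampled <= 1.0:
        raise ValueError("fraction_sampled must be in (0, 1]")
    counts = np.asarray(list(area_counts))
    if (counts < 0).any():
        raise ValueError("area counts must be non-negative")
    return int(round(counts.sum() / fraction_sampled))


def grubbs_critical(n: int, alpha: float, side: str = "max") -> float:
    """Critical value of the Grubbs statistic.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the Student
    quantile at tail probability alpha/n (one-sided tests) or alpha/(2n)
    (two-sided), df = n-2.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    tail = alpha / n if side in ("max", "min") else alpha / (2 * n)
    t = sps.t.ppf(1.0 - tail, df=n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outlier(
    values, alpha: float = 0.05, side: str = "max", iterative: bool = False
):
    """Smirnoff-Grubbs single-outlier test.

    ``side="max"`` (default) is the one-tailed test of the largest value,
    G = (max - mean)/SD; ``side="min"`` symmetric for the smallest; and
    ``side="both"`` tests the most extreme deviation max|x - mean|/SD against
    the two-sided critical value.  Every variant rejects a true null with
    probability alpha.  At most one observation is flagged per pass; with
    ``iterative=True`` flagged points are removed and the test repeated,
    returning the list of flagged indices (into the original series).

    Returns the index of the outlier, or None (empty list when iterative).
    A zero-SD (constant) series flags nothing.
    """
    if side not in ("max", "min", "both"):
        raise ValueError("side must be 'max', 'min' or 'both'")
    x = np.asarray(list(values), dtype=float)
    if iterative:
        flagged: list[int] = []
        alive = np.arange(len(x))
        while len(alive) >= 3:
            idx = grubbs_outlier(x[alive], alpha=alpha, side=side, iterative=False)
            if idx is None:
                break
            flagged.append(int(alive[idx]))
            alive = np.delete(alive, idx)
        return flagged
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("constant series: no outlier")
        return None
    mean = x.mean()
    if side == "max":
        idx = int(np.argmax(x))
        g = (x[idx] - mean) / sd
    elif side == "min":
        idx = int(np.argmin(x))
        g = (mean - x[idx]) / sd
    else:
        idx = int(np.argmax(np.abs(x - mean)))
        g = abs(x[idx] - mean) / sd
    return idx if g > grubbs_critical(n, alpha, side) else None


def two_tailed_t(series_a, series_b, equal_variance: bool = True) -> float:
    """Two-tailed two-sample t-test p-value (Student by default, Welch
    optional).  Two zero-variance groups with equal means give p = 1 by
    convention; with different means, p = 0."""
    a = np.asarray(list(series_a), dtype=float)
    b = np.asarray(list(series_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        logger.info("degenerate variances: p = %g by convention", p)
        return p
    return float(sps.ttest_ind(a, b, equal_var=equal_variance).pvalue)
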