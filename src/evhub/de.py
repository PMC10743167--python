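"""Differential miRNA filtering: volcano classification and top-k selection.

The first stage of the pipeline reduces a miRNA count matrix (miRNAs x
samples, two conditions A and B) to a short list of strongly shifted miRNAs:

1. ``compute_stats`` — per-miRNA log2 fold change of B over A on CPM scale and
   a two-tailed Welch t p-value on log2(CPM + pseudocount).
2. ``classify`` — the volcano filter: ``up`` iff Fc > fc_thresh and
   p < p_thresh, ``down`` symmetric (Fc < 1/fc_thresh), else ``ns``.
3. ``select_top`` — up to k miRNAs per direction in descending |log2FC|.

The upstream vendor pipelines that produce such statistics vary; the module
therefore also reads precomputed (log2fc, p) tables so external output can be
slotted in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["mirna", "log2fc", "p", "direction"]


@dataclass
class ExpressionMatrix:
    """miRNA x sample count matrix with a two-level group labelling.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, index = miRNA ids, columns = sample ids.
    groups : mapping
        sample id -> "A" or "B"; every column must be labelled.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate miRNA ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        unlabelled = [s for s in self.counts.columns if s not in self.groups]
        if unlabelled:
            raise ValueError(f"samples without group label: {unlabelled}")
        bad = {g for g in self.groups.values()} - {"A", "B"}
        if bad:
            raise ValueError(f"group labels must be 'A' or 'B', got {sorted(bad)}")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


@dataclass
class Selection:
    """Ordered top-k volcano selection, one list per direction."""

    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    comparison: str = ""

    @property
    def mirnas(self) -> list[str]:
        return list(self.up) + list(self.down)

    def direction_of(self, mirna: str) -> str:
        if mirna in self.up:
            return "up"
        if mirna in self.down:
            return "down"
        raise KeyError(mirna)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million column normalization."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero library size")
    return counts.div(libsize, axis=1) * 1e6


def compute_stats(
    matrix: ExpressionMatrix, pseudocount: float = 0.5, normalize: bool = True
) -> pd.DataFrame:
    """Per-miRNA log2 fold change (B over A) and Welch two-tailed p-value.

    log2fc = log2((mean CPM_B + pseudocount) / (mean CPM_A + pseudocount));
    the p-value comes from an unequal-variance t test on log2(CPM +
    pseudocount).  A group with fewer than two samples yields p = NaN while
    the fold change is still reported.  ``normalize=False`` skips the CPM
    step and works on raw counts (for inputs already depth-normalized
    upstream; note CPM cancels any uniform between-group scaling).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    norm = cpm(matrix.counts) if normalize else matrix.counts.astype(float)
    a = norm[matrix.samples("A")]
    b = norm[matrix.samples("B")]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("each group needs at least one sample")
    log2fc = np.log2(b.mean(axis=1) + pseudocount) - np.log2(a.mean(axis=1) + pseudocount)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
        p = sps.ttest_ind(lb, la, axis=1, equal_var=False).pvalue
        # zero variance in both groups: identical -> p = 1, separated -> p = 0
        flat = (la.std(axis=1, ddof=1) == 0) & (lb.std(axis=1, ddof=1) == 0)
        if flat.any():
            p = np.where(flat, np.where(np.isclose(log2fc, 0.0), 1.0, 0.0), p)
    else:
        logger.warning("group with < 2 samples: p-values reported as missing")
        p = np.full(len(log2fc), np.nan)
    out = pd.DataFrame(
        {"mirna": matrix.counts.index, "log2fc": log2fc.to_numpy(), "p": p}
    )
    out["direction"] = "ns"
    return out.reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def classify(
    stats: pd.DataFrame,
    fc_thresh: float = 2.0,
    p_thresh: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Volcano classification into up / down / ns.

    ``up`` iff log2fc > log2(fc_thresh) and p < p_thresh; ``down`` iff
    log2fc < -log2(fc_thresh) and p < p_thresh; otherwise ``ns``.  Missing
    p-values classify as ``ns``.  With ``adjust=True`` the threshold is
    applied to Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValueError("thresholds must be positive")
    out = stats.copy()
    lfc_cut = np.log2(fc_thresh)
    p = _bh_adjust(out["p"].to_numpy()) if adjust else out["p"].to_numpy()
    sig = p < p_thresh  # NaN compares False
    out["direction"] = np.where(
        sig & (out["log2fc"] > lfc_cut),
        "up",
        np.where(sig & (out["log2fc"] < -lfc_cut), "down", "ns"),
    )
    n_up, n_down = (out["direction"] == "up").sum(), (out["direction"] == "down").sum()
    logger.info("volcano filter: %d up, %d down, %d ns", n_up, n_down, len(out) - n_up - n_down)
    return out


def select_top(
    classified: pd.DataFrame, k_per_direction: int = 4, comparison: str = ""
) -> Selection:
    """Up to k miRNAs per direction in descending |log2FC| ("up to" semantics).

    Ties in |log2FC| break lexicographically by miRNA id for reproducibility.
    """
    if k_per_direction < 0:
        raise ValueError("k_per_direction must be >= 0")

    def _top(direction: str, ascending_sign: int) -> list[str]:
        sub = classified[classified["direction"] == direction].copy()
        sub["_key"] = ascending_sign * sub["log2fc"]
        sub = sub.sort_values(["_key", "mirna"], ascending=[True, True])
        return sub["mirna"].head(k_per_direction).tolist()

    return Selection(
        up=_top("up", -1), down=_top("down", +1), comparison=comparison
    )


# ---------------------------------------------------------------------------
# TSV I/O


def read_counts(counts_path, groups_path) -> ExpressionMatrix:
    """Read a TSV count matrix (first column miRNA id, header = samples) and a
    two-column sample->group file (no header required: sample<TAB>A|B)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    grp = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
    return ExpressionMatrix(counts=counts, groups=dict(zip(grp["sample"], grp["group"])))


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_stats(path) -> pd.DataFrame:
    """Read a precomputed per-miRNA stats table (mirna, log2fc, p[, direction])."""
    out = pd.read_csv(path, sep="\t")
    missing = {"mirna", "log2fc", "p"} - set(out.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    if "direction" not in out.columns:
        out["direction"] = "ns"
    return out[STAT_COLUMNS]
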