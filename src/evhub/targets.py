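"""miRNA target mapping from context-score tables.

Consumes TargetScan-style tables of predicted miRNA->gene links scored by the
cumulative weighted context++ score (CWCS, log2 repression units; more
negative = stronger predicted knockdown), applies the reliability threshold
(default CWCS <= -0.4, i.e. >= ~24% predicted knockdown), and builds
per-comparison target-set unions for the up- and down-regulated miRNA groups.

Target records are held as a tidy DataFrame with columns ``mirna``, ``gene``,
``cwcs``; duplicate (mirna, gene) rows aggregate to the most negative score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .de import Selection

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["mirna", "gene", "cwcs"]

#: default column names of TargetScan "context scores" downloads
DEFAULT_DIALECT = {
    "mirna": "miRNA",
    "gene": "Gene Symbol",
    "cwcs": "Cumulative weighted context++ score",
}


def _normalize_records(records: pd.DataFrame) -> pd.DataFrame:
    records = records[RECORD_COLUMNS].copy()
    records["mirna"] = records["mirna"].astype(str).str.strip()
    records["gene"] = records["gene"].astype(str).str.strip()
    records["cwcs"] = records["cwcs"].astype(float)
    if not records["cwcs"].map(pd.notna).all() or not records["cwcs"].abs().lt(float("inf")).all():
        raise ValueError("non-finite CWCS value in target table")
    # most-negative score wins for duplicated (miRNA, gene) pairs
    return (
        records.groupby(["mirna", "gene"], as_index=False)["cwcs"]
        .min()
        .sort_values(["mirna", "gene"])
        .reset_index(drop=True)
    )


def read_targetscan(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Parse a context-score TSV into tidy (mirna, gene, cwcs) records.

    ``dialect`` maps the internal names to the file's column headers; column
    order in the file is irrelevant.  Duplicate (miRNA, gene) rows are
    aggregated by the most negative CWCS.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    table = pd.read_csv(path, sep="\t")
    for internal, column in dialect.items():
        if column not in table.columns:
            raise ValueError(f"target table is missing required column {column!r}")
    renamed = table.rename(columns={v: k for k, v in dialect.items()})
    return _normalize_records(renamed)


def write_targetscan(records: pd.DataFrame, path, dialect: dict[str, str] | None = None) -> None:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    records[RECORD_COLUMNS].rename(columns=dialect).to_csv(path, sep="\t", index=False)


def filter_targets(
    records: pd.DataFrame, cwcs_max: float = -0.4, inclusive: bool = True
) -> pd.DataFrame:
    """Keep links with CWCS <= cwcs_max (or < with ``inclusive=False``)."""
    if cwcs_max > 0:
        raise ValueError("cwcs_max must be <= 0")
    keep = records["cwcs"] <= cwcs_max if inclusive else records["cwcs"] < cwcs_max
    return records[keep].reset_index(drop=True)


@dataclass
class TargetMap:
    """Per-comparison target-gene bookkeeping for a miRNA selection.

    ``groups`` maps direction -> union of that group's per-miRNA target sets.
    The comparison total is reported as |up union| + |down union|: each
    direction group is counted on its own, matching how the per-direction
    subtotals are tallied downstream.
    """

    comparison: str
    per_mirna: dict[str, set[str]]
    groups: dict[str, set[str]]
    records: pd.DataFrame = field(repr=False)

    @property
    def group_counts(self) -> dict[str, int]:
        return {d: len(g) for d, g in self.groups.items()}

    @property
    def total(self) -> int:
        return sum(len(g) for g in self.groups.values())

    def cwcs(self, mirna: str, gene: str) -> float:
        hit = self.records[(self.records["mirna"] == mirna) & (self.records["gene"] == gene)]
        if hit.empty:
            raise KeyError((mirna, gene))
        return float(hit["cwcs"].iloc[0])


def build_target_map(
    selection: Selection, records: pd.DataFrame, comparison: str | None = None
) -> TargetMap:
    """Union the filtered target sets of the selected miRNAs per direction.

    A selected miRNA absent from the records contributes an empty set (with a
    warning) rather than failing, mirroring the "up to k" selection semantics.
    """
    per_mirna: dict[str, set[str]] = {}
    for mirna in selection.mirnas:
        genes = set(records.loc[records["mirna"] == mirna, "gene"])
        if not genes:
            logger.warning("selected miRNA %s has no target records", mirna)
        per_mirna[mirna] = genes
    groups = {
        "up": set().union(*(per_mirna[m] for m in selection.up)) if selection.up else set(),
        "down": set().union(*(per_mirna[m] for m in selection.down)) if selection.down else set(),
    }
    kept = records[records["mirna"].isin(per_mirna)].reset_index(drop=True)
    tm = TargetMap(
        comparison=comparison if comparison is not None else selection.comparison,
        per_mirna=per_mirna,
        groups=groups,
        records=kept,
    )
    logger.info(
        "target map %s: up union %d, down union %d, total %d",
        tm.comparison, len(groups["up"]), len(groups["down"]), tm.total,
    )
    return tm
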