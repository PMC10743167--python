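"""Candidate integration: merge both branches and infer regulation direction.

Each hub candidate is annotated with the selected miRNA that regulates it.
When several selected miRNAs target the same gene the one with the most
negative context score (strongest predicted repression) is assigned, with a
lexicographic tie-break on miRNA id.  Because miRNAs repress their targets,
the inferred regulation of the gene is the opposite of the miRNA's direction:
an up-regulated EV miRNA predicts down-regulation of its target gene, and
vice versa.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from .de import Selection
from .targets import TargetMap

logger = logging.getLogger(__name__)

_OPPOSITE = {"up": "down", "down": "up"}


@dataclass
class HubCandidate:
    """One predicted hub gene with provenance and regulation annotation."""

    gene: str
    branches: list[str]                     # subset of {"GD", "SK"}
    comparison: str = ""
    regulating_mirna: str | None = None     # None <=> unassigned
    mirna_direction: str | None = None      # "up" / "down"
    inferred_gene_regulation: str | None = None  # opposite of mirna_direction
    evidence: dict = field(default_factory=dict)  # mcc/degree or matched keywords
    note: str = ""                          # free-text biological annotation

    @property
    def assigned(self) -> bool:
        return self.regulating_mirna is not None


def assign_regulation(
    gene: str, target_map: TargetMap, selection: Selection
) -> tuple[str, str] | None:
    """(regulating miRNA, its direction) for a gene, or None if no selected
    miRNA targets it.

    Among selected miRNAs whose target set contains the gene, the most
    negative CWCS wins; ties break lexicographically by miRNA id.
    """
    hitting = [m for m in selection.mirnas if gene in target_map.per_mirna.get(m, ())]
    if not hitting:
        return None
    best = min(hitting, key=lambda m: (target_map.cwcs(m, gene), m))
    return best, selection.direction_of(best)


@dataclass
class ComparisonReport:
    """Integrated hub-candidate report for one comparison."""

    comparison: str
    candidates: list[HubCandidate]

    @property
    def branch_counts(self) -> dict[str, int]:
        return {
            b: sum(1 for c in self.candidates if b in c.branches) for b in ("GD", "SK")
        }

    @property
    def total(self) -> int:
        return len(self.candidates)

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "candidates": [asdict(c) for c in self.candidates],
            "branch_counts": self.branch_counts,
            "total": self.total,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            raw = json.loads(source)
        else:
            with open(source) as fh:
                raw = json.load(fh)
        return cls(
            comparison=raw["comparison"],
            candidates=[HubCandidate(**c) for c in raw["candidates"]],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "comparison": self.comparison,
                    "gene": c.gene,
                    "predicted_by": "+".join(c.branches),
                    "regulating_mirna": c.regulating_mirna or "unassigned",
                    "mirna_direction": c.mirna_direction or "",
                    "inferred_gene_regulation": c.inferred_gene_regulation or "",
                    "evidence": json.dumps(c.evidence, sort_keys=True),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _annotate(
    candidate: HubCandidate, target_map: TargetMap, selection: Selection
) -> HubCandidate:
    hit = assign_regulation(candidate.gene, target_map, selection)
    if hit is None:
        logger.warning(
            "%s: no selected miRNA targets %s — left unassigned",
            target_map.comparison, candidate.gene,
        )
        return candidate
    mirna, direction = hit
    candidate.regulating_mirna = mirna
    candidate.mirna_direction = direction
    candidate.inferred_gene_regulation = _OPPOSITE[direction]
    return candidate


def merge_candidates(
    gd_candidates: list[HubCandidate],
    sk_candidates: list[HubCandidate],
    target_map: TargetMap | None = None,
    selection: Selection | None = None,
    comparison: str = "",
) -> ComparisonReport:
    """Union both branches into one report, deduplicating by gene.

    A gene nominated by both branches appears once with both provenance tags
    and merged evidence.  When a target map and selection are supplied every
    candidate gets its regulating miRNA (or an explicit unassigned state).
    """
    merged: dict[str, HubCandidate] = {}
    for cand in [*gd_candidates, *sk_candidates]:
        if cand.gene in merged:
            kept = merged[cand.gene]
            kept.branches = sorted(set(kept.branches) | set(cand.branches))
            kept.evidence = {**cand.evidence, **kept.evidence}
        else:
            merged[cand.gene] = HubCandidate(
                gene=cand.gene,
                branches=sorted(set(cand.branches)),
                comparison=comparison or cand.comparison,
                regulating_mirna=cand.regulating_mirna,
                mirna_direction=cand.mirna_direction,
                inferred_gene_regulation=cand.inferred_gene_regulation,
                evidence=dict(cand.evidence),
                note=cand.note,
            )
    candidates = list(merged.values())
    if target_map is not None and selection is not None:
        candidates = [_annotate(c, target_map, selection) for c in candidates]
    report = ComparisonReport(comparison=comparison, candidates=candidates)
    logger.info(
        "report %s: %d candidates (%s)", comparison, report.total, report.branch_counts
    )
    return report


def gd_to_candidates(ranking, comparison: str = "") -> list[HubCandidate]:
    """Wrap a :class:`~evhub.network.HubRanking` candidate list."""
    rows = ranking.top.set_index("gene")
    return [
        HubCandidate(
            gene=g,
            branches=["GD"],
            comparison=comparison,
            evidence={"mcc": int(rows.loc[g, "mcc"]), "degree": int(rows.loc[g, "degree"])},
        )
        for g in ranking.candidates
    ]


def sk_to_candidates(hits: pd.DataFrame, selected_genes, comparison: str = "") -> list[HubCandidate]:
    """Wrap keyword-branch selections with their matched keyword evidence."""
    matched = dict(zip(hits["gene"], hits["matched"]))
    return [
        HubCandidate(
            gene=g,
            branches=["SK"],
            comparison=comparison,
            evidence={"keywords": list(matched.get(g, ()))},
        )
        for g in selected_genes
    ]
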