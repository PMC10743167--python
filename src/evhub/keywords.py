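"""Specific-keyword branch: bipartite keyword-gene annotation networks.

A curated lexicon of immune/inflammation keywords (18 canonical keywords in
three categories by default) is matched against free-text gene annotation
descriptions.  Each (keyword, gene) match is an edge of a bipartite network;
a gene's bipartite degree — the number of distinct canonical keywords its
description contains — is the selection statistic.

Matching is deliberately conservative: case-insensitive, token-boundary
matching after normalizing hyphens, slashes and whitespace, so "T-cell" and
"T cell" are equivalent while "CD3" does not fire inside "CD34".  Each
canonical keyword may carry variant spellings (synonyms); a keyword matches
iff any variant occurs as a contiguous token sequence, and counts once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES: dict[str, list[str]] = {
    "Immune Responses": ["Immune", "Cytotoxicity", "Phagocytosis"],
    "Immune Cells": ["T cell", "B cell", "Dendritic", "Helper", "Macrophage", "Myeloid"],
    "Inflammation Signaling": [
        "Inflammation", "Cytokine", "Interleukin", "NF-kappaB", "TGF-beta",
        "JAK/Stat", "CD3", "CD4", "CD8",
    ],
}

# variant spellings beyond the canonical surface form (user-overridable)
DEFAULT_SYNONYMS: dict[str, list[str]] = {
    "Immune": ["immunity"],
    "Cytotoxicity": ["cytotoxic"],
    "Phagocytosis": ["phagocytic"],
    "T cell": ["T cells", "T lymphocyte", "T lymphocytes"],
    "B cell": ["B cells", "B lymphocyte", "B lymphocytes"],
    "Macrophage": ["macrophages"],
    "Inflammation": ["inflammatory"],
    "Cytokine": ["cytokines"],
    "Interleukin": ["interleukins"],
    "NF-kappaB": ["NF-kB", "NF-κB", "NF kappa B", "nuclear factor kappa B"],
    "TGF-beta": ["TGF-β", "TGFbeta", "transforming growth factor beta"],
    "JAK/Stat": ["JAK-STAT", "JAK/STAT"],
}

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)
_DASHES = "-‐‑‒–—/"


def _tokens(text: str) -> tuple[str, ...]:
    text = str(text).lower().translate({ord(c): " " for c in _DASHES})
    return tuple(_TOKEN_RE.findall(text))


@dataclass
class KeywordLexicon:
    """Canonical keywords grouped by category, with variant spellings."""

    categories: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATEGORIES.items()}
    )
    synonyms: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SYNONYMS.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for words in self.categories.values():
            for w in words:
                if w in seen:
                    raise ValueError(f"duplicate canonical keyword {w!r}")
                seen.add(w)
        stray = set(self.synonyms) - seen
        if stray:
            raise ValueError(f"synonyms for unknown keywords: {sorted(stray)}")

    @property
    def keywords(self) -> list[str]:
        return [w for words in self.categories.values() for w in words]

    def variants(self, keyword: str) -> list[str]:
        return [keyword, *self.synonyms.get(keyword, [])]

    def compiled(self) -> dict[str, list[tuple[str, ...]]]:
        """keyword -> tokenized variant sequences, ready for matching."""
        return {
            kw: [_tokens(v) for v in self.variants(kw)] for kw in self.keywords
        }

    @classmethod
    def from_yaml(cls, path) -> "KeywordLexicon":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            categories=raw["categories"], synonyms=raw.get("synonyms", {})
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"categories": self.categories, "synonyms": self.synonyms}, fh,
                allow_unicode=True, sort_keys=False,
            )


def default_lexicon() -> KeywordLexicon:
    return KeywordLexicon()


def _contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    if not needle or len(needle) > len(haystack):
        return False
    first = needle[0]
    span = len(needle)
    for i, tok in enumerate(haystack[: len(haystack) - span + 1]):
        if tok == first and haystack[i : i + span] == needle:
            return True
    return False


def match_keywords(text: str, lexicon: KeywordLexicon | None = None) -> set[str]:
    """Canonical keywords whose variants occur in the text (each at most once)."""
    lexicon = lexicon or default_lexicon()
    toks = _tokens(text)
    return {
        kw
        for kw, variant_tokens in lexicon.compiled().items()
        if any(_contains(toks, v) for v in variant_tokens)
    }


def build_keyword_network(
    genes,
    annotations: pd.DataFrame | dict[str, str],
    lexicon: KeywordLexicon | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite keyword-gene network over a gene set.

    ``annotations`` is a (gene, description) table or mapping; a gene without
    an annotation scores degree 0 (logged).  Returns the bipartite graph
    (keyword nodes carry ``bipartite=0``, genes ``bipartite=1``; only genes
    with degree >= 1 enter the graph) and a per-gene hit table with columns
    ``gene``, ``matched`` (sorted tuple) and ``degree``.
    """
    lexicon = lexicon or default_lexicon()
    if isinstance(annotations, pd.DataFrame):
        annotations = dict(zip(annotations["gene"], annotations["description"]))
    compiled = lexicon.compiled()
    graph = nx.Graph()
    graph.add_nodes_from(compiled, bipartite=0)
    rows = []
    for gene in genes:
        text = annotations.get(gene)
        if text is None:
            logger.warning("gene %s has no annotation: degree 0", gene)
            matched: set[str] = set()
        else:
            toks = _tokens(text)
            matched = {
                kw for kw, vs in compiled.items() if any(_contains(toks, v) for v in vs)
            }
        if matched:
            graph.add_node(gene, bipartite=1)
            graph.add_edges_from((kw, gene) for kw in matched)
        rows.append((gene, tuple(sorted(matched)), len(matched)))
    hits = pd.DataFrame(rows, columns=["gene", "matched", "degree"])
    return graph, hits


def select_by_degree(hits: pd.DataFrame, min_degree: int = 4) -> list[str]:
    """Genes with bipartite degree >= min_degree, degree-descending then
    lexicographic."""
    kept = hits[hits["degree"] >= min_degree]
    return kept.sort_values(["degree", "gene"], ascending=[False, True])["gene"].tolist()


def write_bipartite_sif(graph: nx.Graph, path, relation: str = "kw") -> None:
    """Keyword-gene edges in simple interaction format (keyword first)."""
    with open(path, "w") as fh:
        for kw, gene in sorted(
            (u, v) if graph.nodes[u].get("bipartite") == 0 else (v, u)
            for u, v in graph.edges
        ):
            fh.write(f"{kw}\t{relation}\t{gene}\n")
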