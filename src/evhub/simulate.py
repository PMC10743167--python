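"""Seeded synthetic-data generators for every pipeline stage.

Raw EV small-RNA sequencing data behind studies of this kind is rarely
deposited, so the package ships generators that reproduce the *statistical
structure* each stage assumes: overdispersed negative-binomial miRNA counts
with planted fold changes, target tables with controlled per-miRNA set sizes
and overlap, interaction graphs with planted cliques, and annotation texts
with planted keywords embedded in keyword-free filler prose.  Every generator
is a pure function of its seed and spec: the same seed yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .keywords import KeywordLexicon, default_lexicon, match_keywords
from .targets import RECORD_COLUMNS

#: fixed keyword-free vocabulary for annotation filler prose; none of these
#: tokens occurs in any default lexicon variant, so filler can never create
#: an accidental keyword match
FILLER_WORDS = (
    "protein binding domain receptor membrane transport pathway regulation "
    "expression kinase enzyme substrate nucleus mitochondria ribosome "
    "transcription translation metabolic vesicle growth division repair "
    "replication conserved motif residue structural catalytic activity "
    "localization tissue organ development adhesion polymerase ligase "
    "phosphatase ubiquitin chaperone cytoskeleton secretion endosome"
).split()


@dataclass
class SimSpec:
    """Study design for the count generator.

    ``planted_effects`` maps miRNA ids to true log2 fold changes of group B
    over group A; every other miRNA is null.  Counts are negative binomial
    with variance mean + dispersion * mean^2; per-miRNA baseline means are
    log-normal around ``baseline_mean`` (sdlog ``mean_sdlog``), mimicking the
    wide abundance range of small-RNA libraries.
    """

    seed: int = 0
    n_mirnas: int = 500
    n_per_group: int = 3
    planted_effects: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    baseline_mean: float = 200.0
    mean_sdlog: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_mirnas <= 0 or self.n_per_group <= 0:
            raise ValueError("n_mirnas and n_per_group must be positive")
        bad = set(self.planted_effects) - set(self.mirna_ids)
        if bad:
            raise ValueError(f"planted effects for unknown miRNAs: {sorted(bad)}")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-sim-{i:04d}" for i in range(self.n_mirnas)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_counts(spec: SimSpec) -> ExpressionMatrix:
    """Negative-binomial count matrix for a two-group design.

    Group B means are the group A means scaled by 2**(planted log2FC).
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.mirna_ids
    base = spec.baseline_mean * rng.lognormal(
        mean=0.0, sigma=spec.mean_sdlog, size=spec.n_mirnas
    )
    lfc = np.array([spec.planted_effects.get(m, 0.0) for m in ids])
    mean_a = np.tile(base[:, None], (1, spec.n_per_group))
    mean_b = np.tile((base * 2.0**lfc)[:, None], (1, spec.n_per_group))
    counts_a = _nb_draw(rng, mean_a, spec.dispersion)
    counts_b = _nb_draw(rng, mean_b, spec.dispersion)
    samples = [f"A{i + 1}" for i in range(spec.n_per_group)] + [
        f"B{i + 1}" for i in range(spec.n_per_group)
    ]
    counts = pd.DataFrame(
        np.hstack([counts_a, counts_b]), index=pd.Index(ids, name="mirna"),
        columns=samples,
    )
    groups = {s: s[0] for s in samples}
    return ExpressionMatrix(counts=counts, groups=groups)


@dataclass
class TargetTableSpec:
    """Shape of a synthetic target table.

    ``overlap_mode="disjoint"`` gives every miRNA a fresh, pairwise-disjoint
    gene set — the regime in which group-union sizes are exactly additive.
    ``overlap_mode="random"`` reuses an already-generated gene with
    probability ``overlap_p`` per link, so unions can shrink by collision.
    """

    per_mirna_counts: dict[str, int]
    overlap_mode: str = "disjoint"
    overlap_p: float = 0.5
    cwcs_range: tuple[float, float] = (-1.2, -0.4)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.per_mirna_counts.values()):
            raise ValueError("per-miRNA target counts must be >= 0")
        if self.overlap_mode not in ("disjoint", "random"):
            raise ValueError("overlap_mode must be 'disjoint' or 'random'")
        if not 0.0 <= self.overlap_p <= 1.0:
            raise ValueError("overlap_p must be a probability")
        lo, hi = self.cwcs_range
        if not (lo <= hi <= 0):
            raise ValueError("cwcs_range must be an interval of scores <= 0")


def gen_target_table(spec: TargetTableSpec, seed: int = 0) -> pd.DataFrame:
    """Tidy (mirna, gene, cwcs) records with exact per-miRNA set sizes."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.cwcs_range
    rows = []
    pool: list[str] = []
    fresh = 0
    for mirna in sorted(spec.per_mirna_counts):
        count = spec.per_mirna_counts[mirna]
        genes: set[str] = set()
        while len(genes) < count:
            if (
                spec.overlap_mode == "random"
                and pool
                and rng.random() < spec.overlap_p
            ):
                gene = pool[rng.integers(len(pool))]
                if gene in genes:  # keep per-miRNA sets duplicate-free
                    continue
            else:
                gene = f"G{fresh:06d}"
                fresh += 1
            genes.add(gene)
        for gene in sorted(genes):
            rows.append((mirna, gene, float(rng.uniform(lo, hi))))
        pool.extend(sorted(genes - set(pool)))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def gen_ppi(
    n_background: int,
    edge_prob: float,
    planted_cliques: list[int] | tuple[int, ...] = (),
    seed: int = 0,
) -> nx.Graph:
    """Erdos-Renyi background graph with complete cliques planted on fresh
    nodes.

    Background nodes are labelled ``BG####``; planted-clique nodes carry the
    reserved ``PC`` prefix (``PC<k>_<i>``) so tests can identify them without
    the labels influencing any score.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be a probability")
    if any(s < 2 for s in planted_cliques):
        raise ValueError("planted clique sizes must be >= 2")
    rng = np.random.default_rng(seed)
    graph = nx.Graph()
    background = [f"BG{i:04d}" for i in range(n_background)]
    graph.add_nodes_from(background)
    if n_background > 1 and edge_prob > 0:
        iu, ju = np.triu_indices(n_background, k=1)
        mask = rng.random(len(iu)) < edge_prob
        graph.add_edges_from(
            (background[i], background[j]) for i, j in zip(iu[mask], ju[mask])
        )
    for k, size in enumerate(planted_cliques):
        members = [f"PC{k}_{i:02d}" for i in range(size)]
        graph.add_edges_from(
            (members[i], members[j]) for i in range(size) for j in range(i + 1, size)
        )
    return graph


def gen_annotations(
    keyword_plan: dict[str, set[str] | tuple[str, ...] | list[str]],
    n_decoys: int = 0,
    lexicon: KeywordLexicon | None = None,
    seed: int = 0,
    decoy_max_keywords: int = 0,
    filler_len: int = 12,
) -> pd.DataFrame:
    """Annotation corpus with planted keywords in keyword-free filler prose.

    Each planned gene's description contains exactly its planned keywords
    (via a deterministic variant choice) interleaved with filler words; decoy
    genes (``DEC###``) get filler descriptions with at most
    ``decoy_max_keywords`` randomly drawn lexicon keywords.  The output is
    self-checked with the matcher: a planned description that matches
    anything beyond its plan is a bug, not a warning.
    """
    lexicon = lexicon or default_lexicon()
    canonical = set(lexicon.keywords)
    for gene, kws in keyword_plan.items():
        stray = set(kws) - canonical
        if stray:
            raise ValueError(f"planned keywords outside lexicon for {gene}: {sorted(stray)}")
    rng = np.random.default_rng(seed)

    def filler(n: int) -> list[str]:
        return [FILLER_WORDS[i] for i in rng.integers(len(FILLER_WORDS), size=n)]

    rows = []
    for gene in sorted(keyword_plan):
        words = filler(filler_len)
        for kw in sorted(keyword_plan[gene]):
            variants = lexicon.variants(kw)
            surface = variants[rng.integers(len(variants))]
            words.insert(int(rng.integers(len(words) + 1)), surface)
        text = " ".join(words)
        if match_keywords(text, lexicon) != set(keyword_plan[gene]):
            raise AssertionError(f"generated text for {gene} does not match its plan")
        rows.append((gene, text))
    for d in range(n_decoys):
        words = filler(filler_len)
        n_kw = int(rng.integers(decoy_max_keywords + 1))
        for kw in rng.choice(sorted(canonical), size=n_kw, replace=False):
            words.insert(int(rng.integers(len(words) + 1)), kw)
        rows.append((f"DEC{d:03d}", " ".join(words)))
    return pd.DataFrame(rows, columns=["gene", "description"])


def write_counts(matrix: ExpressionMatrix, counts_path, groups_path) -> None:
    """TSV companions to :func:`evhub.de.read_counts`."""
    matrix.counts.to_csv(counts_path, sep="\t")
    with open(groups_path, "w") as fh:
        for sample in matrix.counts.columns:
            fh.write(f"{sample}\t{matrix.groups[sample]}\n")
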