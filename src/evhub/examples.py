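"""Reference fixtures and end-to-end workflow over the bundled dataset.

These builders turn the bundled study summary (:mod:`evhub.datasets`) into
complete stage inputs: a per-miRNA stats table and selection, a synthetic
disjoint target table with the published per-miRNA set sizes (and the
published hub genes injected as targets of their regulating miRNAs), an
annotation corpus embedding the published keyword assignments among decoys,
and finally the integrated per-comparison report.  They drive the README
example, the test fixtures and the acceptance script.
"""

from __future__ import annotations

import pandas as pd

from . import datasets, de, integrate, keywords, simulate, targets


def reference_stats(comparison: str) -> pd.DataFrame:
    """Per-miRNA (log2fc, p) table for one comparison.

    The bundled summary lists only miRNAs that passed the volcano filter, so
    each gets a placeholder p-value well below the 0.05 threshold.
    """
    summary = datasets.mirna_summary()
    rows = summary[summary["comparison"] == comparison]
    return pd.DataFrame(
        {
            "mirna": rows["mirna"],
            "log2fc": rows["log2fc"],
            "p": 0.001,
            "direction": "ns",
        }
    ).reset_index(drop=True)


def reference_selection(comparison: str) -> de.Selection:
    """Top-4-per-direction selection recomputed through the volcano filter."""
    classified = de.classify(reference_stats(comparison))
    return de.select_top(classified, k_per_direction=4, comparison=comparison)


def reference_target_table(comparison: str, seed: int = 0) -> pd.DataFrame:
    """Disjoint synthetic target table with the published per-miRNA sizes.

    Target-set sizes equal the bundled per-miRNA counts and sets are pairwise
    disjoint, the regime in which direction-group unions are exactly
    additive.  Each published hub candidate replaces one synthetic gene in
    its regulating miRNA's set, so regulation assignment can be exercised on
    real gene symbols without changing any set size.
    """
    sizes = datasets.target_set_sizes(comparison)
    spec = simulate.TargetTableSpec(per_mirna_counts=sizes, overlap_mode="disjoint")
    table = simulate.gen_target_table(spec, seed=seed)
    injected = [
        (gene, mirna)
        for gene, _, _, mirna in datasets.GD_CANDIDATES[comparison]
    ] + [
        (gene, mirna) for gene, mirna, _ in datasets.SK_CANDIDATES[comparison]
    ]
    used: dict[str, int] = {}
    for gene, mirna in injected:
        slots = table.index[table["mirna"] == mirna]
        slot = slots[used.get(mirna, 0)]
        used[mirna] = used.get(mirna, 0) + 1
        table.loc[slot, "gene"] = gene
    return table


def reference_annotations(comparison: str, n_decoys: int = 20, seed: int = 0) -> pd.DataFrame:
    """Annotation corpus embedding the published keyword assignments."""
    plan = {
        gene: set(kws) for gene, _, kws in datasets.SK_CANDIDATES[comparison]
    }
    return simulate.gen_annotations(plan, n_decoys=n_decoys, seed=seed)


def reference_report(comparison: str, seed: int = 0) -> integrate.ComparisonReport:
    """Integrated hub-candidate report for one comparison, recomputed from
    the reference fixtures through every pipeline stage that applies."""
    selection = reference_selection(comparison)
    records = targets.filter_targets(reference_target_table(comparison, seed=seed))
    target_map = targets.build_target_map(selection, records, comparison=comparison)

    gd = [
        integrate.HubCandidate(
            gene=gene, branches=["GD"], comparison=comparison,
            evidence={"mcc": mcc, "degree": degree},
        )
        for gene, mcc, degree, _ in datasets.GD_CANDIDATES[comparison]
    ]

    corpus = reference_annotations(comparison, seed=seed)
    gene_pool = corpus["gene"].tolist()
    _, hits = keywords.build_keyword_network(gene_pool, corpus)
    sk_genes = keywords.select_by_degree(hits, min_degree=4)
    sk = integrate.sk_to_candidates(hits, sk_genes, comparison=comparison)

    return integrate.merge_candidates(
        gd, sk, target_map=target_map, selection=selection, comparison=comparison
    )


def grand_total(seed: int = 0) -> dict:
    """Target-union bookkeeping for both comparisons plus the grand total."""
    out: dict = {"comparisons": {}}
    total = 0
    for comparison in datasets.COMPARISONS:
        selection = reference_selection(comparison)
        records = targets.filter_targets(reference_target_table(comparison, seed=seed))
        tm = targets.build_target_map(selection, records, comparison=comparison)
        out["comparisons"][comparison] = {
            "group_counts": tm.group_counts,
            "total": tm.total,
        }
        total += tm.total
    out["grand_total"] = total
    return out
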