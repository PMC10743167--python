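"""Bundled reference dataset: a two-comparison mouse melanoma EV miRNA screen.

The package ships the summary tables of an extracellular-vesicle (EV) miRNA
study on mouse melanoma metastasis as its worked example.  Two comparisons are
covered: metastasis-suppressive Nanog+F10 EVs versus parental F10 EVs, and
iPS-cell EVs versus Nanog+F10 EVs.  For each comparison the screen retained
the four most up- and four most down-regulated miRNAs, mapped their predicted
targets (cumulative weighted context++ score <= -0.4), and nominated hub genes
through two branches: interaction-network MCC ranking ("GD", global data) and
bipartite keyword-network degree ("SK", specific keyword).

These constants are used by the test-suite fixtures, the acceptance script and
the README example; they are plain inputs, not results computed here.
"""

from __future__ import annotations

import pandas as pd

NANOG_VS_F10 = "Nanog+F10-EVs/F10-EVs"
IPS_VS_NANOG = "iPS-EVs/Nanog+F10-EVs"

COMPARISONS = (NANOG_VS_F10, IPS_VS_NANOG)

# Per-miRNA differential summary: log2 fold change of the selected miRNAs,
# the size of each miRNA's filtered target-gene set, and how many of its
# targets fall inside the comparison's top-30 MCC genes.
_MIRNA_ROWS = [
    # comparison, mirna, log2fc, n_targets, n_top30_links
    (NANOG_VS_F10, "miR-18a-5p", 2.46, 42, 4),
    (NANOG_VS_F10, "miR-3473e", 1.75, 6, 0),
    (NANOG_VS_F10, "miR-19a-3p", 1.20, 126, 11),
    (NANOG_VS_F10, "miR-3473b", 1.18, 127, 5),
    (NANOG_VS_F10, "miR-210-3p", -3.62, 6, 0),
    (NANOG_VS_F10, "miR-369-3p", -2.52, 7, 2),
    (NANOG_VS_F10, "miR-122-5p", -1.79, 29, 5),
    (NANOG_VS_F10, "miR-706", -1.28, 62, 3),
    (IPS_VS_NANOG, "miR-466h-3p", 7.62, 58, 1),
    (IPS_VS_NANOG, "miR-706", 6.23, 62, 3),
    (IPS_VS_NANOG, "miR-323-3p", 6.23, 10, 0),
    (IPS_VS_NANOG, "miR-466f-3p", 6.07, 145, 5),
    (IPS_VS_NANOG, "miR-30a-3p", -4.99, 49, 0),
    (IPS_VS_NANOG, "miR-342-5p", -4.74, 335, 20),
    (IPS_VS_NANOG, "let-7c-5p", -4.63, 2, 0),
    (IPS_VS_NANOG, "miR-423-3p", -4.36, 8, 1),
]


def mirna_summary() -> pd.DataFrame:
    """The selected miRNAs of both comparisons as a tidy DataFrame."""
    return pd.DataFrame(
        _MIRNA_ROWS,
        columns=["comparison", "mirna", "log2fc", "n_targets", "n_top30_links"],
    )


# GD-branch hub candidates: gene, MCC score, interaction degree, and the
# regulating miRNA reported for each (direction implied by the miRNA's sign
# in the differential summary).
GD_CANDIDATES = {
    NANOG_VS_F10: [
        ("Trp53", 1058, 23, "miR-3473b"),
        ("Hif1a", 990, 19, "miR-18a-5p"),
        ("Esr1", 919, 11, "miR-18a-5p"),
        ("Atm", 872, 9, "miR-18a-5p"),
        ("Cdkn1b", 847, 7, "miR-706"),
    ],
    IPS_VS_NANOG: [
        ("Ins1", 13801, 19, "miR-466f-3p"),
        ("Kitl", 13493, 15, "miR-466f-3p"),
        ("Fgf16", 13254, 11, "miR-466f-3p"),
        ("Grb2", 11784, 15, "miR-466f-3p"),
        ("Fgf1", 11640, 11, "miR-342-5p"),
    ],
}

# SK-branch hub candidates: gene, regulating miRNA, and the four lexicon
# keywords matched in the gene's annotation description.
SK_CANDIDATES = {
    NANOG_VS_F10: [
        ("Rnf11", "miR-19a-3p", ("Immune", "Cytokine", "NF-kappaB", "TGF-beta")),
    ],
    IPS_VS_NANOG: [
        ("Malt1", "miR-466f-3p", ("Immune", "T cell", "B cell", "Helper")),
        ("Il1f6", "miR-30a-3p", ("T cell", "Dendritic", "Interleukin", "NF-kappaB")),
        ("Cmklr1", "miR-342-5p", ("Immune", "Macrophage", "Inflammation", "NF-kappaB")),
        ("Siglec1", "miR-342-5p", ("T cell", "Macrophage", "B cell", "CD8")),
        ("Cd28", "miR-342-5p", ("Cytotoxicity", "Immune", "T cell", "CD4")),
    ],
}


def target_set_sizes(comparison: str) -> dict[str, int]:
    """Per-miRNA filtered target-set size for one comparison."""
    return {
        m: n for c, m, _, n, _ in _MIRNA_ROWS if c == comparison
    }


def mirna_directions(comparison: str) -> dict[str, str]:
    """Direction call ('up'/'down') per selected miRNA of a comparison."""
    return {
        m: ("up" if lfc > 0 else "down")
        for c, m, lfc, _, _ in _MIRNA_ROWS
        if c == comparison
    }
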