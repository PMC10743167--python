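import numpy as np
import pandas as pd
import pytest

from evhub import datasets, examples
from evhub.de import ExpressionMatrix


@pytest.fixture
def nanog():
    return datasets.NANOG_VS_F10


@pytest.fixture
def ips():
    return datasets.IPS_VS_NANOG


@pytest.fixture
def tiny_matrix():
    """4 miRNAs x 6 samples with hand-checkable structure."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(50, 500, size=(4, 6)),
        index=[f"miR-{i}" for i in range(4)],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"],
    )
    return ExpressionMatrix(counts=counts, groups={s: s[0] for s in counts.columns})


@pytest.fixture
def reference_maps():
    """Target maps for both comparisons built from the bundled fixtures."""
    from evhub import targets

    out = {}
    for comparison in datasets.COMPARISONS:
        sel = examples.reference_selection(comparison)
        records = targets.filter_targets(examples.reference_target_table(comparison))
        out[comparison] = (sel, targets.build_target_map(sel, records, comparison=comparison))
    return out
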