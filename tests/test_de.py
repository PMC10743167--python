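"""Differential-expression stage: statistics, volcano filter, top-k selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evhub import de, examples
from evhub.simulate import SimSpec, gen_counts


def _stats_frame(rows):
    return pd.DataFrame(rows, columns=["mirna", "log2fc", "p"]).assign(direction="ns")


class TestComputeStats:
    def test_identical_groups_give_zero_log2fc(self):
        counts = pd.DataFrame(
            {"A1": [10, 200], "A2": [30, 50], "B1": [10, 200], "B2": [30, 50]},
            index=["miR-1", "miR-2"],
        )
        m = de.ExpressionMatrix(counts, {s: s[0] for s in counts.columns})
        stats = de.compute_stats(m)
        assert np.allclose(stats["log2fc"], 0.0)

    def test_uniform_eightfold_scaling_is_exactly_three_unnormalized(self):
        # on pre-normalized data, B = 8x A uniformly gives log2fc = 3 exactly
        counts = pd.DataFrame(
            {"A1": [100, 40], "A2": [100, 40], "B1": [800, 320], "B2": [800, 320]},
            index=["m1", "m2"],
        )
        m = de.ExpressionMatrix(counts, {s: s[0] for s in counts.columns})
        stats = de.compute_stats(m, pseudocount=1e-12, normalize=False)
        assert np.allclose(stats["log2fc"], 3.0)

    def test_cpm_cancels_library_depth(self):
        # doubling one sample's depth uniformly must not shift fold changes
        counts = pd.DataFrame(
            {"A1": [100, 40], "A2": [200, 80], "B1": [100, 40], "B2": [100, 40]},
            index=["m1", "m2"],
        )
        m = de.ExpressionMatrix(counts, {s: s[0] for s in counts.columns})
        stats = de.compute_stats(m, pseudocount=1e-12)
        assert np.allclose(stats["log2fc"], 0.0, atol=1e-9)

    def test_single_sample_group_reports_missing_p(self):
        counts = pd.DataFrame(
            {"A1": [10, 20], "B1": [40, 20], "B2": [41, 19]}, index=["m1", "m2"]
        )
        m = de.ExpressionMatrix(counts, {"A1": "A", "B1": "B", "B2": "B"})
        stats = de.compute_stats(m)
        assert stats["p"].isna().all()
        assert np.isfinite(stats["log2fc"]).all()

    def test_planted_effect_recovered_on_average(self):
        # planted log2FC = 2.46 estimated within +-0.5 averaged over seeds
        target = 2.46
        ests = []
        for seed in range(30):
            spec = SimSpec(
                seed=seed, n_mirnas=30, n_per_group=10, dispersion=0.1,
                planted_effects={"miR-sim-0000": target},
            )
            stats = de.compute_stats(gen_counts(spec)).set_index("mirna")
            ests.append(stats.loc["miR-sim-0000", "log2fc"])
        assert abs(np.mean(ests) - target) < 0.5

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"A1": [-1], "B1": [2]}, index=["m"])
        with pytest.raises(ValueError, match="non-negative"):
            de.ExpressionMatrix(counts, {"A1": "A", "B1": "B"})


class TestClassify:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (2.46, 0.01, "up"),       # strong fold change, significant
            (-3.62, 0.01, "down"),
            (0.9, 0.001, "ns"),       # below fold-change threshold
            (3.0, 0.2, "ns"),         # not significant
            (1.0, 0.01, "ns"),        # boundary: log2fc must exceed log2(2)
            (np.nan, np.nan, "ns"),   # missing p never classifies
        ],
    )
    def test_volcano_rule(self, log2fc, p, expected):
        out = de.classify(_stats_frame([("m", log2fc, p)]))
        assert out["direction"].iloc[0] == expected

    def test_idempotent(self):
        stats = _stats_frame([("a", 2.0, 0.01), ("b", -2.0, 0.2), ("c", 0.1, 0.5)])
        once = de.classify(stats)
        twice = de.classify(once)
        pd.testing.assert_frame_equal(once, twice)

    @given(st.floats(min_value=1.0, max_value=16.0), st.floats(min_value=1.0, max_value=16.0))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotone(self, fc_lo, fc_hi):
        # raising fc_thresh never adds members to up/down
        lo, hi = sorted([fc_lo, fc_hi])
        stats = _stats_frame(
            [(f"m{i}", lfc, 0.01) for i, lfc in enumerate(np.linspace(-5, 5, 21))]
        )
        strict = de.classify(stats, fc_thresh=hi)
        loose = de.classify(stats, fc_thresh=lo)
        for direction in ("up", "down"):
            assert set(strict[strict["direction"] == direction]["mirna"]) <= set(
                loose[loose["direction"] == direction]["mirna"]
            )


class TestSelectTop:
    def test_published_ordering_recovered(self, nanog):
        sel = examples.reference_selection(nanog)
        assert sel.up == ["miR-18a-5p", "miR-3473e", "miR-19a-3p", "miR-3473b"]
        assert sel.down == ["miR-210-3p", "miR-369-3p", "miR-122-5p", "miR-706"]

    def test_up_to_semantics(self):
        stats = de.classify(_stats_frame([("a", 2.0, 0.01), ("b", 3.0, 0.01)]))
        sel = de.select_top(stats, k_per_direction=4)
        assert sel.up == ["b", "a"] and sel.down == []

    def test_k_zero_gives_empty_selection(self):
        stats = de.classify(_stats_frame([("a", 2.0, 0.01)]))
        sel = de.select_top(stats, k_per_direction=0)
        assert sel.mirnas == []

    def test_ties_break_lexicographically(self):
        stats = de.classify(_stats_frame([("zzz", 2.0, 0.01), ("aaa", 2.0, 0.01)]))
        assert de.select_top(stats, k_per_direction=1).up == ["aaa"]

    def test_selection_subset_of_classified(self, tiny_matrix):
        stats = de.classify(de.compute_stats(tiny_matrix))
        sel = de.select_top(stats, k_per_direction=2)
        up_set = set(stats[stats["direction"] == "up"]["mirna"])
        down_set = set(stats[stats["direction"] == "down"]["mirna"])
        assert set(sel.up) <= up_set and set(sel.down) <= down_set
        assert len(sel.up) <= 2 and len(sel.down) <= 2


def test_stats_tsv_round_trip(tmp_path, tiny_matrix):
    stats = de.classify(de.compute_stats(tiny_matrix))
    path = tmp_path / "stats.tsv"
    de.write_stats(stats, path)
    back = de.read_stats(path)
    pd.testing.assert_frame_equal(back, stats[de.STAT_COLUMNS])


def test_counts_tsv_round_trip(tmp_path, tiny_matrix):
    from evhub.simulate import write_counts

    write_counts(tiny_matrix, tmp_path / "c.tsv", tmp_path / "g.tsv")
    back = de.read_counts(tmp_path / "c.tsv", tmp_path / "g.tsv")
    pd.testing.assert_frame_equal(back.counts, tiny_matrix.counts)
    assert dict(back.groups) == dict(tiny_matrix.groups)
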