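"""Replicate aggregation, compositional closure, presence calls."""

import numpy as np
import pandas as pd
import pytest

from ndmmkit.profiles import (
    AbundanceTable,
    aggregate_replicates,
    close_composition,
    presence_absence,
    within_class_percentages,
)


def _table(rows, class_map):
    return AbundanceTable(
        pd.DataFrame(rows, columns=["species", "compound", "replicate",
                                    "area"]),
        class_map,
    )


@pytest.fixture()
def small_table():
    rows = [
        ("sp1", "dasc#1", r, a) for r, a in [(1, 3000.0), (2, 0.0), (3, 3000.0)]
    ] + [
        ("sp1", "dasc#4", r, 1000.0) for r in (1, 2, 3)
    ] + [
        ("sp1", "ubas#1", r, 200.0) for r in (1, 2, 3)
    ] + [
        ("sp1", "ubas#28", r, 800.0) for r in (1, 2, 3)
    ] + [
        ("sp2", "dasc#1", r, 500.0) for r in (1, 2, 3)
    ]
    return _table(
        rows,
        {
            "dasc#1": "DASC",
            "dasc#4": "DASC",
            "ubas#1": "UBAS-monomeric",
            "ubas#28": "UBAS-dimeric",
        },
    )


class TestAggregate:
    def test_mean_with_missing_replicate_as_zero(self, small_table):
        means = aggregate_replicates(small_table)
        assert means.loc["sp1", "dasc#1"] == 2000.0
        # sp2 never measured ubas compounds -> zero
        assert means.loc["sp2", "ubas#1"] == 0.0

    def test_single_replicate_identity(self):
        t = _table([("sp1", "c", 1, 123.0)], {"c": "simple"})
        assert aggregate_replicates(t).loc["sp1", "c"] == 123.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            _table([("sp1", "c", 1, -5.0)], {"c": "simple"})


class TestWithinClass:
    def test_class_sums_and_separate_ubas(self, small_table):
        means = aggregate_replicates(small_table)
        prof = within_class_percentages(means, small_table.class_map)
        row = prof.values.loc["sp1"]
        assert row["dasc#1"] == pytest.approx(2000 / 3000 * 100)
        assert row["dasc#4"] == pytest.approx(1000 / 3000 * 100)
        # monomeric and dimeric UBAS standardised separately -> both 100%
        assert row["ubas#1"] == pytest.approx(100.0)
        assert row["ubas#28"] == pytest.approx(100.0)

    def test_absent_class_yields_zeros(self, small_table):
        means = aggregate_replicates(small_table)
        prof = within_class_percentages(means, small_table.class_map)
        assert prof.values.loc["sp2", "ubas#1"] == 0.0

    def test_nonzero_class_rows_sum_to_100(self, small_table):
        means = aggregate_replicates(small_table)
        prof = within_class_percentages(means, small_table.class_map)
        cmap = small_table.class_map
        for cls in set(cmap.values()):
            cols = [c for c in prof.values.columns if cmap[c] == cls]
            sums = prof.values[cols].sum(axis=1)
            class_present = means[cols].sum(axis=1) > 0
            assert np.allclose(sums[class_present], 100.0, atol=1e-9)
            assert np.allclose(sums[~class_present], 0.0)

    def test_unmapped_compound_rejected(self, small_table):
        means = aggregate_replicates(small_table)
        with pytest.raises(ValueError):
            within_class_percentages(means, {"dasc#1": "DASC"})


class TestClosed:
    def test_simple_cases(self):
        means = pd.DataFrame(
            {"a": [60.0, 1.0], "b": [40.0, 1.0], "c": [0.0, 2.0]},
            index=["s1", "s2"],
        )
        prof = close_composition(means)
        assert prof.values.loc["s1"].tolist() == pytest.approx([60, 40, 0])
        assert prof.values.loc["s2"].tolist() == pytest.approx([25, 25, 50])

    def test_rows_sum_to_100(self, small_table):
        means = aggregate_replicates(small_table)
        prof = close_composition(means)
        assert np.allclose(prof.values.sum(axis=1), 100.0, atol=1e-9)

    def test_scale_invariance(self, small_table):
        means = aggregate_replicates(small_table)
        scaled = means.copy()
        scaled.loc["sp1"] *= 37.5
        a = close_composition(means).values
        b = close_composition(scaled).values
        assert np.allclose(a, b)
        wa = within_class_percentages(means, small_table.class_map).values
        wb = within_class_percentages(scaled, small_table.class_map).values
        assert np.allclose(wa, wb)

    def test_all_zero_row_rejected(self):
        means = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["s1"])
        with pytest.raises(ValueError):
            close_composition(means)


class TestPresence:
    def test_threshold_calls(self, small_table):
        pm = presence_absence(small_table, threshold=1.0e3)
        assert bool(pm.values.loc["sp1", "dasc#1"]) is True
        # sp2's mean of 500 is trace level -> coded absent
        assert bool(pm.values.loc["sp2", "dasc#1"]) is False

    def test_zero_threshold_means_any_detection(self, small_table):
        pm = presence_absence(small_table, threshold=0.0)
        assert bool(pm.values.loc["sp2", "dasc#1"]) is True
        assert bool(pm.values.loc["sp2", "ubas#1"]) is False

    def test_monotone_in_threshold(self, small_table):
        thresholds = [0.0, 1e2, 1e3, 1e4, 1e6]
        counts = [
            presence_absence(small_table, t).values.to_numpy().sum()
            for t in thresholds
        ]
        assert counts == sorted(counts, reverse=True)
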