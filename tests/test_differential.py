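"""Group comparisons, experimental null, FADR grid, cutoff selection, AP calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import apquant as aq
from conftest import make_annotation


def protein_table(rows: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples).rename_axis(
        "protein_group_id"
    )


def closed_form_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook equal-variance two-sample t-test, written independently."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(2.0 * stats.t.sf(abs(t), nx + ny - 2))


class TestCompareGroups:
    def test_identical_groups_fc_one_p_one(self):
        vals = [100.0, 120.0, 90.0]
        table = protein_table({"A": vals + vals}, [f"s{i}" for i in range(6)])
        ann = make_annotation(list(table.columns), ["case"] * 3 + ["ctrl"] * 3)
        comp = aq.compare_groups(table, ann, "case", "ctrl")
        assert comp["fc"].iloc[0] == pytest.approx(1.0)
        assert comp["p_value"].iloc[0] == pytest.approx(1.0)

    def test_two_fold_change_matches_closed_form(self):
        case, ctrl = [190.0, 200.0, 210.0], [95.0, 100.0, 105.0]
        table = protein_table({"A": case + ctrl}, [f"s{i}" for i in range(6)])
        ann = make_annotation(list(table.columns), ["case"] * 3 + ["ctrl"] * 3)
        comp = aq.compare_groups(table, ann, "case", "ctrl")
        assert comp["fc"].iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert comp["log2fc"].iloc[0] == pytest.approx(1.0, rel=1e-9)
        expected_p = closed_form_t_p(np.log2(case), np.log2(ctrl))
        assert comp["p_value"].iloc[0] == pytest.approx(expected_p, abs=1e-12)

    def test_p_values_match_closed_form_on_random_vectors(self):
        """Implementation vs independent closed-form oracle to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            nx = int(rng.integers(3, 12))
            ny = int(rng.integers(3, 12))
            x = rng.normal(10, 1, nx)
            y = rng.normal(10, 1, ny)
            samples = [f"s{i}" for i in range(nx + ny)]
            table = protein_table({"A": list(np.exp2(x)) + list(np.exp2(y))}, samples)
            ann = make_annotation(samples, ["case"] * nx + ["ctrl"] * ny)
            comp = aq.compare_groups(table, ann, "case", "ctrl")
            assert abs(comp["p_value"].iloc[0] - closed_form_t_p(x, y)) < 1e-10

    def test_unknown_group_is_an_error(self):
        table = protein_table({"A": [1.0, 2.0, 3.0, 4.0]}, ["s0", "s1", "s2", "s3"])
        ann = make_annotation(list(table.columns), ["case"] * 2 + ["ctrl"] * 2)
        with pytest.raises(ValueError, match="bogus"):
            aq.compare_groups(table, ann, "bogus", "ctrl")

    def test_untestable_proteins_reported_not_dropped(self):
        table = protein_table(
            {"A": [100, np.nan, np.nan, 90, 95, 100], "B": [100, 110, 90, 90, 95, 100]},
            [f"s{i}" for i in range(6)],
        )
        ann = make_annotation(list(table.columns), ["case"] * 3 + ["ctrl"] * 3)
        comp = aq.compare_groups(table, ann, "case", "ctrl").set_index("protein_group_id")
        assert not comp.loc["A", "testable"]
        assert np.isnan(comp.loc["A", "p_value"])
        assert comp.loc["B", "testable"]

    def test_zero_variance_degenerate_flags(self):
        table = protein_table(
            {"same": [100.0] * 6, "diff": [200.0] * 3 + [100.0] * 3},
            [f"s{i}" for i in range(6)],
        )
        ann = make_annotation(list(table.columns), ["case"] * 3 + ["ctrl"] * 3)
        comp = aq.compare_groups(table, ann, "case", "ctrl").set_index("protein_group_id")
        assert comp.loc["same", "degenerate"] and comp.loc["same", "p_value"] == 1.0
        assert comp.loc["diff", "degenerate"] and comp.loc["diff", "p_value"] == 0.0


class TestExperimentalNull:
    def _table_and_ann(self, n_sh=10, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"sh{i}" for i in range(n_sh)]
        table = protein_table(
            {f"P{j}": list(rng.lognormal(8, 0.3, n_sh)) for j in range(50)}, samples
        )
        ann = make_annotation(samples, ["SH"] * n_sh)
        return table, ann

    def test_ten_controls_split_five_vs_five(self):
        table, ann = self._table_and_ann(10)
        nulls = aq.experimental_null(table, ann, "SH", n_splits=5, seed=1)
        assert len(nulls) == 5
        for comp in nulls:
            assert (comp["n_case"] == 5).all()
            assert (comp["n_control"] == 5).all()

    def test_same_seed_same_splits(self):
        table, ann = self._table_and_ann(10)
        a = aq.experimental_null(table, ann, "SH", n_splits=6, seed=9)
        b = aq.experimental_null(table, ann, "SH", n_splits=6, seed=9)
        for ca, cb in zip(a, b):
            pd.testing.assert_frame_equal(ca, cb)

    def test_identical_samples_give_null_fc_one_p_one(self):
        samples = [f"sh{i}" for i in range(6)]
        table = protein_table({f"P{j}": [100.0 * (j + 1)] * 6 for j in range(5)}, samples)
        ann = make_annotation(samples, ["SH"] * 6)
        nulls = aq.experimental_null(table, ann, "SH", n_splits=3, seed=0)
        for comp in nulls:
            assert np.allclose(comp["fc"], 1.0)
            assert np.allclose(comp["p_value"], 1.0)

    def test_small_control_group_is_an_error(self):
        table, ann = self._table_and_ann(3)
        with pytest.raises(ValueError, match="need >= 4"):
            aq.experimental_null(table, ann, "SH")

    def test_partitions_unique_and_exhaustive_when_space_is_small(self):
        table, ann = self._table_and_ann(4)
        nulls = aq.experimental_null(table, ann, "SH", n_splits=20, seed=2)
        assert len(nulls) == 3  # C(4,2)/2 distinct balanced partitions


def comparison_frame(fcs: list[float], ps: list[float], contrast="TM/SH") -> pd.DataFrame:
    n = len(fcs)
    return pd.DataFrame(
        {
            "protein_group_id": [f"P{i}" for i in range(n)],
            "contrast": contrast,
            "fc": fcs,
            "log2fc": np.log2(fcs),
            "p_value": ps,
            "n_case": 5,
            "n_control": 5,
            "testable": True,
            "degenerate": False,
        }
    )


class TestFadrGrid:
    def test_hand_computed_fadr(self):
        """Case counts {100, 60, 40}, mean null {10, 3, 1} -> FADR {.10, .05, .025}."""
        case = comparison_frame(
            [2.5] * 40 + [1.45] * 20 + [1.25] * 40 + [1.0] * 50,
            [0.01] * 100 + [0.5] * 50,
        )
        null = comparison_frame(
            [2.5] * 1 + [1.45] * 2 + [1.25] * 7 + [1.0] * 140,
            [0.01] * 10 + [0.5] * 140,
        )
        grid = aq.fadr_grid(case, [null], fc_thresholds=(1.2, 1.4, 2.0), alpha=0.05)
        assert grid["n_case_aps"].tolist() == [100, 60, 40]
        assert grid["n_null_aps"].tolist() == [10.0, 3.0, 1.0]
        assert grid["fadr"].tolist() == pytest.approx([0.10, 0.05, 0.025])

    def test_zero_null_aps_give_zero_fadr(self):
        case = comparison_frame([2.0] * 10, [0.01] * 10)
        null = comparison_frame([1.0] * 10, [0.9] * 10)
        grid = aq.fadr_grid(case, [null])
        assert (grid["fadr"] == 0).all()

    def test_default_thresholds(self):
        case = comparison_frame([2.0] * 4, [0.01] * 4)
        grid = aq.fadr_grid(case, [])
        assert grid["fc_threshold"].tolist() == [1.2, 1.3, 1.4, 1.5, 2.0]

    def test_case_counts_non_increasing_in_threshold(self, planted_analysis):
        result, _ = planted_analysis
        for grid in result.grids.values():
            counts = grid.sort_values("fc_threshold")["n_case_aps"].to_numpy()
            assert (np.diff(counts) <= 0).all()

    def test_empty_case_is_an_error(self):
        with pytest.raises(ValueError):
            aq.fadr_grid(comparison_frame([], []), [])


def grid_frame(rows: list[tuple[float, int, float]], contrast="TM/SH") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fc_threshold": t,
                "contrast": contrast,
                "n_case_aps": n,
                "n_null_aps": n * f,
                "fadr": f,
                "alpha": 0.05,
            }
            for t, n, f in rows
        ]
    )


class TestSelectCutoff:
    def test_first_threshold_reaching_tolerance_is_selected(self):
        grid = grid_frame(
            [(1.2, 500, 0.113), (1.3, 300, 0.07), (1.4, 200, 0.040),
             (1.5, 150, 0.037), (2.0, 70, 0.010)]
        )
        choice = aq.select_cutoff(grid)
        assert choice["selected_fc_threshold"] == 1.4
        assert not choice["no_threshold_met_tolerance"]

    def test_zero_fadr_everywhere_selects_smallest(self):
        grid = grid_frame([(1.2, 500, 0.0), (1.4, 300, 0.0), (2.0, 100, 0.0)])
        assert aq.select_cutoff(grid)["selected_fc_threshold"] == 1.2

    def test_retention_rule_refuses_large_ap_loss(self):
        """A >65% AP drop from 1.4 to 2.0 is not worth a small FADR gain."""
        grid = grid_frame([(1.2, 500, 0.113), (1.4, 200, 0.040), (2.0, 69, 0.010)])
        assert aq.select_cutoff(grid)["selected_fc_threshold"] == 1.4

    def test_no_qualifying_threshold_warns_and_returns_largest(self):
        grid = grid_frame([(1.2, 500, 0.3), (1.4, 200, 0.2), (2.0, 50, 0.1)])
        choice = aq.select_cutoff(grid)
        assert choice["selected_fc_threshold"] == 2.0
        assert choice["no_threshold_met_tolerance"]


class TestCallAps:
    def test_empty_comparisons_give_empty_set(self):
        aps = aq.call_aps(comparison_frame([], []), fc_cutoff=1.4)
        assert len(aps.members) == 0
        assert aps.protein_ids == set()

    def test_enumerated_filter(self):
        """(1.5,.01) and (0.6,.01) pass at cutoff 1.4; 0.75 > 1/1.4 fails."""
        comp = comparison_frame(
            [1.5, 1.3, 1.5, 0.6, 0.75], [0.01, 0.01, 0.2, 0.01, 0.01]
        )
        aps = aq.call_aps(comp, fc_cutoff=1.4, alpha=0.05)
        assert aps.protein_ids == {"P0", "P3"}
        assert aps.directions() == {"P0": "up", "P3": "down"}

    def test_cutoff_must_exceed_one(self):
        with pytest.raises(ValueError):
            aq.call_aps(comparison_frame([2.0], [0.01]), fc_cutoff=1.0)

    def test_ap_count_monotone_in_cutoff_and_alpha(self, planted_analysis):
        result, _ = planted_analysis
        comp = result.comparisons[result.comparisons["contrast"] == "TSm/SH"]
        counts_fc = [
            len(aq.call_aps(comp, fc_cutoff=t).members) for t in (1.2, 1.3, 1.4, 1.5, 2.0)
        ]
        assert all(a >= b for a, b in zip(counts_fc, counts_fc[1:]))
        counts_alpha = [
            len(aq.call_aps(comp, fc_cutoff=1.4, alpha=a).members)
            for a in (0.10, 0.05, 0.01, 0.001)
        ]
        assert all(a >= b for a, b in zip(counts_alpha, counts_alpha[1:]))

    def test_union_across_treatment_groups(self, planted_analysis):
        result, truth = planted_analysis
        union = set()
        for s in result.ap_sets.values():
            union |= s.protein_ids
        assert union == result.ap_union
        assert len(union) >= max(len(s.members) for s in result.ap_sets.values())


def test_type_i_error_matches_alpha(all_null_analysis):
    """Pure p-filter on null data calls ~alpha of testable proteins."""
    _, comps, _ = all_null_analysis
    comp = comps["TM"]
    frac = (comp.loc[comp["testable"], "p_value"] < 0.05).mean()
    n = int(comp["testable"].sum())
    band = 3 * np.sqrt(0.05 * 0.95 / n)
    assert abs(frac - 0.05) < band
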