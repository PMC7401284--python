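import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fpmiron.composition import InvalidInputError
from fpmiron.diagnostics import (
    ConfusionTable,
    OutcomeCutoffGrid,
    compare_all,
    confusion,
    default_grids,
    dichotomize_test,
    fisher_exact,
    metrics,
    paired_compare,
    quartile_thresholds,
    roc_grid,
    summarize_method,
)


class TestQuartileThresholds:
    def test_closest_rank_interpolation(self):
        qt = quartile_thresholds(range(1, 9))
        assert (qt.q25, qt.q50, qt.q75) == (2.75, 4.5, 6.25)

    def test_median_of_four(self):
        assert quartile_thresholds([0.1, 0.2, 0.3, 0.4]).q50 == pytest.approx(0.25)

    def test_constant_input_flagged_degenerate(self):
        qt = quartile_thresholds([3.0, 3.0, 3.0, 3.0])
        assert qt.degenerate
        assert qt.q25 == qt.q50 == qt.q75 == 3.0

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(InvalidInputError):
            quartile_thresholds([1.0, 2.0, 3.0])


class TestDichotomize:
    @pytest.mark.parametrize(
        "value,threshold,direction,expected",
        [
            (0.5, 0.47, "enhancer", True),
            (0.8, 2.9, "inhibitor", True),
            (0.47, 0.47, "enhancer", False),  # tie -> negative
            (0.47, 0.47, "inhibitor", False),
            (0.4, 0.47, "enhancer", False),
            (3.0, 2.9, "inhibitor", False),
        ],
    )
    def test_direction_and_tie_rule(self, value, threshold, direction, expected):
        assert dichotomize_test([value], threshold, direction)[0] == expected


class TestConfusion:
    def test_all_concordant_positives(self):
        ct = confusion([True] * 10, [True] * 10)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (10, 0, 0, 0)

    def test_one_of_each_cell(self):
        ct = confusion([True, True, False, False], [True, False, True, False])
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 1, 1, 1)

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion([], [])
        with pytest.raises(InvalidInputError):
            confusion([True], [True, False])


class TestMetrics:
    def test_textbook_table(self):
        m = metrics(ConfusionTable(tp=8, fp=4, fn=2, tn=6))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.ppv == pytest.approx(2 / 3)
        assert m.npv == pytest.approx(0.75)
        assert m.lr_plus == pytest.approx(2.0)

    def test_zero_denominator_flags_undefined(self):
        m = metrics(ConfusionTable(tp=0, fp=3, fn=0, tn=7))
        assert m.sensitivity is None
        assert m.ppv == 0.0

    def test_perfect_table(self):
        m = metrics(ConfusionTable(tp=5, fp=0, fn=0, tn=5))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)
        assert m.lr_plus is None  # specificity 1 -> undefined


class TestFisherExact:
    def test_most_probable_table_has_p_one(self):
        assert fisher_exact(ConfusionTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfectly_discordant_table(self):
        assert fisher_exact(ConfusionTable(10, 0, 0, 10)) == pytest.approx(2 / 184756, rel=1e-12)

    def test_enumerated_symmetric_table(self):
        # margins (4,4,4,4): p = sum of hypergeometric masses <= that of k=3
        assert fisher_exact(ConfusionTable(3, 1, 1, 3)) == pytest.approx(34 / 70, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy_on_random_tables(self, seed):
        """Independent cross-check of the enumeration against scipy's
        implementation of the same two-sided test."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 15, size=4)
            if tp + fp + fn + tn == 0:
                continue
            ours = fisher_exact(ConfusionTable(int(tp), int(fp), int(fn), int(tn)))
            scipys = stats.fisher_exact([[tp, fp], [fn, tn]])[1]
            assert ours == pytest.approx(scipys, abs=1e-9)


class TestPairedCompare:
    def make_cells(self, sens, spec):
        n = len(sens)
        return pd.DataFrame(
            {
                "outcome_cutoff": np.arange(n, dtype=float),
                "threshold_rank": ["q50"] * n,
                "sensitivity": sens,
                "specificity": spec,
            }
        )

    def test_identical_vectors_flagged_degenerate(self):
        sens = [0.2, 0.4, 0.6, 0.8]
        spec = [0.5, 0.6, 0.7, 0.8]
        a = self.make_cells(sens, spec)
        p_sens, p_spec, flags = paired_compare(a, a.copy())
        assert p_sens == 1.0 and p_spec == 1.0
        assert flags["sensitivity"] and flags["specificity"]

    def test_constant_nonzero_difference_takes_degenerate_path(self):
        # dyadic values keep the differences exactly constant in floats
        sens = np.arange(10) * 0.0625
        a = self.make_cells(sens, sens)
        b = self.make_cells(sens + 0.125, sens + 0.25)
        p_sens, p_spec, flags = paired_compare(a, b)
        assert p_sens == 1.0 and flags["sensitivity"]
        assert p_spec == 1.0 and flags["specificity"]

    def test_matches_closed_form_paired_t(self):
        """p equals the textbook paired-t closed form on the differences."""
        diffs = np.array([0.1, -0.1, 0.05, -0.05, 0.2, 0.0])
        base = np.full(6, 0.5)
        a = self.make_cells(base, base + diffs)
        b = self.make_cells(base + diffs, base)
        p_sens, p_spec, flags = paired_compare(a, b)
        n = len(diffs)
        t = (-diffs).mean() / ((-diffs).std(ddof=1) / math.sqrt(n))
        expected = 2 * stats.t.sf(abs(t), df=n - 1)
        assert p_sens == pytest.approx(expected, rel=1e-12)
        assert not flags["sensitivity"]
        # zero-mean, zero... spec differences are the negated diffs: same p
        assert p_spec == pytest.approx(expected, rel=1e-12)

    def test_too_few_complete_pairs_rejected(self):
        a = self.make_cells([0.5, np.nan, np.nan], [0.5, 0.6, 0.7])
        b = self.make_cells([0.6, 0.7, np.nan], [0.5, 0.6, 0.7])
        with pytest.raises(InvalidInputError):
            paired_compare(a, b)


class TestRocGrid:
    def test_default_grid_cell_counts(self, cohort_profiles, cohort):
        grids = default_grids()
        expected = {"hemoglobin": 21, "ferritin": 33, "absorption": 33}
        for outcome, n_cells in expected.items():
            cells = roc_grid(cohort_profiles, cohort.hematology, grids[outcome], "iron", "MIE")
            assert len(cells) == n_cells

    def test_out_of_range_cutoffs_flagged_degenerate(self, cohort_profiles, cohort):
        """With hemoglobin confined to a narrow band above most of the grid,
        cells at the all-positive cutoffs are flagged and excluded while the
        one discriminating cutoff is retained."""
        panels = cohort.hematology.copy()
        rng = np.random.default_rng(0)
        panels["hemoglobin_g_dl"] = rng.uniform(13.6, 14.4, len(panels))
        grid = default_grids()["hemoglobin"]
        cells = roc_grid(cohort_profiles, panels, grid, "iron", "MIE")
        below = cells[cells["outcome_cutoff"] < 14.0]
        at_top = cells[cells["outcome_cutoff"] == 14.0]
        assert below["degenerate"].all()
        assert not at_top["degenerate"].any()

    def test_sensitivity_monotone_in_enhancer_threshold(self, cohort_profiles, cohort):
        """Lowering the positivity threshold can only add test-positives, so
        sensitivity is non-increasing across q25 <= q50 <= q75."""
        cells = roc_grid(
            cohort_profiles, cohort.hematology, default_grids()["ferritin"], "iron", "FPM"
        )
        for _, sub in cells[~cells["degenerate"]].groupby("outcome_cutoff"):
            by_rank = sub.set_index("threshold_rank")["sensitivity"]
            ranks = [r for r in ("q25", "q50", "q75") if r in by_rank.index]
            sens = by_rank.loc[ranks].to_numpy()
            assert (np.diff(sens) <= 1e-12).all()

    def test_bayes_identity_on_every_retained_cell(self, cohort_profiles, cohort):
        """PPV must equal sens*prev / (sens*prev + (1-spec)(1-prev))."""
        for outcome, grid in default_grids().items():
            cells = roc_grid(cohort_profiles, cohort.hematology, grid, "phytate", "MIE")
            r = cells[~cells["degenerate"]]
            prev = (r.tp + r.fn) / (r.tp + r.fp + r.fn + r.tn)
            denom = r.sensitivity * prev + (1 - r.specificity) * (1 - prev)
            ok = denom > 0
            np.testing.assert_allclose(
                r.ppv[ok], (r.sensitivity * prev)[ok] / denom[ok], rtol=1e-10
            )

    def test_no_joinable_participants_is_error(self, cohort_profiles, cohort):
        panels = cohort.hematology.copy()
        panels["participant_id"] = "zz" + panels["participant_id"]
        with pytest.raises(InvalidInputError):
            roc_grid(cohort_profiles, panels, default_grids()["ferritin"], "iron", "MIE")


class TestSummarizeMethod:
    def test_unweighted_mean_as_percent(self):
        cells = pd.DataFrame(
            {
                "sensitivity": [0.2, 0.4],
                "specificity": [0.5, 0.7],
                "ppv": [0.5, 0.5],
                "npv": [0.25, 0.75],
                "degenerate": [False, False],
            }
        )
        means = summarize_method(cells)
        assert means["sensitivity"] == pytest.approx(30.0)
        assert means["specificity"] == pytest.approx(60.0)

    def test_undefined_cells_dropped_per_metric(self):
        cells = pd.DataFrame(
            {
                "sensitivity": [0.2, np.nan],
                "specificity": [0.5, 0.7],
                "ppv": [0.5, 0.5],
                "npv": [0.25, 0.75],
                "degenerate": [False, False],
            }
        )
        means = summarize_method(cells)
        assert means["sensitivity"] == pytest.approx(20.0)
        assert means["specificity"] == pytest.approx(60.0)

    def test_all_degenerate_is_error(self):
        cells = pd.DataFrame({"sensitivity": [np.nan], "degenerate": [True]})
        with pytest.raises(InvalidInputError):
            summarize_method(cells)


class TestCompareAll:
    def test_full_report_shape(self, cohort_profiles, cohort):
        summary, roc = compare_all(cohort_profiles, cohort.hematology, with_fisher=False)
        assert len(summary) == 24
        assert set(summary["method"]) == {"MIE", "FPM"}
        assert len(roc) == 2 * 4 * (21 + 33 + 33)
        retained = roc[~roc["degenerate"]]
        np.testing.assert_allclose(retained["fpr"], 1 - retained["specificity"])

    def test_flipping_direction_complements_sensitivity(self):
        """Reversing a variable's test direction swaps positive and negative
        labels, so per-cell sensitivity becomes its complement (values are
        continuous, so no label ties at the quartile thresholds)."""
        from fpmiron.recalls import build_profiles
        from fpmiron.simulate import generate_cohort

        c = generate_cohort(seed=5, n_participants=30)
        profiles = build_profiles(c.recalls, c.composition)
        grid = {"ferritin": default_grids()["ferritin"]}
        base = {"iron": "enhancer", "ascorbic": "enhancer", "phytate": "inhibitor", "ratio": "inhibitor"}
        flipped = dict(base, phytate="enhancer")
        _, roc_a = compare_all(profiles, c.hematology, grids=grid, directions=base, with_fisher=False)
        _, roc_b = compare_all(profiles, c.hematology, grids=grid, directions=flipped, with_fisher=False)
        key = ["outcome_cutoff", "threshold_rank"]
        # MIE values are continuous, so no value sits exactly at a threshold
        sel = lambda r: r[(r["variable"] == "phytate") & (r["method"] == "MIE")]
        a = sel(roc_a).set_index(key).sort_index()
        b = sel(roc_b).set_index(key).sort_index()
        both = ~(a["degenerate"] | b["degenerate"])
        assert both.any()
        np.testing.assert_allclose(
            b.loc[both, "sensitivity"], 1.0 - a.loc[both, "sensitivity"], atol=1e-12
        )

    def test_constant_outcome_raises_cleanly(self, cohort_profiles, cohort):
        panels = cohort.hematology.assign(ferritin_ng_dl=100.0)
        with pytest.raises(InvalidInputError, match="degenerate"):
            compare_all(cohort_profiles, panels, with_fisher=False)

    def test_four_participant_pipeline_matches_hand_enumeration(self):
        """A cohort of 4 hand-built profiles: every cell of a tiny grid is
        recomputed by explicit enumeration."""
        profiles = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "mie_iron": [5.0, 10.0, 15.0, 20.0],
            }
        )
        panels = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "hemoglobin_g_dl": [11.5, 12.5, 13.5, 14.5],
                "ferritin_ng_dl": [10.0, 20.0, 30.0, 40.0],
                "absorption_pct": [0.0, 5.0, 10.0, 15.0],
            }
        )
        grid = OutcomeCutoffGrid("hemoglobin", 12.0, 14.0, 1.0)
        cells = roc_grid(profiles, panels, grid, "iron", "MIE", "enhancer", with_fisher=False)
        # quartiles of (5,10,15,20): q25=8.75, q50=12.5, q75=16.25
        # at cutoff 13.0 outcome+ = {c,d}; threshold q50=12.5 -> test+ = {c,d}
        cell = cells[(cells.outcome_cutoff == 13.0) & (cells.threshold_rank == "q50")].iloc[0]
        assert (cell.tp, cell.fp, cell.fn, cell.tn) == (2, 0, 0, 2)
        assert cell.sensitivity == 1.0 and cell.specificity == 1.0
        # at cutoff 14.0 outcome+ = {d}; threshold q75=16.25 -> test+ = {d}
        cell = cells[(cells.outcome_cutoff == 14.0) & (cells.threshold_rank == "q75")].iloc[0]
        assert (cell.tp, cell.fp, cell.fn, cell.tn) == (1, 0, 0, 3)


class TestGridPoints:
    def test_inclusive_endpoints(self):
        grid = OutcomeCutoffGrid("hemoglobin", 11.0, 14.0, 0.5)
        np.testing.assert_allclose(grid.points, [11.0, 11.5, 12.0, 12.5, 13.0, 13.5, 14.0])

    def test_invalid_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            OutcomeCutoffGrid("x", 5.0, 5.0, 1.0)
        with pytest.raises(InvalidInputError):
            OutcomeCutoffGrid("x", 0.0, 5.0, 0.0)
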