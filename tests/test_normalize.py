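"""Normalization chain: stage arithmetic, invariants, and the worked fixture."""

import numpy as np
import pandas as pd
import pytest

from conftest import REFERENCE_LOG2, REFERENCE_RAW, REFERENCE_UNDETECTED, build_dataset
from proteofix.datatypes import CountMatrix, ValidationError
from proteofix.normalize import (
    NormalizationOptions,
    background_correct,
    detect_above_background,
    geometric_mean,
    housekeeping_normalize,
    impute_and_log,
    positive_control_normalize,
    run_normalization,
    select_housekeeping,
)


@pytest.mark.parametrize(
    "values, expected",
    [
        ((7, 7, 7), 7.0),
        ((1, 4), 2.0),
        ((2, 4, 8, 16, 32, 64), 2.0**3.5),
    ],
)
def test_geometric_mean_values(values, expected):
    assert geometric_mean(values) == pytest.approx(expected, rel=1e-12)


def test_geometric_mean_rejects_bad_input():
    with pytest.raises(ValidationError):
        geometric_mean([])
    with pytest.raises(ValidationError):
        geometric_mean([1.0, 0.0])


def test_geometric_mean_scale_equivariance(rng):
    x = rng.uniform(0.1, 50, size=12)
    assert geometric_mean(3.7 * x) == pytest.approx(
        3.7 * geometric_mean(x), rel=1e-12
    )


class TestPositiveControlNormalize:
    def test_two_lane_factors(self):
        # lane spike-in geomeans 10 and 40 -> reference 20, factors 2 and 0.5
        data = {
            "POS1": (5, 20), "POS2": (10, 40), "POS3": (20, 80),
            "NEG1": (1, 1), "HK1": (10, 10), "END1": (30, 30),
        }
        ds = build_dataset(data)
        m, factors = positive_control_normalize(ds.counts, ds)
        assert factors.tolist() == pytest.approx([2.0, 0.5])
        assert m.values.loc["END1"].tolist() == pytest.approx([60.0, 15.0])
        # post-normalization spike-in geomeans are equal across lanes
        pos = m.values.loc[["POS1", "POS2", "POS3"]]
        gms = np.exp(np.log(pos).mean(axis=0))
        assert gms.tolist() == pytest.approx([20.0, 20.0], rel=1e-9)

    def test_identical_lanes_are_untouched(self):
        data = {"POS1": (8, 8, 8), "NEG1": (1, 1, 1), "HK1": (5, 5, 5),
                "END1": (9, 9, 9)}
        ds = build_dataset(data)
        m, factors = positive_control_normalize(ds.counts, ds)
        assert factors.tolist() == pytest.approx([1.0, 1.0, 1.0])
        pd.testing.assert_frame_equal(m.values, ds.counts.values)

    def test_single_lane_factor_is_one(self):
        data = {"POS1": (13,), "NEG1": (1,), "HK1": (5,), "END1": (9,)}
        ds = build_dataset(data)
        _, factors = positive_control_normalize(ds.counts, ds)
        assert factors.tolist() == pytest.approx([1.0])

    def test_zero_spike_in_names_the_lane(self):
        data = {"POS1": (5, 0), "NEG1": (1, 1), "HK1": (5, 5), "END1": (9, 9)}
        ds = build_dataset(data)
        with pytest.raises(ValidationError, match="L2"):
            positive_control_normalize(ds.counts, ds)


class TestBackgroundCorrect:
    def _dataset(self):
        # negative geomean 10, IgG (after negative subtraction) geomean 5
        return build_dataset(
            {
                "POS1": (10,), "NEG1": (10,), "IGG1": (15,),
                "HK1": (50,), "END1": (100,), "END2": (8,),
            }
        )

    def test_subtracts_negative_then_igg(self):
        ds = self._dataset()
        m, _ = positive_control_normalize(ds.counts, ds)
        out, b_neg, b_igg = background_correct(m, ds)
        assert b_neg.tolist() == pytest.approx([10.0])
        assert b_igg.tolist() == pytest.approx([5.0])
        assert out.values.loc["END1", "L1"] == pytest.approx(100 - 10 - 5)

    def test_floors_at_zero(self):
        ds = self._dataset()
        m, _ = positive_control_normalize(ds.counts, ds)
        out, _, _ = background_correct(m, ds)
        assert out.values.loc["END2", "L1"] == 0.0  # 8 - 10 floored

    def test_igg_toggle_off(self):
        ds = self._dataset()
        m, _ = positive_control_normalize(ds.counts, ds)
        out, _, b_igg = background_correct(
            m, ds, NormalizationOptions(subtract_igg=False)
        )
        assert b_igg.tolist() == [0.0]
        assert out.values.loc["END1", "L1"] == pytest.approx(90.0)

    def test_controls_pass_through(self):
        ds = self._dataset()
        m, _ = positive_control_normalize(ds.counts, ds)
        out, _, _ = background_correct(m, ds)
        for probe in ("POS1", "NEG1", "IGG1"):
            assert out.values.loc[probe, "L1"] == m.values.loc[probe, "L1"]


class TestSelectHousekeeping:
    def test_constant_candidate_wins(self):
        data = {"POS1": (1, 1, 1, 1), "NEG1": (1, 1, 1, 1),
                "HKA": (16, 16, 16, 16), "HKB": (4, 16, 64, 16),
                "END1": (5, 5, 5, 5)}
        ds = build_dataset(data)
        probe, table = select_housekeeping(ds.counts, ds)
        assert probe == "HKA"
        assert table["HKA"] == 0.0

    def test_single_candidate_returned_unconditionally(self):
        data = {"POS1": (1, 1), "NEG1": (1, 1), "HK1": (3, 300), "END1": (5, 5)}
        ds = build_dataset(data)
        probe, table = select_housekeeping(ds.counts, ds)
        assert probe == "HK1"
        assert len(table) == 1

    def test_lower_cv_candidate_selected(self):
        # log2 counts (5,5,7,7) vs (6,6,6,8): CVs 0.19245 vs 0.15385
        data = {
            "POS1": (1, 1, 1, 1), "NEG1": (1, 1, 1, 1),
            "HKA": (32, 32, 128, 128), "HKB": (64, 64, 64, 256),
            "END1": (5, 5, 5, 5),
        }
        ds = build_dataset(data)
        probe, table = select_housekeeping(ds.counts, ds)
        logs_a = np.log2([32, 32, 128, 128])
        logs_b = np.log2([64, 64, 64, 256])
        cv = lambda v: np.std(v, ddof=1) / np.mean(v)
        assert probe == ("HKA" if cv(logs_a) < cv(logs_b) else "HKB")
        assert table["HKA"] == pytest.approx(cv(logs_a))
        assert table["HKB"] == pytest.approx(cv(logs_b))


class TestHousekeepingNormalize:
    @staticmethod
    def _corrected(ds):
        return CountMatrix(ds.counts.values, "background_corrected")

    def test_two_lane_ratio(self):
        # hk counts (2, 8): geomean 4, ratios (0.5, 2); endogenous 10 -> (20, 5)
        data = {"POS1": (1, 1), "NEG1": (1, 1), "HK1": (2, 8), "END1": (10, 10)}
        ds = build_dataset(data)
        out = housekeeping_normalize(self._corrected(ds), ds, "HK1")
        assert out.values.loc["END1"].tolist() == pytest.approx([20.0, 5.0])
        hk = out.values.loc["HK1"]
        assert hk.tolist() == pytest.approx([4.0, 4.0], rel=1e-9)

    def test_constant_hk_is_identity(self):
        data = {"POS1": (1, 1), "NEG1": (1, 1), "HK1": (6, 6), "END1": (10, 3)}
        ds = build_dataset(data)
        out = housekeeping_normalize(self._corrected(ds), ds, "HK1")
        assert out.values.loc["END1"].tolist() == pytest.approx([10.0, 3.0])

    def test_single_lane_is_identity(self):
        data = {"POS1": (1,), "NEG1": (1,), "HK1": (7,), "END1": (10,)}
        ds = build_dataset(data)
        out = housekeeping_normalize(self._corrected(ds), ds, "HK1")
        assert out.values.loc["END1", "L1"] == pytest.approx(10.0)


class TestImputeAndLog:
    def _expr(self, end1):
        data = {"POS1": (1,) * len(end1), "NEG1": (1,) * len(end1),
                "HK1": (4,) * len(end1), "END1": end1}
        ds = build_dataset(data)
        return CountMatrix(ds.counts.values, "housekeeping_normalized"), ds

    def test_half_minimum_imputation(self):
        m, ds = self._expr((0, 4, 8))
        out, log = impute_and_log(m, ds)
        assert out.values.loc["END1"].tolist() == pytest.approx([1.0, 2.0, 3.0])
        assert log == [("END1", "L1", 2.0)]

    def test_multiple_zeros_share_fill(self):
        m, ds = self._expr((0, 0, 6))
        out, log = impute_and_log(m, ds)
        assert out.values.loc["END1"].tolist() == pytest.approx(
            [np.log2(3), np.log2(3), np.log2(6)]
        )
        assert len(log) == 2

    def test_no_zeros_logs_nothing(self):
        m, ds = self._expr((1, 1, 1))
        out, log = impute_and_log(m, ds)
        assert out.values.loc["END1"].tolist() == pytest.approx([0.0, 0.0, 0.0])
        assert log == []

    def test_all_zero_probe_is_an_error(self):
        m, ds = self._expr((0, 0, 0))
        with pytest.raises(ValidationError, match="END1"):
            impute_and_log(m, ds)


class TestDetectAboveBackground:
    def test_quantifier_all_lanes(self):
        # END1 below IgG everywhere; END2 above in one lane only
        data = {"POS1": (1, 1), "NEG1": (1, 1), "IGG1": (20, 20),
                "HK1": (50, 50), "END1": (5, 10), "END2": (5, 30)}
        ds = build_dataset(data)
        assert detect_above_background(ds.counts, ds) == ["END1"]

    def test_requires_igg_probes(self):
        data = {"POS1": (1, 1), "NEG1": (1, 1), "HK1": (50, 50), "END1": (5, 10)}
        ds = build_dataset(data)
        with pytest.raises(ValidationError):
            detect_above_background(ds.counts, ds)


class TestRunNormalization:
    def test_reference_fixture_all_stages(self, reference_dataset):
        """Hand-worked 12-probe x 3-lane fixture through the full chain."""
        expr, report = run_normalization(reference_dataset)
        assert report.undetected_probes == REFERENCE_UNDETECTED
        assert sorted(expr.probe_ids) == sorted(REFERENCE_LOG2)
        for probe, expected in REFERENCE_LOG2.items():
            got = expr.values.loc[probe].tolist()
            assert got == pytest.approx(expected, abs=1e-9)
        assert report.lane_scaling_factors.tolist() == pytest.approx(
            [2.0, 0.5, 1.0]
        )
        assert report.per_lane_negative_background.tolist() == pytest.approx(
            [10.0, 10.0, 5.0]
        )
        assert report.per_lane_igg_background.tolist() == pytest.approx(
            [6.0, 8.0, 4.0]
        )
        assert report.housekeeping_choice == "HK1"
        # one zero imputed for END1 in lane L1
        (probe, lane, fill), = report.zero_imputation_log
        assert (probe, lane) == ("END1", "L1")
        assert fill == pytest.approx(5.0)

    def test_flat_controls_reduce_to_log2(self):
        # constant controls, background at the documented 0.5 floor for
        # zero-count control probes -> chain subtracts exactly 1 and is
        # otherwise the identity up to log2
        data = {
            "POS1": (50, 50, 50), "NEG1": (0, 0, 0), "IGG1": (0, 0, 0),
            "HK1": (21, 21, 21), "END1": (3, 9, 33),
        }
        ds = build_dataset(data)
        expr, _ = run_normalization(ds)
        assert expr.values.loc["END1"].tolist() == pytest.approx([1.0, 3.0, 5.0])

    def test_igg_toggle_changes_only_that_stage(self, reference_dataset):
        expr_default, _ = run_normalization(reference_dataset)
        expr_no_igg, report = run_normalization(
            reference_dataset, NormalizationOptions(subtract_igg=False)
        )
        assert report.per_lane_igg_background.tolist() == [0.0, 0.0, 0.0]
        # corrected END2 without IgG subtraction: (46, 16, 20); hk becomes
        # (14, 40, 20) with geomean (11200)^(1/3)
        hk_gm = (14 * 40 * 20) ** (1 / 3)
        expected = np.log2(
            np.array([46, 16, 20]) / (np.array([14, 40, 20]) / hk_gm)
        )
        assert expr_no_igg.values.loc["END2"].tolist() == pytest.approx(
            expected.tolist(), abs=1e-9
        )
        assert not np.allclose(
            expr_default.values.loc["END2"], expr_no_igg.values.loc["END2"]
        )

    def test_lane_scaling_invariance(self, reference_dataset):
        """A lane-wide scale factor shifts the log2 output by one global
        constant only (the lane-scaling reference is data-dependent), so
        every within-matrix contrast is left unchanged."""
        expr_ref, _ = run_normalization(reference_dataset)
        scaled = reference_dataset.counts.values.copy()
        scaled["L2"] = scaled["L2"] * 7.3
        ds2 = build_dataset(
            {p: tuple(scaled.loc[p]) for p in scaled.index}
        )
        expr_scaled, _ = run_normalization(ds2)
        delta = (expr_scaled.values - expr_ref.values).to_numpy()
        assert delta == pytest.approx(np.full_like(delta, np.log2(7.3) / 3), abs=1e-9)
        # lane contrasts (the difference statistic's ingredients) are exact
        contrast_ref = expr_ref.values["L2"] - expr_ref.values["L1"]
        contrast_scaled = expr_scaled.values["L2"] - expr_scaled.values["L1"]
        assert contrast_scaled.tolist() == pytest.approx(
            contrast_ref.tolist(), abs=1e-9
        )

    def test_lane_permutation_equivariance(self, reference_dataset):
        expr_ref, _ = run_normalization(reference_dataset)
        perm = ["L3", "L1", "L2"]
        permuted = build_dataset(
            {
                p: tuple(reference_dataset.counts.values.loc[p, perm])
                for p in reference_dataset.counts.probe_ids
            }
        )
        expr_perm, _ = run_normalization(permuted)
        # lane i of the permuted run equals lane perm[i] of the reference
        expected = expr_ref.values[perm]
        expected.columns = expr_perm.values.columns
        pd.testing.assert_frame_equal(expr_perm.values, expected, atol=1e-12, rtol=0)

    def test_output_is_finite_and_report_complete(self, reference_dataset):
        expr, report = run_normalization(reference_dataset)
        assert np.isfinite(expr.values.to_numpy()).all()
        assert report.housekeeping_cv_table is not None
        assert np.exp(np.log(report.lane_scaling_factors).mean()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_probe_zero_after_correction_is_excluded_not_fatal(self):
        # END1 ties the IgG level in lane L1 (strict "below" leaves it
        # unflagged) yet has no signal left after background subtraction
        # anywhere: excluded like an undetected probe, not a fatal error
        data = {
            "POS1": (10, 10), "NEG1": (10, 10), "IGG1": (12, 30),
            "HK1": (50, 50), "END1": (12, 9), "END2": (100, 100),
        }
        ds = build_dataset(data)
        expr, report = run_normalization(ds)
        assert "END1" in report.undetected_probes
        assert expr.probe_ids == ["END2"]

    def test_stage_errors_are_annotated(self):
        data = {"POS1": (5, 0), "NEG1": (1, 1), "HK1": (5, 5), "END1": (9, 9)}
        ds = build_dataset(data)
        with pytest.raises(ValidationError, match="positive_control_normalize"):
            run_normalization(ds)
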