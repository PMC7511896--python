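"""Costing engine: unit-cost derivations and person-level cost totals."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mhcapitation import costing
from mhcapitation.costing import (
    DegenerateClusterError,
    UnitCostTable,
    annualise_cluster_costs,
    compute_person_costs,
    contact_weight,
    derive_bedday_unit_costs,
    derive_contact_unit_costs,
    derive_iapt_unit_cost,
    truncate_cost,
)


def make_schedule(rows):
    df = pd.DataFrame(rows, columns=["cluster_id", "setting", "total_annual_cost", "volume"])
    df["unit_cost"] = np.where(df["volume"] > 0, df["total_annual_cost"] / df["volume"], 0.0)
    return df


def make_activity(rows):
    return pd.DataFrame(rows, columns=["person_id", "event_type", "cluster_id", "pay_band", "provider_id", "count"])


class TestAnnualise:
    def test_nine_month_scaling(self):
        sched = make_schedule([(0, "admitted", 1000.0, 4)])
        out = annualise_cluster_costs(sched, 0.75)
        assert out.loc[0, "total_annual_cost"] == pytest.approx(750.0)

    def test_identity_factor(self):
        sched = make_schedule([(0, "admitted", 1000.0, 4), (0, "iapt", 500.0, 5)])
        pd.testing.assert_frame_equal(annualise_cluster_costs(sched, 1.0), sched)

    def test_iapt_untouched(self):
        sched = make_schedule([(0, "iapt", 940.0, 10)])
        out = annualise_cluster_costs(sched, 0.75)
        assert out.loc[0, "total_annual_cost"] == pytest.approx(940.0)

    def test_invalid_factor(self):
        sched = make_schedule([(0, "admitted", 1000.0, 4)])
        with pytest.raises(ValueError):
            annualise_cluster_costs(sched, 0.0)


class TestBeddayUnits:
    def test_single_cluster_hand_arithmetic(self):
        sched = make_schedule([(0, "admitted", 1000.0, 3)])
        act = make_activity(
            [(1, "general_bedday", 0, np.nan, 0, 2), (2, "intensive_bedday", 0, np.nan, 0, 1)]
        )
        general, intensive, per_cluster = derive_bedday_unit_costs(sched, act, 1.97)
        assert general == pytest.approx(1000.0 / 3.97)  # 251.889...
        assert intensive == pytest.approx(1.97 * 1000.0 / 3.97)  # 496.22...
        assert per_cluster.loc[0, "intensive_unit"] / per_cluster.loc[0, "general_unit"] == pytest.approx(1.97)

    def test_cross_cluster_bedday_weighted_average(self):
        # cluster 0: unit 100 with 8 general days; cluster 1: unit 200 with 2
        sched = make_schedule([(0, "admitted", 800.0, 8), (1, "admitted", 400.0, 2)])
        act = make_activity(
            [(1, "general_bedday", 0, np.nan, 0, 8), (2, "general_bedday", 1, np.nan, 0, 2)]
        )
        general, _, _ = derive_bedday_unit_costs(sched, act, 1.97)
        assert general == pytest.approx((100 * 8 + 200 * 2) / 10)

    def test_no_intensive_days_reduces_to_division(self):
        sched = make_schedule([(0, "admitted", 600.0, 3)])
        act = make_activity([(1, "general_bedday", 0, np.nan, 0, 3)])
        general, intensive, _ = derive_bedday_unit_costs(sched, act, 1.97)
        assert general == pytest.approx(200.0)
        assert intensive == pytest.approx(1.97 * 200.0)

    def test_degenerate_cluster_named_in_error(self):
        sched = make_schedule([(4, "admitted", 600.0, 3)])
        act = make_activity([(1, "care_contact", 4, 2.0, 0, 3)])
        with pytest.raises(DegenerateClusterError, match="4"):
            derive_bedday_unit_costs(sched, act, 1.97)


class TestContactWeights:
    def test_band_two_is_denominator(self):
        assert contact_weight(2) == 1.0

    def test_missing_band_treated_as_band_six(self):
        assert contact_weight(None) == contact_weight(6)
        assert contact_weight(float("nan")) == contact_weight(6)

    def test_custom_pay_scale_ratio(self):
        scale = pd.DataFrame({"band": [2, 6], "midpoint_salary": [20_000, 30_000]})
        assert contact_weight(6, scale) == pytest.approx(1.5)

    @pytest.mark.parametrize("band", [1, 10])
    def test_band_outside_scale_rejected(self, band):
        with pytest.raises(ValueError):
            contact_weight(band)


class TestContactUnits:
    def test_equal_bands_split_evenly(self):
        sched = make_schedule([(0, "non_admitted", 300.0, 3)])
        act = make_activity([(i, "care_contact", 0, 2.0, 0, 1) for i in range(3)])
        by_band, _ = derive_contact_unit_costs(sched, act)
        assert by_band[2] == pytest.approx(100.0)

    def test_two_band_fixture_solves_weighted_split(self):
        scale = pd.DataFrame({"band": [2, 6], "midpoint_salary": [20_000, 40_000]})
        sched = make_schedule([(0, "non_admitted", 300.0, 2)])
        act = make_activity(
            [(1, "care_contact", 0, 2.0, 0, 1), (2, "care_contact", 0, 6.0, 0, 1)]
        )
        by_band, _ = derive_contact_unit_costs(sched, act, scale)
        assert by_band[2] == pytest.approx(100.0)  # w + 2w = 300
        assert by_band[6] == pytest.approx(200.0)

    def test_band_units_ordered_like_midpoints(self, small_run):
        by_band, _ = derive_contact_unit_costs(
            costing.annualise_cluster_costs(small_run.schedule), small_run.activity, small_run.pay_scale
        )
        mid = small_run.pay_scale.set_index("band")["midpoint_salary"]
        bands = sorted(by_band)
        units = np.array([by_band[b] for b in bands])
        mids = mid.loc[bands].to_numpy()
        assert (np.argsort(units, kind="stable") == np.argsort(mids, kind="stable")).all()


class TestIaptUnit:
    def test_division(self):
        sched = make_schedule([(0, "iapt", 940.0, 10)])
        assert derive_iapt_unit_cost(sched) == pytest.approx(94.0)

    def test_zero_total_is_zero(self):
        sched = make_schedule([(0, "iapt", 0.0, 0)])
        assert derive_iapt_unit_cost(sched) == 0.0

    def test_zero_volume_with_cost_rejected(self):
        sched = make_schedule([(0, "iapt", 940.0, 0)])
        with pytest.raises(DegenerateClusterError):
            derive_iapt_unit_cost(sched)


class TestPersonCosts:
    def test_single_iapt_contact_costs_94(self):
        act = make_activity([(1, "iapt_contact", 0, np.nan, 0, 1)])
        out = compute_person_costs(act)
        assert out.loc[0, "raw_cost"] == pytest.approx(94.0)

    def test_truncation_at_cap(self):
        act = make_activity([(1, "general_bedday", 0, np.nan, 0, 2806)])  # 2806 × 371 = 1 041 026
        out = compute_person_costs(act)
        assert out.loc[0, "raw_cost"] > 100_000
        assert out.loc[0, "truncated_cost"] == 100_000.0

    def test_hand_summed_mixed_activity(self):
        act = make_activity(
            [(1, "general_bedday", 0, np.nan, 0, 2), (1, "care_contact", 0, 2.0, 0, 1)]
        )
        out = compute_person_costs(act)
        assert out.loc[0, "raw_cost"] == pytest.approx(2 * 371 + 109)  # 851

    def test_inactive_persons_get_zero(self):
        act = make_activity([(1, "iapt_contact", 0, np.nan, 0, 1)])
        pop = pd.DataFrame({"person_id": [0, 1, 2]})
        out = compute_person_costs(act, population=pop).set_index("person_id")
        assert out.loc[0, "raw_cost"] == 0.0
        assert out.loc[2, "truncated_cost"] == 0.0

    def test_unknown_event_type_rejected(self):
        act = make_activity([(1, "assessment", 0, np.nan, 0, 1)])
        with pytest.raises(ValueError):
            compute_person_costs(act)


@given(st.floats(min_value=0, max_value=1e7), st.floats(min_value=0, max_value=1e7))
@settings(deadline=None, max_examples=50)
def test_truncation_idempotent_and_monotone(x, y):
    cap = 100_000.0
    assert truncate_cost(truncate_cost(x, cap), cap) == truncate_cost(x, cap)
    lo, hi = sorted((x, y))
    assert truncate_cost(lo, cap) <= truncate_cost(hi, cap)


def test_conservation_against_schedule(small_run):
    """Person raw costs computed with derived units reproduce the scheduled
    totals (annualised to the activity window) exactly."""
    total_cost = small_run.person_costs["raw_cost"].sum()
    sched = small_run.schedule
    part_year = sched["setting"].isin(["admitted", "non_admitted"])
    scheduled = (
        sched.loc[part_year, "total_annual_cost"].sum() * 0.75
        + sched.loc[~part_year, "total_annual_cost"].sum()
    )
    assert total_cost == pytest.approx(scheduled, rel=1e-9)


def test_derived_table_matches_generative_units(small_run):
    uc = small_run.unit_costs
    assert uc.general_bedday == pytest.approx(371.0)
    assert uc.intensive_bedday == pytest.approx(1.97 * 371.0)
    assert uc.contact_by_band[2] == pytest.approx(109.0)
    assert uc.iapt_contact == pytest.approx(94.0)
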