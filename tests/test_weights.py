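"""Sterilisation, stratum weights, CCG indices, deprivation report."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mhcapitation import weights
from mhcapitation.needs_model import FittedNeedsModel, predict
from mhcapitation.covariates import DesignMatrix
from mhcapitation.weights import (
    SterilisationPolicy,
    aggregate_strata_weights,
    index_vs_deprivation_report,
    normalise_and_index,
    sterilise_predict,
)


@pytest.fixture(scope="module")
def sterilised(small_run):
    return sterilise_predict(small_run.model, small_run.design)


class TestSterilisePredict:
    def test_supply_perturbation_has_exactly_zero_effect(self, small_run):
        design = small_run.design
        means = design.X.mean()
        base = sterilise_predict(small_run.model, design, column_means=means)
        perturbed = design.X.copy()
        supply_cols = design.columns_with_role("supply")
        perturbed.loc[perturbed.index[:5], supply_cols] += 100.0
        pdesign = DesignMatrix(X=perturbed, roles=design.roles, outcome=design.outcome)
        after = sterilise_predict(small_run.model, pdesign, column_means=means)
        assert (after - base).abs().max() == 0.0

    def test_identical_need_different_distance_same_estimate(self, small_run):
        design = small_run.design
        X2 = design.X.iloc[:1].copy()
        X3 = X2.copy()
        X3["distance_minutes"] += 30.0
        pair = DesignMatrix(X=pd.concat([X2, X3]), roles=design.roles)
        est = sterilise_predict(small_run.model, pair, column_means=design.X.mean())
        assert est.iloc[0] == est.iloc[1]

    def test_empty_policy_equals_plain_predict(self, small_run):
        est = sterilise_predict(small_run.model, small_run.design, SterilisationPolicy(frozenset()))
        plain = predict(small_run.model, small_run.design)
        np.testing.assert_allclose(est.to_numpy(), plain.to_numpy())

    def test_population_mean_preserved(self, small_run, sterilised):
        plain = predict(small_run.model, small_run.design)
        assert sterilised.mean() == pytest.approx(plain.mean(), abs=1e-8)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            SterilisationPolicy(frozenset({"not_a_role"}))


class TestStratumWeights:
    def test_singleton_stratum_weight_is_the_estimate(self):
        pop = pd.DataFrame(
            {
                "person_id": [0, 1],
                "practice_id": [0, 0],
                "gender": ["female", "male"],
                "age_years": [30, 30],
            }
        )
        est = pd.Series([120.0, 80.0], index=[0, 1])
        table = aggregate_strata_weights(est, pop)
        assert set(table["need_weight"]) == {120.0, 80.0}
        assert (table["registered_count"] == 1).all()

    def test_weighted_sum_identity(self, small_run, sterilised):
        table = aggregate_strata_weights(sterilised, small_run.persons)
        lhs = (table["need_weight"] * table["registered_count"]).sum()
        assert lhs == pytest.approx(sterilised.sum(), rel=1e-10)

    def test_external_registration_counts_override(self):
        pop = pd.DataFrame(
            {
                "person_id": [0, 1],
                "practice_id": [0, 0],
                "gender": ["female", "female"],
                "age_years": [30, 31],
            }
        )
        est = pd.Series([100.0, 200.0], index=[0, 1])
        counts = pd.DataFrame(
            {"practice_id": [0], "gender": ["female"], "age_band": ["30_34"], "registered_count": [7]}
        )
        table = aggregate_strata_weights(est, pop, registered_counts=counts)
        assert table.loc[0, "registered_count"] == 7
        assert table.loc[0, "need_weight"] == pytest.approx(150.0)


def two_ccg_population():
    # two CCGs, one practice each, one person per stratum, equal populations
    return pd.DataFrame(
        {
            "person_id": [0, 1],
            "practice_id": [0, 1],
            "ccg_id": [0, 1],
            "gender": ["female", "female"],
            "age_years": [30, 30],
        }
    )


class TestIndices:
    def test_homogeneous_population_all_indices_one(self):
        pop = two_ccg_population()
        est = pd.Series([100.0, 100.0], index=[0, 1])
        idx = normalise_and_index(aggregate_strata_weights(est, pop), pop)
        np.testing.assert_allclose(idx["need_index"].to_numpy(), 1.0)

    def test_two_to_one_need_gives_four_thirds_and_two_thirds(self):
        pop = two_ccg_population()
        est = pd.Series([200.0, 100.0], index=[0, 1])
        idx = normalise_and_index(aggregate_strata_weights(est, pop), pop).set_index("ccg_id")
        assert idx.loc[0, "need_index"] == pytest.approx(4 / 3)
        assert idx.loc[1, "need_index"] == pytest.approx(2 / 3)

    def test_normalised_weighted_population_sums_to_registered(self, small_run, sterilised):
        table = aggregate_strata_weights(sterilised, small_run.persons)
        idx = normalise_and_index(table, small_run.persons)
        assert idx["weighted_population"].sum() == pytest.approx(len(small_run.persons), rel=1e-12)

    def test_population_weighted_mean_index_is_one(self, small_run, sterilised):
        table = aggregate_strata_weights(sterilised, small_run.persons)
        idx = normalise_and_index(table, small_run.persons)
        mean = np.average(idx["need_index"], weights=idx["unweighted_population"])
        assert mean == pytest.approx(1.0, abs=1e-10)

    def test_index_range_straddles_one_when_need_varies(self, small_run, sterilised):
        table = aggregate_strata_weights(sterilised, small_run.persons)
        idx = normalise_and_index(table, small_run.persons)
        assert idx["need_index"].min() < 1 < idx["need_index"].max()

    def test_zero_need_run_degenerates_to_unity(self):
        pop = two_ccg_population()
        est = pd.Series([0.0, 0.0], index=[0, 1])
        idx = normalise_and_index(aggregate_strata_weights(est, pop), pop)
        np.testing.assert_allclose(idx["need_index"].to_numpy(), 1.0)


class TestDeprivationReport:
    def indices_frame(self, values):
        return pd.DataFrame(
            {
                "ccg_id": range(len(values)),
                "unweighted_population": 100,
                "weighted_population": [100 * v for v in values],
                "need_index": values,
            }
        )

    def test_perfect_monotone_correlation(self):
        idx = self.indices_frame([0.8, 0.9, 1.0, 1.1, 1.2])
        dep = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=range(5))
        _, rho = index_vs_deprivation_report(idx, dep)
        assert rho == pytest.approx(1.0)

    def test_independent_fixture_near_zero(self):
        rng = np.random.default_rng(0)
        idx = self.indices_frame(list(1 + 0.1 * rng.normal(size=30)))
        dep = pd.Series(rng.normal(size=30), index=range(30))
        _, rho = index_vs_deprivation_report(idx, dep)
        assert abs(rho) < 0.4

    def test_default_generator_positive_gradient(self, small_run, sterilised):
        table = aggregate_strata_weights(sterilised, small_run.persons)
        idx = normalise_and_index(table, small_run.persons)
        dep = weights.ccg_deprivation_scores(small_run.persons, small_run.area.lsoa)
        _, rho = index_vs_deprivation_report(idx, dep)
        assert rho > 0
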