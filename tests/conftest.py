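"""Shared fixtures: one small synthetic run reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from mhcapitation import costing, covariates, needs_model, synthetic_data, weights


@dataclass
class SmallRun:
    config: synthetic_data.SimConfig
    persons: object
    area: synthetic_data.AreaTables
    activity: object
    schedule: object
    pay_scale: object
    unit_costs: costing.UnitCostTable
    person_costs: object
    design: covariates.DesignMatrix
    split: needs_model.SampleSplit
    model: needs_model.FittedNeedsModel


@pytest.fixture(scope="session")
def small_config() -> synthetic_data.SimConfig:
    return synthetic_data.SimConfig(
        n_persons=20_000,
        n_practices=40,
        n_ccgs=4,
        n_lsoas=80,
        n_providers=4,
        n_clusters=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_config) -> SmallRun:
    persons, area = synthetic_data.generate_population(small_config)
    activity = synthetic_data.generate_activity(persons, area, small_config)
    schedule, pay_scale = synthetic_data.generate_reference_schedule(activity, small_config)
    unit_costs = costing.derive_unit_cost_table(schedule, activity, pay_scale)
    person_costs = costing.compute_person_costs(activity, unit_costs, population=persons)
    design = covariates.build_design_matrix(persons, area, person_costs)
    split = needs_model.split_sample(persons["practice_id"], seed=1)
    model = needs_model.fit_ols_robust(design, split=split)
    return SmallRun(
        config=small_config,
        persons=persons,
        area=area,
        activity=activity,
        schedule=schedule,
        pay_scale=pay_scale,
        unit_costs=unit_costs,
        person_costs=person_costs,
        design=design,
        split=split,
        model=model,
    )
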