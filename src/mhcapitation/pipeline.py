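"""End-to-end orchestration: simulate → cost → fit → weights → evaluate.

Every run writes its resolved configuration (and a hash of it) beside the
output artefacts, logs counts at each stage, and is deterministic under
the configured seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import costing, metrics, needs_model, synthetic_data, weights
from .covariates import DesignMatrix, build_design_matrix, DEFAULT_COMMUNAL_THRESHOLD
from .synthetic_data import AreaTables, SimConfig

logger = logging.getLogger(__name__)

#: Model variants reported in the evaluation table, from the leanest
#: covariate set to the full need-plus-supply specification.
VARIANT_ROLES: dict[str, tuple[str, ...]] = {
    "age_gender_only": (),  # special-cased: ag_* columns only
    "individual_need": ("individual_need",),
    "all_need": ("individual_need", "attributed_need", "unmet_need"),
    "need_and_supply": ("individual_need", "attributed_need", "unmet_need", "supply"),
}


@dataclass
class RunConfig:
    """Full configuration for one pipeline run; round-trips through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    split_seed: int = 1
    intensity_weight: float = 1.97
    annualisation_factor: float = 0.75
    truncation_cap: float = 100_000.0
    communal_threshold: int = DEFAULT_COMMUNAL_THRESHOLD
    roles_to_sterilise: tuple[str, ...] = ("supply", "unmet_need")
    outside_threshold: float = 0.10
    affected_threshold: float = 0.05

    def to_yaml(self) -> str:
        d = asdict(self)
        d["roles_to_sterilise"] = list(self.roles_to_sterilise)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        sim = SimConfig(**(d.pop("sim", {}) or {}))
        if "roles_to_sterilise" in d:
            d["roles_to_sterilise"] = tuple(d["roles_to_sterilise"])
        return cls(sim=sim, **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def variant_columns(design: DesignMatrix, variant: str) -> list[str]:
    if variant == "age_gender_only":
        return [c for c in design.X.columns if c.startswith("ag_")]
    return design.columns_with_role(*VARIANT_ROLES[variant])


def evaluate_variants(
    design: DesignMatrix,
    split: needs_model.SampleSplit,
    variants: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Predictive metrics per model variant, on estimation and validation arms.

    Each variant is refit on the estimation arm with its covariate subset;
    practice-level actual and predicted cost totals are compared within
    each arm. Rows: variants; columns: arm × metric.
    """
    names = list(variants) if variants is not None else list(VARIANT_ROLES)
    actual = design.outcome.groupby(design.practice_ids.to_numpy()).sum()
    rows = []
    for name in names:
        cols = variant_columns(design, name)
        model = needs_model.fit_ols_robust(design, split=split, columns=cols)
        pred = needs_model.predict(model, design)
        predicted = pred.groupby(design.practice_ids.to_numpy()).sum()
        row: dict[str, float | str] = {"variant": name}
        for arm in ("estimation", "validation"):
            ids = split.arm(arm)
            rep = metrics.predictive_report(actual.loc[actual.index.isin(ids)], predicted.loc[predicted.index.isin(ids)])
            row.update({f"{arm}_{k}": v for k, v in rep.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full weighted-capitation pipeline and write all artefacts.

    Returns a dict of in-memory results (tables, model, metric reports).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(config.to_yaml())

    # --- simulate -----------------------------------------------------
    persons, area = synthetic_data.generate_population(config.sim)
    activity = synthetic_data.generate_activity(persons, area, config.sim)
    schedule, pay_scale = synthetic_data.generate_reference_schedule(
        activity, config.sim, config.annualisation_factor
    )
    synthetic_data.write_fixture_set(outdir / "fixtures", persons, area, activity, schedule, pay_scale, config.sim)
    n_users = activity["person_id"].nunique() if len(activity) else 0
    logger.info("simulated %d persons, %d service users (%.2f%%)", len(persons), n_users, 100 * n_users / len(persons))

    # --- cost ---------------------------------------------------------
    if len(activity) and schedule["total_annual_cost"].sum() > 0:
        unit_costs = costing.derive_unit_cost_table(
            schedule,
            activity,
            pay_scale,
            intensity_weight=config.intensity_weight,
            annualisation_factor=config.annualisation_factor,
            truncation_cap=config.truncation_cap,
        )
    else:
        logger.warning("no costed activity; falling back to the default unit-cost table")
        unit_costs = costing.UnitCostTable(truncation_cap=config.truncation_cap)
    person_costs = costing.compute_person_costs(activity, unit_costs, population=persons)
    n_trunc = int((person_costs["raw_cost"] > unit_costs.truncation_cap).sum())
    logger.info("%d persons truncated at the cost cap", n_trunc)
    person_costs.to_csv(outdir / "person_costs.csv", index=False)
    (outdir / "unit_costs.json").write_text(
        json.dumps(
            {
                "general_bedday": unit_costs.general_bedday,
                "intensive_bedday": unit_costs.intensive_bedday,
                "contact_by_band": unit_costs.contact_by_band,
                "iapt_contact": unit_costs.iapt_contact,
                "intensity_weight": unit_costs.intensity_weight,
                "annualisation_factor": unit_costs.annualisation_factor,
                "truncation_cap": unit_costs.truncation_cap,
            },
            indent=2,
        )
    )

    # --- fit ----------------------------------------------------------
    design = build_design_matrix(persons, area, person_costs, config.communal_threshold)
    split = needs_model.split_sample(persons["practice_id"], config.split_seed)
    model = needs_model.fit_ols_robust(design, split=split)
    model.save(outdir / "needs_model.json")
    logger.info("fitted needs model on %d persons; dropped columns: %s", model.n_obs, model.dropped_columns)

    # --- weights ------------------------------------------------------
    policy = weights.SterilisationPolicy(frozenset(config.roles_to_sterilise))
    need_est = weights.sterilise_predict(model, design, policy)
    weight_table = weights.aggregate_strata_weights(need_est, persons)
    indices = weights.normalise_and_index(weight_table, persons)
    weight_table.to_csv(outdir / "need_weights.csv", index=False)
    indices.to_csv(outdir / "ccg_need_index.csv", index=False)
    dep = weights.ccg_deprivation_scores(persons, area.lsoa)
    dep_table, spearman_rho = weights.index_vs_deprivation_report(indices, dep)
    dep_table.to_csv(outdir / "index_vs_deprivation.csv", index=False)

    # --- evaluate -----------------------------------------------------
    variant_table = evaluate_variants(design, split)
    variant_table.to_csv(outdir / "model_variants.csv")
    actual_by_prac = design.outcome.groupby(design.practice_ids.to_numpy()).sum()
    need_by_prac = need_est.groupby(design.practice_ids.to_numpy()).sum()
    if float(actual_by_prac.sum()) > 0 and float(need_by_prac.sum()) > 0:
        redist = metrics.redistribution_report(need_by_prac, actual_by_prac)
    else:
        logger.warning("degenerate run (zero total cost); redistribution metrics undefined")
        redist = {k: float("nan") for k in ("redistribution_index", "mean_abs_pct_change", "prop_substantially_affected")}
    report = {
        "config_hash": config.config_hash,
        "n_persons": int(len(persons)),
        "n_service_users": int(n_users),
        "contact_fraction": float(n_users / len(persons)),
        "mean_cost_all": float(person_costs["truncated_cost"].mean()),
        "n_truncated": n_trunc,
        "spearman_index_vs_deprivation": float(spearman_rho) if not math.isnan(spearman_rho) else float("nan"),
        "redistribution": redist,
        "need_index_range": [float(indices["need_index"].min()), float(indices["need_index"].max())],
    }
    (outdir / "metrics.json").write_text(json.dumps(_jsonable(report), indent=2))

    return {
        "persons": persons,
        "area": area,
        "activity": activity,
        "schedule": schedule,
        "unit_costs": unit_costs,
        "person_costs": person_costs,
        "design": design,
        "split": split,
        "model": model,
        "need_estimates": need_est,
        "weight_table": weight_table,
        "indices": indices,
        "spearman_index_vs_deprivation": spearman_rho,
        "variant_table": variant_table,
        "report": report,
    }
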