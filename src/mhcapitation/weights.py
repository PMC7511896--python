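"""Supply sterilisation, stratum need weights and CCG need indices.

Sterilisation replaces every column of a chosen role (by default supply
and unmet-need columns) with its population-average value before applying
the fitted linear predictor, so that person-level need estimates vary only
with need variables. Estimates are then averaged within
(practice, gender, 5-year age band) strata, multiplied by stratum
registration counts, normalised so weighted populations sum to the total
registered population, and aggregated to CCG indices (weighted over
unweighted population; population-weighted national mean exactly 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import DesignMatrix, ROLES, age_band_label
from .needs_model import INTERCEPT, FittedNeedsModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SterilisationPolicy:
    """Which column roles to fix at their population-average values."""

    roles_to_sterilise: frozenset[str] = frozenset({"supply", "unmet_need"})
    # the fixing rule is population-average by construction; kept explicit
    fixing_rule: str = "population_average"

    def __post_init__(self) -> None:
        unknown = set(self.roles_to_sterilise) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles in sterilisation policy: {sorted(unknown)}")


def sterilise_predict(
    model: FittedNeedsModel,
    design: DesignMatrix,
    policy: SterilisationPolicy | None = None,
    column_means: pd.Series | None = None,
) -> pd.Series:
    """Person-level need estimates with policy-role columns sterilised.

    Columns whose role is in the policy are replaced, for every person, by
    the population-average value of that column; all other columns are
    untouched, so the estimate no longer depends on anyone's own supply
    values. ``column_means`` fixes the averages externally (they are
    constants of an allocation run, e.g. national averages); by default
    they are computed from the supplied design. By linearity the population
    mean prediction is preserved exactly. An empty policy reduces to the
    plain prediction.
    """
    if policy is None:
        policy = SterilisationPolicy()
    cols = [c for c in model.coefficients.index if c != INTERCEPT]
    missing = set(cols) - set(design.X.columns)
    if missing:
        raise ValueError(f"design lacks model columns: {sorted(missing)}")
    beta = model.coefficients[cols].to_numpy()
    X = design.X[cols].to_numpy(dtype=float)
    sterilise = np.array([model.column_roles[c] in policy.roles_to_sterilise for c in cols])
    if sterilise.any():
        names = [c for c, s in zip(cols, sterilise) if s]
        if column_means is not None:
            absent = set(names) - set(column_means.index)
            if absent:
                raise ValueError(f"column_means lacks sterilised columns: {sorted(absent)}")
            means = column_means[names].to_numpy(dtype=float)
        else:
            means = X[:, sterilise].mean(axis=0)
        X = X.copy()
        X[:, sterilise] = means  # broadcast: every person gets the average
    yhat = model.intercept + X @ beta
    return pd.Series(yhat, index=design.X.index, name="need_estimate")


def aggregate_strata_weights(
    need_estimates: pd.Series,
    population: pd.DataFrame,
    registered_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stratum need weights: mean estimate by (practice, gender, age band).

    ``registered_counts`` optionally supplies external registration counts
    per stratum (columns practice_id, gender, age_band, registered_count);
    the allocation-year registers need not be the estimation-year
    population. By default the simulated population's own counts are used.
    Strata absent from the population yield no row.
    """
    df = population[["person_id", "practice_id", "gender"]].copy()
    df["age_band"] = age_band_label(population["age_years"])
    est = need_estimates.reindex(population["person_id"])
    if est.isna().any():
        raise ValueError("need estimates do not cover the population")
    df["need_estimate"] = est.to_numpy()
    out = (
        df.groupby(["practice_id", "gender", "age_band"], observed=True)
        .agg(need_weight=("need_estimate", "mean"), registered_count=("person_id", "count"))
        .reset_index()
    )
    if registered_counts is not None:
        ext = registered_counts.set_index(["practice_id", "gender", "age_band"])["registered_count"]
        key = out.set_index(["practice_id", "gender", "age_band"]).index
        matched = ext.reindex(key)
        n_missing = int(matched.isna().sum())
        if n_missing:
            logger.warning("%d strata lack external registration counts; keeping internal counts", n_missing)
        out["registered_count"] = np.where(matched.isna(), out["registered_count"], matched)
    return out


def normalise_and_index(
    weight_table: pd.DataFrame,
    population: pd.DataFrame,
) -> pd.DataFrame:
    """Normalised weighted populations and per-CCG need indices.

    Practice raw weighted populations (Σ stratum weight × count) are scaled
    so their total equals the total registered population, aggregated to
    CCG, and divided by the CCG's unweighted population. If every need
    estimate is zero (a run with no activity at all) the indices are set to
    1.0 and a warning is logged.
    """
    total_pop = float(weight_table["registered_count"].sum())
    if total_pop <= 0:
        raise ValueError("total registered population must be positive")
    prac_ccg = population.drop_duplicates("practice_id").set_index("practice_id")["ccg_id"]
    wt = weight_table.copy()
    wt["raw_weighted"] = wt["need_weight"] * wt["registered_count"]
    by_prac = wt.groupby("practice_id").agg(
        raw_weighted=("raw_weighted", "sum"), registered=("registered_count", "sum")
    )
    total_raw = float(by_prac["raw_weighted"].sum())
    if total_raw == 0:
        logger.warning("all need estimates are zero; need indices degenerate to 1.0")
        by_prac["normalised_weighted"] = by_prac["registered"].astype(float)
    else:
        by_prac["normalised_weighted"] = by_prac["raw_weighted"] * (total_pop / total_raw)
    by_prac["ccg_id"] = prac_ccg.reindex(by_prac.index)
    if by_prac["ccg_id"].isna().any():
        raise ValueError("practices in weight table missing from population practice→CCG map")
    ccg = by_prac.groupby("ccg_id").agg(
        unweighted_population=("registered", "sum"),
        weighted_population=("normalised_weighted", "sum"),
    )
    if (ccg["unweighted_population"] <= 0).any():
        raise ValueError("CCG with zero registered population")
    ccg["need_index"] = ccg["weighted_population"] / ccg["unweighted_population"]
    return ccg.reset_index()


def ccg_deprivation_scores(population: pd.DataFrame, lsoa: pd.DataFrame) -> pd.Series:
    """Population-weighted mean LSOA deprivation score per CCG (synthetic
    stand-in for an area deprivation index)."""
    col = "deprivation_score" if "deprivation_score" in lsoa.columns else "out_of_work_benefit_pct"
    dep = lsoa.set_index("lsoa_id")[col]
    per_person = dep.reindex(population["lsoa_id"]).to_numpy()
    return pd.Series(per_person, index=population.index).groupby(population["ccg_id"].to_numpy()).mean()


def index_vs_deprivation_report(
    indices: pd.DataFrame, deprivation: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Pair CCG need indices with deprivation and return the Spearman rho.

    On the default generator the correlation is positive, since deprivation
    drives the attributed-need variables that the model rewards.
    """
    table = indices.set_index("ccg_id").copy()
    table["deprivation"] = deprivation.reindex(table.index)
    rho = stats.spearmanr(table["deprivation"], table["need_index"]).statistic
    return table.reset_index(), float(rho)
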