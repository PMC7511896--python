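"""Regression design construction with need/supply role tagging.

Every column of the design matrix carries exactly one role:

- ``individual_need``: gender × 5-year age band interactions, household
  type, physical-health admission diagnoses;
- ``attributed_need``: area / practice variables attributed to the person
  (out-of-work benefit %, practice SMI prevalence, student-practice flag);
- ``unmet_need``: ethnicity indicators (reference White British) — these
  enter the model but are later sterilised, as systematically lower
  utilisation for a group is read as unmet need, not lower need;
- ``supply``: distance to the nearest provider, provider contact-share
  columns, and commissioning-area (CCG) indicators.

Roles drive sterilisation downstream; nothing downstream matches on column
names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("individual_need", "attributed_need", "supply", "unmet_need")

AGE_BAND_EDGES = list(range(20, 90, 5))  # 20,25,...,85 ; last band is open-ended
AGE_BAND_LABELS = [f"{lo}_{lo + 4}" for lo in AGE_BAND_EDGES[:-1]] + ["85plus"]
GENDERS = ("female", "male")
REFERENCE_AGE_GENDER = "female_20_24"

ETHNICITY_LEVELS = (
    "white_british",  # reference
    "irish",
    "white_and_black_caribbean",
    "black_caribbean",
    "black_african",
    "other_black",
    "asian",
    "mixed_other",
)

HOUSEHOLD_LEVELS = (
    "two_adult_opposite_gender",  # reference
    "alone",
    "two_plus_adults_or_children",
    "communal",
    "care_home",
)

DIAGNOSIS_FLAGS = (
    "diag_poisoning",
    "diag_viral_hepatitis",
    "diag_diabetes",
    "diag_endocrine_metabolic",
    "diag_cerebrovascular",
    "diag_chronic_respiratory",
    "diag_cognition_symptoms",
)

DEFAULT_COMMUNAL_THRESHOLD = 7


class LinkageError(ValueError):
    """Person records could not be matched across the input tables."""


@dataclass
class DesignMatrix:
    """Numeric design matrix plus column metadata and (optionally) outcome."""

    X: pd.DataFrame  # indexed by person_id
    roles: dict[str, str]
    references: dict[str, str] = field(default_factory=dict)
    outcome: pd.Series | None = None  # truncated annual cost, same index
    practice_ids: pd.Series | None = None  # person's practice of registration

    @property
    def person_ids(self) -> pd.Index:
        return self.X.index

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.X.columns if self.roles[c] in roles]

    def validate(self) -> None:
        missing = set(self.X.columns) - set(self.roles)
        if missing:
            raise ValueError(f"columns without a role: {sorted(missing)}")
        bad = set(self.roles.values()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing values")


def age_band_label(age_years: np.ndarray | pd.Series) -> np.ndarray:
    """Map age in years (≥ 20) to a 5-year band label, open-ended at 85+."""
    age = np.asarray(age_years)
    if (age < 20).any():
        raise ValueError("ages below 20 must be filtered before design construction")
    idx = np.clip((age - 20) // 5, 0, len(AGE_BAND_LABELS) - 1).astype(int)
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def build_age_gender_bands(population: pd.DataFrame) -> pd.DataFrame:
    """One indicator per gender × 5-year age band cell, female 20–24 omitted.

    Each person falls in exactly one cell; the reference cell has all
    indicators at zero.
    """
    band = age_band_label(population["age_years"])
    cell = population["gender"].astype(str) + "_" + band
    all_cells = [f"{g}_{b}" for g in GENDERS for b in AGE_BAND_LABELS]
    dummies = pd.get_dummies(pd.Categorical(cell, categories=all_cells), dtype=float)
    dummies = dummies.drop(columns=[REFERENCE_AGE_GENDER])
    dummies.columns = [f"ag_{c}" for c in dummies.columns]
    dummies.index = population.index
    return dummies


def derive_household_type(
    population: pd.DataFrame, communal_threshold: int = DEFAULT_COMMUNAL_THRESHOLD
) -> pd.Series:
    """Classify each person's household from co-residents at their address.

    Precedence: a care-home flag wins outright; then a sole resident is
    ``alone``; two residents of opposite gender form the reference
    two-adult household; addresses at or above the communal threshold are
    ``communal``; everything else is ``two_plus_adults_or_children``.
    """
    size = population.groupby("address_id")["person_id"].transform("count")
    n_female = (
        population.assign(is_f=(population["gender"] == "female").astype(int))
        .groupby("address_id")["is_f"]
        .transform("sum")
    )
    out = np.full(len(population), "two_plus_adults_or_children", dtype=object)
    out[(size == 2) & (n_female == 1)] = "two_adult_opposite_gender"
    out[size >= communal_threshold] = "communal"
    out[size == 1] = "alone"
    out[population["care_home_flag"].to_numpy(dtype=bool)] = "care_home"
    return pd.Series(out, index=population.index, name="household_type")


def _dummies(values: pd.Series, levels: tuple[str, ...], reference: str, prefix: str) -> pd.DataFrame:
    cat = pd.Categorical(values, categories=list(levels))
    if pd.isna(cat).any():
        bad = sorted(set(values) - set(levels))
        raise ValueError(f"unknown {prefix} levels: {bad}")
    d = pd.get_dummies(cat, dtype=float).drop(columns=[reference])
    d.columns = [f"{prefix}_{c}" for c in d.columns]
    d.index = values.index
    return d


def build_design_matrix(
    population: pd.DataFrame,
    area: "AreaTables",
    costs: pd.DataFrame | None = None,
    communal_threshold: int = DEFAULT_COMMUNAL_THRESHOLD,
) -> DesignMatrix:
    """Assemble the full tagged design matrix (and outcome, if costs given).

    Attributed variables are merged by LSOA or practice of registration;
    supply columns are distance, per-provider contact shares and CCG
    indicators (first CCG id is the reference and omitted).
    """
    pop = population.reset_index(drop=True)
    roles: dict[str, str] = {}
    references: dict[str, str] = {}
    blocks: list[pd.DataFrame] = []

    ag = build_age_gender_bands(pop)
    roles.update({c: "individual_need" for c in ag.columns})
    references["age_gender"] = REFERENCE_AGE_GENDER
    blocks.append(ag)

    eth = _dummies(pop["ethnicity"], ETHNICITY_LEVELS, "white_british", "eth")
    roles.update({c: "unmet_need" for c in eth.columns})
    references["ethnicity"] = "white_british"
    blocks.append(eth)

    hh = _dummies(
        derive_household_type(pop, communal_threshold),
        HOUSEHOLD_LEVELS,
        "two_adult_opposite_gender",
        "hh",
    )
    roles.update({c: "individual_need" for c in hh.columns})
    references["household"] = "two_adult_opposite_gender"
    blocks.append(hh)

    diag = pop[list(DIAGNOSIS_FLAGS)].astype(float)
    roles.update({c: "individual_need" for c in diag.columns})
    blocks.append(diag)

    lsoa = area.lsoa.set_index("lsoa_id")
    missing_lsoa = set(pop["lsoa_id"]) - set(lsoa.index)
    if missing_lsoa:
        raise LinkageError(f"{len(missing_lsoa)} LSOA ids in population not in area table")
    attributed = lsoa.loc[pop["lsoa_id"], ["out_of_work_benefit_pct"]].reset_index(drop=True)
    distance = lsoa.loc[pop["lsoa_id"], ["distance_minutes"]].reset_index(drop=True)

    practice = area.practice.set_index("practice_id")
    missing_prac = set(pop["practice_id"]) - set(practice.index)
    if missing_prac:
        raise LinkageError(f"{len(missing_prac)} practice ids in population not in practice table")
    prac_cols = practice.loc[pop["practice_id"], ["smi_prevalence_pct", "student_practice_flag"]].reset_index(drop=True)
    attributed["smi_prevalence_pct"] = prac_cols["smi_prevalence_pct"].to_numpy(dtype=float)
    attributed["student_practice"] = prac_cols["student_practice_flag"].to_numpy(dtype=float)
    roles.update({c: "attributed_need" for c in attributed.columns})
    blocks.append(attributed)

    roles["distance_minutes"] = "supply"
    blocks.append(distance)

    shares = area.provider_share.pivot_table(
        index="practice_id", columns="provider_id", values="share", fill_value=0.0
    )
    share_block = shares.loc[pop["practice_id"]].reset_index(drop=True)
    share_block.columns = [f"share_provider_{int(j)}" for j in share_block.columns]
    roles.update({c: "supply" for c in share_block.columns})
    blocks.append(share_block)

    ccg_ids = sorted(pd.unique(pop["ccg_id"]))
    ccg = pd.get_dummies(pd.Categorical(pop["ccg_id"], categories=ccg_ids), dtype=float)
    ccg = ccg.drop(columns=[ccg_ids[0]])
    ccg.columns = [f"ccg_{int(c)}" for c in ccg.columns]
    references["ccg"] = str(ccg_ids[0])
    roles.update({c: "supply" for c in ccg.columns})
    blocks.append(ccg)

    X = pd.concat([b.reset_index(drop=True) for b in blocks], axis=1)
    X.index = pd.Index(pop["person_id"], name="person_id")

    outcome = None
    if costs is not None:
        cost_by_person = costs.set_index("person_id")["truncated_cost"]
        unmatched = int((~X.index.isin(cost_by_person.index)).sum())
        if unmatched:
            raise LinkageError(f"{unmatched} persons lack a cost record")
        outcome = cost_by_person.loc[X.index].rename("truncated_cost")

    practice_ids = pd.Series(pop["practice_id"].to_numpy(), index=X.index, name="practice_id")
    dm = DesignMatrix(X=X, roles=roles, references=references, outcome=outcome, practice_ids=practice_ids)
    dm.validate()
    return dm
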