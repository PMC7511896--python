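"""Unit-cost derivation and person-level annual cost computation.

Costs for admitted care are expressed per bed-day, with intensive bed-days
weighted as a fixed multiple of general bed-days; community care contacts
are costed by the pay band of the professional delivering them, weighted by
the ratio of pay-band mid-point salaries to the band-2 mid-point; IAPT
(psychological-therapy) contacts carry a single flat unit cost.

The engine can either run from the packaged default unit costs (the
published 2015/16 figures) or derive a fresh :class:`UnitCostTable` from a
reference-cost schedule plus observed activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SETTINGS = ("admitted", "non_admitted", "iapt")
EVENT_TYPES = ("general_bedday", "intensive_bedday", "care_contact", "iapt_contact")

#: Default pay-band mid-point salaries (GBP / year). Bands 8 and 9 share a
#: mid-point, which is why their contact unit costs coincide.
DEFAULT_PAY_SCALE = pd.DataFrame(
    {
        "band": [2, 3, 4, 5, 6, 7, 8, 9],
        "midpoint_salary": [21800, 23400, 26800, 31600, 38800, 46000, 54800, 54800],
    }
)

#: Published contact unit costs by pay band (GBP per care contact).
DEFAULT_CONTACT_COSTS = {2: 109.0, 3: 117.0, 4: 134.0, 5: 158.0, 6: 194.0, 7: 230.0, 8: 274.0, 9: 274.0}

MISSING_BAND_FALLBACK = 6  # professionals with unknown role are costed at band 6


class DegenerateClusterError(ValueError):
    """A cluster carries scheduled cost but no activity to spread it over."""


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs applied to activity events, GBP.

    Defaults are the published national figures: general bed-day £371,
    intensive bed-day £752, contacts £109–£274 by pay band, IAPT contact £94.
    """

    general_bedday: float = 371.0
    intensive_bedday: float = 752.0
    contact_by_band: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CONTACT_COSTS))
    iapt_contact: float = 94.0
    intensity_weight: float = 1.97
    annualisation_factor: float = 0.75
    truncation_cap: float = 100_000.0

    def contact_cost(self, band: float | int | None) -> float:
        """Unit cost of one care contact; a missing band is costed at band 6."""
        if band is None or (isinstance(band, float) and math.isnan(band)):
            band = MISSING_BAND_FALLBACK
        band = int(band)
        if band not in self.contact_by_band:
            raise ValueError(f"pay band {band} outside the pay scale (bands {sorted(self.contact_by_band)})")
        return self.contact_by_band[band]


DEFAULT_UNIT_COSTS = UnitCostTable()


def validate_schedule(schedule: pd.DataFrame) -> None:
    required = {"cluster_id", "setting", "total_annual_cost", "unit_cost", "volume"}
    missing = required - set(schedule.columns)
    if missing:
        raise ValueError(f"reference schedule missing columns: {sorted(missing)}")
    bad = set(schedule["setting"]) - set(SETTINGS)
    if bad:
        raise ValueError(f"unknown settings in schedule: {sorted(bad)}")
    if (schedule[["total_annual_cost", "unit_cost", "volume"]] < 0).any().any():
        raise ValueError("schedule contains negative costs or volumes")


def annualise_cluster_costs(schedule: pd.DataFrame, factor: float = 0.75) -> pd.DataFrame:
    """Scale admitted and non-admitted scheduled totals to a part-year window.

    The default factor 0.75 converts a full-year total to the nine-month
    equivalent under constant service delivery. IAPT rows are left untouched
    (their totals are already expressed for the costing window).
    """
    if not 0 < factor <= 1:
        raise ValueError(f"annualisation factor must be in (0, 1], got {factor}")
    validate_schedule(schedule)
    out = schedule.copy()
    mask = out["setting"].isin(["admitted", "non_admitted"])
    out.loc[mask, "total_annual_cost"] = out.loc[mask, "total_annual_cost"] * factor
    out.loc[mask, "unit_cost"] = out.loc[mask, "unit_cost"] * factor
    return out


def _bedday_counts(activity: pd.DataFrame) -> pd.DataFrame:
    days = (
        activity[activity["event_type"].isin(["general_bedday", "intensive_bedday"])]
        .pivot_table(index="cluster_id", columns="event_type", values="count", aggfunc="sum", fill_value=0.0)
        .reindex(columns=["general_bedday", "intensive_bedday"], fill_value=0.0)
    )
    days.columns = ["general_days", "intensive_days"]
    return days


def derive_bedday_unit_costs(
    schedule: pd.DataFrame,
    activity: pd.DataFrame,
    intensity_weight: float = 1.97,
) -> tuple[float, float, pd.DataFrame]:
    """Derive general and intensive bed-day unit costs from admitted totals.

    Per cluster the admitted cost is divided by the weighted sum of bed-days
    (intensive days counting as ``intensity_weight`` general days), which
    gives the cluster general unit cost; the intensive unit cost is that
    times ``intensity_weight``. Cluster units are then averaged across
    clusters weighting by the cluster's own bed-day counts (general days
    weight the general average, intensive days the intensive average).

    Returns ``(general_unit, intensive_unit, per_cluster_table)``. The
    schedule passed in should already be annualised to the activity window.
    """
    validate_schedule(schedule)
    admitted = schedule[schedule["setting"] == "admitted"].set_index("cluster_id")
    days = _bedday_counts(activity)
    tab = admitted[["total_annual_cost"]].join(days, how="left").fillna(0.0)

    active = tab[tab["total_annual_cost"] > 0]
    weighted = active["general_days"] + intensity_weight * active["intensive_days"]
    dead = active.index[weighted <= 0]
    if len(dead):
        raise DegenerateClusterError(
            f"clusters with admitted cost but no bed-days: {sorted(dead.tolist())}"
        )
    silent = tab.index[(tab["total_annual_cost"] == 0) & (tab[["general_days", "intensive_days"]].sum(axis=1) > 0)]
    if len(silent):
        logger.warning("clusters with bed-days but zero scheduled admitted cost: %s", sorted(silent.tolist()))

    per_cluster = active.copy()
    per_cluster["general_unit"] = active["total_annual_cost"] / weighted
    per_cluster["intensive_unit"] = intensity_weight * per_cluster["general_unit"]

    gw = per_cluster["general_days"].to_numpy()
    iw = per_cluster["intensive_days"].to_numpy()
    general = float(np.average(per_cluster["general_unit"], weights=gw)) if gw.sum() > 0 else float("nan")
    if iw.sum() > 0:
        intensive = float(np.average(per_cluster["intensive_unit"], weights=iw))
    else:
        intensive = intensity_weight * general
    return general, intensive, per_cluster.reset_index()


def contact_weight(band: float | int | None, pay_scale: pd.DataFrame | None = None) -> float:
    """Pay-band contact weight: mid-point salary over the band-2 mid-point.

    A missing band is treated as band 6 (the fallback used when the
    professional's role is unrecorded).
    """
    if pay_scale is None:
        pay_scale = DEFAULT_PAY_SCALE
    mid = pay_scale.set_index("band")["midpoint_salary"]
    if 2 not in mid.index:
        raise ValueError("pay scale must contain band 2 (the weighting denominator)")
    if band is None or (isinstance(band, float) and math.isnan(band)):
        band = MISSING_BAND_FALLBACK
    band = int(band)
    if band not in mid.index:
        raise ValueError(f"pay band {band} outside the pay scale (bands {sorted(mid.index.tolist())})")
    return float(mid.loc[band] / mid.loc[2])


def derive_contact_unit_costs(
    schedule: pd.DataFrame,
    activity: pd.DataFrame,
    pay_scale: pd.DataFrame | None = None,
) -> tuple[dict[int, float], pd.DataFrame]:
    """Derive care-contact unit costs by pay band from non-admitted totals.

    Per cluster, the non-admitted cost is divided by the weighted sum of
    contacts (pay-band weights relative to band 2) to give the cluster
    band-2 base cost; band-b units are base × weight(b). The overall band
    units are contact-count-weighted averages of the cluster bases, scaled
    by the band weights.
    """
    if pay_scale is None:
        pay_scale = DEFAULT_PAY_SCALE
    validate_schedule(schedule)
    non_adm = schedule[schedule["setting"] == "non_admitted"].set_index("cluster_id")
    contacts = activity[activity["event_type"] == "care_contact"].copy()
    contacts["weight"] = [contact_weight(b, pay_scale) for b in contacts["pay_band"]]
    contacts["weighted_count"] = contacts["count"] * contacts["weight"]
    grp = contacts.groupby("cluster_id").agg(
        n_contacts=("count", "sum"), weighted=("weighted_count", "sum")
    )
    tab = non_adm[["total_annual_cost"]].join(grp, how="left").fillna(0.0)
    active = tab[tab["total_annual_cost"] > 0]
    dead = active.index[active["weighted"] <= 0]
    if len(dead):
        raise DegenerateClusterError(
            f"clusters with non-admitted cost but no contacts: {sorted(dead.tolist())}"
        )
    per_cluster = active.copy()
    per_cluster["base_unit"] = active["total_annual_cost"] / active["weighted"]
    base = float(np.average(per_cluster["base_unit"], weights=per_cluster["n_contacts"]))
    mid = pay_scale.set_index("band")["midpoint_salary"]
    by_band = {int(b): base * float(mid.loc[b] / mid.loc[2]) for b in mid.index}
    return by_band, per_cluster.reset_index()


def derive_iapt_unit_cost(schedule: pd.DataFrame) -> float:
    """IAPT unit cost: total scheduled IAPT cost over total IAPT contacts."""
    validate_schedule(schedule)
    iapt = schedule[schedule["setting"] == "iapt"]
    volume = float(iapt["volume"].sum())
    total = float(iapt["total_annual_cost"].sum())
    if total == 0:
        return 0.0
    if volume <= 0:
        raise DegenerateClusterError("IAPT setting has scheduled cost but zero contact volume")
    return total / volume


def derive_unit_cost_table(
    schedule: pd.DataFrame,
    activity: pd.DataFrame,
    pay_scale: pd.DataFrame | None = None,
    intensity_weight: float = 1.97,
    annualisation_factor: float = 0.75,
    truncation_cap: float = 100_000.0,
) -> UnitCostTable:
    """Full derivation: annualise the schedule, then derive every unit cost."""
    annualised = annualise_cluster_costs(schedule, annualisation_factor)
    general, intensive, _ = derive_bedday_unit_costs(annualised, activity, intensity_weight)
    by_band, _ = derive_contact_unit_costs(annualised, activity, pay_scale)
    iapt = derive_iapt_unit_cost(annualised)
    return UnitCostTable(
        general_bedday=general,
        intensive_bedday=intensive,
        contact_by_band=by_band,
        iapt_contact=iapt,
        intensity_weight=intensity_weight,
        annualisation_factor=annualisation_factor,
        truncation_cap=truncation_cap,
    )


def truncate_cost(raw: pd.Series | np.ndarray | float, cap: float = 100_000.0):
    """Cap raw annual cost at the truncation threshold (outlier control)."""
    return np.minimum(raw, cap)


def compute_person_costs(
    activity: pd.DataFrame,
    unit_costs: UnitCostTable | None = None,
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Total annual mental-healthcare cost per person, raw and truncated.

    Each activity row contributes ``count`` times the matching unit cost;
    care contacts with a missing pay band are costed at band 6. When a
    population table is given, persons without any activity are included
    with cost 0.
    """
    if unit_costs is None:
        unit_costs = DEFAULT_UNIT_COSTS
    bad = set(activity["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types in activity log: {sorted(bad)}")
    act = activity.copy()
    unit = np.empty(len(act), dtype=float)
    et = act["event_type"].to_numpy()
    unit[et == "general_bedday"] = unit_costs.general_bedday
    unit[et == "intensive_bedday"] = unit_costs.intensive_bedday
    unit[et == "iapt_contact"] = unit_costs.iapt_contact
    cc = et == "care_contact"
    if cc.any():
        bands = act.loc[cc, "pay_band"].to_numpy(dtype=float)
        unit[cc] = [unit_costs.contact_cost(b) for b in bands]
    act["cost"] = act["count"].to_numpy(dtype=float) * unit
    raw = act.groupby("person_id")["cost"].sum()
    if population is not None:
        raw = raw.reindex(population["person_id"], fill_value=0.0)
    out = raw.rename("raw_cost").reset_index()
    out["truncated_cost"] = truncate_cost(out["raw_cost"], unit_costs.truncation_cap)
    return out
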