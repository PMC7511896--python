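"""Synthetic person-level populations, activity logs and reference schedules.

The generator emulates the statistical structure a person-based capitation
analysis assumes, at desk scale: a registered adult population (ages 20+)
nested person → address → LSOA and person → practice → CCG; rare service
use (about 4% of persons with any contact); heavy-tailed annual costs among
users; area deprivation spatially correlated and driving both attributed
need variables and latent need, so that a need-vs-deprivation gradient is
reproducible; and supply variation (distance to providers, provider contact
shares, CCG effects) that is recoverable by regression because expected
person cost is linear in the generated covariates with known ground-truth
coefficients.

Two regimes:

- ``noise_sd > 0`` (default): a ``contact_rate`` fraction of persons are
  service users; a user's cost target is the linear predictor divided by
  the contact rate, times a mean-one lognormal multiplier, plus Gaussian
  noise; integer event counts are drawn Poisson so that the expected cost
  given covariates equals the linear predictor.
- ``noise_sd == 0``: the noise-free limit used for exact-recovery checks —
  gating, multiplier and Poisson discretisation are disabled and every
  person's activity encodes the linear predictor exactly (event counts are
  then fractional).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates
from .costing import DEFAULT_CONTACT_COSTS, DEFAULT_PAY_SCALE

# service-mix parameters for users: probability of each service type and the
# relative cost share assigned to the types a user actually touches
P_ADMITTED, P_CONTACT, P_IAPT = 0.08, 0.85, 0.45
SHARE_ADMITTED, SHARE_CONTACT, SHARE_IAPT = 0.55, 0.35, 0.10
INTENSIVE_DAY_FRACTION = 0.25  # share of weighted bed-days that are intensive

GENERAL_BEDDAY_BASE = 371.0
CONTACT_BAND2_BASE = 109.0
IAPT_UNIT = 94.0
INTENSITY_WEIGHT = 1.97

BAND_PROBS = {2: 0.10, 3: 0.13, 4: 0.14, 5: 0.17, 6: 0.22, 7: 0.13, 8: 0.07, 9: 0.04}

ADDRESS_SIZE_PROBS = [0.30, 0.34, 0.16, 0.10, 0.05, 0.03, 0.01, 0.01]  # sizes 1..8

ETHNICITY_PROBS = [0.85, 0.02, 0.01, 0.02, 0.03, 0.01, 0.04, 0.02]

DIAG_BASE_PREVALENCE = {
    "diag_poisoning": 0.008,
    "diag_viral_hepatitis": 0.005,
    "diag_diabetes": 0.030,
    "diag_endocrine_metabolic": 0.020,
    "diag_cerebrovascular": 0.012,
    "diag_chronic_respiratory": 0.030,
    "diag_cognition_symptoms": 0.008,
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    ``true_coefficients`` maps design-matrix column names to GBP effects on
    expected annual cost; ``None`` selects the package defaults (published
    effect sizes where available). ``noise_sd`` is the additive Gaussian
    noise on a user's cost target, in GBP.
    """

    n_persons: int = 200_000
    n_practices: int = 200
    n_ccgs: int = 10
    n_lsoas: int = 400
    n_providers: int = 5
    n_clusters: int = 5
    contact_rate: float = 0.0401
    true_coefficients: dict[str, float] | None = None
    intercept: float = 100.0
    noise_sd: float = 50.0
    lognormal_sigma: float = 0.5
    missing_payband_rate: float = 0.027
    care_home_rate: float = 0.005
    cluster_cost_spread: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_persons >= self.n_practices >= self.n_ccgs >= 1):
            raise ConfigurationError("need n_persons >= n_practices >= n_ccgs >= 1")
        if min(self.n_lsoas, self.n_providers, self.n_clusters) < 1:
            raise ConfigurationError("n_lsoas, n_providers, n_clusters must be >= 1")
        if not 0 <= self.contact_rate < 1:
            raise ConfigurationError("contact_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.missing_payband_rate < 1:
            raise ConfigurationError("missing_payband_rate must be in [0, 1)")


@dataclass
class AreaTables:
    """Attributed-variable tables: LSOA-level, practice-level, provider shares."""

    lsoa: pd.DataFrame
    practice: pd.DataFrame
    provider_share: pd.DataFrame


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return {name: np.random.default_rng(s) for name, s in zip(("population", "activity", "misc"), children)}


def default_true_coefficients(config: SimConfig) -> dict[str, float]:
    """Ground-truth GBP effects for every design column the generator emits.

    Published effect sizes are used where available (diagnoses, household
    type, ethnicity contrasts, out-of-work benefit, SMI prevalence, student
    practice, distance). The age–gender profile is a smooth bump peaking in
    the early 40s with men costing more under 30 and women more between 30
    and 65; CCG effects are deterministic pseudo-random values in [0, 400]
    and provider-share effects ramp over [0, 60], so that supply variation
    contributes materially to practice-level cost variation at desk scale.
    """
    coefs: dict[str, float] = {}

    def bump(age_mid: float) -> float:
        return 120.0 * math.exp(-(((age_mid - 42.0) / 16.0) ** 2))

    ref = bump(22.0)
    for gender in covariates.GENDERS:
        for label in covariates.AGE_BAND_LABELS:
            mid = 88.0 if label == "85plus" else float(int(label.split("_")[0]) + 2)
            adj = 0.0
            if gender == "male":
                adj = 12.0 if mid < 30 else (-12.0 if mid < 65 else 0.0)
            name = f"ag_{gender}_{label}"
            if name == f"ag_{covariates.REFERENCE_AGE_GENDER}":
                continue
            coefs[name] = round(bump(mid) + adj - ref, 2)

    coefs.update(
        {
            "eth_irish": 34.0,
            "eth_white_and_black_caribbean": 140.0,
            "eth_black_caribbean": 134.0,
            "eth_black_african": 120.0,
            "eth_other_black": 125.0,
            "eth_asian": 45.0,
            "eth_mixed_other": 60.0,
            "hh_alone": 101.0,
            "hh_two_plus_adults_or_children": -20.0,
            "hh_communal": 147.0,
            "hh_care_home": 437.0,
            "diag_poisoning": 1699.0,
            "diag_viral_hepatitis": 285.0,
            "diag_diabetes": 70.0,
            "diag_endocrine_metabolic": 63.0,
            "diag_cerebrovascular": 52.0,
            "diag_chronic_respiratory": 73.0,
            "diag_cognition_symptoms": 838.0,
            "out_of_work_benefit_pct": 2.70,
            "smi_prevalence_pct": 22.0,
            "student_practice": -28.0,
            "distance_minutes": -0.33,
        }
    )
    for j in range(config.n_providers):
        if config.n_providers > 1:
            coefs[f"share_provider_{j}"] = round(60.0 * j / (config.n_providers - 1), 2)
        else:
            coefs["share_provider_0"] = 0.0
    for k in range(1, config.n_ccgs):
        # deterministic per CCG and independent of the run seed, scrambled so
        # the supply pattern is not collinear with the deprivation gradient
        coefs[f"ccg_{k}"] = round(400.0 * np.random.default_rng(10_000 + k).random(), 2)
    return coefs


def resolve_coefficients(config: SimConfig, columns: list[str]) -> np.ndarray:
    coefs = config.true_coefficients
    if coefs is None:
        coefs = default_true_coefficients(config)
    else:
        unknown = set(coefs) - set(columns)
        if unknown:
            raise ConfigurationError(f"true_coefficients name unknown design columns: {sorted(unknown)}")
    return np.array([coefs.get(c, 0.0) for c in columns], dtype=float)


def _cluster_factor(config: SimConfig) -> np.ndarray:
    c = np.arange(config.n_clusters, dtype=float)
    if config.n_clusters == 1:
        return np.ones(1)
    return 1.0 + config.cluster_cost_spread * (c / (config.n_clusters - 1) - 0.5)


def cluster_general_unit(config: SimConfig) -> np.ndarray:
    """Generative general bed-day unit cost per cluster."""
    return GENERAL_BEDDAY_BASE * _cluster_factor(config)


def cluster_contact_base(config: SimConfig) -> np.ndarray:
    """Generative band-2 care-contact unit cost per cluster."""
    return CONTACT_BAND2_BASE * _cluster_factor(config)


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, AreaTables]:
    """Generate the registered adult population and attributed-area tables.

    Geography is a synthetic unit square: provider, practice and LSOA
    locations are uniform; deprivation follows a spatial gradient plus
    noise; practices are assigned to CCGs by contiguous location bands, so
    CCGs differ systematically in deprivation. Persons share addresses
    (1–8 residents) and every address maps to one LSOA; each address
    registers with one of the three practices nearest its LSOA.
    """
    rng = _streams(config)["population"]

    provider_xy = rng.uniform(0, 1, (config.n_providers, 2))
    # practices on a jittered grid: roughly even spacing, hence roughly even
    # list sizes, as practices locate to serve population
    side = int(np.ceil(np.sqrt(config.n_practices)))
    cells = rng.permutation(side * side)[: config.n_practices]
    centres = np.column_stack([(cells % side + 0.5) / side, (cells // side + 0.5) / side])
    practice_xy = np.clip(centres + rng.uniform(-0.25 / side, 0.25 / side, (config.n_practices, 2)), 0, 1)
    order = np.argsort(practice_xy[:, 0])
    rank = np.empty(config.n_practices, dtype=int)
    rank[order] = np.arange(config.n_practices)
    practice_ccg = (rank * config.n_ccgs) // config.n_practices

    lsoa_xy = rng.uniform(0, 1, (config.n_lsoas, 2))
    deprivation = 3.0 * (0.5 - lsoa_xy[:, 0]) + rng.normal(0, 0.5, config.n_lsoas)
    out_of_work = np.clip(12.0 + 10.0 * deprivation, 0.5, 45.0)
    d_prov = np.linalg.norm(lsoa_xy[:, None, :] - provider_xy[None, :, :], axis=2)
    distance_minutes = 55.0 * d_prov.min(axis=1)

    # practice-level attributed variables; deprivation taken from nearby LSOAs
    d_lp = np.linalg.norm(practice_xy[:, None, :] - lsoa_xy[None, :, :], axis=2)
    k = min(5, config.n_lsoas)
    near = np.argsort(d_lp, axis=1)[:, :k]
    practice_dep = deprivation[near].mean(axis=1)
    smi = np.clip(0.9 + 0.5 * practice_dep + rng.normal(0, 0.08, config.n_practices), 0.05, 3.5)
    # about 5% of practices are student practices; at least one so the
    # indicator is never degenerate
    n_student = max(1, int(round(0.05 * config.n_practices)))
    student_flag = np.zeros(config.n_practices, dtype=int)
    if config.n_practices > 1:
        student_flag[rng.choice(config.n_practices, n_student, replace=False)] = 1

    d_pp = np.linalg.norm(practice_xy[:, None, :] - provider_xy[None, :, :], axis=2)
    w = np.exp(-4.0 * d_pp)
    shares = w / w.sum(axis=1, keepdims=True) * rng.uniform(0.5, 0.95, config.n_practices)[:, None]

    # addresses: sizes 1..8, truncated so person count is exact
    mean_size = float(np.dot(np.arange(1, 9), ADDRESS_SIZE_PROBS))
    n_addr_guess = int(config.n_persons / mean_size * 1.25) + 16
    sizes = rng.choice(np.arange(1, 9), size=n_addr_guess, p=ADDRESS_SIZE_PROBS)
    while sizes.sum() < config.n_persons:
        sizes = np.concatenate([sizes, rng.choice(np.arange(1, 9), size=n_addr_guess, p=ADDRESS_SIZE_PROBS)])
    cum = np.cumsum(sizes)
    n_addr = int(np.searchsorted(cum, config.n_persons) + 1)
    sizes = sizes[:n_addr]
    sizes[-1] -= int(cum[n_addr - 1] - config.n_persons)
    if sizes[-1] <= 0:  # degenerate tiny-n corner
        sizes = sizes[sizes > 0]
        n_addr = len(sizes)
    addr_lsoa = rng.integers(0, config.n_lsoas, n_addr)
    addr_care_home = rng.random(n_addr) < config.care_home_rate

    # practice choice: one of the 3 nearest practices to the address's LSOA
    kp = min(3, config.n_practices)
    near_prac = np.argsort(d_lp.T, axis=1)[:, :kp]  # n_lsoas x kp
    probs = np.array([0.60, 0.25, 0.15][:kp])
    probs = probs / probs.sum()
    pick = rng.choice(kp, size=n_addr, p=probs)
    addr_practice = near_prac[addr_lsoa, pick]

    person_addr = np.repeat(np.arange(n_addr), sizes)
    n = len(person_addr)
    assert n == config.n_persons

    ages = 20 + np.floor(rng.beta(1.1, 1.6, n) * 72).astype(int)
    gender = np.where(rng.random(n) < 0.5, "female", "male")
    ethnicity = rng.choice(np.array(covariates.ETHNICITY_LEVELS, dtype=object), size=n, p=ETHNICITY_PROBS)

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age_years": ages,
            "gender": gender,
            "address_id": person_addr,
            "lsoa_id": addr_lsoa[person_addr],
            "practice_id": addr_practice[person_addr],
            "ccg_id": practice_ccg[addr_practice[person_addr]],
            "ethnicity": ethnicity,
            "care_home_flag": addr_care_home[person_addr].astype(int),
        }
    )
    person_dep = deprivation[persons["lsoa_id"].to_numpy()]
    for name, base in DIAG_BASE_PREVALENCE.items():
        prev = np.clip(base * (1.0 + 0.3 * person_dep), 0.0005, 0.5)
        persons[name] = (rng.random(n) < prev).astype(int)

    lsoa = pd.DataFrame(
        {
            "lsoa_id": np.arange(config.n_lsoas),
            "x": lsoa_xy[:, 0],
            "y": lsoa_xy[:, 1],
            "deprivation_score": deprivation,
            "out_of_work_benefit_pct": out_of_work,
            "distance_minutes": distance_minutes,
        }
    )
    practice = pd.DataFrame(
        {
            "practice_id": np.arange(config.n_practices),
            "ccg_id": practice_ccg,
            "x": practice_xy[:, 0],
            "y": practice_xy[:, 1],
            "smi_prevalence_pct": smi,
            "student_practice_flag": student_flag,
        }
    )
    provider_share = pd.DataFrame(
        {
            "practice_id": np.repeat(np.arange(config.n_practices), config.n_providers),
            "provider_id": np.tile(np.arange(config.n_providers), config.n_practices),
            "share": shares.ravel(),
        }
    )
    return persons, AreaTables(lsoa=lsoa, practice=practice, provider_share=provider_share)


def expected_costs(persons: pd.DataFrame, area: AreaTables, config: SimConfig) -> pd.Series:
    """Linear-predictor expected annual cost per person (the ground truth)."""
    design = covariates.build_design_matrix(persons, area)
    beta = resolve_coefficients(config, list(design.X.columns))
    mu = config.intercept + design.X.to_numpy(dtype=float) @ beta
    return pd.Series(mu, index=design.X.index, name="expected_cost")


def _activity_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["person_id", "event_type", "cluster_id", "pay_band", "provider_id", "count"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def _append_block(blocks, person_id, event_type, cluster, pay_band, provider, count):
    mask = count > 0
    if not np.any(mask):
        return
    blocks.append(
        pd.DataFrame(
            {
                "person_id": person_id[mask],
                "event_type": event_type,
                "cluster_id": cluster[mask] if isinstance(cluster, np.ndarray) else cluster,
                "pay_band": pay_band[mask] if isinstance(pay_band, np.ndarray) else pay_band,
                "provider_id": provider[mask] if isinstance(provider, np.ndarray) else provider,
                "count": count[mask],
            }
        )
    )


def generate_activity(persons: pd.DataFrame, area: AreaTables, config: SimConfig) -> pd.DataFrame:
    """Generate the person-level service-activity log.

    In the stochastic regime, users are a Bernoulli(``contact_rate``) draw
    independent of covariates; a user's cost target is
    ``mu / contact_rate × lognormal(mean 1) + N(0, noise_sd)`` (floored at
    zero), split across admitted care, care contacts and IAPT according to
    a random service mix, and converted to integer event counts by Poisson
    draws at the generative unit costs, so expected cost given covariates
    equals ``mu``. Pay bands are multinomial with a configurable missing
    fraction. With ``noise_sd == 0`` the log instead encodes ``mu`` exactly
    as (fractional) band-2 care contacts in cluster 0.
    """
    rng = _streams(config)["activity"]
    mu = expected_costs(persons, area, config).to_numpy()
    person_ids = persons["person_id"].to_numpy()

    share_wide = area.provider_share.pivot_table(
        index="practice_id", columns="provider_id", values="share", fill_value=0.0
    )

    if config.noise_sd == 0:
        t = np.clip(mu, 0.0, None)
        counts = t / CONTACT_BAND2_BASE
        prac = persons["practice_id"].to_numpy()
        top_provider = share_wide.columns.to_numpy()[np.argmax(share_wide.to_numpy(), axis=1)]
        blocks: list[pd.DataFrame] = []
        _append_block(
            blocks, person_ids, "care_contact", np.zeros(len(t), dtype=int),
            np.full(len(t), 2.0), top_provider[prac], counts,
        )
        if not blocks:
            return _activity_frame([])
        return pd.concat(blocks, ignore_index=True)

    users = rng.random(len(mu)) < config.contact_rate
    m = int(users.sum())
    if m == 0:
        return _activity_frame([])
    uid = person_ids[users]
    mu_u = mu[users]
    sigma = config.lognormal_sigma
    mult = rng.lognormal(-0.5 * sigma**2, sigma, m)
    t = mu_u / config.contact_rate * mult + rng.normal(0, config.noise_sd, m)
    t = np.clip(t, 0.0, None)

    cluster = rng.integers(0, config.n_clusters, m)
    g_unit = cluster_general_unit(config)[cluster]
    c_base = cluster_contact_base(config)[cluster]

    adm = rng.random(m) < P_ADMITTED
    con = rng.random(m) < P_CONTACT
    iap = rng.random(m) < P_IAPT
    none = ~(adm | con | iap)
    con[none] = True
    w_adm = SHARE_ADMITTED * adm
    w_con = SHARE_CONTACT * con
    w_iap = SHARE_IAPT * iap
    total_w = w_adm + w_con + w_iap
    t_adm = t * w_adm / total_w
    t_con = t * w_con / total_w
    t_iap = t * w_iap / total_w

    # provider of care: categorical over the practice's provider shares
    prac = persons.loc[users, "practice_id"].to_numpy()
    share_mat = share_wide.to_numpy()[prac]
    share_mat = share_mat / share_mat.sum(axis=1, keepdims=True)
    u = rng.random(m)[:, None]
    provider = share_wide.columns.to_numpy()[(share_mat.cumsum(axis=1) < u).sum(axis=1)]

    blocks: list[pd.DataFrame] = []

    weighted_days = t_adm / g_unit
    gen_days = rng.poisson((1 - INTENSIVE_DAY_FRACTION) * weighted_days)
    int_days = rng.poisson(INTENSIVE_DAY_FRACTION * weighted_days / INTENSITY_WEIGHT)
    _append_block(blocks, uid, "general_bedday", cluster, np.nan, provider, gen_days)
    _append_block(blocks, uid, "intensive_bedday", cluster, np.nan, provider, int_days)

    bands = np.array(sorted(BAND_PROBS), dtype=float)
    base_p = np.array([BAND_PROBS[int(b)] for b in bands])
    base_p = base_p / base_p.sum()
    miss = config.missing_payband_rate
    cat_p = np.concatenate([(1 - miss) * base_p, [miss]])
    band_units = np.array([DEFAULT_CONTACT_COSTS[int(b)] for b in bands] + [DEFAULT_CONTACT_COSTS[6]])
    # expected unit cost of one contact in the band mix, per cluster scale
    ubar = (c_base / CONTACT_BAND2_BASE) * float(np.dot(cat_p, band_units))
    n_contacts = rng.poisson(t_con / ubar)
    band_counts = rng.multinomial(n_contacts, cat_p)
    for j, band in enumerate(list(bands) + [np.nan]):
        _append_block(blocks, uid, "care_contact", cluster, band, provider, band_counts[:, j])

    n_iapt = rng.poisson(t_iap / IAPT_UNIT)
    _append_block(blocks, uid, "iapt_contact", cluster, np.nan, provider, n_iapt)

    if not blocks:
        return _activity_frame([])
    out = pd.concat(blocks, ignore_index=True)
    return out.sort_values(["person_id", "event_type", "cluster_id"], kind="stable").reset_index(drop=True)


def generate_reference_schedule(
    activity: pd.DataFrame, config: SimConfig, annualisation_factor: float = 0.75
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the reference-cost schedule consistent with a generated log.

    Admitted and non-admitted totals are the generative cost of the logged
    activity, grossed up by the annualisation factor so that the costing
    engine's part-year scaling recovers them exactly; IAPT totals are
    already window-equivalent. Also returns the pay-scale table (band
    mid-point salaries proportional to the published contact unit costs).
    """
    g_units = cluster_general_unit(config)
    c_bases = cluster_contact_base(config)
    rows = []
    for c in range(config.n_clusters):
        sub = activity[activity["cluster_id"] == c] if len(activity) else activity
        gen = float(sub.loc[sub["event_type"] == "general_bedday", "count"].sum()) if len(sub) else 0.0
        intv = float(sub.loc[sub["event_type"] == "intensive_bedday", "count"].sum()) if len(sub) else 0.0
        cost9 = g_units[c] * (gen + INTENSITY_WEIGHT * intv)
        vol = (gen + intv) / annualisation_factor
        rows.append(
            {
                "cluster_id": c,
                "setting": "admitted",
                "total_annual_cost": cost9 / annualisation_factor,
                "unit_cost": (cost9 / annualisation_factor / vol) if vol > 0 else 0.0,
                "volume": vol,
            }
        )
        contacts = sub[sub["event_type"] == "care_contact"] if len(sub) else sub
        if len(contacts):
            band = contacts["pay_band"].fillna(6).astype(int)
            w = band.map(DEFAULT_CONTACT_COSTS) / DEFAULT_CONTACT_COSTS[2]
            weighted = float((contacts["count"] * w).sum())
            n_con = float(contacts["count"].sum())
        else:
            weighted = n_con = 0.0
        cost9 = c_bases[c] * weighted
        vol = n_con / annualisation_factor
        rows.append(
            {
                "cluster_id": c,
                "setting": "non_admitted",
                "total_annual_cost": cost9 / annualisation_factor,
                "unit_cost": (cost9 / annualisation_factor / vol) if vol > 0 else 0.0,
                "volume": vol,
            }
        )
        n_iapt = float(sub.loc[sub["event_type"] == "iapt_contact", "count"].sum()) if len(sub) else 0.0
        rows.append(
            {
                "cluster_id": c,
                "setting": "iapt",
                "total_annual_cost": n_iapt * IAPT_UNIT,
                "unit_cost": IAPT_UNIT if n_iapt > 0 else 0.0,
                "volume": n_iapt,
            }
        )
    schedule = pd.DataFrame(rows)
    return schedule, DEFAULT_PAY_SCALE.copy()


def write_fixture_set(
    outdir: str | Path,
    persons: pd.DataFrame,
    area: AreaTables,
    activity: pd.DataFrame,
    schedule: pd.DataFrame,
    pay_scale: pd.DataFrame,
    config: SimConfig,
) -> None:
    """Write the tables as CSV with a schema manifest and the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "persons": persons,
        "lsoa": area.lsoa,
        "practice": area.practice,
        "provider_share": area.provider_share,
        "activity": activity,
        "schedule": schedule,
        "pay_scale": pay_scale,
    }
    manifest: dict[str, dict] = {}
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
        manifest[name] = {col: str(dt) for col, dt in df.dtypes.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "sim_config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def read_fixture_set(indir: str | Path):
    """Read back a fixture set written by :func:`write_fixture_set`."""
    indir = Path(indir)
    read = lambda name: pd.read_csv(indir / f"{name}.csv")
    persons = read("persons")
    area = AreaTables(lsoa=read("lsoa"), practice=read("practice"), provider_share=read("provider_share"))
    activity = read("activity")
    schedule = read("schedule")
    pay_scale = read("pay_scale")
    config = SimConfig(**yaml.safe_load((indir / "sim_config.yaml").read_text()))
    return persons, area, activity, schedule, pay_scale, config
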