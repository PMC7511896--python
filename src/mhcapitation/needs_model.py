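"""Person-level cost regression: practice-level split, OLS with robust SEs.

The outcome is the truncated annual cost; the model is ordinary least
squares with heteroskedasticity-consistent (HC1) standard errors. The
estimation/validation split is at GP-practice level so that validation
measures out-of-sample performance for whole practices, the unit at which
allocations are evaluated.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import DesignMatrix

logger = logging.getLogger(__name__)

INTERCEPT = "const"


@dataclass
class SampleSplit:
    """Practice-level partition into estimation and validation arms."""

    assignment: pd.Series  # practice_id -> "estimation" | "validation"
    seed: int

    def arm(self, name: str) -> np.ndarray:
        return self.assignment.index[self.assignment == name].to_numpy()

    @property
    def estimation_practices(self) -> np.ndarray:
        return self.arm("estimation")

    @property
    def validation_practices(self) -> np.ndarray:
        return self.arm("validation")


@dataclass
class FittedNeedsModel:
    """Fitted coefficients with robust standard errors and column roles."""

    coefficients: pd.Series  # includes the intercept under "const"
    robust_se: pd.Series
    column_roles: dict[str, str]
    n_obs: int
    dropped_columns: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def intercept(self) -> float:
        return float(self.coefficients[INTERCEPT])

    def to_json(self) -> str:
        payload = {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "robust_se": {k: float(v) for k, v in self.robust_se.items()},
            "column_roles": self.column_roles,
            "n_obs": int(self.n_obs),
            "dropped_columns": list(self.dropped_columns),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FittedNeedsModel":
        payload = json.loads(text)
        return cls(
            coefficients=pd.Series(payload["coefficients"], dtype=float),
            robust_se=pd.Series(payload["robust_se"], dtype=float),
            column_roles=payload["column_roles"],
            n_obs=payload["n_obs"],
            dropped_columns=payload.get("dropped_columns", []),
            seed=payload.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedNeedsModel":
        return cls.from_json(Path(path).read_text())


def split_sample(practice_ids, seed: int) -> SampleSplit:
    """Randomly assign practices 50/50 to estimation and validation arms.

    With an odd practice count the estimation arm receives the extra
    practice (ceiling rule). Deterministic under the seed.
    """
    ids = np.unique(np.asarray(list(practice_ids)))
    if len(ids) < 2:
        raise ValueError("need at least 2 practices to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_est = math.ceil(len(ids) / 2)
    labels = np.where(np.isin(np.arange(len(ids)), perm[:n_est]), "estimation", "validation")
    return SampleSplit(assignment=pd.Series(labels, index=pd.Index(ids, name="practice_id")), seed=seed)


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8) -> tuple[list[int], list[str]]:
    """Greedy pivoted-Cholesky column selection on the Gram matrix.

    Keeps columns in order, dropping any column whose residual after
    projection on the kept set is numerically zero (later-indexed columns
    are the ones dropped).
    """
    G = X.T @ X
    n = G.shape[0]
    kept: list[int] = []
    dropped: list[str] = []
    L = np.zeros((n, n))
    diag_scale = np.maximum(np.diag(G), 1.0)
    for j in range(n):
        lj = np.zeros(len(kept))
        for idx, kcol in enumerate(kept):
            lj[idx] = (G[j, kcol] - lj[:idx] @ L[kcol, :idx]) / L[kcol, idx]
        resid = G[j, j] - lj @ lj
        if resid <= tol * diag_scale[j]:
            dropped.append(names[j])
            continue
        L[j, : len(kept)] = lj
        L[j, len(kept)] = np.sqrt(resid)
        kept.append(j)
    return kept, dropped


def fit_ols_robust(
    design: DesignMatrix,
    split: SampleSplit | None = None,
    columns: list[str] | None = None,
    cov_type: str = "HC1",
) -> FittedNeedsModel:
    """Fit OLS of truncated cost on the design, with robust standard errors.

    If a split is given, only persons in estimation-arm practices are used
    (the design must then be indexed consistently with a ``practice_id``
    lookup attached via ``design.X`` rows ordered as the population).
    Collinear columns are dropped (later-indexed ones) with a warning.
    """
    if design.outcome is None:
        raise ValueError("design has no outcome attached")
    X = design.X if columns is None else design.X[list(columns)]
    y = design.outcome
    if split is not None:
        if design.practice_ids is None:
            raise ValueError("design lacks practice ids; attach via design.practice_ids")
        mask = design.practice_ids.isin(split.estimation_practices).to_numpy()
        X = X.loc[mask]
        y = y.loc[mask]
    if len(X) == 0:
        raise ValueError("estimation arm is empty")

    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(arr)), arr])
    kept_idx, dropped = _drop_collinear(Xc, [INTERCEPT] + names)
    if dropped:
        logger.warning("dropping collinear columns: %s", dropped)
    kept_names = [([INTERCEPT] + names)[i] for i in kept_idx]
    Xk = Xc[:, kept_idx]

    res = sm.OLS(y.to_numpy(dtype=float), Xk).fit(cov_type=cov_type)
    coefs = pd.Series(res.params, index=kept_names)
    ses = pd.Series(res.bse, index=kept_names)
    return FittedNeedsModel(
        coefficients=coefs,
        robust_se=ses,
        column_roles=dict(design.roles),
        n_obs=int(res.nobs),
        dropped_columns=dropped,
        seed=split.seed if split is not None else None,
    )


def predict(model: FittedNeedsModel, design: DesignMatrix) -> pd.Series:
    """Linear-predictor cost per person; negatives are retained (and logged).

    Flooring negative predictions would break the aggregate-conservation
    property of OLS means that the weight normalisation relies on, so they
    are kept and only counted in the log.
    """
    cols = [c for c in model.coefficients.index if c != INTERCEPT]
    missing = set(cols) - set(design.X.columns)
    if missing:
        raise ValueError(f"design lacks model columns: {sorted(missing)}")
    yhat = model.intercept + design.X[cols].to_numpy(dtype=float) @ model.coefficients[cols].to_numpy()
    n_neg = int((yhat < 0).sum())
    if n_neg:
        logger.info("%d of %d predictions are negative (retained)", n_neg, len(yhat))
    return pd.Series(yhat, index=design.X.index, name="predicted_cost")
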