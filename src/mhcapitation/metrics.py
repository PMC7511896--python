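"""Predictive-performance and redistribution statistics.

Predictive metrics compare actual and predicted cost totals across units
(GP practices or CCGs): R² as the squared Pearson correlation of unit
totals, the mean absolute prediction error in GBP, and the proportion of
units whose prediction is not within 10% of the actual total.

Redistributive metrics compare two share vectors over units (shares of
need vs shares of actual cost): the redistribution index (half the summed
absolute share differences — the budget fraction that would move between
units), the mean absolute percentage change in share, and the proportion
of units whose share changes by at least 5%.

Note on range: by its formula the redistribution index can reach 1 on
disjoint-support shares, although with non-negative shares summing to one
it is commonly described as ranging 0–0.5 (half the budget moving is the
maximum when shares overlap); the formula is implemented verbatim.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _align(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have matching units")
    return a, p


def practice_r2(actual, predicted) -> float:
    """Squared Pearson correlation between actual and predicted unit totals.

    Returns NaN when either vector has zero variance (undefined).
    """
    a, p = _align(actual, predicted)
    if len(a) < 2:
        raise ValueError("need at least 2 units")
    if np.std(a) == 0 or np.std(p) == 0:
        return float("nan")
    return float(np.corrcoef(a, p)[0, 1] ** 2)


def mean_abs_prediction_error(actual, predicted) -> float:
    """Mean over units of |actual − predicted|, in GBP."""
    a, p = _align(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def prop_outside_10pct(actual, predicted, threshold: float = 0.10) -> float:
    """Fraction of units whose prediction is not within 10% of actual.

    Strictly greater than the threshold counts as outside (a prediction at
    exactly 10% off is "within 10%"). Units with zero actual cost are
    excluded with a warning.
    """
    a, p = _align(actual, predicted)
    ok = a > 0
    if (~ok).any():
        logger.warning("excluding %d units with zero actual cost", int((~ok).sum()))
    a, p = a[ok], p[ok]
    if len(a) == 0:
        return float("nan")
    return float(np.mean(np.abs(p - a) / a > threshold))


def _validate_shares(need_share, cost_share, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    ns, cs = _align(need_share, cost_share)
    for name, s in (("need", ns), ("cost", cs)):
        if abs(s.sum() - 1.0) > tol:
            raise ValueError(f"{name} shares sum to {s.sum():.8f}, not 1")
    if (cs < 0).any():
        raise ValueError("cost shares must be non-negative")
    if (ns < 0).any():
        logger.warning("%d negative need shares (negative weights propagated)", int((ns < 0).sum()))
    return ns, cs


def shares(totals) -> np.ndarray:
    """Convert unit totals to shares of the overall total."""
    t = np.asarray(totals, dtype=float)
    s = t.sum()
    if s == 0:
        raise ValueError("cannot form shares from an all-zero total")
    return t / s


def redistribution_index(need_share, cost_share) -> float:
    """Half the sum over units of |need share − cost share|.

    The proportion of the total budget that would move from units whose
    cost share exceeds their need share to the others.
    """
    ns, cs = _validate_shares(need_share, cost_share)
    return float(0.5 * np.sum(np.abs(ns - cs)))


def mean_abs_pct_change(need_share, cost_share) -> float:
    """Mean over units of |need share − cost share| / cost share.

    Units with zero cost share are excluded with a warning. Scale-free:
    identical whether computed from shares or raw totals.
    """
    ns, cs = _validate_shares(need_share, cost_share)
    ok = cs > 0
    if (~ok).any():
        logger.warning("excluding %d units with zero cost share", int((~ok).sum()))
    if ok.sum() == 0:
        return float("nan")
    return float(np.mean(np.abs(ns[ok] - cs[ok]) / cs[ok]))


def prop_substantially_affected(need_share, cost_share, threshold: float = 0.05) -> float:
    """Fraction of units whose absolute percentage change in share is at
    least the threshold (default 5%, inclusive)."""
    ns, cs = _validate_shares(need_share, cost_share)
    ok = cs > 0
    if (~ok).any():
        logger.warning("excluding %d units with zero cost share", int((~ok).sum()))
    if ok.sum() == 0:
        return float("nan")
    return float(np.mean(np.abs(ns[ok] - cs[ok]) / cs[ok] >= threshold))


def predictive_report(actual_totals: pd.Series, predicted_totals: pd.Series) -> dict[str, float]:
    """The three predictive metrics on matched unit totals."""
    common = actual_totals.index.intersection(predicted_totals.index)
    a = actual_totals.loc[common]
    p = predicted_totals.loc[common]
    return {
        "r2": practice_r2(a, p),
        "mean_abs_prediction_error": mean_abs_prediction_error(a, p),
        "prop_outside_10pct": prop_outside_10pct(a, p),
    }


def redistribution_report(need_totals: pd.Series, cost_totals: pd.Series) -> dict[str, float]:
    """The three redistributive metrics from unit need and cost totals."""
    common = need_totals.index.intersection(cost_totals.index)
    ns = shares(need_totals.loc[common])
    cs = shares(cost_totals.loc[common])
    return {
        "redistribution_index": redistribution_index(ns, cs),
        "mean_abs_pct_change": mean_abs_pct_change(ns, cs),
        "prop_substantially_affected": prop_substantially_affected(ns, cs),
    }
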