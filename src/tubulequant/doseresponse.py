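"""Viability inhibition and log-dose sigmoidal IC50 estimation.

Inhibition is the fractional viability loss of a treated sample relative to
the untreated control, in percent.  The log-dose response is fitted with the
four-parameter logistic (4PL)

    y(c) = floor + (ceiling - floor) / (1 + 10 ** ((log10 IC50 - log10 c) * hill))

by bounded least squares from five deterministic starting points.  An IC50 is
only reported when the fit converged AND the observed maximum inhibition
exceeds 50% — a series whose top dose never reaches half-maximal inhibition
cannot anchor the midpoint, and the estimator returns an explicit failure
value instead of an extrapolated number.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .types import InsufficientDataError


class FitFailure(str, Enum):
    NONE = "none"
    MAX_INHIBITION_BELOW_50 = "max_inhibition_below_50"
    NO_CONVERGENCE = "no_convergence"


@dataclass
class DoseResponsePoint:
    """One dose: concentration (M) and inhibition (%), optionally derived
    from raw viability readouts."""

    concentration: float
    inhibition: float
    viability_treated: Optional[float] = None
    viability_untreated: Optional[float] = None

    @classmethod
    def from_viability(
        cls, concentration: float, treated: float, untreated: float
    ) -> "DoseResponsePoint":
        return cls(
            concentration=concentration,
            inhibition=inhibition(treated, untreated),
            viability_treated=treated,
            viability_untreated=untreated,
        )


@dataclass
class SigmoidFit:
    """4PL fit result; ``ic50`` is populated only for an honest convergence."""

    ic50: Optional[float]
    hill_slope: float
    floor: float
    ceiling: float
    converged: bool
    failure_reason: FitFailure = FitFailure.NONE
    residual_rms: float = float("nan")


@dataclass
class Ic50Failure:
    """Failure value returned instead of an IC50 (not an exception)."""

    reason: FitFailure

    def __bool__(self) -> bool:  # truthiness mirrors "got a number"
        return False


def inhibition(viability_treated: float, viability_untreated: float) -> float:
    """Percent inhibition: (untreated - treated) / untreated * 100.

    Negative values indicate growth stimulation.  Scale-invariant in the
    viability units.
    """
    if not viability_untreated > 0:
        raise ValueError("untreated viability must be positive")
    return (viability_untreated - viability_treated) / viability_untreated * 100.0


def four_param_logistic(
    c: np.ndarray, log10_ic50: float, hill: float, floor: float, ceiling: float
) -> np.ndarray:
    """4PL response in percent at concentrations ``c`` (M)."""
    c = np.asarray(c, dtype=float)
    return floor + (ceiling - floor) / (1.0 + 10.0 ** ((log10_ic50 - np.log10(c)) * hill))


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        c = points["concentration_M"].to_numpy(dtype=float)
        y = points["inhibition_pct"].to_numpy(dtype=float)
    else:
        c = np.array([p.concentration for p in points], dtype=float)
        y = np.array([p.inhibition for p in points], dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    return c, y


def fit_sigmoid(
    points: Union[Sequence[DoseResponsePoint], pd.DataFrame],
    constrain_0_100: bool = False,
    allow_negative_hill: bool = False,
) -> SigmoidFit:
    """Least-squares 4PL fit of an inhibition series in log10 concentration.

    Requires at least four distinct concentrations.  Five deterministic
    starts seed the midpoint at quantiles of the tested log-concentration
    range; the best bounded solution wins.  ``constrain_0_100`` pins the
    floor/ceiling at 0 and 100%; otherwise they are free within [-20, 120]%.
    A non-negative Hill slope is enforced by default so the fitted curve is
    monotone in concentration.
    """
    c, y = _as_arrays(points)
    if len(np.unique(c)) < 4:
        raise InsufficientDataError(
            "at least 4 distinct concentrations are required for a 4PL fit"
        )
    logc = np.log10(c)

    if constrain_0_100:
        lo_f, hi_f, lo_c, hi_c = -1e-9, 1e-9, 100.0 - 1e-9, 100.0 + 1e-9
    else:
        lo_f, hi_f, lo_c, hi_c = -20.0, 120.0, -20.0, 120.0
    hill_lo = -10.0 if allow_negative_hill else 0.0
    lower = np.array([logc.min() - 3.0, hill_lo, lo_f, lo_c])
    upper = np.array([logc.max() + 3.0, 10.0, hi_f, hi_c])

    y_lo = float(np.clip(y.min(), lo_f, hi_f)) if not constrain_0_100 else 0.0
    y_hi = float(np.clip(y.max(), lo_c, hi_c)) if not constrain_0_100 else 100.0

    def resid(theta: np.ndarray) -> np.ndarray:
        return four_param_logistic(c, *theta) - y

    best = None
    for q in (0.1, 0.3, 0.5, 0.7, 0.9):
        x0 = np.array([np.quantile(logc, q), 1.0, y_lo, y_hi])
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(resid, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return SigmoidFit(
            ic50=None, hill_slope=float("nan"), floor=float("nan"),
            ceiling=float("nan"), converged=False,
            failure_reason=FitFailure.NO_CONVERGENCE,
        )
    log_ic50, hill, flr, ceil = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return SigmoidFit(
        ic50=float(10.0**log_ic50),
        hill_slope=float(hill),
        floor=float(flr),
        ceiling=float(ceil),
        converged=True,
        failure_reason=FitFailure.NONE,
        residual_rms=rms,
    )


def estimate_ic50(
    fit: SigmoidFit, points: Union[Sequence[DoseResponsePoint], pd.DataFrame]
) -> Union[float, Ic50Failure]:
    """Final IC50 decision with the assay's fit-failure behaviour.

    The IC50 is returned only when the fit converged and the maximum observed
    inhibition strictly exceeds 50%.  Otherwise an ``Ic50Failure`` value is
    returned, mirroring how the sigmoid fit of a weak inhibitor is
    interrupted when the top dose never reaches half-maximal inhibition.
    """
    if not fit.converged or fit.ic50 is None:
        return Ic50Failure(FitFailure.NO_CONVERGENCE)
    _c, y = _as_arrays(points)
    if not float(np.max(y)) > 50.0:
        return Ic50Failure(FitFailure.MAX_INHIBITION_BELOW_50)
    return float(fit.ic50)


def fit_dose_table(
    table: pd.DataFrame, constrain_0_100: bool = False
) -> pd.DataFrame:
    """Fit one 4PL per condition in a tidy dose table.

    Expects columns ``concentration_M`` and ``inhibition_pct`` (viability
    pairs are converted on read; see :func:`tubulequant.io.read_dose_table`);
    an optional ``condition`` column splits the fits.  Returns one row per
    condition with the fitted parameters, the IC50 decision and its failure
    reason.
    """
    df = table.copy()
    if "condition" not in df.columns:
        df["condition"] = ""
    rows = []
    for cond, sub in df.groupby("condition", sort=True):
        try:
            fit = fit_sigmoid(sub, constrain_0_100=constrain_0_100)
        except InsufficientDataError:
            rows.append(
                {"condition": cond, "ic50_M": None, "hill_slope": None,
                 "floor_pct": None, "ceiling_pct": None, "converged": False,
                 "failure_reason": FitFailure.NO_CONVERGENCE.value}
            )
            continue
        result = estimate_ic50(fit, sub)
        failed = isinstance(result, Ic50Failure)
        rows.append(
            {
                "condition": cond,
                "ic50_M": None if failed else result,
                "hill_slope": fit.hill_slope,
                "floor_pct": fit.floor,
                "ceiling_pct": fit.ceiling,
                "converged": fit.converged,
                "failure_reason": (result.reason.value if failed else FitFailure.NONE.value),
            }
        )
    return pd.DataFrame(rows)
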