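"""Internal-standard response modeling.

Quantitation is ratio-based: for each calibration level the response ratio
y = A_s / A_is (analyte over internal-standard peak area) is regressed on
the nominal concentration x with weighted least squares.  The default model
is a weighted quadratic with 1/x^2 weights, appropriate for detector noise
with constant coefficient of variation, and wide (500-fold) calibration
ranges where the response saturates at high load.

Quality metrics follow common bioanalytical practice:

* r^2 on the weighted sums of squares (matching the fitting objective;
  the unweighted r^2 is also computed and carried along),
* %RSE = 100 * sqrt( sum_i ((x_i' - x_i)/x_i)^2 / (n - p) ), where x_i'
  is the back-calculated concentration of level i and p counts model terms
  (2 linear, 3 quadratic),
* per-level recovery = 100 * x_i' / x_i,
* RRF = (A_s * C_is) / (A_is * C_s), the relative response factor used to
  judge internal-standard suitability (minimum 0.01, ideal 1).

Inverse prediction solves the fitted model for concentration on its
increasing branch; out-of-range responses raise signals rather than
returning silent numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    ArgumentError,
    BelowRangeSignal,
    EmptyRangeError,
    FitError,
    OverRangeSignal,
)

Model = Literal["linear", "quadratic"]
Weighting = Literal["1/x^2", "1/x", "none"]

P_TERMS = {"linear": 2, "quadratic": 3}


@dataclass
class CalibrationPoint:
    """One calibration level: nominal concentration and measured ratio."""

    level_conc: float
    response_ratio: float
    weight: float | None = None
    included: bool = True

    def __post_init__(self):
        if self.level_conc <= 0:
            raise ArgumentError("calibration level concentration must be positive")
        if self.response_ratio < 0:
            raise ArgumentError("response ratio must be nonnegative")
        if self.weight is not None and self.weight <= 0:
            raise ArgumentError("weight must be positive")


@dataclass
class CalibrationFit:
    """A fitted concentration-response model and its quality metrics."""

    analyte_name: str
    model: Model
    coefficients: tuple[float, ...]  # (a, b) or (a, b, c)
    r2: float
    r2_unweighted: float
    rse_percent: float
    points: list[CalibrationPoint]
    p_terms: int
    weighting: Weighting
    recoveries: list[tuple[float, float]] = field(default_factory=list)

    @property
    def a(self) -> float:
        return self.coefficients[0]

    @property
    def b(self) -> float:
        return self.coefficients[1]

    @property
    def c(self) -> float:
        return self.coefficients[2] if len(self.coefficients) > 2 else 0.0

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        """Forward model: expected response ratio at concentration x."""
        return self.a + self.b * np.asarray(x, dtype=float) + self.c * np.asarray(x, dtype=float) ** 2

    @property
    def top_level(self) -> float:
        return max(p.level_conc for p in self.points if p.included)

    @property
    def bottom_level(self) -> float:
        return min(p.level_conc for p in self.points if p.included)

    @property
    def levels(self) -> list[float]:
        return sorted({p.level_conc for p in self.points if p.included})


def relative_response_factor(
    area_s: float, area_is: float, conc_s: float, conc_is: float
) -> float:
    """RRF = (A_s * C_is) / (A_is * C_s)."""
    if area_is <= 0:
        raise ArgumentError("internal-standard area must be positive")
    if conc_s <= 0 or conc_is <= 0:
        raise ArgumentError("concentrations must be positive")
    if area_s < 0:
        raise ArgumentError("analyte area must be nonnegative")
    return (area_s * conc_is) / (area_is * conc_s)


def _weights_for(points: Sequence[CalibrationPoint], weighting: Weighting) -> np.ndarray:
    x = np.array([p.level_conc for p in points])
    explicit = np.array([np.nan if p.weight is None else p.weight for p in points])
    if weighting == "1/x^2":
        w = 1.0 / x**2
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ArgumentError(f"unknown weighting {weighting!r}")
    return np.where(np.isnan(explicit), w, explicit)


def fit_calibration(
    points: Iterable[CalibrationPoint],
    model: Model = "quadratic",
    weighting: Weighting = "1/x^2",
    analyte_name: str = "",
) -> CalibrationFit:
    """Weighted least-squares fit of response ratio on concentration.

    Requires at least ``p_terms + 1`` included points with distinct
    concentrations.  Back-calculated recoveries and %RSE are filled in by
    inverse-predicting every included point against the fitted curve.
    """
    points = list(points)
    if model not in P_TERMS:
        raise ArgumentError(f"unknown model {model!r}")
    p_terms = P_TERMS[model]
    used = [p for p in points if p.included]
    if len({p.level_conc for p in used}) < p_terms + 1:
        raise FitError(
            f"{analyte_name or 'fit'}: need at least {p_terms + 1} distinct "
            f"included levels for a {model} model"
        )
    x = np.array([p.level_conc for p in used])
    y = np.array([p.response_ratio for p in used])
    w = _weights_for(used, weighting)

    cols = [np.ones_like(x), x] + ([x**2] if model == "quadratic" else [])
    X = np.column_stack(cols)
    res = sm.WLS(y, X, weights=w).fit()
    coef = tuple(float(v) for v in res.params)

    yhat = X @ np.asarray(coef)
    ybar_w = float(np.sum(w * y) / np.sum(w))
    sstot_w = float(np.sum(w * (y - ybar_w) ** 2))
    ssres_w = float(np.sum(w * (y - yhat) ** 2))
    r2 = 1.0 - ssres_w / sstot_w if sstot_w > 0 else 1.0
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2_plain = 1.0 - float(np.sum((y - yhat) ** 2)) / sstot if sstot > 0 else 1.0

    # keep the caller's weight bookkeeping on the returned points
    out_points = [replace(p, weight=float(wi)) for p, wi in zip(used, w)]
    out_points += [replace(p) for p in points if not p.included]

    fit = CalibrationFit(
        analyte_name=analyte_name,
        model=model,
        coefficients=coef,
        r2=r2,
        r2_unweighted=r2_plain,
        rse_percent=float("nan"),
        points=out_points,
        p_terms=p_terms,
        weighting=weighting,
    )
    fit.recoveries = _back_calculate(fit)
    fit.rse_percent = calibration_rse(fit)
    return fit


def _invert(fit: CalibrationFit, y: float) -> float:
    """Raw inverse of the fitted curve on its increasing branch (may be < 0)."""
    a, b, c = fit.a, fit.b, fit.c
    if abs(c) < 1e-14 * max(1.0, abs(b)):
        if b == 0:
            raise FitError(f"{fit.analyte_name}: degenerate flat calibration curve")
        return (y - a) / b
    disc = b * b - 4.0 * c * (a - y)
    if disc < 0:
        raise OverRangeSignal(
            f"{fit.analyte_name}: response {y:g} above the calibration curve maximum",
            estimate=None,
        )
    # (-b + sqrt(disc)) / (2c) is the increasing-branch root for either sign of c
    return (-b + math.sqrt(disc)) / (2.0 * c)


def _back_calculate(fit: CalibrationFit) -> list[tuple[float, float]]:
    recs = []
    for p in fit.points:
        if not p.included:
            continue
        try:
            xprime = _invert(fit, p.response_ratio)
        except OverRangeSignal:
            xprime = float("nan")
        recs.append((p.level_conc, 100.0 * xprime / p.level_conc))
    return recs


def calibration_rse(fit: CalibrationFit) -> float:
    """%RSE = 100 * sqrt( sum_i ((x_i' - x_i)/x_i)^2 / (n - p) ).

    x_i' is the back-calculated concentration of included level i; levels
    whose back-calculation failed (saturated response) are skipped.
    """
    rel_sq = [
        ((rec / 100.0) - 1.0) ** 2 for _, rec in fit.recoveries if math.isfinite(rec)
    ]
    n = len(rel_sq)
    if n <= fit.p_terms:
        raise FitError(
            f"{fit.analyte_name}: RSE undefined with n={n} points and p={fit.p_terms} terms"
        )
    return 100.0 * math.sqrt(sum(rel_sq) / (n - fit.p_terms))


def inverse_predict(
    fit: CalibrationFit,
    response_ratio: float,
    uloq: float | None = None,
    range_slack: float = 1.2,
) -> float:
    """Concentration whose fitted response equals *response_ratio*.

    Linear model: x = (y - a) / b.  Quadratic: the real root on the
    increasing branch of the parabola.  Results below zero raise
    :class:`BelowRangeSignal` (a BLOQ indication); results beyond
    ``range_slack * uloq`` (or a response above the curve maximum) raise
    :class:`OverRangeSignal` carrying the estimate when one exists.
    """
    if response_ratio < 0:
        raise ArgumentError("response ratio must be nonnegative")
    xprime = _invert(fit, response_ratio)
    if xprime < 0:
        raise BelowRangeSignal(xprime)
    top = uloq if uloq is not None else fit.top_level
    if xprime > range_slack * top:
        raise OverRangeSignal(
            f"{fit.analyte_name}: back-calculated {xprime:g} mg/ml exceeds "
            f"{range_slack:g} x ULOQ ({top:g} mg/ml)",
            estimate=xprime,
        )
    return xprime


def blank_concentration(fit: CalibrationFit, response_ratio: float) -> float:
    """Apparent concentration in a blank, via the curve's low-end tangent.

    Blanks sit below the admissible range by construction, so the quadratic
    term is irrelevant; the linear low-end extrapolation x = (y - a)/b is
    used and negative results clamp to zero.
    """
    if fit.b == 0:
        raise FitError(f"{fit.analyte_name}: flat curve, blank inversion undefined")
    return max(0.0, (response_ratio - fit.a) / fit.b)


@dataclass
class WorkingRange:
    """Outcome of working-range determination across batches."""

    lloq: float
    uloq: float
    level_table: list[dict]  # per level: mean recovery, cv, pass flags


def _evaluate_levels(
    per_batch_fits: Sequence[CalibrationFit], acceptance: float
) -> tuple[list[dict], list[float]]:
    by_level: dict[float, list[float]] = {}
    for fit in per_batch_fits:
        for level, rec in fit.recoveries:
            by_level.setdefault(round(level, 6), []).append(rec)
    table, passing = [], []
    for level in sorted(by_level):
        recs = np.array(by_level[level], dtype=float)
        finite = recs[np.isfinite(recs)]
        saturated = len(finite) < len(recs)
        if len(finite) >= 2:
            mean = float(finite.mean())
            cv = float(finite.std(ddof=1) / abs(mean) * 100) if mean != 0 else float("inf")
        elif len(finite) == 1:
            mean, cv = float(finite[0]), float("nan")
        else:
            mean, cv = float("nan"), float("nan")
        ok_mean = math.isfinite(mean) and abs(mean - 100.0) <= acceptance
        ok_cv = math.isfinite(cv) and cv <= acceptance
        ok = ok_mean and ok_cv and not saturated
        table.append(
            dict(level=level, mean_recovery=mean, cv_recovery=cv, passed=ok, saturated=saturated)
        )
        if ok:
            passing.append(level)
    return table, passing


def determine_working_range(
    per_batch_fits: Sequence[CalibrationFit], acceptance: float = 20.0
) -> WorkingRange:
    """Lowest/highest levels whose cross-batch recovery passes acceptance.

    A level passes when its average back-calculated recovery across batches
    is within 100 +/- acceptance and the CV of those recoveries is at most
    *acceptance*; saturated (non-invertible) responses count as failures.

    Detector saturation at the top of the series distorts a single
    polynomial fit well below the saturated level, so the determination is
    iterative: while the highest remaining level fails its recovery gates,
    that level is excluded and every batch refit on the truncated series
    (the working range ends "before detector saturation").
    """
    if len(per_batch_fits) < 2:
        raise ArgumentError("working-range determination needs at least two batches")
    fits = list(per_batch_fits)
    while True:
        table, passing = _evaluate_levels(fits, acceptance)
        if not passing:
            raise EmptyRangeError("no calibration level met the working-range criteria")
        top = table[-1]["level"]
        if table[-1]["passed"]:
            return WorkingRange(lloq=min(passing), uloq=max(passing), level_table=table)
        try:
            fits = [
                fit_calibration(
                    [
                        replace(p, included=p.included and round(p.level_conc, 6) != top)
                        for p in f.points
                    ],
                    model=f.model,
                    weighting=f.weighting,
                    analyte_name=f.analyte_name,
                )
                for f in fits
            ]
        except FitError:
            # cannot truncate further; report the evaluation as it stands
            return WorkingRange(lloq=min(passing), uloq=max(passing), level_table=table)


def fit_summary_frame(fits: Sequence[CalibrationFit]):
    """Tabulate fits for delimited-text export (one row per analyte fit)."""
    import pandas as pd

    rows = []
    for f in fits:
        row = {
            "analyte": f.analyte_name,
            "model": f.model,
            "a": f.a,
            "b": f.b,
            "c": f.c if f.model == "quadratic" else float("nan"),
            "r2": f.r2,
            "r2_unweighted": f.r2_unweighted,
            "rse_percent": f.rse_percent,
        }
        for level, rec in f.recoveries:
            row[f"recovery_{level:g}"] = rec
        rows.append(row)
    return pd.DataFrame(rows)
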