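"""Method-validation battery (SWGTOX-style).

Covers accuracy (%Bias) and precision (%CV) of fortified-matrix samples
within and across batches, LLOQ determination with carryover escalation,
dilution integrity, one-month stability, between-calibration drift inside
an acquisition batch, and a linear-versus-quadratic model comparison.

Acceptance conventions: |%Bias| and %CV within +/-20% (inclusive),
carryover below 5% of the reported LLOQ, stability recovery within
80-120%, |drift| within 20%.  All limits are arguments, with these
defaults.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationFit,
    CalibrationPoint,
    blank_concentration,
    fit_calibration,
)
from .errors import ArgumentError

Scope = Literal["intra_day", "inter_day"]


@dataclass
class RecoveryStats:
    """Mean/SD/%CV/%Bias of replicate measurements at one nominal level."""

    analyte_name: str
    nominal: float
    scope: Scope
    n: int
    mean: float
    sd: float
    cv_percent: float
    bias_percent: float
    batch_id: str | None = None  # intra-day only

    @property
    def passes(self) -> bool:
        return self.passes_at(20.0)

    def passes_at(self, acceptance: float) -> bool:
        ok_bias = abs(self.bias_percent) <= acceptance
        ok_cv = (not math.isfinite(self.cv_percent)) or self.cv_percent <= acceptance
        return ok_bias and ok_cv


@dataclass
class LloqDecision:
    """Outcome of the carryover-driven LLOQ escalation for one analyte."""

    analyte_name: str
    candidate_lloq: float
    final_lloq: float
    carryover_conc: float  # mg/ml apparent in the worst blank
    carryover_fraction_at_lloq: float  # % of the final LLOQ
    escalated: bool
    trail: list[tuple[float, bool, bool, bool]] = field(default_factory=list)
    # trail rows: (level, passed_recovery, passed_cv, carryover_ok)


@dataclass
class DriftRecord:
    """Signed % change of one standard between bracketing calibrations."""

    analyte_name: str
    level_conc: float
    first_conc: float
    second_conc: float
    drift_percent: float


def percent_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD over mean, x 100."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ArgumentError("CV needs at least two values")
    mean = vals.mean()
    if mean <= 0:
        raise ArgumentError("CV undefined for non-positive mean")
    return float(vals.std(ddof=1) / mean * 100.0)


def percent_bias(measured: Sequence[float], expected: float) -> float:
    """%Bias = (mean(measured) - expected) / expected x 100."""
    if expected <= 0:
        raise ArgumentError("expected concentration must be positive")
    return float((np.mean(measured) - expected) / expected * 100.0)


def percent_drift(first_conc: float, second_conc: float) -> float:
    """Signed drift of the closing calibration against the opening one."""
    if first_conc <= 0:
        raise ArgumentError("reference (opening) concentration must be positive")
    return (second_conc - first_conc) / first_conc * 100.0


def stability_check(recovery_percent: float, window: tuple[float, float] = (80.0, 120.0)) -> bool:
    """Pass iff recovery after storage lies within the window (inclusive)."""
    if recovery_percent < 0:
        raise ArgumentError("recovery must be nonnegative")
    return window[0] <= recovery_percent <= window[1]


def recovery_battery(
    measurements: pd.DataFrame, acceptance: float = 20.0
) -> list[RecoveryStats]:
    """Intra- and inter-day accuracy/precision of replicate measurements.

    *measurements* is tidy with columns ``batch_id, analyte, nominal,
    measured``.  Intra-day statistics are computed per (batch, analyte,
    level); inter-day statistics pool the per-batch means at each level.
    Single-replicate cells are excluded from CV with a warning.
    """
    required = {"batch_id", "analyte", "nominal", "measured"}
    if not required.issubset(measurements.columns):
        raise ArgumentError(f"measurements must have columns {sorted(required)}")
    stats: list[RecoveryStats] = []
    df = measurements.dropna(subset=["measured"])
    for (batch, analyte, nominal), grp in df.groupby(["batch_id", "analyte", "nominal"]):
        vals = grp["measured"].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"{analyte} {nominal} mg/ml in batch {batch}: single replicate, CV skipped",
                stacklevel=2,
            )
            cv = float("nan")
            sd = float("nan")
        else:
            sd = float(np.std(vals, ddof=1))
            # a non-positive mean (wildly noisy back-calculations) leaves the
            # CV undefined; the bias statistic still reports the failure
            cv = percent_cv(vals) if vals.mean() > 0 else float("nan")
        stats.append(
            RecoveryStats(
                analyte_name=str(analyte),
                nominal=float(nominal),
                scope="intra_day",
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
                cv_percent=cv,
                bias_percent=percent_bias(vals, float(nominal)),
                batch_id=str(batch),
            )
        )
    # inter-day: pool batch means per level
    means = (
        df.groupby(["analyte", "nominal", "batch_id"])["measured"].mean().reset_index()
    )
    for (analyte, nominal), grp in means.groupby(["analyte", "nominal"]):
        vals = grp["measured"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
        cv = percent_cv(vals) if len(vals) >= 2 and vals.mean() > 0 else float("nan")
        stats.append(
            RecoveryStats(
                analyte_name=str(analyte),
                nominal=float(nominal),
                scope="inter_day",
                n=len(vals),
                mean=float(vals.mean()),
                sd=sd,
                cv_percent=cv,
                bias_percent=percent_bias(vals, float(nominal)),
            )
        )
    return stats


def recovery_frame(stats: Iterable[RecoveryStats], acceptance: float = 20.0) -> pd.DataFrame:
    rows = []
    for s in stats:
        rows.append(
            {
                "analyte": s.analyte_name,
                "nominal": s.nominal,
                "scope": s.scope,
                "batch_id": s.batch_id,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "cv_percent": s.cv_percent,
                "bias_percent": s.bias_percent,
                "passed": s.passes_at(acceptance),
            }
        )
    return pd.DataFrame(rows)


def assess_carryover(
    fit: CalibrationFit,
    blank_ratios: Sequence[float],
    candidate_lloq: float,
    levels: Sequence[float] | None = None,
    limit_percent: float = 5.0,
    level_gates: Mapping[float, tuple[bool, bool]] | None = None,
) -> LloqDecision:
    """Carryover fraction in post-top-standard blanks, with LLOQ escalation.

    The apparent blank concentration is inverse-predicted via the curve's
    low-end tangent (blanks sit below the quantifiable range); the worst
    blank governs.  If carryover exceeds ``limit_percent`` of the candidate
    LLOQ, the LLOQ is raised level-by-level up the calibration series until
    the fraction is within the limit, recording the decision trail.

    ``level_gates`` optionally maps each level to its (recovery, CV) pass
    flags from working-range determination; levels failing either gate are
    skipped during escalation.
    """
    if candidate_lloq <= 0:
        raise ArgumentError("candidate LLOQ must be positive")
    if not blank_ratios:
        carry = 0.0
    else:
        carry = max(blank_concentration(fit, r) for r in blank_ratios)
    series = sorted(levels) if levels is not None else fit.levels
    gates = level_gates or {}

    def gate(level: float) -> tuple[bool, bool]:
        return gates.get(level, gates.get(round(level, 6), (True, True)))

    tol = limit_percent * 1e-9  # boundary is inclusive; forgive float dust
    trail: list[tuple[float, bool, bool, bool]] = []
    final = candidate_lloq
    fraction = carry / candidate_lloq * 100.0
    ok_rec, ok_cv = gate(candidate_lloq)
    trail.append((candidate_lloq, ok_rec, ok_cv, fraction <= limit_percent + tol))
    if fraction > limit_percent + tol or not (ok_rec and ok_cv):
        for level in series:
            if level <= candidate_lloq:
                continue
            frac = carry / level * 100.0
            ok_rec, ok_cv = gate(level)
            ok = frac <= limit_percent + tol and ok_rec and ok_cv
            trail.append((level, ok_rec, ok_cv, frac <= limit_percent + tol))
            final = level
            fraction = frac
            if ok:
                break
    return LloqDecision(
        analyte_name=fit.analyte_name,
        candidate_lloq=candidate_lloq,
        final_lloq=final,
        carryover_conc=carry,
        carryover_fraction_at_lloq=fraction,
        escalated=final > candidate_lloq,
        trail=trail,
    )


def dilution_integrity(
    measurements: pd.DataFrame,
    working_ranges: Mapping[str, tuple[float, float]],
    acceptance: float = 20.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Recovery of concentrated samples measured after dilution.

    *measurements* columns: ``analyte, source_conc, factor, measured`` with
    ``measured`` already corrected back to the undiluted sample.  Each
    (analyte, source, factor) cell whose diluted target falls outside the
    analyte's working range is excluded (or raises, when ``strict``).
    """
    from .errors import ConfigError

    required = {"analyte", "source_conc", "factor", "measured"}
    if not required.issubset(measurements.columns):
        raise ArgumentError(f"measurements must have columns {sorted(required)}")
    rows = []
    for (analyte, source, factor), grp in measurements.groupby(
        ["analyte", "source_conc", "factor"]
    ):
        lloq, uloq = working_ranges[str(analyte)]
        target = float(source) / float(factor)
        in_range = lloq <= target <= uloq
        if not in_range and strict:
            raise ConfigError(
                f"{analyte}: diluted target {target:g} mg/ml (factor {factor:g}) "
                f"outside working range [{lloq:g}, {uloq:g}]"
            )
        raw = grp["measured"].to_numpy(dtype=float)
        vals = raw[np.isfinite(raw)]  # over-top responses are unquantifiable
        n_excluded = len(raw) - len(vals)
        rows.append(
            {
                "analyte": analyte,
                "source_conc": float(source),
                "factor": float(factor),
                "target_conc": target,
                "in_range": in_range,
                "n": len(vals),
                "n_excluded": n_excluded,
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "cv_percent": percent_cv(vals) if len(vals) >= 2 else float("nan"),
                "bias_percent": percent_bias(vals, float(source))
                if len(vals) else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        # a cell fails if accuracy/precision miss, or if more than 20% of its
        # replicates could not be quantified at all
        quantifiable = out["n"] >= 0.8 * (out["n"] + out["n_excluded"])
        out["passed"] = (
            out["in_range"]
            & quantifiable
            & (out["bias_percent"].abs() <= acceptance)
            & (out["cv_percent"].fillna(0.0) <= acceptance)
        )
    return out


def calibration_drift(
    pooled_fit: CalibrationFit,
    first_points: Sequence[CalibrationPoint],
    second_points: Sequence[CalibrationPoint],
) -> list[DriftRecord]:
    """Per-level drift between the opening and closing calibration sets.

    Both sets are back-calculated against the batch's pooled fit; the
    opening set is the reference.
    """
    from .calibration import _invert  # low-level root solve, range-unchecked

    first = {round(p.level_conc, 6): p for p in first_points}
    second = {round(p.level_conc, 6): p for p in second_points}
    records = []
    for level in sorted(set(first) & set(second)):
        try:
            c1 = _invert(pooled_fit, first[level].response_ratio)
            c2 = _invert(pooled_fit, second[level].response_ratio)
        except Exception:
            continue
        if c1 <= 0:
            continue
        records.append(
            DriftRecord(
                analyte_name=pooled_fit.analyte_name,
                level_conc=level,
                first_conc=c1,
                second_conc=c2,
                drift_percent=percent_drift(c1, c2),
            )
        )
    return records


def model_comparison(
    points_by_analyte: Mapping[str, Sequence[CalibrationPoint]],
    weighting: str = "1/x^2",
    r2_threshold: float = 0.990,
) -> pd.DataFrame:
    """Refit every analyte with linear and quadratic models, side by side.

    Reports both r^2 values, both %RSE values, the largest absolute
    per-level recovery difference between the models, and a flag for
    analytes whose linear r^2 falls below *r2_threshold* (the saturating
    chemicals for which the quadratic model is genuinely needed).
    """
    rows = []
    for analyte, pts in points_by_analyte.items():
        quad = fit_calibration(pts, model="quadratic", weighting=weighting, analyte_name=analyte)
        lin = fit_calibration(pts, model="linear", weighting=weighting, analyte_name=analyte)
        rec_q = dict(quad.recoveries)
        rec_l = dict(lin.recoveries)
        deltas = [
            abs(rec_l[lv] - rec_q[lv])
            for lv in rec_q
            if lv in rec_l and math.isfinite(rec_l[lv]) and math.isfinite(rec_q[lv])
        ]
        rows.append(
            {
                "analyte": analyte,
                "r2_linear": lin.r2,
                "r2_quadratic": quad.r2,
                "rse_linear": lin.rse_percent,
                "rse_quadratic": quad.rse_percent,
                "max_recovery_delta": max(deltas) if deltas else float("nan"),
                "linear_adequate": lin.r2 >= r2_threshold,
            }
        )
    return pd.DataFrame(rows)
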