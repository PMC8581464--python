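"""Production quantitation: batch assembly, measurement, summaries.

An acquisition batch carries bracketing calibration sets (one injected
before the unknowns, one after); both sets pool into a single calibration
fit per analyte, while the per-set fits feed the drift table.  Unknowns
are measured by inverse prediction of the analyte/IS area ratio, scaled
by any dilution factor, and flagged: ``ok``, ``bloq`` (below the working
LLOQ), ``estimated_below_range`` (quantifiable but under the working
LLOQ), ``over_range`` (above the ULOQ, with a suggested re-run dilution)
or ``invalid`` (no internal-standard peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationFit,
    CalibrationPoint,
    fit_calibration,
    inverse_predict,
)
from .errors import (
    ArgumentError,
    BelowRangeSignal,
    ConfigError,
    OverRangeSignal,
)
from .io import decode_nominal
from .panel import Panel
from .validation import DriftRecord, calibration_drift

Flag = Literal["ok", "bloq", "estimated_below_range", "over_range", "invalid"]

ALLOWED_DILUTION_FACTORS = (2, 5, 10, 20, 50)


@dataclass
class MeasuredConcentration:
    """One (sample, analyte) quantitation result on the undiluted basis."""

    sample_id: str
    analyte_name: str
    value: float | None
    flag: Flag
    dilution_factor: float = 1.0
    is_recovery: float = float("nan")  # % of the batch's typical IS response
    suggested_factor: float | None = None
    reason: str | None = None


@dataclass
class DilutionPlan:
    """Volumetric dilution arithmetic for the sample-preparation step."""

    total_factor: float
    is_final_conc: float  # mg/ml in the injected aliquot
    is_conc_deviation_percent: float
    flagged: bool


def prepare_dilution_plan(
    aliquot_volume_ul: float = 30.0,
    is_volume_ul: float = 30.0,
    solvent_volume_ul: float = 3000.0,
    is_stock_conc: float = 1.0,
    reference_is_conc: float | None = None,
) -> DilutionPlan:
    """Volumetric dilution factor and final IS concentration of an aliquot.

    The standard preparation (30 uL sample + 30 uL IS + 3 ml methanol)
    gives a volumetric factor of 102 - the scheme's nominal label is
    "100-fold", and since calibrators share the identical preparation the
    2% discrepancy cancels in ratio-based quantitation.  The plan flags IS
    concentrations deviating more than +/-20% from the reference
    preparation (IS volumes must track total-volume changes).
    """
    if min(aliquot_volume_ul, is_volume_ul, solvent_volume_ul) <= 0:
        raise ArgumentError("all volumes must be positive")
    total = aliquot_volume_ul + is_volume_ul + solvent_volume_ul
    factor = total / aliquot_volume_ul
    is_conc = is_stock_conc * is_volume_ul / total
    if reference_is_conc is None:
        reference_is_conc = is_stock_conc * 30.0 / 3060.0
    deviation = (is_conc - reference_is_conc) / reference_is_conc * 100.0
    return DilutionPlan(
        total_factor=factor,
        is_final_conc=is_conc,
        is_conc_deviation_percent=deviation,
        flagged=abs(deviation) > 20.0,
    )


def suggest_dilution(
    over_range_estimate: float,
    working_range: tuple[float, float],
    target: float = 1.0,
    factors: Sequence[int] = ALLOWED_DILUTION_FACTORS,
) -> int:
    """Pick the re-run dilution factor for an over-range liquid.

    Among the allowed factors whose resulting concentration lands inside
    the working range, choose the one nearest *target* on a log scale
    (exact ties go to the smaller factor).  Raises
    :class:`OverRangeSignal` when even the largest factor cannot bring the
    estimate into range.
    """
    lloq, uloq = working_range
    if over_range_estimate <= uloq:
        return 1  # already in range: no dilution
    candidates = [f for f in factors if lloq <= over_range_estimate / f <= uloq]
    if not candidates:
        raise OverRangeSignal(
            f"estimate {over_range_estimate:g} mg/ml not reachable with factors {tuple(factors)}",
            estimate=over_range_estimate,
        )
    return min(candidates, key=lambda f: (abs(math.log(over_range_estimate / f / target)), f))


@dataclass
class BatchResult:
    """Assembled batch: pooled fits, per-set fits, QC table, drift, flags."""

    batch_id: str
    fits: dict[str, CalibrationFit]
    first_set_points: dict[str, list[CalibrationPoint]]
    second_set_points: dict[str, list[CalibrationPoint]]
    qc_recoveries: pd.DataFrame
    drift: list[DriftRecord]
    is_reference_area: float
    rejected: bool = False
    warnings: list[str] = field(default_factory=list)


def _area_lookup(peaks: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {
        (str(r.sample_id), str(r.analyte)): float(r.area)
        for r in peaks.itertuples(index=False)
    }


def _ratio(areas, sample_id: str, analyte: str, is_name: str) -> float | None:
    a = areas.get((sample_id, analyte))
    i = areas.get((sample_id, is_name))
    if a is None or i is None or i <= 0:
        return None
    return a / i


def assemble_batch(
    manifest: pd.DataFrame,
    peaks: pd.DataFrame,
    panel: Panel,
    model: str = "quadratic",
    weighting: str = "1/x^2",
    acceptance: float = 20.0,
    restrict_to_working_range: bool = False,
    reject_on_qc_failure: bool = False,
) -> BatchResult:
    """Fit pooled bracketing calibrations and check QC recoveries.

    The calibrators are split into opening/closing sets by injection
    order (first half versus second half).  A missing closing set degrades
    to a single-set fit with a warning.  QC samples inside each analyte's
    working range must recover within +/-acceptance; failures flag the
    batch (and reject it when ``reject_on_qc_failure``).
    """
    batch_ids = manifest["batch_id"].unique()
    if len(batch_ids) != 1:
        raise ConfigError(f"assemble_batch expects one batch, got {list(batch_ids)}")
    batch_id = str(batch_ids[0])
    warnings_list: list[str] = []
    areas = _area_lookup(peaks)

    cal = manifest[manifest["role"] == "calibrator"].sort_values("injection_order")
    if cal.empty:
        raise ConfigError(f"batch {batch_id}: no calibrators present")
    n_cal = len(cal)
    n_levels = len(
        {
            lv
            for nom in cal["nominal"]
            for lv in decode_nominal(nom).values()
        }
    )
    first_ids = list(cal["sample_id"].iloc[: n_cal // 2])
    second_ids = list(cal["sample_id"].iloc[n_cal // 2 :])
    if n_cal < 2 * n_levels:
        warnings_list.append(f"batch {batch_id}: missing bracketing set, single-set fit")
        first_ids, second_ids = list(cal["sample_id"]), []

    nominal_by_sample = {
        str(r.sample_id): decode_nominal(r.nominal) for r in cal.itertuples(index=False)
    }

    is_areas = [
        areas[(sid, isn)]
        for sid in nominal_by_sample
        for isn in panel.internal_standards
        if (sid, isn) in areas
    ]
    is_reference = float(np.median(is_areas)) if is_areas else float("nan")

    fits: dict[str, CalibrationFit] = {}
    first_pts: dict[str, list[CalibrationPoint]] = {}
    second_pts: dict[str, list[CalibrationPoint]] = {}
    drift_records: list[DriftRecord] = []
    for name, analyte in panel.analytes.items():
        is_name = analyte.is_name

        def points_for(sample_ids: list[str]) -> list[CalibrationPoint]:
            pts = []
            for sid in sample_ids:
                level = nominal_by_sample.get(sid, {}).get(name)
                if level is None or level <= 0:
                    continue
                if restrict_to_working_range and not (
                    analyte.working_lloq - 1e-9 <= level <= analyte.working_uloq + 1e-9
                ):
                    continue
                ratio = _ratio(areas, sid, name, is_name)
                if ratio is None:
                    continue
                pts.append(CalibrationPoint(level_conc=level, response_ratio=max(ratio, 0.0)))
            return pts

        fp, sp = points_for(first_ids), points_for(second_ids)
        first_pts[name], second_pts[name] = fp, sp
        pooled = fp + sp
        fits[name] = fit_calibration(pooled, model=model, weighting=weighting, analyte_name=name)
        if fp and sp:
            drift_records += calibration_drift(fits[name], fp, sp)

    qc_rows = []
    qc = manifest[manifest["role"] == "qc"]
    for r in qc.itertuples(index=False):
        nominal = decode_nominal(r.nominal)
        for name, level in nominal.items():
            analyte = panel.analytes.get(name)
            if analyte is None:
                continue
            in_range = analyte.working_lloq - 1e-9 <= level <= analyte.working_uloq + 1e-9
            ratio = _ratio(areas, str(r.sample_id), name, analyte.is_name)
            if ratio is None:
                continue
            try:
                measured = inverse_predict(fits[name], ratio, uloq=analyte.working_uloq)
                recovery = measured / level * 100.0
            except (BelowRangeSignal, OverRangeSignal):
                measured, recovery = float("nan"), float("nan")
            qc_rows.append(
                {
                    "sample_id": r.sample_id,
                    "analyte": name,
                    "nominal": level,
                    "measured": measured,
                    "recovery_percent": recovery,
                    "in_working_range": in_range,
                    "passed": (not in_range)
                    or (math.isfinite(recovery) and abs(recovery - 100.0) <= acceptance),
                }
            )
    qc_df = pd.DataFrame(qc_rows)
    rejected = False
    if not qc_df.empty and not qc_df["passed"].all():
        failures = qc_df[~qc_df["passed"]]
        warnings_list.append(
            f"batch {batch_id}: {len(failures)} in-range QC failures "
            f"({', '.join(sorted(failures['analyte'].unique()))})"
        )
        rejected = reject_on_qc_failure
    return BatchResult(
        batch_id=batch_id,
        fits=fits,
        first_set_points=first_pts,
        second_set_points=second_pts,
        qc_recoveries=qc_df,
        drift=drift_records,
        is_reference_area=is_reference,
        rejected=rejected,
        warnings=warnings_list,
    )


def measure_sample(
    sample: Mapping,
    batch: BatchResult,
    peaks: pd.DataFrame,
    panel: Panel,
    lloq_overrides: Mapping[str, float] | None = None,
) -> list[MeasuredConcentration]:
    """Measure every panel analyte in one sample against the batch fits.

    Every (sample, analyte) pair yields exactly one record - BLOQ,
    over-range and invalid outcomes are explicit, never dropped.
    """
    sid = str(sample["sample_id"])
    factor = float(sample.get("dilution_factor", 1.0) or 1.0)
    areas = _area_lookup(peaks[peaks["sample_id"] == sid])
    lloqs = lloq_overrides or {}
    out: list[MeasuredConcentration] = []
    for name, analyte in panel.analytes.items():
        fit = batch.fits[name]
        lloq = float(lloqs.get(name, analyte.working_lloq))
        uloq = analyte.working_uloq
        is_area = areas.get((sid, analyte.is_name))
        a_area = areas.get((sid, name))
        is_rec = (
            is_area / batch.is_reference_area * 100.0
            if is_area is not None and math.isfinite(batch.is_reference_area)
            else float("nan")
        )
        if is_area is None or is_area <= 0:
            out.append(
                MeasuredConcentration(sid, name, None, "invalid", factor, float("nan"),
                                      reason="missing internal-standard peak")
            )
            continue
        if a_area is None:
            out.append(
                MeasuredConcentration(sid, name, None, "bloq", factor, is_rec,
                                      reason="no analyte peak")
            )
            continue
        ratio = a_area / is_area
        try:
            measured = inverse_predict(fit, ratio, uloq=uloq)
        except BelowRangeSignal:
            out.append(MeasuredConcentration(sid, name, None, "bloq", factor, is_rec))
            continue
        except OverRangeSignal as sig:
            est = sig.estimate
            try:
                suggested = (
                    suggest_dilution(est * factor, (lloq, uloq)) if est is not None else 50
                )
            except OverRangeSignal:
                suggested = max(ALLOWED_DILUTION_FACTORS)
            out.append(
                MeasuredConcentration(
                    sid, name, None, "over_range", factor, is_rec,
                    suggested_factor=suggested, reason=str(sig),
                )
            )
            continue
        value = measured * factor
        if measured < lloq - 1e-9:
            if measured < fit.bottom_level:
                out.append(MeasuredConcentration(sid, name, None, "bloq", factor, is_rec))
            else:
                out.append(
                    MeasuredConcentration(
                        sid, name, value, "estimated_below_range", factor, is_rec,
                        reason="below working LLOQ; estimate only",
                    )
                )
        elif measured > uloq + 1e-9:
            suggested = suggest_dilution(value, (lloq, uloq))
            out.append(
                MeasuredConcentration(
                    sid, name, None, "over_range", factor, is_rec, suggested_factor=suggested
                )
            )
        else:
            out.append(MeasuredConcentration(sid, name, value, "ok", factor, is_rec))
    return out


def measurements_frame(results: Sequence[MeasuredConcentration]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "analyte": m.analyte_name,
                "value": m.value,
                "flag": m.flag,
                "dilution_factor": m.dilution_factor,
                "is_recovery": m.is_recovery,
                "suggested_factor": m.suggested_factor,
                "reason": m.reason,
            }
            for m in results
        ]
    )


def summarize_panel(
    measurements: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection frequency and concentration summaries over commercial liquids.

    Detection means flag ``ok`` (at or above the working LLOQ).  Means are
    reported both over detects only (the convention for "average
    concentration among liquids containing the chemical") and over the
    whole panel with non-detects as zero.  The second frame breaks
    detection frequency down by flavor category.
    """
    if measurements.empty:
        raise ArgumentError("no measurements to summarize")
    commercial = manifest[manifest["role"] == "commercial"][["sample_id", "flavor_category"]]
    if commercial.empty:
        raise ArgumentError("no commercial samples in manifest")
    df = measurements.merge(commercial, on="sample_id", how="inner")
    n_samples = df["sample_id"].nunique()
    per_analyte = []
    for analyte, grp in df.groupby("analyte"):
        detects = grp[grp["flag"] == "ok"]["value"].astype(float)
        per_analyte.append(
            {
                "analyte": analyte,
                "n_samples": n_samples,
                "n_detects": len(detects),
                "detection_percent": 100.0 * len(detects) / n_samples,
                "mean_detects": detects.mean() if len(detects) else float("nan"),
                "min_detects": detects.min() if len(detects) else float("nan"),
                "max_detects": detects.max() if len(detects) else float("nan"),
                "mean_all": detects.sum() / n_samples,
            }
        )
    per_analyte_df = pd.DataFrame(per_analyte).sort_values(
        "detection_percent", ascending=False, ignore_index=True
    )
    by_cat = []
    for (cat, analyte), grp in df.groupby(["flavor_category", "analyte"]):
        n_cat = grp["sample_id"].nunique()
        detects = grp[grp["flag"] == "ok"]["value"].astype(float)
        by_cat.append(
            {
                "flavor_category": cat,
                "analyte": analyte,
                "n_samples": n_cat,
                "n_detects": len(detects),
                "detection_percent": 100.0 * len(detects) / n_cat,
                "mean_detects": detects.mean() if len(detects) else float("nan"),
            }
        )
    return per_analyte_df, pd.DataFrame(by_cat)
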