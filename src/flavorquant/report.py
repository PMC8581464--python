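"""Validation dossiers and quantitation reports.

``run_validate`` executes the whole validation battery over a multi-batch
dataset and renders one machine-readable dossier (YAML) plus one
human-readable delimited summary per analyte.  ``run_quantify`` runs the
production pipeline over a batch of unknowns and writes the concentration
table and a structured batch log.  Every number in the rendered summaries
is copied from the machine-readable output - no report-only arithmetic.

Between-calibration drift is reported as a diagnostic, not a pass/fail
gate: isolated low-level drift excursions are expected and documented
rather than failing a validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import _invert, determine_working_range
from .config import RunConfig
from .errors import EmptyRangeError, FlavorQuantError, OverRangeSignal
from .io import decode_nominal
from .panel import Panel
from .quantify import BatchResult, assemble_batch, measure_sample, measurements_frame
from .validation import (
    assess_carryover,
    model_comparison,
    recovery_battery,
    recovery_frame,
    stability_check,
)


def _raw_backcalc(fit, ratio: float) -> float:
    """Range-unchecked back-calculation (validation wants raw numbers)."""
    try:
        return _invert(fit, ratio)
    except (OverRangeSignal, FlavorQuantError):
        return float("nan")


def _ratios_for_samples(
    manifest: pd.DataFrame, peaks: pd.DataFrame, panel: Panel, role: str
) -> pd.DataFrame:
    """Tidy (batch_id, sample_id, analyte, nominal, ratio) for one role."""
    sel = manifest[manifest["role"] == role]
    areas = {
        (str(r.sample_id), str(r.analyte)): float(r.area)
        for r in peaks.itertuples(index=False)
    }
    rows = []
    for r in sel.itertuples(index=False):
        nominal = decode_nominal(r.nominal)
        for name, analyte in panel.analytes.items():
            a = areas.get((str(r.sample_id), name))
            i = areas.get((str(r.sample_id), analyte.is_name))
            if a is None or i is None or i <= 0:
                continue
            rows.append(
                {
                    "batch_id": str(r.batch_id),
                    "sample_id": str(r.sample_id),
                    "analyte": name,
                    "nominal": nominal.get(name, 0.0),
                    "dilution_factor": float(r.dilution_factor or 1.0),
                    "ratio": a / i,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Everything the validation battery produced, ready to render."""

    config: RunConfig
    dossier: dict  # per-analyte machine-readable record
    summary: pd.DataFrame  # one row per analyte
    fortified_stats: pd.DataFrame
    lloq_stats: pd.DataFrame
    dilution_stats: pd.DataFrame
    drift_table: pd.DataFrame
    model_table: pd.DataFrame
    qc_table: pd.DataFrame
    all_pass: bool
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "validation_dossier.yaml", "w") as fh:
            yaml.safe_dump(
                {"config": self.config.to_dict(), "analytes": self.dossier,
                 "all_pass": bool(self.all_pass), "warnings": self.warnings},
                fh, sort_keys=False,
            )
        self.summary.to_csv(outdir / "validation_summary.tsv", sep="\t", index=False,
                            float_format="%.4g")
        self.fortified_stats.to_csv(outdir / "fortified_recovery.tsv", sep="\t", index=False,
                                    float_format="%.4g")
        self.lloq_stats.to_csv(outdir / "lloq_recovery.tsv", sep="\t", index=False,
                               float_format="%.4g")
        self.dilution_stats.to_csv(outdir / "dilution_integrity.tsv", sep="\t", index=False,
                                   float_format="%.4g")
        self.drift_table.to_csv(outdir / "drift.tsv", sep="\t", index=False,
                                float_format="%.4g")
        self.model_table.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False,
                                float_format="%.4g")


def run_validate(
    config: RunConfig, manifest: pd.DataFrame, peaks: pd.DataFrame, panel: Panel
) -> ValidationReport:
    """Execute the full validation battery over a multi-batch dataset."""
    warnings_list: list[str] = []
    batches: dict[str, BatchResult] = {}
    for batch_id, m in manifest.groupby("batch_id"):
        p = peaks[peaks["sample_id"].isin(m["sample_id"])]
        batch = assemble_batch(
            m, p, panel,
            model=config.model, weighting=config.weighting,
            acceptance=config.acceptance,
            restrict_to_working_range=False,
            reject_on_qc_failure=config.reject_on_qc_failure,
        )
        batches[str(batch_id)] = batch
        warnings_list += batch.warnings

    # recovery batteries
    fort = _ratios_for_samples(manifest, peaks, panel, "fortified")
    lloq_fort = _ratios_for_samples(manifest, peaks, panel, "lloq_fortified")
    dil = _ratios_for_samples(manifest, peaks, panel, "dilution_check")
    stab = _ratios_for_samples(manifest, peaks, panel, "stability")
    for df in (fort, lloq_fort, dil, stab):
        if not df.empty:
            df["measured"] = [
                _raw_backcalc(batches[b].fits[a], r) * f
                for b, a, r, f in zip(
                    df["batch_id"], df["analyte"], df["ratio"], df["dilution_factor"]
                )
            ]

    fort_stats = recovery_battery(fort, config.acceptance) if not fort.empty else []
    lloq_stats = recovery_battery(lloq_fort, config.acceptance) if not lloq_fort.empty else []
    fort_df = recovery_frame(fort_stats, config.acceptance)
    lloq_df = recovery_frame(lloq_stats, config.acceptance)

    # blanks for carryover, per batch
    blank_ratios: dict[tuple[str, str], list[float]] = {}
    blanks = manifest[manifest["role"].isin(["blank_pgvg", "blank_methanol"])]
    areas = {
        (str(r.sample_id), str(r.analyte)): float(r.area)
        for r in peaks.itertuples(index=False)
    }
    for r in blanks.itertuples(index=False):
        for name, analyte in panel.analytes.items():
            a = areas.get((str(r.sample_id), name))
            i = areas.get((str(r.sample_id), analyte.is_name))
            if a is None or a <= 0 or i is None or i <= 0:
                continue  # no peak in the blank
            blank_ratios.setdefault((str(r.batch_id), name), []).append(a / i)

    dossier: dict[str, dict] = {}
    summary_rows = []
    drift_rows = []
    all_pass = True
    from .validation import dilution_integrity

    working_ranges: dict[str, tuple[float, float]] = {}
    for name, analyte in panel.analytes.items():
        fits = [b.fits[name] for b in batches.values()]
        r2s = [f.r2 for f in fits]
        rses = [f.rse_percent for f in fits]
        try:
            wr = determine_working_range(fits, acceptance=config.acceptance)
            lloq0, uloq = wr.lloq, wr.uloq
            gates = {
                round(row["level"], 6): (
                    abs(row["mean_recovery"] - 100.0) <= config.acceptance
                    if math.isfinite(row["mean_recovery"]) else False,
                    row["cv_recovery"] <= config.acceptance
                    if math.isfinite(row["cv_recovery"]) else False,
                )
                for row in wr.level_table
            }
        except EmptyRangeError:
            lloq0, uloq, gates = float("nan"), float("nan"), {}
            warnings_list.append(f"{name}: no level met working-range criteria")

        # carryover: worst batch governs
        decision = None
        if math.isfinite(lloq0):
            for batch_id, batch in batches.items():
                ratios = blank_ratios.get((batch_id, name), [])
                d = assess_carryover(
                    batch.fits[name], ratios, lloq0,
                    levels=batch.fits[name].levels,
                    limit_percent=config.carryover_limit,
                    level_gates=gates,
                )
                if decision is None or d.carryover_conc > decision.carryover_conc:
                    decision = d
        final_lloq = decision.final_lloq if decision else lloq0
        working_ranges[name] = (
            final_lloq if math.isfinite(lloq0) else 0.02,
            uloq if math.isfinite(uloq) else 10.0,
        )

        # fortified gates for this analyte
        a_fort = fort_df[fort_df["analyte"] == name] if not fort_df.empty else fort_df
        fort_pass = bool(a_fort["passed"].all()) if len(a_fort) else True
        max_bias = float(a_fort["bias_percent"].abs().max()) if len(a_fort) else float("nan")
        max_cv = float(a_fort["cv_percent"].max()) if len(a_fort) else float("nan")

        # drift diagnostic
        for b in batches.values():
            for rec in b.drift:
                if rec.analyte_name == name:
                    drift_rows.append(
                        {
                            "batch_id": b.batch_id,
                            "analyte": name,
                            "level": rec.level_conc,
                            "first_conc": rec.first_conc,
                            "second_conc": rec.second_conc,
                            "drift_percent": rec.drift_percent,
                            "in_working_range": working_ranges[name][0] - 1e-9
                            <= rec.level_conc
                            <= working_ranges[name][1] + 1e-9,
                        }
                    )

        # stability: mean recovery over stability levels inside the range
        stab_recovery = float("nan")
        stab_pass = True
        if not stab.empty:
            a_stab = stab[
                (stab["analyte"] == name)
                & (stab["nominal"] >= working_ranges[name][0] - 1e-9)
                & (stab["nominal"] <= working_ranges[name][1] + 1e-9)
            ]
            if len(a_stab):
                recs = 100.0 * a_stab["measured"] / a_stab["nominal"]
                stab_recovery = float(recs.mean())
                stab_pass = stability_check(stab_recovery, config.stability_window)

        carry_ok = decision is None or (
            decision.carryover_fraction_at_lloq <= config.carryover_limit
        )
        gates_pass = (
            fort_pass
            and carry_ok
            and stab_pass
            and math.isfinite(lloq0)
            and not any(b.rejected for b in batches.values())
        )
        all_pass &= gates_pass

        dossier[name] = {
            "instrument_range_lloq": float(lloq0) if math.isfinite(lloq0) else None,
            "working_uloq": float(uloq) if math.isfinite(uloq) else None,
            "final_lloq": float(final_lloq) if math.isfinite(final_lloq) else None,
            "carryover_conc_mg_ml": float(decision.carryover_conc) if decision else 0.0,
            "carryover_fraction_percent": float(decision.carryover_fraction_at_lloq)
            if decision else 0.0,
            "lloq_escalated": bool(decision.escalated) if decision else False,
            "lloq_trail": [
                {"level": float(lv), "passed_recovery": bool(pr),
                 "passed_cv": bool(pc), "carryover_ok": bool(co)}
                for lv, pr, pc, co in (decision.trail if decision else [])
            ],
            "r2_min": float(np.min(r2s)),
            "r2_mean": float(np.mean(r2s)),
            "rse_mean_percent": float(np.mean(rses)),
            "fortified_max_abs_bias_percent": max_bias,
            "fortified_max_cv_percent": max_cv,
            "stability_recovery_percent": stab_recovery if math.isfinite(stab_recovery) else None,
            "passes": bool(gates_pass),
        }
        summary_rows.append(
            {
                "analyte": name,
                "final_lloq": final_lloq,
                "uloq": uloq,
                "r2_min": float(np.min(r2s)),
                "rse_mean": float(np.mean(rses)),
                "fortified_max_abs_bias": max_bias,
                "fortified_max_cv": max_cv,
                "carryover_percent": float(decision.carryover_fraction_at_lloq)
                if decision else 0.0,
                "stability_recovery": stab_recovery,
                "passes": gates_pass,
            }
        )

    if not dil.empty:
        dil_in = pd.DataFrame(
            {
                "analyte": dil["analyte"],
                "source_conc": dil["nominal"],
                "factor": dil["dilution_factor"],
                "measured": dil["measured"],
            }
        )
        dil_df = dilution_integrity(dil_in, working_ranges, acceptance=config.acceptance)
    else:
        dil_df = pd.DataFrame()
    if not dil_df.empty:
        bad = dil_df[dil_df["in_range"] & ~dil_df["passed"]]
        if len(bad):
            all_pass = False
            warnings_list.append(
                f"dilution integrity failures: {sorted(bad['analyte'].unique())}"
            )

    # model comparison on the first batch's pooled calibration points
    first_batch = next(iter(batches.values()))
    pts = {
        name: first_batch.first_set_points[name] + first_batch.second_set_points[name]
        for name in panel.analytes
    }
    model_df = model_comparison(pts, weighting=config.weighting)

    qc_df = pd.concat(
        [b.qc_recoveries.assign(batch_id=b.batch_id) for b in batches.values()],
        ignore_index=True,
    ) if batches else pd.DataFrame()

    return ValidationReport(
        config=config,
        dossier=dossier,
        summary=pd.DataFrame(summary_rows),
        fortified_stats=fort_df,
        lloq_stats=lloq_df,
        dilution_stats=dil_df,
        drift_table=pd.DataFrame(drift_rows),
        model_table=model_df,
        qc_table=qc_df,
        all_pass=bool(all_pass),
        warnings=warnings_list,
    )


@dataclass
class QuantifyReport:
    """Production-batch output: concentrations plus a structured log."""

    concentrations: pd.DataFrame
    batch_log: dict
    rejected: bool

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.concentrations.to_csv(outdir / "concentrations.csv", index=False,
                                   float_format="%.5g")
        with open(outdir / "batch_log.yaml", "w") as fh:
            yaml.safe_dump(self.batch_log, fh, sort_keys=False)


def run_quantify(
    config: RunConfig, manifest: pd.DataFrame, peaks: pd.DataFrame, panel: Panel,
    lloq_overrides: dict[str, float] | None = None,
) -> QuantifyReport:
    """Measure all commercial samples, batch by batch, with full logging."""
    frames = []
    log: dict = {"config": config.to_dict(), "batches": {}}
    rejected = False
    for batch_id, m in manifest.groupby("batch_id"):
        p = peaks[peaks["sample_id"].isin(m["sample_id"])]
        batch = assemble_batch(
            m, p, panel,
            model=config.model, weighting=config.weighting,
            acceptance=config.acceptance,
            restrict_to_working_range=True,
            reject_on_qc_failure=config.reject_on_qc_failure,
        )
        rejected |= batch.rejected
        results = []
        for r in m[m["role"] == "commercial"].to_dict("records"):
            results += measure_sample(r, batch, p, panel, lloq_overrides=lloq_overrides)
        df = measurements_frame(results)
        if not df.empty:
            frames.append(df.assign(batch_id=str(batch_id)))
        log["batches"][str(batch_id)] = {
            "rejected": bool(batch.rejected),
            "warnings": batch.warnings,
            "fits": {
                name: {
                    "model": f.model,
                    "coefficients": [float(v) for v in f.coefficients],
                    "r2": float(f.r2),
                    "rse_percent": float(f.rse_percent),
                }
                for name, f in batch.fits.items()
            },
            "qc_failures": int((~batch.qc_recoveries["passed"]).sum())
            if not batch.qc_recoveries.empty else 0,
            "drift_max_abs_percent": float(
                max((abs(d.drift_percent) for d in batch.drift), default=float("nan"))
            ),
        }
    conc = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return QuantifyReport(concentrations=conc, batch_log=log, rejected=rejected)
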