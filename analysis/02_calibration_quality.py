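#!/usr/bin/env python
"""Calibration quality across the seven simulated batches.

For every analyte: weighted-quadratic r^2 (minimum and mean over batches),
average %RSE of back-calculated concentrations, and the mean relative
response factor (RRF) across calibration levels.  Writes
results/calibration_quality.csv and one example calibration figure.

Reads scratch/validation_study (run 01_simulate_study.py first; the data
are regenerated automatically if missing).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flavorquant import load_panel, relative_response_factor
from flavorquant.io import decode_nominal, read_manifest, read_peak_table
from flavorquant.quantify import assemble_batch
from flavorquant.simulate import RRF_TARGETS

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def load_study(panel):
    d = ROOT / "scratch/validation_study"
    if not (d / "manifest.csv").exists():
        from flavorquant import generate_validation_study, well_behaved

        generate_validation_study(well_behaved(panel), panel, seed=SEED, n_batches=7).write(d)
    return read_manifest(d / "manifest.csv"), read_peak_table(d / "peaks.csv")


def main() -> None:
    panel = load_panel()
    manifest, peaks = load_study(panel)

    batches = {}
    for batch_id, m in manifest.groupby("batch_id"):
        p = peaks[peaks["sample_id"].isin(m["sample_id"])]
        batches[batch_id] = assemble_batch(m, p, panel)

    areas = {(r.sample_id, r.analyte): r.area for r in peaks.itertuples(index=False)}
    cal = manifest[manifest["role"] == "calibrator"]

    rows = []
    for name, analyte in panel.analytes.items():
        r2s = [b.fits[name].r2 for b in batches.values()]
        rses = [b.fits[name].rse_percent for b in batches.values()]
        rrfs = []
        for r in cal.itertuples(index=False):
            lv = decode_nominal(r.nominal).get(name)
            a = areas.get((r.sample_id, name))
            i = areas.get((r.sample_id, analyte.is_name))
            if lv and a and i:
                rrfs.append(relative_response_factor(a, i, lv, 1.0))
        rows.append(
            {
                "analyte": name,
                "r2_min": min(r2s),
                "r2_mean": float(np.mean(r2s)),
                "rse_mean_percent": float(np.mean(rses)),
                "rrf_mean": float(np.mean(rrfs)),
                "rrf_design": RRF_TARGETS[name],
            }
        )
    table = pd.DataFrame(rows).sort_values("analyte", ignore_index=True)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "calibration_quality.csv", index=False, float_format="%.4g")

    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        f"\nminimum r2 over all analytes/batches: {table.r2_min.min():.4f} "
        f"(every fit exceeds 0.990: {bool((table.r2_min >= 0.990).all())})"
    )
    print(
        f"largest per-analyte mean RSE: {table.rse_mean_percent.max():.2f}% "
        f"(all below 10%: {bool((table.rse_mean_percent < 10).all())})"
    )
    print(
        f"mean RRF spans {table.rrf_mean.min():.3f}-{table.rrf_mean.max():.3f} "
        "across the panel"
    )

    # one illustrative calibration curve (vanillin, batch B1)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fit = batches["B1"].fits["Vanillin"]
        xs = np.array([p.level_conc for p in fit.points if p.included])
        ys = np.array([p.response_ratio for p in fit.points if p.included])
        grid = np.geomspace(xs.min(), xs.max(), 200)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.loglog(xs, ys, "o", label="calibrators (both sets)")
        ax.loglog(grid, fit.predict(grid), "-", label="weighted quadratic")
        ax.set_xlabel("concentration (mg/ml)")
        ax.set_ylabel("response ratio A$_s$/A$_{is}$")
        ax.set_title(f"Vanillin, batch B1 (r$^2$={fit.r2:.4f}, RSE={fit.rse_percent:.1f}%)")
        ax.legend()
        fig.tight_layout()
        (out / "figures").mkdir(exist_ok=True)
        fig.savefig(out / "figures/calibration_vanillin.png", dpi=120)
        print("figure: results/figures/calibration_vanillin.png")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
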