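"""Synthetic GC-MS detector-response generator.

Emulates the statistical structure the downstream analysis assumes, so
that calibration, validation and quantitation are fully testable without
an instrument:

* peak area approximately quadratic in concentration,
  mean = baseline + k * c * (1 + q * c), with q <= 0 for saturation and an
  optional hard ceiling reproducing detector saturation at high load;
* multiplicative lognormal noise with constant CV (the heteroscedasticity
  that motivates 1/x^2 weighting);
* an internal-standard channel with its own (smaller) noise;
* injection-to-injection carryover: a configurable percent of the previous
  injection's area bleeds into the next one, optionally suppressed in
  methanol blanks for matrix-retained chemicals;
* slow per-batch drift of the analyte/IS response ratio, linear in
  injection order, so bracketing calibrations genuinely differ.

Per-analyte sensitivities are set from target relative response factors
spanning 0.03-0.70, the span reported for this chemistry.

Three instrument personas ship as factories:

``well_behaved``   5% CV noise, mild curvature, all validation gates pass.
``saturating``     strongly curved response for dl-limonene, eucalyptol,
                   furaneol and trans-cinnamaldehyde; the latter two plus
                   benzyl alcohol hit a hard ceiling at 5 mg/ml.
``sticky``         noise off, 2% carryover on the six carryover-prone
                   chemicals (butanoic acid and ethyl vanillin in PG:VG
                   blanks only).

Everything is driven by ``numpy.random.SeedSequence`` spawning, so a fixed
seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .io import MANIFEST_COLUMNS, PEAK_COLUMNS, encode_nominal
from .panel import Panel

#: Design targets for per-analyte relative response factors (dimensionless),
#: spanning the reported 0.03 (acetoin) to 0.70 (2,3,5-trimethylpyrazine).
RRF_TARGETS: dict[str, float] = {
    "Acetoin": 0.03,
    "Butanoic Acid": 0.05,
    "Benzaldehyde": 0.45,
    "2,3,5-Trimethylpyrazine": 0.70,
    "dl-Limonene": 0.25,
    "Eucalyptol": 0.30,
    "Benzyl Alcohol": 0.35,
    "Furaneol": 0.06,
    "Maltol": 0.10,
    "L-Menthol": 0.40,
    "Methyl Salicylate": 0.50,
    "Ethyl Maltol": 0.12,
    "(+)Pulegone": 0.35,
    "Ethyl Salicylate": 0.55,
    "trans-Cinnamaldehyde": 0.30,
    "Triacetin": 0.20,
    "Eugenol": 0.25,
    "Vanillin": 0.15,
    "Ethyl Vanillin": 0.18,
    "Isovanillin": 0.12,
}

#: Chemicals the method found to carry over between injections.
CARRYOVER_PRONE = (
    "Butanoic Acid",
    "Ethyl Maltol",
    "Ethyl Vanillin",
    "Isovanillin",
    "Maltol",
    "Vanillin",
)
#: Of those, the two seen in PG:VG blanks only (not in methanol blanks).
PGVG_ONLY = ("Butanoic Acid", "Ethyl Vanillin")

#: Chemicals that reached detector saturation at 5 mg/ml.
SATURATING = ("Benzyl Alcohol", "Furaneol", "trans-Cinnamaldehyde")

#: Chemicals whose response is strongly curved (a linear model is inadequate
#: for them, while the remaining 16 are close to linear).
CURVED_Q: dict[str, float] = {
    "dl-Limonene": -0.03,
    "Eucalyptol": -0.03,
    "Furaneol": -0.03,
    "trans-Cinnamaldehyde": -0.03,
}
#: Mild default curvature for the remaining, near-linear chemicals.
DEFAULT_Q = -0.005

#: Printed sample-preparation level schemes (mg/ml, undiluted basis).
CALIBRATION_TOP, CALIBRATION_LEVELS = 10.0, 10
QC_TOP, QC_LEVELS = 8.0, 9
FORTIFIED_LEVELS = (0.04, 0.10, 0.88, 1.75, 3.50, 7.00)
LLOQ_LEVELS = (0.01, 0.04, 0.07, 0.10, 0.27)
DILUTION_SCHEMES: dict[float, tuple[int, ...]] = {
    5.0: (2, 5),
    10.0: (2, 5, 10, 50),
    18.6: (2, 5, 10, 50),
}


@dataclass
class AnalyteResponse:
    """Detector-response parameters for one analyte channel."""

    k: float  # sensitivity, counts per mg/ml
    q: float = 0.0  # curvature per (mg/ml); <= 0 saturates
    baseline: float = 0.0  # counts
    noise_cv: float = 5.0  # % multiplicative lognormal
    saturation_area: float | None = None  # hard ceiling on the mean, counts
    carryover_percent: float | None = None  # None -> instrument default
    meoh_carryover_scale: float = 1.0  # 0 for PG:VG-only carryover
    stability_recovery: float = 100.0  # % recovered after 1-month storage

    def mean_area(self, conc: float) -> float:
        a = self.baseline + self.k * conc * (1.0 + self.q * conc)
        if self.saturation_area is not None:
            a = min(a, self.saturation_area)
        return max(a, 0.0)


@dataclass
class SyntheticInstrument:
    """A full synthetic instrument: per-analyte responses plus IS channel."""

    responses: dict[str, AnalyteResponse]
    is_response: float = 1.0e6  # counts at the nominal IS concentration
    is_noise_cv: float = 2.0  # %
    carryover_percent: float = 0.0  # default, unless the analyte overrides
    batch_drift_sd: float = 0.0  # % ratio drift accumulated over one batch
    name: str = "custom"

    def carryover_for(self, analyte: str) -> float:
        r = self.responses[analyte]
        return self.carryover_percent if r.carryover_percent is None else r.carryover_percent


def _base_responses(panel: Panel, noise_cv: float, is_response: float, q: float = DEFAULT_Q):
    out = {}
    for name in panel.analytes:
        rrf = RRF_TARGETS.get(name, 0.25)
        out[name] = AnalyteResponse(k=rrf * is_response, q=q, noise_cv=noise_cv)
    return out


def well_behaved(panel: Panel, noise_cv: float = 5.0) -> SyntheticInstrument:
    """All validation gates pass: 5% CV noise, mild saturating curvature."""
    inst = SyntheticInstrument(
        responses=_base_responses(panel, noise_cv, is_response=1.0e6),
        is_noise_cv=2.0,
        batch_drift_sd=2.0,
        name="well_behaved",
    )
    return inst


def saturating(panel: Panel, noise_cv: float = 5.0) -> SyntheticInstrument:
    """Nonlinear-response persona.

    The four strongly curved chemicals get their pronounced curvature
    (a linear model is inadequate for them), and benzyl alcohol, furaneol
    and trans-cinnamaldehyde additionally hit a hard ceiling at 5 mg/ml.
    """
    inst = well_behaved(panel, noise_cv)
    inst.name = "saturating"
    for name, q in CURVED_Q.items():
        inst.responses[name] = replace(inst.responses[name], q=q)
    for name in SATURATING:
        r = inst.responses[name]
        # ceiling sits just above the 5 mg/ml response: the 5 mg/ml standard
        # still reads true, everything beyond flattens out
        inst.responses[name] = replace(r, saturation_area=r.mean_area(6.0))
    return inst


def sticky(panel: Panel, carryover_percent: float = 2.0) -> SyntheticInstrument:
    """Vanillin-like: noise off, carryover on the six carryover-prone chemicals."""
    inst = SyntheticInstrument(
        responses=_base_responses(panel, noise_cv=0.0, is_response=1.0e6),
        is_noise_cv=0.0,
        batch_drift_sd=0.0,
        name="sticky",
    )
    for name in CARRYOVER_PRONE:
        inst.responses[name] = replace(
            inst.responses[name],
            carryover_percent=carryover_percent,
            meoh_carryover_scale=0.0 if name in PGVG_ONLY else 0.5,
        )
    return inst


PERSONAS = {"well_behaved": well_behaved, "saturating": saturating, "sticky": sticky}


class DilutionLevel(NamedTuple):
    """One serial-dilution level: exact value and its rounded nominal label."""

    exact: float
    nominal: float


def serial_dilution_series(
    top: float, factor: float, n_levels: int, rounding: int = 2
) -> list[DilutionLevel]:
    """Descending 2-fold-style series: level i = top / factor**(i-1).

    Returns exact values alongside nominals rounded to *rounding* decimals
    (the convention used on printed level schemes, e.g. 0.01953125 -> 0.02).
    """
    if top <= 0:
        raise ArgumentError("top concentration must be positive")
    if n_levels < 1:
        raise ArgumentError("need at least one level")
    if n_levels > 1 and factor <= 1:
        raise ArgumentError("dilution factor must exceed 1")
    out = []
    for i in range(n_levels):
        exact = top / factor**i
        out.append(DilutionLevel(exact, round(exact, rounding)))
    return out


def _lognoise(rng: np.random.Generator, cv_percent: float) -> float:
    if cv_percent <= 0:
        return 1.0
    cv = cv_percent / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_response(
    conc: float,
    response: AnalyteResponse,
    rng: np.random.Generator,
    drift: float = 1.0,
    carryover_area: float = 0.0,
) -> float:
    """One analyte peak area: mean response x drift x lognormal noise + carryover."""
    if conc < 0:
        raise ArgumentError("concentration must be nonnegative")
    mean = response.mean_area(conc) * drift + carryover_area
    return mean * _lognoise(rng, response.noise_cv)


@dataclass
class _Injection:
    sample_id: str
    role: str
    concs: dict[str, float]  # undiluted-liquid basis
    dilution_factor: float = 1.0
    nominal: dict[str, float] = field(default_factory=dict)
    flavor_category: str = ""
    response_scale: dict[str, float] = field(default_factory=dict)  # e.g. aged samples
    blank_kind: str | None = None  # "pgvg" | "methanol"


@dataclass
class SyntheticStudy:
    """Generated dataset: manifest + peak table + hidden ground truth."""

    manifest: pd.DataFrame
    peaks: pd.DataFrame
    truth: pd.DataFrame  # sample_id, analyte, true_conc (undiluted), factor

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_manifest, write_peak_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, outdir / "manifest.csv")
        write_peak_table(self.peaks, outdir / "peaks.csv")
        self.truth.to_csv(outdir / "ground_truth.csv", index=False)


def _run_batch(
    injections: Sequence[_Injection],
    instrument: SyntheticInstrument,
    panel: Panel,
    batch_id: str,
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict], list[dict]]:
    """Simulate one acquisition batch in injection order."""
    n_inj = max(len(injections), 1)
    drift_slope = {
        name: rng.normal(0.0, instrument.batch_drift_sd / 100.0)
        for name in panel.analytes
    }
    memory: dict[str, float] = {name: 0.0 for name in panel.analytes}
    manifest_rows, peak_rows, truth_rows = [], [], []
    for order, inj in enumerate(injections, start=1):
        manifest_rows.append(
            {
                "sample_id": inj.sample_id,
                "role": inj.role,
                "batch_id": batch_id,
                "injection_order": order,
                "flavor_category": inj.flavor_category,
                "dilution_factor": inj.dilution_factor,
                "aliquot_volume_ul": 30.0,
                "is_volume_ul": 30.0,
                "solvent_volume_ul": 3000.0,
                "nominal": encode_nominal(inj.nominal),
            }
        )
        for name, resp in instrument.responses.items():
            conc_inj = inj.concs.get(name, 0.0) / inj.dilution_factor
            drift = 1.0 + drift_slope[name] * (order - 1) / (n_inj - 1 or 1)
            co = instrument.carryover_for(name) / 100.0
            if inj.blank_kind == "methanol":
                co *= resp.meoh_carryover_scale
            carry = co * memory[name]
            scale = inj.response_scale.get(name, 1.0)
            area = simulate_response(conc_inj, resp, rng, drift=drift * scale, carryover_area=carry)
            memory[name] = area
            peak_rows.append(
                {
                    "sample_id": inj.sample_id,
                    "analyte": name,
                    "area": area,
                    "rt": panel.analytes[name].rt + rng.normal(0.0, 0.005),
                    "fwhm": 0.04,
                    "mz": panel.analytes[name].quant_mz,
                }
            )
            if inj.concs.get(name, 0.0) > 0:
                truth_rows.append(
                    {
                        "sample_id": inj.sample_id,
                        "analyte": name,
                        "true_conc": inj.concs[name],
                        "factor": inj.dilution_factor,
                    }
                )
        for is_name, istd in panel.internal_standards.items():
            area = instrument.is_response * _lognoise(rng, instrument.is_noise_cv)
            peak_rows.append(
                {
                    "sample_id": inj.sample_id,
                    "analyte": is_name,
                    "area": area,
                    "rt": istd.rt + rng.normal(0.0, 0.005),
                    "fwhm": 0.04,
                    "mz": istd.quant_mz,
                }
            )
    return manifest_rows, peak_rows, truth_rows


def _validation_batch_injections(
    panel: Panel,
    batch_tag: str,
    n_replicates: int = 3,
    include_dilution_checks: bool = True,
    include_stability: bool = False,
    stability_instrument: SyntheticInstrument | None = None,
) -> list[_Injection]:
    cal = [lv.nominal for lv in serial_dilution_series(CALIBRATION_TOP, 2, CALIBRATION_LEVELS)]
    qc = [lv.nominal for lv in serial_dilution_series(QC_TOP, 2, QC_LEVELS)]
    all_names = list(panel.analytes)

    def spike(level: float) -> dict[str, float]:
        return {n: level for n in all_names}

    inj: list[_Injection] = []
    # opening calibration, ascending, ending at the top standard
    for lv in sorted(cal):
        inj.append(_Injection(f"{batch_tag}-CALA-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
    # carryover blanks straight after the 10 mg/ml standard: PG:VG first
    for i in range(3):
        inj.append(_Injection(f"{batch_tag}-BLKPGVG-{i+1}", "blank_pgvg", {}, blank_kind="pgvg"))
    # QC series ascending, ending at 8 mg/ml, then methanol blanks
    for lv in sorted(qc):
        inj.append(_Injection(f"{batch_tag}-QC-{lv:g}", "qc", spike(lv), nominal=spike(lv)))
    for i in range(3):
        inj.append(_Injection(f"{batch_tag}-BLKMEOH-{i+1}", "blank_methanol", {}, blank_kind="methanol"))
    for lv in FORTIFIED_LEVELS:
        for r in range(n_replicates):
            inj.append(
                _Injection(f"{batch_tag}-FORT-{lv:g}-{r+1}", "fortified", spike(lv), nominal=spike(lv))
            )
    for lv in LLOQ_LEVELS:
        for r in range(n_replicates):
            inj.append(
                _Injection(
                    f"{batch_tag}-LLOQ-{lv:g}-{r+1}", "lloq_fortified", spike(lv), nominal=spike(lv)
                )
            )
    if include_dilution_checks:
        for source, factors in DILUTION_SCHEMES.items():
            for f in factors:
                for r in range(n_replicates):
                    inj.append(
                        _Injection(
                            f"{batch_tag}-DIL-{source:g}x{f}-{r+1}",
                            "dilution_check",
                            spike(source),
                            dilution_factor=float(f),
                            nominal=spike(source),
                        )
                    )
    if include_stability and stability_instrument is not None:
        scale = {
            n: stability_instrument.responses[n].stability_recovery / 100.0
            for n in all_names
        }
        for lv in (0.16, 1.25, 10.0):
            inj.append(
                _Injection(
                    f"{batch_tag}-STAB-{lv:g}",
                    "stability",
                    spike(lv),
                    nominal=spike(lv),
                    response_scale=scale,
                )
            )
    # closing calibration
    for lv in sorted(cal):
        inj.append(_Injection(f"{batch_tag}-CALB-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
    return inj


def generate_validation_study(
    instrument: SyntheticInstrument,
    panel: Panel,
    seed: int,
    n_batches: int = 7,
    n_replicates: int = 3,
    include_dilution_checks: bool = True,
    include_stability: bool = True,
) -> SyntheticStudy:
    """The full validation dataset: seven bracketed batches on separate days.

    Each batch holds an opening and closing 10-level calibration, a 9-level
    QC series, carryover blanks (three PG:VG after the 10 mg/ml standard,
    three methanol after the 8 mg/ml QC), fortified triplicates at
    0.04/0.10/0.88/1.75/3.50/7.00 mg/ml, LLOQ fortified triplicates at
    0.01/0.04/0.07/0.10/0.27 mg/ml and dilution-capability samples at
    5, 10 and 18.6 mg/ml; stability re-injections ride in the last batch.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_batches)
    manifest_rows, peak_rows, truth_rows = [], [], []
    for b in range(n_batches):
        tag = f"B{b+1}"
        inj = _validation_batch_injections(
            panel,
            tag,
            n_replicates=n_replicates,
            include_dilution_checks=include_dilution_checks,
            include_stability=include_stability and b == n_batches - 1,
            stability_instrument=instrument,
        )
        m, p, t = _run_batch(inj, instrument, panel, tag, np.random.default_rng(children[b]))
        manifest_rows += m
        peak_rows += p
        truth_rows += t
    return SyntheticStudy(
        manifest=pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS),
        peaks=pd.DataFrame(peak_rows, columns=PEAK_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=["sample_id", "analyte", "true_conc", "factor"]),
    )


#: Flavor-category mix of the surveyed commercial liquids (sums to 1).
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "Fruit (tropical)": 0.17,
    "Fruit (berry)": 0.14,
    "Fruit (other)": 0.13,
    "Menthol/Mint": 0.12,
    "Candy": 0.10,
    "Dessert": 0.09,
    "Other Beverages": 0.08,
    "Tobacco": 0.08,
    "Other Sweets": 0.09,
}

#: Baseline per-analyte occurrence probabilities (any category).
DEFAULT_OCCURRENCE: dict[str, float] = {
    "Benzyl Alcohol": 0.41,
    "Ethyl Maltol": 0.32,
    "Triacetin": 0.29,
    "L-Menthol": 0.10,
    "Vanillin": 0.25,
    "Ethyl Vanillin": 0.20,
    "Acetoin": 0.12,
    "Maltol": 0.15,
    "Benzaldehyde": 0.12,
    "dl-Limonene": 0.10,
    "Eucalyptol": 0.02,
    "Eugenol": 0.02,
    "Furaneol": 0.08,
    "Methyl Salicylate": 0.05,
    "(+)Pulegone": 0.02,
    "2,3,5-Trimethylpyrazine": 0.04,
    "Butanoic Acid": 0.06,
    "Ethyl Salicylate": 0.0,
    "Isovanillin": 0.0,
    "trans-Cinnamaldehyde": 0.0,
}

#: Category-specific occurrence overrides (analyte, category) -> probability.
CATEGORY_OCCURRENCE: dict[tuple[str, str], float] = {
    ("Eugenol", "Fruit (tropical)"): 1.0,
    ("Eucalyptol", "Menthol/Mint"): 1.0,
    ("(+)Pulegone", "Menthol/Mint"): 0.83,
    ("2,3,5-Trimethylpyrazine", "Tobacco"): 0.62,
    ("Acetoin", "Dessert"): 0.50,
    ("L-Menthol", "Menthol/Mint"): 0.48,
}

#: Log-uniform concentration ranges (mg/ml) for liquids containing an analyte.
DEFAULT_CONC_RANGES: dict[str, tuple[float, float]] = {
    "Benzyl Alcohol": (0.02, 12.0),
    "Ethyl Maltol": (0.1, 32.0),
    "Triacetin": (0.1, 23.0),
    "L-Menthol": (0.5, 19.0),
    "Vanillin": (0.3, 16.0),
    "Ethyl Vanillin": (0.2, 19.0),
    "(+)Pulegone": (0.02, 0.32),
    "2,3,5-Trimethylpyrazine": (0.02, 0.30),
    "Eugenol": (0.02, 0.9),
}
_FALLBACK_RANGE = (0.02, 5.0)


def generate_commercial_panel(
    instrument: SyntheticInstrument,
    panel: Panel,
    n_liquids: int,
    seed: int,
    category_mix: Mapping[str, float] | None = None,
    occurrence: Mapping[str, float] | None = None,
    conc_ranges: Mapping[str, tuple[float, float]] | None = None,
    liquids_per_batch: int = 75,
) -> SyntheticStudy:
    """Synthetic commercial e-liquid survey with known ground truth.

    Liquids draw a flavor category, per-category analyte presence, and
    log-uniform concentrations (defaults span 0.02-32 mg/ml, so some
    liquids exceed the ULOQ and exercise the over-range dilution path).
    Liquids are packed into acquisition batches of at most
    ``liquids_per_batch``, each bracketed by calibration and QC sets.
    """
    if n_liquids < 1:
        raise ArgumentError("need at least one liquid")
    mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    occ = dict(occurrence or DEFAULT_OCCURRENCE)
    ranges = dict(conc_ranges or DEFAULT_CONC_RANGES)
    bad = [p for p in list(mix.values()) + list(occ.values()) if not 0 <= p <= 1]
    if bad:
        raise ArgumentError("probabilities must be in [0, 1]")
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    ss = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(ss.spawn(1)[0])
    liquids = []
    for i in range(n_liquids):
        cat = cats[design_rng.choice(len(cats), p=probs)]
        concs: dict[str, float] = {}
        for name in panel.analytes:
            p_occ = CATEGORY_OCCURRENCE.get((name, cat), occ.get(name, 0.0))
            if design_rng.random() < p_occ:
                lo, hi = ranges.get(name, _FALLBACK_RANGE)
                concs[name] = float(np.exp(design_rng.uniform(np.log(lo), np.log(hi))))
        liquids.append((f"EC{i+1:04d}", cat, concs))

    cal = [lv.nominal for lv in serial_dilution_series(CALIBRATION_TOP, 2, CALIBRATION_LEVELS)]
    qc = [lv.nominal for lv in serial_dilution_series(QC_TOP, 2, QC_LEVELS)]
    all_names = list(panel.analytes)

    def spike(level: float) -> dict[str, float]:
        return {n: level for n in all_names}

    n_batches = math.ceil(n_liquids / liquids_per_batch)
    children = ss.spawn(n_batches + 1)[1:]
    manifest_rows, peak_rows, truth_rows = [], [], []
    for b in range(n_batches):
        tag = f"C{b+1}"
        chunk = liquids[b * liquids_per_batch : (b + 1) * liquids_per_batch]
        inj: list[_Injection] = []
        for lv in sorted(cal):
            inj.append(_Injection(f"{tag}-CALA-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
        for lv in sorted(qc):
            inj.append(_Injection(f"{tag}-QC-{lv:g}", "qc", spike(lv), nominal=spike(lv)))
        for liquid_id, cat, concs in chunk:
            inj.append(_Injection(liquid_id, "commercial", concs, flavor_category=cat))
        for lv in sorted(cal):
            inj.append(_Injection(f"{tag}-CALB-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
        m, p, t = _run_batch(inj, instrument, panel, tag, np.random.default_rng(children[b]))
        manifest_rows += m
        peak_rows += p
        truth_rows += t
    study = SyntheticStudy(
        manifest=pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS),
        peaks=pd.DataFrame(peak_rows, columns=PEAK_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=["sample_id", "analyte", "true_conc", "factor"]),
    )
    return study


def simulate_reruns(
    instrument: SyntheticInstrument,
    panel: Panel,
    rerun_requests: Sequence[tuple[str, dict[str, float], float]],
    seed: int,
    batch_id: str = "RERUN1",
) -> SyntheticStudy:
    """Re-inject over-range liquids at suggested dilution factors.

    *rerun_requests*: (sample_id, true concs, dilution factor) triples.
    The re-run batch carries its own bracketing calibrators, mirroring the
    practice of re-injecting diluted liquids with fresh calibration sets.
    """
    cal = [lv.nominal for lv in serial_dilution_series(CALIBRATION_TOP, 2, CALIBRATION_LEVELS)]
    all_names = list(panel.analytes)

    def spike(level: float) -> dict[str, float]:
        return {n: level for n in all_names}

    inj: list[_Injection] = []
    for lv in sorted(cal):
        inj.append(_Injection(f"{batch_id}-CALA-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
    for sample_id, concs, factor in rerun_requests:
        inj.append(
            _Injection(f"{sample_id}-D{factor:g}", "commercial", dict(concs), dilution_factor=factor)
        )
    for lv in sorted(cal):
        inj.append(_Injection(f"{batch_id}-CALB-{lv:g}", "calibrator", spike(lv), nominal=spike(lv)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m, p, t = _run_batch(inj, instrument, panel, batch_id, rng)
    return SyntheticStudy(
        manifest=pd.DataFrame(m, columns=MANIFEST_COLUMNS),
        peaks=pd.DataFrame(p, columns=PEAK_COLUMNS),
        truth=pd.DataFrame(t, columns=["sample_id", "analyte", "true_conc", "factor"]),
    )
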