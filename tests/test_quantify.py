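"""Batch assembly, sample measurement, dilution planning, panel summaries."""

import numpy as np
import pandas as pd
import pytest

from flavorquant.calibration import CalibrationPoint, fit_calibration
from flavorquant.errors import ConfigError, OverRangeSignal
from flavorquant.io import decode_nominal, encode_nominal
from flavorquant.quantify import (
    assemble_batch,
    measure_sample,
    measurements_frame,
    prepare_dilution_plan,
    suggest_dilution,
    summarize_panel,
)


class TestDilutionPlan:
    def test_standard_preparation_is_102_fold(self):
        plan = prepare_dilution_plan(30, 30, 3000)
        assert plan.total_factor == pytest.approx(102.0)
        assert plan.is_final_conc == pytest.approx(30 / 3060)
        assert not plan.flagged

    def test_halved_aliquot_doubles_factor_keeps_is(self):
        # aliquot halved, solvent adjusted so the total volume is unchanged
        plan = prepare_dilution_plan(15, 30, 3015)
        assert plan.total_factor == pytest.approx(204.0)
        assert plan.is_final_conc == pytest.approx(30 / 3060)
        assert not plan.flagged

    def test_doubled_is_volume_trips_flag(self):
        plan = prepare_dilution_plan(30, 60, 2970)
        assert plan.is_final_conc == pytest.approx(60 / 3060)
        assert plan.flagged


class TestSuggestDilution:
    RANGE = (0.02, 10.0)

    def test_log_distance_tie_break(self):
        # 32/20 = 1.6 vs 32/50 = 0.64: |log 1.6| > |log 0.64|, so 50 wins
        assert suggest_dilution(32.0, self.RANGE) == 50

    def test_nearest_to_target(self):
        assert suggest_dilution(12.0, self.RANGE) == 10

    def test_in_range_estimate_needs_no_dilution(self):
        assert suggest_dilution(8.0, self.RANGE) == 1

    def test_unreachable_estimate_escalates(self):
        with pytest.raises(OverRangeSignal):
            suggest_dilution(10.0 * 51, self.RANGE)


class TestNominalEncoding:
    def test_round_trip(self):
        nominal = {"Vanillin": 0.88, "Acetoin": 10.0}
        assert decode_nominal(encode_nominal(nominal)) == nominal
        assert decode_nominal("") == {}


class TestAssembleBatch:
    def test_pooled_duplicate_sets_equal_single_set(self, panel):
        """Identical bracketing sets give exactly the single-set fit."""
        levels = [10 / 2**i for i in range(10)]
        rows_m, rows_p = [], []
        order = 0
        for setname in ("A", "B"):
            for lv in levels:
                order += 1
                sid = f"X-CAL{setname}-{lv:g}"
                rows_m.append(
                    {"sample_id": sid, "role": "calibrator", "batch_id": "X",
                     "injection_order": order, "flavor_category": "",
                     "dilution_factor": 1.0, "aliquot_volume_ul": 30.0,
                     "is_volume_ul": 30.0, "solvent_volume_ul": 3000.0,
                     "nominal": encode_nominal({n: lv for n in panel.analytes})}
                )
                for name, a in panel.analytes.items():
                    rows_p.append({"sample_id": sid, "analyte": name,
                                   "area": 0.25e6 * lv * (1 - 0.01 * lv),
                                   "rt": a.rt, "fwhm": 0.04, "mz": a.quant_mz})
                for isn, istd in panel.internal_standards.items():
                    rows_p.append({"sample_id": sid, "analyte": isn, "area": 1e6,
                                   "rt": istd.rt, "fwhm": 0.04, "mz": istd.quant_mz})
        manifest, peaks = pd.DataFrame(rows_m), pd.DataFrame(rows_p)
        batch = assemble_batch(manifest, peaks, panel)
        single = fit_calibration(
            [CalibrationPoint(lv, 0.25 * lv * (1 - 0.01 * lv)) for lv in levels],
            analyte_name="Vanillin",
        )
        pooled = batch.fits["Vanillin"]
        # identical up to the WLS solver's numerical tolerance
        assert pooled.coefficients == pytest.approx(single.coefficients, rel=1e-5, abs=1e-7)
        # and the drift table reports zero drift between identical sets
        assert all(abs(d.drift_percent) < 1e-6 for d in batch.drift)

    def test_no_calibrators_raises(self, panel, small_study):
        m = small_study.manifest
        m1 = m[(m["batch_id"] == "B1") & (m["role"] != "calibrator")]
        p1 = small_study.peaks[small_study.peaks["sample_id"].isin(m1["sample_id"])]
        with pytest.raises(ConfigError):
            assemble_batch(m1, p1, panel)

    def test_drift_populated_on_shifted_second_set(self, panel, batch_one):
        m1, p1, _ = batch_one
        cal_b = m1[m1["sample_id"].str.contains("CALB")]["sample_id"]
        p_shift = p1.copy()
        analyte_rows = p_shift["sample_id"].isin(cal_b) & p_shift["analyte"].isin(
            panel.analytes
        )
        p_shift.loc[analyte_rows, "area"] *= 1.15
        batch = assemble_batch(m1, p_shift, panel)
        drift = [d.drift_percent for d in batch.drift]
        assert len(drift) > 0
        assert np.median(drift) == pytest.approx(15.0, abs=4.0)

    def test_qc_recoveries_reported(self, panel, batch_one):
        _, _, batch = batch_one
        qc = batch.qc_recoveries
        in_range = qc[qc["in_working_range"]]
        assert len(in_range) > 0
        assert (in_range["recovery_percent"].dropna() - 100).abs().median() < 10


class TestMeasureSample:
    def _setup(self, panel):
        levels = [10 / 2**i for i in range(10)]
        rows_m, rows_p = [], []
        order = 0
        for setname in ("A", "B"):
            for lv in levels:
                order += 1
                sid = f"Y-CAL{setname}-{lv:g}"
                rows_m.append({"sample_id": sid, "role": "calibrator", "batch_id": "Y",
                               "injection_order": order, "flavor_category": "",
                               "dilution_factor": 1.0, "aliquot_volume_ul": 30.0,
                               "is_volume_ul": 30.0, "solvent_volume_ul": 3000.0,
                               "nominal": encode_nominal({n: lv for n in panel.analytes})})
                for name in panel.analytes:
                    rows_p.append({"sample_id": sid, "analyte": name, "area": 1e5 * lv,
                                   "rt": 1, "fwhm": 0.04, "mz": 1})
                for isn in panel.internal_standards:
                    rows_p.append({"sample_id": sid, "analyte": isn, "area": 1e6,
                                   "rt": 1, "fwhm": 0.04, "mz": 1})
        batch = assemble_batch(pd.DataFrame(rows_m), pd.DataFrame(rows_p), panel)
        return batch

    def _sample_peaks(self, panel, sid, analyte_areas):
        rows = [{"sample_id": sid, "analyte": n, "area": a, "rt": 1, "fwhm": 0.04, "mz": 1}
                for n, a in analyte_areas.items()]
        rows += [{"sample_id": sid, "analyte": isn, "area": 1e6, "rt": 1,
                  "fwhm": 0.04, "mz": 1} for isn in panel.internal_standards]
        return pd.DataFrame(rows)

    def test_every_pair_yields_exactly_one_record(self, panel):
        batch = self._setup(panel)
        peaks = self._sample_peaks(panel, "S1", {"Vanillin": 1e5})
        out = measure_sample({"sample_id": "S1", "dilution_factor": 1.0}, batch, peaks, panel)
        assert len(out) == len(panel.analytes)
        assert len({m.analyte_name for m in out}) == len(panel.analytes)

    def test_ratio_at_lloq_measures_lloq_times_factor(self, panel):
        batch = self._setup(panel)
        lloq = panel.analytes["Vanillin"].working_lloq
        peaks = self._sample_peaks(panel, "S2", {"Vanillin": 1e5 * lloq})
        out = {m.analyte_name: m for m in measure_sample(
            {"sample_id": "S2", "dilution_factor": 10.0}, batch, peaks, panel)}
        v = out["Vanillin"]
        assert v.flag == "ok"
        assert v.value == pytest.approx(lloq * 10.0, rel=1e-6)

    def test_zero_area_with_is_present_is_bloq(self, panel):
        batch = self._setup(panel)
        peaks = self._sample_peaks(panel, "S3", {"Vanillin": 0.0})
        out = {m.analyte_name: m for m in measure_sample(
            {"sample_id": "S3"}, batch, peaks, panel)}
        assert out["Vanillin"].flag == "bloq"
        assert out["Vanillin"].value is None

    def test_missing_is_invalidates_with_reason(self, panel):
        batch = self._setup(panel)
        peaks = pd.DataFrame([{"sample_id": "S4", "analyte": "Vanillin", "area": 1e5,
                               "rt": 1, "fwhm": 0.04, "mz": 1}])
        out = {m.analyte_name: m for m in measure_sample(
            {"sample_id": "S4"}, batch, peaks, panel)}
        assert out["Vanillin"].flag == "invalid"
        assert "internal-standard" in out["Vanillin"].reason

    def test_quantifiable_below_working_lloq_is_estimated(self, panel):
        """A response quantifiable on the curve but under the working LLOQ
        is reported as an estimate, not silently dropped or zeroed."""
        batch = self._setup(panel)
        lloq = panel.analytes["Vanillin"].working_lloq  # 0.63, curve reaches 0.02
        peaks = self._sample_peaks(panel, "S6", {"Vanillin": 1e5 * lloq / 3})
        out = {m.analyte_name: m for m in measure_sample(
            {"sample_id": "S6"}, batch, peaks, panel)}
        v = out["Vanillin"]
        assert v.flag == "estimated_below_range"
        assert v.value == pytest.approx(lloq / 3, rel=1e-6)

    def test_over_range_carries_suggested_factor(self, panel):
        batch = self._setup(panel)
        peaks = self._sample_peaks(panel, "S5", {"Vanillin": 1e5 * 25})
        out = {m.analyte_name: m for m in measure_sample(
            {"sample_id": "S5"}, batch, peaks, panel)}
        v = out["Vanillin"]
        assert v.flag == "over_range" and v.value is None
        assert v.suggested_factor in (2, 5, 10, 20, 50)

    def test_detection_monotone_in_lloq(self, panel):
        batch = self._setup(panel)
        rng = np.random.default_rng(0)
        frames, overrides = [], {n: panel.analytes[n].working_lloq * 4 for n in panel.analytes}
        for i in range(15):
            conc = float(rng.uniform(0.01, 2.0))
            peaks = self._sample_peaks(panel, f"L{i}", {"Vanillin": 1e5 * conc})
            lo = measure_sample({"sample_id": f"L{i}"}, batch, peaks, panel)
            hi = measure_sample({"sample_id": f"L{i}"}, batch, peaks, panel,
                                lloq_overrides=overrides)
            frames.append((sum(m.flag == "ok" for m in lo), sum(m.flag == "ok" for m in hi)))
        assert all(hi <= lo for lo, hi in frames)


class TestSummarize:
    def _panel_frames(self):
        manifest = pd.DataFrame(
            [
                {"sample_id": "E1", "role": "commercial", "batch_id": "C1",
                 "injection_order": 1, "flavor_category": "Dessert"},
                {"sample_id": "E2", "role": "commercial", "batch_id": "C1",
                 "injection_order": 2, "flavor_category": "Candy"},
            ]
        )
        measurements = pd.DataFrame(
            [
                {"sample_id": "E1", "analyte": "Vanillin", "value": 3.81, "flag": "ok"},
                {"sample_id": "E2", "analyte": "Vanillin", "value": None, "flag": "bloq"},
                {"sample_id": "E1", "analyte": "Acetoin", "value": None, "flag": "bloq"},
                {"sample_id": "E2", "analyte": "Acetoin", "value": None, "flag": "bloq"},
            ]
        )
        return measurements, manifest

    def test_single_detect_mean_is_identity(self):
        measurements, manifest = self._panel_frames()
        per_analyte, per_cat = summarize_panel(measurements, manifest)
        v = per_analyte.set_index("analyte").loc["Vanillin"]
        assert v["detection_percent"] == 50.0
        assert v["mean_detects"] == pytest.approx(3.81)
        assert v["mean_all"] == pytest.approx(3.81 / 2)

    def test_all_bloq_panel(self):
        measurements, manifest = self._panel_frames()
        a = summarize_panel(measurements, manifest)[0].set_index("analyte").loc["Acetoin"]
        assert a["detection_percent"] == 0.0
        assert np.isnan(a["mean_detects"])

    def test_generated_panel_frequencies_match_design(self, panel):
        """Observed detection frequencies sit within binomial noise of truth."""
        from flavorquant import generate_commercial_panel, well_behaved
        from flavorquant.config import RunConfig
        from flavorquant.report import run_quantify
        from flavorquant.simulate import CATEGORY_OCCURRENCE, DEFAULT_OCCURRENCE

        inst = well_behaved(panel)
        study = generate_commercial_panel(inst, panel, n_liquids=150, seed=21)
        rep = run_quantify(RunConfig(seed=21), study.manifest, study.peaks, panel)
        per_analyte, per_cat = summarize_panel(rep.concentrations, study.manifest)
        commercial_ids = study.manifest[study.manifest["role"] == "commercial"]["sample_id"]
        truth = study.truth[study.truth["sample_id"].isin(commercial_ids)]
        truth_present = truth.groupby("analyte")["sample_id"].nunique()
        n = 150
        for name in ("Benzyl Alcohol", "Ethyl Maltol", "Triacetin"):
            p_true = truth_present.get(name, 0) / n
            observed = per_analyte.set_index("analyte").loc[name, "n_detects"] / n
            # detects can lag presence (BLOQ/over-range) but never exceed it,
            # and must sit within a few binomial SDs below it
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert observed <= p_true + 1e-9
            assert observed >= p_true - 4 * se - 0.05
        # category-specific structure: menthol/mint liquids carry eucalyptol
        mm = per_cat[(per_cat["flavor_category"] == "Menthol/Mint")
                     & (per_cat["analyte"] == "Eucalyptol")]
        assert mm["detection_percent"].iloc[0] > 50.0
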