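# Methods

## Scope and data model

The package implements a targeted, internal-standard GC-MS quantitation
workflow for 20 e-liquid flavoring chemicals and its validation battery.
Inputs are plain delimited text: a panel-definition file (one row per
species: retention time, accurate-mass quant/qualifier ions, assigned
internal standard, working range), per-injection peak tables
(`sample_id, analyte, area, rt, fwhm, mz`) and batch manifests describing
each injection's role (calibrator, QC, fortified, LLOQ-fortified, blanks,
dilution check, stability, commercial), its batch, injection order,
dilution factor and nominal spike map. Raw spectra are out of scope; the
pipeline starts from integrated peak areas, the point where chromatography
software hands over.

## Calibration model

Each analyte's response ratio y = A_s/A_is is regressed on nominal
concentration x by weighted least squares (statsmodels WLS) with weights
1/x² by default (1/x and unweighted are available). The default model is
quadratic, y = a + bx + cx², chosen over curve splitting for 500-fold
ranges where the detector response flattens at high load. Inverse
prediction solves the quadratic on its increasing branch — the root
(−b + √(b² − 4c(a − y)))/(2c), which is the increasing-branch root for
either sign of c — inside the admissible window [0, 1.2·ULOQ]. A result
below zero raises a BLOQ signal and a response above the curve maximum (or
beyond the window) raises an over-range signal; out-of-range inversions
never propagate as silent numbers.

Quality metrics:

* r² is computed on weighted sums of squares, matching the fitting
  objective; the unweighted r² is carried alongside for reference.
* %RSE = 100·√(Σ[(xᵢ′−xᵢ)/xᵢ]²/(n−p)) with back-calculated xᵢ′ obtained by
  inverse prediction against the same fit (not refitting), and p = 2
  (linear) or 3 (quadratic). The square root is part of the definition:
  without it the statistic would not be on the percent scale.
* Per-level recovery = 100·xᵢ′/xᵢ feeds working-range determination.

Apparent concentrations in blanks (for carryover) use the curve's low-end
tangent x = (y − a)/b, clamped at zero: blanks sit below the quantifiable
range by construction and the quadratic term is irrelevant there.

## Working range and saturation

A calibration level passes when its mean back-calculated recovery across
batches lies within 100 ± 20% and the recovery CV is at most 20%. Because a
hard saturation knee at the top of the series distorts a single polynomial
well below the saturated level, determination is iterative: while the
highest remaining level fails its gates, it is excluded and every batch is
refit on the truncated series. This reproduces the intended behavior for
saturating chemicals — the 10 mg/ml level collapses, the refit clears the
5 mg/ml level, and the working range ends at 5 mg/ml ("before detector
saturation") — without hand-flagging levels.

## Validation battery

* **Accuracy/precision.** %CV = SD/mean·100 and %Bias =
  (mean − expected)/expected·100, acceptance ±20% inclusive. Intra-day
  statistics are per (batch, analyte, level) over triplicates; inter-day
  statistics pool the per-batch means at each level. Single-replicate
  cells skip the CV with a warning. Cells whose back-calculated mean is
  non-positive (pathologically noisy data) report bias but leave the CV
  undefined rather than crashing.
* **LLOQ and carryover.** Blanks injected immediately after the top
  standards are inverse-predicted; the worst blank governs (matrix PG:VG
  blanks and methanol blanks are both assessed, and a chemical retained
  only by the matrix escalates on the PG:VG blanks alone). If carryover
  exceeds 5% of the candidate LLOQ, the LLOQ is raised level-by-level up
  the calibration series until the fraction is within 5%, skipping levels
  that failed their recovery/CV gates; the full decision trail is recorded.
  Blank rows with zero area count as "no peak" (carryover zero) — a fitted
  intercept must not manufacture phantom carryover in clean blanks.
* **Dilution integrity.** Concentrated samples (5, 10, 18.6 mg/ml) are
  measured after 2/5/10/50-fold dilution, corrected by the factor, and
  compared to nominal at ±20%. Replicates whose response cannot be
  quantified (above the fitted curve's maximum near the top of the range)
  are excluded and counted; a cell fails if more than 20% of its
  replicates are unquantifiable.
* **Stability.** Recovery of aged standards within 80–120% (inclusive),
  averaged over the stability levels inside the working range.
* **Drift.** Both bracketing calibration sets are back-calculated against
  the batch's pooled fit; drift = (second − first)/first·100, signed, with
  the opening set as reference. Drift is reported as a diagnostic, not a
  pass/fail gate: with triplicate-free single injections per level, the
  statistic has roughly √2 times the single-measurement CV, and isolated
  low-level excursions beyond 20% are expected in routine operation.
* **Model comparison.** One batch is refit with a universal linear (1/x²)
  model; the table reports r² and %RSE for both models, the largest
  per-level recovery difference, and flags analytes whose linear r² falls
  below 0.990.

QC recoveries inside the working range are tabulated with ±20% flags. A
failing in-range QC flags the batch; outright rejection is behind a
configuration switch (`reject_on_qc_failure`) since with ~1260 single
injections per study the 20% gate will be touched occasionally by noise
alone.

## Quantitation pipeline

A production batch carries an opening and a closing calibration set
(split by injection order); both pool into one fit per analyte, restricted
to the working range, while the per-set points feed the drift table. A
missing closing set degrades to a single-set fit with a warning. Unknowns
are measured by inverse prediction times the dilution factor, flagged
`ok`, `bloq`, `estimated_below_range` (quantifiable on the curve but below
the working LLOQ), `over_range` (with a suggested re-run factor) or
`invalid` (no internal-standard peak); every (sample, analyte) pair yields
exactly one record. Re-run factors come from {2, 5, 10, 20, 50}: among
factors landing the estimate inside the working range, the one nearest
1 mg/ml on a log scale wins, smaller factor on ties. The sample
preparation (30 µL sample + 30 µL internal standard + 3 ml methanol) is a
volumetric 102-fold dilution nominally labeled "100-fold"; calibrators and
unknowns share the identical preparation, so the discrepancy cancels in
ratio-based quantitation, and the dilution-plan helper tracks the actual
factor and the internal-standard concentration (flagging deviations beyond
±20%, since re-run dilutions must adjust the IS volume with the total
volume).

Panel summaries report detection (flag `ok`) frequency per analyte, means
over detects (the convention for "average concentration among liquids
containing the chemical") and over the whole panel with non-detects as
zero, plus a per-flavor-category breakdown.

## Synthetic instrument

The generator provides the statistical structure the analysis assumes,
not chromatographic realism (no peak shapes, spectra or ionization
physics). Mean peak area is baseline + k·c·(1 + q·c), optionally capped by
a hard ceiling; areas are multiplied by lognormal noise with configured CV
(mean-preserving), the internal-standard channel has its own smaller
noise, carryover adds a configured percent of the previous injection's
area, and a per-batch, per-analyte drift factor grows linearly with
injection order. Sensitivities k are set from target relative response
factors spanning 0.03 (acetoin) to 0.70 (2,3,5-trimethylpyrazine), the
span this chemistry exhibits, on a 10⁶-count internal-standard response.

Parameter choices, with units and rationale:

* **Analyte noise CV: 5%** (multiplicative, lognormal). No instrument
  noise figure is published for this method; 5% is a realistic
  split-injection GC-MS repeatability and is the stated study condition
  for every stochastic acceptance check.
* **Internal-standard noise CV: 2%.** The deuterated standards sit at one
  fixed concentration in every injection; their repeatability is better
  than that of analytes spanning 500-fold.
* **Curvature q: −0.005 per (mg/ml)** for the 16 near-linear chemicals
  (the top standard reads ~5% below linear), **q = −0.03** for the four
  strongly curved ones (dl-limonene, eucalyptol, furaneol,
  trans-cinnamaldehyde), matching the reported split in which only those
  four fail a universal linear model. The strongly curved four belong to
  the `saturating` persona; the `well_behaved` persona is, by definition,
  the configuration in which every validation gate passes, and near the
  curve top the q = −0.03 inverse prediction amplifies noise ~1.7-fold,
  which at 5% CV genuinely trips the ±20% intra-day gate in a noticeable
  fraction of seeded runs (the analogous real-world exception — eucalyptol
  within ±30% — is documented for this chemistry).
* **Batch drift SD: 2%** of the analyte/IS ratio accumulated over one
  batch, drawn per analyte per batch.
* **Saturation ceiling:** mean area frozen at its value just above the
  5 mg/ml response for benzyl alcohol, furaneol and trans-cinnamaldehyde
  in the `saturating` persona, so the 5 mg/ml standard still reads true
  and the working range ends there.
* **Carryover: 2%** of the previous injection's area in the `sticky`
  persona (noise off), applied to the six carryover-prone chemicals;
  butanoic acid and ethyl vanillin carry over in PG:VG blanks only
  (methanol-blank scale 0), the others at half scale in methanol.
* **Level schemes** are the printed preparation schemes: 10-level 2-fold
  calibration from 10.00 mg/ml (bottoming at 0.02 after 2-decimal
  rounding), 9-level QC from 8.00 (0.03), fortified triplicates at
  0.04/0.10/0.88/1.75/3.50/7.00, LLOQ samples at
  0.01/0.04/0.07/0.10/0.27, dilution checks at 5, 10 and 18.6 mg/ml with
  factors {2,5}, {2,5,10,50}, {2,5,10,50} respectively.
* **Commercial panel defaults:** nine flavor categories with a
  fruit-heavy mix, per-analyte occurrence probabilities anchored to the
  reported detection frequencies with category-specific overrides
  (eucalyptol certain in menthol/mint, eugenol certain in tropical fruit,
  and so on), and log-uniform concentrations whose upper ends (to
  ~32 mg/ml) deliberately exceed the ULOQ to exercise the over-range
  dilution path.

All randomness flows through `numpy.random.SeedSequence` spawning from a
single seed, so generated studies are byte-identical across runs.

What passing tests show — and don't. The generator's noise is exactly the
constant-CV lognormal the 1/x² weighting is optimal for, its curves are
exactly quadratic (plus the ceiling), and drift is linear in injection
order. Real chromatography adds integration errors, retention shifts,
co-elution, matrix effects and non-quadratic saturation; green gates here
demonstrate that the statistics, decision rules and plumbing are correct
under the stated assumptions, not that any physical instrument would pass.

## Numerical choices and degenerate inputs

* Quadratic fits with |c| below 1e−14·|b| invert as linear.
* Acceptance boundaries are inclusive; carryover comparisons allow
  relative float slack of 1e−9 so an exactly-5% fraction passes.
* Pooled duplicate calibration sets reproduce the single-set fit to the
  WLS solver's numerical tolerance (~1e−6 relative), not bit-exactly.
* Calibrators are split into opening/closing sets at the midpoint of
  their injection-order sequence; fewer calibrators than two full level
  sets triggers the degraded single-set path.
* Rank-deficient designs (fewer distinct levels than p+1) raise fit
  errors; RSE requires n > p.
* The "average" model (p = 1) appears in the RSE bookkeeping convention
  but is not a fitting option.

## Problem sizes

The shipped studies are desk-scale by design: seven batches of ~100
injections (about 17k peak rows) for validation, 200 liquids in bracketed
batches for the survey. The full test suite runs in a few seconds; the
acceptance script regenerates everything it reports in well under a
minute.

## Known limitations

* The panel's per-analyte working LLOQ/ULOQ values are plausible
  assignments consistent with the published range (0.02–0.63 mg/ml LLOQ;
  5 mg/ml ULOQ for the saturating chemicals), not instrument-certified
  values.
* Identification (ion matching, qualifier abundances, RRT, resolution) is
  exposed as pure functions and exercised on synthetic peaks; the
  simulator does not generate decoy peaks to mis-identify.
* Inter-day statistics pool batch means; pooling all replicates flat is
  available by passing the raw frame but is not the reported convention.
* The drift statistic is diagnostic only (see above).
* No spectral deconvolution, unknown-peak identification, or
  acetal/diacetyl formation chemistry.
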