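# Methods

## The assay and its decision model

The h-CLAT addresses the dendritic-cell-activation key event of the skin
sensitization adverse outcome pathway. THP-1 cells are exposed for 24 h to
eight concentrations of a test substance, stained with FITC-conjugated
anti-CD86, anti-CD54 or an IgG1 isotype control, and acquired with
propidium iodide for live/dead discrimination. The package implements the
downstream analysis as a fixed, auditable rule set rather than a fitted
model, because that is what the guideline prescribes:

* **Viability** of a tube is the exact fraction of PI-negative events.
  No scatter gating, doublet exclusion or compensation is modelled; the
  live gate is PI only.
* **MFI** summarizes the live gate. The default is the geometric mean —
  the conventional estimator for lognormal cytometry fluorescence, and the
  exact median of the simulator's event model — with the arithmetic mean
  available (`mfi_method="arithmetic"`) since published reports often say
  only "mean fluorescence intensity". Intensities below 1 a.u. are clamped
  to 1 before logs so nonpositive readings cannot poison the geometric
  mean.
* **CV75** is interpolated between the two tested doses bracketing 75%
  viability, log-linearly in concentration (dilution series span orders of
  magnitude; the interpolation scale is configurable). On non-monotone
  curves the first crossing scanning upward from the lowest dose is used:
  deterministic, and conservative in the sense of returning the lowest
  toxic estimate. When no dose is toxic the highest tested concentration
  stands in (`no_toxicity_fallback`); when even the lowest dose is below
  75% viability the lowest dose is returned flagged `out_of_range`.
  Run-level CV75s are averaged arithmetically on the linear scale.
* **RFI** corrects both numerator and denominator by the isotype MFI at
  the matching concentration. A non-positive corrected vehicle denominator
  makes the RFI undefined (a QC failure, reported as `None`/N/A); a
  negative corrected test signal is reported as 0%.
* **EC150/EC200** interpolate the threshold crossing linearly in
  concentration among gated (viability ≥ 50%) doses. The main series spans
  only a 3.6-fold range, so linear versus log interpolation is immaterial
  there; the scale is configurable. The first upward crossing from the
  lowest gated dose is used; a run whose lowest gated dose already exceeds
  the threshold yields that dose censored "≤ lowest tested". Final ECs
  average marker-positive runs only — a run positive solely via the other
  marker contributes nothing.
* **Decision rule.** Positivity thresholds are inclusive (CD86 RFI ≥ 150%,
  CD54 RFI ≥ 200%, viability gate CV ≥ 50%); the DNCB positive-control
  checks are strict (> 150% / > 200%), mirroring how the criteria are
  stated. Final call: positive iff ≥ 2 of 3 runs positive; 2 concordant
  runs may decide when the design allows early stopping (proficiency
  testing does; test substances default to 3 runs). Two discordant runs
  raise an explicit "third run required" signal rather than guessing.
* **Run acceptance** defaults: DNCB CD86 RFI > 150% and CD54 RFI > 200%
  with DNCB viability ≥ 50%, vehicle viability ≥ 90%, and ≥ 4 test
  concentrations passing the viability gate. The guideline states these
  criteria qualitatively; the numeric defaults are configurable
  (`AcceptanceConfig`). Rejected runs are excluded, never imputed.
* **Proficiency evaluation** checks the final call and, where applicable,
  CV75/EC150/EC200 against bundled reference ranges. Range checks are
  skipped for censored CV75s (recorded as "> top tested"), for undefined
  ECs, and for markers the guideline flags as historically negative (CD86
  for 2-mercaptobenzothiazole and R(+)-limonene), which are treated as
  non-gating.

## The synthetic-data generator

`synthetic_flow` emulates the study design: two dose-finding runs of eight
two-fold dilutions (PI-only tubes), then three main runs of eight 1.2-fold
concentrations re-derived from the simulated dose-finding data through the
same CV75 code path the analysis uses, each with CD86/CD54/isotype tubes,
stained vehicle tubes, a 4 ug/ml DNCB positive control with DMSO vehicle,
plus particle-only interference tubes and an unstained-cell reference.

Ground truth is fully parametric:

* cytotoxicity is log-logistic, `viability(c) = 100/(1 + (c/lc50)^h)`,
  giving the closed-form `CV75 = lc50 · (1/3)^(1/h)`;
* marker induction is Hill-shaped on the RFI scale with plateau `rmax`,
  half-max `k` and slope `h`, giving the closed-form
  `EC_t = k · ((t−100)/(rmax−t))^(1/h)`;
* event intensities are lognormal (spread `sigma_log`, log10 a.u.) around
  the tube target, so the geometric-mean MFI is a consistent estimator of
  the target; CD86/CD54 targets are placed so the tube's expected
  isotype-corrected RFI equals the truth RFI;
* between-run variability is one unit-mean lognormal factor per run
  (sigma `run_cv`) multiplying the induction amplitude `RFI − 100` — the
  simplest mechanism reproducing run-to-run RFI spread;
* each event is PI-positive independently with probability
  `1 − viability/100`.

Default parameters describe a plausible, clearly positive metal-oxide
particle: `lc50 = 44.7`, `hill_tox = 2` (CV75 ≈ 25.8 ug/ml), CD86 plateau
350% with half-max 20 ug/ml, CD54 plateau 4500% with half-max 65 ug/ml —
placing both ECs inside the main series — vehicle MFI 300 a.u. over an
isotype background of 50 a.u., `sigma_log = 0.15`, `run_cv = 0.10`, and
DNCB control RFIs of 611%/426% at 83% viability with 96.5% vehicle
viability, matching reported control behaviour. No instrument data exist
to fit these to; they were chosen once for plausibility.

Randomness is reproducible by construction: each tube's stream derives
from a SHA-256 hash of (substance, run, concentration, stain, role) mixed
with the global seed, so tube order never changes results and identical
seeds give bit-identical studies.

**What the simulator does not emulate:** scatter/doublet gating,
compensation and spillover, instrument voltages and time drift,
particle–antibody binding artifacts, non-monotone (hormetic) dose
responses, and settling/agglomeration of particle suspensions. Passing
recovery tests therefore demonstrate correctness of the analysis logic
under the stated noise model, not robustness to every real-data pathology.

## Numerical choices and degenerate inputs

* Interpolations are closed-form on the tested grid; no parametric (4PL)
  curve fitting anywhere, by design.
* Threshold comparisons at exactly 150/200/50 are inclusive; the
  interference check (particle background > 1.5× unstained cells,
  configurable) is strict, with a 1e-9 relative tolerance absorbing the
  geometric mean's log/exp round-trip at the exact boundary.
* Reported ECs are rounded half-away-from-zero to integer ug/ml at the
  report layer only; machine outputs keep full precision, and rounded
  values are never fed back into computation.
* Empty tubes, missing controls, unknown stain/role labels, mixed
  summary-table schemas and negative concentrations are hard errors with
  the offending row identified; tubes with no viable events yield an
  undefined (NaN) MFI that propagates to an undefined RFI.

## Problem sizes used in the test suite

Unit and property tests run at a few hundred to a few thousand events per
tube. The parameter-recovery suite uses the study conditions it verifies:
20 seeds at 10^4 events per tube with `run_cv = 0`, checking CV75 within
10% and ECs within 15% of their closed-form truths, always-negative null
inductions, and ≥ 95% positive calls for a strong CD54 inducer. Grid
oracles for the interpolators use 10^5-point scans at 0.5% relative
tolerance.

## Known limitations

* The event tier models FITC and PI only; multi-channel panels and FCS
  binary files are out of scope (the CSV event schema is the interchange
  format).
* Potency sub-categorization and multi-assay defined approaches are not
  implemented; the output is the binary guideline call plus ECs.
* The proficiency evaluator treats historically-negative markers as
  non-gating; a stricter policy would require a guideline interpretation
  the source material does not settle.
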