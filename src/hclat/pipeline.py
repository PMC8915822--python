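"""End-to-end study analysis: tubes -> summaries -> CV75 -> RFI -> prediction.

Ties the stage modules together for one substance's worth of tubes, exactly
in the order the assay prescribes: dose-finding tubes yield the averaged
CV75; main-run tubes are scored into isotype-corrected RFIs per
concentration, gated on viability, reduced to per-run EC estimates and run
calls, QC-checked against the DNCB/vehicle controls, and finally combined
into the 2-of-3 substance prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import activation_scoring, cytometry_metrics, dose_response
from . import prediction_engine as pe
from .config import StudyConfig
from .cytometry_metrics import TubeSummary
from .synthetic_flow import EventSample

STAINED = ("CD86", "CD54", "isotype")


@dataclass(frozen=True)
class StudyReport:
    """Everything the analysis derives for one substance."""

    substance: str
    cv75: Optional[dose_response.Cv75Estimate]
    runs: tuple[pe.RunResult, ...]
    prediction: Optional[pe.SubstancePrediction]
    interference: Optional[dict[float, bool]]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        def ec_val(ec: Optional[activation_scoring.EcRunResult]):
            return None if ec is None else ec.value

        return {
            "substance": self.substance,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "cv75": None if self.cv75 is None else {
                "value": self.cv75.value,
                "per_run_values": list(self.cv75.per_run_values),
                "no_toxicity_fallback": list(self.cv75.no_toxicity_fallback),
            },
            "runs": [
                {
                    "run_id": r.run_id,
                    "cd86_positive": r.cd86_positive,
                    "cd54_positive": r.cd54_positive,
                    "run_call": r.run_call,
                    "accepted": (None if r.acceptance is None
                                 else r.acceptance.accepted),
                    "acceptance_reasons": (
                        [] if r.acceptance is None
                        else list(r.acceptance.reasons)),
                    "ec150": ec_val(r.ec150),
                    "ec200": ec_val(r.ec200),
                    "concentrations": [
                        {
                            "concentration_ug_ml": cr.concentration,
                            "cv_pct": cr.cv_pct,
                            "rfi_cd86": cr.rfi_cd86,
                            "rfi_cd54": cr.rfi_cd54,
                        }
                        for cr in r.concentration_results
                    ],
                }
                for r in self.runs
            ],
            "prediction": None if self.prediction is None else {
                "final_call": self.prediction.final_call,
                "run_calls": list(self.prediction.run_calls),
                "n_runs_used": self.prediction.n_runs_used,
                "final_ec150": self.prediction.final_ec150,
                "final_ec200": self.prediction.final_ec200,
                "excluded_runs": list(self.prediction.excluded_runs),
            },
            "interference": None if self.interference is None else {
                f"{conc:g}": bool(flag)
                for conc, flag in self.interference.items()
            },
        }


def summarize_samples(samples: Sequence[EventSample],
                      config: StudyConfig | None = None) -> list[TubeSummary]:
    cfg = config or StudyConfig()
    return [cytometry_metrics.summarize(s, cfg.mfi_method) for s in samples]


def estimate_cv75(summaries: Sequence[TubeSummary],
                  config: StudyConfig | None = None
                  ) -> Optional[dose_response.Cv75Estimate]:
    """Averaged CV75 from the dose-finding (unstained, PI-only) tubes."""
    cfg = config or StudyConfig()
    dose = [s for s in summaries if s.stain == "unstained" and s.role == "test"]
    if not dose:
        return None
    runs = sorted({s.run_id for s in dose})
    per_run = []
    for run in runs:
        viab = {s.concentration: s.viability_pct
                for s in dose if s.run_id == run}
        per_run.append(dose_response.cv75_from_run(
            viab, target=cfg.cv75_target, scale=cfg.cv75_interp))
    return dose_response.average_cv75(per_run)


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def _tube_mfi(tubes: Sequence[TubeSummary], stain: str, role: str,
              conc: Optional[float] = None) -> Optional[float]:
    sel = [t for t in tubes if t.stain == stain and t.role == role
           and (conc is None or t.concentration == conc)]
    if not sel:
        return None
    return _mean([t.mfi for t in sel])


def score_run_summaries(run_tubes: Sequence[TubeSummary],
                        run_id: int,
                        config: StudyConfig | None = None) -> pe.RunResult:
    """Score one main run's stained tubes into a RunResult.

    Per concentration, the three stained tubes supply the marker and isotype
    MFIs; the concentration's viability is the mean over those tubes.  RFIs
    are computed against the stained media-vehicle tubes, the DNCB control
    against its DMSO vehicle.
    """
    cfg = config or StudyConfig()
    veh_cd86 = _tube_mfi(run_tubes, "CD86", "vehicle")
    veh_cd54 = _tube_mfi(run_tubes, "CD54", "vehicle")
    veh_iso = _tube_mfi(run_tubes, "isotype", "vehicle")
    if veh_cd86 is None or veh_cd54 is None or veh_iso is None:
        raise ValueError(f"run {run_id}: missing stained vehicle tubes")

    concs = sorted({t.concentration for t in run_tubes if t.role == "test"
                    and t.stain in STAINED})
    results: list[activation_scoring.ConcentrationResult] = []
    for conc in concs:
        at = [t for t in run_tubes if t.role == "test"
              and t.concentration == conc and t.stain in STAINED]
        mfi_cd86 = _tube_mfi(at, "CD86", "test", conc)
        mfi_cd54 = _tube_mfi(at, "CD54", "test", conc)
        mfi_iso = _tube_mfi(at, "isotype", "test", conc)
        if mfi_cd86 is None or mfi_cd54 is None or mfi_iso is None:
            raise ValueError(f"run {run_id}: incomplete staining at "
                             f"{conc} ug/ml")
        cv = _mean([t.viability_pct for t in at])
        results.append(activation_scoring.ConcentrationResult(
            concentration=conc, cv_pct=cv,
            rfi_cd86=activation_scoring.rfi(mfi_cd86, mfi_iso,
                                            veh_cd86, veh_iso),
            rfi_cd54=activation_scoring.rfi(mfi_cd54, mfi_iso,
                                            veh_cd54, veh_iso),
        ))

    ec150 = activation_scoring.ec_from_run(
        {r.concentration: r.rfi_cd86 for r in results},
        {r.concentration: r.cv_pct for r in results},
        cfg.cd86_threshold, cfg.cv_gate, cfg.ec_interp)
    ec200 = activation_scoring.ec_from_run(
        {r.concentration: r.rfi_cd54 for r in results},
        {r.concentration: r.cv_pct for r in results},
        cfg.cd54_threshold, cfg.cv_gate, cfg.ec_interp)

    acceptance = None
    dncb = [t for t in run_tubes if t.role == "dncb_positive_control"]
    dmso = [t for t in run_tubes if t.role == "dmso_vehicle"]
    if dncb and dmso:
        dncb_cd86 = activation_scoring.rfi(
            _tube_mfi(dncb, "CD86", "dncb_positive_control"),
            _tube_mfi(dncb, "isotype", "dncb_positive_control"),
            _tube_mfi(dmso, "CD86", "dmso_vehicle"),
            _tube_mfi(dmso, "isotype", "dmso_vehicle"))
        dncb_cd54 = activation_scoring.rfi(
            _tube_mfi(dncb, "CD54", "dncb_positive_control"),
            _tube_mfi(dncb, "isotype", "dncb_positive_control"),
            _tube_mfi(dmso, "CD54", "dmso_vehicle"),
            _tube_mfi(dmso, "isotype", "dmso_vehicle"))
        veh_viab = _mean([t.viability_pct for t in run_tubes
                          if t.role == "vehicle" and t.stain in STAINED])
        dncb_viab = _mean([t.viability_pct for t in dncb])
        acceptance = pe.run_acceptance(
            dncb_cd86, dncb_cd54, dncb_viab, veh_viab,
            [r.cv_pct for r in results], cfg.acceptance)

    return pe.score_run(run_id, results, acceptance=acceptance,
                        ec150=ec150, ec200=ec200, cv_gate=cfg.cv_gate)


def analyze_study(samples: Sequence[EventSample],
                  config: StudyConfig | None = None,
                  substance: Optional[str] = None) -> StudyReport:
    """Full analysis of one substance's tubes.

    Dose-finding tubes (unstained, role test) feed the CV75 estimate; main
    runs are scored and combined into the final prediction.  Particle-only
    tubes, when present, trigger the fluorescence-interference QC against
    the unstained-cell reference.
    """
    cfg = config or StudyConfig()
    if substance is not None:
        samples = [s for s in samples if s.substance == substance]
    if not samples:
        raise ValueError("no tubes to analyze")
    names = {s.substance for s in samples}
    if len(names) > 1:
        raise ValueError(f"multiple substances in input: {sorted(names)}; "
                         "pass substance= to select one")
    name = names.pop()

    summaries = summarize_samples(samples, cfg)
    cv75 = estimate_cv75(summaries, cfg)

    main = [s for s in summaries if s.stain in STAINED]
    runs: list[pe.RunResult] = []
    for run_id in sorted({s.run_id for s in main if s.role == "test"}):
        run_tubes = [s for s in main if s.run_id == run_id]
        runs.append(score_run_summaries(run_tubes, run_id, cfg))

    prediction = None
    if len(runs) >= 2:
        prediction = pe.classify_substance(
            name, runs, allow_early_stop=cfg.allow_early_stop)

    interference = None
    np_tubes = [s for s in samples if s.role == "np_only"]
    unstained = [s for s in samples
                 if s.stain == "unstained" and s.role == "vehicle"]
    if np_tubes and unstained:
        interference = cytometry_metrics.interference_check(
            np_tubes, unstained[0], cfg.interference_ratio)

    return StudyReport(
        substance=name, cv75=cv75, runs=tuple(runs), prediction=prediction,
        interference=interference, config_hash=cfg.hash(), seed=cfg.seed,
    )
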