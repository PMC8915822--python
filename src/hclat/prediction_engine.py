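"""Run acceptance, per-run positivity, the 2-of-3 prediction model and
proficiency-substance evaluation.

A run is positive when any tested concentration with viability >= 50% shows
CD86 RFI >= 150% or CD54 RFI >= 200% (inclusive thresholds).  A substance is
predicted Positive when at least 2 of 3 independent runs are positive; two
concordant runs may stand alone when the study design allows early stopping.
DNCB positive-control checks use strict inequalities (RFI > 150 / > 200).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .activation_scoring import ConcentrationResult, EcRunResult, final_ec

MARKER_THRESHOLDS = {"CD86": 150.0, "CD54": 200.0}
CV_GATE = 50.0


class ThirdRunRequiredError(ValueError):
    """Two discordant runs cannot decide the call; a third run is required."""


class InsufficientRunsError(ValueError):
    """Fewer than two usable (accepted) runs: no prediction can be made."""


@dataclass(frozen=True)
class AcceptanceConfig:
    """Numeric run-acceptance criteria (all configurable)."""

    dncb_cd86_min: float = 150.0      # strict >, positive control
    dncb_cd54_min: float = 200.0      # strict >
    dncb_viability_min: float = 50.0  # %
    vehicle_viability_min: float = 90.0  # %
    min_eligible_concentrations: int = 4  # with CV >= cv_gate
    cv_gate: float = CV_GATE


@dataclass(frozen=True)
class RunAcceptance:
    """QC flags for one run, with human-readable failure reasons."""

    dncb_cd86_ok: bool
    dncb_cd54_ok: bool
    dncb_viability_ok: bool
    vehicle_viability_ok: bool
    n_conc_cv_ok: bool
    dncb_viability_pct: float
    vehicle_viability_pct: float
    n_eligible_concentrations: int
    accepted: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunResult:
    """Scored outcome of one independent run."""

    run_id: int
    concentration_results: tuple[ConcentrationResult, ...]
    cd86_positive: bool
    cd54_positive: bool
    run_call: bool
    acceptance: Optional[RunAcceptance] = None
    ec150: Optional[EcRunResult] = None
    ec200: Optional[EcRunResult] = None


@dataclass(frozen=True)
class SubstancePrediction:
    """Final sensitizer call for one substance."""

    substance: str
    run_calls: tuple[bool, ...]
    final_call: str  # "Positive" | "Negative"
    n_runs_used: int
    final_ec150: Optional[float]
    final_ec200: Optional[float]
    excluded_runs: tuple[int, ...] = ()


@dataclass(frozen=True)
class ProficiencyReference:
    """Expected outcome and reference ranges for one proficiency substance.

    Open-ended bounds are None.  A marker flagged historically negative is
    expected negative by the guideline and its range is non-gating.
    """

    substance: str
    expected_call: str  # "Positive" | "Negative"
    cv75_range: tuple[Optional[float], Optional[float]] = (None, None)
    ec150_range: tuple[Optional[float], Optional[float]] = (None, None)
    ec200_range: tuple[Optional[float], Optional[float]] = (None, None)
    ec150_historically_negative: bool = False
    ec200_historically_negative: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.cv75_range, self.ec150_range, self.ec200_range):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError("range low bound exceeds high bound")


@dataclass(frozen=True)
class ProficiencyOutcome:
    """Per-substance evaluation against its reference."""

    substance: str
    call: str
    expected_call: str
    call_match: bool
    cv75_in_range: Optional[bool]   # None = not applicable / censored
    ec150_in_range: Optional[bool]
    ec200_in_range: Optional[bool]
    passed: bool
    notes: tuple[str, ...] = ()


def marker_positive(run_concentrations: Sequence[ConcentrationResult],
                    marker: str,
                    threshold: Optional[float] = None,
                    cv_gate: float = CV_GATE) -> bool:
    """True iff any viability-gated concentration has RFI >= threshold."""
    if len(run_concentrations) < 1:
        raise ValueError("need at least one concentration result")
    thr = MARKER_THRESHOLDS[marker] if threshold is None else threshold
    return any(
        cr.cv_pct >= cv_gate
        and cr.rfi(marker) is not None
        and cr.rfi(marker) >= thr
        for cr in run_concentrations
    )


def run_acceptance(dncb_rfi_cd86: Optional[float],
                   dncb_rfi_cd54: Optional[float],
                   dncb_viability: float,
                   vehicle_viability: float,
                   concentration_cvs: Sequence[float],
                   config: AcceptanceConfig | None = None) -> RunAcceptance:
    """Evaluate one run's QC gates; any failure rejects the run."""
    cfg = config or AcceptanceConfig()
    if dncb_rfi_cd86 is None or dncb_rfi_cd54 is None:
        raise ValueError("missing DNCB positive-control RFI")
    cd86_ok = dncb_rfi_cd86 > cfg.dncb_cd86_min
    cd54_ok = dncb_rfi_cd54 > cfg.dncb_cd54_min
    dncb_viab_ok = dncb_viability >= cfg.dncb_viability_min
    veh_ok = vehicle_viability >= cfg.vehicle_viability_min
    n_eligible = sum(1 for cv in concentration_cvs if cv >= cfg.cv_gate)
    n_ok = n_eligible >= cfg.min_eligible_concentrations

    reasons = []
    if not cd86_ok:
        reasons.append(f"DNCB CD86 RFI {dncb_rfi_cd86:.0f}% not > "
                       f"{cfg.dncb_cd86_min:.0f}%")
    if not cd54_ok:
        reasons.append(f"DNCB CD54 RFI {dncb_rfi_cd54:.0f}% not > "
                       f"{cfg.dncb_cd54_min:.0f}%")
    if not dncb_viab_ok:
        reasons.append(f"DNCB viability {dncb_viability:.1f}% below "
                       f"{cfg.dncb_viability_min:.0f}%")
    if not veh_ok:
        reasons.append(f"vehicle viability {vehicle_viability:.1f}% below "
                       f"{cfg.vehicle_viability_min:.0f}%")
    if not n_ok:
        reasons.append(f"only {n_eligible} concentrations with CV >= "
                       f"{cfg.cv_gate:.0f}% (need "
                       f"{cfg.min_eligible_concentrations})")
    return RunAcceptance(
        dncb_cd86_ok=cd86_ok, dncb_cd54_ok=cd54_ok,
        dncb_viability_ok=dncb_viab_ok, vehicle_viability_ok=veh_ok,
        n_conc_cv_ok=n_ok, dncb_viability_pct=dncb_viability,
        vehicle_viability_pct=vehicle_viability,
        n_eligible_concentrations=n_eligible,
        accepted=all((cd86_ok, cd54_ok, dncb_viab_ok, veh_ok, n_ok)),
        reasons=tuple(reasons),
    )


def score_run(run_id: int,
              concentration_results: Sequence[ConcentrationResult],
              acceptance: Optional[RunAcceptance] = None,
              ec150: Optional[EcRunResult] = None,
              ec200: Optional[EcRunResult] = None,
              cv_gate: float = CV_GATE) -> RunResult:
    """Assemble a RunResult: per-marker positivity and the run call."""
    cd86 = marker_positive(concentration_results, "CD86", cv_gate=cv_gate)
    cd54 = marker_positive(concentration_results, "CD54", cv_gate=cv_gate)
    return RunResult(
        run_id=run_id,
        concentration_results=tuple(concentration_results),
        cd86_positive=cd86, cd54_positive=cd54, run_call=cd86 or cd54,
        acceptance=acceptance, ec150=ec150, ec200=ec200,
    )


def final_call(run_calls: Sequence[bool],
               allow_early_stop: bool = False) -> tuple[bool, int]:
    """Final prediction from 2 or 3 run calls.

    Three runs decide by majority (>= 2 positive).  Two concordant runs
    decide directly when early stopping is allowed; two discordant runs
    raise ThirdRunRequiredError.
    """
    calls = [bool(c) for c in run_calls]
    if len(calls) == 3:
        return sum(calls) >= 2, 3
    if len(calls) == 2:
        if calls[0] == calls[1] and allow_early_stop:
            return calls[0], 2
        if calls[0] != calls[1]:
            raise ThirdRunRequiredError(
                "two discordant runs: a third run is required")
        raise ThirdRunRequiredError(
            "early stopping not allowed: a third run is required")
    raise ValueError(f"need 2 or 3 run calls, got {len(calls)}")


def classify_substance(substance: str,
                       runs: Sequence[RunResult],
                       allow_early_stop: bool = False) -> SubstancePrediction:
    """Final sensitizer call with final ECs averaged over positive runs.

    Runs failing acceptance are excluded (never imputed); fewer than two
    usable runs raise InsufficientRunsError.  Negative substances carry
    undefined final ECs.
    """
    usable = [r for r in runs
              if r.acceptance is None or r.acceptance.accepted]
    excluded = tuple(r.run_id for r in runs
                     if r.acceptance is not None and not r.acceptance.accepted)
    if len(usable) < 2:
        raise InsufficientRunsError(
            f"{substance}: only {len(usable)} accepted runs; "
            "at least 2 are required")
    calls = [r.run_call for r in usable]
    call, n_used = final_call(calls, allow_early_stop=allow_early_stop)

    ec150 = ec200 = None
    if call:
        ec150 = final_ec(
            [r.ec150.value if r.ec150 else None for r in usable],
            [r.cd86_positive for r in usable],
        )
        ec200 = final_ec(
            [r.ec200.value if r.ec200 else None for r in usable],
            [r.cd54_positive for r in usable],
        )
    return SubstancePrediction(
        substance=substance, run_calls=tuple(calls),
        final_call="Positive" if call else "Negative",
        n_runs_used=n_used, final_ec150=ec150, final_ec200=ec200,
        excluded_runs=excluded,
    )


def _in_range(value: float,
              bounds: tuple[Optional[float], Optional[float]]) -> bool:
    lo, hi = bounds
    return (lo is None or value >= lo) and (hi is None or value <= hi)


@dataclass(frozen=True)
class ProficiencyResult:
    """Observed proficiency-substance outcome to be checked against reference.

    ``cv75_censored`` marks a CV75 recorded as ">top tested" (no toxicity
    fallback); censored values cannot confirm a range and skip the check.
    """

    substance: str
    call: str
    cv75: Optional[float] = None
    cv75_censored: bool = False
    ec150: Optional[float] = None
    ec200: Optional[float] = None


def evaluate_proficiency(
    results: Sequence[ProficiencyResult],
    references: Sequence[ProficiencyReference],
) -> list[ProficiencyOutcome]:
    """Check each substance's call and ranges against its reference.

    Range checks are skipped (reported as None) when the observed value is
    censored or undefined, and for markers the guideline flags historically
    negative; overall pass requires the call match plus every applicable
    range check.
    """
    by_name = {r.substance: r for r in references}
    outcomes: list[ProficiencyOutcome] = []
    for res in results:
        ref = by_name.get(res.substance)
        if ref is None:
            outcomes.append(ProficiencyOutcome(
                substance=res.substance, call=res.call, expected_call="?",
                call_match=False, cv75_in_range=None, ec150_in_range=None,
                ec200_in_range=None, passed=False,
                notes=("no reference for this substance",),
            ))
            continue
        notes: list[str] = []
        call_match = res.call == ref.expected_call

        cv75_ok: Optional[bool] = None
        if res.cv75 is not None and not res.cv75_censored:
            cv75_ok = _in_range(res.cv75, ref.cv75_range)
        elif res.cv75_censored:
            notes.append("CV75 censored at top tested dose; range not checked")

        ec150_ok: Optional[bool] = None
        if ref.ec150_historically_negative:
            notes.append("CD86 historically negative; EC150 range non-gating")
        elif res.ec150 is not None:
            ec150_ok = _in_range(res.ec150, ref.ec150_range)

        ec200_ok: Optional[bool] = None
        if ref.ec200_historically_negative:
            notes.append("CD54 historically negative; EC200 range non-gating")
        elif res.ec200 is not None:
            ec200_ok = _in_range(res.ec200, ref.ec200_range)

        applicable = [f for f in (cv75_ok, ec150_ok, ec200_ok) if f is not None]
        outcomes.append(ProficiencyOutcome(
            substance=res.substance, call=res.call,
            expected_call=ref.expected_call, call_match=call_match,
            cv75_in_range=cv75_ok, ec150_in_range=ec150_ok,
            ec200_in_range=ec200_ok,
            passed=call_match and all(applicable),
            notes=tuple(notes),
        ))
    return outcomes
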