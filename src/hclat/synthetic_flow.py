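"""Synthetic flow-cytometry event generator for the h-CLAT workflow.

The h-CLAT measures upregulation of the dendritic-cell activation markers
CD86 and CD54 on THP-1 cells after 24 h exposure to a test substance.  This
module generates event-level tubes (per-event FITC intensity plus a
propidium-iodide dead/alive flag) for an entire study — dose-finding runs,
main runs with CD86/CD54/isotype staining, DNCB positive controls, vehicle
controls and particle-only interference tubes — from a fully specified
ground truth, so every downstream stage can be tested against closed-form
answers.

Ground-truth model
------------------
* Cytotoxicity is log-logistic: viability(c) = 100 / (1 + (c/lc50)^h).
* Marker induction is Hill-shaped on the RFI scale:
  RFI_m(c) = 100 + (rmax_m - 100) * c^h_m / (c^h_m + k_m^h_m).
* Event intensities are lognormal around the tube's target MFI, so the
  geometric mean of a tube estimates its target.
* Between-run variability is a single multiplicative factor on the
  induction amplitude (RFI - 100), shared by all tubes of a run.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

MARKERS = ("CD86", "CD54")
STAINS = ("CD86", "CD54", "isotype", "unstained")
ROLES = ("test", "vehicle", "dncb_positive_control", "dmso_vehicle", "np_only")
#: roles whose tubes are unexposed controls and must carry concentration 0
VEHICLE_ROLES = ("vehicle", "dmso_vehicle")


@dataclass(frozen=True)
class HillInduction:
    """Hill parameters for one marker's induction curve (RFI scale).

    rmax is the RFI plateau in percent (>= 100, i.e. at least baseline),
    k the half-max concentration in ug/ml and hill the unitless slope.
    """

    rmax: float
    k: float
    hill: float

    def __post_init__(self) -> None:
        if self.rmax < 100:
            raise ValueError(f"rmax must be >= 100 (baseline), got {self.rmax}")
        if self.k <= 0 or self.hill <= 0:
            raise ValueError("k and hill must be strictly positive")


@dataclass(frozen=True)
class TruthModel:
    """Complete ground truth for a simulated h-CLAT study.

    Defaults emulate a moderately cytotoxic, clearly sensitizing metal-oxide
    particle: CV75 near 26 ug/ml and both markers induced well above their
    positivity thresholds inside the main dilution series.
    """

    lc50: float = 44.7           # ug/ml, viability midpoint
    hill_tox: float = 2.0        # log-logistic slope, unitless
    markers: Mapping[str, HillInduction] = field(
        default_factory=lambda: {
            "CD86": HillInduction(rmax=350.0, k=20.0, hill=1.8),
            "CD54": HillInduction(rmax=4500.0, k=65.0, hill=2.0),
        }
    )
    mfi_vehicle: float = 300.0   # a.u., stained vehicle-control signal
    mfi_isotype: float = 50.0    # a.u., isotype-control background
    mfi_unstained: float = 40.0  # a.u., cellular autofluorescence
    buffer_mfi: float = 5.0      # a.u., cell-free buffer background
    np_autofluorescence: float = 0.0  # a.u. per ug/ml added to np_only tubes
    sigma_log: float = 0.15      # lognormal event spread, log10 a.u.
    run_cv: float = 0.10         # between-run amplitude noise (fraction)
    vehicle_viability: float = 96.5  # %, vehicle/DMSO control viability
    dncb_rfi: Mapping[str, float] = field(
        default_factory=lambda: {"CD86": 611.0, "CD54": 426.0}
    )
    dncb_viability: float = 83.0  # %, viability under 4 ug/ml DNCB
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("lc50", self.lc50),
            ("mfi_vehicle", self.mfi_vehicle),
            ("mfi_isotype", self.mfi_isotype),
            ("mfi_unstained", self.mfi_unstained),
            ("buffer_mfi", self.buffer_mfi),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.hill_tox < 0:
            raise ValueError("hill_tox must be >= 0")
        if self.sigma_log < 0 or self.run_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if set(self.markers) != set(MARKERS):
            raise ValueError(f"markers must be exactly {MARKERS}")
        if self.mfi_vehicle <= self.mfi_isotype:
            raise ValueError("mfi_vehicle must exceed mfi_isotype "
                             "(RFI denominator must be positive)")


@dataclass(frozen=True)
class EventSample:
    """One cytometry tube: per-event FITC intensities and PI flags."""

    fitc: np.ndarray
    pi_positive: np.ndarray
    substance: str
    concentration: float
    stain: str
    role: str
    run_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fitc", np.asarray(self.fitc, dtype=float))
        object.__setattr__(
            self, "pi_positive", np.asarray(self.pi_positive, dtype=bool)
        )
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.role in VEHICLE_ROLES and self.concentration != 0:
            raise ValueError("vehicle-role tubes must have concentration 0")
        if self.role == "np_only":
            if self.pi_positive.size != 0:
                raise ValueError("np_only tubes contain no cells: pi_positive "
                                 "must be empty")
            if self.fitc.size < 1:
                raise ValueError("np_only tube needs >= 1 background reading")
        else:
            if self.fitc.size != self.pi_positive.size:
                raise ValueError("fitc and pi_positive must have equal length")
            if self.fitc.size < 1:
                raise ValueError("tube must contain >= 1 event")

    @property
    def n_events(self) -> int:
        return int(self.fitc.size)


def truth_viability(truth: TruthModel, conc: float) -> float:
    """Expected viability (%) at ``conc`` under the log-logistic model."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return 100.0
    return 100.0 / (1.0 + (conc / truth.lc50) ** truth.hill_tox)


def truth_rfi(truth: TruthModel, marker: str, conc: float) -> float:
    """Expected RFI (%) of ``marker`` at ``conc`` under the Hill model."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    m = truth.markers[marker]
    if conc == 0:
        return 100.0
    ch = conc ** m.hill
    return 100.0 + (m.rmax - 100.0) * ch / (ch + m.k ** m.hill)


def truth_ec(truth: TruthModel, marker: str, threshold: float) -> float | None:
    """Closed-form effective concentration at which RFI reaches ``threshold``.

    Inverts the Hill induction curve; returns None when the plateau never
    reaches the threshold (no such concentration exists).
    """
    if threshold <= 100:
        raise ValueError("threshold must exceed the 100% baseline")
    m = truth.markers[marker]
    if m.rmax <= threshold:
        return None
    return m.k * ((threshold - 100.0) / (m.rmax - threshold)) ** (1.0 / m.hill)


def truth_cv75(truth: TruthModel) -> float:
    """Concentration giving 75% viability: the inverse of truth_viability."""
    return truth.lc50 * (1.0 / 3.0) ** (1.0 / truth.hill_tox)


def _tube_rng(seed: int, substance: str, run_id: int, conc: float,
              stain: str, role: str) -> np.random.Generator:
    """Per-tube random stream derived from tube identity, not tube order."""
    key = f"{substance}|{run_id}|{conc:.12g}|{stain}|{role}".encode()
    digest = int.from_bytes(hashlib.sha256(key).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def run_factor(truth: TruthModel, run_id: int, seed: int | None = None) -> float:
    """Multiplicative induction-amplitude factor shared by one run.

    Lognormal with unit mean; sigma is ``truth.run_cv``. Zero run_cv gives
    exactly 1.0.
    """
    if truth.run_cv == 0:
        return 1.0
    rng = _tube_rng(truth.seed if seed is None else seed,
                    "__run_factor__", run_id, 0.0, "unstained", "test")
    sigma = truth.run_cv
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _target_mfi(truth: TruthModel, conc: float, stain: str, role: str,
                factor: float) -> float:
    """Expected (geometric-mean) MFI for a tube of the given identity."""
    if role == "np_only":
        return truth.buffer_mfi + truth.np_autofluorescence * conc
    if stain == "unstained":
        return truth.mfi_unstained
    if stain == "isotype":
        return truth.mfi_isotype
    # CD86 / CD54 stain: place the tube so that its isotype-corrected RFI
    # against the stained vehicle equals the (run-scaled) truth RFI.
    if role in VEHICLE_ROLES:
        rfi = 100.0
    elif role == "dncb_positive_control":
        rfi = 100.0 + (truth.dncb_rfi[stain] - 100.0) * factor
    else:
        rfi = 100.0 + (truth_rfi(truth, stain, conc) - 100.0) * factor
    return truth.mfi_isotype + (truth.mfi_vehicle - truth.mfi_isotype) * rfi / 100.0


def _viability_pct(truth: TruthModel, conc: float, role: str) -> float:
    if role in VEHICLE_ROLES:
        return truth.vehicle_viability
    if role == "dncb_positive_control":
        return truth.dncb_viability
    return truth_viability(truth, conc)


def simulate_tube(truth: TruthModel, substance: str, conc: float, stain: str,
                  role: str, run_id: int, n_events: int,
                  seed: int | None = None) -> EventSample:
    """Draw one tube of events.

    FITC intensities are lognormal around the stain-appropriate target so the
    tube's geometric mean estimates the target MFI; each event is PI-positive
    with probability 1 - viability/100.  Reproducible: the random stream is a
    deterministic function of (seed, substance, run_id, conc, stain, role),
    never of tube order.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if stain not in STAINS:
        raise ValueError(f"unknown stain {stain!r}")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    seed = truth.seed if seed is None else seed
    rng = _tube_rng(seed, substance, run_id, conc, stain, role)
    factor = run_factor(truth, run_id, seed)
    target = _target_mfi(truth, conc, stain, role, factor)
    fitc = 10.0 ** rng.normal(math.log10(target), truth.sigma_log, n_events)
    if role == "np_only":
        pi = np.empty(0, dtype=bool)
    else:
        p_dead = 1.0 - _viability_pct(truth, conc, role) / 100.0
        pi = rng.random(n_events) < p_dead
    return EventSample(fitc=fitc, pi_positive=pi, substance=substance,
                       concentration=conc, stain=stain, role=role,
                       run_id=run_id)


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design of a full h-CLAT study.

    Mirrors the guideline layout: two dose-finding runs of eight two-fold
    dilutions (PI-only tubes), then three main runs of eight 1.2-fold
    concentrations centred on the averaged CV75, each with CD86/CD54/isotype
    tubes, stained vehicle tubes, a DNCB positive control with its DMSO
    vehicle, plus particle-only interference tubes and an unstained-cell
    reference.
    """

    substance: str = "test substance"
    dose_top: float = 1000.0        # ug/ml, top of the dose-finding series
    n_dose_points: int = 8
    dose_dilution: float = 2.0
    n_dose_runs: int = 2
    n_main_points: int = 8
    main_dilution: float = 1.2
    n_main_runs: int = 3
    n_events: int = 4000
    dncb_conc: float = 4.0          # ug/ml
    include_interference: bool = True

    def __post_init__(self) -> None:
        if self.dose_top <= 0:
            raise ValueError("dose_top must be strictly positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class StudySimulation:
    """Simulated study: all tubes plus the simulator's own CV75 bookkeeping."""

    samples: tuple[EventSample, ...]
    truth: TruthModel
    design: StudyDesign
    cv75_per_run: tuple[float, ...]
    cv75: float
    main_concentrations: tuple[float, ...]

    def __iter__(self) -> Iterator[EventSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


def simulate_study(truth: TruthModel, design: StudyDesign | None = None,
                   seed: int | None = None) -> StudySimulation:
    """Simulate a complete study and derive the main series like the assay does.

    The main-run concentrations are not taken from the ground truth: they are
    obtained by running the dose-finding tubes through the same viability
    summarization and CV75 interpolation the analysis pipeline uses, exactly
    as the wet-lab workflow would.
    """
    from . import cytometry_metrics, dose_response

    design = design or StudyDesign()
    seed = truth.seed if seed is None else seed
    samples: list[EventSample] = []

    dose_series = dose_response.twofold_series(
        design.dose_top, design.n_dose_points, design.dose_dilution
    )
    per_run_cv75: list[float] = []
    for run in range(1, design.n_dose_runs + 1):
        run_tubes = [
            simulate_tube(truth, design.substance, c, "unstained", "test",
                          run, design.n_events, seed)
            for c in dose_series.concentrations
        ]
        samples.extend(run_tubes)
        samples.append(simulate_tube(truth, design.substance, 0.0, "unstained",
                                     "vehicle", run, design.n_events, seed))
        viab = {t.concentration: cytometry_metrics.viability(t) for t in run_tubes}
        per_run_cv75.append(dose_response.cv75_from_run(viab).value)

    cv75 = dose_response.average_cv75(per_run_cv75).value
    main = dose_response.main_series(cv75, design.n_main_points,
                                     design.main_dilution)

    stained = ("CD86", "CD54", "isotype")
    for run in range(1, design.n_main_runs + 1):
        for conc in main.concentrations:
            for stain in stained:
                samples.append(simulate_tube(truth, design.substance, conc,
                                             stain, "test", run,
                                             design.n_events, seed))
        for stain in stained:
            samples.append(simulate_tube(truth, design.substance, 0.0, stain,
                                         "vehicle", run, design.n_events, seed))
            samples.append(simulate_tube(truth, design.substance,
                                         design.dncb_conc, stain,
                                         "dncb_positive_control", run,
                                         design.n_events, seed))
            samples.append(simulate_tube(truth, design.substance, 0.0, stain,
                                         "dmso_vehicle", run,
                                         design.n_events, seed))

    if design.include_interference:
        # particle-only tubes carry cell-free background readings; the
        # unstained vehicle tube emitted with dose-finding run 1 serves as
        # the unstained-cell reference for the interference check
        n_bg = min(design.n_events, 1000)
        for conc in main.concentrations:
            samples.append(simulate_tube(truth, design.substance, conc,
                                         "unstained", "np_only", 1, n_bg, seed))

    return StudySimulation(
        samples=tuple(samples), truth=truth, design=design,
        cv75_per_run=tuple(per_run_cv75), cv75=cv75,
        main_concentrations=main.concentrations,
    )
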