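"""Dilution series construction and CV75 estimation.

CV75 — the concentration maintaining 75% viability relative to the vehicle
control — anchors the main h-CLAT dilution series.  The guideline procedure
interpolates between tested doses rather than fitting a parametric curve;
interpolation here is log-linear in concentration by default, the natural
scale for dilution series spanning orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

InterpScale = Literal["log", "linear"]


@dataclass(frozen=True)
class DoseSeries:
    """A geometric dilution series, highest concentration first."""

    concentrations: tuple[float, ...]
    dilution_factor: float
    top: float

    def __post_init__(self) -> None:
        if self.top <= 0:
            raise ValueError("top concentration must be strictly positive")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if any(b >= a for a, b in zip(self.concentrations,
                                      self.concentrations[1:])):
            raise ValueError("concentrations must be strictly decreasing")


@dataclass(frozen=True)
class Cv75Run:
    """CV75 from a single dose-finding run.

    ``no_toxicity_fallback`` marks runs where every tested dose stayed above
    75% viability, so the highest tested concentration stands in for CV75.
    ``out_of_range`` marks runs already below 75% viability at the lowest
    dose, where the lowest dose is returned as a bounding value.
    """

    value: float
    no_toxicity_fallback: bool = False
    out_of_range: bool = False


@dataclass(frozen=True)
class Cv75Estimate:
    """Averaged CV75 over independent dose-finding runs."""

    value: float
    per_run_values: tuple[float, ...]
    no_toxicity_fallback: tuple[bool, ...]


def twofold_series(top: float, n_points: int = 8,
                   dilution: float = 2.0) -> DoseSeries:
    """Dose-finding series: [top, top/2, ..., top/2^(n-1)]."""
    if top <= 0:
        raise ValueError("top concentration must be strictly positive")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    return DoseSeries(
        concentrations=tuple(top / dilution ** i for i in range(n_points)),
        dilution_factor=dilution, top=top,
    )


def main_series(cv75: float, n_points: int = 8,
                dilution: float = 1.2) -> DoseSeries:
    """Main-run series centred on CV75: [1.2*CV75, CV75, ..., CV75/1.2^(n-2)]."""
    if cv75 <= 0:
        raise ValueError("cv75 must be strictly positive")
    top = cv75 * dilution
    return DoseSeries(
        concentrations=tuple(top / dilution ** i for i in range(n_points)),
        dilution_factor=dilution, top=top,
    )


def cv75_from_run(dose_viability: Mapping[float, float],
                  target: float = 75.0,
                  scale: InterpScale = "log") -> Cv75Run:
    """Interpolate the viability-75% crossing from one run's dose curve.

    Scanning from the lowest concentration upward: a tested dose sitting
    exactly at the target is returned as-is; otherwise the first adjacent
    pair bracketing the target is interpolated (log-linearly in
    concentration by default).  With no crossing, either every dose stayed
    above target (no-toxicity fallback: highest dose) or the curve was
    already below target at the lowest dose (out-of-range: lowest dose).
    """
    if len(dose_viability) < 2:
        raise ValueError("need at least 2 tested concentrations")
    concs = sorted(dose_viability)
    if concs[0] <= 0:
        raise ValueError("concentrations must be strictly positive")
    viab = [float(dose_viability[c]) for c in concs]

    for c, v in zip(concs, viab):
        if v == target:
            return Cv75Run(value=c)
    for (c_lo, v_lo), (c_hi, v_hi) in zip(zip(concs, viab),
                                          zip(concs[1:], viab[1:])):
        if v_lo > target > v_hi:
            frac = (v_lo - target) / (v_lo - v_hi)
            if scale == "log":
                value = 10.0 ** (math.log10(c_lo)
                                 + frac * (math.log10(c_hi) - math.log10(c_lo)))
            else:
                value = c_lo + frac * (c_hi - c_lo)
            return Cv75Run(value=value)

    if all(v > target for v in viab):
        return Cv75Run(value=concs[-1], no_toxicity_fallback=True)
    return Cv75Run(value=concs[0], out_of_range=True)


def average_cv75(per_run: Sequence[float | Cv75Run]) -> Cv75Estimate:
    """Unweighted arithmetic mean of per-run CV75 values."""
    if len(per_run) == 0:
        raise ValueError("need at least one run")
    runs = [r if isinstance(r, Cv75Run) else Cv75Run(value=float(r))
            for r in per_run]
    values = tuple(r.value for r in runs)
    return Cv75Estimate(
        value=sum(values) / len(values),
        per_run_values=values,
        no_toxicity_fallback=tuple(r.no_toxicity_fallback for r in runs),
    )
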