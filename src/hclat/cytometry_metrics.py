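"""Reduce event-level tubes to viability (%) and MFI, plus the interference QC.

The assay consumes exactly two numbers per tube: the percentage of
PI-negative (live) events, and the mean fluorescence intensity of the live
gate.  MFI defaults to the geometric mean — the conventional summary for
lognormally distributed cytometry fluorescence — with the arithmetic mean
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic_flow import EventSample

MfiMethod = Literal["geometric", "arithmetic"]

#: intensities below this are clamped before taking logs for the geometric
#: mean, so zero/negative a.u. readings cannot poison the summary
GEOMETRIC_FLOOR = 1.0


@dataclass(frozen=True)
class TubeSummary:
    """Per-tube summary: MFI (a.u.), viability (%) and event count.

    ``viability_pct`` is NaN for cell-free (np_only) tubes; ``mfi`` is NaN
    when a tube has no viable events to summarize.
    """

    mfi: float
    viability_pct: float
    n_events: int
    substance: str
    concentration: float
    stain: str
    role: str
    run_id: int
    mfi_method: MfiMethod = "geometric"


def viability(sample: EventSample) -> float:
    """Percentage of PI-negative events: 100 * live / total, exactly."""
    if sample.role == "np_only":
        raise ValueError("np_only tubes contain no cells; viability is undefined")
    n = sample.pi_positive.size
    if n < 1:
        raise ValueError("empty tube: no events to gate")
    return 100.0 * float(np.count_nonzero(~sample.pi_positive)) / n


def mfi(sample: EventSample, method: MfiMethod = "geometric") -> float:
    """MFI over PI-negative (viable) events.

    np_only tubes have no PI gate; their MFI summarizes all background
    readings.  Returns NaN when no viable events remain (undefined summary).
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown MFI method {method!r}")
    if sample.role == "np_only":
        values = sample.fitc
    else:
        values = sample.fitc[~sample.pi_positive]
    if values.size == 0:
        return float("nan")
    if method == "arithmetic":
        return float(np.mean(values))
    clamped = np.maximum(values, GEOMETRIC_FLOOR)
    return float(10.0 ** np.mean(np.log10(clamped)))


def summarize(sample: EventSample, method: MfiMethod = "geometric") -> TubeSummary:
    """Reduce one tube to its TubeSummary."""
    viab = float("nan") if sample.role == "np_only" else viability(sample)
    return TubeSummary(
        mfi=mfi(sample, method), viability_pct=viab, n_events=sample.n_events,
        substance=sample.substance, concentration=sample.concentration,
        stain=sample.stain, role=sample.role, run_id=sample.run_id,
        mfi_method=method,
    )


def interference_check(np_tubes: Sequence[EventSample],
                       unstained: EventSample,
                       ratio: float = 1.5) -> dict[float, bool]:
    """Flag particle autofluorescence against an unstained-cell reference.

    A concentration is interfering when its cell-free background MFI
    strictly exceeds ``ratio`` times the unstained reference; a ratio exactly
    at the threshold is clear.  Returns {concentration: interfering?}.
    """
    if unstained is None:
        raise ValueError("missing unstained reference tube")
    if unstained.stain != "unstained":
        raise ValueError("reference tube must be unstained")
    tubes = [t for t in np_tubes if t.role == "np_only"]
    if not tubes:
        raise ValueError("no np_only tubes to check")
    ref = mfi(unstained)
    flags = {}
    for t in tubes:
        r = mfi(t) / ref
        # strict inequality; tolerance absorbs the geometric mean's
        # log/exp round-trip so a ratio exactly at threshold stays clear
        flags[t.concentration] = r > ratio and not math.isclose(
            r, ratio, rel_tol=1e-9)
    return flags


def summaries_to_frame(summaries: Iterable[TubeSummary]) -> pd.DataFrame:
    """Tabulate summaries with one row per tube."""
    rows = [
        {
            "substance": s.substance, "run_id": s.run_id, "role": s.role,
            "stain": s.stain, "concentration_ug_ml": s.concentration,
            "mfi": s.mfi, "viability_pct": s.viability_pct,
            "n_events": s.n_events, "mfi_method": s.mfi_method,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
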