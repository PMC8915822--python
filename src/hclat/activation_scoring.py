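"""Isotype-corrected RFI scoring and EC150/EC200 derivation.

RFI (relative fluorescence intensity) expresses a marker's induction as the
isotype-corrected test MFI relative to the isotype-corrected vehicle MFI:

    RFI% = 100 * (MFI_test - MFI_isotype_test)
               / (MFI_vehicle - MFI_isotype_vehicle)

with the isotype tube matched to the test tube's concentration.  EC150
(CD86) and EC200 (CD54) are the concentrations at which RFI reaches the
respective positivity threshold, interpolated linearly between tested doses
among concentrations passing the viability gate (CV >= 50%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

InterpScale = Literal["linear", "log"]


@dataclass(frozen=True)
class ConcentrationResult:
    """Scored quantities for one tested concentration of one run."""

    concentration: float
    cv_pct: float
    rfi_cd86: Optional[float]
    rfi_cd54: Optional[float]
    flags: tuple[str, ...] = ()

    def rfi(self, marker: str) -> Optional[float]:
        if marker == "CD86":
            return self.rfi_cd86
        if marker == "CD54":
            return self.rfi_cd54
        raise ValueError(f"unknown marker {marker!r}")


@dataclass(frozen=True)
class EcRunResult:
    """EC estimate from a single run.

    ``value`` is None when no gated concentration reached the threshold or
    no concentration passed the viability gate at all (``no_eligible``).
    ``below_lowest`` marks runs where even the lowest gated concentration
    met the threshold, so the EC is censored at that concentration.
    """

    value: Optional[float]
    below_lowest: bool = False
    no_eligible: bool = False


@dataclass(frozen=True)
class EcEstimate:
    """Per-marker EC across runs plus the final average over positive runs."""

    marker: str
    threshold: float
    per_run: tuple[tuple[int, Optional[float]], ...]
    final: Optional[float]


def rfi(mfi_test: float, mfi_isotype_test: float, mfi_vehicle: float,
        mfi_isotype_vehicle: float) -> Optional[float]:
    """Isotype-corrected RFI in percent.

    Returns None (undefined — a QC failure) when the corrected vehicle
    denominator is not positive; a negative corrected test signal is
    reported as 0%.
    """
    for name, v in (("mfi_test", mfi_test),
                    ("mfi_isotype_test", mfi_isotype_test),
                    ("mfi_vehicle", mfi_vehicle),
                    ("mfi_isotype_vehicle", mfi_isotype_vehicle)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    denom = mfi_vehicle - mfi_isotype_vehicle
    if denom <= 0:
        return None
    num = mfi_test - mfi_isotype_test
    if num < 0:
        return 0.0
    return 100.0 * num / denom


def ec_from_run(dose_rfi: Mapping[float, Optional[float]],
                dose_cv: Mapping[float, float],
                threshold: float,
                cv_gate: float = 50.0,
                scale: InterpScale = "linear") -> EcRunResult:
    """Effective concentration at which RFI reaches ``threshold`` in one run.

    Only concentrations with viability >= ``cv_gate`` (and a defined RFI)
    are considered.  Scanning from the lowest eligible concentration upward,
    the first pair bracketing the threshold is interpolated linearly in
    concentration (configurable to log scale).  A run whose lowest eligible
    concentration already meets the threshold yields that concentration,
    censored (``below_lowest``).
    """
    if threshold <= 100:
        raise ValueError("threshold must exceed the 100% baseline")
    if len(dose_rfi) < 2:
        raise ValueError("need at least 2 tested concentrations")
    eligible = sorted(
        c for c, r in dose_rfi.items()
        if r is not None and dose_cv.get(c, float("-inf")) >= cv_gate
    )
    if not eligible:
        return EcRunResult(value=None, no_eligible=True)
    rfis = [float(dose_rfi[c]) for c in eligible]

    if all(r < threshold for r in rfis):
        return EcRunResult(value=None)
    if rfis[0] >= threshold:
        return EcRunResult(value=eligible[0], below_lowest=True)
    for (c_b, r_b), (c_a, r_a) in zip(zip(eligible, rfis),
                                      zip(eligible[1:], rfis[1:])):
        if r_b < threshold <= r_a:
            frac = (threshold - r_b) / (r_a - r_b)
            if scale == "log":
                value = 10.0 ** (math.log10(c_b)
                                 + frac * (math.log10(c_a) - math.log10(c_b)))
            else:
                value = c_b + frac * (c_a - c_b)
            return EcRunResult(value=value)
    raise AssertionError("unreachable: a first upward crossing must exist")


def final_ec(per_run: Sequence[Optional[float]],
             marker_positive_flags: Sequence[bool]) -> Optional[float]:
    """Final EC: arithmetic mean over marker-positive runs with a defined EC.

    Runs negative for this marker contribute nothing even when the substance
    is positive overall via the other marker.  Returns None when no positive
    run has a defined EC.
    """
    if len(per_run) != len(marker_positive_flags):
        raise ValueError("per_run and marker_positive_flags must align by run")
    used = [ec for ec, pos in zip(per_run, marker_positive_flags)
            if pos and ec is not None]
    if not used:
        return None
    return sum(used) / len(used)


def ec_estimate(marker: str, threshold: float,
                per_run: Sequence[tuple[int, Optional[float]]],
                marker_positive_flags: Sequence[bool]) -> EcEstimate:
    """Bundle per-run ECs with their final average."""
    return EcEstimate(
        marker=marker, threshold=threshold, per_run=tuple(per_run),
        final=final_ec([ec for _, ec in per_run], marker_positive_flags),
    )
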