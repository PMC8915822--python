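"""Readers and writers: event tables, summary tables, bundled printed-table
fixtures, ground-truth sidecars, and report-layer rounding.

Two entry tiers exist.  The event tier carries one CSV row per cytometry
event (columns: substance, run_id, role, stain, concentration_ug_ml, fitc,
pi_positive) and exists for simulation-based testing.  The summary tier
carries per-tube MFI/viability rows — or pre-computed per-concentration RFI
rows — so published result tables can be analyzed without raw events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import prediction_engine as pe
from .activation_scoring import ConcentrationResult, EcRunResult
from .cytometry_metrics import TubeSummary
from .synthetic_flow import (EventSample, HillInduction, TruthModel,
                             ROLES, STAINS)

EVENT_COLUMNS = ("substance", "run_id", "role", "stain",
                 "concentration_ug_ml", "fitc", "pi_positive")
SUMMARY_COLUMNS = ("substance", "run_id", "role", "stain",
                   "concentration_ug_ml", "mfi", "viability_pct")
RFI_COLUMNS = ("substance", "run_id", "concentration_ug_ml", "cv_pct",
               "rfi_cd86", "rfi_cd54")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2.5 -> 3), the convention for reported ECs.

    Report-layer only: rounded values are never fed back into computation.
    """
    scale = 10.0 ** decimals
    scaled = x * scale
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / scale


# ---------------------------------------------------------------------------
# event tier

def write_event_table(samples: Sequence[EventSample], path: str | Path) -> None:
    """One CSV row per event; np_only tubes leave pi_positive empty."""
    frames = []
    for s in samples:
        n = s.fitc.size
        frames.append(pd.DataFrame({
            "substance": s.substance, "run_id": s.run_id, "role": s.role,
            "stain": s.stain, "concentration_ug_ml": s.concentration,
            "fitc": s.fitc,
            "pi_positive": (pd.array([pd.NA] * n) if s.role == "np_only"
                            else s.pi_positive.astype(int)),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_event_table(path: str | Path) -> list[EventSample]:
    """Parse and validate an event CSV back into tubes.

    Malformed rows are reported with 1-based data line numbers; unknown
    stain/role labels and negative concentrations are hard errors.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no tubes (empty event table)")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    for col, allowed in (("stain", STAINS), ("role", ROLES)):
        bad = df.loc[~df[col].isin(allowed)]
        if not bad.empty:
            row = int(bad.index[0]) + 1
            raise ValueError(
                f"{path}: unknown {col} {bad[col].iloc[0]!r} at data row {row}")
    neg = df.loc[df["concentration_ug_ml"] < 0]
    if not neg.empty:
        row = int(neg.index[0]) + 1
        raise ValueError(f"{path}: negative concentration at data row {row}")

    samples = []
    keys = ["substance", "run_id", "role", "stain", "concentration_ug_ml"]
    for (substance, run_id, role, stain, conc), grp in df.groupby(
            keys, sort=False):
        if role == "np_only":
            pi = np.empty(0, dtype=bool)
        else:
            if grp["pi_positive"].isna().any():
                row = int(grp.index[grp["pi_positive"].isna()][0]) + 1
                raise ValueError(
                    f"{path}: missing pi_positive at data row {row}")
            pi = grp["pi_positive"].astype(float).astype(bool).to_numpy()
        samples.append(EventSample(
            fitc=grp["fitc"].to_numpy(dtype=float), pi_positive=pi,
            substance=str(substance), concentration=float(conc),
            stain=str(stain), role=str(role), run_id=int(run_id),
        ))
    return samples


# ---------------------------------------------------------------------------
# ground-truth sidecar

def truth_to_dict(truth: TruthModel) -> dict:
    d = {
        "lc50": truth.lc50, "hill_tox": truth.hill_tox,
        "markers": {m: {"rmax": h.rmax, "k": h.k, "hill": h.hill}
                    for m, h in truth.markers.items()},
        "mfi_vehicle": truth.mfi_vehicle, "mfi_isotype": truth.mfi_isotype,
        "mfi_unstained": truth.mfi_unstained, "buffer_mfi": truth.buffer_mfi,
        "np_autofluorescence": truth.np_autofluorescence,
        "sigma_log": truth.sigma_log, "run_cv": truth.run_cv,
        "vehicle_viability": truth.vehicle_viability,
        "dncb_rfi": dict(truth.dncb_rfi),
        "dncb_viability": truth.dncb_viability, "seed": truth.seed,
    }
    return d


def truth_from_dict(data: dict) -> TruthModel:
    data = dict(data)
    if "markers" in data:
        data["markers"] = {m: HillInduction(**h)
                           for m, h in data["markers"].items()}
    return TruthModel(**data)


def write_truth(truth: TruthModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth_to_dict(truth), fh, sort_keys=True)


def read_truth(path: str | Path) -> TruthModel:
    with open(path) as fh:
        return truth_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# summary tier

@dataclass(frozen=True)
class SummaryTable:
    """Parsed summary-tier input.

    ``mode`` is "mfi" (per-tube summaries, the rfi op still applies) or
    "rfi" (pre-computed per-concentration RFIs that bypass it).
    """

    mode: str
    tubes: tuple[TubeSummary, ...] = ()
    concentration_results: tuple[tuple[str, int, ConcentrationResult], ...] = ()


def read_summary_table(path: str | Path) -> SummaryTable:
    """Read per-tube MFI/viability rows or pre-computed RFI rows.

    A file mixing both schemas is rejected: the two modes answer different
    questions and cannot be combined row-wise.
    """
    df = pd.read_csv(path, na_values=["N/A"])
    has_mfi = "mfi" in df.columns
    has_rfi = "rfi_cd86" in df.columns or "rfi_cd54" in df.columns
    if has_mfi and has_rfi:
        raise ValueError(f"{path}: mixed MFI and RFI modes in one file")
    if has_mfi:
        missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        tubes = tuple(
            TubeSummary(
                mfi=float(r.mfi), viability_pct=float(r.viability_pct),
                n_events=int(getattr(r, "n_events", 0) or 0),
                substance=str(r.substance),
                concentration=float(r.concentration_ug_ml),
                stain=str(r.stain), role=str(r.role), run_id=int(r.run_id),
            )
            for r in df.itertuples()
        )
        return SummaryTable(mode="mfi", tubes=tubes)
    if has_rfi:
        missing = [c for c in RFI_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        results = tuple(
            (str(r.substance), int(r.run_id), ConcentrationResult(
                concentration=float(r.concentration_ug_ml),
                cv_pct=float(r.cv_pct),
                rfi_cd86=None if pd.isna(r.rfi_cd86) else float(r.rfi_cd86),
                rfi_cd54=None if pd.isna(r.rfi_cd54) else float(r.rfi_cd54),
            ))
            for r in df.itertuples()
        )
        return SummaryTable(mode="rfi", concentration_results=results)
    raise ValueError(f"{path}: neither MFI nor RFI schema recognized")


# ---------------------------------------------------------------------------
# bundled printed-table fixtures

def _load_bundled(name: str) -> pd.DataFrame:
    with resources.files("hclat.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str).convert_dtypes()


def load_table1_fixture() -> pd.DataFrame:
    """Proficiency-substance results: per-run CV75 and marker RFI maxima."""
    return _load_bundled("table1_proficiency.csv")


def load_table2_fixture() -> pd.DataFrame:
    """Nanoparticle results: per-run RFI maxima and per-run EC150/EC200."""
    return _load_bundled("table2_nanoparticles.csv")


def load_reference_ranges(path: str | Path | None = None
                          ) -> list[pe.ProficiencyReference]:
    """Guideline reference ranges for the eight proficiency substances.

    ``path`` replaces the bundled table with a user CSV of the same schema.
    """
    if path is None:
        df = _load_bundled("reference_ranges.csv")
    else:
        df = pd.read_csv(path, dtype=str).convert_dtypes()

    def bound(v) -> Optional[float]:
        return None if pd.isna(v) or v == "" else float(v)

    refs = []
    for r in df.itertuples():
        refs.append(pe.ProficiencyReference(
            substance=str(r.substance), expected_call=str(r.expected_call),
            cv75_range=(bound(r.cv75_low), bound(r.cv75_high)),
            ec150_range=(bound(r.ec150_low), bound(r.ec150_high)),
            ec200_range=(bound(r.ec200_low), bound(r.ec200_high)),
            ec150_historically_negative=str(r.ec150_historically_negative)
            .lower() == "true",
            ec200_historically_negative=str(r.ec200_historically_negative)
            .lower() == "true",
        ))
    return refs


def _parse_number(value) -> Optional[float]:
    """Parse a printed table cell: 'N/A' -> None, '>x' -> x (censored)."""
    if value is None or pd.isna(value):
        return None
    s = str(value).strip()
    if s in ("N/A", "NA", ""):
        return None
    return float(s.lstrip(">").replace(",", ""))


def _is_censored(value) -> bool:
    return isinstance(value, str) and value.strip().startswith(">")


def predictions_from_run_maxima(df: pd.DataFrame,
                                cd86_threshold: float = 150.0,
                                cd54_threshold: float = 200.0,
                                allow_early_stop: bool = False,
                                ) -> dict[str, pe.SubstancePrediction]:
    """Apply the prediction model to printed per-run maxima.

    Expects columns substance, run_id, cd86_rfi_max_pct, cd54_rfi_max_pct and
    (optionally) ec150_ug_ml / ec200_ug_ml per run, plus an optional size_nm
    column folded into the substance key.  Viability is taken as passing the
    gate: published maxima are only reported at gated concentrations.
    """
    df = df.copy()
    if "size_nm" in df.columns:
        df["__key"] = df["substance"].astype(str) + " " + \
            df["size_nm"].astype(str) + " nm"
    else:
        df["__key"] = df["substance"].astype(str)

    out: dict[str, pe.SubstancePrediction] = {}
    for key, grp in df.groupby("__key", sort=False):
        runs = []
        for r in grp.sort_values("run_id").itertuples():
            cd86 = _parse_number(r.cd86_rfi_max_pct)
            cd54 = _parse_number(r.cd54_rfi_max_pct)
            cr = ConcentrationResult(
                concentration=float("nan"), cv_pct=100.0,
                rfi_cd86=cd86, rfi_cd54=cd54)
            ec150 = (EcRunResult(_parse_number(r.ec150_ug_ml))
                     if hasattr(r, "ec150_ug_ml") else None)
            ec200 = (EcRunResult(_parse_number(r.ec200_ug_ml))
                     if hasattr(r, "ec200_ug_ml") else None)
            runs.append(pe.RunResult(
                run_id=int(r.run_id), concentration_results=(cr,),
                cd86_positive=cd86 is not None and cd86 >= cd86_threshold,
                cd54_positive=cd54 is not None and cd54 >= cd54_threshold,
                run_call=(cd86 is not None and cd86 >= cd86_threshold)
                or (cd54 is not None and cd54 >= cd54_threshold),
                ec150=ec150, ec200=ec200,
            ))
        out[key] = pe.classify_substance(key, runs,
                                         allow_early_stop=allow_early_stop)
    return out


def proficiency_from_table1(df: pd.DataFrame | None = None,
                            references: Sequence[pe.ProficiencyReference]
                            | None = None) -> list[pe.ProficiencyOutcome]:
    """Evaluate the bundled proficiency results against reference ranges.

    Per substance: run calls from RFI maxima, a 2-run early-stop final call,
    the mean CV75 (censored when recorded as '>top'), and the published
    averaged EC150/EC200.
    """
    df = load_table1_fixture() if df is None else df
    references = load_reference_ranges() if references is None else references

    results = []
    for substance, grp in df.groupby("substance", sort=False):
        grp = grp.sort_values("run_id")
        calls = [
            (_parse_number(r.cd86_rfi_max_pct) or 0) >= 150.0
            or (_parse_number(r.cd54_rfi_max_pct) or 0) >= 200.0
            for r in grp.itertuples()
        ]
        call, _ = pe.final_call(calls, allow_early_stop=True)
        censored = any(_is_censored(v) for v in grp["cv75_ug_ml"])
        cv75_vals = [_parse_number(v) for v in grp["cv75_ug_ml"]]
        cv75 = (sum(cv75_vals) / len(cv75_vals)
                if all(v is not None for v in cv75_vals) else None)
        results.append(pe.ProficiencyResult(
            substance=str(substance),
            call="Positive" if call else "Negative",
            cv75=cv75, cv75_censored=censored,
            ec150=_parse_number(grp["ec150_ug_ml"].iloc[0]),
            ec200=_parse_number(grp["ec200_ug_ml"].iloc[0]),
        ))
    return pe.evaluate_proficiency(results, references)
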