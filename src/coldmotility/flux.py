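"""Mitochondrial respiration parameters from phase-labeled OCR/ECAR traces.

A mito-stress-test trace has four phases in fixed injection order — basal,
oligomycin (ATP-synthase inhibitor), FCCP (uncoupler), rotenone/antimycin A
(complex I+III inhibitors) — and the derived parameters follow the standard
report conventions:

    non-mitochondrial OCR = rotAA level
    basal respiration     = basal level - nonmito
    proton leak           = oligomycin level - nonmito
    ATP-linked            = basal level - oligomycin level
    maximal respiration   = FCCP level - nonmito
    spare capacity        = maximal - basal   (also as % of basal)

so that ATP-linked + proton leak = basal respiration identically.  Phase
levels default to the report-generator rules (last basal cycle, minimum
post-oligomycin, maximum post-FCCP, mean of rotAA cycles); a mean-of-phase
alternative is available and the chosen rule is carried in the output.
Negative post-subtraction values are reported with a warning, never clamped,
so QC can flag bad wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import welch_t_test
from .synthetic import FLUX_PHASES

__all__ = ["FluxParameters", "phase_summary", "compute_parameters", "group_flux"]

PHASE_RULES = ("report", "phase_mean")


@dataclass
class FluxParameters:
    """Derived respiration parameters for one well (OCR units)."""

    basal_respiration: float
    atp_linked: float
    proton_leak: float
    maximal_respiration: float
    spare_capacity_abs: float
    spare_capacity_pct: float
    nonmito: float
    protein_normalized: bool = False
    level_rule: str = "report"


def _validate_trace(trace: pd.DataFrame) -> None:
    required = {"phase", "ocr", "cycle"}
    missing = required - set(trace.columns)
    if missing:
        raise ValueError(f"trace missing columns: {sorted(missing)}")
    present = list(dict.fromkeys(trace["phase"]))
    absent = [p for p in FLUX_PHASES if p not in present]
    if absent:
        raise ValueError(f"trace missing phases: {absent}")
    order = [p for p in present if p in FLUX_PHASES]
    if order != [p for p in FLUX_PHASES if p in order]:
        raise ValueError(f"phases out of order: {present}, expected {list(FLUX_PHASES)}")


def phase_summary(trace: pd.DataFrame, rule: str = "report") -> dict[str, float]:
    """Summarize a well's trace to one OCR level per phase (raw units).

    ``rule="report"``: basal = last basal cycle, oligomycin = minimum cycle,
    FCCP = maximum cycle, rotAA = mean of cycles.  ``rule="phase_mean"``:
    mean of cycles for every phase.
    """
    _validate_trace(trace)
    if rule not in PHASE_RULES:
        raise ValueError(f"unknown phase-level rule {rule!r}; options: {PHASE_RULES}")
    trace = trace.sort_values("cycle")
    by = {p: trace.loc[trace["phase"] == p, "ocr"].to_numpy() for p in FLUX_PHASES}
    if rule == "phase_mean":
        return {p: float(v.mean()) for p, v in by.items()}
    return {
        "basal": float(by["basal"][-1]),
        "oligomycin": float(by["oligomycin"].min()),
        "FCCP": float(by["FCCP"].max()),
        "rotAA": float(by["rotAA"].mean()),
    }


def compute_parameters(
    levels: Mapping[str, float],
    protein_ug: float | None = None,
    normalize: bool = False,
    level_rule: str = "report",
) -> FluxParameters:
    """Respiration parameters from per-phase OCR levels.

    With ``normalize=True`` every parameter is divided by ``protein_ug``
    (spare capacity % is a ratio and is left unscaled).
    """
    missing = [p for p in FLUX_PHASES if p not in levels]
    if missing:
        raise ValueError(f"levels missing phases: {missing}")
    nonmito = levels["rotAA"]
    basal = levels["basal"] - nonmito
    leak = levels["oligomycin"] - nonmito
    atp = levels["basal"] - levels["oligomycin"]
    maximal = levels["FCCP"] - nonmito
    spare = maximal - basal
    if spare < 0:
        warnings.warn(
            f"FCCP level {levels['FCCP']} below basal level {levels['basal']}: "
            "negative spare capacity reported (possible bad well)",
            RuntimeWarning,
            stacklevel=2,
        )
    spare_pct = 100.0 * maximal / basal if basal != 0 else np.nan
    scale = 1.0
    if normalize:
        if protein_ug is None or protein_ug <= 0:
            raise ValueError("normalize=True requires protein_ug > 0")
        scale = 1.0 / protein_ug
    return FluxParameters(
        basal_respiration=basal * scale,
        atp_linked=atp * scale,
        proton_leak=leak * scale,
        maximal_respiration=maximal * scale,
        spare_capacity_abs=spare * scale,
        spare_capacity_pct=spare_pct,
        nonmito=nonmito * scale,
        protein_normalized=normalize,
        level_rule=level_rule,
    )


def _well_parameters(
    trace: pd.DataFrame, rule: str, normalize: bool
) -> FluxParameters:
    protein = float(trace["protein_ug"].iloc[0]) if "protein_ug" in trace else None
    levels = phase_summary(trace, rule=rule)
    return compute_parameters(levels, protein, normalize=normalize, level_rule=rule)


PARAMETER_COLUMNS = (
    "basal_respiration",
    "atp_linked",
    "proton_leak",
    "maximal_respiration",
    "spare_capacity_abs",
    "spare_capacity_pct",
    "nonmito",
)


def group_flux(
    traces_by_condition: Mapping[str, Sequence[pd.DataFrame]],
    rule: str = "report",
    normalize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Condition-level flux summary.

    Returns ``(timecourse, parameters, comparisons)``:

    * ``timecourse`` — per condition and cycle: mean +/- SEM of OCR across
      wells (SEM per the time-course reporting convention);
    * ``parameters`` — per-well derived parameters plus per-condition
      mean +/- SD;
    * ``comparisons`` — Welch's t-test on each summary parameter between the
      first two conditions (empty if only one condition).

    Wells within a condition must share the cycle grid.
    """
    if any(len(ws) < 2 for ws in traces_by_condition.values()):
        raise ValueError("each condition needs >= 2 wells")
    tc_rows, par_rows = [], []
    for cond, wells in traces_by_condition.items():
        grids = [tuple(w.sort_values("cycle")["cycle"]) for w in wells]
        if len(set(grids)) != 1:
            raise ValueError(f"condition {cond!r}: wells have differing cycle grids")
        ocr = np.vstack([w.sort_values("cycle")["ocr"].to_numpy() for w in wells])
        phases = wells[0].sort_values("cycle")["phase"].to_numpy()
        n = ocr.shape[0]
        for j, cyc in enumerate(grids[0]):
            sd = ocr[:, j].std(ddof=1)
            tc_rows.append(
                {
                    "condition": cond,
                    "cycle": cyc,
                    "phase": phases[j],
                    "mean_ocr": ocr[:, j].mean(),
                    "sem_ocr": sd / np.sqrt(n),
                    "n_wells": n,
                }
            )
        for w in wells:
            p = _well_parameters(w, rule, normalize)
            row = {"condition": cond, "well": w["well"].iloc[0], **asdict(p)}
            par_rows.append(row)
    timecourse = pd.DataFrame(tc_rows)
    parameters = pd.DataFrame(par_rows)

    cmp_rows = []
    conds = list(traces_by_condition)
    if len(conds) >= 2:
        a, b = conds[0], conds[1]
        for col in PARAMETER_COLUMNS:
            va = parameters.loc[parameters["condition"] == a, col].to_numpy()
            vb = parameters.loc[parameters["condition"] == b, col].to_numpy()
            res = welch_t_test(va, vb)
            cmp_rows.append(
                {
                    "parameter": col,
                    "reference": a,
                    "test": b,
                    f"mean_{a}": res.mean_a,
                    f"sd_{a}": res.sd_a,
                    f"mean_{b}": res.mean_b,
                    f"sd_{b}": res.sd_b,
                    "p_value": res.p_value,
                    "stars": res.stars,
                    "fold_change": res.fold_change,
                }
            )
    comparisons = pd.DataFrame(cmp_rows)
    return timecourse, parameters, comparisons
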