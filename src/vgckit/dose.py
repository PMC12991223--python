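"""Effective-dose model for chest tomosynthesis protocols.

Effective dose (mSv) is obtained from the dose-area product (DAP, Gy·cm²)
of a tomosynthesis examination by a Monte-Carlo-derived conversion
coefficient, 0.26 mSv/(Gy·cm²) for a standard-sized adult.  The exposure of
a protocol is set by its *dose ratio* — the multiplier applied to the scout
image's tube load — so a ratio of 7 against the vendor default of 10 aims
at a 30% dose reduction and a ratio of 5 at 50%.

Cohort summaries stratify by body-mass index (BMI < 25, 25–30 inclusive,
> 30) and express each reduced-ratio group-mean effective dose as an
integer percentage of the reference-ratio group mean (ratio of group
means, half-up rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CONVERSION_COEFFICIENT",
    "BMI_GROUPS",
    "DoseRecord",
    "DoseSummary",
    "effective_dose",
    "percent_vs_reference",
    "nominal_relative_exposure",
    "bmi_group",
    "summarize_by_bmi",
    "read_dose_records",
    "write_dose_summaries",
]

#: mSv per Gy·cm² for chest tomosynthesis, standard-sized adult.
DEFAULT_CONVERSION_COEFFICIENT = 0.26

#: BMI strata labels in reporting order.
BMI_GROUPS = ("under25", "b25to30", "over30")


def bmi_group(bmi: float) -> str:
    """BMI stratum: ``under25`` (< 25), ``b25to30`` (25–30 incl.), ``over30``."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 25:
        return "under25"
    if bmi <= 30:
        return "b25to30"
    return "over30"


def effective_dose(
    dap: float, coefficient: float = DEFAULT_CONVERSION_COEFFICIENT
) -> float:
    """Effective dose (mSv) = DAP (Gy·cm²) × conversion coefficient."""
    if dap < 0:
        raise ValueError(f"DAP must be non-negative, got {dap}")
    if coefficient <= 0:
        raise ValueError(f"conversion coefficient must be positive, got {coefficient}")
    return dap * coefficient


def percent_vs_reference(e_reduced: float, e_reference: float) -> int:
    """Reduced-protocol dose as an integer percentage of the reference dose.

    Half-up rounding: 0.695 → 70.
    """
    if e_reference <= 0:
        raise ValueError(f"reference dose must be positive, got {e_reference}")
    if e_reduced < 0:
        raise ValueError(f"reduced dose must be non-negative, got {e_reduced}")
    return int(math.floor(100.0 * e_reduced / e_reference + 0.5))


def nominal_relative_exposure(dose_ratio: int, reference_ratio: int) -> float:
    """Designed exposure fraction of a protocol: dose_ratio / reference_ratio."""
    if dose_ratio <= 0 or reference_ratio <= 0:
        raise ValueError("dose ratios must be positive")
    return dose_ratio / reference_ratio


@dataclass(frozen=True)
class DoseRecord:
    """Per-patient exposure of one protocol (one dose ratio)."""

    patient_id: str
    dap: float
    dose_ratio: int
    bmi: float
    effective_dose: float = field(default=None)  # type: ignore[assignment]
    coefficient: float = DEFAULT_CONVERSION_COEFFICIENT

    def __post_init__(self):
        if not str(self.patient_id):
            raise ValueError("patient_id must be non-empty")
        if self.dap < 0:
            raise ValueError("DAP must be non-negative")
        if self.bmi <= 0:
            raise ValueError("BMI must be positive")
        if self.dose_ratio <= 0:
            raise ValueError("dose ratio must be positive")
        if self.effective_dose is None:
            object.__setattr__(
                self, "effective_dose", effective_dose(self.dap, self.coefficient)
            )

    @property
    def bmi_group(self) -> str:
        return bmi_group(self.bmi)


@dataclass(frozen=True)
class DoseSummary:
    """Per-BMI-group dose aggregates for all dose ratios.

    ``mean_dap``/``sd_dap`` describe the reference-ratio DAP; effective-dose
    means/SDs are per ratio; ``percent_vs_reference`` maps each non-reference
    ratio to its integer percentage of the reference group-mean dose.
    """

    bmi_group: str
    n_patients: int
    mean_dap: float
    sd_dap: float
    mean_effective_dose: dict[int, float]
    sd_effective_dose: dict[int, float]
    percent_vs_reference: dict[int, int]
    reference_ratio: int


def summarize_by_bmi(
    records, reference_ratio: int = 10
) -> list[DoseSummary]:
    """BMI-stratified dose summary over a cohort of :class:`DoseRecord`.

    Percentages are computed from group-mean effective doses (ratio of
    means), not as the mean of per-patient ratios.  Every BMI group present
    in the cohort must contain reference-ratio records.
    """
    records = list(records)
    if not records:
        raise ValueError("no dose records supplied")
    df = pd.DataFrame(
        {
            "patient": [r.patient_id for r in records],
            "dap": [r.dap for r in records],
            "ratio": [r.dose_ratio for r in records],
            "bmi": [r.bmi for r in records],
            "e": [r.effective_dose for r in records],
            "group": [r.bmi_group for r in records],
        }
    )
    out: list[DoseSummary] = []
    for grp in BMI_GROUPS:
        g = df[df["group"] == grp]
        if g.empty:
            continue
        ref = g[g["ratio"] == reference_ratio]
        if ref.empty:
            raise ValueError(
                f"BMI group {grp!r} has no records at reference ratio {reference_ratio}"
            )
        ratios = sorted(g["ratio"].unique(), reverse=True)
        mean_e = {int(r): float(g[g["ratio"] == r]["e"].mean()) for r in ratios}
        sd_e = {
            int(r): float(g[g["ratio"] == r]["e"].std(ddof=1))
            if len(g[g["ratio"] == r]) > 1
            else 0.0
            for r in ratios
        }
        pct = {
            int(r): percent_vs_reference(mean_e[int(r)], mean_e[reference_ratio])
            for r in ratios
            if int(r) != reference_ratio
        }
        out.append(
            DoseSummary(
                bmi_group=grp,
                n_patients=int(ref["patient"].nunique()),
                mean_dap=float(ref["dap"].mean()),
                sd_dap=float(ref["dap"].std(ddof=1)) if len(ref) > 1 else 0.0,
                mean_effective_dose=mean_e,
                sd_effective_dose=sd_e,
                percent_vs_reference=pct,
                reference_ratio=reference_ratio,
            )
        )
    return out


def read_dose_records(
    path: str | Path, coefficient: float = DEFAULT_CONVERSION_COEFFICIENT
) -> list[DoseRecord]:
    """Read a ``patient,dap_gycm2,dose_ratio,bmi`` CSV into dose records."""
    df = pd.read_csv(path, dtype={"patient": str})
    required = ["patient", "dap_gycm2", "dose_ratio", "bmi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: dose file contains no records")
    return [
        DoseRecord(
            patient_id=row.patient,
            dap=float(row.dap_gycm2),
            dose_ratio=int(row.dose_ratio),
            bmi=float(row.bmi),
            coefficient=coefficient,
        )
        for row in df.itertuples(index=False)
    ]


def write_dose_summaries(summaries: list[DoseSummary], path: str | Path) -> None:
    """Write BMI-group dose summaries to CSV (one row per group)."""
    if not summaries:
        raise ValueError("no summaries to write")
    rows = []
    for s in summaries:
        row: dict = {
            "bmi_group": s.bmi_group,
            "n_patients": s.n_patients,
            "mean_dap_gycm2": round(s.mean_dap, 4),
            "sd_dap_gycm2": round(s.sd_dap, 4),
        }
        for ratio in sorted(s.mean_effective_dose, reverse=True):
            row[f"mean_e_ratio{ratio}_msv"] = round(s.mean_effective_dose[ratio], 4)
            row[f"sd_e_ratio{ratio}_msv"] = round(s.sd_effective_dose[ratio], 4)
            if ratio in s.percent_vs_reference:
                row[f"percent_ratio{ratio}_vs_ratio{s.reference_ratio}"] = (
                    s.percent_vs_reference[ratio]
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
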