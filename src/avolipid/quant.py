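"""Targeted quantification: calibration-curve inversion of UV peak areas,
total acetogenin concentration, fresh/dry-weight basis conversion, profile
shares and fatty-acid table summaries.

Persin and Persenone B co-elute and are never reported separately: the
merged "Persin/Persenone B" analyte is quantified with the Persenone B
calibration curve. The UPA peak is quantified in Persenone A equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ACETOGENIN_ANALYTES

DETECTION_LIMIT = 0.01  # mg/gFW censoring threshold

FATTY_ACIDS = ("Linolenic", "Palmitoleic", "Linoleic", "Palmitic", "Oleic", "Stearic")


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float  # area per (mg/gFW) at unit volume factor
    intercept: float = 0.0
    basis: str = "own standard"

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"calibration slope for {self.analyte} must be positive")


def default_calibration() -> dict[str, CalibrationCurve]:
    """Default registry: per-analyte slopes, with the two shared-basis rules."""
    slopes = {
        "Persenone A": 1450.0,
        "Persin/Persenone B": 1210.0,
        "Persenone C": 980.0,
        "AcO-avocadene": 1340.0,
        "AcO-avocadenyne": 1105.0,
    }
    curves = {
        name: CalibrationCurve(name, slope,
                               basis="Persenone B curve" if name == "Persin/Persenone B"
                               else "own standard")
        for name, slope in slopes.items()
    }
    curves["UPA"] = CalibrationCurve(
        "UPA", slopes["Persenone A"], basis="Persenone A equivalents"
    )
    return curves


@dataclass
class QuantResult:
    sample_id: str
    concentrations_fw: dict[str, float]  # mg/gFW
    concentrations_dw: dict[str, float]  # mg/gDW
    tac_fw: float
    tac_dw: float
    shares: dict[str, float]
    clamped: list[str] = field(default_factory=list)


def quantify(
    areas: dict[str, float],
    curves: dict[str, CalibrationCurve],
    dw_fraction: float,
    sample_id: str = "",
    volume_factor: float = 1.0,
) -> QuantResult:
    """Invert calibration curves to concentrations and summarize.

    concentration = (area - intercept) / slope * volume_factor; negative
    results are clamped to zero and flagged. TAC is the sum over the
    acetogenin registry; shares are fractions of TAC (basis-invariant).
    """
    missing = [a for a in areas if a not in curves]
    if missing:
        raise KeyError(f"no calibration curve for analyte(s): {', '.join(sorted(missing))}")
    if not 0.0 < dw_fraction < 1.0:
        raise ValueError(f"dw_fraction must be in (0,1), got {dw_fraction}")

    conc_fw: dict[str, float] = {}
    clamped: list[str] = []
    for analyte, area in areas.items():
        curve = curves[analyte]
        c = (area - curve.intercept) / curve.slope * volume_factor
        if c < 0:
            clamped.append(analyte)
            c = 0.0
        conc_fw[analyte] = c
    conc_dw = {a: to_dry_weight(c, dw_fraction) for a, c in conc_fw.items()}
    tac_fw = sum(conc_fw.get(a, 0.0) for a in ACETOGENIN_ANALYTES)
    tac_dw = to_dry_weight(tac_fw, dw_fraction) if tac_fw else 0.0
    shares = profile_shares_from_concentrations(conc_fw) if tac_fw > 0 else {}
    return QuantResult(
        sample_id=sample_id,
        concentrations_fw=conc_fw,
        concentrations_dw=conc_dw,
        tac_fw=tac_fw,
        tac_dw=tac_dw,
        shares=shares,
        clamped=clamped,
    )


def to_dry_weight(conc_fw: float, dw_fraction: float) -> float:
    """Convert mg/gFW to mg/gDW."""
    if not 0.0 < dw_fraction < 1.0:
        raise ValueError(f"dw_fraction must be in (0,1), got {dw_fraction}")
    return conc_fw / dw_fraction


def to_fresh_weight(conc_dw: float, dw_fraction: float) -> float:
    if not 0.0 < dw_fraction < 1.0:
        raise ValueError(f"dw_fraction must be in (0,1), got {dw_fraction}")
    return conc_dw * dw_fraction


def profile_shares_from_concentrations(
    conc: dict[str, float], analytes: tuple[str, ...] = ACETOGENIN_ANALYTES
) -> dict[str, float]:
    tac = sum(conc.get(a, 0.0) for a in analytes)
    if tac <= 0:
        raise ValueError("TAC is zero; profile shares undefined")
    return {a: conc.get(a, 0.0) / tac for a in analytes if a in conc}


def profile_shares(result: QuantResult) -> dict[str, float]:
    """Acetogenin shares of TAC, as percentages."""
    if result.tac_fw <= 0:
        raise ValueError(f"sample {result.sample_id}: TAC is zero; shares undefined")
    return {a: 100.0 * s for a, s in result.shares.items()}


def summarize_fatty_acids(replicates: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd table per tissue with a Total column.

    ``replicates``: long-format frame with columns (tissue, analyte,
    concentration), at least 2 replicates per (tissue, analyte). Totals
    are the sum of the per-analyte means; total sd is the sd of
    per-replicate sums when a replicate index is present, otherwise the
    root-sum-square of analyte sds.
    """
    required = {"tissue", "analyte", "concentration"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicate table must have columns {sorted(required)}")
    counts = replicates.groupby(["tissue", "analyte"])["concentration"].count()
    if (counts < 2).any():
        raise ValueError("at least 2 replicates per tissue/analyte are required")
    stats = (
        replicates.groupby(["tissue", "analyte"])["concentration"]
        .agg(["mean", "std"])
        .reset_index()
    )
    rows = []
    for tissue, sub in stats.groupby("tissue"):
        row = {"tissue": tissue}
        for _, rec in sub.iterrows():
            row[f"{rec['analyte']}_mean"] = rec["mean"]
            row[f"{rec['analyte']}_sd"] = rec["std"]
        row["Total_mean"] = float(sub["mean"].sum())
        if "replicate" in replicates.columns:
            sums = (
                replicates[replicates["tissue"] == tissue]
                .groupby("replicate")["concentration"].sum()
            )
            row["Total_sd"] = float(sums.std())
        else:
            row["Total_sd"] = float(np.sqrt((sub["std"] ** 2).sum()))
        rows.append(row)
    return pd.DataFrame(rows)


def fold_ratio(summary: pd.DataFrame, tissue_a: str, tissue_b: str, analyte: str) -> int:
    """Cross-tissue mean ratio, rounded to the integer reported as 'n-fold'."""
    col = f"{analyte}_mean"
    a = float(summary.loc[summary["tissue"] == tissue_a, col].iloc[0])
    b = float(summary.loc[summary["tissue"] == tissue_b, col].iloc[0])
    return int(round(a / b))
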