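"""Assemble per-membrane measurements into a cohort-level table.

Three rules defined by the profiling procedure live here:

* **Exposure selection** — for a given patient and protein, if the short
  (3 min) exposure gave a detectable signal at all three time points,
  the short-exposure levels are used for that patient-protein at all
  three time points; otherwise the long (30 min) exposure is used.  The
  decision is per patient-protein, so within-patient changes stay on a
  single gain scale.
* **Half-minimum imputation** — a below-detection entry of a protein is
  set to 50% of the lowest *detected* level of that protein over all
  patients and time points (never to zero); proteins detected nowhere
  are excluded from statistical analysis altogether.
* **Detectability accounting** — per-protein percentages of patients
  with detectable signal at BL/SOM/EOT, integer-rounded, with 0%
  rendered as ``ND``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import TIMEPOINTS

__all__ = [
    "CohortTable",
    "select_exposure",
    "impute_below_detection",
    "assemble_cohort",
    "cohort_from_truth",
    "detectability_table",
    "count_all_nd_proteins",
    "proportion_fully_detected",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CohortTable:
    """Patient x protein x time point levels after exposure merging and
    imputation, plus the clinical outcome table.

    ``data`` columns: patient, protein, timepoint, level, detectable,
    imputed, saturated, exposure_used.  ``excluded_proteins`` were
    detected in no sample and appear in no statistical output.
    """

    data: pd.DataFrame
    clinical: pd.DataFrame  # patient, ttp1_days, ttp2_days
    excluded_proteins: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        retained = self.data[~self.data["protein"].isin(self.excluded_proteins)]
        if len(retained) and not (retained["level"] > 0).all():
            raise DataError("retained cohort entries must all have positive levels")
        if len(retained) and (retained["imputed"] & retained["detectable"]).any():
            raise DataError("an imputed entry cannot be detectable")
        missing = set(self.data["patient"]) - set(self.clinical["patient"])
        if missing:
            raise DataError(f"patients without clinical data: {sorted(missing)}")

    @property
    def patients(self) -> list[str]:
        return sorted(self.data["patient"].unique())

    @property
    def proteins(self) -> list[str]:
        """Retained (analyzable) proteins."""
        return sorted(set(self.data["protein"].unique()) - self.excluded_proteins)

    def wide(self, column: str = "level") -> dict[str, pd.DataFrame]:
        """Per-timepoint patient x protein matrices for ``column``."""
        out = {}
        for tp in TIMEPOINTS:
            sub = self.data[self.data["timepoint"] == tp]
            out[tp] = sub.pivot(index="patient", columns="protein", values=column)
        return out

    def ttp(self, variable: str) -> pd.Series:
        if variable not in ("ttp1_days", "ttp2_days"):
            raise DataError(f"unknown TTP variable {variable!r}")
        return self.clinical.set_index("patient")[variable]


def select_exposure(levels: pd.DataFrame) -> pd.DataFrame:
    """Merge dual-exposure measurements per patient-protein.

    ``levels`` is the long-format densitometry output with both
    exposures present for every patient x timepoint.  Returns a merged
    long table with one row per (patient, protein, timepoint) and an
    ``exposure_used`` column ('short' or 'long', constant within each
    patient-protein).
    """
    df = levels.copy()
    df["exposure"] = df["exposure"].map(
        lambda e: "short" if str(e).startswith("short") else "long"
    )
    keys = ["patient", "protein", "timepoint", "exposure"]
    if df.duplicated(keys).any():
        raise DataError("duplicate measurements for a patient/protein/timepoint/exposure")

    pivot = df.pivot_table(
        index=["patient", "protein"],
        columns=["exposure", "timepoint"],
        values=["level", "detectable", "saturated"],
        aggfunc="first",
    )
    for exposure in ("short", "long"):
        for tp in TIMEPOINTS:
            for value in ("level", "detectable", "saturated"):
                if (value, exposure, tp) not in pivot.columns or pivot[(value, exposure, tp)].isna().any():
                    bad = (
                        pivot.index.tolist()
                        if (value, exposure, tp) not in pivot.columns
                        else pivot.index[pivot[(value, exposure, tp)].isna()].tolist()
                    )
                    raise DataError(
                        f"missing {exposure}-exposure {tp} measurement for {bad[:5]}"
                        + ("..." if len(bad) > 5 else "")
                    )

    short_all = np.ones(len(pivot), dtype=bool)
    for tp in TIMEPOINTS:
        short_all &= pivot[("detectable", "short", tp)].astype(bool).to_numpy()

    rows = []
    for (patient, protein), use_short in zip(pivot.index, short_all):
        exposure = "short" if use_short else "long"
        for tp in TIMEPOINTS:
            rows.append(
                {
                    "patient": patient,
                    "protein": protein,
                    "timepoint": tp,
                    "level": float(pivot.loc[(patient, protein), ("level", exposure, tp)]),
                    "detectable": bool(pivot.loc[(patient, protein), ("detectable", exposure, tp)]),
                    "saturated": bool(pivot.loc[(patient, protein), ("saturated", exposure, tp)]),
                    "exposure_used": exposure,
                }
            )
    return pd.DataFrame(rows)


def impute_below_detection(merged: pd.DataFrame, clinical: pd.DataFrame) -> CohortTable:
    """Apply half-minimum imputation and exclusion of all-ND proteins.

    Idempotent: already-imputed entries are recomputed from the same
    detected minimum (imputed values never feed back into the minimum).
    """
    df = merged.copy()
    if "imputed" not in df.columns:
        df["imputed"] = False
    df["imputed"] = False
    excluded = set()
    for protein, sub in df.groupby("protein", sort=False):
        detected = sub.loc[sub["detectable"].astype(bool), "level"]
        if detected.empty:
            excluded.add(protein)
            continue
        fill = 0.5 * float(detected.min())
        nd_idx = sub.index[~sub["detectable"].astype(bool)]
        df.loc[nd_idx, "level"] = fill
        df.loc[nd_idx, "imputed"] = True
    return CohortTable(data=df, clinical=clinical.copy(), excluded_proteins=frozenset(excluded))


def assemble_cohort(levels: pd.DataFrame, clinical: pd.DataFrame) -> CohortTable:
    """Full assembly: exposure selection followed by imputation."""
    return impute_below_detection(select_exposure(levels), clinical)


def cohort_from_truth(
    truth,
    short_detection_limit: float = 3.0,
    long_detection_limit: float = 0.3,
) -> CohortTable:
    """Measurement-free shortcut for simulation studies: apply the
    exposure-selection and imputation rules directly to true
    concentrations, with detection defined by per-exposure concentration
    limits (a sample is detectable at an exposure iff its true level
    exceeds that exposure's limit).  Levels keep the concentration scale,
    which is irrelevant to the rank-based statistics downstream."""
    levels = truth.levels  # (n_pat, n_prot, 3)
    det_short = levels > short_detection_limit
    det_long = levels > long_detection_limit
    use_short = det_short.all(axis=2)  # (n_pat, n_prot)
    detect = np.where(use_short[:, :, None], det_short, det_long)

    n_pat, n_prot, _ = levels.shape
    names = truth.panel.names
    df = pd.DataFrame(
        {
            "patient": np.repeat(truth.patients, n_prot * 3),
            "protein": np.tile(np.repeat(names, 3), n_pat),
            "timepoint": np.tile(TIMEPOINTS, n_pat * n_prot),
            "level": levels.reshape(-1),
            "detectable": detect.reshape(-1),
            "saturated": False,
            "exposure_used": np.repeat(
                np.where(use_short, "short", "long").reshape(-1), 3
            ),
        }
    )
    return impute_below_detection(df, truth.clinical_frame())


def detectability_table(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Per-protein percentage of patients with detectable signal at each
    time point, rounded to the nearest integer (half away from zero);
    0% is rendered as the string ``'ND'``.  Index: protein; columns:
    BL, SOM, EOT (object dtype mixing ints and 'ND')."""
    data = cohort.data if isinstance(cohort, CohortTable) else cohort
    table = {}
    for protein, sub in data.groupby("protein", sort=True):
        row = {}
        for tp in TIMEPOINTS:
            at_tp = sub[sub["timepoint"] == tp]
            pct = 100.0 * at_tp["detectable"].astype(bool).sum() / len(at_tp)
            row[tp] = "ND" if pct == 0 else _round_half_away(pct)
        table[protein] = row
    out = pd.DataFrame.from_dict(table, orient="index", columns=list(TIMEPOINTS))
    out.index.name = "protein"
    return out


def _cell_percent(value) -> float:
    if isinstance(value, str) and value.strip().upper() == "ND":
        return 0.0
    return float(value)


def count_all_nd_proteins(table: pd.DataFrame) -> int:
    """Number of panel proteins detected in no sample at any time point."""
    vals = table[list(TIMEPOINTS)].map(_cell_percent)
    return int((vals == 0).all(axis=1).sum())


def proportion_fully_detected(table: pd.DataFrame, timepoint: str) -> int:
    """Percentage (nearest integer) of panel proteins detected in 100%
    of patients at ``timepoint``."""
    if timepoint not in TIMEPOINTS:
        raise DataError(f"unknown timepoint {timepoint!r}")
    vals = table[timepoint].map(_cell_percent)
    return _round_half_away(100.0 * (vals == 100).sum() / len(table))
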