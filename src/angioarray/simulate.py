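"""Synthetic serum cohorts with known ground truth.

The generator emulates the structure of a 22-patient maintenance-therapy
cohort sampled at three protocol time points — baseline (BL), start of
maintenance (SOM) and end of treatment at progression (EOT) — with each
sample assayed on two film exposures of the same membrane.

Per protein, patient baselines are log-normal with a protein-specific
abundance tier pitched so that the expected fraction of patients above
the long-exposure detection limit matches a bundled reference
detectability grid (so the panel spans all-absent, rarely detectable and
always-detectable proteins).  Programmed multiplicative fold-changes act
between adjacent time points on a configurable fraction of patients, and
time-to-progression on maintenance (TTP2) can be coupled to the BL->SOM
log-change of chosen proteins with a target Spearman correlation via a
Gaussian-copula rank interleaving.  TTP1 = TTP2 + the induction-phase
length, so TTP1 > TTP2 always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

import importlib.resources

from .errors import ConfigurationError, ParameterError
from .panel import ProteinPanel, default_panel

__all__ = [
    "TIMEPOINTS",
    "Effect",
    "CohortPlan",
    "CohortTruth",
    "simulate_cohort",
    "default_plan",
    "null_plan",
    "default_abundance",
    "load_reference_detectability",
]

TIMEPOINTS = ("BL", "SOM", "EOT")


def load_reference_detectability() -> pd.DataFrame:
    """The bundled per-protein detectability grid (percent of patients
    with detectable signal at BL/SOM/EOT in the original 22-patient
    serum study; 'ND' = detected in no patient)."""
    with importlib.resources.as_file(
        importlib.resources.files("angioarray.data") / "reference_detectability.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", dtype=str).set_index("protein")


def default_abundance(panel: ProteinPanel) -> dict[str, float]:
    """Target detectable fraction per protein (mean over the three time
    points of the reference grid; all-ND proteins map to 0.0 = truly
    absent)."""
    grid = load_reference_detectability()
    out: dict[str, float] = {}
    for entry in panel:
        if entry.name not in grid.index:
            out[entry.name] = 0.5
            continue
        row = grid.loc[entry.name]
        vals = [0.0 if v == "ND" else float(v) / 100.0 for v in row[["BL", "SOM", "EOT"]]]
        out[entry.name] = float(np.mean(vals))
    return out


@dataclass(frozen=True)
class Effect:
    """A programmed multiplicative change between two adjacent time
    points, applied to a random ``fraction`` of patients."""

    fold: float
    fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ParameterError("fold must be positive")
        if not 0 <= self.fraction <= 1:
            raise ParameterError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortPlan:
    """Ground-truth effect and association configuration.

    induction / maintenance
        protein name -> :class:`Effect` acting BL->SOM / SOM->EOT.
    association
        protein name -> target Spearman correlation between the protein's
        BL->SOM log-change and TTP2.
    abundance
        protein name -> target detectable fraction (None: derived from
        the bundled reference grid).
    sigma_between / sigma_within
        between-patient and within-patient (per-sample) log-scale SDs.
    anchor_concentration
        concentration at the long-exposure detection limit; abundance
        tiers are pitched against it.
    """

    induction: dict[str, Effect] = field(default_factory=dict)
    maintenance: dict[str, Effect] = field(default_factory=dict)
    association: dict[str, float] = field(default_factory=dict)
    abundance: dict[str, float] | None = None
    sigma_between: float = 1.0
    sigma_within: float = 0.3
    anchor_concentration: float = 0.3
    ttp2_median_days: float = 119.0
    ttp2_log_sd: float = 0.5
    ttp2_min_days: int = 30
    induction_days_range: tuple[int, int] = (118, 163)

    def validate_against(self, panel: ProteinPanel) -> None:
        for name in (*self.induction, *self.maintenance, *self.association):
            if name not in panel:
                raise ConfigurationError(f"plan references unknown protein {name!r}")
        for rho in self.association.values():
            if not -1 < rho < 1:
                raise ConfigurationError("association targets must lie in (-1, 1)")


@dataclass
class CohortTruth:
    """True (noise-free of measurement, but biologically noisy) protein
    concentrations and outcomes for one simulated cohort."""

    patients: tuple[str, ...]
    panel: ProteinPanel
    levels: np.ndarray  # (n_patients, n_proteins, 3), concentration units, >= 0
    ttp1_days: np.ndarray  # (n_patients,), int
    ttp2_days: np.ndarray  # (n_patients,), int

    TIMEPOINTS = TIMEPOINTS

    def __post_init__(self) -> None:
        self._p_idx = {p: i for i, p in enumerate(self.patients)}
        self._a_idx = {e.index: j for j, e in enumerate(self.panel)}
        self._name_idx = {e.name: j for j, e in enumerate(self.panel)}
        if not np.all(np.isfinite(self.levels)) or np.any(self.levels < 0):
            raise ParameterError("true levels must be finite and >= 0")
        if np.any(self.ttp1_days <= self.ttp2_days):
            raise ParameterError("ttp1 must exceed ttp2 for every patient")

    def patient_index(self, patient: str) -> int:
        return self._p_idx[patient]

    def level(self, patient: str, protein, timepoint: str) -> float:
        """Level for one (patient, protein, timepoint); ``protein`` may be
        a panel analyte index (int) or a protein name."""
        j = self._a_idx[protein] if isinstance(protein, (int, np.integer)) else self._name_idx[protein]
        return float(self.levels[self._p_idx[patient], j, TIMEPOINTS.index(timepoint)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (patient, protein, timepoint, true_level)."""
        n_pat, n_prot, _ = self.levels.shape
        names = self.panel.names
        rows = {
            "patient": np.repeat(self.patients, n_prot * 3),
            "protein": np.tile(np.repeat(names, 3), n_pat),
            "timepoint": np.tile(TIMEPOINTS, n_pat * n_prot),
            "true_level": self.levels.reshape(-1),
        }
        return pd.DataFrame(rows)

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient": self.patients, "ttp1_days": self.ttp1_days, "ttp2_days": self.ttp2_days}
        )


def default_plan(panel: ProteinPanel | None = None) -> CohortPlan:
    """The default study conditions: fold-changes mirroring the observed
    induction/maintenance dynamics and TTP2 couplings for the three
    proteins whose BL->SOM increase tracked longer maintenance benefit."""
    return CohortPlan(
        induction={
            "Endothelin-1": Effect(0.5),
            "MMP-8": Effect(0.5),
            "PDGF-AB/PDGF-BB": Effect(0.5),
            "PDGF-AA": Effect(0.5),
            "Angiopoietin-1": Effect(0.5),
            "EGF": Effect(0.5),
            "HB-EGF": Effect(0.5),
            "TIMP-4": Effect(0.6),
            "TIMP-1": Effect(1.8),
            "Pentraxin 3 (PTX3)": Effect(1.8),
            "IGFBP-3": Effect(1.5),
            "Platelet Factor 4": Effect(1.5),
        },
        maintenance={
            "TIMP-4": Effect(1.8),
            "MMP-8": Effect(1.8),
            "EGF": Effect(1.6),
            "Amphiregulin": Effect(1.6),
            "Coagulation Factor III": Effect(1.6),
            "DPPIV": Effect(0.6),
        },
        association={"IL-8": 0.53, "IGFBP-2": 0.43, "Activin A": 0.43},
    )


def null_plan() -> CohortPlan:
    """No programmed effects and no TTP coupling."""
    return CohortPlan()


def _normal_scores(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank-based normal scores; random tie-break keeps the copula exact."""
    order = np.argsort(x + 1e-12 * rng.standard_normal(x.size), kind="stable")
    ranks = np.empty(x.size)
    ranks[order] = np.arange(1, x.size + 1)
    return sps.norm.ppf((ranks - 0.5) / x.size)


def simulate_cohort(
    n_patients: int,
    panel: ProteinPanel | None = None,
    plan: CohortPlan | None = None,
    seed: int = 0,
) -> CohortTruth:
    """Draw one cohort: log-normal baselines per abundance tier,
    programmed phase effects, per-sample biological noise, and TTP
    outcomes rank-coupled to the planned proteins' induction changes.
    Fully reproducible from ``seed``."""
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    panel = panel if panel is not None else default_panel()
    plan = plan if plan is not None else default_plan(panel)
    plan.validate_against(panel)
    rng = np.random.default_rng(seed)

    abundance = plan.abundance if plan.abundance is not None else default_abundance(panel)
    names = panel.names
    n_prot = len(names)
    patients = tuple(f"P{i + 1:02d}" for i in range(n_patients))

    # protein-tier medians: detect fraction p -> median exp(mu) with
    # P(baseline > anchor) = p under the between-patient log-normal
    mu = np.full(n_prot, -np.inf)
    present = np.ones(n_prot, dtype=bool)
    for j, name in enumerate(names):
        p = abundance.get(name, 0.5)
        if p <= 0:
            present[j] = False
            continue
        z = sps.norm.ppf(np.clip(p, 0.02, 0.995))
        mu[j] = np.log(plan.anchor_concentration) + plan.sigma_between * z

    base = np.zeros((n_patients, n_prot))
    base[:, present] = np.exp(
        mu[present][None, :] + plan.sigma_between * rng.standard_normal((n_patients, present.sum()))
    )

    # cumulative phase multipliers per patient x protein
    mult_som = np.ones((n_patients, n_prot))
    mult_eot = np.ones((n_patients, n_prot))
    for name, eff in plan.induction.items():
        j = names.index(name)
        hit = rng.random(n_patients) < eff.fraction
        mult_som[hit, j] *= eff.fold
    for name, eff in plan.maintenance.items():
        j = names.index(name)
        hit = rng.random(n_patients) < eff.fraction
        mult_eot[hit, j] *= eff.fold

    within = np.exp(plan.sigma_within * rng.standard_normal((n_patients, n_prot, 3)))
    levels = np.zeros((n_patients, n_prot, 3))
    levels[:, :, 0] = base * within[:, :, 0]
    levels[:, :, 1] = base * mult_som * within[:, :, 1]
    levels[:, :, 2] = base * mult_som * mult_eot * within[:, :, 2]
    levels[:, ~present, :] = 0.0

    # TTP2 order statistics assigned by rank of a latent score carrying
    # the planned Spearman weight for each association protein
    ttp2_pool = np.maximum(
        plan.ttp2_min_days,
        np.round(
            np.exp(np.log(plan.ttp2_median_days) + plan.ttp2_log_sd * rng.standard_normal(n_patients))
        ).astype(int),
    )
    if plan.association:
        cs, zs = [], []
        for name, rho in plan.association.items():
            j = names.index(name)
            if not present[j]:
                raise ConfigurationError(f"association target {name!r} is an absent-tier protein")
            d = np.log(levels[:, j, 1]) - np.log(levels[:, j, 0])
            zs.append(_normal_scores(d, rng))
            cs.append(2.0 * np.sin(np.pi * rho / 6.0))  # Pearson weight hitting the Spearman target
        cs = np.asarray(cs)
        if (cs**2).sum() >= 1.0:
            raise ConfigurationError("association targets jointly too strong (sum of squared weights >= 1)")
        latent = np.tensordot(cs, np.asarray(zs), axes=1)
        latent = latent + np.sqrt(1.0 - (cs**2).sum()) * rng.standard_normal(n_patients)
        ttp2 = np.empty(n_patients, dtype=int)
        ttp2[np.argsort(latent, kind="stable")] = np.sort(ttp2_pool)
    else:
        ttp2 = ttp2_pool
    lo, hi = plan.induction_days_range
    induction_days = rng.integers(lo, hi + 1, size=n_patients)
    ttp1 = ttp2 + induction_days

    return CohortTruth(
        patients=patients, panel=panel, levels=levels, ttp1_days=ttp1, ttp2_days=ttp2
    )


def write_truth(truth: CohortTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the truth and clinical tables as CSV; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_path = out / "truth.csv"
    clinical_path = out / "clinical.csv"
    truth.to_frame().to_csv(truth_path, index=False)
    truth.clinical_frame().to_csv(clinical_path, index=False)
    return truth_path, clinical_path
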