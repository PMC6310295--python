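"""Longitudinal nonparametric statistics for the assembled cohort.

Per protein and treatment phase (BL->SOM: induction; SOM->EOT:
maintenance), within-patient changes of log protein level are tested
with the Wilcoxon matched-pairs signed-rank test; zero differences —
which include patient pairs non-detectable at both time points, since
half-minimum imputation makes those two values equal — drop from the
test but are tallied separately (the "ND" column of the direction
counts).  The exact null distribution with midrank ties is computed by a
convolution over doubled midranks for up to 25 effective pairs (the
cohort size of 22 keeps the primary path exact); larger samples use the
tie-corrected normal approximation.

Associations with time to progression use Spearman rank correlation with
midranks (imputed values tie at the imputed level): BL level vs TTP1,
SOM level vs TTP2, and — as a landmark analysis — the BL->SOM relative
change (SOM/BL ratio, rank-equivalent to the log difference) vs TTP2.
The exact permutation p-value is enumerated for n <= 10, otherwise the
t approximation is used.

All p-values are two-sided and reported without multiple-testing
adjustment; their purpose is to rank proteins by evidence, with
0.005 <= p < 0.05 labelled "weak" evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assembly import CohortTable
from .errors import DataError, ParameterError
from .simulate import TIMEPOINTS

__all__ = [
    "PHASES",
    "DynamicsResult",
    "AssociationResult",
    "exact_signed_rank_p",
    "signed_rank_test",
    "min_attainable_p",
    "paired_dynamics",
    "dynamics_all",
    "spearman",
    "level_ttp_association",
    "landmark_change_association",
    "rank_and_band",
    "UNADJUSTED_NOTE",
]

PHASES = {"BL->SOM": ("BL", "SOM"), "SOM->EOT": ("SOM", "EOT")}
_PHASE_ALIASES = {
    "induction": "BL->SOM",
    "maintenance": "SOM->EOT",
    "BL->SOM": "BL->SOM",
    "SOM->EOT": "SOM->EOT",
    "BL→SOM": "BL->SOM",
    "SOM→EOT": "SOM->EOT",
}

UNADJUSTED_NOTE = (
    "Nominal two-sided p-values without adjustment for multiple testing; "
    "intended to rank proteins by evidence and to be interpreted with caution. "
    "'weak' labels 0.005 <= p < 0.05."
)

EXACT_MAX_N = 25  # exact signed-rank enumeration threshold
SPEARMAN_EXACT_MAX_N = 10


def _signed_rank_null_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the null distribution of 2*W+ over sums 0..sum(ranks),
    by polynomial convolution (each rank independently in/out)."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist += shifted
    return dist


def exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p with midrank ties for the nonzero
    differences ``d`` (zeros must already be removed).

    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) under the uniform
    sign-flip null, with the tied null distribution enumerated exactly.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    doubled = np.round(2.0 * ranks).astype(int)  # midranks -> integers
    w2 = int(round(float(doubled[d > 0].sum())))
    dist = _signed_rank_null_cdf(doubled)
    total = dist.sum()
    lower = dist[: w2 + 1].sum() / total
    upper = dist[w2:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_signed_rank_p(d: np.ndarray) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0:
        return 1.0
    z = (w - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def signed_rank_test(d: np.ndarray) -> tuple[float, int]:
    """Two-sided signed-rank p for differences ``d`` after dropping
    zeros; returns ``(p, n_effective)``."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0, 0
    if d.size <= EXACT_MAX_N:
        return exact_signed_rank_p(d), d.size
    return _approx_signed_rank_p(d), d.size


def min_attainable_p(n_effective: int) -> float:
    """Smallest two-sided p the exact test can produce with
    ``n_effective`` untied pairs (all signs equal): 2 / 2**n."""
    if n_effective <= 0:
        return 1.0
    return min(1.0, 2.0 ** (1 - n_effective))


@dataclass(frozen=True)
class DynamicsResult:
    protein: str
    phase: str  # "BL->SOM" | "SOM->EOT"
    n_increased: int
    n_nd: int  # non-detectable at both time points
    n_decreased: int
    n_unchanged: int  # detected ties (zero difference but not both-ND)
    direction: str  # "up" | "down" | "none"
    p_value: float
    n_effective: int


def _phase(phase: str) -> tuple[str, str, str]:
    try:
        canon = _PHASE_ALIASES[phase]
    except KeyError:
        raise ParameterError(f"unknown phase {phase!r}; expected one of {sorted(set(_PHASE_ALIASES))}") from None
    earlier, later = PHASES[canon]
    return canon, earlier, later


def paired_dynamics(cohort: CohortTable, protein: str, phase: str) -> DynamicsResult:
    """Direction counts and the paired log-scale signed-rank test for one
    protein over one treatment phase."""
    canon, earlier, later = _phase(phase)
    if protein in cohort.excluded_proteins:
        raise DataError(f"protein {protein!r} was excluded (detected in no sample)")
    sub = cohort.data[cohort.data["protein"] == protein]
    if sub.empty:
        raise DataError(f"protein {protein!r} not present in cohort table")
    return _dynamics_from_wide(
        protein,
        canon,
        sub.pivot(index="patient", columns="timepoint", values="level"),
        sub.pivot(index="patient", columns="timepoint", values="detectable"),
        earlier,
        later,
    )


def _dynamics_from_wide(
    protein: str,
    canon: str,
    levels: pd.DataFrame,
    detect: pd.DataFrame,
    earlier: str,
    later: str,
) -> DynamicsResult:
    for tp in (earlier, later):
        if tp not in levels.columns or levels[tp].isna().any():
            raise DataError(f"protein {protein!r}: missing {tp} measurements")
    a = levels[earlier].to_numpy(dtype=float)
    b = levels[later].to_numpy(dtype=float)
    d = np.log(b) - np.log(a)
    nd_both = ~detect[earlier].to_numpy(dtype=bool) & ~detect[later].to_numpy(dtype=bool)
    n_inc = int((d > 0).sum())
    n_dec = int((d < 0).sum())
    n_nd = int(nd_both.sum())
    n_unchanged = int((d == 0).sum()) - n_nd
    p, n_eff = signed_rank_test(d)
    nz = d[d != 0]
    if nz.size == 0:
        direction = "none"
    else:
        med = float(np.median(nz))
        direction = "up" if med > 0 else ("down" if med < 0 else "none")
    return DynamicsResult(
        protein=protein,
        phase=canon,
        n_increased=n_inc,
        n_nd=n_nd,
        n_decreased=n_dec,
        n_unchanged=n_unchanged,
        direction=direction,
        p_value=p,
        n_effective=n_eff,
    )


def dynamics_all(cohort: CohortTable, phase: str) -> list[DynamicsResult]:
    """Paired dynamics for every retained protein (one pivot, shared)."""
    canon, earlier, later = _phase(phase)
    levels = {tp: m for tp, m in cohort.wide("level").items()}
    detect = {tp: m for tp, m in cohort.wide("detectable").items()}
    out = []
    for protein in cohort.proteins:
        lv = pd.DataFrame({tp: levels[tp][protein] for tp in TIMEPOINTS})
        dt = pd.DataFrame({tp: detect[tp][protein] for tp in TIMEPOINTS})
        out.append(_dynamics_from_wide(protein, canon, lv, dt, earlier, later))
    return out


@dataclass(frozen=True)
class AssociationResult:
    protein: str
    x_quantity: str  # "BL level" | "SOM level" | "BL->SOM relative change"
    y_variable: str  # "ttp1_days" | "ttp2_days"
    rho: float  # NaN when undefined
    p_value: float  # NaN when undefined
    n_used: int
    valid: bool


def spearman(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = SPEARMAN_EXACT_MAX_N
) -> tuple[float, float, bool]:
    """Spearman rho with midranks and a two-sided p-value: exact by full
    permutation enumeration for n <= ``exact_max_n``, t approximation
    otherwise.  Returns ``(rho, p, valid)``; ``valid=False`` (NaN rho)
    when either variable has zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan"), False
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    rho = float((rxc * ryc).mean() / (sx * sy))
    if n <= exact_max_n:
        # denominators are permutation-invariant: compare covariances
        target = abs((rxc * ryc).sum()) - 1e-9
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs((rxc * ryc[list(perm)]).sum()) >= target:
                count += 1
        return rho, count / total, True
    if abs(rho) >= 1.0:
        return rho, 0.0, True
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2))), True


def _association(
    cohort: CohortTable, protein: str, x: pd.Series, x_quantity: str, ttp_variable: str
) -> AssociationResult:
    if protein in cohort.excluded_proteins:
        raise DataError(f"protein {protein!r} was excluded (detected in no sample)")
    y = cohort.ttp(ttp_variable).reindex(x.index)
    if y.isna().any():
        raise DataError(f"missing {ttp_variable} for patients {list(x.index[y.isna()])[:5]}")
    if len(x) < 4:
        raise DataError("association requires at least 4 patients")
    rho, p, valid = spearman(x.to_numpy(), y.to_numpy())
    return AssociationResult(
        protein=protein,
        x_quantity=x_quantity,
        y_variable=ttp_variable,
        rho=rho,
        p_value=p,
        n_used=len(x),
        valid=valid,
    )


def level_ttp_association(
    cohort: CohortTable, protein: str, timepoint: str, ttp_variable: str
) -> AssociationResult:
    """Spearman association of a protein's level at one time point with a
    TTP variable (imputed values tie at the common imputed level)."""
    if timepoint not in TIMEPOINTS:
        raise ParameterError(f"unknown timepoint {timepoint!r}")
    sub = cohort.data[
        (cohort.data["protein"] == protein) & (cohort.data["timepoint"] == timepoint)
    ].set_index("patient")["level"]
    return _association(cohort, protein, sub, f"{timepoint} level", ttp_variable)


def landmark_change_association(cohort: CohortTable, protein: str) -> AssociationResult:
    """Landmark analysis: Spearman association of the BL->SOM relative
    change (SOM/BL ratio of imputed levels) with TTP2, measured from the
    start of maintenance."""
    sub = cohort.data[cohort.data["protein"] == protein]
    wide = sub.pivot(index="patient", columns="timepoint", values="level")
    ratio = wide["SOM"] / wide["BL"]
    return _association(cohort, protein, ratio, "BL->SOM relative change", "ttp2_days")


def rank_and_band(
    results: list, thresholds: tuple[float, float] = (0.005, 0.05)
) -> pd.DataFrame:
    """Order results by ascending nominal p (ties broken by protein name)
    and attach evidence bands: 'stronger' below the lower threshold,
    'weak' in [lower, upper), 'none' at or above the upper threshold.
    No multiplicity adjustment is applied; the returned frame carries
    the caveat in ``.attrs['note']``."""
    lower, upper = thresholds
    rows = [r.__dict__.copy() for r in results]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["protein", "p_value", "evidence_band"])
        df.attrs["note"] = UNADJUSTED_NOTE
        return df

    def band(p: float) -> str:
        if not np.isfinite(p):
            return "none"
        if p < lower:
            return "stronger"
        if p < upper:
            return "weak"
        return "none"

    df["evidence_band"] = df["p_value"].map(band)
    df = df.sort_values(["p_value", "protein"], kind="stable").reset_index(drop=True)
    df.attrs["note"] = UNADJUSTED_NOTE
    return df
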