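"""Longitudinal statistics: exact signed-rank against brute-force
enumeration, Spearman against permutation, direction counts, banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from angioarray import (
    CohortPlan,
    CohortTable,
    Effect,
    cohort_from_truth,
    landmark_change_association,
    level_ttp_association,
    paired_dynamics,
    rank_and_band,
    simulate_cohort,
    spearman,
)
from angioarray.stats import signed_rank_test, min_attainable_p, UNADJUSTED_NOTE
from angioarray.errors import DataError
from conftest import oracle_signed_rank_p

TPS = ("BL", "SOM", "EOT")


# ---------------------------------------------------------------- signed rank

def test_all_positive_n5_gives_exact_p():
    """n = 5, every difference positive: two-sided p = 2/2^5 = 0.0625."""
    p, n_eff = signed_rank_test(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert n_eff == 5
    assert p == pytest.approx(0.0625, abs=1e-12)


def test_mixed_signs_match_enumeration_oracle():
    d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])  # midrank tie at |d| = 1
    p, _ = signed_rank_test(d)
    assert p == pytest.approx(oracle_signed_rank_p(d), abs=1e-12)


def test_all_zero_differences_give_p_one():
    p, n_eff = signed_rank_test(np.zeros(8))
    assert (p, n_eff) == (1.0, 0)


@pytest.mark.parametrize("seed", range(30))
def test_exact_p_matches_bruteforce_on_random_tied_data(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 11))
    d = rng.choice([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0], size=n) * rng.choice([0.5, 1.0], size=n)
    p, _ = signed_rank_test(d)
    assert p == pytest.approx(oracle_signed_rank_p(d), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st_h.lists(st_h.integers(min_value=-4, max_value=4), min_size=1, max_size=10))
def test_exact_p_property_valid_and_matches_oracle(ints):
    d = np.array(ints, dtype=float)
    p, _ = signed_rank_test(d)
    assert 0 < p <= 1
    assert p == pytest.approx(oracle_signed_rank_p(d), abs=1e-12)


def test_min_attainable_p_boundary():
    assert min_attainable_p(5) == 0.0625  # cannot reach 0.05
    assert min_attainable_p(6) == 0.03125


# ------------------------------------------------------------------ dynamics

def _cohort(levels_by_patient, detect_by_patient, ttp2=None):
    """Build a single-protein cohort table from explicit values."""
    rows = []
    patients = sorted(levels_by_patient)
    for p in patients:
        for tp, lv, det in zip(TPS, levels_by_patient[p], detect_by_patient[p]):
            rows.append(
                {
                    "patient": p,
                    "protein": "VEGF",
                    "timepoint": tp,
                    "level": lv,
                    "detectable": det,
                    "imputed": not det,
                    "saturated": False,
                    "exposure_used": "long",
                }
            )
    clinical = pd.DataFrame(
        {
            "patient": patients,
            "ttp1_days": [260 + 5 * i for i in range(len(patients))],
            "ttp2_days": ttp2 if ttp2 is not None else [119 + 7 * i for i in range(len(patients))],
        }
    )
    return CohortTable(data=pd.DataFrame(rows), clinical=clinical)


def test_direction_counts_and_nd_accounting():
    """Both-ND pairs drop from the test and land in the ND column; a
    mixed pair (imputed on one side) counts as a real change."""
    imput = 0.05
    cohort = _cohort(
        {
            "P1": (1.0, 2.0, 2.0),  # increased
            "P2": (1.0, 0.5, 0.5),  # decreased
            "P3": (imput, imput, imput),  # ND at both -> ND column
            "P4": (imput, 1.5, 1.5),  # ND at BL only -> increased
        },
        {
            "P1": (True, True, True),
            "P2": (True, True, True),
            "P3": (False, False, False),
            "P4": (False, True, True),
        },
    )
    res = paired_dynamics(cohort, "VEGF", "BL->SOM")
    assert (res.n_increased, res.n_nd, res.n_decreased, res.n_unchanged) == (2, 1, 1, 0)
    assert res.n_effective == 3
    assert res.n_increased + res.n_nd + res.n_decreased + res.n_unchanged == 4
    assert res.direction == "up"


def test_all_equal_levels_give_p_one_direction_none():
    cohort = _cohort(
        {p: (1.0, 1.0, 1.0) for p in ("P1", "P2", "P3")},
        {p: (True, True, True) for p in ("P1", "P2", "P3")},
    )
    res = paired_dynamics(cohort, "VEGF", "SOM->EOT")
    assert res.p_value == 1.0 and res.n_effective == 0 and res.direction == "none"


def test_scale_invariance_of_dynamics():
    base = {
        "P1": (1.0, 2.5, 2.0),
        "P2": (1.2, 0.8, 0.7),
        "P3": (0.9, 1.7, 2.2),
        "P4": (2.0, 1.1, 0.3),
        "P5": (1.4, 2.8, 1.9),
    }
    det = {p: (True, True, True) for p in base}
    r1 = paired_dynamics(_cohort(base, det), "VEGF", "BL->SOM")
    scaled = {p: tuple(40.0 * v for v in vals) for p, vals in base.items()}
    r2 = paired_dynamics(_cohort(scaled, det), "VEGF", "BL->SOM")
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
    assert (r1.n_increased, r1.n_decreased, r1.direction) == (r2.n_increased, r2.n_decreased, r2.direction)


def test_excluded_protein_refused():
    cohort = _cohort(
        {"P1": (1.0, 1.0, 1.0), "P2": (1.0, 1.0, 1.0)},
        {p: (True, True, True) for p in ("P1", "P2")},
    )
    cohort = CohortTable(data=cohort.data, clinical=cohort.clinical, excluded_proteins=frozenset({"VEGF"}))
    with pytest.raises(DataError):
        paired_dynamics(cohort, "VEGF", "BL->SOM")


def test_programmed_decrease_detected_with_down_direction(panel):
    plan = CohortPlan(induction={"MMP-8": Effect(0.5, 0.8)})
    truth = simulate_cohort(22, panel, plan, seed=77)
    res = paired_dynamics(cohort_from_truth(truth), "MMP-8", "BL->SOM")
    assert res.p_value < 0.05 and res.direction == "down"


# ------------------------------------------------------------------ spearman

def test_monotone_series_give_unit_rho():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    rho, p, valid = spearman(x, 10 * x + 3)
    assert valid and rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 720, abs=1e-12)  # only the two extreme orderings
    rho_d, _, _ = spearman(x, -x)
    assert rho_d == pytest.approx(-1.0)


def test_zero_variance_flags_undefined_rho():
    rho, p, valid = spearman(np.ones(6), np.arange(6.0))
    assert not valid and np.isnan(rho)


def test_exact_permutation_p_matches_mc_oracle():
    from conftest import oracle_spearman_mc_p

    rng = np.random.default_rng(123)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    _, p, _ = spearman(x, y)
    p_mc = oracle_spearman_mc_p(x, y, n_perm=20000, seed=9)
    assert p == pytest.approx(p_mc, abs=0.02)


def test_landmark_ratio_equals_log_difference_ranks(panel):
    """SOM/BL ratio and log(SOM)-log(BL) are rank-equivalent, so the
    landmark association is identical under either operationalization."""
    truth = simulate_cohort(12, panel, seed=31)
    cohort = cohort_from_truth(truth)
    res = landmark_change_association(cohort, "IGFBP-2")
    wide = cohort.data[cohort.data["protein"] == "IGFBP-2"].pivot(
        index="patient", columns="timepoint", values="level"
    )
    logdiff = np.log(wide["SOM"]) - np.log(wide["BL"])
    rho2, p2, _ = spearman(logdiff.to_numpy(), cohort.ttp("ttp2_days").reindex(wide.index).to_numpy())
    assert res.rho == pytest.approx(rho2, abs=1e-12)
    assert res.p_value == pytest.approx(p2, abs=1e-12)


def test_identical_ratios_flagged_undefined():
    cohort = _cohort(
        {p: (1.0, 2.0, 2.0) for p in ("P1", "P2", "P3", "P4")},
        {p: (True, True, True) for p in ("P1", "P2", "P3", "P4")},
    )
    res = landmark_change_association(cohort, "VEGF")
    assert not res.valid and np.isnan(res.rho)


def test_level_ttp_association_perfect_monotone():
    cohort = _cohort(
        {f"P{i}": (float(i + 1), 1.0, 1.0) for i in range(6)},
        {f"P{i}": (True, True, True) for i in range(6)},
        ttp2=list(range(100, 106)),
    )
    res = level_ttp_association(cohort, "VEGF", "BL", "ttp1_days")
    assert res.rho == pytest.approx(1.0)


# ------------------------------------------------------------------- banding

def test_rank_and_band_thresholds_and_order():
    from angioarray.stats import AssociationResult

    results = [
        AssociationResult("B", "BL level", "ttp1_days", 0.5, 0.03, 10, True),
        AssociationResult("A", "BL level", "ttp1_days", 0.6, 0.004, 10, True),
        AssociationResult("C", "BL level", "ttp1_days", 0.1, 0.2, 10, True),
    ]
    report = rank_and_band(results)
    assert report["protein"].tolist() == ["A", "B", "C"]
    assert report["evidence_band"].tolist() == ["stronger", "weak", "none"]
    assert report.attrs["note"] == UNADJUSTED_NOTE


def test_tied_p_values_break_by_protein_name():
    from angioarray.stats import AssociationResult

    results = [
        AssociationResult(name, "BL level", "ttp1_days", 0.5, 0.02, 10, True)
        for name in ("Zeta", "Alpha", "Mid")
    ]
    report = rank_and_band(results)
    assert report["protein"].tolist() == ["Alpha", "Mid", "Zeta"]


def test_empty_result_list_gives_empty_report():
    report = rank_and_band([])
    assert report.empty
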