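"""Coverage intervals, episode merging, exposure and average daily dose."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rxdur import (
    average_daily_dose,
    build_coverage,
    build_episodes,
    patient_exposure,
)
from conftest import make_rx
from oracles import day, oracle_episode_bounds, oracle_supply_queue


@pytest.mark.parametrize(
    "strength,quantity,instruction,supply,exp_days,exp_dose",
    [
        (50.0, 30.0, 50.0, None, 30, 50.0),   # qty x strength / instruction
        (70.0, 28.0, None, 28, 28, 70.0),     # recorded supply wins
        (50.0, 60.0, 100.0, None, 30, 100.0), # 3000 mg at 100 mg/day
        (None, None, None, None, 30, np.nan), # default supply, unknown dose
    ],
)
def test_coverage_length_and_dose(strength, quantity, instruction, supply, exp_days, exp_dose):
    rx = make_rx([("P1", "LDX", "2015-01-01", strength, quantity, instruction, supply)])
    cov = build_coverage(rx, default_supply_days=30)
    assert cov.loc[0, "days"] == exp_days
    assert cov.loc[0, "end"] == day(0) + pd.Timedelta(exp_days, "D")
    if np.isnan(exp_dose):
        assert np.isnan(cov.loc[0, "dose_mg_per_day"])
    else:
        assert cov.loc[0, "dose_mg_per_day"] == pytest.approx(exp_dose)


def test_coverage_without_basis_and_without_default_raises():
    rx = make_rx([("P1", "LDX", "2015-01-01", None, None, None, None)])
    with pytest.raises(ValueError, match="no supply_days"):
        build_coverage(rx, default_supply_days=None)


def test_total_coverage_equals_sum_of_record_lengths():
    rng = np.random.default_rng(0)
    rows = []
    expected = 0
    for i in range(100):
        supply = int(rng.integers(7, 91))
        expected += supply
        rows.append((f"P{i % 10}", "LDX", day(int(rng.integers(0, 1000))), 50.0, float(supply), 50.0, supply))
    cov = build_coverage(make_rx(rows))
    assert cov["days"].sum() == expected


@pytest.mark.parametrize(
    "gap,expected_episodes,covered,span",
    [
        (10, 1, 60, 70),   # small gap merges
        (30, 1, 60, 90),   # gap equal to the grace period still merges
        (31, 2, None, None),  # one day beyond the grace period splits
    ],
)
def test_episode_merging_boundaries(gap, expected_episodes, covered, span):
    rx = make_rx(
        [
            ("P1", "LDX", day(0), 50.0, 30.0, 50.0, 30),
            ("P1", "LDX", day(30 + gap), 50.0, 30.0, 50.0, 30),
        ]
    )
    eps = build_episodes(build_coverage(rx), gap_days=30)
    assert len(eps) == expected_episodes
    if expected_episodes == 1:
        assert eps.loc[0, "covered_days"] == covered
        assert eps.loc[0, "span_days"] == span


def test_episode_partition_matches_union_oracle():
    """Enumerated gap patterns around the 30-day tolerance reproduce the
    brute-force interval-union oracle's episode boundaries."""
    gaps_grid = [0, 5, 29, 30, 31, 45, 60]
    rng = np.random.default_rng(1)
    cases = []
    for n in (1, 2, 3):
        for _ in range(80):
            gaps = rng.choice(gaps_grid, size=n - 1)
            issues, t = [0], 0
            for g in gaps:
                t += 30 + int(g)
                issues.append(t)
            cases.append(issues)
    for i, issues in enumerate(cases):
        rx = make_rx([(f"P{i}", "LDX", day(t), 50.0, 30.0, 50.0, 30) for t in issues])
        eps = build_episodes(build_coverage(rx), gap_days=30)
        got = [
            ((s - day(0)).days, (e - day(0)).days)
            for s, e in zip(eps["start"], eps["end"])
        ]
        assert got == oracle_episode_bounds(issues, supply=30, gap=30), issues


def test_overlapping_refills_conserve_supply_against_queue_oracle():
    """Early refills stockpile: the day-queue oracle and the vectorised
    builder agree on episode bounds, covered days and prescription counts."""
    rng = np.random.default_rng(2)
    for case in range(150):
        n = int(rng.integers(1, 7))
        records = []
        t = 0
        for _ in range(n):
            records.append((t, int(rng.integers(7, 45))))
            t += int(rng.integers(-20, 61))  # negative step -> overlap
            t = max(t, 0)
        rx = make_rx(
            [(f"C{case}", "LDX", day(t), 50.0, float(s), 50.0, s) for t, s in records]
        )
        eps = build_episodes(build_coverage(rx), gap_days=30, overlap="shift")
        want = oracle_supply_queue(records, gap=30)
        got = [
            {
                "start": (row.start - day(0)).days,
                "end": (row.end - day(0)).days,
                "covered": int(row.covered_days),
                "n": int(row.n_prescriptions),
            }
            for row in eps.itertuples()
        ]
        assert got == want, records


def test_merging_conserves_mg_and_days(sim_small):
    cov = build_coverage(sim_small.prescriptions)
    eps = build_episodes(cov, gap_days=30, overlap="shift")
    assert eps["covered_days"].sum() == pytest.approx(cov["days"].sum())
    assert eps["total_mg"].sum() == pytest.approx(cov["total_mg"].sum())


def test_episode_building_is_idempotent(sim_small):
    cov = build_coverage(sim_small.prescriptions)
    eps = build_episodes(cov, gap_days=30)
    # re-express episodes as intervals and merge again
    as_intervals = pd.DataFrame(
        {
            "patient_id": eps["patient_id"],
            "drug": eps["drug"],
            "start": eps["start"],
            "end": eps["end"],
            "days": eps["covered_days"],
            "dose_mg_per_day": np.nan,
            "total_mg": eps["total_mg"],
            "rx_index": range(len(eps)),
        }
    )
    again = build_episodes(as_intervals, gap_days=30)
    left = eps[["patient_id", "drug", "start"]].reset_index(drop=True)
    right = again[["patient_id", "drug", "start"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(left, right)
    assert (again["covered_days"].to_numpy() == eps["covered_days"].to_numpy()).all()


def test_episode_count_monotone_in_gap_days(sim_small):
    cov = build_coverage(sim_small.prescriptions)
    counts = [len(build_episodes(cov, gap_days=g)) for g in (7, 14, 30, 60, 90)]
    assert counts == sorted(counts, reverse=True)


def test_exposure_and_repeat_user():
    one = make_rx([("P1", "LDX", day(0), 50.0, 30.0, 50.0, 30)])
    exp = patient_exposure(build_episodes(build_coverage(one)))
    assert not exp.loc[0, "repeat_user"]
    assert exp.loc[0, "duration_days"] == 30

    two = make_rx(
        [
            ("P1", "LDX", day(0), 50.0, 30.0, 50.0, 30),
            ("P1", "LDX", day(40), 50.0, 30.0, 50.0, 30),
        ]
    )
    exp = patient_exposure(build_episodes(build_coverage(two)))
    assert bool(exp.loc[0, "repeat_user"])
    assert exp.loc[0, "n_episodes"] == 1


def test_forced_single_prescription_cohort_has_no_repeat_users():
    from rxdur import SimulationConfig, simulate_cohort

    co = simulate_cohort(
        SimulationConfig(
            n_patients=100, seed=1, discontinuation_hazard=1.0, switch_hazard=0.0,
            p_continuation_from_adolescence=0.0,
        )
    )
    exp = patient_exposure(build_episodes(build_coverage(co.prescriptions)))
    assert not exp["repeat_user"].any()


@pytest.mark.parametrize(
    "doses,days,expected,over",
    [
        ([(50.0, 30)], 30, 50.0, False),
        ([(100.0, 30)], 30, 100.0, True),
        ([(30.0, 30), (70.0, 30)], 60, 50.0, False),  # weighted mean oracle
    ],
)
def test_average_daily_dose(doses, days, expected, over):
    rows = []
    t = 0
    for dose, supply in doses:
        rows.append(("P1", "LDX", day(t), dose, float(supply), dose, supply))
        t += supply
    add = average_daily_dose(build_coverage(make_rx(rows)), cap_mg=70.0)
    assert add.loc[0, "add_mg_per_day"] == pytest.approx(expected)
    assert bool(add.loc[0, "exceeds_cap"]) is over
    assert add.loc[0, "covered_days"] == days


def test_dose_at_cap_does_not_exceed():
    rx = make_rx([("P1", "LDX", day(0), 70.0, 30.0, 70.0, 30)])
    add = average_daily_dose(build_coverage(rx), cap_mg=70.0)
    assert not bool(add.loc[0, "exceeds_cap"])


@given(
    dose=st.sampled_from([20.0, 30.0, 50.0, 70.0]),
    supply=st.integers(min_value=2, max_value=60).filter(lambda s: s % 2 == 0),
)
def test_add_invariant_to_splitting_a_prescription(dose, supply):
    """Splitting one prescription into two half-quantity prescriptions
    covering the same days leaves the average daily dose unchanged."""
    whole = make_rx([("P1", "LDX", day(0), dose, float(supply), dose, supply)])
    half = supply // 2
    split = make_rx(
        [
            ("P1", "LDX", day(0), dose, float(half), dose, half),
            ("P1", "LDX", day(half), dose, float(half), dose, half),
        ]
    )
    add_w = average_daily_dose(build_coverage(whole))
    add_s = average_daily_dose(build_coverage(split))
    assert add_w.loc[0, "add_mg_per_day"] == pytest.approx(add_s.loc[0, "add_mg_per_day"])
    assert add_w.loc[0, "covered_days"] == add_s.loc[0, "covered_days"]
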