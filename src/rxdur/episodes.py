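"""Treatment-episode construction from prescription events.

Each dispensing is first expanded into a *coverage interval* — the days it
is assumed to supply medication — and intervals for one patient and drug
are then chained into *treatment episodes*: maximal runs in which no gap
between the end of one prescription period and the next issue exceeds a
grace period (30 days by default, the convention shared with the
discontinuation and switching definitions).

Coverage length is taken from the recorded days' supply where the source
captures it, else derived as ``quantity x strength / daily instruction``,
else a configured default.  When a refill is issued before the previous
supply runs out the default behaviour is *stockpiling*: the new coverage
starts when the previous ends, so no dispensed supply is discarded
(``overlap="truncate"`` clips instead).

Exposure duration is reported as the sum of episode spans (first issue to
end of final coverage, per episode), which is consistent with >30-day gaps
terminating an episode.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .types import Drug

COVERAGE_COLUMNS = [
    "patient_id",
    "drug",
    "start",
    "end",
    "days",
    "dose_mg_per_day",
    "total_mg",
    "rx_index",
]

_DAY = np.timedelta64(1, "D")


def build_coverage(
    prescriptions: pd.DataFrame,
    default_supply_days: Optional[int] = 30,
) -> pd.DataFrame:
    """Map each prescription to one coverage interval.

    Interval length precedence: recorded ``supply_days``; else
    ``quantity x strength_mg / daily_dose_instruction_mg`` (rounded to whole
    days, minimum 1); else ``default_supply_days``.  The daily dose is the
    recorded instruction where present, else total mg spread over the
    interval.

    Raises
    ------
    ValueError
        If a prescription has no basis for an interval length and no
        default is configured (``default_supply_days=None``).
    """
    rx = prescriptions.reset_index(drop=True)
    n = len(rx)
    if n == 0:
        return pd.DataFrame(columns=COVERAGE_COLUMNS)

    strength = pd.to_numeric(rx.get("strength_mg"), errors="coerce")
    quantity = pd.to_numeric(rx.get("quantity"), errors="coerce")
    instruction = pd.to_numeric(rx.get("daily_dose_instruction_mg"), errors="coerce")
    supply = pd.to_numeric(rx.get("supply_days"), errors="coerce")

    total_mg_disp = strength * quantity  # NaN when either is missing

    days = supply.astype(float)
    derivable = days.isna() & total_mg_disp.notna() & instruction.notna()
    days[derivable] = np.maximum(
        1.0, np.rint(total_mg_disp[derivable] / instruction[derivable])
    )
    missing = days.isna()
    if missing.any():
        if default_supply_days is None:
            bad = list(rx.index[missing][:5])
            raise ValueError(
                f"{int(missing.sum())} prescriptions (e.g. rows {bad}) have no "
                "supply_days, no quantity/strength/instruction, and no default "
                "supply is configured"
            )
        days[missing] = float(default_supply_days)
    days = days.astype(int)

    dose = instruction.astype(float)
    dose_missing = dose.isna()
    dose[dose_missing] = total_mg_disp[dose_missing] / days[dose_missing]
    # with neither instruction nor quantity x strength, the dose is unknown;
    # leave NaN (dose enters ADD and off-label checks, not episode timing)
    total_mg = total_mg_disp.where(total_mg_disp.notna(), dose * days)

    start = pd.to_datetime(rx["issue_date"])
    out = pd.DataFrame(
        {
            "patient_id": rx["patient_id"],
            "drug": rx["drug"],
            "start": start,
            "end": start + days.to_numpy() * _DAY,
            "days": days,
            "dose_mg_per_day": dose,
            "total_mg": total_mg,
            "rx_index": rx.index,
        }
    )
    return out


def _merges(gap: float, gap_days: int, boundary: str) -> bool:
    return gap <= gap_days if boundary == "inclusive" else gap < gap_days


def stack_coverage(
    coverage: pd.DataFrame,
    gap_days: int = 30,
    overlap: str = "shift",
    boundary: str = "inclusive",
) -> pd.DataFrame:
    """Resolve overlaps and assign an episode id to every coverage interval.

    Returns the coverage table with ``eff_start``, ``eff_end``, ``eff_days``,
    ``eff_mg`` and ``episode_id`` columns.  ``overlap="shift"`` defers early
    refills to the end of the running supply (conserving dispensed days and
    mg); ``"truncate"`` clips them, discarding the overlapped supply.
    An interval opens a new episode when its issue date falls more than
    ``gap_days`` after the running episode's coverage end.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be non-negative")
    if overlap not in ("shift", "truncate"):
        raise ValueError(f"unknown overlap policy {overlap!r}")
    if boundary not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown boundary convention {boundary!r}")
    if coverage.empty:
        out = coverage.copy()
        for col in ("eff_start", "eff_end"):
            out[col] = pd.Series(dtype="datetime64[ns]")
        for col in ("eff_days", "eff_mg", "episode_id"):
            out[col] = pd.Series(dtype=float)
        return out

    cov = coverage.sort_values(
        ["patient_id", "drug", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)

    starts = cov["start"].to_numpy("datetime64[D]")
    ends = cov["end"].to_numpy("datetime64[D]")
    days = cov["days"].to_numpy(float)
    mg = cov["total_mg"].to_numpy(float)
    keys = (cov["patient_id"].astype(str) + "\x00" + cov["drug"].astype(str)).to_numpy()

    eff_start = starts.copy()
    eff_end = ends.copy()
    eff_days = days.copy()
    eff_mg = mg.copy()
    episode = np.zeros(len(cov), dtype=int)

    running_end = None
    ep = 0
    prev_key = None
    for i in range(len(cov)):
        if keys[i] != prev_key:
            prev_key = keys[i]
            running_end = None
            ep = 0
        if running_end is None:
            ep = 0
        else:
            gap = (starts[i] - running_end) / _DAY
            if not _merges(gap, gap_days, boundary):
                ep += 1
                running_end = None
        if running_end is not None and starts[i] < running_end:
            if overlap == "shift":
                eff_start[i] = running_end
                eff_end[i] = running_end + int(days[i]) * _DAY
            else:  # truncate
                eff_start[i] = running_end
                new_end = max(ends[i], running_end)
                eff_end[i] = new_end
                kept = (new_end - running_end) / _DAY
                if days[i] > 0:
                    eff_mg[i] = mg[i] * kept / days[i]
                eff_days[i] = kept
        episode[i] = ep
        end_i = eff_end[i]
        running_end = end_i if running_end is None else max(running_end, end_i)

    cov["eff_start"] = pd.to_datetime(eff_start)
    cov["eff_end"] = pd.to_datetime(eff_end)
    cov["eff_days"] = eff_days
    cov["eff_mg"] = eff_mg
    cov["episode_id"] = episode
    return cov


def build_episodes(
    coverage: pd.DataFrame,
    gap_days: int = 30,
    overlap: str = "shift",
    boundary: str = "inclusive",
) -> pd.DataFrame:
    """Merge coverage intervals into treatment episodes.

    A gap of at most ``gap_days`` between the running coverage end and the
    next issue keeps the episode alive (under the default inclusive
    boundary); a longer gap closes it.  Overlapping supply is handled per
    ``overlap`` (see :func:`stack_coverage`).

    Returns one row per (patient, drug, episode) with the issue count,
    total mg, covered days and the episode span in days.
    """
    stacked = stack_coverage(coverage, gap_days, overlap, boundary)
    if stacked.empty:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "drug",
                "episode_id",
                "start",
                "end",
                "n_prescriptions",
                "total_mg",
                "covered_days",
                "span_days",
            ]
        )
    grouped = stacked.groupby(["patient_id", "drug", "episode_id"], sort=True)
    ep = grouped.agg(
        start=("eff_start", "min"),
        end=("eff_end", "max"),
        n_prescriptions=("rx_index", "size"),
        total_mg=("eff_mg", "sum"),
        covered_days=("eff_days", "sum"),
    ).reset_index()
    ep["span_days"] = (ep["end"] - ep["start"]).dt.days
    return ep


def patient_exposure(episodes: pd.DataFrame, drug: str = Drug.LDX.value) -> pd.DataFrame:
    """Per-patient exposure measures for one drug.

    ``duration_days`` (the headline exposure figure) sums episode spans;
    ``overall_span_days`` (first issue to last coverage end, crossing any
    gaps) is also reported for comparability with span-based conventions.
    A *repeat user* has more than one prescription of the drug overall.
    """
    sub = episodes[episodes["drug"] == drug]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "n_episodes",
                "n_prescriptions",
                "duration_days",
                "covered_days",
                "first_start",
                "last_end",
                "overall_span_days",
                "repeat_user",
            ]
        )
    g = sub.groupby("patient_id", sort=True)
    out = g.agg(
        n_episodes=("episode_id", "size"),
        n_prescriptions=("n_prescriptions", "sum"),
        duration_days=("span_days", "sum"),
        covered_days=("covered_days", "sum"),
        first_start=("start", "min"),
        last_end=("end", "max"),
    ).reset_index()
    out["overall_span_days"] = (out["last_end"] - out["first_start"]).dt.days
    out["repeat_user"] = out["n_prescriptions"] > 1
    return out


def average_daily_dose(
    coverage: pd.DataFrame,
    cap_mg: float = 70.0,
    drug: str = Drug.LDX.value,
) -> pd.DataFrame:
    """Per-patient average daily dose: total mg over total covered days.

    Gaps between prescriptions are excluded (covered days form the
    denominator), so long treatment pauses do not dilute the dose — the
    quantity is mg per day *on supply*.  ``exceeds_cap`` is strict
    (``> cap_mg``); the conventional maximum for the index drug is
    70 mg/day.  Patients whose intervals carry no dose information
    (missing instruction and quantity/strength) get a NaN dose.
    """
    sub = coverage[coverage["drug"] == drug]
    if sub.empty:
        return pd.DataFrame(
            columns=["patient_id", "add_mg_per_day", "exceeds_cap", "total_mg", "covered_days"]
        )
    g = sub.groupby("patient_id", sort=True)
    # a missing per-interval mg (no instruction, no quantity/strength) makes
    # the patient's dose unknown rather than silently smaller
    out = g.agg(
        total_mg=("total_mg", lambda s: s.sum(skipna=False)),
        covered_days=("days", "sum"),
    ).reset_index()
    if (out["covered_days"] <= 0).any():
        raise ValueError("zero covered days for at least one patient")
    out["add_mg_per_day"] = out["total_mg"] / out["covered_days"]
    out["exceeds_cap"] = out["add_mg_per_day"] > cap_mg
    return out[["patient_id", "add_mg_per_day", "exceeds_cap", "total_mg", "covered_days"]]
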