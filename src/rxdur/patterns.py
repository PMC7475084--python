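"""Treatment-pattern classification: discontinuation and switching.

All three definitions share one grace period (30 days by default) and are
anchored at the *end of a prescription period* (the coverage end, after
overlap resolution), not at issue dates:

* **discontinuation** — an index-drug prescription period ends and no ADHD
  medication (index or other) is issued within the grace window after it,
  with no evidence of switching;
* **switch to the index drug** — an index-drug issue within the grace
  window after the end of another ADHD drug's prescription period;
* **switch from the index drug** — an issue of any other ADHD medication
  within the grace window after the end of an index-drug prescription
  period.

A patient whose last prescription period ends too close to the end of the
observation window to adjudicate (end + grace > window end) is *censored*
rather than discontinued; the unadjudicated ("naive") count is reported
alongside for comparability with analyses that ignore censoring.

``boundary="inclusive"`` means an event exactly ``gap_days`` after a period
end still falls in the window (day 30 counts, day 31 does not).
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np
import pandas as pd

from .episodes import build_episodes, stack_coverage
from .types import ADHD_DRUGS, OTHER_ADHD_DRUGS, Drug

FLAG_COLUMNS = [
    "patient_id",
    "discontinued",
    "discontinued_naive",
    "switched_to_ldx",
    "switched_from_ldx",
    "censored",
    "overlap_initiation",
    "discontinuation_date",
    "switch_to_date",
    "switch_from_date",
]

WindowEnd = Union[pd.Timestamp, str, Mapping, pd.Series]

_ADHD_VALUES = {d.value for d in ADHD_DRUGS}
_OTHER_VALUES = {d.value for d in OTHER_ADHD_DRUGS}


def _in_window(diff_days: pd.Series, gap_days: int, boundary: str) -> pd.Series:
    upper = diff_days <= gap_days if boundary == "inclusive" else diff_days < gap_days
    return (diff_days >= 0) & upper


def _window_end_series(window_end: WindowEnd, patient_ids: pd.Series) -> pd.Series:
    """Broadcast a scalar or per-patient window end over a patient column."""
    if isinstance(window_end, (pd.Series, dict)):
        we = pd.Series(window_end)
        we = pd.to_datetime(we)
        return patient_ids.map(we)
    return pd.Series(pd.to_datetime(window_end), index=patient_ids.index)


def _anchored_hits(
    anchors: pd.DataFrame,
    issues: pd.DataFrame,
    gap_days: int,
    boundary: str,
) -> pd.DataFrame:
    """All (anchor end, issue) pairs with the issue inside the grace window.

    ``anchors`` needs columns patient_id/end; ``issues`` patient_id/issue_date.
    """
    if anchors.empty or issues.empty:
        return pd.DataFrame(columns=["patient_id", "end", "issue_date"])
    merged = anchors.merge(issues, on="patient_id", how="inner")
    diff = (merged["issue_date"] - merged["end"]).dt.days
    return merged[_in_window(diff, gap_days, boundary)]


def classify_discontinuation(
    ldx_episodes: pd.DataFrame,
    prescriptions: pd.DataFrame,
    window_end: WindowEnd,
    gap_days: int = 30,
    boundary: str = "inclusive",
) -> pd.DataFrame:
    """Per-patient discontinuation and censoring flags.

    A discontinuation event occurs at an index-drug episode end with no
    ADHD-medication issue in the grace window, provided the window is fully
    observed (end + gap <= window end).  The patient-level flag is "ever
    discontinued"; ``discontinuation_date`` is the first qualifying end.
    ``discontinued_naive`` ignores the censoring condition.
    """
    eps = ldx_episodes[ldx_episodes["drug"] == Drug.LDX.value]
    cols = ["patient_id", "discontinued", "discontinued_naive", "censored", "discontinuation_date"]
    if eps.empty:
        return pd.DataFrame(columns=cols)
    if eps["end"].isna().any():
        raise ValueError("episodes carry missing end dates")

    adhd_issues = prescriptions.loc[
        prescriptions["drug"].isin(_ADHD_VALUES), ["patient_id", "issue_date"]
    ]
    ends = eps[["patient_id", "end"]].copy()
    hits = _anchored_hits(ends, adhd_issues, gap_days, boundary)
    hit_keys = set(zip(hits["patient_id"], hits["end"]))
    ends["event_free"] = [
        (p, e) not in hit_keys for p, e in zip(ends["patient_id"], ends["end"])
    ]
    we = _window_end_series(window_end, ends["patient_id"])
    if we.isna().any():
        raise ValueError("window_end missing for some patients")
    ends["adjudicable"] = ends["end"] + pd.to_timedelta(gap_days, "D") <= we

    disc_events = ends[ends["event_free"] & ends["adjudicable"]]
    per = ends.groupby("patient_id", sort=True)
    out = pd.DataFrame({"patient_id": sorted(ends["patient_id"].unique())})
    out["discontinued"] = out["patient_id"].isin(disc_events["patient_id"].unique())
    out["discontinued_naive"] = out["patient_id"].isin(
        ends.loc[ends["event_free"], "patient_id"].unique()
    )
    # censoring is judged at the final episode end only
    last = ends.loc[per["end"].idxmax()]
    censored_ids = set(last.loc[last["event_free"] & ~last["adjudicable"], "patient_id"])
    out["censored"] = out["patient_id"].isin(censored_ids)
    first_date = disc_events.groupby("patient_id")["end"].min()
    out["discontinuation_date"] = out["patient_id"].map(first_date)
    return out[cols]


def classify_switch_to_ldx(
    other_coverage: pd.DataFrame,
    prescriptions: pd.DataFrame,
    gap_days: int = 30,
    boundary: str = "inclusive",
) -> pd.DataFrame:
    """Per-patient flag: index drug issued within the grace window after the
    end of another ADHD drug's prescription period.

    ``other_coverage`` is stacked coverage (``eff_end`` present) or raw
    coverage (falls back to ``end``) for non-index ADHD drugs.  An index
    issue during *ongoing* other-drug coverage is reported separately as
    ``overlap_initiation`` and only counts as a switch if it also lands
    within the window after that coverage's end.
    """
    end_col = "eff_end" if "eff_end" in other_coverage.columns else "end"
    others = other_coverage[other_coverage["drug"].isin(_OTHER_VALUES)]
    ldx_issues = prescriptions.loc[
        prescriptions["drug"] == Drug.LDX.value, ["patient_id", "issue_date"]
    ]
    cols = ["patient_id", "switched_to_ldx", "overlap_initiation", "switch_to_date"]
    anchors = others[["patient_id", end_col]].rename(columns={end_col: "end"})
    hits = _anchored_hits(anchors, ldx_issues, gap_days, boundary)

    pids = sorted(
        set(others["patient_id"]).union(ldx_issues["patient_id"].unique())
    )
    out = pd.DataFrame({"patient_id": pids})
    out["switched_to_ldx"] = out["patient_id"].isin(hits["patient_id"].unique())

    if others.empty or ldx_issues.empty:
        out["overlap_initiation"] = False
    else:
        start_col = "eff_start" if "eff_start" in other_coverage.columns else "start"
        spans = others[["patient_id", start_col, end_col]].rename(
            columns={start_col: "start", end_col: "end"}
        )
        m = spans.merge(ldx_issues, on="patient_id")
        inside = m[(m["issue_date"] >= m["start"]) & (m["issue_date"] < m["end"])]
        out["overlap_initiation"] = out["patient_id"].isin(inside["patient_id"].unique())
    first = hits.groupby("patient_id")["issue_date"].min()
    out["switch_to_date"] = out["patient_id"].map(first)
    return out[cols]


def classify_switch_from_ldx(
    ldx_coverage: pd.DataFrame,
    prescriptions: pd.DataFrame,
    gap_days: int = 30,
    boundary: str = "inclusive",
) -> pd.DataFrame:
    """Per-patient flag: any other ADHD medication issued within the grace
    window after the end of an index-drug prescription period."""
    end_col = "eff_end" if "eff_end" in ldx_coverage.columns else "end"
    ldx = ldx_coverage[ldx_coverage["drug"] == Drug.LDX.value]
    other_issues = prescriptions.loc[
        prescriptions["drug"].isin(_OTHER_VALUES), ["patient_id", "issue_date"]
    ]
    anchors = ldx[["patient_id", end_col]].rename(columns={end_col: "end"})
    hits = _anchored_hits(anchors, other_issues, gap_days, boundary)
    pids = sorted(set(ldx["patient_id"]))
    out = pd.DataFrame({"patient_id": pids})
    out["switched_from_ldx"] = out["patient_id"].isin(hits["patient_id"].unique())
    first = hits.groupby("patient_id")["issue_date"].min()
    out["switch_from_date"] = out["patient_id"].map(first)
    return out[["patient_id", "switched_from_ldx", "switch_from_date"]]


def classify_patterns(
    coverage: pd.DataFrame,
    prescriptions: pd.DataFrame,
    window_end: WindowEnd,
    gap_days: int = 30,
    boundary: str = "inclusive",
    overlap: str = "shift",
) -> pd.DataFrame:
    """Full per-patient pattern flags from coverage + prescription events.

    Builds stacked coverage and index-drug episodes internally (with the
    same grace period, so the three definitions stay coherent) and returns
    one row per patient appearing in ``prescriptions``.
    """
    stacked = stack_coverage(coverage, gap_days, overlap, boundary)
    episodes = build_episodes(coverage, gap_days, overlap, boundary)

    pids = sorted(prescriptions["patient_id"].unique())
    out = pd.DataFrame({"patient_id": pids})

    disc = classify_discontinuation(episodes, prescriptions, window_end, gap_days, boundary)
    to = classify_switch_to_ldx(stacked, prescriptions, gap_days, boundary)
    frm = classify_switch_from_ldx(stacked, prescriptions, gap_days, boundary)

    out = (
        out.merge(disc, on="patient_id", how="left")
        .merge(to, on="patient_id", how="left")
        .merge(frm, on="patient_id", how="left")
    )
    for col in (
        "discontinued",
        "discontinued_naive",
        "switched_to_ldx",
        "switched_from_ldx",
        "censored",
        "overlap_initiation",
    ):
        out[col] = out[col].astype("boolean").fillna(False).astype(bool)
    return out[FLAG_COLUMNS]
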