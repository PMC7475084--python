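"""Independent brute-force oracles used by the test suite.

Everything here works on plain integers (days since an epoch) and python
lists, deliberately avoiding the vectorised pandas code paths of the
package, so agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

EPOCH = pd.Timestamp("2015-01-01")


def day(n: int) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(int(n), "D")


def events_to_frames(events, patient_id="P0", supply=30):
    """Turn [(drug, issue_day), ...] into a prescriptions DataFrame."""
    rows = [
        {
            "patient_id": patient_id,
            "drug": drug,
            "issue_date": day(issue),
            "strength_mg": 50.0,
            "quantity": float(supply),
            "daily_dose_instruction_mg": 50.0,
            "supply_days": supply,
        }
        for drug, issue in events
    ]
    return pd.DataFrame(rows)


def oracle_episode_bounds(issues, supply=30, gap=30):
    """Episode (start, end) list for one drug's non-overlapping issues.

    Interval-union-with-tolerance: a new issue at most ``gap`` days after
    the running coverage end extends the episode.
    """
    episodes = []
    for issue in sorted(issues):
        end = issue + supply
        if episodes and issue - episodes[-1][1] <= gap:
            episodes[-1][1] = max(episodes[-1][1], end)
        else:
            episodes.append([issue, end])
    return [tuple(e) for e in episodes]


def oracle_supply_queue(records, gap=30):
    """Stockpiling oracle for possibly-overlapping records of one drug.

    ``records`` is [(issue_day, supply_days), ...].  Supply is modelled as
    a queue of medication-days consumed from ``max(issue, previous end)``;
    an issue more than ``gap`` days after the running end starts a fresh
    episode.  Returns per-episode dicts with start/end/covered/n.
    """
    episodes = []
    running_end = None
    for issue, supply_days in sorted(records):
        if running_end is not None and issue - running_end > gap:
            running_end = None
        if running_end is None:
            start = issue
            episodes.append({"start": issue, "end": issue, "covered": 0, "n": 0})
            running_end = issue
        consume_from = max(issue, running_end)
        running_end = consume_from + supply_days
        episodes[-1]["end"] = running_end
        episodes[-1]["covered"] += supply_days
        episodes[-1]["n"] += 1
    return episodes


def oracle_pattern_flags(events, window_end, supply=30, gap=30):
    """Quadratic-scan pattern flags for one patient's event list.

    ``events`` is [(drug, issue_day), ...] with same-drug issues at least
    ``supply`` apart (no within-drug overlap); drugs other than 'LDX' and
    'non_ADHD' count as other ADHD medication.
    """
    ldx_issues = sorted(i for d, i in events if d == "LDX")
    other_issues = sorted(i for d, i in events if d not in ("LDX", "non_ADHD"))
    adhd_issues = sorted(ldx_issues + other_issues)
    ldx_ends = [i + supply for i in ldx_issues]
    other_ends = [i + supply for i in other_issues]

    def in_window(d, e):
        return 0 <= d - e <= gap

    switched_from = any(in_window(d, e) for e in ldx_ends for d in other_issues)
    switched_to = any(in_window(d, e) for e in other_ends for d in ldx_issues)

    # an LDX coverage end is an episode end iff no LDX issue follows within the gap
    episode_ends = [
        e for e in ldx_ends if not any(in_window(d, e) for d in ldx_issues)
    ]
    event_free = [
        e for e in episode_ends if not any(in_window(d, e) for d in adhd_issues)
    ]
    discontinued = any(e + gap <= window_end for e in event_free)
    discontinued_naive = bool(event_free)
    censored = False
    if ldx_ends:
        last = max(episode_ends) if episode_ends else max(ldx_ends)
        censored = (
            last + gap > window_end
            and not any(in_window(d, last) for d in adhd_issues)
        )
    return {
        "discontinued": discontinued,
        "discontinued_naive": discontinued_naive,
        "switched_to_ldx": switched_to,
        "switched_from_ldx": switched_from,
        "censored": censored,
    }


def oracle_summarize(patients, prescriptions, diagnoses, truth, cap_mg=70.0):
    """Recompute headline cohort quantities straight from raw events.

    Used as the independent side of the dual-path aggregation check; works
    per patient with dict loops, no pandas groupbys.
    """
    ldx_counts = defaultdict(int)
    for _, row in prescriptions.iterrows():
        if row["drug"] == "LDX":
            ldx_counts[row["patient_id"]] += 1
    n_users = len(ldx_counts)
    repeat = sum(1 for c in ldx_counts.values() if c > 1)
    return {
        "n_patients": n_users,
        "n_prescriptions": sum(ldx_counts.values()),
        "repeat_users_n": repeat,
        "repeat_users_pct": 100.0 * repeat / n_users if n_users else float("nan"),
    }
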