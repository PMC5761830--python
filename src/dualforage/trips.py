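"""Foraging-trip extraction, short/long classification and session exclusions.

A foraging trip is a maximal run of colony absence.  Dual-foraging seabirds mix
short provisioning trips (ST) with long self-maintenance trips (LT); the two
populations are well described by log-normal durations, so the ST/LT threshold
is the cut-off that minimizes the summed within-class variance of
log-durations.  Trips clipped by the start or end of the 48-h watch are never
classified: their windows — and the partner's records over the same span — are
masked out before any coordination statistic is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CO, LT, MASKED, ST, SessionGrid, presence_runs

#: one 10-min window expressed in hours
WINDOW_HOURS = 10.0 / 60.0


@dataclass
class Trip:
    pair_id: str
    session_id: str
    bird_role: str
    start_window: int
    n_windows: int
    truncated_start: bool
    truncated_end: bool
    trip_type: Optional[str] = None  # "ST" | "LT" | None (unclassified)

    @property
    def duration_h(self) -> float:
        return self.n_windows * WINDOW_HOURS

    @property
    def truncated(self) -> bool:
        return self.truncated_start or self.truncated_end

    @property
    def end_window(self) -> int:
        """First window after the trip (half-open convention)."""
        return self.start_window + self.n_windows


@dataclass(frozen=True)
class CutoffResult:
    cutoff_h: float
    objective: float
    n_short: int
    n_long: int


@dataclass(frozen=True)
class FeedingEvent:
    pair_id: str
    session_id: str
    bird_role: str
    window_index: int


@dataclass
class PairSession:
    """Both birds' processed timelines for one 48-h session.

    ``labels_*`` hold per-window codes (CO/ST/LT/MASKED); ``excluded`` flags a
    session dropped from the coordination analysis (female desertion or faded
    colour marks), without deleting its data.
    """

    pair_id: str
    session_id: str
    grid: SessionGrid
    labels_female: np.ndarray
    labels_male: np.ndarray
    trips: list  # all trips of both birds, classified where possible
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def labels(self, role: str) -> np.ndarray:
        return self.labels_female if role == "female" else self.labels_male


def extract_trips(
    present: np.ndarray, pair_id: str, session_id: str, bird_role: str
) -> list[Trip]:
    """One Trip per colony-absence run, with truncation flags from run position."""
    runs = presence_runs(present)
    n = len(present)
    trips = []
    for state, start, length in runs:
        if state != "absent":
            continue
        trips.append(
            Trip(
                pair_id=pair_id,
                session_id=session_id,
                bird_role=bird_role,
                start_window=start,
                n_windows=length,
                truncated_start=(start == 0),
                truncated_end=(start + length == n),
            )
        )
    return trips


def _split_objective(logs_sorted: np.ndarray, k: int) -> float:
    """Sum of sample variances of logs_sorted[:k] and logs_sorted[k:]."""
    return float(np.var(logs_sorted[:k], ddof=1) + np.var(logs_sorted[k:], ddof=1))


def estimate_cutoff(durations_h: Sequence[float], min_class_size: int = 2) -> CutoffResult:
    """Short/long cut-off minimizing the summed within-class variance of log-durations.

    Candidate cut-offs are the midpoints (in log space) between consecutive
    distinct sorted log-durations — the objective is piecewise constant between
    data points, so this grid is exact.  Splits leaving either class below
    ``min_class_size`` (variance needs n >= 2) are skipped.  The cut-off is
    returned in hours, ``exp`` of the best log-space candidate.
    """
    d = np.asarray(durations_h, dtype=float)
    if d.size < 2 * min_class_size:
        raise ValueError(
            f"need at least {2 * min_class_size} durations, got {d.size}"
        )
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    logs = np.sort(np.log(d))
    distinct = np.unique(logs)
    if distinct.size < 2:
        raise ValueError("all durations identical; no split exists")

    best: Optional[tuple[float, float, int]] = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cand = 0.5 * (lo + hi)
        k = int(np.searchsorted(logs, cand))  # size of the short class (< cand)
        if k < min_class_size or logs.size - k < min_class_size:
            continue
        obj = _split_objective(logs, k)
        if best is None or obj < best[1]:
            best = (cand, obj, k)
    if best is None:
        raise ValueError(
            f"no admissible split with min_class_size={min_class_size}"
        )
    cand, obj, k = best
    return CutoffResult(
        cutoff_h=float(np.exp(cand)),
        objective=obj,
        n_short=k,
        n_long=int(logs.size - k),
    )


def classify_trips(trips: Sequence[Trip], cutoff_h: float) -> list[Trip]:
    """Assign ST (< cutoff) or LT (>= cutoff); truncated trips stay unclassified."""
    if cutoff_h <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_h}")
    out = []
    for t in trips:
        if t.truncated:
            out.append(replace(t, trip_type=None))
        else:
            out.append(replace(t, trip_type="ST" if t.duration_h < cutoff_h else "LT"))
    return out


def build_labels(present: np.ndarray, trips: Sequence[Trip]) -> np.ndarray:
    """Per-window activity codes for one bird: CO where present, trip type where absent.

    Truncated (unclassified) trips are coded MASKED here; partner-side masking
    is applied afterwards by :func:`apply_exclusions`.
    """
    labels = np.full(len(present), CO, dtype=np.int8)
    for t in trips:
        if t.trip_type == "ST":
            code = ST
        elif t.trip_type == "LT":
            code = LT
        else:
            code = MASKED
        labels[t.start_window : t.end_window] = code
    return labels


def feedings_from_trips(trips: Sequence[Trip]) -> list[FeedingEvent]:
    """One feeding per trip that ends inside the session, at the first colony window after it."""
    events = [
        FeedingEvent(t.pair_id, t.session_id, t.bird_role, t.end_window)
        for t in trips
        if not t.truncated_end
    ]
    return sorted(events, key=lambda e: e.window_index)


def apply_exclusions(
    pair_id: str,
    session_id: str,
    grid: SessionGrid,
    present_female: np.ndarray,
    present_male: np.ndarray,
    trips_female: Sequence[Trip],
    trips_male: Sequence[Trip],
    faded_marks: bool = False,
    partner_masking: bool = True,
    mask_style: str = "span",
) -> PairSession:
    """Build masked pair timelines and apply the session-level exclusion rules.

    Masking removes every truncated trip along with the partner's concurrent
    records, symmetrically: both birds end up with the identical MASKED span
    (the default ``mask_style="span"``).  A partner trip clipped by that span
    survives as a *fragment*; the randomization engine pins fragments in place
    rather than shuffling them, because trips straddling a masked span are
    length-biased and not exchangeable with complete trips.
    ``mask_style="whole_trip"`` instead expands the mask over any straddling
    trip of either bird to a fixed point (no fragments, but far more data
    masked); ``partner_masking=False`` masks only the owner's records.  Both
    alternatives are diagnostics.

    A session is flagged excluded when the female fed at most once in the
    whole 48 h (brood desertion) or when colour marks had faded.
    """
    lab_f = build_labels(present_female, trips_female)
    lab_m = build_labels(present_male, trips_male)

    n = len(present_female)
    if partner_masking:
        mask = np.zeros(n, dtype=bool)
        for t in list(trips_female) + list(trips_male):
            if t.truncated:
                mask[t.start_window : t.end_window] = True
        if mask_style == "whole_trip":
            changed = mask.any()
            while changed:
                changed = False
                for t in list(trips_female) + list(trips_male):
                    span = mask[t.start_window : t.end_window]
                    if span.any() and not span.all():
                        mask[t.start_window : t.end_window] = True
                        changed = True
        elif mask_style != "span":
            raise ValueError(f"unknown mask_style {mask_style!r}")
        lab_f[mask] = MASKED
        lab_m[mask] = MASKED
    else:
        for trips, own in ((trips_female, lab_f), (trips_male, lab_m)):
            for t in trips:
                if t.truncated:
                    own[t.start_window : t.end_window] = MASKED

    excluded = False
    reason = None
    n_female_feeds = len(feedings_from_trips(trips_female))
    if n_female_feeds <= 1:
        excluded, reason = True, "female_desertion"
    if faded_marks:
        excluded, reason = True, "faded_marks"

    return PairSession(
        pair_id=pair_id,
        session_id=session_id,
        grid=grid,
        labels_female=lab_f,
        labels_male=lab_m,
        trips=list(trips_female) + list(trips_male),
        excluded=excluded,
        exclusion_reason=reason,
    )


def pair_sessions_from_records(
    records: pd.DataFrame,
    grids: dict[str, SessionGrid],
    cutoff_h: Optional[float] = None,
    min_class_size: int = 2,
    faded: Optional[set[tuple[str, str]]] = None,
    partner_masking: bool = True,
    mask_style: str = "span",
) -> tuple[list[PairSession], CutoffResult]:
    """Full trip stage over a record table: extract, pool, cut, classify, exclude.

    The cut-off is estimated on untruncated trip durations pooled across every
    bird, session and year (one study-wide threshold), unless an override is
    given, in which case the reported objective refers to that cut-off.
    """
    faded = faded or set()
    per_bird: dict[tuple[str, str, str], np.ndarray] = {}
    for (pid, sid, role), bird in records.groupby(
        ["pair_id", "session_id", "bird_role"], sort=True
    ):
        n = grids[sid].n_windows
        present = np.zeros(n, dtype=bool)
        present[bird.loc[bird["present"], "window_index"].to_numpy()] = True
        per_bird[(pid, sid, role)] = present

    all_trips: dict[tuple[str, str, str], list[Trip]] = {
        key: extract_trips(present, *key) for key, present in per_bird.items()
    }
    pooled = [
        t.duration_h
        for trips in all_trips.values()
        for t in trips
        if not t.truncated
    ]
    if cutoff_h is None:
        cut = estimate_cutoff(pooled, min_class_size=min_class_size)
    else:
        logs = np.sort(np.log(pooled))
        k = int(np.searchsorted(logs, np.log(cutoff_h)))
        obj = _split_objective(logs, k) if min(k, logs.size - k) >= 2 else float("nan")
        cut = CutoffResult(cutoff_h=float(cutoff_h), objective=obj,
                           n_short=k, n_long=int(logs.size - k))

    sessions = []
    pairs = sorted({(pid, sid) for (pid, sid, _) in per_bird})
    for pid, sid in pairs:
        roles_here = [r for r in ("female", "male") if (pid, sid, r) in per_bird]
        if len(roles_here) < 2:
            warnings.warn(f"pair {pid} session {sid}: missing one bird; skipped",
                          stacklevel=2)
            continue
        tf = classify_trips(all_trips[(pid, sid, "female")], cut.cutoff_h)
        tm = classify_trips(all_trips[(pid, sid, "male")], cut.cutoff_h)
        sessions.append(
            apply_exclusions(
                pid,
                sid,
                grids[sid],
                per_bird[(pid, sid, "female")],
                per_bird[(pid, sid, "male")],
                tf,
                tm,
                faded_marks=(pid, sid) in faded,
                partner_masking=partner_masking,
                mask_style=mask_style,
            )
        )
    return sessions, cut


def trip_table(sessions: Sequence[PairSession]) -> pd.DataFrame:
    """Flat export of every extracted trip."""
    rows = [
        {
            "pair_id": t.pair_id,
            "session_id": t.session_id,
            "bird_role": t.bird_role,
            "start_window": t.start_window,
            "n_windows": t.n_windows,
            "duration_h": t.duration_h,
            "trip_type": t.trip_type or "unclassified",
            "truncated_start": t.truncated_start,
            "truncated_end": t.truncated_end,
        }
        for s in sessions
        for t in s.trips
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "session_id", "bird_role", "start_window", "n_windows",
            "duration_h", "trip_type", "truncated_start", "truncated_end",
        ],
    )
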