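"""Monte Carlo randomization engine for pair coordination statistics.

The null model shuffles each bird's sequence of activity *strings* (maximal
runs of CO / ST / LT windows) within a session: trip strings (ST or LT) are
re-ordered uniformly at random over the positions that held trip strings, and
CO strings over the positions that held CO strings — because every foraging
trip ends at the colony, this keeps exactly one randomly sampled CO string
between consecutive trip strings while leaving the number of ST and LT in a
row unconstrained.  All strings are sampled without replacement, so every
shuffle conserves the total window count, the multiset of string durations,
and each bird's per-category window totals — only the arrangement changes.

Two statistics are tested against this null, separately per session:

* ``st_lt_overlap`` — the number of windows in which one pair member is on a
  short trip while the other is on a long trip (higher = offset, coordinated
  schedules; upper-tail test);
* ``interfeed_cv`` — the coefficient of variation of inter-feeding intervals,
  feedings pooled over both parents and placed at each trip's end (lower =
  more even provisioning; lower-tail test).

Masked window spans (truncated trips and their partner's concurrent records)
are excised before string extraction; each unmasked sub-series is shuffled
separately and re-placed in its original slot, so shuffled trips never bleed
across excluded spans and observed and null statistics share the same support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations, product
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .io import CO, LT, MASKED, NAME_CODES, ST
from .trips import PairSession


class ActivityString(NamedTuple):
    """A maximal run of identical activity windows; the shuffling unit."""

    category: str  # "CO" | "ST" | "LT"
    n_windows: int


@dataclass(frozen=True)
class Segment:
    """Run-length-encoded unmasked sub-series starting at ``start``.

    ``pinned`` marks strings that are *fragments* — portions of a trip whose
    remainder was masked away by the partner-side exclusion.  Fragments are
    length-biased (long trips are the ones that straddle masked spans) and are
    therefore not exchangeable with complete trips: the shuffle keeps them
    fixed in place and permutes only complete strings.
    """

    start: int
    cats: np.ndarray  # int8 codes
    lens: np.ndarray  # int window counts
    pinned: Optional[np.ndarray] = None  # bool per string; None = none pinned

    @property
    def n_windows(self) -> int:
        return int(self.lens.sum())


@dataclass
class FeedingSeries:
    """Pooled parent feeding times of one session (windows deduplicated)."""

    pair_id: str
    session_id: str
    event_windows: np.ndarray
    bin_minutes: int = 10

    @property
    def intervals_min(self) -> np.ndarray:
        return np.diff(self.event_windows) * float(self.bin_minutes)


@dataclass
class RandomizationResult:
    statistic_name: str
    observed: float
    null_samples: np.ndarray
    p_value: float  # proportion of null draws strictly beyond the observed value
    p_mid: float  # mid-p: ties with the observed value counted half
    p_plus1: float  # (#beyond + 1) / (n_valid + 1); never exactly 0 or 1
    null_mean: float
    index: float  # (observed - null_mean) / null_mean
    n_iter: int
    n_valid_null: int
    degenerate: bool = False
    note: Optional[str] = None


# ---------------------------------------------------------------------------
# run-length encoding and segments


def _rle(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts].astype(np.int8), (ends - starts).astype(np.int64)


def timeline_to_strings(labels: np.ndarray) -> list[ActivityString]:
    """Run-length encode a timeline into activity strings (no MASKED allowed)."""
    labels = np.asarray(labels)
    if np.any(labels == MASKED):
        raise ValueError(
            "timeline contains MASKED windows; excise them first (see segments())"
        )
    cats, lens = _rle(labels)
    from .io import CODE_NAMES

    return [ActivityString(CODE_NAMES[int(c)], int(n)) for c, n in zip(cats, lens)]


def segments(labels: np.ndarray, trips: Optional[Sequence] = None) -> list[Segment]:
    """Split a timeline at MASKED spans into RLE'd unmasked sub-series.

    When the bird's ``trips`` are given, trip strings whose window span is a
    strict subset of their source trip (fragments clipped by masking) are
    marked pinned.
    """
    labels = np.asarray(labels)
    spans = set()
    if trips is not None:
        spans = {(t.start_window, t.end_window) for t in trips}
    unmasked = labels != MASKED
    segs: list[Segment] = []
    cats, lens = _rle(unmasked.astype(np.int8))
    pos = 0
    for c, n in zip(cats, lens):
        if c == 1:
            sub_cats, sub_lens = _rle(labels[pos : pos + n])
            pinned = None
            if trips is not None and len(sub_cats):
                starts = pos + np.concatenate([[0], np.cumsum(sub_lens)[:-1]])
                pinned = np.array(
                    [
                        cat != CO and (int(s), int(s + ln)) not in spans
                        for cat, s, ln in zip(sub_cats, starts, sub_lens)
                    ]
                )
                if not pinned.any():
                    pinned = None
            segs.append(Segment(start=pos, cats=sub_cats, lens=sub_lens, pinned=pinned))
        pos += int(n)
    return segs


# ---------------------------------------------------------------------------
# the constrained shuffle


def _orders(
    cats: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    pinned: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(n_iter, m) matrix of string orderings drawn from the constrained shuffle.

    The shuffle preserves the observed positional skeleton: trip strings are
    permuted uniformly at random over the positions that held trip strings,
    and CO strings over the positions that held CO strings.  Since an observed
    series alternates trips and COs, this keeps exactly one CO between
    consecutive trips while leaving the number of ST and LT in a row free —
    and it conserves the boundary structure of the series (a sub-series that
    started or ended at the colony still does so in every shuffle), which is
    what keeps the test calibrated at the session edges, where truncation
    masking makes colony presence certain.  Pinned strings (trip fragments at
    mask boundaries) never move.
    """
    m = len(cats)
    free = np.ones(m, dtype=bool) if pinned is None else ~np.asarray(pinned)
    trip_pos = np.flatnonzero((cats != CO) & free)
    co_pos = np.flatnonzero((cats == CO) & free)
    t, c = len(trip_pos), len(co_pos)
    out = np.tile(np.arange(m, dtype=np.int64), (n_iter, 1))
    if t:
        tp = np.argsort(rng.random((n_iter, t)), axis=1)
        out[:, trip_pos] = trip_pos[tp]
    if c:
        cp = np.argsort(rng.random((n_iter, c)), axis=1)
        out[:, co_pos] = co_pos[cp]
    return out


def shuffle_strings(
    strings: Sequence[ActivityString], rng: np.random.Generator
) -> list[ActivityString]:
    """One constrained shuffle of an activity-string series (see module docstring)."""
    cats = np.array([NAME_CODES[s.category] for s in strings], dtype=np.int8)
    if not np.any(cats != CO):
        warnings.warn("series contains no trip strings; returning COs in random order",
                      stacklevel=2)
    order = _orders(cats, 1, rng)[0]
    return [strings[j] for j in order]


# ---------------------------------------------------------------------------
# statistics


def st_lt_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> int:
    """Windows where one bird is on ST and the other on LT (MASKED contributes 0)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"timeline length mismatch: {a.shape} vs {b.shape}")
    return int((((a == ST) & (b == LT)) | ((a == LT) & (b == ST))).sum())


def interfeed_cv(intervals: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean) of inter-feeding intervals."""
    iv = np.asarray(intervals, dtype=float)
    if iv.size < 2:
        raise ValueError(f"need at least 2 intervals, got {iv.size}")
    return float(np.std(iv, ddof=1) / np.mean(iv))


# ---------------------------------------------------------------------------
# null construction

def _bird_matrices(
    segs: Sequence[Segment],
    n_windows: int,
    n_iter: int,
    rng: Optional[np.random.Generator],
    identity: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled (or observed, with identity=True) label matrix and feeding windows.

    Returns ``labels`` of shape (n_iter, n_windows) (MASKED outside segments)
    and ``events`` of shape (n_iter, n_strings_total) holding feeding windows
    (``inf`` marks no-event slots).  A trip ending flush with its sub-series
    end yields no feeding (truncated within the sub-series).
    """
    lab = np.full((n_iter, n_windows), MASKED, dtype=np.int8)
    ev_cols: list[np.ndarray] = []
    for seg in segs:
        m = len(seg.cats)
        if m == 0:
            continue
        if identity:
            orders = np.tile(np.arange(m, dtype=np.int64), (n_iter, 1))
        else:
            orders = _orders(seg.cats, n_iter, rng, seg.pinned)
        cats_m = seg.cats[orders]
        lens_m = seg.lens[orders]
        seg_len = seg.n_windows
        lab[:, seg.start : seg.start + seg_len] = np.repeat(
            cats_m.ravel(), lens_m.ravel()
        ).reshape(n_iter, seg_len)
        ends = np.cumsum(lens_m, axis=1)
        feeding = (cats_m != CO) & (ends < seg_len)
        ev_cols.append(np.where(feeding, seg.start + ends, np.inf).astype(float))
    events = (
        np.concatenate(ev_cols, axis=1)
        if ev_cols
        else np.full((n_iter, 0), np.inf)
    )
    return lab, events


def _cv_rows(events_pooled: np.ndarray) -> np.ndarray:
    """Row-wise interval CV from pooled event windows (inf = missing, dupes merged)."""
    ev = np.sort(events_pooled, axis=1)
    with np.errstate(invalid="ignore"):
        d = np.diff(ev, axis=1)
    valid = np.isfinite(d) & (d > 0)  # drops same-window duplicates
    dd = np.where(valid, d, np.nan)
    n = valid.sum(axis=1)
    out = np.full(events_pooled.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(dd[ok], axis=1)
            sd = np.nanstd(dd[ok], axis=1, ddof=1)
        out[ok] = sd / mean
    return out


def feeding_series(pair_session: PairSession) -> FeedingSeries:
    """Observed pooled-parent feeding series on the masked timelines.

    Derived through the same sub-series machinery as the randomization null, so
    observed and null CV statistics share one support; events of both parents
    falling in the same window are merged.
    """
    evs = []
    for role in ("female", "male"):
        _, ev = _bird_matrices(
            segments(pair_session.labels(role)),
            pair_session.grid.n_windows,
            1,
            None,
            identity=True,
        )
        evs.append(ev)
    pooled = np.concatenate(evs, axis=1)[0]
    windows = np.unique(pooled[np.isfinite(pooled)]).astype(int)
    return FeedingSeries(
        pair_id=pair_session.pair_id,
        session_id=pair_session.session_id,
        event_windows=windows,
        bin_minutes=pair_session.grid.bin_minutes,
    )


_STATS = ("st_lt_overlap", "interfeed_cv")


def _p_values(
    null: np.ndarray, observed: float, lower_tail: bool
) -> tuple[float, float, float, float, int]:
    valid = np.isfinite(null)
    n_valid = int(valid.sum())
    nv = null[valid]
    if n_valid == 0 or not np.isfinite(observed):
        nan = float("nan")
        return nan, nan, nan, nan, n_valid
    beyond = int((nv < observed).sum()) if lower_tail else int((nv > observed).sum())
    ties = int((nv == observed).sum())
    p = beyond / n_valid
    # mid-p: on a discrete statistic the strict rule is anti-conservative by up
    # to the tie mass at the critical value; half-counting ties restores
    # type-I calibration and is the package's default decision rule
    p_mid = (beyond + 0.5 * ties) / n_valid
    p1 = (beyond + 1) / (n_valid + 1)
    return p, p_mid, p1, float(nv.mean()), n_valid


def run_randomization(
    pair_session: PairSession,
    statistic: str = "both",
    n_iter: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> dict[str, RandomizationResult]:
    """Session-level Monte Carlo randomization test(s).

    Both birds' string series are shuffled independently ``n_iter`` times, the
    timelines rebuilt, and the requested statistic(s) recomputed on each
    shuffle.  The p-value is the proportion of null draws beyond the observed
    value in the statistic's tail (strictly greater for ``st_lt_overlap``,
    strictly lower for ``interfeed_cv``); ``p_plus1`` is the (+1)-corrected
    version used wherever a zero p would break downstream combination.  The
    coordination index is ``(observed - null_mean) / null_mean``.
    """
    if statistic not in _STATS + ("both",):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if rng is None:
        rng = np.random.default_rng(seed)

    want = list(_STATS) if statistic == "both" else [statistic]
    n_win = pair_session.grid.n_windows
    segs = {
        r: segments(
            pair_session.labels(r),
            [t for t in pair_session.trips if t.bird_role == r] or None,
        )
        for r in ("female", "male")
    }
    n_trips = {
        r: sum(int((s.cats != CO).sum()) for s in segs[r]) for r in ("female", "male")
    }
    degenerate = min(n_trips.values()) == 0
    note = None
    if degenerate:
        note = "no trips for at least one bird; statistics undefined"

    obs_lab = {}
    obs_ev = {}
    null_lab = {}
    null_ev = {}
    for r in ("female", "male"):
        obs_lab[r], obs_ev[r] = _bird_matrices(segs[r], n_win, 1, None, identity=True)
        null_lab[r], null_ev[r] = _bird_matrices(segs[r], n_win, n_iter, rng)

    results: dict[str, RandomizationResult] = {}
    for stat in want:
        if stat == "st_lt_overlap":
            observed = float(st_lt_overlap(obs_lab["female"][0], obs_lab["male"][0]))
            a, b = null_lab["female"], null_lab["male"]
            null = (
                (((a == ST) & (b == LT)) | ((a == LT) & (b == ST)))
                .sum(axis=1)
                .astype(float)
            )
            lower = False
        else:
            pooled_obs = np.concatenate([obs_ev["female"], obs_ev["male"]], axis=1)
            observed = float(_cv_rows(pooled_obs)[0])
            pooled = np.concatenate([null_ev["female"], null_ev["male"]], axis=1)
            null = _cv_rows(pooled)
            lower = True
        if degenerate:
            nan = float("nan")
            results[stat] = RandomizationResult(
                stat, observed, null, nan, nan, nan, nan, nan, n_iter, 0,
                degenerate=True, note=note,
            )
            continue
        p, p_mid, p1, null_mean, n_valid = _p_values(null, observed, lower)
        point_mass = n_valid > 0 and float(np.nanstd(null[np.isfinite(null)])) == 0.0
        index = (
            (observed - null_mean) / null_mean
            if np.isfinite(null_mean) and null_mean != 0
            else float("nan")
        )
        results[stat] = RandomizationResult(
            stat, observed, null, p, p_mid, p1, null_mean, index, n_iter, n_valid,
            degenerate=not np.isfinite(p) or point_mass,
            note=(
                "point-mass null: the shuffle admits a single arrangement"
                if point_mass
                else note if np.isfinite(p) else (note or "statistic undefined")
            ),
        )
    return results


# ---------------------------------------------------------------------------
# exact enumeration oracle for small sessions


def _segment_count(cats: np.ndarray, pinned: Optional[np.ndarray] = None) -> int:
    free = np.ones(len(cats), dtype=bool) if pinned is None else ~np.asarray(pinned)
    t = int(((cats != CO) & free).sum())
    c = int(((cats == CO) & free).sum())
    return math.factorial(t) * math.factorial(c)


def _enumerate_segment_orders(cats: np.ndarray, pinned: Optional[np.ndarray] = None):
    """Yield every equally likely ordering the skeleton-preserving shuffle can produce."""
    free = np.ones(len(cats), dtype=bool) if pinned is None else ~np.asarray(pinned)
    trip_pos = np.flatnonzero((cats != CO) & free)
    co_pos = np.flatnonzero((cats == CO) & free)
    t, c = len(trip_pos), len(co_pos)
    m = len(cats)
    base = list(range(m))
    for tp in permutations(range(t)):
        for cp in permutations(range(c)):
            order = list(base)
            for pos, j in zip(trip_pos, tp):
                order[pos] = int(trip_pos[j])
            for pos, j in zip(co_pos, cp):
                order[pos] = int(co_pos[j])
            yield order


@dataclass
class ExactNull:
    statistic_name: str
    values: np.ndarray  # distinct finite statistic values
    probs: np.ndarray  # matching probabilities
    p_undefined: float  # probability mass on undefined statistic (CV with <2 intervals)
    n_arrangements: int

    def p_value(self, observed: float, lower_tail: bool) -> float:
        """Tail probability under the exact null, conditioned on defined values."""
        mask = self.values < observed if lower_tail else self.values > observed
        total = self.probs.sum()
        return float(self.probs[mask].sum() / total) if total > 0 else float("nan")


def exact_null_small(
    pair_session: PairSession,
    statistic: str,
    max_arrangements: int = 100_000,
) -> ExactNull:
    """Exact null distribution by full enumeration of the constrained shuffle.

    Enumerates every admissible joint arrangement of both birds' strings with
    its exact probability; feasible only for small sessions (the arrangement
    count across both birds must not exceed ``max_arrangements``).
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    n_win = pair_session.grid.n_windows
    segs = {
        r: segments(
            pair_session.labels(r),
            [t for t in pair_session.trips if t.bird_role == r] or None,
        )
        for r in ("female", "male")
    }

    counts = {
        r: math.prod(_segment_count(s.cats, s.pinned) for s in segs[r])
        for r in ("female", "male")
    }
    total = counts["female"] * counts["male"]
    if total > max_arrangements:
        raise ValueError(
            f"{total} joint arrangements exceed max_arrangements={max_arrangements}"
        )

    def bird_outcomes(role: str) -> list[tuple[np.ndarray, np.ndarray]]:
        seg_orders = [
            list(_enumerate_segment_orders(s.cats, s.pinned)) for s in segs[role]
        ]
        outcomes = []
        for combo in product(*seg_orders) if seg_orders else [()]:
            lab = np.full(n_win, MASKED, dtype=np.int8)
            evs = []
            for seg, order in zip(segs[role], combo):
                cats_o = seg.cats[list(order)]
                lens_o = seg.lens[list(order)]
                lab[seg.start : seg.start + seg.n_windows] = np.repeat(cats_o, lens_o)
                ends = np.cumsum(lens_o)
                feeding = (cats_o != CO) & (ends < seg.n_windows)
                evs.append((seg.start + ends[feeding]).astype(float))
            outcomes.append((lab, np.concatenate(evs) if evs else np.empty(0)))
        return outcomes

    out_f = bird_outcomes("female")
    out_m = bird_outcomes("male")
    prob = 1.0 / (len(out_f) * len(out_m))

    acc: dict[float, float] = {}
    p_undef = 0.0
    for lab_f, ev_f in out_f:
        for lab_m, ev_m in out_m:
            if statistic == "st_lt_overlap":
                v = float(st_lt_overlap(lab_f, lab_m))
            else:
                pooled = np.unique(np.concatenate([ev_f, ev_m]))
                iv = np.diff(pooled)
                iv = iv[iv > 0]
                if iv.size < 2:
                    p_undef += prob
                    continue
                v = float(np.std(iv, ddof=1) / np.mean(iv))
            acc[v] = acc.get(v, 0.0) + prob
    values = np.array(sorted(acc))
    probs = np.array([acc[v] for v in values])
    return ExactNull(statistic, values, probs, p_undef, total)
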