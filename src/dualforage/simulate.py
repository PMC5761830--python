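"""Synthetic study corpus: dual-foraging pair sessions and chick-mass trajectories.

The generator reproduces the data *structure* the pipeline assumes: two marked
birds per pair alternate colony bouts (truncated log-normal, mean 49 min on
10-80 min) with foraging trips whose durations are a bimodal mixture of
log-normals (short trips mean 1.9 h, long trips mean 12.8 h), observed over a
48-h session on a 10-min grid; a feeding event ends every trip.  A single
coupling knob ``kappa`` induces pair coordination: at each trip start the trip
is long with probability ``p_lt * (1 - kappa * [partner currently on LT])`` —
``kappa = 0`` gives independent birds (the calibration null), ``kappa = 1``
forbids starting a long trip while the partner is already on one.  Chick mass
follows a saturating rise to a peak near day 20 and a linear pre-fledging
recession, optionally depressed by the pair's realized inter-feeding interval
CV (``growth_effect_beta``).

Every quantity is simulated in whole 10-min windows so the generator and the
pipeline share one resolution, and everything is deterministic under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import OBS_COLUMNS, SessionGrid


@dataclass
class SimParams:
    """Generator settings; defaults are the study-shaped conditions."""

    n_pairs: int = 25
    sessions_per_pair: int = 3
    vary_sessions: bool = True  # draw 1-5 sessions/pair (median 3) instead of fixed
    session_hours: float = 48.0
    bin_minutes: int = 10
    # trip-duration mixture (log-hours); meanlog offsets make the *means* 1.9 / 12.8 h
    st_meanlog: float = math.log(1.9) - 0.5**2 / 2
    st_sdlog: float = 0.5
    lt_meanlog: float = math.log(12.8) - 0.4**2 / 2
    lt_sdlog: float = 0.4
    # colony bouts: truncated log-normal, minutes
    co_mean_min: float = 49.0
    co_min_min: float = 10.0
    co_max_min: float = 80.0
    co_sdlog: float = 0.5
    p_lt: float = 0.25  # baseline probability the next trip is long
    kappa: float = 0.6  # coordination coupling in [0, 1]
    growth_effect_beta: float = 0.0  # grams of peak mass per unit interval CV
    mass_noise_sd: float = 3.0  # measurement noise, g
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must be in [0,1], got {self.kappa}")
        if not (0.0 < self.p_lt < 1.0):
            raise ValueError(f"p_lt must be in (0,1), got {self.p_lt}")
        for name in ("st_sdlog", "lt_sdlog", "co_mean_min", "co_min_min",
                     "co_max_min", "session_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_windows(self) -> int:
        return int(round(self.session_hours * 60 / self.bin_minutes))


@dataclass
class TrueTrip:
    bird_role: str
    trip_type: str  # "ST" | "LT"
    start_window: int  # session coordinates, clipped to the observation window
    n_windows: int  # observed (clipped) length
    truncated_start: bool
    truncated_end: bool
    true_n_windows: int = 0  # full trip length regardless of clipping


@dataclass
class SimTruth:
    """Generator-side ground truth for one pair-session (pipeline test oracle)."""

    pair_id: str
    session_id: str
    trips: list  # TrueTrip, clipped to the session
    feeding_windows: dict  # role -> list of first-colony-window-after-trip
    n_simultaneous_lt: int  # windows with both birds on LT


def _co_meanlog(params: SimParams) -> float:
    """meanlog of the colony-bout log-normal whose [min,max]-truncated mean is co_mean_min."""
    lo, hi, sd = params.co_min_min, params.co_max_min, params.co_sdlog

    def trunc_mean(mu: float) -> float:
        a = (math.log(lo) - mu) / sd
        b = (math.log(hi) - mu) / sd
        # E[e^{mu + sd Z} | a<Z<b] for standard normal Z
        num = stats.norm.cdf(b - sd) - stats.norm.cdf(a - sd)
        den = stats.norm.cdf(b) - stats.norm.cdf(a)
        return math.exp(mu + sd**2 / 2) * num / den

    return float(optimize.brentq(lambda mu: trunc_mean(mu) - params.co_mean_min,
                                 math.log(1.0), math.log(500.0)))


def _draw_co_windows(params: SimParams, meanlog: float, rng: np.random.Generator) -> int:
    a = (math.log(params.co_min_min) - meanlog) / params.co_sdlog
    b = (math.log(params.co_max_min) - meanlog) / params.co_sdlog
    z = stats.truncnorm.rvs(a, b, loc=meanlog, scale=params.co_sdlog, random_state=rng)
    minutes = math.exp(z)
    return max(1, int(round(minutes / params.bin_minutes)))


def _draw_trip_windows(params: SimParams, trip_type: str, rng: np.random.Generator) -> int:
    if trip_type == "ST":
        hours = float(rng.lognormal(params.st_meanlog, params.st_sdlog))
    else:
        hours = float(rng.lognormal(params.lt_meanlog, params.lt_sdlog))
    return max(1, int(round(hours * 60 / params.bin_minutes)))


def simulate_pair_session(
    params: SimParams,
    pair_id: str,
    session_id: str,
    rng: np.random.Generator,
    chick_age: Optional[float] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """One 48-h pair-session: observation records for both birds plus ground truth.

    Both birds are co-simulated event by event (the coupling needs the
    partner's instantaneous state) from a 24-h burn-in before the observation
    window, so session-boundary trips arrive truncated exactly as in the field.
    """
    n_win = params.n_windows
    burnin = n_win // 2  # 24 h of unobserved behaviour before the session
    co_meanlog = _co_meanlog(params)

    # per-bird: current state ("CO"/"ST"/"LT"), segment start & end (window coords)
    roles = ("female", "male")
    state = {}
    for role in roles:
        start = -burnin
        dur = _draw_co_windows(params, co_meanlog, rng)
        state[role] = {"kind": "CO", "start": start, "end": start + dur}

    raw_trips: dict[str, list[tuple[str, int, int]]] = {r: [] for r in roles}
    while min(state[r]["end"] for r in roles) < n_win:
        role = min(roles, key=lambda r: (state[r]["end"], r))  # female first on ties
        s = state[role]
        t0 = s["end"]
        other = state["male" if role == "female" else "female"]
        if s["kind"] == "CO":
            partner_on_lt = other["kind"] == "LT" and other["start"] <= t0 < other["end"]
            p = params.p_lt * (1.0 - params.kappa * partner_on_lt)
            trip_type = "LT" if rng.random() < p else "ST"
            dur = _draw_trip_windows(params, trip_type, rng)
            raw_trips[role].append((trip_type, t0, dur))
            state[role] = {"kind": trip_type, "start": t0, "end": t0 + dur}
        else:
            dur = _draw_co_windows(params, co_meanlog, rng)
            state[role] = {"kind": "CO", "start": t0, "end": t0 + dur}

    present = {r: np.ones(n_win, dtype=bool) for r in roles}
    true_trips: list[TrueTrip] = []
    feeding: dict[str, list[int]] = {r: [] for r in roles}
    lt_mask = {r: np.zeros(n_win, dtype=bool) for r in roles}
    for role in roles:
        for trip_type, t0, dur in raw_trips[role]:
            t1 = t0 + dur
            if t1 <= 0 or t0 >= n_win:
                continue
            a, b = max(t0, 0), min(t1, n_win)
            present[role][a:b] = False
            if trip_type == "LT":
                lt_mask[role][a:b] = True
            true_trips.append(
                TrueTrip(role, trip_type, a, b - a,
                         truncated_start=t0 < 0, truncated_end=t1 > n_win,
                         true_n_windows=dur)
            )
            if 0 < t1 < n_win:
                feeding[role].append(t1)

    truth = SimTruth(
        pair_id=pair_id,
        session_id=session_id,
        trips=true_trips,
        feeding_windows={r: sorted(feeding[r]) for r in roles},
        n_simultaneous_lt=int((lt_mask["female"] & lt_mask["male"]).sum()),
    )
    frames = []
    for role in roles:
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": pair_id,
                    "session_id": session_id,
                    "bird_role": role,
                    "window_index": np.arange(n_win),
                    "present": present[role],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)[OBS_COLUMNS]
    return records, truth


def simulate_chick_growth(
    params: SimParams,
    chick_id: str,
    rng: np.random.Generator,
    interval_cv: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Mass trajectory, nest-check records and noiseless truth for one chick.

    Saturating rise (rate 0.1/day) to a peak drawn near day 20, then linear
    recession to fledging between days 21 and 31; the peak is depressed by
    ``growth_effect_beta * interval_cv``.  Weighing every 3 days from day 13
    or 14; truth growth indicators are taken on the noiseless sampled grid.
    """
    if noise_sd is None:
        noise_sd = params.mass_noise_sd
    cv = float(interval_cv) if interval_cv is not None else 0.0

    peak_day = int(np.clip(round(rng.normal(20.0, 1.5)), 17, 23))
    fledge_day = int(rng.integers(24, 31))
    peak_mass = float(rng.normal(150.0, 8.0)) - params.growth_effect_beta * cv
    fledge_frac = float(np.clip(rng.normal(0.78, 0.03), 0.6, 0.95))
    fledge_mass = peak_mass * fledge_frac

    r = 0.1  # 1/day rise rate

    def true_mass(d: float) -> float:
        if d <= peak_day:
            return peak_mass * (1 - math.exp(-r * d)) / (1 - math.exp(-r * peak_day))
        frac = (d - peak_day) / (fledge_day - peak_day)
        return peak_mass + (fledge_mass - peak_mass) * frac

    start_day = int(rng.integers(13, 15))
    days = list(range(start_day, fledge_day + 1, 3))
    clean = np.array([true_mass(d) for d in days])
    noisy = np.maximum(clean + rng.normal(0.0, noise_sd, size=len(days)), 1.0)

    masses = pd.DataFrame({"pair_id": chick_id, "day_of_life": days, "mass_g": noisy})
    check_days = list(range(start_day, fledge_day + 7, 3))
    checks = pd.DataFrame(
        {
            "pair_id": chick_id,
            "day_of_life": check_days,
            "chick_present": [int(d < fledge_day) for d in check_days],
        }
    )
    ipk = int(np.argmax(clean))
    truth = {
        "pair_id": chick_id,
        "peak_mass": float(clean[ipk]),
        "peak_day": int(days[ipk]),
        "fledge_mass": float(clean[-1]),
        "fledge_day": fledge_day,
        "interval_cv": cv,
    }
    return masses, checks, truth


@dataclass
class Corpus:
    params: SimParams
    observations: pd.DataFrame
    masses: pd.DataFrame  # includes chick_id (one chick per pair per breeding year)
    nest_checks: pd.DataFrame
    grids: dict
    truths: list  # SimTruth per pair-session
    chick_truths: list
    session_meta: pd.DataFrame  # pair_id, session_id, year, chick_id, chick_age


def _session_ages(n_sessions: int, rng: np.random.Generator) -> list[float]:
    """Mean chick ages per session, spaced like the study's repeat visits."""
    first = float(rng.uniform(6, 12))
    return [first + 7 * j + float(rng.normal(0, 1)) for j in range(n_sessions)]


def simulate_corpus(params: SimParams, out_dir: Optional[Path] = None) -> Corpus:
    """A full study-shaped corpus, deterministic under ``params.seed``.

    Defaults give 25 pairs with 1-5 sessions each (median 3), spread over two
    breeding years (earlier sessions in year 1, later ones in year 2); each
    pair rears one chick per year it was observed, so pairs watched in both
    years contribute two chicks — mirroring the repeated-season structure the
    mixed models rely on.  When ``out_dir`` is given, writes observations.csv,
    chick_masses.csv, nest_checks.csv, sessions.csv, truth.json and the
    effective config (sim_params.json).
    """
    rng = np.random.default_rng(params.seed)
    obs_frames, mass_frames, check_frames = [], [], []
    truths: list[SimTruth] = []
    chick_truths = []
    grids: dict[str, SessionGrid] = {}
    meta_rows = []

    for ip in range(params.n_pairs):
        pid = f"pair{ip + 1:02d}"
        if params.vary_sessions:
            k = int(rng.choice([1, 2, 3, 4, 5], p=[0.1, 0.2, 0.4, 0.2, 0.1]))
        else:
            k = params.sessions_per_pair
        years = [1] * ((k + 1) // 2) + [2] * (k // 2)
        cvs_by_year: dict[int, list[float]] = {}
        ages_y1 = _session_ages(years.count(1), rng)
        ages_y2 = _session_ages(years.count(2), rng)
        age_iter = {1: iter(ages_y1), 2: iter(ages_y2)}
        for js in range(k):
            sid = f"s{js + 1}"
            year = years[js]
            records, truth = simulate_pair_session(params, pid, sid, rng)
            obs_frames.append(records)
            truths.append(truth)
            meta_rows.append(
                {
                    "pair_id": pid,
                    "session_id": sid,
                    "year": year,
                    "chick_id": f"{pid}_y{year}",
                    "chick_age": next(age_iter[year]),
                }
            )
            grids.setdefault(
                sid,
                SessionGrid(session_id=sid, n_windows=params.n_windows,
                            bin_minutes=params.bin_minutes),
            )
            pooled = np.unique(
                np.concatenate(
                    [truth.feeding_windows["female"], truth.feeding_windows["male"]]
                ).astype(float)
            )
            iv = np.diff(pooled)
            iv = iv[iv > 0]
            if iv.size >= 2:
                cvs_by_year.setdefault(year, []).append(
                    float(np.std(iv, ddof=1) / np.mean(iv))
                )
        for year in sorted(set(years)):
            cid = f"{pid}_y{year}"
            mean_cv = float(np.mean(cvs_by_year.get(year, []) or [0.0]))
            masses, checks, chick_truth = simulate_chick_growth(
                params, cid, rng, interval_cv=mean_cv
            )
            masses = masses.rename(columns={"pair_id": "chick_id"})
            masses.insert(0, "pair_id", pid)
            checks = checks.rename(columns={"pair_id": "chick_id"})
            checks.insert(0, "pair_id", pid)
            chick_truth["chick_id"] = cid
            chick_truth["pair_id"] = pid
            mass_frames.append(masses)
            check_frames.append(checks)
            chick_truths.append(chick_truth)

    corpus = Corpus(
        params=params,
        observations=pd.concat(obs_frames, ignore_index=True),
        masses=pd.concat(mass_frames, ignore_index=True),
        nest_checks=pd.concat(check_frames, ignore_index=True),
        grids=grids,
        truths=truths,
        chick_truths=chick_truths,
        session_meta=pd.DataFrame(meta_rows),
    )
    if out_dir is not None:
        write_corpus(corpus, Path(out_dir))
    return corpus


def write_corpus(corpus: Corpus, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs = corpus.observations.copy()
    obs["present"] = obs["present"].astype(int)
    obs.to_csv(out_dir / "observations.csv", index=False)
    corpus.masses.to_csv(out_dir / "chick_masses.csv", index=False)
    corpus.nest_checks.to_csv(out_dir / "nest_checks.csv", index=False)
    corpus.session_meta.to_csv(out_dir / "sessions.csv", index=False)
    truth = {
        "sessions": [
            {
                "pair_id": t.pair_id,
                "session_id": t.session_id,
                "n_simultaneous_lt": t.n_simultaneous_lt,
                "feeding_windows": t.feeding_windows,
                "trips": [asdict(tr) for tr in t.trips],
            }
            for t in corpus.truths
        ],
        "chicks": corpus.chick_truths,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    (out_dir / "sim_params.json").write_text(
        json.dumps(asdict(corpus.params), indent=1)
    )
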