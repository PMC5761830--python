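"""Reading and writing binned colony presence/absence records and chick-mass files.

The sampling unit of the whole pipeline is the 10-minute *time window*: during a
continuous 48-h watch each marked bird is scored present/absent at the colony once
per window.  Files are plain delimited text; the column layout is described by a
*dialect* mapping so the same reader serves both the synthetic generator's output
and externally supplied raw data after a one-time dialect configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

#: per-window activity codes shared across the package
CO, ST, LT, MASKED = 0, 1, 2, 3
CODE_NAMES = {CO: "CO", ST: "ST", LT: "LT", MASKED: "MASKED"}
NAME_CODES = {v: k for k, v in CODE_NAMES.items()}

ROLES = ("female", "male")

OBS_COLUMNS = ["pair_id", "session_id", "bird_role", "window_index", "present"]


@dataclass(frozen=True)
class SessionGrid:
    """Shared time grid of one observation session (default 48 h of 10-min bins)."""

    session_id: str
    n_windows: int = 288
    bin_minutes: int = 10
    chick_age_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_windows < 1:
            raise ValueError(f"n_windows must be >= 1, got {self.n_windows}")
        if self.bin_minutes <= 0:
            raise ValueError(f"bin_minutes must be > 0, got {self.bin_minutes}")


@dataclass(frozen=True)
class Dialect:
    """Column layout of an observation file.

    ``window`` selects how the time axis is encoded: ``"index"`` (0-based window
    number), ``"minutes"`` (minutes from session start, must sit on the 10-min
    grid) or ``"clock"`` (``HH:MM`` strings plus an optional 0-based day column
    for multi-day sessions).
    """

    delimiter: str = ","
    pair_col: str = "pair_id"
    session_col: str = "session_id"
    role_col: str = "bird_role"
    window_col: str = "window_index"
    present_col: str = "present"
    day_col: Optional[str] = None
    window: str = "index"  # index | minutes | clock
    true_values: tuple = ("1", "true", "True", "yes")
    implicit_absence: bool = False
    bin_minutes: int = 10

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Dialect":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(cfg) - known
        if bad:
            raise ValueError(f"unknown dialect keys: {sorted(bad)}")
        cfg = dict(cfg)
        if "true_values" in cfg:
            cfg["true_values"] = tuple(cfg["true_values"])
        return cls(**cfg)


DEFAULT_DIALECT = Dialect()


def load_dialect(path) -> Dialect:
    """Load a dialect mapping from a YAML (or JSON) config file.

    Keys may be flat (``window: clock``) or nested under ``io.dialect``.
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("io", "dialect"):
        if isinstance(cfg, dict) and key in cfg and isinstance(cfg[key], dict):
            cfg = cfg[key]
    return Dialect.from_mapping(cfg)


def _windows_from_column(df: pd.DataFrame, dialect: Dialect) -> np.ndarray:
    col = df[dialect.window_col]
    if dialect.window == "index":
        return col.astype(int).to_numpy()
    if dialect.window == "minutes":
        minutes = col.astype(float).to_numpy()
        win, rem = np.divmod(minutes, dialect.bin_minutes)
        if np.any(rem != 0):
            raise ValueError(
                f"minute offsets not on the {dialect.bin_minutes}-min grid: "
                f"{sorted(set(minutes[rem != 0]))[:5]}"
            )
        return win.astype(int)
    if dialect.window == "clock":
        parts = col.astype(str).str.split(":", expand=True)
        minutes = parts[0].astype(int) * 60 + parts[1].astype(int)
        if dialect.day_col is not None:
            minutes = minutes + df[dialect.day_col].astype(int) * 24 * 60
        win, rem = np.divmod(minutes.to_numpy(), dialect.bin_minutes)
        if np.any(rem != 0):
            raise ValueError(f"clock times not on the {dialect.bin_minutes}-min grid")
        return win.astype(int)
    raise ValueError(f"unknown window encoding {dialect.window!r}")


def read_observations(
    path, dialect: Dialect | Mapping | None = None
) -> tuple[pd.DataFrame, dict[str, SessionGrid]]:
    """Read an observation file into the canonical record table.

    Returns a DataFrame with columns ``pair_id, session_id, bird_role,
    window_index, present`` (one row per bird per window, gap-free) and a
    ``SessionGrid`` per session.  Unless the dialect declares absence as
    implicit, every (bird, session) must cover its session's windows without
    gaps; duplicates are always an error.
    """
    if dialect is None:
        dialect = DEFAULT_DIALECT
    elif not isinstance(dialect, Dialect):
        dialect = Dialect.from_mapping(dialect)

    raw = pd.read_csv(path, delimiter=dialect.delimiter, dtype=str)
    required = [dialect.pair_col, dialect.session_col, dialect.role_col,
                dialect.window_col, dialect.present_col]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"observation file missing columns {missing}")

    df = pd.DataFrame(
        {
            "pair_id": raw[dialect.pair_col].astype(str),
            "session_id": raw[dialect.session_col].astype(str),
            "bird_role": raw[dialect.role_col].astype(str).str.lower(),
            "window_index": _windows_from_column(raw, dialect),
            "present": raw[dialect.present_col].astype(str).isin(dialect.true_values),
        }
    )

    bad_roles = set(df["bird_role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown bird_role values {sorted(bad_roles)}; expected {ROLES}")

    dup = df.duplicated(["pair_id", "session_id", "bird_role", "window_index"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["pair_id", "session_id", "bird_role", "window_index"]]
        raise ValueError(
            "duplicate observation for "
            f"(pair={key['pair_id']}, session={key['session_id']}, "
            f"bird={key['bird_role']}, window={key['window_index']})"
        )
    if (df["window_index"] < 0).any():
        raise ValueError("negative window_index")

    grids: dict[str, SessionGrid] = {}
    pieces = []
    for sid, sess in df.groupby("session_id", sort=True):
        n_windows = int(sess["window_index"].max()) + 1
        grids[sid] = SessionGrid(session_id=sid, n_windows=n_windows,
                                 bin_minutes=dialect.bin_minutes)
        for (pid, role), bird in sess.groupby(["pair_id", "bird_role"], sort=True):
            have = np.zeros(n_windows, dtype=bool)
            have[bird["window_index"].to_numpy()] = True
            if not have.all():
                if dialect.implicit_absence:
                    gaps = np.flatnonzero(~have)
                    filler = pd.DataFrame(
                        {
                            "pair_id": pid,
                            "session_id": sid,
                            "bird_role": role,
                            "window_index": gaps,
                            "present": False,
                        }
                    )
                    bird = pd.concat([bird, filler], ignore_index=True)
                else:
                    gaps = np.flatnonzero(~have)
                    raise ValueError(
                        f"non-contiguous windows for (pair={pid}, session={sid}, "
                        f"bird={role}); missing windows {gaps[:10].tolist()}"
                        + ("..." if len(gaps) > 10 else "")
                    )
            pieces.append(bird)
    out = pd.concat(pieces, ignore_index=True) if pieces else df
    out = out.sort_values(
        ["pair_id", "session_id", "bird_role", "window_index"]
    ).reset_index(drop=True)[OBS_COLUMNS]
    out["window_index"] = out["window_index"].astype(int)
    out["present"] = out["present"].astype(bool)
    return out, grids


def write_observations(records: pd.DataFrame, path, dialect: Dialect | None = None) -> None:
    """Write canonical observation records; round-trips through :func:`read_observations`."""
    if dialect is None:
        dialect = DEFAULT_DIALECT
    if dialect.window != "index":
        raise ValueError("writing is supported for the index-based dialect only")
    df = records.copy()
    if list(df.columns) != OBS_COLUMNS:
        df = df[OBS_COLUMNS]
    df = df.sort_values(["pair_id", "session_id", "bird_role", "window_index"])
    out = pd.DataFrame(
        {
            dialect.pair_col: df["pair_id"],
            dialect.session_col: df["session_id"],
            dialect.role_col: df["bird_role"],
            dialect.window_col: df["window_index"].astype(int),
            dialect.present_col: df["present"].astype(int),
        }
    )
    out.to_csv(path, sep=dialect.delimiter, index=False)


def presence_runs(present: Iterable[bool]) -> list[tuple[str, int, int]]:
    """Run-length encode a gap-free presence string.

    Returns ``[(state, start_window, n_windows), ...]`` with ``state`` in
    ``{"present", "absent"}``; runs partition ``[0, n)`` and adjacent runs
    alternate state.
    """
    arr = np.asarray(list(present) if not isinstance(present, np.ndarray) else present,
                     dtype=bool)
    if arr.size == 0:
        return []
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    return [
        ("present" if arr[s] else "absent", int(s), int(e - s))
        for s, e in zip(starts, ends)
    ]


def read_chick_masses(path) -> pd.DataFrame:
    """Read chick body-mass records (pair_id, day_of_life, mass_g).

    Warns (does not fail) when the measurement schedule departs strongly from
    the every-3-days protocol starting on day 13/14.
    """
    df = pd.read_csv(path, dtype={"pair_id": str, "chick_id": str})
    missing = [c for c in ("pair_id", "day_of_life", "mass_g") if c not in df.columns]
    if missing:
        raise ValueError(f"chick-mass file missing columns {missing}")
    df["day_of_life"] = df["day_of_life"].astype(int)
    df["mass_g"] = df["mass_g"].astype(float)
    if (df["mass_g"] <= 0).any():
        raise ValueError("non-positive chick mass")
    if (df["day_of_life"] < 0).any():
        raise ValueError("negative day_of_life")
    id_col = "chick_id" if "chick_id" in df.columns else "pair_id"
    first = df.groupby(id_col)["day_of_life"].min()
    if ((first < 12) | (first > 16)).any():
        warnings.warn("chick weighing does not start on day 13-14 for all nests",
                      stacklevel=2)
    return df.sort_values([id_col, "day_of_life"]).reset_index(drop=True)


def read_nest_checks(path) -> pd.DataFrame:
    """Read nest-check records (pair_id, day_of_life, chick_present)."""
    df = pd.read_csv(path, dtype={"pair_id": str, "chick_id": str})
    missing = [c for c in ("pair_id", "day_of_life", "chick_present") if c not in df.columns]
    if missing:
        raise ValueError(f"nest-check file missing columns {missing}")
    df["day_of_life"] = df["day_of_life"].astype(int)
    df["chick_present"] = df["chick_present"].astype(int).astype(bool)
    id_col = "chick_id" if "chick_id" in df.columns else "pair_id"
    return df.sort_values([id_col, "day_of_life"]).reset_index(drop=True)
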