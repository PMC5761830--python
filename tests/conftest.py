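import numpy as np
import pytest

from dualforage.io import LT, ST, SessionGrid
from dualforage.trips import PairSession, Trip


def labels_to_trips(labels, pair_id="p", session_id="s", bird_role="female"):
    """Build consistent Trip objects from a label array (untruncated, classified)."""
    labels = np.asarray(labels)
    trips = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in (ST, LT):
            trips.append(
                Trip(pair_id, session_id, bird_role, i, j - i, False, False,
                     "ST" if labels[i] == ST else "LT")
            )
        i = j
    return trips


def make_pair_session(labels_f, labels_m, pair_id="p", session_id="s"):
    """PairSession from two label arrays, with matching trip metadata."""
    lf = np.asarray(labels_f, dtype=np.int8)
    lm = np.asarray(labels_m, dtype=np.int8)
    assert len(lf) == len(lm)
    trips = labels_to_trips(lf, pair_id, session_id, "female") + labels_to_trips(
        lm, pair_id, session_id, "male"
    )
    return PairSession(
        pair_id, session_id, SessionGrid(session_id, n_windows=len(lf)),
        lf, lm, trips,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic 6-pair corpus shared by the slower integration tests."""
    from dualforage import SimParams, simulate_corpus

    return simulate_corpus(SimParams(n_pairs=6, vary_sessions=False,
                                     sessions_per_pair=3, seed=7))
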