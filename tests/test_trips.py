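import numpy as np
import pytest

from dualforage.io import MASKED, SessionGrid
from dualforage.trips import (
    apply_exclusions,
    classify_trips,
    estimate_cutoff,
    extract_trips,
    feedings_from_trips,
    pair_sessions_from_records,
)


def _trips(present, role="female"):
    return extract_trips(np.asarray(present, dtype=bool), "p", "s", role)


class TestExtractTrips:
    def test_single_interior_trip(self):
        trips = _trips([1, 1, 0, 0, 0, 1])
        assert len(trips) == 1
        t = trips[0]
        assert (t.start_window, t.n_windows) == (2, 3)
        assert t.duration_h == pytest.approx(0.5)
        assert not t.truncated

    def test_start_truncation_flag(self):
        trips = _trips([0, 0, 1, 1, 1, 1])
        assert len(trips) == 1
        assert trips[0].truncated_start and not trips[0].truncated_end

    def test_end_truncation_flag(self):
        trips = _trips([1, 1, 0, 0])
        assert trips[0].truncated_end

    def test_all_present_yields_no_trips(self):
        assert _trips([1] * 10) == []


class TestEstimateCutoff:
    def test_perfectly_separated_clusters(self):
        res = estimate_cutoff([1, 1, 1, 10, 10, 10])
        assert res.objective == pytest.approx(0.0)
        assert res.cutoff_h == pytest.approx(np.sqrt(10), rel=1e-12)
        assert (res.n_short, res.n_long) == (3, 3)

    def test_cutoff_between_clusters_on_bimodal_sample(self, rng):
        d = np.concatenate([
            rng.lognormal(np.log(1.9), 0.5, 200),
            rng.lognormal(np.log(12.8), 0.4, 100),
        ])
        res = estimate_cutoff(d)
        assert 1.9 < res.cutoff_h < 12.8

    def test_matches_exhaustive_bruteforce_scan(self, rng):
        """Independent oracle: evaluate the objective at every midpoint split."""
        for _ in range(5):
            d = np.concatenate([
                rng.lognormal(np.log(1.9), 0.5, 40),
                rng.lognormal(np.log(12.8), 0.4, 20),
            ])
            logs = np.sort(np.log(d))
            best_obj, best_cut = np.inf, None
            distinct = np.unique(logs)
            for lo, hi in zip(distinct[:-1], distinct[1:]):
                cand = (lo + hi) / 2
                k = int((logs < cand).sum())
                if k < 2 or len(logs) - k < 2:
                    continue
                obj = np.var(logs[:k], ddof=1) + np.var(logs[k:], ddof=1)
                if obj < best_obj:
                    best_obj, best_cut = obj, cand
            res = estimate_cutoff(d)
            assert res.objective == pytest.approx(best_obj, rel=1e-12)
            assert np.log(res.cutoff_h) == pytest.approx(best_cut, rel=1e-12)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_cutoff([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="identical"):
            estimate_cutoff([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            estimate_cutoff([1.0, -1.0, 2.0, 3.0])


class TestClassify:
    def test_short_and_long_relative_to_study_cutoff(self):
        trips = _trips([1] + [0] * 11 + [1])  # 11 windows < 7.1 h
        short = classify_trips(trips, 7.1)
        assert short[0].trip_type == "ST"
        trips = _trips([1] + [0] * 77 + [1])  # 12.8 h > 7.1 h
        assert classify_trips(trips, 7.1)[0].trip_type == "LT"

    def test_boundary_duration_equal_to_cutoff_is_long(self):
        trips = _trips([1, 0, 0, 0, 0, 0, 0, 1])  # 6 windows = 1 h
        assert classify_trips(trips, 1.0)[0].trip_type == "LT"

    def test_truncated_trips_stay_unclassified(self):
        trips = _trips([0, 0, 1, 1])
        assert classify_trips(trips, 1.0)[0].trip_type is None

    def test_nonpositive_cutoff_errors(self):
        with pytest.raises(ValueError):
            classify_trips([], 0.0)


class TestExclusions:
    def _session(self, pf, pm):
        pf = np.asarray(pf, dtype=bool)
        pm = np.asarray(pm, dtype=bool)
        tf = classify_trips(extract_trips(pf, "p", "s", "female"), 1.0)
        tm = classify_trips(extract_trips(pm, "p", "s", "male"), 1.0)
        return apply_exclusions(
            "p", "s", SessionGrid("s", n_windows=len(pf)), pf, pm, tf, tm
        )

    def test_truncated_trip_masks_both_birds_over_same_span(self):
        pf = [1] * 24
        pm = [0] * 12 + [1] * 12  # male trip truncated at session start
        ps = self._session(pf, pm)
        assert (ps.labels_female[:12] == MASKED).all()
        assert (ps.labels_male[:12] == MASKED).all()
        assert (ps.labels_female[12:] != MASKED).all()

    def test_masking_is_symmetric(self, small_corpus):
        sessions, _ = pair_sessions_from_records(
            small_corpus.observations, small_corpus.grids
        )
        for s in sessions:
            np.testing.assert_array_equal(
                s.labels_female == MASKED, s.labels_male == MASKED
            )

    def test_female_desertion_excludes_session(self):
        pf = [1] * 20 + [0, 0, 0, 0]  # single end-truncated trip: zero feedings
        pm = ([1, 0, 0, 1] * 6)
        ps = self._session(pf, pm)
        assert ps.excluded and ps.exclusion_reason == "female_desertion"

    def test_clean_session_included_and_unchanged(self):
        pf = [1, 0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1]
        pm = [1, 1, 0, 0, 1, 1, 0, 0, 1, 0, 0, 1]
        ps = self._session(pf, pm)
        assert not ps.excluded
        assert not (ps.labels_female == MASKED).any()

    def test_faded_marks_flag_excludes(self):
        pf = [1, 0, 0, 1] * 3
        tf = classify_trips(extract_trips(np.array(pf, bool), "p", "s", "female"), 1.0)
        ps = apply_exclusions(
            "p", "s", SessionGrid("s", n_windows=12),
            np.array(pf, bool), np.array(pf, bool), tf,
            classify_trips(extract_trips(np.array(pf, bool), "p", "s", "male"), 1.0),
            faded_marks=True,
        )
        assert ps.excluded and ps.exclusion_reason == "faded_marks"


class TestFeedings:
    def test_feeding_at_first_colony_window_after_trip(self):
        trips = _trips([1, 1, 0, 0, 0, 1])
        events = feedings_from_trips(trips)
        assert [e.window_index for e in events] == [5]

    def test_end_truncated_trip_has_no_feeding(self):
        trips = _trips([1, 1, 0, 0])
        assert feedings_from_trips(trips) == []

    def test_counts_match_generator_truth(self, small_corpus):
        sessions, _ = pair_sessions_from_records(
            small_corpus.observations, small_corpus.grids
        )
        truth = {(t.pair_id, t.session_id): t for t in small_corpus.truths}
        for s in sessions:
            t = truth[(s.pair_id, s.session_id)]
            for role in ("female", "male"):
                got = [
                    e.window_index
                    for e in feedings_from_trips(
                        [x for x in s.trips if x.bird_role == role]
                    )
                ]
                assert got == t.feeding_windows[role]
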