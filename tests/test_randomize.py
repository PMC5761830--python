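from collections import Counter

import numpy as np
import pytest
from scipy import stats

from dualforage.io import CO, LT, MASKED, ST
from dualforage.randomize import (
    ActivityString,
    exact_null_small,
    interfeed_cv,
    run_randomization,
    segments,
    shuffle_strings,
    st_lt_overlap,
    timeline_to_strings,
)

from conftest import make_pair_session


class TestStrings:
    def test_rle_hand_case(self):
        labels = [CO, CO, ST, ST, ST, CO] + [LT] * 10
        assert timeline_to_strings(labels) == [
            ActivityString("CO", 2),
            ActivityString("ST", 3),
            ActivityString("CO", 1),
            ActivityString("LT", 10),
        ]

    def test_all_colony_is_single_string(self):
        assert timeline_to_strings([CO] * 7) == [ActivityString("CO", 7)]

    def test_masked_windows_rejected(self):
        with pytest.raises(ValueError, match="MASKED"):
            timeline_to_strings([CO, MASKED, CO])

    def test_round_trip_identity(self, rng):
        for _ in range(20):
            labels = rng.choice([CO, ST, LT], size=60)
            rebuilt = [
                code
                for s in timeline_to_strings(labels)
                for code in [{"CO": CO, "ST": ST, "LT": LT}[s.category]] * s.n_windows
            ]
            assert rebuilt == list(labels)


class TestShuffle:
    def test_conservation_of_multiset_and_length(self, rng):
        strings = [
            ActivityString("CO", 2),
            ActivityString("ST", 3),
            ActivityString("CO", 1),
            ActivityString("LT", 10),
        ]
        for _ in range(200):
            out = shuffle_strings(strings, rng)
            assert sorted(out) == sorted(strings)
            assert sum(s.n_windows for s in out) == 16

    def test_one_co_kept_between_consecutive_trips(self, rng):
        strings = [
            ActivityString("CO", 1), ActivityString("ST", 2),
            ActivityString("CO", 3), ActivityString("LT", 4),
            ActivityString("CO", 5), ActivityString("ST", 6),
        ]
        for _ in range(100):
            cats = [s.category for s in shuffle_strings(strings, rng)]
            for a, b in zip(cats, cats[1:]):
                assert not (a != "CO" and b != "CO")

    def test_uniform_over_arrangement_space(self, rng):
        """3 trips + 2 interleaved COs: 3! x 2! = 12 equally likely orderings."""
        strings = [
            ActivityString("ST", 3), ActivityString("CO", 1),
            ActivityString("ST", 4), ActivityString("CO", 2),
            ActivityString("LT", 5),
        ]
        n = 6000
        counts = Counter(
            tuple(s.n_windows for s in shuffle_strings(strings, rng))
            for _ in range(n)
        )
        assert len(counts) == 12
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_no_trips_warns(self, rng):
        with pytest.warns(UserWarning, match="no trip"):
            shuffle_strings([ActivityString("CO", 4)], rng)


class TestStatistics:
    def test_overlap_hand_enumeration(self):
        a = np.array([ST] * 6 + [CO] * 3 + [LT] * 12)
        b = np.array([LT] * 13 + [CO] * 1 + [ST] * 7)
        assert st_lt_overlap(a, b) == 13
        assert st_lt_overlap(b, a) == 13

    def test_overlap_zero_when_partner_at_colony(self):
        a = np.array([ST, LT, ST, LT])
        b = np.full(4, CO)
        assert st_lt_overlap(a, b) == 0

    def test_overlap_ignores_masked(self):
        a = np.array([ST, ST, LT])
        b = np.array([LT, MASKED, ST])
        assert st_lt_overlap(a, b) == 2

    def test_overlap_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            st_lt_overlap(np.array([CO]), np.array([CO, CO]))

    def test_cv_equal_spacing_is_zero(self):
        assert interfeed_cv([100, 100, 100]) == pytest.approx(0.0)

    def test_cv_hand_arithmetic(self):
        assert interfeed_cv([60, 120, 180]) == pytest.approx(0.5)

    def test_cv_scale_invariance(self):
        iv = [30, 70, 110, 50]
        assert interfeed_cv(iv) == pytest.approx(interfeed_cv([2 * x for x in iv]))

    def test_cv_needs_two_intervals(self):
        with pytest.raises(ValueError):
            interfeed_cv([120])


def _rich_session():
    """Two birds, two trips + two COs each: 2!x2! = 4 arrangements per bird."""
    lf = [CO] * 3 + [ST] * 3 + [CO] * 2 + [LT] * 6
    lm = [CO] * 3 + [LT] * 5 + [CO] * 2 + [ST] * 4
    return make_pair_session(lf, lm)


class TestRunRandomization:
    def test_reproducible_under_seed(self):
        ps = _rich_session()
        r1 = run_randomization(ps, "both", n_iter=500, seed=3)
        r2 = run_randomization(ps, "both", n_iter=500, seed=3)
        for k in r1:
            np.testing.assert_array_equal(r1[k].null_samples, r2[k].null_samples)

    def test_null_support_conserves_window_totals(self, small_corpus):
        from dualforage.trips import pair_sessions_from_records
        from dualforage.randomize import _bird_matrices

        sessions, _ = pair_sessions_from_records(
            small_corpus.observations, small_corpus.grids
        )
        s = next(x for x in sessions if not x.excluded)
        rng = np.random.default_rng(0)
        for role in ("female", "male"):
            labels = s.labels(role)
            segs = segments(labels, [t for t in s.trips if t.bird_role == role])
            lab, _ = _bird_matrices(segs, s.grid.n_windows, 50, rng)
            for code in (CO, ST, LT, MASKED):
                assert ((lab == code).sum(axis=1) == (labels == code).sum()).all()

    def test_index_formula(self):
        ps = _rich_session()
        r = run_randomization(ps, "st_lt_overlap", n_iter=400, seed=1)["st_lt_overlap"]
        assert r.index == pytest.approx((r.observed - r.null_mean) / r.null_mean)

    def test_invalid_n_iter(self):
        with pytest.raises(ValueError):
            run_randomization(_rich_session(), "both", n_iter=0)

    def test_no_trips_is_degenerate(self):
        ps = make_pair_session([CO] * 12, [CO] * 4 + [ST] * 4 + [CO] * 4)
        r = run_randomization(ps, "st_lt_overlap", n_iter=50, seed=0)["st_lt_overlap"]
        assert r.degenerate
        assert np.isnan(r.p_value)

    def test_point_mass_null_flagged_uninformative(self):
        # one trip + one CO per bird: the skeleton shuffle admits one arrangement
        ps = make_pair_session([CO] * 3 + [ST] * 3, [LT] * 4 + [CO] * 2)
        r = run_randomization(ps, "st_lt_overlap", n_iter=100, seed=0)["st_lt_overlap"]
        assert r.degenerate
        assert "point-mass" in r.note

    def test_pinned_fragment_never_moves(self):
        # female: masked span then a clipped LT fragment, then CO/ST/CO/LT/CO
        lf = np.array([MASKED] * 4 + [LT] * 3 + [CO] * 2 + [ST] * 2 + [CO] * 2
                      + [LT] * 2 + [CO] * 1, dtype=np.int8)
        lm = np.array([MASKED] * 4 + [CO] * 2 + [ST] * 3 + [CO] * 2 + [LT] * 4
                      + [CO] * 1, dtype=np.int8)
        from dualforage.trips import Trip

        trips_f = [
            Trip("p", "s", "female", 2, 5, True, False, None),  # source of fragment
            Trip("p", "s", "female", 9, 2, False, False, "ST"),
            Trip("p", "s", "female", 13, 2, False, False, "LT"),
        ]
        trips_m = [
            Trip("p", "s", "male", 6, 3, False, False, "ST"),
            Trip("p", "s", "male", 11, 4, False, False, "LT"),
        ]
        from dualforage.io import SessionGrid
        from dualforage.trips import PairSession

        ps = PairSession("p", "s", SessionGrid("s", n_windows=16), lf, lm,
                         trips_f + trips_m)
        from dualforage.randomize import _bird_matrices

        segs = segments(lf, trips_f)
        assert any(seg.pinned is not None for seg in segs)
        lab, _ = _bird_matrices(segs, 16, 200, np.random.default_rng(0))
        # fragment windows 4-6 hold LT in every shuffle
        assert (lab[:, 4:7] == LT).all()


class TestExactNull:
    def test_matches_monte_carlo_in_total_variation(self):
        ps = _rich_session()
        ex = exact_null_small(ps, "st_lt_overlap")
        assert ex.n_arrangements == 16
        r = run_randomization(ps, "st_lt_overlap", n_iter=10_000, seed=2)
        null = r["st_lt_overlap"].null_samples
        vals, counts = np.unique(null, return_counts=True)
        emp = dict(zip(vals, counts / len(null)))
        tv = 0.5 * sum(
            abs(emp.get(v, 0.0) - p) for v, p in zip(ex.values, ex.probs)
        ) + 0.5 * sum(p for v, p in emp.items() if v not in set(ex.values))
        assert tv < 0.03

    def test_exact_p_matches_monte_carlo_p(self):
        ps = _rich_session()
        ex = exact_null_small(ps, "st_lt_overlap")
        r = run_randomization(ps, "st_lt_overlap", n_iter=10_000, seed=4)[
            "st_lt_overlap"
        ]
        p_exact = ex.p_value(r.observed, lower_tail=False)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(r.p_value - p_exact) < max(4 * se, 0.01)

    def test_point_mass_instance(self):
        ps = make_pair_session([CO] * 3 + [ST] * 3, [LT] * 4 + [CO] * 2)
        ex = exact_null_small(ps, "st_lt_overlap")
        assert ex.n_arrangements == 1
        assert len(ex.values) == 1 and ex.probs[0] == pytest.approx(1.0)

    def test_combinatorial_bound_enforced(self):
        lf = [CO, CO] + [x for i in range(8) for x in [ST] * 2 + [CO] * 2]
        ps = make_pair_session(lf, lf)
        with pytest.raises(ValueError, match="exceed"):
            exact_null_small(ps, "st_lt_overlap", max_arrangements=10)

    def test_cv_exact_null_probabilities_sum_to_one(self):
        lf = [CO] + [ST] * 2 + [CO] + [ST] * 3 + [CO] + [LT] * 4 + [CO] * 3
        lm = [CO] * 2 + [ST] * 3 + [CO] + [LT] * 5 + [CO] + [ST] * 2 + [CO]
        ps = make_pair_session(lf, lm)
        ex = exact_null_small(ps, "interfeed_cv")
        assert ex.probs.sum() + ex.p_undefined == pytest.approx(1.0)
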