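import numpy as np
import pandas as pd
import pytest

from dualforage.growth import (
    derive_growth_params,
    fit_coordination_models,
    growth_params_table,
    growth_pca,
    sgr,
)
from dualforage.simulate import SimParams, simulate_chick_growth


class TestSGR:
    def test_printed_formula_hand_value(self):
        assert sgr(100, 120, 14, 17) == pytest.approx(6.077e-4, rel=1e-3)
        assert sgr(100, 120, 14, 17, "percent_per_day") == pytest.approx(6.077, rel=1e-3)

    def test_zero_growth(self):
        assert sgr(150, 150, 14, 20) == 0.0

    def test_antisymmetry(self):
        assert sgr(100, 130, 10, 15) == pytest.approx(-sgr(130, 100, 10, 15))

    def test_conventions_differ_by_exactly_1e4(self):
        a = sgr(97.0, 151.0, 13, 21, "paper_literal")
        b = sgr(97.0, 151.0, 13, 21, "percent_per_day")
        assert b / a == pytest.approx(1e4, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            sgr(100, 120, 17, 14)
        with pytest.raises(ValueError):
            sgr(-1, 120, 14, 17)
        with pytest.raises(ValueError):
            sgr(100, 120, 14, 17, "per_week")


def _mass_df(records, pair="n1"):
    return pd.DataFrame(
        [{"pair_id": pair, "day_of_life": d, "mass_g": m} for d, m in records]
    )


class TestGrowthParams:
    def test_hand_evaluation_of_definitions(self):
        masses = _mass_df([(14, 100), (17, 120), (20, 118), (23, 110)])
        checks = pd.DataFrame(
            {"pair_id": "n1", "day_of_life": [14, 17, 20, 23, 25, 28],
             "chick_present": [1, 1, 1, 1, 1, 0]}
        )
        gp = derive_growth_params(masses, checks)
        assert gp.peak_mass == 120 and gp.peak_day == 17
        assert gp.mass_recession == 10
        assert gp.fledge_mass == 110
        assert gp.fledge_day == pytest.approx(26.5)  # midpoint of 25 and 28
        assert gp.mass_d14_16 == 100
        assert gp.sgr1 == pytest.approx(sgr(100, 120, 14, 17))
        assert gp.sgr2 == pytest.approx(sgr(120, 110, 17, 23))

    def test_monotone_growth_has_zero_recession(self):
        gp = derive_growth_params(_mass_df([(14, 100), (17, 120), (20, 140)]))
        assert gp.fledge_mass == gp.peak_mass
        assert gp.mass_recession == 0
        assert gp.sgr2 == 0.0

    def test_peak_tie_broken_to_earliest_day(self):
        gp = derive_growth_params(_mass_df([(14, 100), (17, 120), (20, 120)]))
        assert gp.peak_day == 17

    def test_missing_day_14_16_warns_not_errors(self):
        with pytest.warns(UserWarning, match="14-16"):
            gp = derive_growth_params(_mass_df([(18, 120), (21, 130), (24, 125)]))
        assert gp.mass_d14_16 is None and gp.sgr1 is None

    def test_invariant_to_record_order(self, rng):
        recs = [(14, 100), (17, 120), (20, 118), (23, 110), (26, 105)]
        base = derive_growth_params(_mass_df(recs))
        shuffled = _mass_df(recs).sample(frac=1, random_state=1)
        other = derive_growth_params(shuffled)
        assert vars(base) == vars(other)

    def test_noiseless_generator_round_trip(self, rng):
        params = SimParams(seed=0)
        for _ in range(10):
            masses, checks, truth = simulate_chick_growth(
                params, "c1", rng, interval_cv=0.4, noise_sd=0.0
            )
            gp = derive_growth_params(masses, checks)
            assert gp.peak_mass == pytest.approx(truth["peak_mass"], abs=1e-9)
            assert gp.peak_day == truth["peak_day"]
            assert gp.fledge_mass == pytest.approx(truth["fledge_mass"], abs=1e-9)


class TestPCA:
    def _params(self, n=12, seed=0):
        r = np.random.default_rng(seed)
        masses = []
        for i in range(n):
            m, c, _ = simulate_chick_growth(SimParams(seed=0), f"c{i:02d}", r)
            masses.append(m)
        return growth_params_table(pd.concat(masses, ignore_index=True))

    def test_variance_proportions_sum_to_one_nonincreasing(self):
        pca = growth_pca(self._params())
        v = pca.variance_explained
        assert v.sum() == pytest.approx(1.0)
        assert (np.diff(v) <= 1e-12).all()
        assert ((v >= -1e-12) & (v <= 1 + 1e-12)).all()

    def test_two_perfectly_correlated_variables(self):
        df = pd.DataFrame({
            "pair_id": [f"c{i}" for i in range(6)],
            "peak_mass": [100, 110, 120, 130, 140, 150.0],
            "fledge_mass": [50, 55, 60, 65, 70, 75.0],
        })
        pca = growth_pca(df)
        assert pca.variance_explained[0] == pytest.approx(1.0)

    def test_zero_variance_variable_dropped_with_warning(self):
        df = self._params(8)
        df["peak_day"] = 20
        with pytest.warns(UserWarning, match="zero-variance"):
            pca = growth_pca(df)
        assert "peak_day" in pca.dropped_vars

    def test_scores_reproducible(self):
        df = self._params()
        a = growth_pca(df).scores
        b = growth_pca(df).scores
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_chicks_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            growth_pca(self._params(2))


class TestModels:
    def test_constant_response_gives_zero_slope(self):
        df = pd.DataFrame({
            "pair_id": ["a", "a", "b", "b", "c", "c"],
            "session_id": list("123456"),
            "coordination_level": [0.1, 0.3, -0.2, 0.4, 0.0, 0.2],
            "rel_cv": [-0.1, 0.2, 0.1, -0.3, 0.0, 0.1],
            "chick_age": [9, 16, 10, 17, 11, 18],
        })
        scores = pd.DataFrame({"pair_id": ["a", "b", "c"], "PC1": [1.0, 1.0, 1.0]})
        feeds = df[["pair_id", "session_id"]].assign(n_feedings=12)
        rep = fit_coordination_models(df, scores, feeds)
        c = rep[(rep.name == "c_pc1_vs_coordination")
                & (rep.term == "coordination_level")].iloc[0]
        assert c.estimate == 0.0
        assert c.p_value == 1.0

    def test_strong_cv_growth_link_detected(self):
        """Chicks built with peak mass depressed by interval CV: model (d) finds it."""
        r = np.random.default_rng(3)
        params = SimParams(seed=0, growth_effect_beta=150.0)
        rows, masses = [], []
        for i in range(16):
            pid = f"p{i:02d}"
            for year in (1, 2):
                cid = f"{pid}_y{year}"
                cv = float(r.uniform(0.2, 1.0))
                m, _, _ = simulate_chick_growth(params, cid, r, interval_cv=cv)
                m = m.rename(columns={"pair_id": "chick_id"})
                m.insert(0, "pair_id", pid)
                masses.append(m)
                for js in range(2):
                    rows.append({
                        "pair_id": pid, "session_id": f"s{year}{js}",
                        "chick_id": cid, "chick_age": 8 + 7 * js,
                        "coordination_level": float(r.normal(0, 0.2)),
                        "rel_cv": cv - 0.6 + float(r.normal(0, 0.05)),
                        "n_feedings": int(r.integers(10, 18)),
                    })
        df = pd.DataFrame(rows)
        gp = growth_params_table(pd.concat(masses, ignore_index=True))
        pca = growth_pca(gp)
        rep = fit_coordination_models(
            df.drop(columns=["n_feedings"]), pca.scores,
            df[["pair_id", "session_id", "n_feedings"]],
        )
        d = rep[rep.name.str.startswith("d_") & (rep.term == "rel_cv")]
        assert (d.p_value < 0.05).any()
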