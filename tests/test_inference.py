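"""Person-period expansion, cloglog hazard fit and permutation tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from daphdem import inference, simulate
from daphdem.inference import (build_design, expand_person_period,
                               fit_cloglog_hazard, fit_trait_model,
                               lrt_random_screen,
                               permutation_test_fixed_effect,
                               permutation_two_sample)

from conftest import make_record


class TestPersonPeriod:
    def test_death_on_day_three(self):
        rec = make_record(death_day=3, censored=False, body_size=None)
        pp = expand_person_period([rec], horizon=19)
        assert len(pp) == 3
        assert pp["event"].tolist() == [0, 0, 1]
        assert pp["interval"].tolist() == [1, 2, 3]

    def test_censored_individual_contributes_horizon_rows(self):
        pp = expand_person_period([make_record()], horizon=19)
        assert len(pp) == 19
        assert pp["event"].sum() == 0

    def test_row_count_equals_animal_days(self, default_records):
        pp = expand_person_period(default_records, horizon=19)
        assert len(pp) == sum(min(r.death_day, 19) for r in default_records)
        assert pp.groupby("individual_id")["event"].sum().max() <= 1

    def test_death_beyond_horizon_rejected(self):
        rec = make_record(death_day=19)
        with pytest.raises(ValueError):
            expand_person_period([rec], horizon=10)


class TestDesign:
    def test_interaction_columns_are_products(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 5.0]})
        X = build_design(df, ["a", "b", "a:b"])
        assert X["a:b"].tolist() == [3.0, 10.0]
        assert (X["intercept"] == 1).all()

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            build_design(pd.DataFrame({"a": [1.0]}), ["a:zz"])


class TestCloglogHazard:
    def test_intercept_only_closed_form(self):
        """With event fraction p the intercept is ln(-ln(1-p)); for
        p = 1 - 1/e it is exactly zero."""
        p = 1 - math.exp(-1)
        n = 1000
        k = round(p * n)
        table = pd.DataFrame({"event": [1] * k + [0] * (n - k),
                              "interval": 1})
        fit = fit_cloglog_hazard(table, terms=[])
        expected = math.log(-math.log(1 - k / n))
        assert fit.params["intercept"] == pytest.approx(expected, abs=1e-8)
        assert abs(fit.params["intercept"]) < 5e-4  # k/n ~ 1 - 1/e

    def test_no_events_rejected(self):
        table = pd.DataFrame({"event": [0, 0], "interval": [1, 2]})
        with pytest.raises(ValueError):
            fit_cloglog_hazard(table, terms=[])

    def test_rank_deficient_design_rejected(self, default_records):
        pp = expand_person_period(default_records, horizon=19)
        pp["ca2"] = pp["ca"]
        with pytest.raises(ValueError, match="rank"):
            fit_cloglog_hazard(pp, terms=["ca", "ca2"])

    def test_recovers_generating_coefficients(self):
        """Fitting the generator's own covariate coding (reciprocal Ca)
        returns estimates close to the generating coefficients."""
        cfg = simulate.default_config(seed=60_001, n_replicates=40)  # n=640
        records = simulate.simulate_experiment(cfg)
        pp = expand_person_period(records, horizon=19)
        pp["ca_inv"] = 1.0 / pp["ca"]
        fit = fit_cloglog_hazard(
            pp, terms=["ca_inv", "food", "temp", "ca_inv:food",
                       "ca_inv:temp", "interval"])
        hc = cfg.hazard_coefs
        truth = {"intercept": hc.intercept, "ca_inv": hc.ca_inv,
                 "food": hc.food, "temp": hc.temp,
                 "ca_inv:food": hc.ca_inv_food,
                 "ca_inv:temp": hc.ca_inv_temp, "interval": hc.interval}
        for term, value in truth.items():
            z = (fit.params[term] - value) / fit.bse[term]
            assert abs(z) < 4, f"{term}: {fit.params[term]} vs {value}"

    def test_negative_ca_food_interaction_on_default_data(self, default_records):
        """Raw-scale analysis model recovers the survival-costly low-Ca x
        high-food combination as a negative Ca x food interaction."""
        pp = expand_person_period(default_records, horizon=19)
        fit = fit_cloglog_hazard(pp)
        assert fit.params["ca:food"] < 0
        assert fit.wald_z["ca:food"] < -2


class TestBoxScreen:
    def test_duplicate_boxes_give_near_zero_statistic(self, default_records):
        pp = expand_person_period(default_records[:60], horizon=19)
        pp["box_id"] = "boxA"
        dup = pp.copy()
        dup["box_id"] = "boxB"
        dup["individual_id"] = dup["individual_id"] + "_b"
        both = pd.concat([pp, dup], ignore_index=True)
        stat, p, df = lrt_random_screen(both, terms=["ca", "food", "interval"])
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert df == 1

    def test_single_group_rejected(self, default_records):
        pp = expand_person_period(default_records[:20], horizon=19)
        pp["box_id"] = "only"
        with pytest.raises(ValueError):
            lrt_random_screen(pp)

    def test_null_box_effect_p_values_roughly_uniform(self):
        """With zero box variance the LRT p-values follow U(0,1)."""
        ps = []
        for s in range(100):
            cfg = simulate.default_config(seed=70_000 + s, n_replicates=6)
            pp = expand_person_period(simulate.simulate_experiment(cfg), 19)
            stat, p, df = lrt_random_screen(pp)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_large_injected_box_effects(self):
        hits = 0
        for s in range(20):
            cfg = simulate.default_config(seed=80_000 + s, box_sd=1.0)
            pp = expand_person_period(simulate.simulate_experiment(cfg), 19)
            stat, p, df = lrt_random_screen(pp)
            hits += p < 0.001
        assert hits >= 0.95 * 20 - 2  # >= 17/20 under strong shifts


def _null_design(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.choice([0.2, 2.0], size=n),
        "x3": rng.normal(size=n),
    })


class TestPermutationFixedEffect:
    FULL = ("x1", "x2", "x3", "x1:x2")

    def test_perfectly_explanatory_term_gives_minimal_p(self, rng):
        df = _null_design(40, rng)
        df["y"] = 3.0 * df["x1"] * df["x2"]  # response IS the tested term
        res = permutation_test_fixed_effect(df, "y", self.FULL, "x1:x2",
                                            n_permutations=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_p_value_bounds(self, rng):
        df = _null_design(30, rng)
        df["y"] = rng.normal(size=30)
        res = permutation_test_fixed_effect(df, "y", self.FULL, "x3",
                                            n_permutations=99, seed=2)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_aliased_term_rejected(self, rng):
        df = _null_design(30, rng)
        df["x4"] = df["x1"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="aliased"):
            permutation_test_fixed_effect(df, "y", ("x1", "x4"), "x4",
                                          n_permutations=9, seed=3)

    def test_type_one_error_calibrated_under_null(self):
        """Empirical rejection rate at alpha = 0.05 under an independent
        response, 300 simulations x 999 permutations."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            df = _null_design(48, rng)
            df["y"] = rng.normal(size=48)
            res = permutation_test_fixed_effect(
                df, "y", self.FULL, "x1:x2", n_permutations=999,
                seed=int(rng.integers(2**31)))
            rejections += res.p_perm <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_detects_a_real_interaction(self, rng):
        df = _null_design(96, rng)
        df["y"] = 1.5 * df["x1"] * df["x2"] + rng.normal(size=96)
        res = permutation_test_fixed_effect(df, "y", self.FULL, "x1:x2",
                                            n_permutations=999, seed=5)
        assert res.p_perm < 0.01


class TestTwoSamplePermutation:
    def test_identical_samples_give_p_one(self):
        assert permutation_two_sample([1.0, 2, 3], [1.0, 2, 3],
                                      n_permutations=99, seed=1) == 1.0

    def test_separated_samples_give_small_p(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)
        p = permutation_two_sample(x, y, n_permutations=999, seed=2)
        assert p == pytest.approx(1 / 1000)


class TestTraitModel:
    def test_recovers_linear_trait_structure(self, rng):
        n = 400
        df = pd.DataFrame({"log_ca": rng.normal(size=n),
                           "food": rng.choice([0.2, 2.0], size=n)})
        df["body_size"] = 1000 + 200 * df["log_ca"] + 50 * df["food"] \
            + rng.normal(0, 20, n)
        out = fit_trait_model(df, "body_size", ["log_ca", "food"])
        assert out.loc["log_ca", "estimate"] == pytest.approx(200, abs=10)
        assert out.loc["food", "p"] < 1e-6

    def test_missing_responses_dropped(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10),
                           "y": [1.0, np.nan] * 5})
        out = fit_trait_model(df, "y", ["x"])
        assert out.shape[0] == 2  # intercept + x
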