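"""Prevalence tables, chi-square, logistic ORs, linear fits, delta R^2."""

import math

import numpy as np
import pandas as pd
import pytest

from emospect.annotate import EmotionProfile
from emospect.lexicon import PRIMARY_EMOTIONS
from emospect.preprocess import ReviewRecord
from emospect.sentiment import SentimentScore
from emospect.stats import (
    CollinearityError,
    DeltaR2Result,
    SeparationError,
    StatsInputError,
    fit_emotion_logit,
    fit_ols,
    fit_satisfaction_models,
    fit_sentiment_on_emotions,
    prevalence_table,
    standardize_satisfaction,
)


def _profile(rid, **flags):
    f = {p: 0 for p in PRIMARY_EMOTIONS}
    f.update(flags)
    return EmotionProfile(review_id=rid, flags=f, n_matches=dict(f))


def _record(rid, drug="sildenafil", age_band="<44", duration_band="short",
            year=2015, sat=None):
    return ReviewRecord(
        review_id=rid, source="synthetic", drug=drug, text="x",
        age_band=age_band, duration_band=duration_band, rating_year=year,
        satisfaction_5=sat,
    )


class TestPrevalence:
    def test_pooled_percentage_matches_flag_arithmetic(self):
        profiles = [_profile(f"r{i}", joy=int(i < 1830)) for i in range(3070)]
        records = [_record(f"r{i}") for i in range(3070)]
        tab = prevalence_table(profiles, records, stratifier=None)
        assert tab.percent[("all", "joy")] == pytest.approx(100 * 1830 / 3070)
        assert round(tab.percent[("all", "joy")], 2) == 59.61
        p = 1830 / 3070
        assert tab.se[("all", "joy")] == pytest.approx(math.sqrt(p * (1 - p) / 3070))

    def test_zero_prevalence_level(self):
        profiles = [_profile(f"r{i}") for i in range(100)]
        records = [_record(f"r{i}") for i in range(100)]
        tab = prevalence_table(profiles, records, stratifier=None)
        assert tab.percent[("all", "joy")] == 0.0
        assert tab.se[("all", "joy")] == 0.0

    def test_two_by_two_chi_square_hand_value(self):
        # joy present 20/30 for sildenafil vs 10/30 for vardenafil:
        # chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 6.6667, df = 1
        profiles, records = [], []
        for i in range(60):
            drug = "sildenafil" if i < 30 else "vardenafil"
            joy = int(i < 20 or (30 <= i < 40))
            profiles.append(_profile(f"r{i}", joy=joy))
            records.append(_record(f"r{i}", drug=drug))
        tab = prevalence_table(profiles, records, stratifier="drug")
        chi2, dof, _ = tab.per_emotion_tests["joy"]
        assert chi2 == pytest.approx(6.6667, abs=1e-4)
        assert dof == 1

    def test_chi_square_matches_textbook_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = 400
            drugs = rng.choice(["sildenafil", "vardenafil", "tadalafil"], size=n)
            flag_p = rng.uniform(0.1, 0.8, size=len(PRIMARY_EMOTIONS))
            profiles, records = [], []
            for i in range(n):
                flags = {e: int(rng.random() < flag_p[j]) for j, e in enumerate(PRIMARY_EMOTIONS)}
                profiles.append(EmotionProfile(f"r{i}", flags, dict(flags)))
                records.append(_record(f"r{i}", drug=drugs[i]))
            tab = prevalence_table(profiles, records, stratifier="drug")
            # oracle: sum (O-E)^2/E over the mention-count table
            levels = tab.levels
            obs = np.array(
                [[sum(p.flags[e] for p, r in zip(profiles, records) if r.drug == lv)
                  for e in PRIMARY_EMOTIONS] for lv in levels], float)
            obs = obs[:, obs.sum(axis=0) > 0]
            exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / obs.sum()
            assert tab.chi_square == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-10)
            assert tab.dof == (obs.shape[0] - 1) * (obs.shape[1] - 1)

    def test_missing_stratifier_levels_are_excluded(self):
        profiles = [_profile(f"r{i}", joy=1) for i in range(10)]
        records = [_record(f"r{i}", age_band=None if i < 4 else "<44") for i in range(10)]
        tab = prevalence_table(profiles, records, stratifier="age_band")
        assert tab.n_per_level == {"<44": 6}

    def test_zero_total_table_is_error(self):
        profiles = [_profile(f"r{i}") for i in range(10)]
        records = [_record(f"r{i}", drug="sildenafil" if i < 5 else "vardenafil")
                   for i in range(10)]
        with pytest.raises(StatsInputError):
            prevalence_table(profiles, records, stratifier="drug")


class TestLogit:
    def test_two_by_two_matches_closed_form_odds_ratio(self):
        # outcome x covariate counts: a=35,b=15 (sildenafil), c=20,d=30 (vardenafil)
        profiles, records = [], []
        i = 0
        for drug, k, n in (("sildenafil", 35, 50), ("vardenafil", 20, 50)):
            for j in range(n):
                profiles.append(_profile(f"r{i}", joy=int(j < k)))
                records.append(_record(f"r{i}", drug=drug))
                i += 1
        res = fit_emotion_logit(profiles, records, "joy", covariates=("drug",))
        closed = (20 / 30) / (35 / 15)
        fitted = res.terms["drug[vardenafil]"].odds_ratio
        assert abs(fitted - closed) / closed < 1e-4

    def test_null_covariate_wald_ci_coverage(self):
        # planted OR 1.0: the Wald 95% CI should cover 1.0 at >= 93% of a
        # fixed block of replicate seeds (93% is the binomial tolerance on
        # nominal 95% coverage; the block is large enough for the rate to
        # be stable)
        n = 5000
        n_seeds = 500
        covered = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            drugs = np.where(rng.random(n) < 0.5, "sildenafil", "vardenafil")
            ys = (rng.random(n) < 0.3).astype(int)
            profiles = [_profile(f"r{i}", joy=int(ys[i])) for i in range(n)]
            records = [_record(f"r{i}", drug=drugs[i]) for i in range(n)]
            t = fit_emotion_logit(profiles, records, "joy", covariates=("drug",)).terms[
                "drug[vardenafil]"]
            covered += t.ci_low <= 1.0 <= t.ci_high
        assert covered >= 0.93 * n_seeds

    def test_degenerate_outcome_raises_separation_error(self):
        profiles = [_profile(f"r{i}", joy=1) for i in range(40)]
        records = [_record(f"r{i}", drug="sildenafil" if i % 2 else "vardenafil")
                   for i in range(40)]
        with pytest.raises(SeparationError):
            fit_emotion_logit(profiles, records, "joy", covariates=("drug",))

    def test_perfectly_separating_covariate_raises(self):
        profiles = [_profile(f"r{i}", joy=int(i < 20)) for i in range(40)]
        records = [_record(f"r{i}", drug="sildenafil" if i < 20 else "vardenafil")
                   for i in range(40)]
        with pytest.raises(SeparationError):
            fit_emotion_logit(profiles, records, "joy", covariates=("drug",))


class TestLinear:
    def test_planted_coefficient_recovery(self):
        from emospect.annotate import annotate_corpus
        from emospect.lexicon import default_lexicon
        from emospect.sentiment import score_corpus
        from emospect.simulate import GeneratorConfig, generate_corpus

        cfg = GeneratorConfig(n_reviews=3000, seed=0)
        cfg.sentiment_model = {
            "intercept": 0.0,
            "emotions": {"joy": 0.45, "love": 0.0, "surprise": 0.0,
                         "sadness": -0.40, "fear": 0.0, "anger": 0.0},
            "drug": {}, "age_band": {}, "duration_band": {},
            "year_slope": 0.0, "year_center": 2012, "noise_sd": 0.2,
        }
        lex = default_lexicon()
        recs, _ = generate_corpus(cfg, lexicon=lex)
        profiles, _ = annotate_corpus(recs, lex)
        res = fit_sentiment_on_emotions(profiles, score_corpus(recs), recs)
        for emo in PRIMARY_EMOTIONS:
            planted = cfg.sentiment_model["emotions"][emo]
            t = res.terms[emo]
            assert abs(t.beta - planted) < 3 * t.se

    def test_constant_outcome_gives_zero_slopes_and_r2(self):
        rng = np.random.default_rng(7)
        drugs = ("sildenafil", "vardenafil", "tadalafil")
        ages = ("<44", "45-64", ">=65")
        durs = ("short", "mid", "long")
        profiles = [
            _profile(f"r{i}", **{e: int(rng.random() < 0.4) for e in PRIMARY_EMOTIONS})
            for i in range(60)
        ]
        records = [
            _record(f"r{i}", drug=drugs[i % 3], age_band=ages[(i // 3) % 3],
                    duration_band=durs[(i // 9) % 3], year=2005 + i % 15)
            for i in range(60)
        ]
        scores = [SentimentScore(f"r{i}", compound=0.25, raw_sum=1.0) for i in range(60)]
        res = fit_sentiment_on_emotions(profiles, scores, records)
        assert res.r_squared == 0.0
        assert res.terms["joy"].beta == pytest.approx(0.0, abs=1e-10)

    def test_duplicate_column_raises_collinearity_error(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"Intercept": 1.0, "a": rng.random(30)})
        X["a_copy"] = X["a"]
        y = pd.Series(rng.random(30))
        with pytest.raises(CollinearityError) as exc:
            fit_ols(y, X)
        assert "a_copy" in exc.value.aliased


class TestSatisfaction:
    def test_delta_equals_printed_difference(self):
        d = DeltaR2Result.from_r2(0.259, 0.06928)
        assert d.delta == pytest.approx(0.18972, abs=1e-12)

    def test_delta_requires_consistency(self):
        with pytest.raises(ValueError):
            DeltaR2Result(0.3, 0.1, 0.5, 0.0, 0.0)

    def _pipeline(self, cfg):
        from emospect.sentiment import score_corpus
        from emospect.simulate import generate_corpus

        recs, truth = generate_corpus(cfg)
        return recs, score_corpus(recs), truth

    def test_null_sentiment_slope_gives_tiny_delta(self):
        from emospect.simulate import GeneratorConfig

        cfg = GeneratorConfig(n_reviews=3000, seed=0)
        cfg.satisfaction_model = dict(cfg.satisfaction_model, sentiment_slope=0.0)
        recs, scores, _ = self._pipeline(cfg)
        delta, _, _ = fit_satisfaction_models(recs, scores)
        assert 0.0 <= delta.delta <= 0.01

    def test_delta_matches_variance_decomposition(self):
        # continuous satisfaction = 3 + 1.0*sentiment + N(0, 0.5); population
        # delta is slope^2 * Var(sent | covariates) / Var(satisfaction)
        import statsmodels.api as sm
        from emospect.simulate import GeneratorConfig

        cfg = GeneratorConfig(n_reviews=3000, seed=0)
        cfg.satisfaction_model = {
            "intercept": 3.0, "sentiment_slope": 1.0, "drug": {}, "age_band": {},
            "duration_band": {}, "year_slope": 0.0, "year_center": 2012,
            "noise_sd": 0.5, "likert": False,
        }
        recs, scores, _ = self._pipeline(cfg)
        delta, m1, m2 = fit_satisfaction_models(recs, scores)
        df = pd.DataFrame(
            {"sent": {s.review_id: s.compound for s in scores},
             "sat": {r.review_id: r.satisfaction_5 for r in recs},
             "drug": {r.review_id: r.drug for r in recs},
             "age": {r.review_id: r.age_band for r in recs},
             "dur": {r.review_id: r.duration_band for r in recs},
             "year": {r.review_id: r.rating_year for r in recs}}
        ).dropna()
        Z = pd.get_dummies(df[["drug", "age", "dur"]], drop_first=True).astype(float)
        Z["year"] = df["year"].astype(float)
        Z = sm.add_constant(Z)
        resid = sm.OLS(df["sent"], Z).fit().resid
        pop_delta = 1.0**2 * resid.var() / df["sat"].var()
        assert delta.delta == pytest.approx(pop_delta, abs=0.05)

    def test_nested_delta_is_nonnegative_and_rows_match(self):
        from emospect.simulate import GeneratorConfig

        recs, scores, _ = self._pipeline(GeneratorConfig(n_reviews=1500, seed=4))
        delta, m1, m2 = fit_satisfaction_models(recs, scores)
        assert delta.delta >= 0.0
        assert m1.n_used == m2.n_used


class TestStandardize:
    @pytest.mark.parametrize(
        "raw,scale,expected",
        [(10, 10, 5), (1, 10, 1), (7, 10, 4), (2, 10, 1), (3, 5, 3), (5, 5, 5)],
    )
    def test_mapping(self, raw, scale, expected):
        assert standardize_satisfaction(raw, scale) == expected

    @pytest.mark.parametrize("raw,scale", [(0, 5), (6, 5), (11, 10), (-1, 10), (3, 7)])
    def test_out_of_range_rejected(self, raw, scale):
        with pytest.raises(StatsInputError):
            standardize_satisfaction(raw, scale)
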