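"""Relative-risk estimation: crosstab ratios, modified Poisson, strata,
interactions."""

import numpy as np
import pandas as pd
import pytest

from scdpaf import recode as rc
from scdpaf import synthetic as syn
from scdpaf.pipeline import _design_of
from scdpaf.rr import (
    ModifiedPoissonRR,
    adjusted_rr,
    interaction_test,
    rr_from_records,
    stratified_rr,
    unadjusted_rr,
)
from scdpaf.survey import weighted_2x2

from conftest import srs_design


def _make_2x2(risk1, risk0, n=4000, rng=None, weights=None):
    rng = rng or np.random.default_rng(0)
    x = np.repeat([1.0, 0.0], n // 2)
    y = np.concatenate(
        [(rng.random(n // 2) < risk1), (rng.random(n // 2) < risk0)]
    ).astype(float)
    d = srs_design(n, weights)
    return weighted_2x2(x, y, d), x, y


class TestUnadjusted:
    def test_exact_ratio_two(self):
        n = 1000
        x = np.repeat([1.0, 0.0], n // 2)
        y = np.zeros(n)
        y[:100] = 1  # exposed risk 0.2
        y[500:550] = 1  # unexposed risk 0.1
        t = weighted_2x2(x, y, srs_design(n))
        est = unadjusted_rr(t)
        assert est.rr == pytest.approx(2.0)
        assert est.ci_low < 2.0 < est.ci_high

    def test_independence_gives_unity(self):
        x = np.array([1, 1, 0, 0], float)
        y = np.array([1, 0, 1, 0], float)
        t = weighted_2x2(x, y, srs_design(4, [3.0, 7.0, 6.0, 14.0]))
        assert unadjusted_rr(t).rr == pytest.approx(1.0)

    def test_weight_doubling_leaves_rr_unchanged(self, rng):
        t1, x, y = _make_2x2(0.2, 0.1, rng=rng)
        t2 = weighted_2x2(x, y, srs_design(len(x), np.full(len(x), 2.0)))
        assert unadjusted_rr(t2).rr == pytest.approx(unadjusted_rr(t1).rr, rel=1e-12)

    def test_no_cases_anywhere_raises(self):
        x = np.array([1.0, 0.0])
        y = np.zeros(2)
        with pytest.raises(ValueError, match="no cases"):
            unadjusted_rr(weighted_2x2(x, y, srs_design(2)))

    def test_zero_cell_one_sided(self):
        x = np.array([1, 1, 0, 0], float)
        y = np.array([0, 0, 1, 0], float)
        est = unadjusted_rr(weighted_2x2(x, y, srs_design(4)))
        assert est.rr == 0.0 and est.one_sided

    def test_recovers_generator_rr(self, rng):
        # strong social-isolation-like factor: truth 3.39 at 52% prevalence
        n = 100_000
        x = (rng.random(n) < 0.524).astype(float)
        r0 = 0.045
        y = (rng.random(n) < np.where(x == 1, 3.39 * r0, r0)).astype(float)
        est = unadjusted_rr(weighted_2x2(x, y, srs_design(n)))
        assert abs(np.log(est.rr / 3.39)) < 3 * est.log_se


class TestModifiedPoisson:
    def test_matches_crosstab_without_covariates(self, rng):
        t, x, y = _make_2x2(0.15, 0.06, n=6000, rng=rng)
        crosstab = unadjusted_rr(t)
        df = pd.DataFrame({"f": x, "scd": y})
        est = adjusted_rr(df.assign(_w=1.0), "f", [], srs_design(len(x)))
        assert est.rr == pytest.approx(crosstab.rr, rel=1e-6)

    def test_sklearn_interface_and_prediction(self, rng):
        n = 5000
        x = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < np.where(x == 1, 0.2, 0.1)).astype(float)
        est = ModifiedPoissonRR().fit(pd.DataFrame({"x": x}), y)
        assert est.get_params()["family"] == "poisson"
        assert list(est.feature_names_in_) == ["const", "x"]
        pred = est.predict(pd.DataFrame({"x": np.array([0.0, 1.0])}))
        assert pred[1] / pred[0] == pytest.approx(est.rr_[1])
        lo, hi = est.conf_int_[1]
        assert lo <= est.rr_[1] <= hi

    def test_confounded_factor_needs_adjustment(self, rng):
        """Age-linked factor: unadjusted RR biased away from the
        conditional truth, adjusted recovers it."""
        n = 60_000
        age = rng.integers(3, size=n)
        p_x = np.array([0.1, 0.3, 0.5])[age]
        x = (rng.random(n) < p_x).astype(float)
        base = np.array([0.03, 0.06, 0.12])[age]
        rr_true = 1.5
        y = (rng.random(n) < base * rr_true**x).astype(float)
        df = pd.DataFrame({"f": x, "scd": y, "age_group": age.astype(str)})
        d = srs_design(n)
        unadj = rr_from_records(df, "f", d)
        adj = adjusted_rr(df, "f", ["age_group"], d)
        assert abs(np.log(adj.rr / rr_true)) < 3 * adj.log_se
        assert unadj.rr > adj.ci_high  # confounding visibly inflates

    def test_collapsible_when_no_confounding(self, rng):
        n = 40_000
        x = (rng.random(n) < 0.4).astype(float)
        z = (rng.random(n) < 0.5).astype(float)  # independent covariate
        y = (rng.random(n) < 0.05 * 1.8**x).astype(float)
        df = pd.DataFrame({"f": x, "z": z, "scd": y})
        d = srs_design(n)
        unadj = rr_from_records(df, "f", d)
        adj = adjusted_rr(df, "f", ["z"], d)
        assert np.log(adj.rr / unadj.rr) == pytest.approx(0.0, abs=0.02)

    def test_design_sandwich_close_to_independence_sandwich_under_srs(self, rng):
        n = 8000
        x = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < 0.08 * 2.0**x).astype(float)
        df = pd.DataFrame({"f": x, "scd": y})
        est = adjusted_rr(df, "f", [], srs_design(n))
        # analytic Poisson-sandwich SE for a 2x2: sqrt(sum of (1-r)/events)
        e1, n1 = y[x == 1].sum(), (x == 1).sum()
        e0, n0 = y[x == 0].sum(), (x == 0).sum()
        se = np.sqrt((1 - e1 / n1) / e1 + (1 - e0 / n0) / e0)
        assert est.log_se == pytest.approx(se, rel=0.02)


class TestStratifiedAndInteraction:
    def _frame(self, rng, n=30_000, rr_by_g=(2.0, 2.0)):
        g = rng.integers(2, size=n)
        x = (rng.random(n) < 0.3).astype(float)
        rr = np.asarray(rr_by_g)[g]
        y = (rng.random(n) < 0.05 * rr**x).astype(float)
        return pd.DataFrame(
            {"f": x, "scd": y, "grp": np.array(["a", "b"])[g],
             "z": rng.integers(2, size=n).astype(str)}
        )

    def test_identical_strata_match_pooled(self, rng):
        df = self._frame(rng)
        d = srs_design(len(df))
        pooled = adjusted_rr(df, "f", ["z"], d)
        per = stratified_rr(df, "f", ["z", "grp"], d, "grp")
        assert len(per) == 2
        for est in per:
            assert abs(np.log(est.rr / pooled.rr)) < 3 * est.log_se

    def test_small_stratum_skipped(self, rng):
        df = self._frame(rng, n=2000)
        df.loc[df["grp"] == "b", "grp"] = "a"
        df.loc[:4, "grp"] = "tiny"
        per = stratified_rr(df, "f", ["grp"], srs_design(len(df)), "grp", min_n=50)
        assert [e.stratum for e in per] == ["a"]

    def test_sex_specific_rrs_recovered(self, rng):
        df = self._frame(rng, n=60_000, rr_by_g=(3.6, 1.4))
        per = {e.stratum: e for e in
               stratified_rr(df, "f", ["grp"], srs_design(len(df)), "grp")}
        assert abs(np.log(per["a"].rr / 3.6)) < 3 * per["a"].log_se
        assert abs(np.log(per["b"].rr / 1.4)) < 3 * per["b"].log_se

    def test_constant_modifier_errors(self, rng):
        df = self._frame(rng, n=1000)
        df["grp"] = "a"
        with pytest.raises(ValueError, match="constant"):
            interaction_test(df, "f", "grp", [], srs_design(len(df)))

    def test_detects_strong_interaction(self, rng):
        df = self._frame(rng, n=50_000, rr_by_g=(3.5, 1.2))
        res = interaction_test(df, "f", "grp", [], srs_design(len(df)))
        assert res.p_value < 1e-4
        # reported cell RRs straddle the two truths
        assert res.cell_rrs["a"] > 2.5 and res.cell_rrs["b"] < 1.8

    def test_null_interaction_not_systematically_rejected(self):
        rejections = 0
        for s in range(12):
            rng = np.random.default_rng(900 + s)
            df = self._frame(rng, n=8000, rr_by_g=(2.0, 2.0))
            res = interaction_test(df, "f", "grp", [], srs_design(len(df)))
            rejections += res.p_value < 0.05
        assert rejections <= 3  # ~alpha-level behaviour, loose binomial bound


class TestEndToEndRecovery:
    def test_joint_model_recovers_conditional_truths(self):
        """One synthetic replicate: every configured RR inside its 99.7%
        CI from the joint adjusted fit."""
        cfg = syn.recovery_config(n=40_000, seed=77)
        raw, truth = syn.generate(cfg)
        analytic, _ = rc.build_analytic_set(raw, specs=rc.specs_with_availability({}))
        design = _design_of(analytic, "adjust")
        from scdpaf.rr import _reference_code

        mask = analytic[rc.FACTORS + ["age_group", "scd"]].notna().all(axis=1).to_numpy()
        sub = analytic.loc[mask]
        d = design.subset(mask)
        X = pd.concat(
            [sub[rc.FACTORS].astype(float), _reference_code(sub, ["age_group"])],
            axis=1,
        )
        est = ModifiedPoissonRR().fit(
            X, sub["scd"].to_numpy(float),
            sample_weight=d.weights, strata=d.strata, psu=d.psu,
        )
        for f in rc.FACTORS:
            i = est.term_index(f)
            z = abs(np.log(est.rr_[i] / truth.rrs[f])) / est.bse_[i]
            assert z < 3.5, f
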