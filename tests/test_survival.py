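"""Recurrence endpoint, Cox/KM estimators and signature scoring rules."""

import numpy as np
import pandas as pd
import pytest

from regulonsurv import survival as sv
from regulonsurv.matrix import ExpressionMatrix

from .oracles import cox_beta_grid, km_bruteforce


class TestBCREvent:
    def test_flat_series_censored_at_last_time(self):
        assert sv.bcr_event([(0, 0.1), (6, 0.1), (12, 0.1)]) == (0, 12)

    def test_rise_two_above_nadir_fires_event(self):
        # nadir 0.2; 2.3 >= 2.2 at month 18
        assert sv.bcr_event([(0, 0.5), (6, 0.2), (18, 2.3)]) == (1, 18)

    def test_single_observation_censored(self):
        assert sv.bcr_event([(3, 0.4)]) == (0, 3)

    def test_unordered_series_rejected(self):
        with pytest.raises(ValueError):
            sv.bcr_event([(6, 0.1), (0, 0.1)])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sv.bcr_event([])


def _random_survival_data(rng, n=9):
    """Small two-group dataset with events in both groups (identifiable fit)."""
    while True:
        df = pd.DataFrame({
            "time_months": rng.uniform(1, 30, n).round(0) + 1,
            "event": rng.integers(0, 2, n),
            "x": rng.integers(0, 2, n),
        })
        by = df[df.event == 1].groupby("x").size()
        if len(by) == 2 and df["x"].nunique() == 2:
            return df


class TestCoxFit:
    def test_beta_matches_efron_grid_search(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 15:
            df = _random_survival_data(rng)
            beta_grid = cox_beta_grid(df["time_months"], df["event"], df["x"],
                                      lo=-12.0, hi=12.0)
            if abs(beta_grid) > 4:  # separated data: MLE diverges, skip
                continue
            res = sv.cox_fit(df, ["x"])
            beta_hat = np.log(res.table.loc["x", "hr"])
            assert beta_hat == pytest.approx(beta_grid, abs=1e-3)
            checked += 1

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(1)
        df = _random_survival_data(rng, n=40)
        res = sv.cox_fit(df, ["x"])
        row = res.table.loc["x"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"] and row["hr"] > 0

    def test_zero_events_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [0, 0, 0], "x": [0, 1, 0]})
        with pytest.raises(sv.DegenerateFitError):
            sv.cox_fit(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
        with pytest.raises(sv.DegenerateFitError):
            sv.cox_fit(df, ["x"])

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        group = rng.integers(0, 2, n)
        lam = 0.02 * np.where(group, 6.0, 1.0)
        t = rng.exponential(1 / lam)
        censor = np.quantile(t, 0.7)
        df = pd.DataFrame({
            "time_months": np.minimum(t, censor),
            "event": (t <= censor).astype(int),
            "x": group,
        })
        res = sv.cox_fit(df, ["x"])
        row = res.table.loc["x"]
        assert row["ci_low"] <= 6.0 <= row["ci_high"]


class TestKMLogrank:
    def test_no_events_flat_survival(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [0, 0, 0], "g": "a"})
        km = sv.km_logrank(df, "g")
        assert (km.curves["a"]["survival"] == 1.0).all()
        assert km.logrank_p is None and km.flagged

    def test_product_limit_hand_values(self):
        df = pd.DataFrame({"time_months": [2, 4, 6], "event": [1, 1, 0], "g": "a"})
        km = sv.km_logrank(df, "g")
        curve = km.curves["a"].set_index("time")["survival"]
        assert curve.loc[2.0] == pytest.approx(2 / 3)
        assert curve.loc[4.0] == pytest.approx(1 / 3)

    def test_matches_bruteforce_product_limit_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 11))
            df = pd.DataFrame({
                "time_months": rng.integers(1, 8, n).astype(float),
                "event": rng.integers(0, 2, n),
                "g": "a",
            })
            if df["event"].sum() == 0:
                continue
            km = sv.km_logrank(df, "g")
            curve = km.curves["a"].set_index("time")["survival"]
            for t, s in km_bruteforce(df["time_months"], df["event"]):
                assert curve.loc[t] == pytest.approx(s, abs=1e-12)

    def test_two_group_logrank_p_defined(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "time_months": rng.exponential(10, 40),
            "event": 1,
            "g": ["a"] * 20 + ["b"] * 20,
        })
        km = sv.km_logrank(df, "g")
        assert 0 <= km.logrank_p <= 1


def _expr(values: dict) -> ExpressionMatrix:
    df = pd.DataFrame(values)  # columns = samples
    return ExpressionMatrix(df, pd.Series("tumour", index=df.columns))


class TestSignatureScores:
    def test_tmcc_all_identical_samples_all_low(self):
        m = _expr({f"s{i}": {"g1": 2.0, "g2": 4.0} for i in range(5)})
        sig = sv.SignatureDefinition("t", ["g1", "g2"])
        out = sv.tmcc11_like_score(m, sig)
        assert (out["group"] == "low").all()

    def test_tmcc_interpolated_percentile_split(self):
        # scores (1, 2, 3): 67th percentile = 2.34, only score 3 is high
        m = _expr({"s1": {"g": 1.0}, "s2": {"g": 2.0}, "s3": {"g": 3.0}})
        out = sv.tmcc11_like_score(m, sv.SignatureDefinition("t", ["g"]))
        assert out.loc["s3", "group"] == "high"
        assert (out.drop("s3")["group"] == "low").all()

    def test_tmcc_single_gene_score_is_its_value(self):
        m = _expr({"s1": {"g": 7.0, "h": 1.0}, "s2": {"g": 2.0, "h": 1.0}})
        out = sv.tmcc11_like_score(m, sv.SignatureDefinition("t", ["g"]))
        assert out.loc["s1", "score"] == 7.0

    def test_missing_signature_rejected(self):
        m = _expr({"s1": {"g": 1.0}, "s2": {"g": 2.0}})
        with pytest.raises(ValueError):
            sv.tmcc11_like_score(m, sv.SignatureDefinition("t", ["nope"]))

    def test_weighted_zero_coefficients_all_low(self):
        m = _expr({"s1": {"g": 1.0}, "s2": {"g": 5.0}})
        sig = sv.SignatureDefinition("w", ["g"], coefficients=[0.0], split="median")
        out = sv.weighted_signature_score(m, sig)
        assert (out["score"] == 0.0).all() and (out["group"] == "low").all()

    def test_weighted_dot_product(self):
        m = _expr({"s1": {"g1": 2.0, "g2": 3.0}})
        sig = sv.SignatureDefinition("w", ["g1", "g2"], [1.0, -1.0], split="median")
        assert sv.weighted_signature_score(m, sig).loc["s1", "score"] == -1.0

    def test_weighted_groups_scale_invariant(self):
        rng = np.random.default_rng(5)
        vals = {f"s{i}": {"g1": rng.uniform(1, 9), "g2": rng.uniform(1, 9)}
                for i in range(9)}
        sig = sv.SignatureDefinition("w", ["g1", "g2"], [0.4, 1.3], split="median")
        a = sv.weighted_signature_score(_expr(vals), sig)
        doubled = {s: {g: 2 * v for g, v in d.items()} for s, d in vals.items()}
        b = sv.weighted_signature_score(_expr(doubled), sig)
        np.testing.assert_array_equal(a["group"], b["group"])
        np.testing.assert_allclose(b["score"], 2 * a["score"])

    def test_coefficient_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sv.SignatureDefinition("w", ["g1", "g2"], [1.0])


class TestRankWalk:
    def _four_gene_matrix(self, top_gene):
        # expression ranks g1 > g2 > g3 > g4; top_gene selects the set
        return _expr({"s": {"g1": 8.0, "g2": 6.0, "g3": 4.0, "g4": 2.0}}), [top_gene]

    def test_set_at_top_scores_plus_two(self):
        m, gene_set = self._four_gene_matrix("g1")
        score = sv.rank_walk_enrichment_score(m, gene_set, tau=0.0)["s"]
        assert score == pytest.approx(2.0)

    def test_set_at_bottom_scores_minus_two(self):
        m, gene_set = self._four_gene_matrix("g4")
        score = sv.rank_walk_enrichment_score(m, gene_set, tau=0.0)["s"]
        assert score == pytest.approx(-2.0)

    def test_reversed_ranking_negates_score(self):
        m = _expr({"s": {"g1": 8.0, "g2": 6.0, "g3": 4.0, "g4": 2.0}})
        rev = _expr({"s": {"g1": 2.0, "g2": 4.0, "g3": 6.0, "g4": 8.0}})
        a = sv.rank_walk_enrichment_score(m, ["g1"], tau=0.0)["s"]
        b = sv.rank_walk_enrichment_score(rev, ["g1"], tau=0.0)["s"]
        assert a == pytest.approx(-b)

    def test_full_coverage_set_rejected(self):
        m = _expr({"s": {"g1": 1.0, "g2": 2.0}})
        with pytest.raises(ValueError):
            sv.rank_walk_enrichment_score(m, ["g1", "g2"])


class TestSurvivalReport:
    @staticmethod
    def _clinical_and_activity(seed=0, n=40, hr=6.0):
        rng = np.random.default_rng(seed)
        active = rng.integers(0, 2, n).astype(bool)
        lam = 0.03 * np.where(active, hr, 1.0)
        t = rng.exponential(1 / lam)
        censor = 60.0
        clinical = pd.DataFrame({
            "sample": [f"T{i}" for i in range(n)],
            "time_months": np.minimum(t, censor),
            "event": (t <= censor).astype(int),
            "gleason": rng.integers(6, 10, n),
            "stage": rng.integers(1, 5, n),
        })
        rows = []
        for reg in ["LINKED", "NOISE1", "NOISE2"]:
            for i in range(n):
                if reg == "LINKED":
                    flag = active[i]
                else:
                    flag = rng.random() < 0.3
                rows.append({"sample": f"T{i}", "regulator": reg, "score": 0.5,
                             "p": 0.5, "q": 0.5, "active": bool(flag)})
        return clinical, pd.DataFrame(rows)

    def test_survival_linked_regulon_ranks_first(self):
        clinical, activity = self._clinical_and_activity()
        report = sv.survival_report(clinical, activity)
        assert report["regulon_ranking"].iloc[0]["variable"] == "LINKED"
        assert report["regulon_ranking"].iloc[0]["p"] < 0.05

    def test_multivariate_gated_on_univariate_significance(self):
        clinical, activity = self._clinical_and_activity()
        report = sv.survival_report(clinical, activity)
        models = set(report["multivariate"]["model"])
        assert "LINKED" in models
        ranking = report["regulon_ranking"].set_index("variable")
        for reg in ["NOISE1", "NOISE2"]:
            if ranking.loc[reg, "p"] >= 0.05:
                assert reg not in models

    def test_no_significant_variables_empty_multivariate(self):
        clinical, activity = self._clinical_and_activity(seed=1, hr=1.0)
        report = sv.survival_report(clinical, activity)
        sig = report["regulon_ranking"]["p"].lt(0.05).any()
        if not sig:
            assert report["multivariate"].empty

    def test_signature_groups_enter_univariate_table(self):
        clinical, activity = self._clinical_and_activity(seed=2)
        groups = pd.Series(
            ["high" if i % 2 else "low" for i in range(40)],
            index=[f"T{i}" for i in range(40)],
        )
        report = sv.survival_report(clinical, activity, {"SIGX": groups})
        assert "SIGX" in set(report["univariate"]["variable"])
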