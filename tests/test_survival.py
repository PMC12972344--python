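"""Kaplan-Meier, log-rank, Cox PH and fixed-horizon ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from filab import cox_groups, km_by_group, per_parameter_auc, roc_at_horizon


def km_oracle(times, events):
    """Hand product-limit estimate: S(t) at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def _km_cohort(times, events, groups=None):
    n = len(times)
    return pd.DataFrame({
        "time_days": times,
        "event": events,
        "group": groups if groups is not None else np.ones(n, dtype=int),
    })


class TestKaplanMeier:
    def test_three_deaths_no_censoring(self):
        df = _km_cohort([1, 2, 3], [1, 1, 1], [1, 1, 2])
        # group structure irrelevant for the estimate itself; use two groups
        estimates, _ = km_by_group(df)
        merged = {g.group: dict(zip(g.times, g.survival)) for g in estimates}
        # single-group hand values on the pooled data
        pooled = km_oracle([1, 2, 3], [1, 1, 1])
        assert pooled[1] == pytest.approx(2 / 3)
        assert pooled[2] == pytest.approx(1 / 3)
        assert pooled[3] == pytest.approx(0.0)
        # per-group curves drop to 0 after their own last death
        assert merged[1][2.0] == pytest.approx(0.0)
        assert merged[2][3.0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_product_limit_with_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        times = rng.integers(1, 8, n).astype(float)
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        groups = np.ones(n, dtype=int)
        groups[0] = 2  # second group so the log-rank is defined
        df = _km_cohort(np.concatenate([times, [9.0, 9.0]]),
                        np.concatenate([events, [1, 0]]),
                        np.concatenate([groups, [2, 2]]))
        estimates, _ = km_by_group(df)
        est1 = next(e for e in estimates if e.group == 1)
        mask = groups == 1
        oracle = km_oracle(times[mask], events[mask])
        fitted = dict(zip(est1.times, est1.survival))
        for t, s in oracle.items():
            assert fitted[t] == pytest.approx(s, abs=1e-12)

    def test_survival_curves_monotone_from_one(self):
        rng = np.random.default_rng(1)
        df = _km_cohort(rng.integers(1, 300, 50), rng.integers(0, 2, 50),
                        rng.integers(1, 4, 50))
        estimates, _ = km_by_group(df)
        for est in estimates:
            assert est.survival[0] <= 1.0 and (np.diff(est.survival) <= 1e-12).all()
            assert ((est.survival >= 0) & (est.survival <= 1)).all()

    def test_no_events_survival_one_logrank_one(self):
        df = _km_cohort([100, 200, 300, 365], [0, 0, 0, 0], [1, 1, 2, 2])
        estimates, p = km_by_group(df)
        assert p == 1.0
        for est in estimates:
            assert (est.survival == 1.0).all()

    def test_identical_groups_logrank_near_one(self):
        times = [10, 50, 90, 200, 300, 10, 50, 90, 200, 300]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        groups = [1] * 5 + [2] * 5
        _, p = km_by_group(_km_cohort(times, events, groups))
        assert p > 0.95

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            km_by_group(_km_cohort([1, 2, 3], [1, 1, 1], [2, 2, 2]))

    def test_administrative_censoring_at_horizon(self):
        df = _km_cohort([100, 400], [1, 1], [1, 2])
        estimates, _ = km_by_group(df, horizon_days=365)
        est2 = next(e for e in estimates if e.group == 2)
        assert (est2.survival == 1.0).all()  # death at 400 is censored at 365


def hand_partial_likelihood(beta, times, events, x):
    """Negative log partial likelihood, no ties (independent oracle)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return -ll


class TestCox:
    def test_matches_hand_partial_likelihood_optimum(self):
        # small no-ties fixture; Efron == Breslow == exact here
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 1, 0])
        group = np.array([1, 2, 1, 2, 2, 1])
        df = pd.DataFrame({
            "time_days": times, "event": events, "group": group,
            "age": 80.0, "sex": "female",
        })
        res = cox_groups(df, horizon_days=400)
        x = (group == 2).astype(float)
        opt = optimize.minimize_scalar(
            hand_partial_likelihood, args=(times, events, x), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        term = next(t for t in res.terms if t.name == "group[2]")
        # lifelines' Newton solver stops at its own delta tolerance
        assert term.coef == pytest.approx(opt.x, abs=1e-3)

    def test_null_covariates_cover_one(self):
        """With no true effects, ~95% of Wald CIs should cover HR = 1."""
        rng = np.random.default_rng(7)
        covered = total = 0
        for _ in range(30):
            n = 300
            df = pd.DataFrame({
                "time_days": np.minimum(rng.exponential(500, n), 365.0),
                "group": rng.integers(1, 4, n),
                "age": rng.normal(83, 6, n),
                "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            })
            df["event"] = (df["time_days"] < 365).astype(int)
            res = cox_groups(df)
            for t in res.terms:
                if t.name.startswith("group"):
                    total += 1
                    covered += t.ci_low <= 1.0 <= t.ci_high
        assert covered / total >= 0.85

    def test_planted_hazard_ladder_recovered(self):
        """HRs rise monotonically across groups and cover the planted values."""
        rng = np.random.default_rng(21)
        n = 4000
        group = rng.integers(1, 7, n)
        log_hr_step = 0.35
        rate = 2e-3 * np.exp(log_hr_step * (group - 1))
        raw = rng.exponential(1 / rate)
        df = pd.DataFrame({
            "time_days": np.minimum(raw, 365.0),
            "event": (raw <= 365.0).astype(int),
            "group": group,
            "age": rng.normal(83, 6, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        })
        res = cox_groups(df)
        hrs = [t for t in res.terms if t.name.startswith("group")]
        fitted = [t.hr for t in hrs]
        assert fitted == sorted(fitted)
        for k, t in enumerate(hrs, start=2):
            truth = np.exp(log_hr_step * (k - 1))
            assert t.ci_low < truth < t.ci_high

    def test_terms_are_groups_plus_age_plus_gender(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame({
            "time_days": rng.integers(1, 365, n).astype(float),
            "event": rng.integers(0, 2, n),
            "group": rng.integers(1, 4, n),
            "age": rng.normal(83, 6, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        })
        res = cox_groups(df)
        names = [t.name for t in res.terms]
        assert names == ["group[2]", "group[3]", "age", "gender[2]"]
        for t in res.terms:
            assert t.hr > 0 and t.ci_low < t.hr < t.ci_high


def brute_force_auc(pos, neg):
    """Oracle: proportion of correctly ordered (pos, neg) pairs, ties half."""
    wins = ties = 0
    for x in pos:
        for y in neg:
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        t = np.r_[np.full(10, 100.0), np.full(10, 365.0)]
        e = np.r_[np.ones(10), np.zeros(10)]
        res = roc_at_horizon(scores, t, e, horizon_days=365)
        assert res.auc == 1.0

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        n = 200
        scores = rng.integers(0, 8, n) / 7  # heavy ties
        t = rng.integers(1, 500, n).astype(float)
        e = rng.integers(0, 2, n)
        res = roc_at_horizon(scores, t, e, horizon_days=365)
        pos = scores[(e == 1) & (t <= 365)]
        neg = scores[(t >= 365) & ~((e == 1) & (t <= 365))]
        assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        assert res.n_pos == len(pos) and res.n_neg == len(neg)

    def test_censored_before_horizon_excluded_and_counted(self):
        scores = np.array([0.1, 0.5, 0.9, 0.7])
        t = np.array([50.0, 400.0, 100.0, 300.0])
        e = np.array([0, 0, 1, 1])  # first patient censored pre-horizon
        res = roc_at_horizon(scores, t, e, horizon_days=365)
        assert res.n_excluded == 1
        assert res.n_pos == 2 and res.n_neg == 1

    def test_curve_runs_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        t = rng.integers(1, 500, 100).astype(float)
        e = rng.integers(0, 2, 100)
        res = roc_at_horizon(scores, t, e)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            roc_at_horizon([0.1, 0.2], [365, 365], [0, 0], horizon_days=365)

    def test_same_scores_two_horizons_differ_only_by_outcome(self):
        """No leakage: the score vector is identical at both horizons."""
        rng = np.random.default_rng(9)
        n = 300
        scores = rng.random(n)
        t = rng.integers(1, 500, n).astype(float)
        e = rng.integers(0, 2, n)
        for h in (183, 365):
            res = roc_at_horizon(scores, t, e, horizon_days=h)
            pos = scores[(e == 1) & (t <= h)]
            neg = scores[(t >= h) & ~((e == 1) & (t <= h))]
            assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


class TestPerParameterAUC:
    @staticmethod
    def _outcome(n, rng):
        t = rng.integers(1, 500, n).astype(float)
        e = rng.integers(0, 2, n)
        return t, e

    def test_analyte_identical_to_outcome_has_auc_one(self):
        rng = np.random.default_rng(2)
        n = 100
        t, e = self._outcome(n, rng)
        died = ((e == 1) & (t <= 365)).astype(float)
        mat = pd.DataFrame({"mirror": died})
        table = per_parameter_auc(mat, t, e, horizons=(365,))
        assert table.iloc[0]["auc"] == 1.0

    def test_constant_analyte_auc_half_flagged(self):
        rng = np.random.default_rng(2)
        n = 50
        t, e = self._outcome(n, rng)
        with pytest.warns(UserWarning):
            table = per_parameter_auc(pd.DataFrame({"flat": np.zeros(n)}), t, e,
                                      horizons=(365,))
        assert table.iloc[0]["auc"] == 0.5
        assert not table.iloc[0]["testable"]

    def test_binary_auc_equals_mean_of_sensitivity_specificity(self):
        rng = np.random.default_rng(6)
        n = 400
        t, e = self._outcome(n, rng)
        codes = rng.integers(0, 2, n).astype(float)
        table = per_parameter_auc(pd.DataFrame({"b": codes}), t, e, horizons=(365,))
        pos_mask = (e == 1) & (t <= 365)
        neg_mask = (t >= 365) & ~pos_mask
        sens = codes[pos_mask].mean()
        spec = 1 - codes[neg_mask].mean()
        assert table.iloc[0]["auc"] == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_one_row_per_analyte_per_horizon(self):
        rng = np.random.default_rng(8)
        n = 120
        t, e = self._outcome(n, rng)
        mat = pd.DataFrame(rng.integers(0, 2, (n, 3)).astype(float),
                           columns=["a", "b", "c"])
        table = per_parameter_auc(mat, t, e, horizons=(183, 365))
        assert len(table) == 6
        assert set(table["horizon_days"]) == {183, 365}
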