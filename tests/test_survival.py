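import numpy as np
import pandas as pd
import pytest

from line1mm.simulate import simulate_survival_cohort
from line1mm.survival import (
    PUBLISHED_LINE1_CUTOFF,
    cox_fit,
    km_estimate,
    logrank,
    roc_cutoff,
    survival_report,
)
from oracles import cox_loglik_binary, km_product


def exhaustive_roc(marker, outcome, direction="lower"):
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    distinct = np.unique(marker)
    best = None
    for thr in (distinct[:-1] + distinct[1:]) / 2:
        pred = marker < thr if direction == "lower" else marker > thr
        sens = (pred & (outcome == 1)).sum() / outcome.sum()
        spec = (~pred & (outcome == 0)).sum() / (outcome == 0).sum()
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        if best is None or d2 < best[0] - 1e-15:
            best = (d2, thr)
    return best


class TestRocCutoff:
    def test_perfect_separation_midpoint(self):
        marker = [30, 31, 32, 40, 41, 42]
        outcome = [1, 1, 1, 0, 0, 0]  # low marker -> event
        assert roc_cutoff(marker, outcome) == pytest.approx(36.0)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            marker = rng.normal(40, 6, n).round(1)
            outcome = rng.integers(0, 2, n)
            if len(np.unique(marker)) < 2 or outcome.min() == outcome.max():
                continue
            d2, thr = exhaustive_roc(marker, outcome)
            got = roc_cutoff(marker, outcome)
            pred = marker < got
            sens = (pred & (outcome == 1)).sum() / outcome.sum()
            spec = (~pred & (outcome == 0)).sum() / (outcome == 0).sum()
            assert (1 - sens) ** 2 + (1 - spec) ** 2 == pytest.approx(d2)

    def test_label_inversion_symmetry(self, rng):
        marker = rng.normal(40, 6, 30)
        outcome = rng.integers(0, 2, 30)
        if outcome.min() == outcome.max():
            outcome[0] = 1 - outcome[0]
        d2_orig, _ = exhaustive_roc(marker, outcome, "lower")
        d2_swap, _ = exhaustive_roc(marker, 1 - outcome, "higher")
        assert d2_orig == pytest.approx(d2_swap)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_cutoff([1, 2, 3], [1, 1, 1])

    def test_published_cutoff_constant(self):
        assert PUBLISHED_LINE1_CUTOFF == 36.0


class TestKaplanMeier:
    def test_all_events_stepwise(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        # leading S(0) = 1 row, then the product-limit steps
        assert km["survival"].tolist() == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])

    def test_no_events_flat(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_matches_riskset_oracle(self, rng):
        times = rng.exponential(100, 40).round(1)
        events = rng.integers(0, 2, 40)
        km = km_estimate(times, events)
        expected = dict(km_product(times, events))
        for _, row in km.iterrows():
            if row["time"] in expected:
                assert row["survival"] == pytest.approx(expected[row["time"]])

    def test_nonincreasing_and_greenwood_nonnegative(self, rng):
        times = rng.exponential(100, 60)
        events = rng.integers(0, 2, 60)
        km = km_estimate(times, events)
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert (km["greenwood_var"] >= 0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([10, 20, 30, 40], [1, 1, 0, 1])
        chi2, p = logrank([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_example(self):
        """Two groups, distinct event times; observed-expected computed by hand.

        Group A times 1, 3 (both events); group B times 2, 4 (both events).
        Risk sets: t=1 (2A,2B) E_A=1/2; t=2 (1A,2B) E_A=1/3; t=3 (1A,1B)
        E_A=1/2; t=4 (0A,1B) E_A=0 -> O-E = 2 - 4/3 = 2/3; V = 1/4+2/9+1/4.
        """
        chi2, p = logrank([([1, 3], [1, 1]), ([2, 4], [1, 1])])
        v = 0.25 + 2 / 9 + 0.25
        assert chi2 == pytest.approx((2 / 3) ** 2 / v, rel=1e-9)

    def test_time_rescaling_invariance(self, rng):
        t1 = rng.exponential(100, 30)
        t2 = rng.exponential(60, 30)
        e1, e2 = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        chi_days, _ = logrank([(t1, e1), (t2, e2)])
        chi_months, _ = logrank([(t1 / 30.4, e1), (t2 / 30.4, e2)])
        assert chi_days == pytest.approx(chi_months, rel=1e-9)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank([([1, 2], [0, 0]), ([3, 4], [0, 0])])


class TestCox:
    def test_matches_partial_likelihood_grid(self, rng):
        """n <= 8, no censoring, one binary covariate: the fitted coefficient
        maximizes the brute-force partial likelihood."""
        for _ in range(10):
            n = 8
            group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
            times = rng.exponential(np.where(group == 1, 50, 100))
            grid = np.linspace(-4, 4, 4001)
            lls = [cox_loglik_binary(b, times, np.ones(n), group) for b in grid]
            beta_star = grid[int(np.argmax(lls))]
            if abs(beta_star) >= 3.9:
                continue  # separated draw: no finite partial-likelihood maximum
            df = pd.DataFrame({"os_days": times, "event": 1, "g": group})
            fit = cox_fit(df, ["g"])
            assert fit.summary.loc["g", "coef"] == pytest.approx(beta_star, abs=5e-3)

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"os_days": [1.0, 2, 3, 4], "event": [1, 1, 0, 1], "g": 1})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["g"])

    def test_label_swap_inverts_hr(self, rng):
        df = simulate_survival_cohort(rng, n=60, hazard_ratio=2.0)
        fit = cox_fit(df, ["hypomethylated"])
        df2 = df.assign(hypomethylated=1 - df["hypomethylated"])
        fit2 = cox_fit(df2, ["hypomethylated"])
        assert fit.hr("hypomethylated") == pytest.approx(1 / fit2.hr("hypomethylated"), rel=1e-6)

    def test_ci_contains_point_estimate(self, rng):
        df = simulate_survival_cohort(rng, n=80, hazard_ratio=2.8)
        fit = cox_fit(df, ["hypomethylated"])
        s = fit.summary.loc["hypomethylated"]
        assert s["ci_low"] <= s["hr"] <= s["ci_high"]
        assert fit.n >= fit.events

    def test_stratified_fit_runs(self, rng):
        df = simulate_survival_cohort(rng, n=80, hazard_ratio=2.8)
        df["center"] = np.tile(["A", "B"], 40)
        fit = cox_fit(df, ["hypomethylated"], strata="center")
        assert fit.strata == "center"
        assert np.isfinite(fit.hr("hypomethylated"))


class TestSurvivalReport:
    def make_tables(self, rng, n=60, hr=2.8):
        df = simulate_survival_cohort(rng, n=n, hazard_ratio=hr)
        samples = [f"S{i}" for i in range(n)]
        meth = np.where(df["hypomethylated"] == 1, rng.normal(32, 3, n), rng.normal(44, 3, n))
        clinical = pd.DataFrame(
            {
                "os_days": df["os_days"].to_numpy(),
                "event": df["event"].to_numpy(),
                "iss_stage": rng.integers(1, 4, n),
                "center": np.tile(["A", "B"], n // 2),
                "age": rng.integers(45, 85, n),
                "sex_male": rng.integers(0, 2, n),
                "chr13_loss": rng.integers(0, 2, n),
            },
            index=pd.Index(samples, name="sample"),
        )
        profiles = pd.DataFrame({"line1": meth}, index=clinical.index)
        return clinical, profiles

    def test_planted_hazard_recovered(self, rng):
        clinical, profiles = self.make_tables(rng, n=120, hr=3.0)
        rep = survival_report(clinical, profiles, strata="center")
        assert rep["survival"]["collection"]["logrank_p"] < 0.05
        assert rep["unadjusted"].hr("hypomethylated") > 1.5

    def test_null_hr_near_one(self, rng):
        clinical, profiles = self.make_tables(rng, n=150, hr=1.0)
        rep = survival_report(clinical, profiles, strata=None)
        assert 0.5 < rep["unadjusted"].hr("hypomethylated") < 2.0

    def test_degenerate_cutoff_flagged(self, rng):
        clinical, profiles = self.make_tables(rng, n=40)
        rep = survival_report(clinical, profiles, cutoff=0.0)
        assert "untestable" in rep

    def test_iss_trend_reported(self, rng):
        clinical, profiles = self.make_tables(rng, n=80)
        rep = survival_report(clinical, profiles)
        assert set(rep["iss_trend"]["stage_means"]) <= {1, 2, 3}
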