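import numpy as np
import pandas as pd
import pytest

from line1mm.cna import ArmAberration
from line1mm.stats import (
    corr_burden,
    element_correlations,
    games_howell,
    linear_trend,
    volcano,
    welch_t,
)


class TestWelch:
    def test_hand_computed(self):
        delta, t, p = welch_t([1, 2, 3], [4, 5, 6])
        assert delta == pytest.approx(-3.0)
        assert t == pytest.approx(-3.0 / np.sqrt(2 / 3), rel=1e-12)

    def test_identical_groups(self):
        delta, t, p = welch_t([5, 6, 7], [5, 6, 7])
        assert (delta, t) == (0.0, 0.0)
        assert p == pytest.approx(1.0)

    def test_reduces_to_classical_t_when_balanced(self, rng):
        """With equal n, Welch's statistic equals the pooled t statistic."""
        from scipy import stats as sps

        a, b = rng.normal(0, 2, 20), rng.normal(1, 2, 20)
        _, t, _ = welch_t(a, b)
        t_pooled = sps.ttest_ind(a, b, equal_var=True).statistic
        assert t == pytest.approx(t_pooled, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])


class TestGamesHowell:
    def test_identical_groups_nonsignificant(self):
        g = [10.0, 11.0, 9.0, 10.5]
        out = games_howell({"a": g, "b": g, "c": g})
        assert (out["p"] > 0.95).all()

    def test_shifted_group_detected(self, rng):
        base = {"a": rng.normal(50, 2, 25), "b": rng.normal(50, 2, 25), "c": rng.normal(44, 2, 25)}
        out = games_howell(base)
        sig = out[out["p"] < 0.05]
        assert set(map(tuple, sig[["group_a", "group_b"]].values)) == {("a", "c"), ("b", "c")}

    def test_two_groups_redirects(self):
        with pytest.raises(ValueError, match="welch_t"):
            games_howell({"a": [1, 2], "b": [3, 4]})

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 2, 15), rng.normal(-0.5, 1, 9)])
        grp = np.repeat(["a", "b", "c"], [12, 15, 9])
        ref = pingouin.pairwise_gameshowell(
            data=pd.DataFrame({"y": vals, "g": grp}), dv="y", between="g"
        ).sort_values(["A", "B"]).reset_index(drop=True)
        got = games_howell({k: vals[grp == k] for k in ("a", "b", "c")}).sort_values(
            ["group_a", "group_b"]
        ).reset_index(drop=True)
        assert np.allclose(got["p"], ref["pval"], atol=1e-6)
        assert np.allclose(got["delta"], -(ref["diff"]), atol=1e-9) or np.allclose(
            got["delta"], ref["diff"], atol=1e-9
        )


def make_aberrations(arm_samples, state="loss"):
    out = []
    for arm, samples in arm_samples.items():
        chrom, a = "chr" + arm[:-1], arm[-1]
        out += [ArmAberration(s, chrom, a, state, 60) for s in samples]
    return out


class TestVolcano:
    def test_planted_hypomethylation_flagged(self, rng):
        samples = [f"S{i}" for i in range(30)]
        meth = pd.Series(rng.normal(45, 2, 30), index=samples)
        hit = samples[:12]
        meth[hit] -= 5.0
        profiles = pd.DataFrame({"line1": meth})
        abs_ = make_aberrations({"13q": hit, "5p": samples[15:18]})
        out = volcano(profiles, abs_, element="line1", state="loss")
        row = out.set_index("arm").loc["13q"]
        assert row["flagged"] and row["delta"] < -3
        assert not out.set_index("arm").loc["5p", "flagged"]

    def test_all_aberrant_arm_untestable(self, rng):
        samples = [f"S{i}" for i in range(10)]
        profiles = pd.DataFrame({"line1": rng.normal(45, 2, 10)}, index=samples)
        out = volcano(profiles, make_aberrations({"1p": samples}), state="loss")
        assert not out.loc[0, "testable"]
        assert not out.loc[0, "flagged"]

    def test_loss_flag_requires_negative_delta(self, rng):
        samples = [f"S{i}" for i in range(30)]
        meth = pd.Series(rng.normal(45, 2, 30), index=samples)
        hit = samples[:12]
        meth[hit] += 5.0  # hypermethylated with loss: significant but wrong direction
        profiles = pd.DataFrame({"line1": meth})
        out = volcano(profiles, make_aberrations({"13q": hit}), state="loss")
        assert out.loc[0, "p"] < 0.05 and not out.loc[0, "flagged"]


class TestCorrBurden:
    def test_zero_variance_errors(self):
        profiles = pd.DataFrame({"line1": [40.0, 40.0, 40.0]}, index=["a", "b", "c"])
        burden = pd.Series([1, 10, 100], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            corr_burden(profiles, burden)

    def test_exact_linear_relation(self):
        counts = pd.Series([0, 9, 99, 999, 4999], index=list("abcde"))
        meth = 50 - 5 * np.log10(counts + 1)
        profiles = pd.DataFrame({"line1": meth.to_numpy()}, index=counts.index)
        r, ci, p = corr_burden(profiles, counts)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_scale_invariance(self, rng):
        """Multiplying large burdens by a constant barely moves r (log shift)."""
        counts = pd.Series(rng.integers(500, 50_000, size=40).astype(float))
        profiles = pd.DataFrame(
            {"line1": 50 - 4 * np.log10(counts + 1) + rng.normal(0, 1, 40)}
        )
        r1, _, _ = corr_burden(profiles, counts)
        r2, _, _ = corr_burden(profiles, counts * 7.0)
        assert r1 == pytest.approx(r2, abs=1e-3)

    def test_ci_contains_estimate(self, rng):
        counts = pd.Series(rng.integers(0, 300, size=30).astype(float))
        profiles = pd.DataFrame({"line1": rng.normal(45, 5, 30)})
        r, (lo, hi), _ = corr_burden(profiles, counts)
        assert lo <= r <= hi


class TestLinearTrend:
    def test_equal_means_null(self, rng):
        vals = np.concatenate([rng.normal(10, 1, 30)] * 3)
        groups = np.repeat([1, 2, 3], 30)
        _, p = linear_trend(vals, groups)
        assert p > 0.05

    def test_monotone_means_significant(self, rng):
        vals = np.concatenate([rng.normal(m, 1, 40) for m in (10, 11, 12)])
        _, p = linear_trend(vals, np.repeat([1, 2, 3], 40))
        assert p < 0.001

    def test_two_groups_equal_pooled_t(self, rng):
        from scipy import stats as sps

        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 17)
        t, p = linear_trend(np.concatenate([a, b]), np.repeat([1, 2], [12, 17]))
        ref = sps.ttest_ind(b, a, equal_var=True)
        assert abs(t) == pytest.approx(abs(ref.statistic), abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            linear_trend([1.0, 2.0], [1, 1])


class TestElementCorrelations:
    def test_affine_transform_strong_positive(self, rng):
        line1 = rng.normal(45, 6, 50)
        profiles = pd.DataFrame(
            {"line1": line1, "alu_ya5": 0.6 * line1 + 8 + rng.normal(0, 1, 50)}
        )
        out = element_correlations(profiles, ["line1", "alu_ya5"])
        assert out.loc[0, "r"] > 0.9

    def test_independent_elements_near_zero(self, rng):
        profiles = pd.DataFrame(
            {"line1": rng.normal(45, 6, 400), "sat_alpha": rng.normal(30, 6, 400)}
        )
        out = element_correlations(profiles, ["line1", "sat_alpha"])
        assert abs(out.loc[0, "r"]) < 0.15

    def test_minimal_n(self, rng):
        profiles = pd.DataFrame({"line1": [1.0, 2, 4], "alu_ya5": [2.0, 3, 3.5]})
        out = element_correlations(profiles, ["line1", "alu_ya5"])
        assert len(out) == 1 and np.isfinite(out.loc[0, "r"])

    def test_simulated_cohort_positive_block(self, small_cohort):
        out = element_correlations(small_cohort.profiles)
        assert (out["r"] > 0).all()
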