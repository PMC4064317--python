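import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from line1mm.cna import SegmentCall
from line1mm.genome import GenomicInterval
from line1mm.mbd import (
    add_window_density,
    build_windows,
    cn_normalize,
    density_stratified_mean,
    log_standardize,
    quantify,
    region_mean,
)
from line1mm.repeats import DensityBinning
from oracles import midpoint_bin_naive
from test_cna import probeset_from_ratios


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestBuildWindows:
    def test_k_probes_give_k_minus_one_windows(self):
        win = build_windows(probeset_from_ratios([0.0] * 7))
        assert len(win) == 6
        assert (win["length"] > 0).all()

    def test_no_cross_chromosome_windows(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "probe": [f"p{i}" for i in range(9)],
                "chrom": ["chr1"] * 5 + ["chr2"] * 4,
                "start": [i * 1000 for i in range(5)] + [i * 1000 for i in range(4)],
                "end": [i * 1000 + 60 for i in range(5)] + [i * 1000 + 60 for i in range(4)],
                "S1": 0.0,
            }
        )
        from line1mm.cna import ProbeSet

        win = build_windows(ProbeSet(df))
        assert len(win) == (5 - 1) + (4 - 1)

    def test_windows_tile_interprobe_gaps(self, small_cohort):
        ps = small_cohort.probes
        win = build_windows(ps)
        for chrom in ps.chroms:
            block = ps.chrom_block(chrom)
            gaps = list(zip(block["end"].to_numpy()[:-1], block["start"].to_numpy()[1:]))
            got = win[win["chrom"] == chrom]
            assert list(zip(got["start"], got["end"])) == [(a, b) for a, b in gaps if b > a]


class TestQuantify:
    @pytest.fixture()
    def win(self):
        return build_windows(probeset_from_ratios([0.0] * 5))  # 4 windows of 940 bp

    def test_rate_is_count_over_length(self, win):
        reads = reads_df([("chr1", 100, 150)] * 10)
        out = quantify(win, reads, reads_df([("chr1", 100, 150)]))
        assert out.loc[0, "sample_count"] == 10
        assert out.loc[0, "sample_rate"] == pytest.approx(10 / 940)

    def test_equal_rates_level_one(self, win):
        reads = reads_df([("chr1", 100, 150), ("chr1", 1100, 1150)])
        out = quantify(win, reads, reads)
        assert out.loc[0, "level"] == pytest.approx(1.0)

    def test_no_reads_errors(self, win):
        with pytest.raises(ValueError):
            quantify(win, reads_df([]), reads_df([]))

    def test_low_input_flagged(self, win):
        out = quantify(win, reads_df([("chr1", 100, 150)]), reads_df([("chr1", 1100, 1150)]))
        assert bool(out.loc[0, "excluded"])  # no input reads in window 0
        assert not out.loc[1, "excluded"]

    def test_midpoint_binning_matches_naive(self, rng, small_cohort):
        win = build_windows(small_cohort.probes).head(40).reset_index(drop=True)
        lo, hi = win["start"].min(), win["end"].max()
        reads = reads_df(
            [("chr1", int(s), int(s) + 50) for s in rng.integers(lo - 100, hi + 100, size=300)]
        )
        out = quantify(win, reads, reads)
        assert out["sample_count"].to_numpy().tolist() == midpoint_bin_naive(win, reads).tolist()
        # every read lands in at most one window
        assert out["sample_count"].sum() <= len(reads)


class TestNormalization:
    def test_loss_halving_invariance(self):
        """Halving both copy number and sample reads in a region leaves the
        standardized level unchanged."""
        win = build_windows(probeset_from_ratios([0.0] * 7))
        counts = [8, 12, 6, 10, 14, 16]
        base = [("chr1", 100 + 1000 * k, 150 + 1000 * k) for k, c in enumerate(counts)
                for _ in range(c)]
        inp = [("chr1", 120 + 1000 * k, 170 + 1000 * k) for k in range(6) for _ in range(8)]
        q_neutral = quantify(win, reads_df(base), reads_df(inp), pseudo_reads=0.0)
        z_neutral = log_standardize(cn_normalize(q_neutral, []))["z"]

        # drop every second read in windows 0 and 1: counts exactly halved there
        seen = {}
        halved = []
        for r in base:
            if r[1] < 2000:
                seen[r[1]] = seen.get(r[1], 0) + 1
                if seen[r[1]] % 2 == 0:
                    continue
            halved.append(r)
        loss = SegmentCall("S1", GenomicInterval("chr1", 0, 2060), "loss", 2, -1.0)
        q_loss = quantify(win, reads_df(halved), reads_df(inp), pseudo_reads=0.0)
        z_loss = log_standardize(cn_normalize(q_loss, [loss]))["z"]
        assert np.allclose(z_neutral, z_loss, atol=1e-6)

    def test_neutral_window_unchanged(self):
        win = build_windows(probeset_from_ratios([0.0] * 3))
        reads = reads_df([("chr1", 100, 150)] * 4 + [("chr1", 1100, 1150)] * 4)
        q = quantify(win, reads, reads)
        out = cn_normalize(q, [])
        assert np.allclose(out["level"], q["level"])
        assert (out["copy_number"] == 2.0).all()

    def test_gain_scaling(self):
        win = build_windows(probeset_from_ratios([0.0] * 3))
        reads = reads_df([("chr1", 100, 150)] * 6 + [("chr1", 1100, 1150)] * 6)
        q = quantify(win, reads, reads)
        gain = SegmentCall("S1", GenomicInterval("chr1", 0, 1060), "gain", 2, 0.8)
        out = cn_normalize(q, [gain])
        assert out.loc[0, "level"] == pytest.approx(q.loc[0, "level"] / 1.5)

    def test_level_homogeneity(self):
        """Away from the pseudo-rate floor, level is degree +1 in the sample
        rate and degree -1 in the input rate."""
        win = build_windows(probeset_from_ratios([0.0] * 3))
        r1 = reads_df([("chr1", 100 + i, 150 + i) for i in range(20)]
                      + [("chr1", 1100 + i, 1150 + i) for i in range(20)])
        r2 = reads_df([("chr1", 100 + i, 150 + i) for i in range(40)]
                      + [("chr1", 1100 + i, 1150 + i) for i in range(40)])
        lvl_12 = quantify(win, r1, r2, pseudo_reads=0.0)["level"]
        lvl_11 = quantify(win, r1, r1, pseudo_reads=0.0)["level"]
        assert np.allclose(lvl_12, lvl_11 / 2.0)


class TestStandardize:
    def test_z_identity(self, rng, small_cohort):
        win = build_windows(small_cohort.probes)
        n = len(win)
        win = win.assign(
            level=rng.lognormal(0.0, 0.5, size=n), excluded=np.zeros(n, dtype=bool)
        )
        out = log_standardize(win)
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        # log-normal levels give approximately standard normal z
        assert sps.kstest(out["z"], "norm").pvalue > 0.01

    def test_constant_levels_error(self):
        win = build_windows(probeset_from_ratios([0.0] * 4)).assign(
            level=1.0, excluded=False
        )
        with pytest.raises(ValueError, match="zero variance"):
            log_standardize(win)


class TestRegionMeans:
    @pytest.fixture()
    def zwin(self, rng, small_cohort):
        win = build_windows(small_cohort.probes)
        win = win.assign(level=rng.lognormal(0, 0.5, len(win)), excluded=False)
        return log_standardize(win)

    def test_all_windows_mean_zero(self, zwin, small_cohort):
        regions = [GenomicInterval(c, 0, small_cohort.config.genome.lengths[c])
                   for c in small_cohort.config.genome.chroms]
        assert region_mean(zwin, regions) == pytest.approx(0.0, abs=1e-12)

    def test_single_window_region(self, zwin):
        w = zwin.iloc[3]
        got = region_mean(zwin, [GenomicInterval(w["chrom"], int(w["start"]), int(w["end"]))])
        assert got == pytest.approx(w["z"])

    def test_no_overlap_is_nan(self, zwin):
        assert np.isnan(region_mean(zwin, [GenomicInterval("chrM", 0, 100)]))


class TestDensityStratified:
    def make_zwin(self, rng, cohort, slope):
        win = build_windows(cohort.probes)
        win = add_window_density(win, cohort.repeats)
        binning = DensityBinning(tuple(cohort.truth["binning_edges"]))
        from line1mm.repeats import categorize

        cat = win["density"].map(lambda v: categorize(v, binning)).to_numpy()
        win = win.assign(
            level=np.exp(slope * (cat - 3) + rng.normal(0, 0.3, len(win))), excluded=False
        )
        return log_standardize(win), binning

    def test_null_correlation_near_zero(self, rng, small_cohort):
        zwin, binning = self.make_zwin(rng, small_cohort, slope=0.0)
        _, r = density_stratified_mean(zwin, binning)
        assert abs(r) < 0.1

    @pytest.mark.parametrize("slope,sign", [(-0.4, -1), (0.4, 1)])
    def test_planted_monotone_trend_recovered(self, rng, small_cohort, slope, sign):
        zwin, binning = self.make_zwin(rng, small_cohort, slope)
        per_cat, r = density_stratified_mean(zwin, binning)
        assert np.sign(r) == sign
        assert abs(r) > 0.3
        means = per_cat["mean"].dropna().to_numpy()
        assert np.sign(means[-1] - means[0]) == sign
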