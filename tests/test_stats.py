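"""Regional statistics: per-chromosome means, rank tests, ANOVA, size bias."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from earscan import (GenomeLayout, Region, RegionSet, SignalTrack, define_ears,
                     define_interstitial, ear_excluded_chrom_means, ear_vs_interstitial_test,
                     group_anova_tukey, hotspot_regional_signal, per_chrom_region_means,
                     size_bias_fit)
from earscan.simulate import SyntheticConfig, make_track


def exact_ranksum_p(x, y):
    """Brute-force two-sided exact Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestPerChromRegionMeans:
    def test_constant_track(self, yeast_layout):
        track = SignalTrack.constant(yeast_layout, 1.0)
        means = per_chrom_region_means(track, define_ears(yeast_layout), "EAR")
        assert len(means) == 16
        assert np.allclose(means, 1.0)

    def test_two_domain_average(self, toy_layout):
        bounds = np.array([0.0, 110000.0, 190000.0, 300000.0])
        track = SignalTrack.from_arrays(
            toy_layout, {"toy": (bounds, np.array([2.0, 5.0, 1.0]))})
        means = per_chrom_region_means(track, define_ears(toy_layout), "EAR")
        assert means["toy"] == pytest.approx(1.5)  # (2.0 + 1.0) / 2, equal widths

    def test_short_chromosome_absent(self):
        lay = GenomeLayout(("long", "short"), (300000, 200000), (150000, 100000))
        track = SignalTrack.constant(lay)
        means = per_chrom_region_means(track, define_interstitial(lay), "interstitial")
        assert list(means.index) == ["long"]

    def test_permutation_invariance(self, yeast_layout):
        cfg = SyntheticConfig(layout=yeast_layout, seed=5)
        track = make_track(cfg)
        means = per_chrom_region_means(track, define_ears(yeast_layout), "EAR")
        perm_names = tuple(reversed(yeast_layout.chrom_names))
        perm_layout = GenomeLayout(
            perm_names,
            tuple(yeast_layout.length_of(c) for c in perm_names),
            tuple(yeast_layout.centromere_of(c) for c in perm_names),
            yeast_layout.rdna_interval)
        perm_track = SignalTrack(perm_layout, track.chroms)
        perm_means = per_chrom_region_means(perm_track, define_ears(perm_layout), "EAR")
        pd.testing.assert_series_equal(means.sort_index(), perm_means.sort_index())


class TestEarVsInterstitialTest:
    def test_identical_samples_p_one(self):
        x = pd.Series(np.arange(1.0, 17.0))
        res = ear_vs_interstitial_test(x, x.copy())
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_16v16(self):
        x = pd.Series(np.arange(100.0, 116.0))
        y = pd.Series(np.arange(1.0, 17.0))
        res = ear_vs_interstitial_test(x, y)
        assert res.p_value == pytest.approx(2 / math.comb(32, 16), rel=1e-9)
        assert res.higher_median == "EAR"

    def test_3v3_exact(self):
        res = ear_vs_interstitial_test(pd.Series([1.0, 2.0, 3.0]),
                                       pd.Series([4.0, 5.0, 6.0]))
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (5, 3)])
    def test_matches_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = pd.Series(rng.normal(size=n1))
            y = pd.Series(rng.normal(size=n2))
            res = ear_vs_interstitial_test(x, y)
            assert res.p_value == pytest.approx(exact_ranksum_p(x.values, y.values),
                                                rel=1e-9)

    def test_too_few_chromosomes(self):
        with pytest.raises(ValueError):
            ear_vs_interstitial_test(pd.Series([1.0, 2.0]), pd.Series([3.0, 4.0]))

    def test_paired_option(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(1.3, 0.1, 16), index=[f"c{i}" for i in range(16)])
        y = pd.Series(rng.normal(1.0, 0.1, 16), index=[f"c{i}" for i in range(16)])
        res = ear_vs_interstitial_test(x, y, paired=True)
        assert res.test_name == "wilcoxon-signed-rank"
        assert res.p_value < 0.01


class TestGroupAnovaTukey:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        anova, pairs = group_anova_tukey({"a": g, "b": g.copy(), "c": g.copy()})
        assert anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p.p_value > 0.999 for p in pairs)

    def test_forced_separation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1e-3, 4)
        b = 1.0 + rng.normal(0, 1e-3, 4)
        anova, pairs = group_anova_tukey({"a": a, "b": b})
        assert anova.p_value < 1e-3
        assert pairs[0].p_value < 1e-3

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(0.5, 1.0, size=6)
        anova, _ = group_anova_tukey({"a": a, "b": b})
        t = sps.ttest_ind(a, b, equal_var=True)
        assert anova.statistic == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert anova.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_anova_tukey({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestSizeBiasFit:
    def test_exact_power_law(self, yeast_layout):
        lengths = pd.Series(yeast_layout.lengths(), dtype=float)
        means = 2.0 * lengths ** -0.3
        fit = size_bias_fit(None, yeast_layout, chrom_means={"s": means})
        assert fit.slope["s"] == pytest.approx(-0.3, abs=1e-9)
        assert fit.r_squared["s"] == pytest.approx(1.0, abs=1e-9)

    def test_identical_sample_twice(self, yeast_layout):
        cfg = SyntheticConfig(layout=yeast_layout, size_bias_slope=-0.2, seed=4)
        track = make_track(cfg)
        fit = size_bias_fit({"a": track, "b": track}, yeast_layout)
        assert fit.interaction_p == pytest.approx(1.0, abs=1e-6)
        assert fit.slope["a"] == pytest.approx(fit.slope["b"], abs=1e-12)

    def test_noise_free_slope_difference_significant(self, yeast_layout):
        lengths = pd.Series(yeast_layout.lengths(), dtype=float)
        flat = pd.Series(1.0, index=lengths.index)
        biased = lengths ** -0.4 / (lengths ** -0.4).mean()
        fit = size_bias_fit(None, yeast_layout,
                            chrom_means={"flat": flat, "biased": biased})
        assert fit.interaction_p < 1e-6

    def test_zero_mean_rejected(self, yeast_layout):
        means = pd.Series(0.0, index=list(yeast_layout.chrom_names))
        with pytest.raises(ValueError):
            size_bias_fit(None, yeast_layout, chrom_means={"s": means})


class TestEarExcludedChromMeans:
    def test_constant_track(self, yeast_layout):
        track = SignalTrack.constant(yeast_layout, 2.0)
        df = ear_excluded_chrom_means(track)
        assert len(df) <= 16
        assert np.allclose(df["mean"], 2.0)
        assert np.allclose(df["sd"], 0.0, atol=1e-12)

    def test_half_step_dispersion(self, toy_layout):
        # 2.0 on the first half of [110000, 190000), 0 on the second half
        bounds = np.array([0.0, 110000.0, 150000.0, 190000.0, 300000.0])
        track = SignalTrack.from_arrays(
            toy_layout, {"toy": (bounds, np.array([1.0, 2.0, 0.0, 1.0]))})
        df = ear_excluded_chrom_means(track, margin=110000, n_bins=10)
        assert df.loc["toy", "mean"] == pytest.approx(1.0)
        expected_sd = np.std([2.0] * 5 + [0.0] * 5, ddof=1)  # 1.0541
        assert df.loc["toy", "sd"] == pytest.approx(expected_sd, rel=1e-9)

    def test_short_chromosome_absent(self):
        lay = GenomeLayout(("long", "short"), (400000, 150000), (100000, 75000))
        df = ear_excluded_chrom_means(SignalTrack.constant(lay))
        assert list(df.index) == ["long"]


class TestHotspotRegionalSignal:
    def _classes(self, layout):
        return {"EAR": define_ears(layout), "interstitial": define_interstitial(layout)}

    def test_equal_signals_all_classes_one(self, toy_layout):
        hs = pd.DataFrame({"chrom": ["toy"] * 4,
                           "start": [25000, 150000, 200000, 140000],
                           "end": [25500, 150500, 200500, 140500],
                           "signal": [3.0] * 4})
        out = hotspot_regional_signal(hs, self._classes(toy_layout))
        assert out.pooled["EAR"] == pytest.approx(1.0)
        assert out.pooled["interstitial"] == pytest.approx(1.0)

    def test_worked_arithmetic(self, toy_layout):
        # 4 hotspots, signals {8, 4, 2, 2}; the 8 and 4 sit in EARs
        hs = pd.DataFrame({"chrom": ["toy"] * 4,
                           "start": [25000, 200000, 150000, 160000],
                           "end": [25500, 200500, 150500, 160500],
                           "signal": [8.0, 4.0, 2.0, 2.0]})
        out = hotspot_regional_signal(hs, self._classes(toy_layout))
        assert out.pooled["EAR"] == pytest.approx(1.5)  # (2.0 + 1.0) / 2
        assert out.pooled["interstitial"] == pytest.approx(0.5)

    def test_rdna_exclusion_applied_first(self, yeast_layout):
        rdna = RegionSet([Region("chrXII", 451000, 471000, "rDNA")])
        hs = pd.DataFrame({"chrom": ["chrXII", "chrI"],
                           "start": [460000, 50000],
                           "end": [460500, 50500],
                           "signal": [100.0, 2.0]})
        out = hotspot_regional_signal(hs, self._classes(yeast_layout), exclusions=rdna)
        assert out.n_excluded == 1
        assert out.pooled["EAR"] == pytest.approx(1.0)  # only chrI hotspot remains

    def test_empty_after_filtering_rejected(self, yeast_layout):
        rdna = RegionSet([Region("chrXII", 451000, 471000, "rDNA")])
        hs = pd.DataFrame({"chrom": ["chrXII"], "start": [460000],
                           "end": [460500], "signal": [1.0]})
        with pytest.raises(ValueError):
            hotspot_regional_signal(hs, self._classes(yeast_layout), exclusions=rdna)

    def test_midpoint_membership(self, toy_layout):
        # hotspot straddling the EAR boundary: midpoint decides
        hs = pd.DataFrame({"chrom": ["toy", "toy"],
                           "start": [19800, 150000], "end": [20300, 150500],
                           "signal": [1.0, 1.0]})
        out = hotspot_regional_signal(hs, self._classes(toy_layout))
        assert out.n_hotspots["EAR"] == 1  # midpoint 20050 >= 20000
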