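"""NDR calling, CO-feature distances, Mann-Whitney U, density/region stats."""

import itertools
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magrec.chromstats import (
    StatsConfig,
    call_ndrs,
    centromere_windows,
    classify_ndrs,
    co_density_stats,
    co_feature_distances,
    density_length_correlation,
    expected_region_pct,
    fold_change,
    mann_whitney_u,
    nahr_fraction,
    nahr_fraction_from_counts,
    region_co_fraction,
)
from magrec.events import RecombEvent

CFG = StatsConfig()


def coverage(vals, chrom="chrI", bin_size=1):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(len(vals)) * bin_size,
            "end": (np.arange(len(vals)) + 1) * bin_size,
            "value": vals,
        }
    )


def co(chrom, start, end):
    return RecombEvent("CO", chrom, start, end)


class TestNdrs:
    def test_zero_coverage_run_called(self):
        cfg = StatsConfig(ndr_min_len=3)
        ndrs = call_ndrs(coverage([3, 1, 0, 0, 0, 2]), cfg)
        assert len(ndrs) == 1
        assert (ndrs.iloc[0]["start"], ndrs.iloc[0]["end"]) == (2, 5)

    def test_min_length_filter(self):
        cfg = StatsConfig(ndr_min_len=4)
        assert len(call_ndrs(coverage([3, 1, 0, 0, 0, 2]), cfg)) == 0

    def test_positive_coverage_everywhere_gives_none(self):
        assert len(call_ndrs(coverage([1, 2, 3, 4]), StatsConfig(ndr_min_len=1))) == 0

    def test_track_gap_counts_as_zero(self):
        cov = pd.DataFrame(
            [("chrI", 0, 100, 5.0), ("chrI", 200, 300, 5.0)],
            columns=["chrom", "start", "end", "value"],
        )
        ndrs = call_ndrs(cov, StatsConfig(ndr_min_len=50), chrom_lengths={"chrI": 300})
        assert [(r.start, r.end) for r in ndrs.itertuples(index=False)] == [(100, 200)]

    def test_hot_cold_unclassified_rule_table(self):
        ndrs = pd.DataFrame(
            [("chrI", 100, 200, "?"), ("chrI", 400, 500, "?"), ("chrI", 800, 900, "?")],
            columns=["chrom", "start", "end", "cls"],
        )
        peaks = pd.DataFrame([("chrI", 90, 210, "p1")], columns=["chrom", "start", "end", "name"])
        oligo = coverage([0] * 1000)
        oligo = pd.concat(
            [oligo, pd.DataFrame([("chrI", 810, 820, 2.0)], columns=oligo.columns)]
        )
        oligo = oligo[oligo["value"] > 0]
        out = classify_ndrs(ndrs, peaks, oligo)
        assert out["cls"].tolist() == ["hot", "cold", "unclassified"]


class TestDistances:
    def test_center_at_midpoint_gives_zero(self):
        centers = pd.DataFrame([("chrI", 990, 1010)], columns=["chrom", "start", "end"])
        d = co_feature_distances([co("chrI", 900, 1100)], centers, CFG)
        assert d.tolist() == [0.0]

    def test_wide_marker_interval_excluded(self):
        centers = pd.DataFrame([("chrI", 0, 10)], columns=["chrom", "start", "end"])
        d = co_feature_distances([co("chrI", 1000, 2500)], centers, CFG)
        assert len(d) == 0

    def test_nearest_center_arithmetic(self):
        centers = pd.DataFrame(
            [("chrI", 8995, 9005), ("chrI", 11995, 12005)],
            columns=["chrom", "start", "end"],
        )
        d = co_feature_distances([co("chrI", 9900, 10100)], centers, CFG)
        assert d.tolist() == [1000.0]

    def test_empty_feature_set_is_error(self):
        with pytest.raises(ValueError):
            co_feature_distances([co("chrI", 0, 10)], pd.DataFrame(), CFG)

    def test_feature_at_every_midpoint_gives_all_zero(self):
        cos = [co("chrI", 1000 * i, 1000 * i + 10) for i in range(1, 30)]
        centers = pd.DataFrame(
            [(c.chrom, int(c.midpoint), int(c.midpoint)+1) for c in cos],
            columns=["chrom", "start", "end"],
        )
        # centers at midpoint +- rounding
        d = co_feature_distances(cos, centers, CFG)
        assert np.all(d <= 1.0)


def brute_force_p(a, b):
    """Two-sided exact p by enumerating label assignments, ranks-based U."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = stats.rankdata(pooled)
    center = n * m / 2.0
    def u_of(idx):
        idx = list(idx)
        r = ranks[idx].sum()
        return r - n * (n + 1) / 2.0
    u_obs = u_of(range(n))
    hits = total = 0
    for pick in combinations(range(n + m), n):
        total += 1
        if abs(u_of(pick) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # n^2/2
        assert p >= 0.99

    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    def test_two_singletons(self):
        _, p = mann_whitney_u([1], [2])
        assert p == 1.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (3, 3), (4, 4), (2, 7), (5, 5), (4, 6)])
    def test_exact_p_matches_brute_force_with_ties(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            a = rng.integers(0, 4, n).astype(float)  # small alphabet forces ties
            b = rng.integers(0, 4, m).astype(float)
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(brute_force_p(a, b))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = rng.permutation(100)
            a = perm[:4].astype(float)
            b = perm[4:9].astype(float)
            _, p = mann_whitney_u(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(float(ref.pvalue))

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        _, p = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))


class TestDensityStats:
    def _table(self, counts, lengths, n_spores):
        cc = pd.DataFrame({"chrom": list(lengths), "count": counts})
        return co_density_stats(cc, lengths, n_spores)

    def test_cm_is_mean_switches_per_spore_times_100(self):
        t = self._table([10], {"chrI": 100_000}, n_spores=4)
        assert t.iloc[0]["cM"] == pytest.approx(250.0)
        assert t.iloc[0]["cM_per_kb"] == pytest.approx(2.5)

    def test_perfect_linearity_gives_r_one(self):
        df = pd.DataFrame(
            {"length_bp": [1.0, 2.0, 3.0], "cM_per_kb": [2.0, 4.0, 6.0]}
        )
        r, p = density_length_correlation(df)
        assert r == pytest.approx(1.0)

    def test_inverse_density_correlates_negatively(self):
        lengths = {f"chr{i}": 50_000 * i for i in range(1, 9)}
        counts = [5] * 8  # equal counts -> density ~ 1/length
        t = self._table(counts, lengths, n_spores=4)
        r, _ = density_length_correlation(t)
        assert r < 0

    def test_degenerate_variance_reported_as_nan(self):
        df = pd.DataFrame({"length_bp": [1.0, 2.0, 3.0], "cM_per_kb": [2.0, 2.0, 2.0]})
        r, p = density_length_correlation(df)
        assert np.isnan(r) and np.isnan(p)

    def test_zero_spores_is_error(self):
        with pytest.raises(ValueError):
            self._table([1], {"chrI": 1000}, n_spores=0)


class TestRegionFractions:
    def test_expected_pct_from_printed_lengths(self):
        # 160 kb of centromere-proximal sequence in a 12.07-Mb genome
        assert round(expected_region_pct(160_000, CFG.genome_length), 1) == 1.3
        assert round(expected_region_pct(1_365_000, CFG.genome_length), 1) == 11.3

    def test_observed_fraction_counting(self):
        regions = pd.DataFrame([("chrI", 0, 10_000)], columns=["chrom", "start", "end"])
        cos = [co("chrI", 4000, 4100)] * 3 + [co("chrI", 50_000, 50_100)] * 147
        obs, _ = region_co_fraction(cos, regions, CFG)
        assert obs == pytest.approx(2.0)

    def test_no_events_in_region(self):
        regions = pd.DataFrame([("chrI", 0, 100)], columns=["chrom", "start", "end"])
        obs, _ = region_co_fraction([co("chrI", 5000, 5100)], regions, CFG)
        assert obs == 0.0

    def test_rdna_boundary_shift_counts_once(self):
        regions = pd.DataFrame([("chrXII", 450_000, 500_000)], columns=["chrom", "start", "end"])
        # marker interval spans the whole array: midpoint inside or not,
        # the origin shift across the boundary counts
        ev = co("chrXII", 449_000, 501_000)
        obs, _ = region_co_fraction([ev], regions, CFG, rdna=("chrXII", 450_000, 500_000))
        assert obs == 100.0

    def test_expected_fractions_over_partition_sum_to_100(self):
        lengths = {"chrI": 4_000_000, "chrII": 8_071_326}
        parts = [
            pd.DataFrame([("chrI", 0, lengths["chrI"])], columns=["chrom", "start", "end"]),
            pd.DataFrame([("chrII", 0, lengths["chrII"])], columns=["chrom", "start", "end"]),
        ]
        total = sum(region_co_fraction([co("chrI", 0, 10)], p, CFG)[1] for p in parts)
        assert total == pytest.approx(100.0)

    def test_uniform_cos_match_expected_within_binomial_error(self):
        rng = np.random.default_rng(42)
        lengths = {f"chr{i}": 250_000 for i in range(8)}
        cens = {c: (99_940, 100_060) for c in lengths}
        windows = centromere_windows(cens, lengths, halfwidth=5000)
        cfg = StatsConfig(genome_length=sum(lengths.values()))
        n = 1000
        cos = []
        for _ in range(n):
            chrom = f"chr{rng.integers(8)}"
            pos = int(rng.integers(0, 250_000))
            cos.append(co(chrom, pos, pos + 1))
        obs, exp = region_co_fraction(cos, windows, cfg)
        sigma = 100 * np.sqrt(exp / 100 * (1 - exp / 100) / n)
        assert abs(obs - exp) <= 3 * sigma


class TestNahrFraction:
    @pytest.mark.parametrize(
        "n_nahr,n_other,expected",
        [(2, 285 + 121, 0.49), (1, 1383 + 1969, 0.03), (0, 57, 0.0)],
    )
    def test_fraction_from_counts(self, n_nahr, n_other, expected):
        assert nahr_fraction_from_counts(n_nahr, n_other) == pytest.approx(expected)

    def test_fraction_from_typed_events(self):
        events = (
            [RecombEvent("NAHR", "chrI", 0, 1, chrom2="chrII", pos2=5)]
            + [RecombEvent("CO", "chrI", 0, 10)] * 285
            + [RecombEvent("NCO", "chrI", 0, 10)] * 121
            + [RecombEvent("NAHR", "chrIII", 0, 1, chrom2="chrIV", pos2=5)]
        )
        assert nahr_fraction(events) == pytest.approx(0.49)

    def test_diploid_denominator_uses_hr_events(self):
        events = (
            [RecombEvent("NAHR", "chrI", 0, 1)]
            + [RecombEvent("SGC", "chrI", 0, 10)] * 10
            + [RecombEvent("BIR", "chrII", 0, 10)] * 4
        )
        assert nahr_fraction(events, diploid=True) == pytest.approx(6.67)

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            nahr_fraction_from_counts(0, 0)

    def test_fold_change(self):
        assert fold_change(1.4, 0.1) == pytest.approx(14.0)
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
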