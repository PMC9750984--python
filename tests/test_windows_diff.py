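import numpy as np
import pandas as pd
import pytest

from chiprx.core_io import TSSAnnotation, TSSRecord
from chiprx.windows_diff import (
    WindowGrid,
    adjust_pvalues,
    count_windows,
    coverage_track,
    extend_fragments,
    filter_differential,
    merge_windows,
    nb_test,
    tss_profile,
)


def frame(rows, columns=("chrom", "start", "end", "strand", "sample")):
    return pd.DataFrame(rows, columns=columns)


class TestExtendFragments:
    def test_plus_strand_read_extended_from_five_prime(self):
        pts = extend_fragments(frame([("c", 10, 60, "+", "s")]), 300)
        assert pts["pos"].tolist() == [160]

    def test_minus_strand_read_extended_from_five_prime(self):
        pts = extend_fragments(frame([("c", 450, 500, "-", "s")]), 300)
        assert pts["pos"].tolist() == [350]

    def test_unstranded_fragment_uses_own_midpoint(self):
        pts = extend_fragments(frame([("c", 100, 200, ".", "s")]), 300)
        assert pts["pos"].tolist() == [150]


class TestCountWindows:
    def test_no_points_all_zero(self):
        grid = WindowGrid(300, 100, {"c": 3000})
        windows, counts = count_windows(
            pd.DataFrame(columns=["chrom", "pos", "sample"]), grid, samples=["s"]
        )
        assert counts.sum() == 0
        assert len(windows) == 30

    def test_sliding_windows_cover_point(self):
        # point 160 with w=300, s=100 falls in windows [0,300) and [100,400)
        grid = WindowGrid(300, 100, {"c": 1000})
        pts = pd.DataFrame({"chrom": ["c"], "pos": [160], "sample": ["s"]})
        windows, counts = count_windows(pts, grid, samples=["s"])
        hit = windows[counts[:, 0] > 0]
        assert hit["start"].tolist() == [0, 100]

    def test_non_overlapping_windows_conserve_points(self, rng):
        grid = WindowGrid(300, 300, {"c": 30_000})
        pts = pd.DataFrame(
            {
                "chrom": "c",
                "pos": rng.integers(0, 30_000, size=1000),
                "sample": "s",
            }
        )
        _, counts = count_windows(pts, grid, samples=["s"])
        assert counts[:, 0].sum() == 1000

    def test_point_beyond_length_lands_in_last_window(self):
        grid = WindowGrid(300, 300, {"c": 900})
        pts = pd.DataFrame({"chrom": ["c"], "pos": [1500], "sample": ["s"]})
        _, counts = count_windows(pts, grid, samples=["s"])
        assert counts[-1, 0] == 1


class TestNbTest:
    def test_identical_groups_are_null(self):
        counts = np.tile([[5, 5, 5, 5, 5, 5]], (10, 1))
        res = nb_test(counts, ["a"] * 3 + ["b"] * 3)
        assert (res["log2fc"] == 0).all()
        assert np.allclose(res["pvalue"], 1.0)

    def test_all_zero_window_is_null(self):
        counts = np.zeros((3, 6), dtype=int)
        res = nb_test(counts, ["a"] * 3 + ["b"] * 3)
        assert (res["pvalue"] == 1.0).all() and (res["log2fc"] == 0.0).all()

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(101)
        r, mu = 10.0, 50.0  # dispersion 0.1, mean 50
        counts = rng.negative_binomial(r, r / (r + mu), size=(5000, 6))
        res = nb_test(counts, ["a"] * 3 + ["b"] * 3)
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(202)
        r = 10.0
        counts = rng.negative_binomial(r, r / (r + 50.0), size=(5000, 6))
        counts[:500, 3:] = rng.negative_binomial(r, r / (r + 200.0), size=(500, 3))
        res = nb_test(counts, ["a"] * 3 + ["b"] * 3)
        padj = adjust_pvalues(res["pvalue"].to_numpy())
        called = (padj < 0.05) & (res["log2fc"].to_numpy() > 0)
        recall = called[:500].mean()
        fdr = called[500:].sum() / max(called.sum(), 1)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            nb_test(np.zeros((2, 3), dtype=int), ["a", "a", "a"])


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.013])[0] == pytest.approx(0.013)

    def test_padj_dominates_p(self, rng):
        p = rng.random(200)
        assert (adjust_pvalues(p) >= p - 1e-15).all()


def window_result(chrom, start, end, log2fc, pvalue, padj, total=100):
    return (
        pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]}),
        pd.DataFrame(
            {
                "log2fc": [log2fc],
                "pvalue": [pvalue],
                "padj": [padj],
                "total_count": [total],
            }
        ),
    )


class TestMergeWindows:
    def build(self, rows):
        windows = pd.DataFrame(
            [r[:3] for r in rows], columns=["chrom", "start", "end"]
        )
        results = pd.DataFrame(
            [r[3:] for r in rows],
            columns=["log2fc", "pvalue", "padj", "total_count"],
        )
        return windows, results

    def test_overlapping_same_direction_windows_fuse(self):
        windows, results = self.build(
            [
                ("c", 0, 300, 1.0, 0.001, 0.01, 100),
                ("c", 100, 400, 1.2, 0.002, 0.02, 300),
            ]
        )
        regions = merge_windows(windows, results, 0.05)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (0, 400)
        assert r.pvalue == 0.001 and r.padj == 0.01
        assert r.log2fc == pytest.approx((1.0 * 100 + 1.2 * 300) / 400)

    def test_opposite_directions_stay_separate(self):
        windows, results = self.build(
            [
                ("c", 0, 300, 1.0, 0.001, 0.01, 100),
                ("c", 300, 600, -1.0, 0.001, 0.01, 100),
            ]
        )
        regions = merge_windows(windows, results, 0.05)
        assert [r.direction for r in regions] == ["up", "down"]

    def test_disjoint_windows_stay_disjoint(self):
        windows, results = self.build(
            [
                ("c", 0, 300, 1.0, 0.001, 0.01, 100),
                ("c", 1000, 1300, 1.0, 0.001, 0.01, 100),
                ("c", 5000, 5300, 1.0, 0.001, 0.01, 100),
            ]
        )
        assert len(merge_windows(windows, results, 0.05)) == 3

    def test_regions_disjoint_per_direction(self, rng):
        n = 200
        starts = np.sort(rng.integers(0, 20_000, size=n))
        windows = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 300})
        results = pd.DataFrame(
            {
                "log2fc": rng.normal(size=n),
                "pvalue": rng.random(n) ** 3,
                "total_count": rng.integers(1, 500, size=n),
            }
        )
        regions = merge_windows(windows, results, 0.05, call_on="pvalue")
        for direction in ("up", "down"):
            spans = sorted(
                (r.start, r.end) for r in regions if r.direction == direction
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2  # strictly disjoint, not even abutting


class TestFilterDifferential:
    def region(self, padj, lfc):
        from chiprx.windows_diff import DifferentialRegion

        return DifferentialRegion("c", 0, 100, lfc, padj / 2, padj,
                                  "up" if lfc > 0 else "down")

    def test_strict_thresholds(self):
        kept = filter_differential(
            [self.region(0.01, 1.2), self.region(0.05, 1.2), self.region(0.01, -1.0)]
        )
        assert len(kept) == 1 and kept[0].log2fc == 1.2


class TestCoverageTrack:
    def frags(self, spans):
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": [s for s, _ in spans],
                "end": [e for _, e in spans],
                "genome": "target",
                "sample": "s",
                "role": "IP",
            }
        )

    def test_single_fragment_unit_coverage(self):
        track = coverage_track(self.frags([(10, 20)]), {"c": 30})
        assert track["c"][10:20].tolist() == [1] * 10
        assert track["c"].sum() == 10

    def test_overlap_adds(self):
        track = coverage_track(self.frags([(0, 10), (5, 15)]), {"c": 20})
        assert track["c"][5:10].tolist() == [2] * 5
        assert track["c"].sum() == 20

    def test_empty_sample_zero_track(self):
        track = coverage_track(self.frags([]), {"c": 50})
        assert track["c"].sum() == 0

    def test_binned_track_conserves_total(self):
        track1 = coverage_track(self.frags([(3, 97), (50, 160)]), {"c": 200}, bin_size=1)
        track10 = coverage_track(self.frags([(3, 97), (50, 160)]), {"c": 200}, bin_size=10)
        assert track10["c"].sum() == track1["c"].sum() == 94 + 110


class TestTssProfile:
    def test_uniform_track_gives_flat_profile(self):
        track = {"c": np.full(1000, 3.0)}
        tss = TSSAnnotation([TSSRecord("g1", "c", 500, "+")])
        _, profile = tss_profile(track, tss, flank=100, bin_size=10)
        assert profile == pytest.approx(np.full(20, 3.0))

    def test_minus_strand_profile_reversed(self):
        arr = np.zeros(1000)
        arr[520:540] = 5.0  # asymmetric feature downstream of position 500
        track = {"c": arr}
        plus = TSSAnnotation([TSSRecord("g1", "c", 500, "+")])
        minus = TSSAnnotation([TSSRecord("g1", "c", 500, "-")])
        _, p_plus = tss_profile(track, plus, flank=100, bin_size=10)
        _, p_minus = tss_profile(track, minus, flank=100, bin_size=10)
        assert p_minus == pytest.approx(p_plus[::-1])

    def test_truncated_flank_excluded_from_mean(self):
        track = {"c": np.full(1000, 2.0)}
        tss = TSSAnnotation(
            [TSSRecord("edge", "c", 50, "+"), TSSRecord("ok", "c", 500, "+")]
        )
        matrix, profile = tss_profile(track, tss, flank=100, bin_size=10)
        assert matrix.loc["edge"].isna().all()
        assert profile == pytest.approx(np.full(20, 2.0))
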