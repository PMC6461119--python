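"""Post-capture evaluation: breadth, uniformity, saturation, SNP filters and
comparable positions, each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from islandcap.core import GenomeInterval
from islandcap.evaluate import (
    DepthTrack,
    ReadPlacement,
    SnpCall,
    SnpFilterParams,
    breadth,
    coefficient_of_variation,
    comparable_positions,
    filter_snps,
    flag_high_coverage,
    naive_pileup_caller,
    on_target_fraction,
    per_target_stats,
    saturation_curve,
)


def _call(pos, qual=60.0, depth=10, af=0.9, contig="c"):
    return SnpCall(contig, pos, "A", "G", qual, depth, af)


class TestBreadth:
    def test_all_zero_track(self):
        track = DepthTrack({"c": np.zeros(100)})
        b = breadth(track, [GenomeInterval("c", 0, 100)])
        assert all(v["bp"] == 0 for v in b.values())

    def test_direct_count(self):
        track = DepthTrack({"c": np.array([0, 1, 5, 10, 10])})
        b = breadth(track, [GenomeInterval("c", 0, 5)])
        assert b[1]["pct"] == 80.0
        assert b[5]["pct"] == 60.0
        assert b[10]["pct"] == 40.0

    def test_overlapping_targets_counted_once(self):
        rng = np.random.default_rng(3)
        depths = rng.integers(0, 15, 500)
        track = DepthTrack({"c": depths})
        targets = [GenomeInterval("c", 50, 250), GenomeInterval("c", 200, 400)]
        b = breadth(track, targets)
        union = np.zeros(500, dtype=bool)
        union[50:250] = union[200:400] = True
        for t in (1, 5, 10):
            assert b[t]["bp"] == int((depths[union] >= t).sum())

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        track = DepthTrack({"c": rng.integers(0, 30, 1000)})
        b = breadth(track, [GenomeInterval("c", 0, 1000)])
        assert b[1]["bp"] >= b[5]["bp"] >= b[10]["bp"]


class TestPerTargetStats:
    def test_constant_track(self):
        track = DepthTrack({"c": np.full(100, 7)})
        df = per_target_stats(track, [("t1", GenomeInterval("c", 10, 60))])
        row = df.iloc[0]
        assert row.mean_depth == 7.0 and row.pct_1x == 100.0 and row.covered_flag

    def test_half_covered(self):
        d = np.zeros(100)
        d[:50] = 3
        df = per_target_stats(
            DepthTrack({"c": d}), [("t1", GenomeInterval("c", 0, 100))]
        )
        assert df.iloc[0].pct_1x == 50.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        depths = rng.integers(0, 12, 1000)
        track = DepthTrack({"c": depths})
        targets = [
            (f"t{i}", GenomeInterval("c", s, s + 80))
            for i, s in enumerate(range(0, 900, 90))
        ]
        df = per_target_stats(track, targets).set_index("target_id")
        for tid, iv in targets:
            d = depths[iv.start : iv.end]
            assert df.loc[tid].mean_depth == pytest.approx(d.mean())
            assert df.loc[tid].pct_5x == pytest.approx(100 * (d >= 5).sum() / 80)


class TestCoefficientOfVariation:
    def test_constant_depth_zero(self):
        track = DepthTrack({"c": np.full(50, 9)})
        assert coefficient_of_variation(track, [GenomeInterval("c", 0, 50)]) == 0.0

    def test_closed_form(self):
        track = DepthTrack({"c": np.array([10, 10, 10, 30])})
        cv = coefficient_of_variation(track, [GenomeInterval("c", 0, 4)])
        assert cv == pytest.approx(np.sqrt(75) / 15)
        assert cv < 1  # low-variance classification

    def test_zero_mean_rejected(self):
        track = DepthTrack({"c": np.zeros(10)})
        with pytest.raises(ValueError):
            coefficient_of_variation(track, [GenomeInterval("c", 0, 10)])


class TestOnTarget:
    def test_all_inside(self):
        reads = [ReadPlacement(GenomeInterval("c", i, i + 50)) for i in range(0, 200, 60)]
        assert on_target_fraction(reads, [GenomeInterval("c", 0, 400)]) == 100.0

    def test_none_overlapping(self):
        reads = [ReadPlacement(GenomeInterval("c", 500, 600))]
        assert on_target_fraction(reads, [GenomeInterval("c", 0, 400)]) == 0.0

    def test_matches_interval_overlap_oracle(self):
        rng = np.random.default_rng(6)
        design = [
            GenomeInterval("c", int(s), int(s) + 100)
            for s in rng.integers(0, 5000, 12)
        ]
        reads = []
        for s in rng.integers(0, 5900, 300):
            reads.append(
                ReadPlacement(
                    GenomeInterval("c", int(s), int(s) + 100),
                    is_duplicate=bool(rng.random() < 0.1),
                )
            )
        got = on_target_fraction(reads, design)
        live = [r for r in reads if not r.is_duplicate]
        on = sum(
            1
            for r in live
            if any(
                r.interval.start < d.end and d.start < r.interval.end for d in design
            )
        )
        assert got == pytest.approx(100 * on / len(live))

    def test_duplicates_excluded(self):
        reads = [
            ReadPlacement(GenomeInterval("c", 0, 50), is_duplicate=True),
            ReadPlacement(GenomeInterval("c", 500, 550)),
        ]
        assert on_target_fraction(reads, [GenomeInterval("c", 0, 400)]) == 0.0


class TestFlagHighCoverage:
    def test_uniform_regions_none_flagged(self):
        track = DepthTrack({"c": np.full(1000, 8)})
        regions = [(f"r{i}", GenomeInterval("c", i * 100, i * 100 + 80)) for i in range(10)]
        assert flag_high_coverage(track, regions) == []

    def test_single_outlier_flagged(self):
        d = np.full(1100, 8)
        d[1000:1080] = 150  # median of maxima 8 -> threshold 80
        track = DepthTrack({"c": d})
        regions = [(f"r{i}", GenomeInterval("c", i * 100, i * 100 + 80)) for i in range(11)]
        assert flag_high_coverage(track, regions) == ["r10"]

    def test_all_equal_maxima_never_flagged(self):
        track = DepthTrack({"c": np.full(500, 10_000)})
        regions = [(f"r{i}", GenomeInterval("c", i * 100, i * 100 + 80)) for i in range(5)]
        assert flag_high_coverage(track, regions) == []


class TestSaturation:
    def _reads(self, seed, n=4000, contig_len=5000):
        rng = np.random.default_rng(seed)
        return [
            ReadPlacement(GenomeInterval("c", int(s), int(s) + 100))
            for s in rng.integers(0, contig_len - 100, n)
        ]

    def test_fraction_one_reproduces_full_breadth(self):
        reads = self._reads(7)
        targets = [GenomeInterval("c", 0, 5000)]
        lengths = {"c": 5000}
        table, _ = saturation_curve(reads, targets, lengths, seed=1)
        full = breadth(
            DepthTrack.from_reads(reads, lengths), targets, thresholds=(5,)
        )[5]["pct"]
        assert table.pct_ge_threshold.iloc[-1] == pytest.approx(full)

    def test_monotone_at_fixed_seed(self):
        reads = self._reads(8)
        table, _ = saturation_curve(
            reads, [GenomeInterval("c", 0, 5000)], {"c": 5000}, seed=2
        )
        vals = table.pct_ge_threshold.to_numpy()
        assert (np.diff(vals) >= 0).all()  # nested subsamples

    def test_plateau_detected_stably_across_seeds(self):
        # ~80x mean depth: breadth saturates well before the full read set
        reads = self._reads(9)
        sats = []
        for seed in (1, 2, 3):
            _, sat = saturation_curve(
                reads, [GenomeInterval("c", 0, 5000)], {"c": 5000}, seed=seed
            )
            sats.append(sat)
        assert all(s < 1.0 for s in sats)
        assert max(sats) - min(sats) <= 0.125  # one grid step

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve(
                self._reads(10), [GenomeInterval("c", 0, 5000)], {"c": 5000},
                fractions=(0.0, 1.0),
            )


class TestFilterSnps:
    def test_passing_call_kept(self):
        calls = [_call(100, qual=60, depth=10, af=0.85)]
        assert filter_snps(calls) == calls

    def test_af_boundary_strict(self):
        assert filter_snps([_call(100, af=0.80)]) == []

    def test_quality_and_depth_minimums(self):
        assert filter_snps([_call(100, qual=49.9)]) == []
        assert filter_snps([_call(100, depth=4)]) == []

    def test_window_cluster_removed(self):
        calls = [_call(p) for p in (100, 105, 109, 500)]
        kept = filter_snps(calls)
        assert [c.pos0 for c in kept] == [500]

    def test_window_rule_matches_sliding_oracle(self):
        rng = np.random.default_rng(11)
        pos = np.unique(rng.integers(0, 2000, 120))
        calls = [_call(int(p)) for p in pos]
        kept = {c.pos0 for c in filter_snps(calls)}
        params = SnpFilterParams()
        expected = set()
        for p in pos:
            windows = [
                [q for q in pos if w <= q < w + params.window]
                for w in range(p - params.window + 1, p + 1)
            ]
            if max(len(w) for w in windows) <= params.window_max_snps:
                expected.add(int(p))
        assert kept == expected

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(12)
        calls = [
            _call(int(p), qual=float(rng.uniform(40, 90)),
                  depth=int(rng.integers(2, 20)), af=float(rng.uniform(0.5, 1.0)))
            for p in np.unique(rng.integers(0, 3000, 200))
        ]
        kept = filter_snps(calls)
        assert set(kept) <= set(calls)
        assert filter_snps(kept) == kept


class TestComparablePositions:
    def test_constructed_example(self):
        # p1: s1 SNP, s2 depth 6 ref; p2: s1 depth 6 ref, s2 SNP; p3: s1 depth 3
        d1 = np.zeros(20, dtype=int)
        d2 = np.zeros(20, dtype=int)
        d1[5] = 10  # s1 SNP site
        d2[5] = 6
        d1[10] = 6
        d2[10] = 10  # s2 SNP site
        d1[15] = 3
        d2[15] = 6
        samples = {
            "s1": ([_call(5, depth=10)], DepthTrack({"c": d1})),
            "s2": ([_call(10, depth=10)], DepthTrack({"c": d2})),
        }
        matrix, n = comparable_positions(samples)
        assert n == 2
        assert matrix[("c", 5)] == {"s1": "alt", "s2": "ref"}
        assert matrix[("c", 10)] == {"s1": "ref", "s2": "alt"}
        assert ("c", 15) not in matrix

    def test_zero_depth_everywhere(self):
        samples = {
            "s1": ([], DepthTrack({"c": np.zeros(10, dtype=int)})),
            "s2": ([], DepthTrack({"c": np.zeros(10, dtype=int)})),
        }
        _, n = comparable_positions(samples)
        assert n == 0

    def test_shared_snp_comparable_all_alt(self):
        d = np.zeros(10, dtype=int)
        samples = {
            "s1": ([_call(3)], DepthTrack({"c": d})),
            "s2": ([_call(3)], DepthTrack({"c": d.copy()})),
        }
        matrix, n = comparable_positions(samples)
        assert n == 1
        assert matrix[("c", 3)] == {"s1": "alt", "s2": "alt"}

    def test_count_non_increasing_in_depth_min(self):
        rng = np.random.default_rng(13)
        samples = {
            f"s{i}": ([], DepthTrack({"c": rng.integers(0, 12, 300)}))
            for i in range(3)
        }
        counts = [comparable_positions(samples, depth_min=d)[1] for d in (1, 5, 8)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(14)
        n = 200
        tracks = {s: rng.integers(0, 10, n) for s in ("s1", "s2")}
        snps = {
            s: sorted(int(p) for p in rng.choice(n, 15, replace=False))
            for s in ("s1", "s2")
        }
        samples = {
            s: ([_call(p) for p in snps[s]], DepthTrack({"c": tracks[s]}))
            for s in ("s1", "s2")
        }
        _, got = comparable_positions(samples, depth_min=5)
        expected = 0
        for p in range(n):
            ok = all(
                (p in snps[s]) or tracks[s][p] >= 5 for s in ("s1", "s2")
            )
            expected += ok
        assert got == expected


class TestNaivePileupCaller:
    def test_ratio(self):
        df = pd.DataFrame(
            {"contig": ["c"], "pos0": [5], "depth": [10], "alt_count": [9]}
        )
        (call,) = naive_pileup_caller(df)
        assert call.alt_fraction == 0.9 and call.qual == 99.0

    def test_no_alt_no_call(self):
        df = pd.DataFrame(
            {"contig": ["c"], "pos0": [5], "depth": [10], "alt_count": [0]}
        )
        assert naive_pileup_caller(df) == []

    def test_alt_exceeding_depth_rejected(self):
        df = pd.DataFrame(
            {"contig": ["c"], "pos0": [5], "depth": [4], "alt_count": [5]}
        )
        with pytest.raises(ValueError):
            naive_pileup_caller(df)

    def test_round_trip_through_filter(self):
        # constructed pileup with known post-filter survivors
        df = pd.DataFrame(
            {
                "contig": ["c"] * 5,
                "pos0": [10, 50, 53, 56, 200],
                "depth": [10, 10, 10, 10, 3],
                "alt_count": [9, 9, 9, 10, 3],
            }
        )
        kept = filter_snps(naive_pileup_caller(df))
        # 50/53/56 form a 10-bp cluster; 200 fails depth; only 10 survives
        assert [c.pos0 for c in kept] == [10]
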