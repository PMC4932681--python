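"""Region merging, RPKM/coverage, log2 track, CBS and gene-level calls."""

import numpy as np
import pandas as pd
import pytest

from dsresist import cnv


def regions_df(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


class TestMergeRegions:
    def test_gap_strictly_less_than_threshold_merges(self):
        # gap of exactly 76 bp stays separate; 75 bp merges
        merged = cnv.merge_regions(regions_df([("c1", 0, 100), ("c1", 175, 200)]))
        assert len(merged) == 1 and merged.end.iloc[0] == 200
        kept = cnv.merge_regions(regions_df([("c1", 0, 100), ("c1", 176, 200)]))
        assert len(kept) == 2

    def test_single_region_unchanged(self):
        out = cnv.merge_regions(regions_df([("c1", 10, 50)]))
        assert out[["chrom", "start", "end"]].values.tolist() == [["c1", 10, 50]]

    def test_matches_brute_force_union_oracle(self, rng):
        starts = np.sort(rng.integers(0, 50_000, 100))
        raw = regions_df([("c1", int(s), int(s + rng.integers(10, 300))) for s in starts])

        def oracle(df, gap):
            # fixpoint pairwise merging, no sweep: merge any two intervals
            # whose gap (start2 - end1) is < gap until nothing changes
            ivs = sorted(zip(df.start, df.end))
            changed = True
            while changed:
                changed = False
                for i in range(len(ivs)):
                    for j in range(len(ivs)):
                        if i == j:
                            continue
                        (s1, e1), (s2, e2) = ivs[i], ivs[j]
                        if s2 - e1 < gap and s1 - e2 < gap:  # within gap either way
                            ivs[i] = (min(s1, s2), max(e1, e2))
                            del ivs[j]
                            changed = True
                            break
                    if changed:
                        break
            return sorted(ivs)

        got = cnv.merge_regions(raw, gap_bp=76)
        expect = oracle(raw, 76)
        assert list(zip(got.start, got.end)) == expect

    def test_idempotent_and_min_gap_invariant(self, rng):
        starts = np.sort(rng.integers(0, 20_000, 60))
        raw = regions_df([("c1", int(s), int(s + rng.integers(10, 200))) for s in starts])
        once = cnv.merge_regions(raw)
        twice = cnv.merge_regions(once)
        pd.testing.assert_frame_equal(once, twice)
        gaps = once.start.to_numpy()[1:] - once.end.to_numpy()[:-1]
        assert (gaps >= 76).all()

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            cnv.merge_regions(regions_df([("c1", 100, 100)]))


class TestRegionMetrics:
    def test_unit_rpkm_case(self):
        reg = regions_df([("c1", 0, 1000)]).assign(region_id="r1")
        counts = pd.DataFrame({"region_id": ["r1"], "count": [100]})
        out = cnv.region_metrics(counts, reg, total_mapped_reads=1_000_000)
        assert out.rpkm.iloc[0] == pytest.approx(100.0)

    def test_zero_count_zero_everything(self):
        reg = regions_df([("c1", 0, 500)]).assign(region_id="r1")
        counts = pd.DataFrame({"region_id": ["r1"], "count": [0]})
        out = cnv.region_metrics(counts, reg, total_mapped_reads=1000)
        assert out.rpkm.iloc[0] == 0.0 and out.coverage.iloc[0] == 0.0

    def test_coverage_arithmetic(self):
        reg = regions_df([("c1", 0, 250)]).assign(region_id="r1")
        counts = pd.DataFrame({"region_id": ["r1"], "count": [500]})
        out = cnv.region_metrics(counts, reg, total_mapped_reads=1000, read_length_bp=75)
        assert out.coverage.iloc[0] == pytest.approx(150.0)


def metrics_frame(rpkm, coverage, chrom="c1"):
    n = len(rpkm)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "region_id": [f"r{i}" for i in range(n)],
            "rpkm": rpkm,
            "coverage": coverage,
        }
    )


class TestLog2Track:
    def test_equal_rpkm_gives_zero(self):
        s = metrics_frame([10.0], [100.0])
        out = cnv.build_log2_track(s, s.copy())
        assert out.log2_ratio.iloc[0] == pytest.approx(0.0)

    def test_doubling_gives_one(self):
        s = metrics_frame([20.0], [100.0])
        r = metrics_frame([10.0], [100.0])
        out = cnv.build_log2_track(s, r)
        assert out.log2_ratio.iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_low_coverage_region_excluded_either_side(self):
        s = metrics_frame([10.0, 10.0], [24.9, 100.0])
        r = metrics_frame([10.0, 10.0], [100.0, 24.9])
        out = cnv.build_log2_track(s, r)
        assert out.empty


class TestCbs:
    def test_constant_track_single_segment(self):
        track = metrics_frame([1.0] * 30, [100.0] * 30)
        track["log2_ratio"] = 0.3
        segs = cnv.cbs_segment(track, seed=0)
        assert len(segs) == 1 and segs[0].n_regions == 30

    def test_two_region_chromosome_never_splits(self):
        track = metrics_frame([1.0, 8.0], [100.0, 100.0])
        track["log2_ratio"] = [0.0, 3.0]
        segs = cnv.cbs_segment(track, seed=0)
        assert len(segs) == 1

    def test_embedded_shift_breakpoints_recovered(self, rng):
        n = 200
        x = rng.normal(0.0, 0.2, n)
        x[70:130] += 1.0
        track = metrics_frame([1.0] * n, [100.0] * n)
        track["log2_ratio"] = x
        segs = cnv.cbs_segment(track, alpha=0.01, n_permutations=500, seed=4)
        bounds = sorted({s.start_index for s in segs} | {s.end_index for s in segs})
        assert any(abs(b - 70) <= 2 for b in bounds)
        assert any(abs(b - 130) <= 2 for b in bounds)

    def test_segment_means_reconstruct_track_mean(self, rng):
        n = 120
        x = rng.normal(0.0, 0.3, n)
        x[40:80] -= 1.2
        track = metrics_frame([1.0] * n, [100.0] * n)
        track["log2_ratio"] = x
        segs = cnv.cbs_segment(track, n_permutations=300, seed=2)
        total = sum(s.mean_log2 * s.n_regions for s in segs)
        assert total == pytest.approx(x.sum(), abs=1e-9)
        assert sum(s.n_regions for s in segs) == n

    def test_null_false_split_rate_consistent_with_alpha(self):
        # exact-level permutation test: rate ~ Binomial(200, alpha); allow
        # 3 sigma of sampling noise around alpha = 0.01
        master = np.random.SeedSequence(20240)
        n_split = 0
        for i, ss in enumerate(master.spawn(200)):
            r = np.random.default_rng(ss)
            track = metrics_frame([1.0] * 100, [100.0] * 100)
            track["log2_ratio"] = r.normal(0.0, 0.2, 100)
            segs = cnv.cbs_segment(track, alpha=0.01, n_permutations=1000, seed=i)
            n_split += len(segs) > 1
        limit = 0.01 + 3 * np.sqrt(0.01 * 0.99 / 200)
        assert n_split / 200 <= limit

    def test_deterministic_given_seed(self, rng):
        n = 80
        x = rng.normal(0.0, 0.25, n)
        x[30:55] += 0.9
        track = metrics_frame([1.0] * n, [100.0] * n)
        track["log2_ratio"] = x
        a = cnv.segments_frame(cnv.cbs_segment(track, seed=11))
        b = cnv.segments_frame(cnv.cbs_segment(track, seed=11))
        pd.testing.assert_frame_equal(a, b)


def seg(chrom, start, end, mean):
    return cnv.Segment(chrom, 0, 0, start, end, mean, 1, None)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def call_oracle(vals, low=-0.6, high=0.5):
    vals = np.asarray(vals, float)
    has_low, has_high = (vals <= low).any(), (vals >= high).any()
    if has_low and has_high:
        vmin, vmax = vals.min(), vals.max()
        return vmin if abs(vmin) >= abs(vmax) else vmax
    if has_low:
        return vals.min()
    if has_high:
        return vals.max()
    return float(np.median(vals))


class TestGeneCopyCall:
    @pytest.mark.parametrize(
        "means,expect_log2,expect_cat",
        [
            ([-0.1, 0.2], 0.05, "neutral"),  # median rule
            ([-0.7, -0.1], -0.7, "heterozygous_deletion"),  # extreme-low rule
            ([-1.5, 0.2], -1.5, "homozygous_deletion"),
        ],
    )
    def test_worked_examples(self, means, expect_log2, expect_cat):
        segments = [seg("c1", i * 1000, (i + 1) * 1000, m) for i, m in enumerate(means)]
        genes = genes_df([("c1", 0, len(means) * 1000, "G")])
        out = cnv.gene_copy_call(genes, segments)
        assert out.assigned_log2.iloc[0] == pytest.approx(expect_log2)
        assert out.category.iloc[0] == expect_cat

    def test_conflicting_extremes_flagged_larger_magnitude_wins(self):
        segments = [seg("c1", 0, 1000, -0.8), seg("c1", 1000, 2000, 1.4)]
        out = cnv.gene_copy_call(genes_df([("c1", 500, 1500, "G")]), segments)
        assert out.extreme_conflict.iloc[0]
        assert out.assigned_log2.iloc[0] == pytest.approx(1.4)
        tie = [seg("c1", 0, 1000, -0.9), seg("c1", 1000, 2000, 0.9)]
        out2 = cnv.gene_copy_call(genes_df([("c1", 500, 1500, "G")]), tie)
        assert out2.assigned_log2.iloc[0] == pytest.approx(-0.9)  # tie -> deletion

    def test_no_overlap_gives_no_call(self):
        out = cnv.gene_copy_call(
            genes_df([("c1", 5000, 6000, "G")]), [seg("c1", 0, 1000, 0.0)]
        )
        assert out.empty

    def test_category_thresholds_inclusive(self):
        for val, cat in [(-1.2, "homozygous_deletion"), (-0.4, "heterozygous_deletion"),
                         (0.5, "gain"), (1.3, "amplification"), (0.0, "neutral")]:
            out = cnv.gene_copy_call(
                genes_df([("c1", 0, 500, "G")]), [seg("c1", 0, 1000, val)]
            )
            assert out.category.iloc[0] == cat

    def test_random_layouts_match_oracle(self, rng):
        for _ in range(200):
            n_seg = int(rng.integers(1, 6))
            bounds = np.sort(rng.choice(np.arange(1, 50), n_seg + 1, replace=False)) * 100
            means = rng.uniform(-2, 2, n_seg)
            segments = [
                seg("c1", int(bounds[i]), int(bounds[i + 1]), float(means[i]))
                for i in range(n_seg)
            ]
            gs, ge = sorted(rng.integers(0, 5200, 2))
            out = cnv.gene_copy_call(genes_df([("c1", int(gs), int(ge + 1), "G")]), segments)
            overlapped = [
                m for i, m in enumerate(means)
                if bounds[i] < ge + 1 and bounds[i + 1] > gs
            ]
            if not overlapped:
                assert out.empty
            else:
                assert out.assigned_log2.iloc[0] == pytest.approx(call_oracle(overlapped))

    def test_invariant_to_segment_order(self, rng):
        segments = [seg("c1", i * 1000, (i + 1) * 1000, v)
                    for i, v in enumerate([-0.7, 0.3, 0.6, -0.2])]
        genes = genes_df([("c1", 0, 4000, "G")])
        a = cnv.gene_copy_call(genes, segments)
        b = cnv.gene_copy_call(genes, list(reversed(segments)))
        assert a.assigned_log2.iloc[0] == b.assigned_log2.iloc[0]
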